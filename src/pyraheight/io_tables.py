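"""Tabular containers and file formats for the pipeline.

All files are tab-separated with a mandatory header row. ``NA`` is the sole
missing token. A genotype call is written ``allele1/allele2``; allele labels
are band sizes in base pairs but are treated as opaque categorical strings
throughout — they are compared for equality only, never ordered numerically.
Readers reject malformed input rather than repairing it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

MISSING = "NA"

Call = tuple[str, str]


def _normalise_call(a: str, b: str) -> Call:
    """Calls are unordered allele pairs; store them in sorted order."""
    return (a, b) if a <= b else (b, a)


@dataclass(eq=False)
class GenotypeMatrix:
    """Inbred lines x multi-allelic markers.

    calls is an object array of shape (n_lines, n_markers) whose entries are
    sorted ``(allele, allele)`` tuples or ``None`` for missing. marker_map,
    when present, is indexed by marker_id with columns ``chromosome`` (label)
    and ``position`` (centimorgans, float).
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    marker_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line_ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker_ids")
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        for v in self.calls.flat:
            if v is None:
                continue
            if (
                not isinstance(v, tuple)
                or len(v) != 2
                or not all(isinstance(a, str) and a and a != MISSING for a in v)
            ):
                raise ValidationError(f"malformed call {v!r}")
        if self.marker_map is not None:
            missing = set(self.marker_ids) - set(self.marker_map.index)
            if missing:
                raise ValidationError(f"markers absent from map: {sorted(missing)[:5]}")
        self._marker_pos = {m: j for j, m in enumerate(self.marker_ids)}
        self._line_pos = {l: i for i, l in enumerate(self.line_ids)}

    # -- accessors ---------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def marker_index(self, marker_id: str) -> int:
        try:
            return self._marker_pos[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def line_index(self, line_id: str) -> int:
        try:
            return self._line_pos[line_id]
        except KeyError:
            raise KeyError(f"unknown line {line_id!r}") from None

    def column(self, marker_id: str) -> np.ndarray:
        return self.calls[:, self.marker_index(marker_id)]

    def call(self, line_id: str, marker_id: str) -> Call | None:
        return self.calls[self.line_index(line_id), self.marker_index(marker_id)]

    def allele_catalog(self, marker_id: str) -> tuple[str, ...]:
        """Observed allele labels at a marker, sorted."""
        alleles: set[str] = set()
        for c in self.column(marker_id):
            if c is not None:
                alleles.update(c)
        return tuple(sorted(alleles))

    def chromosome(self, marker_id: str) -> str:
        if self.marker_map is None:
            return MISSING
        return str(self.marker_map.loc[marker_id, "chromosome"])

    def is_fully_homozygous(self) -> bool:
        return all(c is None or c[0] == c[1] for c in self.calls.flat)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        same_map = (self.marker_map is None) == (other.marker_map is None)
        if same_map and self.marker_map is not None:
            same_map = self.marker_map.reindex(self.marker_ids).equals(
                other.marker_map.reindex(other.marker_ids)
            )
        return (
            self.line_ids == other.line_ids
            and self.marker_ids == other.marker_ids
            and same_map
            and all(a == b for a, b in zip(self.calls.flat, other.calls.flat))
        )


class PhenotypeTable:
    """Long-format multi-environment phenotypes.

    One record per (line, environment, replicate); height in cm, strictly
    positive and finite, key triples unique.
    """

    COLUMNS = ("line_id", "environment_id", "replicate", "height")

    def __init__(self, data: pd.DataFrame):
        if list(data.columns) != list(self.COLUMNS):
            missing = set(self.COLUMNS) - set(data.columns)
            if missing:
                raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
            data = data[list(self.COLUMNS)]
        data = data.copy()
        data["line_id"] = data["line_id"].astype(str)
        data["environment_id"] = data["environment_id"].astype(str)
        data["replicate"] = data["replicate"].astype(int)
        data["height"] = data["height"].astype(float)
        h = data["height"].to_numpy()
        if not np.all(np.isfinite(h)) or np.any(h <= 0):
            raise ValidationError("heights must be finite and > 0")
        if data.duplicated(["line_id", "environment_id", "replicate"]).any():
            dup = data[data.duplicated(["line_id", "environment_id", "replicate"])].iloc[0]
            raise ValidationError(
                f"duplicate record ({dup.line_id}, {dup.environment_id}, {dup.replicate})"
            )
        self.data = data.reset_index(drop=True)

    def environments(self) -> list[str]:
        return sorted(self.data["environment_id"].unique())

    def lines(self) -> list[str]:
        return sorted(self.data["line_id"].unique())

    def subset(self, environments: Iterable[str]) -> "PhenotypeTable":
        envs = set(environments)
        unknown = envs - set(self.data["environment_id"].unique())
        if unknown:
            raise ValidationError(f"unknown environments {sorted(unknown)}")
        return PhenotypeTable(self.data[self.data["environment_id"].isin(envs)])

    def line_means(self, environments: Iterable[str] | None = None) -> pd.Series:
        """Per-line mean height, optionally restricted to some environments."""
        df = self.data
        if environments is not None:
            df = self.subset(environments).data
        return df.groupby("line_id")["height"].mean()

    def env_line_means(self) -> pd.DataFrame:
        """Lines x environments matrix of per-environment line means."""
        return (
            self.data.groupby(["line_id", "environment_id"])["height"]
            .mean()
            .unstack("environment_id")
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        a = self.data.sort_values(list(self.COLUMNS[:3])).reset_index(drop=True)
        b = other.data.sort_values(list(self.COLUMNS[:3])).reset_index(drop=True)
        return a.equals(b)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class Locus:
    marker_id: str
    increasing_allele: str


@dataclass(frozen=True)
class LocusSet:
    """Ordered trait-associated loci, each with its height-increasing allele."""

    loci: tuple[Locus, ...] = ()

    def __post_init__(self) -> None:
        ids = [l.marker_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("locus set has duplicate markers")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LocusSet":
        return cls(tuple(Locus(m, a) for m, a in pairs))

    @property
    def marker_ids(self) -> tuple[str, ...]:
        return tuple(l.marker_id for l in self.loci)

    def head(self, k: int) -> "LocusSet":
        return LocusSet(self.loci[:k])

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        from .errors import ConfigurationError

        for l in self.loci:
            if l.marker_id not in genotypes._marker_pos:
                raise ConfigurationError(f"marker {l.marker_id!r} not in genotype matrix")
            if l.increasing_allele not in genotypes.allele_catalog(l.marker_id):
                raise ConfigurationError(
                    f"allele {l.increasing_allele!r} not observed at {l.marker_id!r}"
                )

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)


# ---------------------------------------------------------------------------
# genotype files
# ---------------------------------------------------------------------------

def _parse_call(token: str, path, line_no: int) -> Call | None:
    if token == MISSING:
        return None
    parts = token.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ParseError(f"malformed genotype call {token!r}", path, line_no)
    return _normalise_call(parts[0], parts[1])


def write_genotypes(matrix: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("line_id\t" + "\t".join(matrix.marker_ids) + "\n")
        for i, line in enumerate(matrix.line_ids):
            row = [
                MISSING if c is None else f"{c[0]}/{c[1]}" for c in matrix.calls[i]
            ]
            fh.write(line + "\t" + "\t".join(row) + "\n")


def read_genotypes(path, map_path=None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        cols = header.split("\t")
        if not cols or cols[0] != "line_id":
            raise ParseError("genotype header must start with 'line_id'", path, 1)
        marker_ids = cols[1:]
        if len(set(marker_ids)) != len(marker_ids):
            raise ParseError("duplicate marker columns", path, 1)
        line_ids: list[str] = []
        rows: list[list[Call | None]] = []
        seen: set[str] = set()
        for line_no, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) != len(marker_ids) + 1:
                raise ParseError(
                    f"expected {len(marker_ids) + 1} fields, got {len(fields)}",
                    path,
                    line_no,
                )
            if fields[0] in seen:
                raise ParseError(f"duplicate line_id {fields[0]!r}", path, line_no)
            if not fields[0]:
                raise ParseError("empty line_id", path, line_no)
            seen.add(fields[0])
            line_ids.append(fields[0])
            rows.append([_parse_call(t, path, line_no) for t in fields[1:]])
    calls = np.empty((len(line_ids), len(marker_ids)), dtype=object)
    for i, r in enumerate(rows):
        calls[i, :] = r
    marker_map = read_map(map_path) if map_path is not None else None
    return GenotypeMatrix(line_ids, marker_ids, calls, marker_map)


def write_map(marker_map: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchromosome\tposition\n")
        for m, row in marker_map.iterrows():
            fh.write(f"{m}\t{row['chromosome']}\t{float(row['position'])!r}\n")


def read_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str},
                     float_precision="round_trip")
    expected = ["marker_id", "chromosome", "position"]
    if list(df.columns) != expected:
        raise ParseError(f"map header must be {expected}", path, 1)
    if df["marker_id"].duplicated().any():
        raise ParseError("duplicate marker_id in map", path)
    df["position"] = df["position"].astype(float)
    return df.set_index("marker_id")


# ---------------------------------------------------------------------------
# phenotype files
# ---------------------------------------------------------------------------

def write_phenotypes(table: PhenotypeTable, path) -> None:
    out = table.data.copy()
    out["height"] = out["height"].map(repr)
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> PhenotypeTable:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"line_id": str, "environment_id": str, "replicate": int, "height": float},
            float_precision="round_trip",
        )
    except ValueError as exc:
        raise ParseError(f"cannot parse phenotype table: {exc}", path) from exc
    if list(df.columns) != list(PhenotypeTable.COLUMNS):
        raise ParseError(
            f"phenotype header must be {list(PhenotypeTable.COLUMNS)}", path, 1
        )
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# model files (flat key-value, full float precision via repr)
# ---------------------------------------------------------------------------

def write_model(model, path) -> None:
    """Persist a HeightModel as a flat key<TAB>value file."""
    loci = ",".join(f"{l.marker_id}:{l.increasing_allele}" for l in model.locus_set)
    with open(path, "w") as fh:
        fh.write(f"slope\t{model.slope!r}\n")
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write(f"f_statistic\t{model.f_statistic!r}\n")
        fh.write(f"p_value\t{model.p_value!r}\n")
        fh.write(f"training_label\t{model.training_label}\n")
        fh.write(f"loci\t{loci}\n")


def read_model(path):
    from .prediction_model import HeightModel

    kv: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            if "\t" not in raw:
                raise ParseError("model lines must be key<TAB>value", path, line_no)
            k, v = raw.split("\t", 1)
            kv[k] = v
    for key in ("slope", "intercept", "f_statistic", "p_value", "loci"):
        if key not in kv:
            raise ParseError(f"model file missing {key!r}", path)
    try:
        pairs = [
            tuple(tok.split(":", 1)) for tok in kv["loci"].split(",") if tok
        ]
        locus_set = LocusSet.from_pairs(pairs)  # type: ignore[arg-type]
        model = HeightModel(
            slope=float(kv["slope"]),
            intercept=float(kv["intercept"]),
            f_statistic=float(kv["f_statistic"]),
            p_value=float(kv["p_value"]),
            locus_set=locus_set,
            training_label=kv.get("training_label", ""),
        )
    except (ValueError, ValidationError) as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"invalid model file: {exc}", path) from exc
    return model


# ---------------------------------------------------------------------------
# association results
# ---------------------------------------------------------------------------

ASSOCIATION_COLUMNS = [
    "environment_id",
    "marker_id",
    "chromosome",
    "f_statistic",
    "p_value",
    "marker_r2",
    "best_allele",
]


def write_association_results(results: Sequence, path) -> None:
    rows = [
        {
            "environment_id": r.environment_id,
            "marker_id": r.marker_id,
            "chromosome": r.chromosome,
            "f_statistic": repr(r.f_statistic),
            "p_value": repr(r.p_value),
            "marker_r2": repr(r.marker_r2),
            "best_allele": r.best_allele,
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_association_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str, "best_allele": str})
    if list(df.columns) != ASSOCIATION_COLUMNS:
        raise ParseError(f"association header must be {ASSOCIATION_COLUMNS}", path, 1)
    return df
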