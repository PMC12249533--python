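"""Simulated populations with the structure the analysis assumes.

Three generators cover the study design end to end:

* a structured diversity panel of fully inbred lines scored at multi-allelic
  markers (band-size allele labels), with subpopulation-differentiated allele
  frequencies and a set of ground-truth height QTLs;
* a biparental recombinant-inbred-line (RIL) population built as a homozygous
  mosaic of the two parental haplotypes, with crossovers from the Haldane map
  function and the RIL-adjusted recombination fraction 2r/(1+2r);
* multi-environment replicated phenotypes from an additive model
  height = grand_mean + QTL effects + g_i + e_j + (ge)_ij + eps_ijk,
  with independent zero-mean normal components at configured variances.

Default variance components realize a genotype-dominated partition
(roughly 76% genotype, 4% environment, 20% G x E of the model sum of
squares in a 219-line x 5-environment x 3-replicate trial), the regime
typical of multi-year rice height trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io_tables import GenotypeMatrix, PhenotypeTable


@dataclass(frozen=True)
class PanelConfig:
    """Diversity-panel generator settings.

    qtl_effect_sizes is cm per copy of the increasing allele (a scalar is
    broadcast to every QTL); subpop_divergence is the Balding-Nichols style
    Fst controlling how far subpopulation allele frequencies drift from the
    panel-wide frequencies.
    """

    n_lines: int = 273
    n_markers: int = 218
    n_chromosomes: int = 12
    alleles_per_marker: int = 3
    n_subpopulations: int = 3
    n_qtl: int = 10
    qtl_effect_sizes: float | Sequence[float] = 2.5
    subpop_divergence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_markers", "n_chromosomes", "n_subpopulations"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.alleles_per_marker < 2:
            raise ConfigurationError("alleles_per_marker must be >= 2")
        if not 0 <= self.n_qtl <= self.n_markers:
            raise ConfigurationError("need 0 <= n_qtl <= n_markers")
        if not 0.0 < self.subpop_divergence < 1.0:
            raise ConfigurationError("subpop_divergence must be in (0, 1)")
        effects = self.effects()
        if not np.all(np.isfinite(effects)):
            raise ConfigurationError("qtl_effect_sizes must be finite")

    def effects(self) -> np.ndarray:
        e = np.asarray(self.qtl_effect_sizes, dtype=float)
        if e.ndim == 0:
            return np.full(self.n_qtl, float(e))
        if e.shape != (self.n_qtl,):
            raise ConfigurationError("qtl_effect_sizes length must equal n_qtl")
        return e


@dataclass(frozen=True)
class EnvConfig:
    """Multi-environment trial settings; variances in cm^2.

    Defaults realize the genotype-dominated partition described in the
    module docstring (sigma2: genotype 152, environment 9.3, G x E 49.5,
    residual 10.7; grand mean 115 cm).
    """

    n_environments: int = 5
    n_replicates_per_line: int = 3
    var_genotype: float = 152.0
    var_environment: float = 9.3
    var_gxe: float = 49.5
    var_residual: float = 10.7
    grand_mean: float = 115.0

    def __post_init__(self) -> None:
        if self.n_environments < 1 or self.n_replicates_per_line < 1:
            raise ConfigurationError("environment and replicate counts must be >= 1")
        for name in ("var_genotype", "var_environment", "var_gxe", "var_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class RilConfig:
    """Biparental RIL generator settings.

    marker_positions is a map-style frame (index marker_id, columns
    chromosome and position in cM), nondecreasing within a chromosome.
    residual_het_rate is the per-call probability of a leftover heterozygous
    call; the default 0 treats advanced-generation RILs as fully inbred.
    """

    n_lines: int
    marker_positions: pd.DataFrame
    residual_het_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ConfigurationError("n_lines must be positive")
        if not 0.0 <= self.residual_het_rate <= 1.0:
            raise ConfigurationError("residual_het_rate must be in [0, 1]")
        for _, grp in self.marker_positions.groupby("chromosome", sort=False):
            pos = grp["position"].to_numpy(dtype=float)
            if np.any(np.diff(pos) < 0):
                raise ConfigurationError("map positions must be nondecreasing per chromosome")


@dataclass(frozen=True)
class QtlTruth:
    """Ground truth from simulate_panel: which markers are QTLs, which allele
    increases height, by how much (cm per allele copy), plus the line
    subpopulation labels used for the frequency draws."""

    marker_ids: tuple[str, ...]
    increasing_alleles: tuple[str, ...]
    effects: tuple[float, ...]
    subpopulations: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __len__(self) -> int:
        return len(self.marker_ids)


EMPTY_TRUTH = QtlTruth((), (), ())


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def _band_size_labels(rng: np.random.Generator, n_alleles: int) -> list[str]:
    """Distinct band-size labels (bp) for one marker, e.g. 95/100/110."""
    base = int(rng.integers(80, 300))
    steps = rng.integers(3, 12, size=n_alleles - 1)
    sizes = base + np.concatenate([[0], np.cumsum(steps)])
    return [str(int(s)) for s in sizes]


def simulate_panel(config: PanelConfig) -> tuple[GenotypeMatrix, QtlTruth]:
    """Simulate a structured, fully homozygous diversity panel.

    Subpopulation allele frequencies are drawn from a Dirichlet centred on
    panel-wide frequencies with concentration (1-F)/F, the Balding-Nichols
    construction, so subpop_divergence acts like Fst. Each line draws one
    allele per marker from its subpopulation's frequencies and is recorded
    as the homozygous call.
    """
    rng = np.random.default_rng(config.seed)
    L, M, K = config.n_lines, config.n_markers, config.n_subpopulations
    A = config.alleles_per_marker

    subpops = np.sort(rng.integers(0, K, size=L))
    line_ids = [f"L{i + 1:03d}" for i in range(L)]
    marker_ids = [f"M{j + 1:03d}" for j in range(M)]

    chrom = np.sort(rng.integers(1, config.n_chromosomes + 1, size=M))
    pos = np.empty(M, dtype=float)
    for c in range(1, config.n_chromosomes + 1):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = np.sort(rng.uniform(0.0, 150.0, size=idx.size))
    marker_map = pd.DataFrame(
        {"chromosome": [str(c) for c in chrom], "position": pos},
        index=pd.Index(marker_ids, name="marker_id"),
    )

    conc = (1.0 - config.subpop_divergence) / config.subpop_divergence
    calls = np.empty((L, M), dtype=object)
    labels_per_marker: list[list[str]] = []
    global_freqs = np.empty((M, A))
    for j in range(M):
        labels = _band_size_labels(rng, A)
        labels_per_marker.append(labels)
        base = rng.dirichlet(np.ones(A))
        # keep every allele representable so catalogs are stable across seeds
        base = (base + 0.05) / (1.0 + 0.05 * A)
        global_freqs[j] = base
        sub_freqs = rng.dirichlet(base * conc, size=K)  # (K, A)
        cum = np.cumsum(sub_freqs, axis=1)
        u = rng.random(L)
        allele_idx = (u[:, None] > cum[subpops]).sum(axis=1)
        for i in range(L):
            a = labels[allele_idx[i]]
            calls[i, j] = (a, a)

    qtl_idx = np.sort(rng.choice(M, size=config.n_qtl, replace=False))
    inc_alleles = []
    for j in qtl_idx:
        # pick the allele closest to intermediate frequency: maximises the
        # genetic variance the downstream scan has to detect
        a = int(np.argmin(np.abs(global_freqs[j] - 0.5)))
        inc_alleles.append(labels_per_marker[j][a])
    truth = QtlTruth(
        marker_ids=tuple(marker_ids[j] for j in qtl_idx),
        increasing_alleles=tuple(inc_alleles),
        effects=tuple(config.effects()),
        subpopulations=subpops,
    )
    return GenotypeMatrix(line_ids, marker_ids, calls, marker_map), truth


# ---------------------------------------------------------------------------
# RIL population
# ---------------------------------------------------------------------------

def haldane_recombination(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function r = (1 - exp(-2d))/2 with d in Morgans (input cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination(d_cm: np.ndarray) -> np.ndarray:
    """Expected recombinant fraction between adjacent markers in a RIL
    population derived by selfing: R = 2r/(1+2r), r from Haldane."""
    r = haldane_recombination(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def _parent_allele(call, marker_id: str) -> str:
    if call is None:
        raise ValidationError(f"parent missing call at {marker_id}")
    if call[0] != call[1]:
        raise ValidationError(f"parent heterozygous at {marker_id}")
    return call[0]


def simulate_ril(
    parent_a: Mapping[str, tuple[str, str] | str],
    parent_b: Mapping[str, tuple[str, str] | str],
    config: RilConfig,
) -> GenotypeMatrix:
    """Simulate a homozygous RIL population from two inbred parents.

    Each RIL chromosome is a Markov mosaic over parental origins: the origin
    at the first marker is a fair coin, and it switches between adjacent
    markers with probability 2r/(1+2r) (Haldane r on the map distance). Where
    the parents share an allele the offspring all carry it regardless of
    origin. parent genotypes map marker_id -> homozygous call (or bare
    allele label).
    """
    rng = np.random.default_rng(config.seed)
    mp = config.marker_positions
    marker_ids = list(mp.index)

    def allele_of(parent, m: str) -> str:
        v = parent[m]
        if isinstance(v, str):
            return v
        return _parent_allele(v, m)

    a_alleles = {m: allele_of(parent_a, m) for m in marker_ids}
    b_alleles = {m: allele_of(parent_b, m) for m in marker_ids}

    n = config.n_lines
    origin = np.empty((n, len(marker_ids)), dtype=np.int8)
    col = {m: j for j, m in enumerate(marker_ids)}
    for _, grp in mp.groupby("chromosome", sort=False):
        ms = list(grp.index)
        pos = grp["position"].to_numpy(dtype=float)
        switch = ril_recombination(np.diff(pos))
        j0 = col[ms[0]]
        origin[:, j0] = rng.integers(0, 2, size=n)
        for k in range(1, len(ms)):
            flips = rng.random(n) < switch[k - 1]
            origin[:, col[ms[k]]] = np.where(
                flips, 1 - origin[:, col[ms[k - 1]]], origin[:, col[ms[k - 1]]]
            )

    calls = np.empty((n, len(marker_ids)), dtype=object)
    for j, m in enumerate(marker_ids):
        aa, bb = a_alleles[m], b_alleles[m]
        for i in range(n):
            a = aa if origin[i, j] == 0 else bb
            calls[i, j] = (a, a)
        if config.residual_het_rate > 0 and aa != bb:
            het = rng.random(n) < config.residual_het_rate
            pair = (aa, bb) if aa <= bb else (bb, aa)
            for i in np.flatnonzero(het):
                calls[i, j] = pair

    line_ids = [f"RIL{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(line_ids, marker_ids, calls, mp.copy())


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def qtl_contribution(genotypes: GenotypeMatrix, truth: QtlTruth) -> pd.Series:
    """Per-line additive QTL contribution (cm): effect x copies of the
    increasing allele, summed over QTLs."""
    total = np.zeros(genotypes.n_lines)
    for m, inc, s in zip(truth.marker_ids, truth.increasing_alleles, truth.effects):
        colv = genotypes.column(m)
        copies = np.array(
            [0 if c is None else (c[0] == inc) + (c[1] == inc) for c in colv],
            dtype=float,
        )
        total += s * copies
    return pd.Series(total, index=genotypes.line_ids)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    truth: QtlTruth,
    env: EnvConfig,
    seed: int = 0,
    environment_ids: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Replicated multi-environment heights under the additive model."""
    for m in truth.marker_ids:
        genotypes.marker_index(m)  # raises on unknown marker
    rng = np.random.default_rng(seed)
    L, E, R = genotypes.n_lines, env.n_environments, env.n_replicates_per_line
    if environment_ids is None:
        environment_ids = [f"E{j + 1}" for j in range(E)]
    elif len(environment_ids) != E:
        raise ConfigurationError("environment_ids length must equal n_environments")

    qtl = qtl_contribution(genotypes, truth).to_numpy()
    g = rng.normal(0.0, np.sqrt(env.var_genotype), size=L)
    e = rng.normal(0.0, np.sqrt(env.var_environment), size=E)
    ge = rng.normal(0.0, np.sqrt(env.var_gxe), size=(L, E))
    eps = rng.normal(0.0, np.sqrt(env.var_residual), size=(L, E, R))

    heights = env.grand_mean + (qtl + g)[:, None, None] + e[None, :, None] + ge[:, :, None] + eps
    data = pd.DataFrame(
        {
            "line_id": np.repeat(genotypes.line_ids, E * R),
            "environment_id": np.tile(np.repeat(environment_ids, R), L),
            "replicate": np.tile(np.arange(1, R + 1), L * E),
            "height": heights.ravel(),
        }
    )
    return PhenotypeTable(data)


def expected_anova_percents(env: EnvConfig, n_lines: int) -> dict[str, float]:
    """Expected Type I SS percent contributions of genotype, environment and
    G x E for a balanced trial at the configured variance components.

    Uses the balanced two-way random-model expected-mean-square identities:
    E[MS_G] = s2_eps + r s2_ge + r e s2_g, E[MS_E] = s2_eps + r s2_ge +
    r g s2_e, E[MS_GE] = s2_eps + r s2_ge.
    """
    g, e, r = n_lines, env.n_environments, env.n_replicates_per_line
    ss_g = (g - 1) * (env.var_residual + r * env.var_gxe + r * e * env.var_genotype)
    ss_e = (e - 1) * (env.var_residual + r * env.var_gxe + r * g * env.var_environment)
    ss_ge = (g - 1) * (e - 1) * (env.var_residual + r * env.var_gxe)
    total = ss_g + ss_e + ss_ge
    return {
        "genotype": 100.0 * ss_g / total,
        "environment": 100.0 * ss_e / total,
        "interaction": 100.0 * ss_ge / total,
    }


# ---------------------------------------------------------------------------
# bundled fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: QtlTruth


def make_fixture() -> Fixture:
    """Deterministic 12-line x 6-marker x 2-environment dataset, small enough
    to hand-check every downstream statistic."""
    panel_cfg = PanelConfig(
        n_lines=12,
        n_markers=6,
        n_chromosomes=2,
        alleles_per_marker=2,
        n_subpopulations=2,
        n_qtl=2,
        qtl_effect_sizes=6.0,
        seed=20210,
    )
    genotypes, truth = simulate_panel(panel_cfg)
    env = EnvConfig(
        n_environments=2,
        n_replicates_per_line=2,
        var_genotype=25.0,
        var_environment=4.0,
        var_gxe=4.0,
        var_residual=1.0,
        grand_mean=120.0,
    )
    phenotypes = simulate_phenotypes(genotypes, truth, env, seed=20211)
    return Fixture(genotypes, phenotypes, truth)
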