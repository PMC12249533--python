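"""Marker-trait association scan with population-structure covariates.

Population structure is controlled with principal-component covariates
computed from the allele-indicator matrix (a standard substitute for
subpopulation-membership Q matrices in association models). Each marker is
tested per environment with a nested-model F test: the full linear model
(intercept + structure covariates + marker-class indicators) against the
reduced model (intercept + covariates), on the per-line mean height of that
environment. Markers reaching p below the significance threshold make up the
scan result; markers recurrently significant across environments form the
"stable" locus set used for pyramiding.

Multi-allelic markers enter as categorical factors: one class per homozygous
allele, heterozygous calls as their own class, and classes with fewer than
three carrier lines pooled into an "other" class to keep the fit full rank.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .io_tables import GenotypeMatrix, LocusSet, PhenotypeTable

logger = logging.getLogger(__name__)

MIN_CLASS_CARRIERS = 3


@dataclass(frozen=True)
class AssociationResult:
    """One Table-style association row: marker x environment."""

    marker_id: str
    environment_id: str
    chromosome: str
    f_statistic: float
    p_value: float
    marker_r2: float
    best_allele: str
    n_lines: int = 0


# ---------------------------------------------------------------------------
# structure covariates
# ---------------------------------------------------------------------------

def allele_indicator_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """Lines x (marker-allele) matrix of allele counts (0/1/2), with missing
    calls imputed to the allele's mean count. Monomorphic markers contribute
    nothing (their columns are constant and carry no variance)."""
    cols: list[np.ndarray] = []
    for m in genotypes.marker_ids:
        catalog = genotypes.allele_catalog(m)
        if len(catalog) < 2:
            continue
        col = genotypes.column(m)
        for a in catalog:
            counts = np.array(
                [np.nan if c is None else (c[0] == a) + (c[1] == a) for c in col],
                dtype=float,
            )
            mean = np.nanmean(counts)
            counts[np.isnan(counts)] = mean
            cols.append(counts)
    if not cols:
        raise DegenerateInputError("no polymorphic markers")
    return np.column_stack(cols)


def structure_covariates(genotypes: GenotypeMatrix, n_axes: int = 3) -> np.ndarray:
    """Top principal-component scores of the centered allele-indicator
    matrix; returned columns are mean-centered, one row per panel line."""
    if n_axes >= genotypes.n_lines:
        raise ValidationError("n_axes must be < number of lines")
    X = allele_indicator_matrix(genotypes)
    X = X - X.mean(axis=0)
    # deterministic SVD-based PCA; sign fixed by largest-magnitude loading
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :n_axes] * s[:n_axes]
    for k in range(scores.shape[1]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    return scores - scores.mean(axis=0)


# ---------------------------------------------------------------------------
# per-marker test
# ---------------------------------------------------------------------------

def _marker_classes(col: np.ndarray) -> tuple[np.ndarray, list[str]] | None:
    """Class codes for one marker column. Returns (codes, class labels) over
    all lines; code -1 marks a missing call. Rare classes (< 3 carriers) are
    pooled into 'other'. None when fewer than two classes survive."""
    keys = np.array(
        ["" if c is None else (f"hom:{c[0]}" if c[0] == c[1] else "het") for c in col],
        dtype=object,
    )
    counts = Counter(k for k in keys if k)
    if len(counts) < 2:
        return None
    rare = {k for k, n in counts.items() if n < MIN_CLASS_CARRIERS}
    if rare:
        keys = np.array(["other" if k in rare else k for k in keys], dtype=object)
        counts = Counter(k for k in keys if k)
        if len(counts) < 2:
            return None
    labels = sorted(counts)
    code_of = {k: i for i, k in enumerate(labels)}
    codes = np.array([code_of[k] if k else -1 for k in keys], dtype=int)
    return codes, labels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _nested_f(
    y: np.ndarray, covariates: np.ndarray, codes: np.ndarray
) -> tuple[float, float, float]:
    """F, p and incremental R^2 of the marker-class factor over the reduced
    covariate-only model."""
    n = y.size
    k = codes.max() + 1
    Z = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    ind = np.zeros((n, k - 1))
    for c in range(1, k):
        ind[codes == c, c - 1] = 1.0
    Xf = np.column_stack([Z, ind])
    rss_r = _rss(Z, y)
    rss_f = _rss(Xf, y)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0.0:
        return 0.0, 1.0, 0.0
    df_num = k - 1
    df_den = n - Xf.shape[1]
    if df_den <= 0:
        raise DegenerateInputError("no residual degrees of freedom")
    num = max(rss_r - rss_f, 0.0)
    if rss_f <= max(1e-12 * tss, 0.0):
        return float("inf"), float(np.finfo(float).tiny), min(num / tss, 1.0)
    f = (num / df_num) / (rss_f / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), max(p, np.finfo(float).tiny), min(num / tss, 1.0)


def _best_allele(col: np.ndarray, y: np.ndarray) -> str:
    """Allele whose homozygous carriers have the highest raw mean height."""
    sums: dict[str, float] = defaultdict(float)
    ns: dict[str, int] = defaultdict(int)
    for c, h in zip(col, y):
        if c is not None and c[0] == c[1]:
            sums[c[0]] += h
            ns[c[0]] += 1
    if not ns:
        raise DegenerateInputError("no homozygous carriers")
    well = {a for a, n in ns.items() if n >= MIN_CLASS_CARRIERS} or set(ns)
    return max(sorted(well), key=lambda a: sums[a] / ns[a])


def _env_response(phenotypes: PhenotypeTable, genotypes: GenotypeMatrix, env: str):
    """(y, line mask) of per-line mean heights for one environment, aligned
    to genotype line order."""
    means = phenotypes.subset([env]).line_means()
    idx = [genotypes._line_pos[l] for l in means.index if l in genotypes._line_pos]
    lines = [l for l in means.index if l in genotypes._line_pos]
    if not lines:
        raise ValidationError(f"no phenotyped line of environment {env!r} is genotyped")
    return means.loc[lines].to_numpy(), np.array(idx, dtype=int)


def test_marker(
    marker_id: str,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    covariates: np.ndarray,
    environment_id: str | None = None,
) -> AssociationResult:
    """Nested-model F test of one marker against one environment's line-mean
    heights. phenotypes must cover exactly one environment unless
    environment_id picks one out."""
    envs = phenotypes.environments()
    if environment_id is None:
        if len(envs) != 1:
            raise ValidationError("pass environment_id when phenotypes span several environments")
        environment_id = envs[0]
    y, rows = _env_response(phenotypes, genotypes, environment_id)
    col = genotypes.column(marker_id)[rows]
    covs = np.asarray(covariates, dtype=float)[rows] if np.size(covariates) else np.empty((y.size, 0))

    present = np.array([c is not None for c in col])
    if not present.any():
        raise DegenerateInputError(f"all lines missing at {marker_id}")
    cls = _marker_classes(col[present])
    if cls is None:
        raise DegenerateInputError(f"marker {marker_id} effectively monomorphic")
    codes, _ = cls
    f, p, r2 = _nested_f(y[present], covs[present], codes)
    return AssociationResult(
        marker_id=marker_id,
        environment_id=environment_id,
        chromosome=genotypes.chromosome(marker_id),
        f_statistic=f,
        p_value=p,
        marker_r2=r2,
        best_allele=_best_allele(col[present], y[present]),
        n_lines=int(present.sum()),
    )


def scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    covariates: np.ndarray,
    alpha: float = 0.01,
) -> list[AssociationResult]:
    """Test every (marker, environment) pair; keep p < alpha, sorted by
    environment then ascending p. Monomorphic or all-missing markers are
    skipped with a logged warning."""
    results: list[AssociationResult] = []
    n_tested = 0
    covs = np.asarray(covariates, dtype=float)
    for env in phenotypes.environments():
        y, rows = _env_response(phenotypes, genotypes, env)
        env_covs = covs[rows] if covs.size else np.empty((y.size, 0))
        for m in genotypes.marker_ids:
            col = genotypes.column(m)[rows]
            present = np.array([c is not None for c in col])
            if not present.any():
                logger.warning("marker %s skipped in %s: all calls missing", m, env)
                continue
            cls = _marker_classes(col[present])
            if cls is None:
                logger.warning("marker %s skipped in %s: monomorphic", m, env)
                continue
            codes, _ = cls
            f, p, r2 = _nested_f(y[present], env_covs[present], codes)
            n_tested += 1
            if p < alpha:
                results.append(
                    AssociationResult(
                        marker_id=m,
                        environment_id=env,
                        chromosome=genotypes.chromosome(m),
                        f_statistic=f,
                        p_value=p,
                        marker_r2=r2,
                        best_allele=_best_allele(col[present], y[present]),
                        n_lines=int(present.sum()),
                    )
                )
    logger.info(
        "scan: %d tests, %d significant associations over %d markers",
        n_tested,
        len(results),
        len({r.marker_id for r in results}),
    )
    results.sort(key=lambda r: (r.environment_id, r.p_value))
    return results


def count_tests(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable) -> int:
    """Number of (marker, environment) pairs scan would actually test."""
    n = 0
    for env in phenotypes.environments():
        _, rows = _env_response(phenotypes, genotypes, env)
        for m in genotypes.marker_ids:
            col = genotypes.column(m)[rows]
            present = np.array([c is not None for c in col])
            if present.any() and _marker_classes(col[present]) is not None:
                n += 1
    return n


def stable_loci(results: list[AssociationResult], min_environments: int = 2) -> LocusSet:
    """Markers significant in at least min_environments environments, each
    paired with its height-increasing allele (majority vote over
    environments; ties broken by the environment with the smallest p).
    Ordered by environment count descending, then smallest p ascending."""
    by_marker: dict[str, list[AssociationResult]] = defaultdict(list)
    for r in results:
        by_marker[r.marker_id].append(r)

    entries = []
    for m, rs in by_marker.items():
        n_env = len({r.environment_id for r in rs})
        if n_env < min_environments:
            continue
        votes = Counter(r.best_allele for r in rs)
        top = max(votes.values())
        tied = sorted(a for a, v in votes.items() if v == top)
        if len(tied) == 1:
            allele = tied[0]
        else:
            allele = min(
                (r for r in rs if r.best_allele in tied), key=lambda r: r.p_value
            ).best_allele
        entries.append((n_env, min(r.p_value for r in rs), m, allele))
    entries.sort(key=lambda t: (-t[0], t[1], t[2]))
    return LocusSet.from_pairs([(m, a) for _, _, m, a in entries])
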