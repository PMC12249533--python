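"""Genotypic-value encoding and the allele-pyramiding score.

Every trait-associated locus is collapsed to a three-level code: +2 for a
line homozygous for the locus's height-increasing allele, -2 for any other
homozygote, and 0 for a heterozygous or missing call (the symmetric neutral
completion; inbred material rarely triggers it, but user data can). The
pyramiding score x of a line is the sum of these codes over an ordered locus
set, and is the single predictor of the height model y = a*x + b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateInputError
from .io_tables import Call, GenotypeMatrix, LocusSet, PhenotypeTable


@dataclass(frozen=True)
class PyramidingScore:
    line_id: str
    x: int


def genotypic_value(call: Call | None, increasing_allele: str) -> int:
    """+2 homozygous increasing, -2 any other homozygote, 0 het/missing."""
    if call is None:
        return 0
    if call[0] != call[1]:
        return 0
    return 2 if call[0] == increasing_allele else -2


def score_line(genotypes: GenotypeMatrix, line_id: str, locus_set: LocusSet) -> PyramidingScore:
    """Pyramiding score of one line over an ordered locus set."""
    if len(locus_set) == 0:
        raise ConfigurationError("locus set is empty")
    x = 0
    for locus in locus_set:
        try:
            call = genotypes.call(line_id, locus.marker_id)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        x += genotypic_value(call, locus.increasing_allele)
    return PyramidingScore(line_id=line_id, x=x)


def score_table(genotypes: GenotypeMatrix, locus_set: LocusSet) -> pd.DataFrame:
    """Per-line score breakdown: one column per locus with its genotypic
    value, the pyramiding score x, and the favorable (+2) locus count.
    Indexed by line_id; the table written as scores.tsv."""
    if len(locus_set) == 0:
        raise ConfigurationError("locus set is empty")
    cols: dict[str, np.ndarray] = {}
    for locus in locus_set:
        try:
            col = genotypes.column(locus.marker_id)
        except KeyError as exc:
            raise ConfigurationError(str(exc)) from exc
        cols[locus.marker_id] = np.array(
            [genotypic_value(c, locus.increasing_allele) for c in col], dtype=int
        )
    df = pd.DataFrame(cols, index=pd.Index(genotypes.line_ids, name="line_id"))
    df["x"] = df.sum(axis=1)
    df["favorable_count"] = (df[list(locus_set.marker_ids)] == 2).sum(axis=1)
    return df


def favorable_allele_counts(genotypes: GenotypeMatrix, locus_set: LocusSet) -> pd.Series:
    """Number of loci at which each line is homozygous for the increasing
    allele (the x axis of the height-vs-count regressions)."""
    return score_table(genotypes, locus_set)["favorable_count"]


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    n: int


def favorable_count_regression(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    locus_set: LocusSet,
    environment_id: str | None = None,
) -> RegressionFit:
    """OLS of line-mean height on the favorable-allele count for one
    environment; F and p are the 1-df slope test."""
    envs = phenotypes.environments()
    if environment_id is None:
        if len(envs) != 1:
            raise ConfigurationError(
                "pass environment_id when phenotypes span several environments"
            )
        environment_id = envs[0]
    means = phenotypes.subset([environment_id]).line_means()
    counts = favorable_allele_counts(genotypes, locus_set)
    shared = [l for l in means.index if l in counts.index]
    x = counts.loc[shared].to_numpy(dtype=float)
    y = means.loc[shared].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateInputError("all lines share one favorable-allele count")
    slope, intercept, f, p = _slope_test(x, y)
    return RegressionFit(slope, intercept, f, p, n=x.size)


def _slope_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form simple OLS with the 1-df slope F test."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    slope = float(xc @ yc) / sxx
    intercept = float(y.mean() - slope * x.mean())
    ss_reg = slope * slope * sxx
    rss = float(yc @ yc) - ss_reg
    rss = max(rss, 0.0)
    if n <= 2:
        raise DegenerateInputError("need at least 3 points for the slope test")
    if rss <= 1e-13 * max(float(yc @ yc), 1.0):
        if ss_reg <= 0.0:
            return slope, intercept, 0.0, 1.0
        return slope, intercept, float("inf"), float(np.finfo(float).tiny)
    f = ss_reg / (rss / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return slope, intercept, float(f), max(p, float(np.finfo(float).tiny))
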