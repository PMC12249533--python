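"""Model validation and genotype-by-environment variance partitioning.

Three complementary views of prediction quality and environmental noise:

* average absolute error (AAE) between model-predicted and observed line
  heights in an independent validation population;
* the pairwise between-environment average-absolute-difference (AAD) matrix,
  quantifying how much the same lines' heights move between years — the
  natural variation a useful predictor should not be expected to beat;
* a two-way ANOVA with sequential (Type I) sums of squares in the order
  genotype, environment, genotype x environment, partitioning phenotypic
  variance among the three model factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .io_tables import GenotypeMatrix, LocusSet, PhenotypeTable
from .prediction_model import HeightModel, predict_height
from .pyramiding import score_table


@dataclass(frozen=True)
class AAEReport:
    """Per-line predicted (P) vs real (R) heights and their mean |P - R|."""

    n: int
    aae: float
    per_line: pd.DataFrame  # line_id index; predicted, real, abs_error (cm)
    predicted_mean: float
    real_mean: float


def average_absolute_error(
    model: HeightModel,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    locus_set: LocusSet | None = None,
    environments: list[str] | None = None,
) -> AAEReport:
    """AAE of the model on a validation population.

    Each line's real height R is its mean over the designated environments
    (all by default); P = predict(model, x) from the line's pyramiding score
    on the model's locus set.
    """
    locus_set = locus_set if locus_set is not None else model.locus_set
    means = phenotypes.line_means(environments)
    lines = [l for l in genotypes.line_ids if l in means.index]
    if not lines:
        raise ValidationError("no genotyped line has validation phenotypes")
    x = score_table(genotypes, locus_set).loc[lines, "x"].to_numpy(dtype=float)
    predicted = model.slope * x + model.intercept
    real = means.loc[lines].to_numpy()
    err = np.abs(predicted - real)
    per_line = pd.DataFrame(
        {"predicted": predicted, "real": real, "abs_error": err},
        index=pd.Index(lines, name="line_id"),
    )
    return AAEReport(
        n=len(lines),
        aae=float(err.mean()),
        per_line=per_line,
        predicted_mean=float(predicted.mean()),
        real_mean=float(real.mean()),
    )


def pairwise_environment_aad(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Symmetric environments x environments matrix: mean over shared lines
    of |line-mean height in one environment - in the other|. Diagonal NaN;
    pairs with no shared line NaN with a warning."""
    wide = phenotypes.env_line_means()
    envs = list(wide.columns)
    if len(envs) < 2:
        raise DegenerateInputError("need at least 2 environments")
    out = pd.DataFrame(np.nan, index=envs, columns=envs, dtype=float)
    for i, a in enumerate(envs):
        for b in envs[i + 1 :]:
            diff = (wide[a] - wide[b]).dropna()
            if diff.empty:
                warnings.warn(f"environments {a!r} and {b!r} share no lines")
                continue
            v = float(diff.abs().mean())
            out.loc[a, b] = v
            out.loc[b, a] = v
    return out


def natural_variation_band(phenotypes: PhenotypeTable) -> tuple[float, float]:
    """(min, max) of the off-diagonal between-environment AAD entries — the
    band of ordinary year-to-year height variation."""
    mat = pairwise_environment_aad(phenotypes)
    vals = mat.to_numpy()[~np.eye(len(mat), dtype=bool)]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DegenerateInputError("no comparable environment pair")
    return float(vals.min()), float(vals.max())


@dataclass(frozen=True)
class AnovaTable:
    """Sequential-SS decomposition; rows genotype, environment, interaction,
    error with df, sum_sq, mean_sq, F, p, and percent of the model (non-
    error) sum of squares for the three model factors."""

    table: pd.DataFrame

    @property
    def percents(self) -> dict[str, float]:
        return {
            k: float(self.table.loc[k, "percent"])
            for k in ("genotype", "environment", "interaction")
        }


def _group_rss(y: np.ndarray, codes: np.ndarray) -> float:
    """Residual SS of y around its group means (the RSS of an intercept +
    one-factor model)."""
    df = pd.DataFrame({"y": y, "g": codes})
    means = df.groupby("g")["y"].transform("mean").to_numpy()
    r = y - means
    return float(r @ r)


def _two_factor_rss(y: np.ndarray, c1: np.ndarray, c2: np.ndarray) -> float:
    """RSS of the additive model intercept + factor1 + factor2 (no
    interaction), via least squares on treatment-coded indicators."""
    n = y.size
    k1, k2 = c1.max() + 1, c2.max() + 1
    X = np.zeros((n, 1 + (k1 - 1) + (k2 - 1)))
    X[:, 0] = 1.0
    for c in range(1, k1):
        X[c1 == c, c] = 1.0
    for c in range(1, k2):
        X[c2 == c, k1 - 1 + c] = 1.0
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(
    phenotypes: PhenotypeTable,
    order: tuple[str, str] = ("genotype", "environment"),
) -> AnovaTable:
    """Two-way fixed-effects ANOVA of height on genotype and environment
    with sequential (Type I) SS in the given factor order, interaction last,
    error from within-cell replicates.

    Designs are expected complete in genotype x environment cells; replicate
    counts may be unbalanced (sequential SS handle it). F tests each factor
    mean square against the error mean square.
    """
    if set(order) != {"genotype", "environment"}:
        raise ValidationError("order must be a permutation of ('genotype', 'environment')")
    df = phenotypes.data
    y = df["height"].to_numpy(dtype=float)
    g_codes = pd.factorize(df["line_id"])[0]
    e_codes = pd.factorize(df["environment_id"])[0]
    n_g, n_e = g_codes.max() + 1, e_codes.max() + 1
    if n_g < 2 or n_e < 2:
        raise DegenerateInputError("need >= 2 genotypes and >= 2 environments")
    cell_codes = g_codes * n_e + e_codes
    n_cells = np.unique(cell_codes).size
    df_error = y.size - n_cells
    if df_error <= 0:
        raise DegenerateInputError(
            "no within-cell replication: the error term cannot be estimated"
        )

    ss_total = float(((y - y.mean()) ** 2).sum())
    first, second = order
    c_first = g_codes if first == "genotype" else e_codes
    rss_first = _group_rss(y, c_first)
    rss_additive = _two_factor_rss(y, g_codes, e_codes)
    rss_full = _group_rss(y, cell_codes)  # cell-means model = full interaction model

    ss = {
        first: ss_total - rss_first,
        second: rss_first - rss_additive,
        "interaction": rss_additive - rss_full,
        "error": rss_full,
    }
    dof = {
        "genotype": n_g - 1,
        "environment": n_e - 1,
        "interaction": n_cells - n_g - n_e + 1,
        "error": df_error,
    }

    ms_error = ss["error"] / dof["error"]
    rows = []
    model_ss = ss["genotype"] + ss["environment"] + ss["interaction"]
    if model_ss <= 0.0:
        warnings.warn("all model sums of squares are zero; percents reported as 0")
    for name in ("genotype", "environment", "interaction", "error"):
        s, d = max(ss[name], 0.0), dof[name]
        ms = s / d if d else np.nan
        if name == "error":
            f = p = pct = np.nan
        else:
            f = ms / ms_error if ms_error > 0 else (np.inf if ms > 0 else 0.0)
            p = float(stats.f.sf(f, d, dof["error"])) if np.isfinite(f) else (
                float(np.finfo(float).tiny) if ms > 0 else 1.0
            )
            pct = 100.0 * s / model_ss if model_ss > 0 else 0.0
        rows.append(
            {"source": name, "df": d, "sum_sq": s, "mean_sq": ms, "F": f, "p": p, "percent": pct}
        )
    table = pd.DataFrame(rows).set_index("source")
    return AnovaTable(table=table)
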