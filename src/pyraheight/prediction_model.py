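"""The pyramiding-score height model y = a*x + b and the 2..k locus ladder.

A HeightModel is an ordinary least-squares fit of line height on the
pyramiding score x (sum of ±2 genotypic values over an ordered locus set).
The ladder refits the model on the first k loci of a ranked locus sequence
for a range of k, mirroring the practice of asking how many trait-associated
loci a usable prediction needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .io_tables import GenotypeMatrix, LocusSet, PhenotypeTable
from .pyramiding import PyramidingScore, _slope_test, score_table


@dataclass(frozen=True)
class HeightModel:
    """y = slope*x + intercept with the 1-df slope F test and the ordered
    locus set the score x is computed from."""

    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    locus_set: LocusSet
    training_label: str = ""

    def __post_init__(self) -> None:
        if len(self.locus_set) == 0:
            raise ValidationError("model requires a nonempty locus set")
        if not (self.f_statistic >= 0):
            raise ValidationError("F statistic must be >= 0")

    def equation(self, decimals: int = 5) -> str:
        return f"y = {self.slope:.{decimals}f} x + {self.intercept:.{decimals}f}"


def predict_height(model: HeightModel, x) -> float | np.ndarray:
    """Predicted height (cm) at pyramiding score x: exactly slope*x + intercept."""
    return model.slope * np.asarray(x, dtype=float) + model.intercept if np.ndim(x) else (
        model.slope * float(x) + model.intercept
    )


def fit_height_model(
    scores: Sequence[PyramidingScore] | np.ndarray,
    heights: Sequence[float] | np.ndarray,
    locus_set: LocusSet,
    training_label: str = "",
) -> HeightModel:
    """OLS fit of heights on pyramiding scores.

    scores may be PyramidingScore records or a bare numeric array; heights
    aligns positionally. Requires >= 3 lines and >= 2 distinct scores.
    """
    if scores is not None and len(scores) and isinstance(scores[0], PyramidingScore):
        x = np.array([s.x for s in scores], dtype=float)
    else:
        x = np.asarray(scores, dtype=float)
    y = np.asarray(heights, dtype=float)
    if x.size != y.size:
        raise ValidationError("scores and heights differ in length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 lines")
    if np.unique(x).size < 2:
        raise DegenerateInputError("all pyramiding scores equal; slope undefined")
    slope, intercept, f, p = _slope_test(x, y)
    return HeightModel(
        slope=slope,
        intercept=intercept,
        f_statistic=f,
        p_value=p,
        locus_set=locus_set,
        training_label=training_label,
    )


def build_model_ladder(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    locus_sequence: LocusSet,
    counts: Iterable[int] = range(2, 11),
    training_environments: Sequence[str] | None = None,
    training_label: str = "",
) -> list[HeightModel]:
    """Fit one model per locus count k, each on the first k loci of the
    ranked sequence. The response is every training line's mean height over
    the training environments (all environments when unspecified)."""
    counts = list(counts)
    if not counts:
        raise ValidationError("no locus counts requested")
    if max(counts) > len(locus_sequence):
        raise ValidationError(
            f"ladder needs {max(counts)} loci but the sequence has {len(locus_sequence)}"
        )
    means = phenotypes.line_means(training_environments)
    lines = [l for l in genotypes.line_ids if l in means.index]
    if not lines:
        raise ValidationError("no genotyped line has training phenotypes")
    y = means.loc[lines].to_numpy()

    models = []
    for k in counts:
        subset = locus_sequence.head(k)
        x = score_table(genotypes, subset).loc[lines, "x"].to_numpy(dtype=float)
        label = f"{training_label} k={k}".strip() if training_label else f"k={k}"
        models.append(fit_height_model(x, y, subset, training_label=label))
    return models
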