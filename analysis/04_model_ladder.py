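#!/usr/bin/env python
"""Fit the 2..10-locus prediction ladder and validate it cross-population.

Each model y = a*x + b is trained on the panel's line-mean heights against
the pyramiding score over the first k ranked loci, then applied to the RIL
population; accuracy is the average absolute error (AAE) against each RIL
line's mean height over the six primary-location seasons. Writes one model
file per k plus ladder-summary.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pyraheight.evaluation import average_absolute_error
from pyraheight.io_tables import LocusSet, read_genotypes, read_phenotypes, write_model
from pyraheight.prediction_model import build_model_ladder


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--min-loci", type=int, default=2)
    parser.add_argument("--max-loci", type=int, default=10)
    args = parser.parse_args()

    data = args.results / "data"
    panel = read_genotypes(data / "panel-genotypes.tsv")
    panel_ph = read_phenotypes(data / "panel-phenotypes.tsv")
    ril = read_genotypes(data / "ril-genotypes.tsv")
    ril_ph = read_phenotypes(data / "ril-phenotypes.tsv")
    loci_df = pd.read_csv(args.results / "stable-loci.tsv", sep="\t", dtype=str)
    ranking = LocusSet.from_pairs(zip(loci_df["marker_id"], loci_df["increasing_allele"]))

    counts = [
        k for k in range(args.min_loci, args.max_loci + 1) if k <= len(ranking)
    ]
    models = build_model_ladder(panel, panel_ph, ranking, counts, training_label="panel")
    hz = [e for e in ril_ph.environments() if e.startswith("HZ")]

    model_dir = args.results / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, model in zip(counts, models):
        write_model(model, model_dir / f"model-{k}-loci.tsv")
        rep = average_absolute_error(model, ril, ril_ph, environments=hz)
        rows.append(
            {"n_loci": k, "model": model.equation(), "F": round(model.f_statistic, 2),
             "predicted_mean_cm": round(rep.predicted_mean, 2),
             "real_mean_cm": round(rep.real_mean, 2), "aae_cm": round(rep.aae, 2)}
        )
    table = pd.DataFrame(rows)
    table.to_csv(args.results / "ladder-summary.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    best = table.loc[table["aae_cm"].idxmin()]
    print(
        f"\nAAE at k={counts[0]}: {table['aae_cm'].iloc[0]:.2f} cm; "
        f"at k=5: {float(table.loc[table['n_loci'] == 5, 'aae_cm'].iloc[0]):.2f} cm; "
        f"best ladder model uses {int(best['n_loci'])} loci "
        f"(AAE {best['aae_cm']:.2f} cm)"
    )


if __name__ == "__main__":
    main()
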