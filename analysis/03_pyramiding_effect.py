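#!/usr/bin/env python
"""Does stacking height-increasing alleles raise plant height?

For the top five ranked loci, regresses each environment's line-mean height
on the number of loci carrying the homozygous increasing allele — in the
panel and, as a cross-population check, in the RIL population. A positive
slope in every environment is the pyramiding effect the prediction model
rests on. Writes results/favorable-count-regressions.tsv and a diagnostic
scatter under results/figures/.
"""

import argparse
from pathlib import Path

import pandas as pd

from pyraheight.io_tables import LocusSet, read_genotypes, read_phenotypes
from pyraheight.pyramiding import favorable_allele_counts, favorable_count_regression


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--n-loci", type=int, default=5)
    args = parser.parse_args()

    data = args.results / "data"
    loci_df = pd.read_csv(args.results / "stable-loci.tsv", sep="\t", dtype=str)
    loci = LocusSet.from_pairs(
        zip(loci_df["marker_id"], loci_df["increasing_allele"])
    ).head(args.n_loci)

    rows = []
    for pop, geno_file, pheno_file in (
        ("panel", "panel-genotypes.tsv", "panel-phenotypes.tsv"),
        ("RIL", "ril-genotypes.tsv", "ril-phenotypes.tsv"),
    ):
        geno = read_genotypes(data / geno_file)
        pheno = read_phenotypes(data / pheno_file)
        for env in pheno.environments():
            fit = favorable_count_regression(geno, pheno, loci, environment_id=env)
            rows.append(
                {"population": pop, "environment": env, "slope_cm": round(fit.slope, 3),
                 "intercept_cm": round(fit.intercept, 2), "F": round(fit.f_statistic, 2),
                 "p": f"{fit.p_value:.2e}", "n_lines": fit.n}
            )
    table = pd.DataFrame(rows)
    table.to_csv(args.results / "favorable-count-regressions.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    positive = (table["slope_cm"] > 0).mean()
    print(f"\npositive slope in {positive:.0%} of population x environment fits "
          f"({args.n_loci} loci: {', '.join(loci.marker_ids)})")

    # diagnostic scatter for the panel's first environment
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    geno = read_genotypes(data / "panel-genotypes.tsv")
    pheno = read_phenotypes(data / "panel-phenotypes.tsv")
    env = pheno.environments()[0]
    counts = favorable_allele_counts(geno, loci)
    means = pheno.subset([env]).line_means()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(counts.loc[means.index], means, s=12, alpha=0.5)
    ax.set_xlabel(f"height-increasing alleles pyramided ({args.n_loci} loci)")
    ax.set_ylabel("plant height (cm)")
    ax.set_title(f"panel, environment {env}")
    fig_dir = args.results / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    fig.savefig(fig_dir / "favorable-count-panel.png", dpi=120, bbox_inches="tight")
    print(f"figure: {fig_dir / 'favorable-count-panel.png'}")


if __name__ == "__main__":
    main()
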