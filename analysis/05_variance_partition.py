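#!/usr/bin/env python
"""How much of the height variation is genotype, environment, or G x E?

Two-way Type I ANOVA of the RIL trial at the primary location (five
environments, replicated), plus the between-season average-absolute-
difference matrix over the six primary-location seasons — the natural
variation band against which the prediction ladder's AAE is judged.
Writes results/anova.tsv and results/aad-matrix.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from pyraheight.evaluation import natural_variation_band, pairwise_environment_aad, two_way_anova
from pyraheight.io_tables import read_phenotypes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    ril_ph = read_phenotypes(args.results / "data" / "ril-phenotypes.tsv")
    hz = [e for e in ril_ph.environments() if e.startswith("HZ")]

    anova = two_way_anova(ril_ph.subset(hz[:5]))
    anova.table.round(6).to_csv(args.results / "anova.tsv", sep="\t")
    print(anova.table.round(2).to_string())
    pct = anova.percents
    print(
        f"\npercent of model SS: genotype {pct['genotype']:.2f}, environment "
        f"{pct['environment']:.2f}, G x E {pct['interaction']:.2f}"
    )

    aad = pairwise_environment_aad(ril_ph.subset(hz))
    aad.round(5).to_csv(args.results / "aad-matrix.tsv", sep="\t")
    lo, hi = natural_variation_band(ril_ph.subset(hz))
    print(f"\nbetween-season AAD matrix ({len(hz)} seasons):")
    print(aad.round(2).to_string())
    print(f"natural variation band: {lo:.2f} to {hi:.2f} cm")

    ladder_path = args.results / "ladder-summary.tsv"
    if ladder_path.exists():
        ladder = pd.read_csv(ladder_path, sep="\t")
        k5 = ladder[ladder["n_loci"] >= 5]["aae_cm"]
        if not k5.empty:
            print(
                f"\nprediction AAE with >= 5 loci spans {k5.min():.2f}-{k5.max():.2f} cm, "
                f"comparable to the {lo:.2f}-{hi:.2f} cm season-to-season band"
            )


if __name__ == "__main__":
    main()
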