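"""End-to-end orchestration: simulate (optionally), scan, rank, fit the
model ladder, validate, and partition variance, writing every intermediate
as a TSV so any stage can be rerun in isolation.

The synthetic study design mirrors a two-population setup: a structured
diversity panel (training: association scan + model fitting) and a
biparental RIL population (validation: AAE, between-year AAD, two-way
ANOVA). RIL environments are labelled HZ1..HZ6 (one location, six seasons)
plus HN1..HN2 (a second location); real heights and AAE use the HZ
environments, the ANOVA uses HZ1..HZ5, and the AAD matrix uses all six HZ
seasons.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import scan, stable_loci, structure_covariates
from .errors import ConfigurationError, ValidationError
from .evaluation import (
    average_absolute_error,
    natural_variation_band,
    pairwise_environment_aad,
    two_way_anova,
)
from .io_tables import (
    LocusSet,
    read_genotypes,
    read_phenotypes,
    write_association_results,
    write_genotypes,
    write_map,
    write_model,
    write_phenotypes,
)
from .prediction_model import build_model_ladder
from .pyramiding import score_table
from .synthetic_data import (
    EnvConfig,
    PanelConfig,
    RilConfig,
    qtl_contribution,
    simulate_panel,
    simulate_phenotypes,
    simulate_ril,
)

logger = logging.getLogger(__name__)

RIL_ENVIRONMENTS = ("HZ1", "HZ2", "HZ3", "HZ4", "HZ5", "HZ6", "HN1", "HN2")


@dataclass
class PipelineConfig:
    """Flat configuration of a full run; loadable from a YAML key-value file."""

    # data source: simulate a study, or read the four input tables
    simulate: bool = True
    training_genotypes: str | None = None
    training_phenotypes: str | None = None
    validation_genotypes: str | None = None
    validation_phenotypes: str | None = None
    marker_map: str | None = None

    # simulation scale (panel trains, RIL validates)
    panel_lines: int = 273
    panel_markers: int = 218
    panel_subpopulations: int = 3
    panel_environments: int = 5
    n_qtl: int = 10
    qtl_effect_size: float = 2.5
    ril_lines: int = 219
    replicates: int = 3

    # analysis settings
    alpha: float = 0.01
    n_structure_axes: int = 3
    min_environments: int = 2
    min_loci: int = 2
    max_loci: int = 10
    report_k: int = 5
    training_environments: list[str] | None = None
    validation_environments: list[str] | None = None
    anova_environments: list[str] | None = None

    seed: int = 1
    out_dir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.min_loci < 2 or self.max_loci < self.min_loci:
            raise ConfigurationError("need 2 <= min_loci <= max_loci")
        if not self.simulate:
            for name in (
                "training_genotypes",
                "training_phenotypes",
                "validation_genotypes",
                "validation_phenotypes",
            ):
                if getattr(self, name) is None:
                    raise ConfigurationError(f"{name} is required when simulate is false")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must be a flat key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def derived_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def _simulate_study(config: PipelineConfig, out: Path):
    """Generate the panel, its phenotypes, the RIL population and its
    phenotypes; write all six data tables under out/data."""
    s_panel, s_panel_ph, s_ril, s_ril_ph = derived_seeds(config.seed, 4)
    panel_cfg = PanelConfig(
        n_lines=config.panel_lines,
        n_markers=config.panel_markers,
        n_subpopulations=config.panel_subpopulations,
        n_qtl=config.n_qtl,
        qtl_effect_sizes=config.qtl_effect_size,
        seed=s_panel,
    )
    panel, truth = simulate_panel(panel_cfg)
    base = EnvConfig()
    # offset the grand mean by the realized mean QTL contribution so the
    # population mean sits at the configured grand mean (QTL effects are
    # one-sided: +s per copy of the increasing allele)
    panel_env = EnvConfig(
        n_environments=config.panel_environments,
        n_replicates_per_line=config.replicates,
        grand_mean=base.grand_mean - float(qtl_contribution(panel, truth).mean()),
    )
    panel_ph = simulate_phenotypes(panel, truth, panel_env, seed=s_panel_ph)

    # biparental parents: one carries the increasing allele at every QTL,
    # the other an alternative allele; both homozygous everywhere
    inc = dict(zip(truth.marker_ids, truth.increasing_alleles))
    parent_a: dict[str, str] = {}
    parent_b: dict[str, str] = {}
    for m in panel.marker_ids:
        catalog = panel.allele_catalog(m)
        if m in inc:
            parent_a[m] = inc[m]
            others = [a for a in catalog if a != inc[m]]
            parent_b[m] = others[0] if others else inc[m]
        else:
            parent_a[m] = catalog[0]
            parent_b[m] = catalog[1] if len(catalog) > 1 else catalog[0]
    ril_cfg = RilConfig(
        n_lines=config.ril_lines, marker_positions=panel.marker_map, seed=s_ril
    )
    ril = simulate_ril(parent_a, parent_b, ril_cfg)

    # keep the total genotypic variance at the configured component: the
    # planted QTLs segregate at frequency 1/2 in the RILs and contribute
    # sum(s^2) of genetic variance, which is taken out of the polygenic term
    qtl_var = float(sum(s * s for s in truth.effects))
    ril_env = EnvConfig(
        n_environments=len(RIL_ENVIRONMENTS),
        n_replicates_per_line=config.replicates,
        var_genotype=max(base.var_genotype - qtl_var, 0.0),
        grand_mean=base.grand_mean - float(qtl_contribution(ril, truth).mean()),
    )
    ril_ph = simulate_phenotypes(
        ril, truth, ril_env, seed=s_ril_ph, environment_ids=list(RIL_ENVIRONMENTS)
    )

    data_dir = out / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    write_genotypes(panel, data_dir / "panel-genotypes.tsv")
    write_map(panel.marker_map, data_dir / "map.tsv")
    write_phenotypes(panel_ph, data_dir / "panel-phenotypes.tsv")
    write_genotypes(ril, data_dir / "ril-genotypes.tsv")
    write_phenotypes(ril_ph, data_dir / "ril-phenotypes.tsv")
    return panel, panel_ph, ril, ril_ph, truth


def _load_study(config: PipelineConfig):
    panel = read_genotypes(config.training_genotypes, config.marker_map)
    panel_ph = read_phenotypes(config.training_phenotypes)
    ril = read_genotypes(config.validation_genotypes, config.marker_map)
    ril_ph = read_phenotypes(config.validation_phenotypes)
    return panel, panel_ph, ril, ril_ph, None


def locus_ranking(results, min_environments: int) -> LocusSet:
    """Stable-locus ranking extended, after the multi-environment markers,
    with the remaining significant markers (best p first) so the ladder has
    enough loci to reach its maximum count."""
    primary = stable_loci(results, min_environments)
    extra = stable_loci(results, 1)
    seen = set(primary.marker_ids)
    pairs = [(l.marker_id, l.increasing_allele) for l in primary]
    pairs += [
        (l.marker_id, l.increasing_allele) for l in extra if l.marker_id not in seen
    ]
    return LocusSet.from_pairs(pairs)


def run_full(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the in-memory artifacts and writes
    every output table under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        panel, panel_ph, ril, ril_ph, truth = _simulate_study(config, out)
    else:
        panel, panel_ph, ril, ril_ph, truth = _load_study(config)

    logger.info("stage associate: %d markers x %d environments",
                panel.n_markers, len(panel_ph.environments()))
    covariates = structure_covariates(panel, config.n_structure_axes)
    results = scan(panel, panel_ph, covariates, alpha=config.alpha)
    write_association_results(results, out / "association-results.tsv")
    if not results:
        raise ValidationError("stage associate: no significant marker-trait association")

    ranking = locus_ranking(results, config.min_environments)
    pd.DataFrame(
        [(l.marker_id, l.increasing_allele) for l in ranking],
        columns=["marker_id", "increasing_allele"],
    ).to_csv(out / "stable-loci.tsv", sep="\t", index=False)

    counts = [k for k in range(config.min_loci, config.max_loci + 1) if k <= len(ranking)]
    if not counts:
        raise ValidationError(
            f"stage fit: only {len(ranking)} ranked loci; cannot build any model"
        )
    if len(counts) < config.max_loci - config.min_loci + 1:
        logger.warning("stage fit: ladder truncated to k <= %d", counts[-1])

    train_scores = score_table(panel, ranking)
    train_scores.to_csv(out / "scores.tsv", sep="\t")

    models = build_model_ladder(
        panel,
        panel_ph,
        ranking,
        counts=counts,
        training_environments=config.training_environments,
        training_label="panel",
    )
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)

    val_envs = config.validation_environments
    if val_envs is None and config.simulate:
        val_envs = [e for e in RIL_ENVIRONMENTS[:6]]
    summary_rows = []
    reports = {}
    for k, model in zip(counts, models):
        write_model(model, model_dir / f"model-{k}-loci.tsv")
        report = average_absolute_error(model, ril, ril_ph, environments=val_envs)
        reports[k] = report
        summary_rows.append(
            {
                "n_loci": k,
                "markers": ",".join(model.locus_set.marker_ids),
                "f_statistic": round(model.f_statistic, 2),
                "model": model.equation(),
                "predicted_mean": round(report.predicted_mean, 2),
                "real_mean": round(report.real_mean, 2),
                "aae": round(report.aae, 2),
            }
        )
        logger.info("stage fit: k=%d %s AAE=%.2f", k, model.equation(), report.aae)
    ladder = pd.DataFrame(summary_rows)
    ladder.to_csv(out / "ladder-summary.tsv", sep="\t", index=False)

    report_k = config.report_k if config.report_k in reports else counts[-1]
    rep = reports[report_k]
    per_line = rep.per_line.round(5)
    per_line.to_csv(out / "aae-report.tsv", sep="\t")

    # environmental context: between-year variation and variance partition
    aad_envs = config.anova_environments
    hz = [e for e in ril_ph.environments() if not e.startswith("HN")] if config.simulate else None
    aad_ph = ril_ph.subset(hz) if (config.simulate and hz) else ril_ph
    aad = pairwise_environment_aad(aad_ph)
    aad.round(5).to_csv(out / "aad-matrix.tsv", sep="\t")
    band = natural_variation_band(aad_ph)

    anova_ph = ril_ph
    if aad_envs is not None:
        anova_ph = ril_ph.subset(aad_envs)
    elif config.simulate:
        anova_ph = ril_ph.subset(list(RIL_ENVIRONMENTS[:5]))
    anova = two_way_anova(anova_ph)
    anova.table.round(6).to_csv(out / "anova.tsv", sep="\t")

    manifest = {
        "package": "pyraheight",
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if v is not None
        },
        "n_significant_associations": len(results),
        "n_significant_markers": len({r.marker_id for r in results}),
        "n_ranked_loci": len(ranking),
        "report_k": report_k,
        "aae": rep.aae,
        "natural_variation_band": list(band),
        "anova_percents": anova.percents,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "panel": panel,
        "panel_phenotypes": panel_ph,
        "ril": ril,
        "ril_phenotypes": ril_ph,
        "truth": truth,
        "covariates": covariates,
        "results": results,
        "ranking": ranking,
        "models": dict(zip(counts, models)),
        "reports": reports,
        "ladder": ladder,
        "aad": aad,
        "band": band,
        "anova": anova,
        "manifest": manifest,
    }
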