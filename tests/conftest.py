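import numpy as np
import pandas as pd
import pytest

import pyraheight as ph
from pyraheight.io_tables import GenotypeMatrix, LocusSet, PhenotypeTable


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic 12-line x 6-marker x 2-environment bundle."""
    return ph.make_fixture()


@pytest.fixture(scope="session")
def small_panel():
    """A modest structured panel with planted QTLs, shared across tests."""
    cfg = ph.PanelConfig(n_lines=60, n_markers=12, n_chromosomes=3,
                         n_subpopulations=2, n_qtl=2, qtl_effect_sizes=5.0, seed=11)
    return ph.simulate_panel(cfg)


def toy_genotypes(calls_by_marker: dict[str, list], line_ids=None,
                  marker_map: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from per-marker call lists.

    Entries may be 'a/b' strings, bare allele labels (homozygous), or None.
    """
    markers = list(calls_by_marker)
    n = len(next(iter(calls_by_marker.values())))
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n)]
    calls = np.empty((n, len(markers)), dtype=object)
    for j, m in enumerate(markers):
        for i, v in enumerate(calls_by_marker[m]):
            if v is None:
                calls[i, j] = None
            elif "/" in v:
                a, b = v.split("/")
                calls[i, j] = (a, b) if a <= b else (b, a)
            else:
                calls[i, j] = (v, v)
    return GenotypeMatrix(line_ids, markers, calls, marker_map)


def toy_phenotypes(heights: dict[tuple[str, str], list[float]]) -> PhenotypeTable:
    """PhenotypeTable from {(line, env): [rep heights]}."""
    rows = []
    for (line, env), hs in heights.items():
        for r, h in enumerate(hs, start=1):
            rows.append({"line_id": line, "environment_id": env, "replicate": r, "height": h})
    return PhenotypeTable(pd.DataFrame(rows))


def single_env_phenotypes(line_heights: dict[str, float], env: str = "E1") -> PhenotypeTable:
    return toy_phenotypes({(l, env): [h] for l, h in line_heights.items()})


def locus_set(*pairs) -> LocusSet:
    return LocusSet.from_pairs(pairs)
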