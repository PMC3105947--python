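"""Shared fixtures: small panels for unit tests, a BXD-scale panel for the
acceptance-level checks. All are session-scoped and must not be mutated."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from bxdeqtl import (
    SimulationConfig,
    expected_dosage,
    make_marker_map,
    normalize_panel,
    simulate_expression_panel,
    simulate_ri_genotypes,
    summarize_by_strain,
)


@pytest.fixture(scope="session")
def small_map():
    return make_marker_map(3, 60, 5, 2.0, seed=101)


@pytest.fixture(scope="session")
def small_genotypes(small_map):
    return simulate_ri_genotypes(small_map, 20, seed=102)


@pytest.fixture(scope="session")
def small_sim(small_genotypes):
    cfg = SimulationConfig(
        n_probes=200,
        replicates=3,
        n_cis=8,
        n_trans=8,
        n_modules=2,
        module_size=8,
        n_sex_probes=3,
        n_mendelian=3,
        include_f1=True,
    )
    return simulate_expression_panel(small_genotypes, cfg, seed=103)


@pytest.fixture(scope="session")
def small_panel(small_sim):
    return small_sim[0]


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim[1]


@pytest.fixture(scope="session")
def small_norm(small_panel):
    return normalize_panel(small_panel)


@pytest.fixture(scope="session")
def small_summary(small_norm):
    return summarize_by_strain(small_norm)


@pytest.fixture(scope="session")
def small_grid(small_genotypes):
    return expected_dosage(small_genotypes, 1.0)


# ---- BXD-scale objects (57 strains), shared by the acceptance-level tests ----

@pytest.fixture(scope="session")
def bxd_map():
    """19 autosomes + X, 80 cM each, 0.42 cM spacing: ~3,820 markers."""
    return make_marker_map(20, 80, 0.42, 2.0, seed=11)


@pytest.fixture(scope="session")
def bxd_genotypes(bxd_map):
    return simulate_ri_genotypes(bxd_map, 57, seed=12)


@pytest.fixture(scope="session")
def bxd_grid(bxd_genotypes):
    return expected_dosage(bxd_genotypes, 1.0)


@pytest.fixture(scope="session")
def panel57_genotypes():
    """57 strains on a lighter map, for panels where map density is not at stake."""
    mm = make_marker_map(5, 60, 2.0, 2.0, seed=21)
    return simulate_ri_genotypes(mm, 57, seed=22)
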