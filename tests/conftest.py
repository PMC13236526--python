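import numpy as np
import pandas as pd
import pytest

from codep import synthetic_data as sd
from codep.discovery import DependencyPanel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_panel():
    """Deterministic 15-line panel with one strong planted interaction."""
    spec = sd.PanelSpec(
        n_lines=15, n_genes=40, n_drugs=6,
        planted=(sd.PlantedInteraction(drug=0, on_target=1, co_target=2,
                                       beta_on=3.0, beta_co=-1.5),),
        noise_sd=0.5, seed=7)
    panel, manifest = sd.simulate_panel(spec)
    return panel, manifest


@pytest.fixture
def noise_free_panel():
    """Single planted drug, zero noise: combined model is exact."""
    spec = sd.PanelSpec(
        n_lines=15, n_genes=20, n_drugs=3,
        planted=(sd.PlantedInteraction(drug=0, on_target=0, co_target=5,
                                       beta_on=2.0, beta_co=-1.0),),
        noise_sd=0.0, seed=11)
    return sd.simulate_panel(spec)


@pytest.fixture
def small_cohort():
    spec = sd.CohortSpec(
        n_samples=300, n_genes=40,
        expression_drug_effects=(("ACSL4", "dasatinib", -0.25),
                                 ("ACSL4", "venetoclax", 0.36)),
        null_drugs=("alk_i", "flt3_i", "akt_i"),
        signature_genes=("SRC", "ACSL4"),
        true_log_hr_per_lp_unit=float(np.log(1.27)),
        censoring_rate=0.3,
        mutation_genes=(("IDH1", 0.10, -0.9), ("FLT3", 0.25, 0.0),
                        ("NPM1", 0.25, 0.0), ("TP53", 0.10, 0.0),
                        ("IDH2", 0.10, 0.0)),
        seed=21)
    cohort, manifest = sd.simulate_cohort(spec)
    return cohort, manifest


@pytest.fixture
def tiny_atlas():
    spec = sd.AtlasSpec(
        cell_types=(("mono", 250), ("ery", 250), ("hsc", 250)),
        enriched_type="mono", enrichment_shift=3.0, n_genes=25, seed=5)
    atlas, manifest = sd.simulate_atlas(spec)
    return atlas, manifest


def manual_panel(auc_rows, dep_rows, annotations, lines=None):
    """Build a DependencyPanel from plain dicts for hand-crafted tests."""
    drugs = list(auc_rows)
    genes = list(dep_rows)
    n = len(next(iter(auc_rows.values())))
    lines = lines or [f"L{i}" for i in range(n)]
    return DependencyPanel(
        auc=pd.DataFrame([auc_rows[d] for d in drugs], index=drugs,
                         columns=lines, dtype=float),
        dependency=pd.DataFrame([dep_rows[g] for g in genes], index=genes,
                                columns=lines, dtype=float),
        annotations=annotations)
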