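import numpy as np
import pandas as pd
import pytest

from coldcre.models import HyperparameterGrid
from coldcre.pipeline import PipelineConfig, analyze_models
from coldcre.simulate import PlantedMotif, SimulationConfig, generate_dataset

TIME_POINTS = ("0.5", "1", "3", "6", "16", "24")

# scaled-down study conditions for the planted-motif recovery session:
# short regions, elevated responsive fractions and a reduced grid keep the
# full six-time-point modelling chain tractable on one CPU while preserving
# the planting rates (p_signal=0.8, p_background=0.05)
RECOVERY_SEEDS = (1, 2, 3, 4, 5)
MOTIF_GENERAL = "GATTACA"   # planted at every time point
MOTIF_LATE = "CCACGTG"      # planted only at 24 hr


def recovery_config(seed: int) -> PipelineConfig:
    return PipelineConfig(
        simulation=SimulationConfig(
            n_genes=3000,
            upstream_len=300,
            body_len_range=(200, 500),
            downstream_len=200,
            responsive_fraction_per_timepoint=(0.26, 0.27, 0.28, 0.29, 0.30, 0.31),
            down_fraction_per_timepoint=(0.05,) * 6,
            other_condition_fraction=0.05,
            persistence=0.3,
            planted_motifs=[
                PlantedMotif(MOTIF_GENERAL, TIME_POINTS, 0.8, 0.05),
                PlantedMotif(MOTIF_LATE, ("24",), 0.8, 0.05),
            ],
            seed=seed,
        ),
        grid=HyperparameterGrid(max_depth=(3, 10), max_features=("sqrt", 0.5),
                                n_estimators=(10, 100)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_runs():
    """Full modelling chains over several simulation seeds, shared by the
    planted-motif recovery and categorisation tests."""
    runs = {}
    for seed in RECOVERY_SEEDS:
        cfg = recovery_config(seed)
        genes, de, library, truth = generate_dataset(cfg.simulation)
        labels, tpmodels = analyze_models(genes, de, cfg)
        runs[seed] = {"labels": labels, "models": tpmodels}
    return runs


def make_de(records, time_points=TIME_POINTS, conditions=("dehydration",)):
    """DE table from {gene: {(cond, time): (log2fc, adj_p)}} with null
    defaults for unspecified cells."""
    rows = []
    for gene, cells in records.items():
        for tp in time_points:
            lfc, p = cells.get(("cold", tp), (0.0, 1.0))
            rows.append((gene, "cold", tp, lfc, p))
        for cond in conditions:
            lfc, p = cells.get((cond, "NA"), (0.0, 1.0))
            rows.append((gene, cond, "NA", lfc, p))
    return pd.DataFrame(rows, columns=["gene_id", "condition", "time",
                                       "log2FC", "adj_p"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
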