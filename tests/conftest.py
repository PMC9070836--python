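import numpy as np
import pytest

from dodderlign.simulate.expression import ClusterPlan, ExprSimSpec, simulate_counts
from dodderlign.simulate.sections import SectionSpec, render_section

FOUR_CULTIVARS = ("H1706", "H9775", "H9492", "H9553")
RESISTANT = ("H9492", "H9553")


@pytest.fixture(scope="session")
def small_section():
    """One moderately stained 256x256 section with ground truth."""
    spec = SectionSpec(
        image_size=(256, 256),
        radius_pith=35.0,
        radius_xylem_inner=40.0,
        radius_xylem_outer=60.0,
        radius_cortex_inner=68.0,
        radius_cortex_outer=95.0,
        radius_epidermis=100.0,
        cortex_stain_fraction=0.4,
        seed=42,
    )
    return render_section(spec)


def four_cultivar_spec(**kwargs) -> ExprSimSpec:
    """The study design: four cultivars x two conditions x 3 replicates."""
    defaults = dict(
        n_genes=1000,
        strata=[
            (g, c, 3) for g in FOUR_CULTIVARS for c in ("uninfested", "infested")
        ],
    )
    defaults.update(kwargs)
    return ExprSimSpec(**defaults)


def interaction_cluster(size=50, shift=4.0) -> ClusterPlan:
    """Genes shifted on infestation in the resistant cultivars only."""
    return ClusterPlan(size, {(g, "infested"): shift for g in RESISTANT})


@pytest.fixture(scope="session")
def null_counts():
    """1000 genes, no planted structure."""
    return simulate_counts(four_cultivar_spec(seed=11))[0]


@pytest.fixture(scope="session")
def planted_counts():
    """1000 genes with one 50-gene interaction cluster (log2 shift 4)."""
    return simulate_counts(
        four_cultivar_spec(cluster_plan=[interaction_cluster()], seed=12)
    )
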