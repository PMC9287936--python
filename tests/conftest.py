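import numpy as np
import pytest
from hypothesis import settings

from mqtlmap.core import CoordSystem, QTLRecord, Trait
from mqtlmap.projection import ProjectedQTL, Provenance
from mqtlmap.simulate import SimulationScenario, simulate, write_bundle

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def small_scenario(seed: int = 42, **overrides) -> SimulationScenario:
    """A scaled-down study for fast end-to-end tests."""
    params = dict(
        seed=seed,
        n_chromosomes=4,
        ref_markers_per_group=60,
        group_length=300.0,
        chromosome_bp=5e7,
        n_experiments=10,
        n_mapped_experiments=6,
        n_snp_experiments=1,
        n_gdr_qtls=30,
        n_gwc_qtls=45,
        n_gdr_loci=6,
        n_gwc_loci=9,
        gdr_groups=("2", "3"),
        gwc_groups=("1", "2", "3", "4"),
        genes_per_chromosome=80,
    )
    params.update(overrides)
    return SimulationScenario(**params)


@pytest.fixture(scope="session")
def sim_data():
    return simulate(small_scenario())


@pytest.fixture(scope="session")
def bundle_dir(sim_data, tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    write_bundle(sim_data, out)
    return out


def make_projected(
    qtl_id: str,
    experiment_id: str,
    group: str,
    peak: float,
    ci_width: float,
    r_squared: float | None = 0.1,
    trait: Trait = Trait.GDR,
) -> ProjectedQTL:
    """A hand-built projected QTL for unit tests of the meta layer."""
    record = QTLRecord(
        qtl_id=qtl_id,
        trait=trait,
        experiment_id=experiment_id,
        linkage_group=group,
        peak_pos=peak,
        ci_start=peak - ci_width / 2,
        ci_end=peak + ci_width / 2,
        lod=3.0,
        r_squared=r_squared,
        coord_system=CoordSystem.GENETIC,
    )
    return ProjectedQTL(
        source=record,
        linkage_group=group,
        peak_pos=peak,
        ci_start=peak - ci_width / 2,
        ci_end=peak + ci_width / 2,
        provenance=Provenance.BOTH_FLANKS,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
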