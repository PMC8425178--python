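import pytest

from mitocms.simulate import CoreGeneSpec, PlantedOrf, SimConfig, simulate_pair
from mitocms.synteny import chain_anchors, classify_blocks, find_anchors, unique_regions

SMALL_CORE = (
    CoreGeneSpec("atpA", 300, position_fraction=0.15),
    CoreGeneSpec("atp8", 77, position_fraction=0.04),
    CoreGeneSpec("trnfM", 24, kind="trna", position_fraction=0.55),
    CoreGeneSpec("cox1", 200, position_fraction=0.62),
)


def small_config(seed: int = 11, **overrides) -> SimConfig:
    """A reduced three-block plan that still exercises translocation,
    inversion, two unique regions and two planted ORFs."""
    fields = dict(
        genome_length=20_000,
        n_blocks=3,
        block_fractions=(0.45, 0.25, 0.30),
        cms_order=(1, 3, 2),
        inverted=(3,),
        unique_lengths=(2500, 1800),
        unique_after=(0, 1),
        maintainer_spacer=2500,
        planted_orfs=(
            PlantedOrf(138, "left_edge", 0, tm_segments=1,
                       cotx_partner="atp8"),
            PlantedOrf(102, "interior", 1, offset_fraction=0.5),
        ),
        core_genes=SMALL_CORE,
        seed=seed,
    )
    fields.update(overrides)
    return SimConfig(**fields)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    maintainer, cms, truth = simulate_pair(cfg)
    return cfg, maintainer, cms, truth


@pytest.fixture(scope="session")
def small_blocks(small_sim):
    _, maintainer, cms, _ = small_sim
    anchors = find_anchors(cms, maintainer)
    blocks = classify_blocks(chain_anchors(anchors, query=cms,
                                           subject=maintainer))
    regions = unique_regions(blocks, cms)
    return anchors, blocks, regions


@pytest.fixture(scope="session")
def default_sim():
    """The full default plan (study-sized unique regions, four planted ORFs)."""
    cfg = SimConfig(seed=0)
    maintainer, cms, truth = simulate_pair(cfg)
    return cfg, maintainer, cms, truth


@pytest.fixture(scope="session")
def default_blocks(default_sim):
    _, maintainer, cms, _ = default_sim
    anchors = find_anchors(cms, maintainer)
    blocks = classify_blocks(chain_anchors(anchors, query=cms,
                                           subject=maintainer))
    regions = unique_regions(blocks, cms)
    return anchors, blocks, regions
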