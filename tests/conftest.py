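import dataclasses

import pytest

from cooccur.datamodel import (
    EpiphyteRecord,
    ForestDataset,
    LianaRecord,
    TreeRecord,
)
from cooccur.synthetic import StandParams, generate_stand


@pytest.fixture
def tiny_ds():
    """Three trees, two patches, hand-checkable records."""
    trees = [
        TreeRecord("T1", "A", "p01", "Ocotea porphyria", 45.0),
        TreeRecord("T2", "A", "p01", "Eugenia uniflora", 12.0),
        TreeRecord("T3", "B", "p01", "Tecoma stans", 20.5, x=3.0, y=4.0),
    ]
    lianas = [
        LianaRecord("T1", "Cissus striata", 2.0, "specialized", "trunk"),
        LianaRecord("T1", "Quechualia fulta", 1.5, "leaning", "crown"),
        LianaRecord("T2", "Cissus striata", 1.0, "specialized", "trunk"),
    ]
    epiphytes = [
        EpiphyteRecord("T1", "Pleopeltis tweediana", 3, frozenset({"trunk", "crown"})),
        EpiphyteRecord("T3", "Aechmea distichantha", 1, frozenset({"crown"})),
    ]
    meta = {"A": {"forest_type": "successional"}, "B": {"forest_type": "mature"}}
    ds = ForestDataset(trees, lianas, epiphytes, meta)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def small_stand():
    """A compact generated stand with both forest types and a mapped patch."""
    params = StandParams(
        n_patches=3,
        plots_per_patch=4,
        patch_types={
            "Cedro": "successional",
            "S1": "successional",
            "M1": "mature",
        },
        mapped_plots=4,
    )
    return generate_stand(params, seed=42)


@pytest.fixture(scope="session")
def recovery_params():
    """Stand parameters for host-model parameter recovery (~1000 trees)."""
    return StandParams(
        n_patches=8,
        plots_per_patch=8,
        patch_types={f"S{i}": "successional" for i in range(5)}
        | {f"M{i}": "mature" for i in range(3)},
        mapped_patch="none",
    )


@pytest.fixture
def zeroed_effects_params(recovery_params):
    """Same design but with all tree-species effects set to zero."""
    pool = [
        dataclasses.replace(s, liana_effect=0.0, epi_effect=0.0)
        for s in recovery_params.tree_species_pool
    ]
    return dataclasses.replace(recovery_params, tree_species_pool=pool)
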