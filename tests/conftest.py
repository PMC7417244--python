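import numpy as np
import pandas as pd
import pytest

from timema_ecoevo.io import ArthropodIndividual, MorphCounts, PlantPatch


@pytest.fixture
def square_plants():
    """Four plants on a small square, alternating hosts, full geometry."""
    return [
        PlantPatch("p1", "A", 0.0, 0.0, 2.0, 2.0, 1.0, 2013, 48.0, 2.0),
        PlantPatch("p2", "C", 3.0, 4.0, 1.0, 1.0, 1.0, 2013, 46.0, 2.5),
        PlantPatch("p3", "A", 10.0, 0.0, 0.5, 2.0, 4.0, 2013, 47.0, 1.5),
        PlantPatch("p4", "C", 10.0, 10.0, 1.5, 1.5, 2.0, 2013, 49.0, 2.2),
    ]


@pytest.fixture
def mixed_morphs():
    return MorphCounts("p1", n_striped=3, n_unstriped=7, n_melanic=2)


def make_individuals(plant_id, lengths, morphospecies="m1", masses=None):
    masses = masses if masses is not None else [None] * len(lengths)
    return [
        ArthropodIndividual(
            plant_id=plant_id,
            morphospecies_id=morphospecies if isinstance(morphospecies, str) else morphospecies[i],
            length_mm=length,
            wet_mass_mg=masses[i],
            mass_source="measured" if masses[i] is not None else "predicted",
        )
        for i, length in enumerate(lengths)
    ]


@pytest.fixture
def plants_csv(tmp_path):
    path = tmp_path / "plants.csv"
    pd.DataFrame(
        {
            "plant_id": ["001", "002"],
            "host": ["A", "C"],
            "x": [0.0, 3.0],
            "y": [0.0, 4.0],
            "length_m": [2.0, 1.0],
            "width_m": [2.0, 1.0],
            "height_m": [1.0, 1.0],
            "size_year": [2013, 2013],
            "pct_carbon": [48.0, 46.0],
            "pct_nitrogen": [2.0, 2.5],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def rng(request):
    # deterministic per test and per run, independent of execution order
    import hashlib

    seed = int(hashlib.sha256(request.node.name.encode()).hexdigest()[:8], 16)
    return np.random.default_rng(seed)
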