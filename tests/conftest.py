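import numpy as np
import pytest

import histomorph as hm
from histomorph.synthetic_histology import palette_thresholds


@pytest.fixture(scope="session")
def thresholds():
    return palette_thresholds()


@pytest.fixture(scope="session")
def plain_section():
    """A nucleus-free 50/300/200 μm section with its ground truth."""
    layers = hm.default_layers(50.0, 300.0, 200.0)
    return hm.generate_skin_section(
        layers, nuclei=hm.NucleusField(density=0), seed=7, width_um=1600
    )


@pytest.fixture(scope="session")
def nucleus_section():
    """A full-field tissue section carrying ~500 nuclei/mm²."""
    layers = [
        hm.LayerSpec("epidermis", 100.0),
        hm.LayerSpec("dermis", 500.0),
        hm.LayerSpec("hypodermis", 400.0),
    ]
    return hm.generate_skin_section(
        layers, nuclei=hm.NucleusField(density=500.0), seed=11, width_um=1000, margin_um=30
    )


@pytest.fixture(scope="session")
def mc_training_field():
    """12 resting + 12 activated mast cells with default granulation."""
    cells = [hm.resting_cell() for _ in range(12)] + [hm.activated_cell() for _ in range(12)]
    return hm.generate_mc_field(cells, seed=42, field_um=(420.0, 420.0))


def match_truth_labels(measurements, truth):
    """Truth label of the nearest ground-truth cell for each measurement."""
    labels = []
    for m in measurements:
        d = [
            np.hypot(m.centroid_um[0] - t["center_um"][0], m.centroid_um[1] - t["center_um"][1])
            for t in truth.mast_cells
        ]
        labels.append(truth.mast_cells[int(np.argmin(d))]["label"])
    return labels
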