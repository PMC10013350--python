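import dataclasses

import numpy as np
import pytest

from woundchip import fields, geometry, synthetic


@pytest.fixture(scope="session")
def straight_chip():
    """Straight channel rasterized at the default working resolution."""
    net = geometry.build_layout("straight")
    cmap = geometry.rasterize(net, 0.1)
    cfg = geometry.default_electrodes(net, "uni_directional", 25.0)
    return net, cmap, cfg


@pytest.fixture(scope="session")
def straight_solution(straight_chip):
    _, cmap, cfg = straight_chip
    return fields.solve_field(cmap, cfg)


@pytest.fixture(scope="session")
def tiny_params():
    """Small, fast simulation domain (72 frames) for image-pipeline tests."""
    return dataclasses.replace(
        synthetic.scenario_params("control", seed=3),
        n_cells_per_sheet=60,
        domain_px=(192, 192),
        gap_px=64.0,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_params):
    return synthetic.simulate_collective(tiny_params)


@pytest.fixture(scope="session")
def tiny_stack(tiny_truth):
    return synthetic.render_stack(tiny_truth)


@pytest.fixture(scope="session")
def control_run():
    """Full-size healthy-control run used by the end-to-end checks."""
    truth = synthetic.simulate_collective(synthetic.scenario_params("control", seed=1))
    stack = synthetic.render_stack(truth)
    return truth, stack


def iou(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0
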