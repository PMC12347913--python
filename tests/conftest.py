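import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from nephromorph import (
    Calibration,
    LabeledSection,
    default_taxonomy,
    donor_like_spec,
    generate,
)
from nephromorph.taxonomy import TISSUE


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def donor_scene():
    """One donor-like synthetic scene shared by read-only tests."""
    return generate(donor_like_spec(seed=11))


def build_section(
    masks: dict[str, np.ndarray],
    mpp: float = 0.5,
    capsule: np.ndarray | None = None,
    tissue: np.ndarray | None = None,
    kind: str = "needle-core",
) -> LabeledSection:
    """Assemble a minimal section; the tissue layer defaults to the union
    of all provided masks (so nesting inside Tissue always holds)."""
    layers = dict(masks)
    if TISSUE not in layers:
        if tissue is None:
            tissue = np.zeros(next(iter(layers.values())).shape, dtype=bool)
            for m in layers.values():
                tissue |= m
        layers[TISSUE] = tissue
    return LabeledSection(
        taxonomy=default_taxonomy(),
        calibration=Calibration(microns_per_pixel=mpp),
        masks=layers,
        capsule=capsule,
        kind=kind,
    )
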