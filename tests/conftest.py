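import numpy as np
import pytest

from dentinechron.increments import IncrementTransect, SectionPlane


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def make_transect(widths, gaps=(), tooth_id="t", plane=SectionPlane.TR, start=0.0):
    """Transect from a sequence of increment widths."""
    pos = np.concatenate([[start], start + np.cumsum(widths)])
    return IncrementTransect(
        tooth_id=tooth_id,
        plane=plane,
        boundary_positions=tuple(pos.tolist()),
        gaps=tuple(gaps),
    )


@pytest.fixture
def uniform_transect():
    """10 uniform 12-µm increments: boundaries 0, 12, ..., 120."""
    return make_transect([12.0] * 10)
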