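import numpy as np
import pytest

from disco import TemplateGrid, Tractogram


@pytest.fixture
def grid16():
    return TemplateGrid.isotropic(16, 1.0)


@pytest.fixture
def grid32():
    return TemplateGrid.isotropic(32, 1.0)


def straight_streamline(y, z, x0=2.0, x1=13.0, n=12):
    """A streamline parallel to the x axis at fixed (y, z)."""
    xs = np.linspace(x0, x1, n)
    return np.column_stack([xs, np.full(n, float(y)), np.full(n, float(z))])


@pytest.fixture
def crossing_phantom(grid16):
    """10 controls: bundle A (all 10 identical) plus bundle B, which
    crosses a mid-grid lesion in 6 controls and is shifted away in 4.

    Returns (controls, lesion, expected probability pattern pieces).
    """
    bundle_a = [straight_streamline(7, 7), straight_streamline(7, 8)]
    bundle_b = [straight_streamline(8, 7)]
    bundle_b_shifted = [straight_streamline(12, 12)]
    controls = []
    for i in range(10):
        b = bundle_b if i < 6 else bundle_b_shifted
        controls.append(Tractogram(streamlines=[s.copy() for s in bundle_a + b]))
    lesion = np.zeros(grid16.shape, dtype=bool)
    lesion[6:9, 7:9, 7:9] = True  # covers A and the unshifted B corridor
    lesion[:, 12, 12] = False
    return controls, lesion
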