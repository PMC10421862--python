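import numpy as np
import pytest

from deltarad.regions import extract_peritumoral_rim
from deltarad.synthetic import CohortConfig, generate_phantom


@pytest.fixture(scope="session")
def tiny_config():
    """A small, fast phantom configuration used across tests."""
    return CohortConfig(n_patients=4, shape=(40, 40, 14), spacing=(1.0, 1.0, 3.0),
                        lesion_radius_mm=(4.0, 7.0), seed=7)


@pytest.fixture(scope="session")
def phantom(tiny_config):
    return generate_phantom(tiny_config, 0, "pre")


@pytest.fixture(scope="session")
def region_pair(phantom):
    volume, mask = phantom
    return extract_peritumoral_rim(volume, mask)


def brute_force_glcm(slice2d, region2d, levels, offset):
    """Independent GLCM oracle: explicit loop over every pixel pair."""
    from deltarad.texture import quantize

    q = quantize(np.asarray(slice2d, dtype=float),
                 np.asarray(region2d) > 0, levels)
    H, W = q.shape
    dr, dc = offset
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and q[r, c] >= 0 and q[r2, c2] >= 0:
                counts[q[r, c], q[r2, c2]] += 1
    counts = counts + counts.T
    return counts / counts.sum() if counts.sum() else counts
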