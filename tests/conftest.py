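import numpy as np
import pytest

from vascuquant.roi import RoiPolygon


@pytest.fixture
def node_roi():
    return RoiPolygon([(10, 10), (40, 60)], role="node_A", plane="longitudinal")


@pytest.fixture
def parenchyma_roi():
    return RoiPolygon([(10, 70), (40, 120)], role="parenchyma_B",
                      plane="longitudinal")


def point_in_polygon(r: float, c: float, vertices) -> bool:
    """Independent even-odd (ray casting) point-in-polygon test.

    Casts a ray in +c direction; points exactly on an edge are excluded
    (strict inequality), matching the strict-interior pixel-center rule.
    """
    inside = False
    n = len(vertices)
    for i in range(n):
        r1, c1 = vertices[i]
        r2, c2 = vertices[(i + 1) % n]
        if (r1 > r) != (r2 > r):
            c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
            if c < c_int:
                inside = not inside
    return inside


def brute_force_mask(vertices, shape) -> np.ndarray:
    """Loop-based rasterization oracle over all pixel centers."""
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            mask[r, c] = point_in_polygon(r + 0.5, c + 0.5, vertices)
    return mask
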