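import numpy as np
import pytest

from sbemkit import simulate


@pytest.fixture(scope="session")
def worked_example_texture():
    """Band-limited 1536^2 texture large enough to carve 1024^2 tiles with
    a few hundred pixels of displacement margin."""
    return simulate.gen_texture(
        simulate.TextureSpec(1536, 1536, correlation_length=4.0, seed=1))


@pytest.fixture(scope="session")
def small_texture():
    return simulate.gen_texture(
        simulate.TextureSpec(320, 320, correlation_length=3.0, seed=7))


@pytest.fixture(scope="session")
def ground_truth_skeleton():
    """A 3-branch tree (~25 um of path, nm coordinates)."""
    return simulate.gen_skeleton(3, seed=11)


def spatial_ncc_offset(image_a, image_b, max_offset, floor_frac=0.005):
    """Brute-force oracle: windowed Pearson correlation per lag, computed
    with plain spatial slicing, peak over the search window. Mirrors the
    definition of the production estimator but shares no code with it."""
    a = np.asarray(image_a, float)
    b = np.asarray(image_b, float)
    h, w = a.shape
    floor = max(64.0, floor_frac * h * w)
    best = (-np.inf, None)
    for dy in range(-max_offset, max_offset + 1):
        for dx in range(-max_offset, max_offset + 1):
            ya0, yb0 = max(0, dy), max(0, -dy)
            xa0, xb0 = max(0, dx), max(0, -dx)
            hh, ww = h - abs(dy), w - abs(dx)
            if hh * ww < floor:
                continue
            wa = a[ya0:ya0 + hh, xa0:xa0 + ww]
            wb = b[yb0:yb0 + hh, xb0:xb0 + ww]
            va = wa - wa.mean()
            vb = wb - wb.mean()
            denom = np.sqrt((va * va).sum() * (vb * vb).sum())
            if denom <= 1e-8 * h * w:
                continue
            score = float((va * vb).sum() / denom)
            key = (score, -(dx * dx + dy * dy))
            if best[1] is None or key > best[0]:
                best = (key, (dx, dy))
    return best[1]
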