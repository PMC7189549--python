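import numpy as np
import pytest

from plaquescope.synthetic import SyntheticSlideSpec


def flood_fill_count(raster, connectivity=8):
    """Independent connected-component counter: iterative flood fill."""
    raster = np.asarray(raster, dtype=bool)
    h, w = raster.shape
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    seen = np.zeros_like(raster, dtype=bool)
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if raster[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and raster[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


@pytest.fixture(scope="session")
def small_slide_spec():
    """Default-geometry slide (4096 px, heatmap 241 x 241), seed 7."""
    return SyntheticSlideSpec(seed=7)


@pytest.fixture(scope="session")
def rendered_slide():
    """A 1024 px rendered slide image plus ground truth (session-cached)."""
    from plaquescope.synthetic import generate_slide_image

    spec = SyntheticSlideSpec(width_px=1024, height_px=1024, seed=3)
    return generate_slide_image(spec)
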