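"""Shared fixtures: small deterministic images and point sets."""

import numpy as np
import pytest

from woundkit.synthetic import SyntheticWoundSpec, make_synthetic_wound


@pytest.fixture(scope="session")
def default_wound():
    """One default-condition synthetic wound image with its ground truth."""
    return make_synthetic_wound(SyntheticWoundSpec(seed=0))


@pytest.fixture(scope="session")
def default_segmentation(default_wound):
    from woundkit.pipeline import segment_wound

    img, _truth = default_wound
    return segment_wound(img)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_mask(rng, shape=(16, 16), density=0.3):
    return rng.random(shape) < density


def flood_fill_components(mask, connectivity=8):
    """Brute-force connected components by explicit flood fill.

    Independent of the implementation: visits foreground pixels in row-major
    order and grows each component with a stack.
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and labels[nr, nc] == 0:
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels, current
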