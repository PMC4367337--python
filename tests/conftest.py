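import numpy as np
import pytest

from canopylai.imaging import BinaryCanopyMask


@pytest.fixture
def rng():
    return np.random.default_rng(20150228)


@pytest.fixture
def random_mask_factory(rng):
    """Random binary masks of random sizes for oracle-equivalence tests."""

    def make(min_side=7, max_side=40, p_foliage=None):
        h = int(rng.integers(min_side, max_side + 1))
        w = int(rng.integers(min_side, max_side + 1))
        p = float(rng.uniform(0.1, 0.9)) if p_foliage is None else p_foliage
        grid = rng.random((h, w)) < p
        return BinaryCanopyMask(grid, threshold_used=128)

    return make


def brute_force_gap_counts(mask, subdivision, big_gap_ratio):
    """Independent per-pixel / per-sub-image reimplementation of the big-gap
    rule, using explicit loops and the same near-equal tiling boundaries."""
    grid = mask.is_foliage
    h, w = grid.shape

    def edges(n, parts):
        base, extra = divmod(n, parts)
        sizes = [base + 1] * extra + [base] * (parts - extra)
        out = [0]
        for s in sizes:
            out.append(out[-1] + s)
        return out

    re_, ce = edges(h, subdivision), edges(w, subdivision)
    g_T = g_L = 0
    for i in range(subdivision):
        for j in range(subdivision):
            sky = leaves = 0
            for r in range(re_[i], re_[i + 1]):
                for c in range(ce[j], ce[j + 1]):
                    if grid[r, c]:
                        leaves += 1
                    else:
                        sky += 1
            g_T += sky
            if leaves == 0 or sky / leaves > big_gap_ratio:
                g_L += sky
    return g_T, g_L, h * w
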