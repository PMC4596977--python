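"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def brute_region_query(mask, x: int, y: int, eps: int) -> set[int]:
    """Exhaustive scan of every pixel, testing |dx|+|dy| <= eps.

    Deliberately naive (nested lists, no vectorization): the oracle for the
    windowed region query.
    """
    h, w = len(mask), len(mask[0])
    hits = set()
    for yy in range(h):
        for xx in range(w):
            if mask[yy][xx] and abs(xx - x) + abs(yy - y) <= eps:
                hits.add(yy * w + xx)
    return hits


def brute_neighbor_count(mask, x: int, y: int, eps: int) -> int:
    """Per-pixel density recomputed from first principles (offset loop)."""
    h, w = len(mask), len(mask[0])
    n = 0
    for dy in range(-eps, eps + 1):
        for dx in range(-(eps - abs(dy)), eps - abs(dy) + 1):
            xx, yy = x + dx, y + dy
            if 0 <= xx < w and 0 <= yy < h and mask[yy][xx]:
                n += 1
    return n


@pytest.fixture
def solid_block():
    """Factory for solid rectangular node masks with a margin of background."""

    def _make(height: int, width: int, margin: int = 3) -> np.ndarray:
        mask = np.zeros((height + 2 * margin, width + 2 * margin), dtype=bool)
        mask[margin : margin + height, margin : margin + width] = True
        return mask

    return _make


def random_sweep_cases(n_cases: int, seed: int = 20259):
    """Seeded (mask, eps, min_pts) study conditions for equivalence sweeps.

    Mask sizes 32-128 px per side, node densities 0.2-0.7, eps in {1,2,3}
    and min_pts in {2,4} cycled so every combination is exercised.
    """
    from dermborder.fixtures import FixtureSpec, make_random_mask

    rng = np.random.default_rng(seed)
    combos = [(1, 2), (1, 4), (2, 2), (2, 4), (3, 2), (3, 4)]
    cases = []
    for i in range(n_cases):
        h = int(rng.integers(32, 129))
        w = int(rng.integers(32, 129))
        density = float(rng.uniform(0.2, 0.7))
        mask = make_random_mask(
            FixtureSpec(kind="random_mask", seed=int(rng.integers(2**31)), width=w, height=h, density=density)
        )
        eps, min_pts = combos[i % len(combos)]
        cases.append((mask, eps, min_pts))
    return cases
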