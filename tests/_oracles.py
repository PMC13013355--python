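"""Independent brute-force oracles used by the test suite.

These deliberately avoid scipy/vectorized code paths: components are found by
breadth-first flood fill over explicit neighbour offsets, and overlap metrics
by plain voxel loops, so they share no code with the implementation under
test.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def neighbour_offsets(connectivity: int):
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        offs.append(d)
    return offs


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> list[set]:
    """Connected components of a boolean mask as sets of voxel tuples."""
    mask = np.asarray(mask) > 0
    offs = neighbour_offsets(connectivity)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if seen[idx]:
            continue
        comp = set()
        queue = deque([idx])
        seen[idx] = True
        while queue:
            cur = queue.popleft()
            comp.add(cur)
            for d in offs:
                nxt = tuple(c + o for c, o in zip(cur, d))
                if any(n < 0 or n >= s for n, s in zip(nxt, mask.shape)):
                    continue
                if mask[nxt] and not seen[nxt]:
                    seen[nxt] = True
                    queue.append(nxt)
        comps.append(comp)
    return comps


def dice_loop(a: np.ndarray, b: np.ndarray) -> float:
    """Dice by an explicit voxel loop; both-empty convention 1.0."""
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    inter = na = nb = 0
    for idx in itertools.product(*(range(s) for s in a.shape)):
        if a[idx]:
            na += 1
        if b[idx]:
            nb += 1
        if a[idx] and b[idx]:
            inter += 1
    if na + nb == 0:
        return 1.0
    return 2 * inter / (na + nb)


def fnv_fpv_loop(gt, pred, voxel_ml: float, connectivity: int = 26):
    """Component-based FNV/FPV in mL by flood fill + per-voxel overlap checks."""
    gt = np.asarray(gt) > 0
    pred = np.asarray(pred) > 0
    fnv = sum(
        len(comp) for comp in bfs_components(gt, connectivity)
        if not any(pred[v] for v in comp)
    )
    fpv = sum(
        len(comp) for comp in bfs_components(pred, connectivity)
        if not any(gt[v] for v in comp)
    )
    return fnv * voxel_ml, fpv * voxel_ml


def random_mask_pair(rng: np.random.Generator, max_side: int = 20):
    """A random mask pair on a shared small grid, with varied density."""
    shape = tuple(int(rng.integers(3, max_side + 1)) for _ in range(3))
    p1, p2 = rng.uniform(0.0, 0.35, size=2)
    a = rng.random(shape) < p1
    b = rng.random(shape) < p2
    return a.astype(np.uint8), b.astype(np.uint8)
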