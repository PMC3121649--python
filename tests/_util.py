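"""Independent oracles and small helpers shared by the test modules.

Everything here is deliberately implemented by a different mechanism than
the package code it checks (explicit loops / shifted views / flood fill /
exhaustive assignment), so the tests compare two independent routes.
"""

from __future__ import annotations

import itertools

import numpy as np

from neuromorph import analyze_particles


def neighbor_counts_by_shifts(mask: np.ndarray) -> np.ndarray:
    """Foreground-neighbor counts via 8 explicit shifted views of a padded copy."""
    p = np.pad(mask.astype(np.int32), 1)
    out = np.zeros_like(mask, dtype=np.int32)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            out += p[1 + dr : 1 + dr + mask.shape[0], 1 + dc : 1 + dc + mask.shape[1]]
    return out


def erode_oracle(mask: np.ndarray, count: int) -> np.ndarray:
    """Count-based erosion: >= count background neighbors removes the pixel."""
    bg = 8 - neighbor_counts_by_shifts(mask)
    return mask & (bg < count)


def dilate_oracle(mask: np.ndarray, count: int) -> np.ndarray:
    """Count-based dilation: >= count foreground neighbors sets the pixel."""
    return mask | (neighbor_counts_by_shifts(mask) >= count)


def erode_oracle_loops(mask: np.ndarray, count: int) -> np.ndarray:
    """Pure-Python per-pixel erosion oracle (slow; for small masks)."""
    h, w = mask.shape
    out = mask.copy()
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            bg = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                        bg += 1
            if bg >= count:
                out[r, c] = False
    return out


def flood_fill_components(mask: np.ndarray) -> list[set[tuple[int, int]]]:
    """8-connected components by explicit BFS flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                comp = set()
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    pr, pc = stack.pop()
                    comp.add((pr, pc))
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = pr + dr, pc + dc
                            if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                                    and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                comps.append(comp)
    return comps


def optimal_tp(detected, truth, radius: float) -> int:
    """Exhaustive maximum-cardinality matching within radius (small inputs)."""
    det = np.asarray(detected, float).reshape(-1, 2)
    tru = np.asarray(truth, float).reshape(-1, 2)
    if not len(det) or not len(tru):
        return 0
    d = np.linalg.norm(det[:, None] - tru[None, :], axis=2) <= radius
    best = 0
    k = min(len(det), len(tru))
    # enumerate assignments of detected points to distinct truth points
    for subset in itertools.combinations(range(len(det)), k):
        for perm in itertools.permutations(range(len(tru)), k):
            tp = sum(1 for i, j in zip(subset, perm) if d[i, j])
            best = max(best, tp)
        if best == k:
            break
    return best


def centroids(mask: np.ndarray) -> list[tuple[float, float]]:
    return [p.centroid for p in analyze_particles(mask)]


def f1_score(ev) -> float:
    denom = 2 * ev.tp + ev.fp + ev.fn
    return 2 * ev.tp / denom if denom else 1.0


# published per-image detection counts used as worked-example inputs:
# (image id, manual Ma, detected Ne, TP, FP, FN, error %, accuracy %)
ATTACHMENT_TABLE = [
    (1, 15, 15, 15, 0, 0, 0, 100),
    (2, 12, 16, 12, 4, 0, 25, 100),
    (3, 12, 14, 11, 3, 1, 29, 92),
    (4, 9, 10, 9, 1, 0, 10, 100),
    (5, 13, 13, 13, 0, 0, 0, 100),
    (6, 11, 11, 11, 0, 0, 0, 100),
    (7, 12, 12, 12, 0, 0, 0, 100),
]
ATTACHMENT_AVERAGE = (9.08, 98.81)

ENDING_TABLE = [
    (1, 17, 17, 17, 0, 0, 0, 100),
    (2, 14, 19, 10, 9, 4, 68, 71),
    (3, 15, 29, 14, 15, 1, 55, 93),
    (4, 9, 12, 9, 3, 0, 25, 100),
    (5, 14, 14, 12, 2, 2, 29, 86),
    (6, 12, 12, 11, 1, 1, 17, 92),
    (7, 17, 19, 13, 6, 4, 53, 76),
]
ENDING_AVERAGE = (35.21, 88.37)
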