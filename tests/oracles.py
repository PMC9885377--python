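"""Independent brute-force oracles used to validate the package's fast paths.

Everything here is deliberately naive (loops, enumeration, BFS) and shares no
code with the implementation it checks.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def loop_confusion(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) by explicit iteration."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 1 and p == 0:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def rank_sum_statistic(values, idx_a) -> float:
    """Rank sum of sample A with midranks for ties, computed by sorting."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return sum(ranks[i] for i in idx_a)


def exact_rank_sum_p(a, b) -> float:
    """Exact two-sided permutation p-value of the rank-sum statistic.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to sample A
    and counts assignments whose rank sum is at least as far from its null
    mean as the observed one.
    """
    values = list(a) + list(b)
    n1, n = len(a), len(a) + len(b)
    mean = n1 * (n + 1) / 2.0
    observed = abs(rank_sum_statistic(values, range(n1)) - mean)
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(rank_sum_statistic(values, idx) - mean) >= observed - 1e-9:
            count += 1
    return count / total


def flood_fill_interior_air(mask: np.ndarray) -> np.ndarray:
    """Keep true voxels not 6-connected to the grid border: BFS from faces."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    queue: deque = deque()
    it = np.ndindex(mask.shape)
    for idx in it:
        if mask[idx] and any(
            i in (0, s - 1) for i, s in zip(idx, mask.shape)
        ):
            if not visited[idx]:
                visited[idx] = True
                queue.append(idx)
    while queue:
        x, y, z = queue.popleft()
        for dx, dy, dz in (
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
        ):
            nx, ny, nz = x + dx, y + dy, z + dz
            if (
                0 <= nx < mask.shape[0]
                and 0 <= ny < mask.shape[1]
                and 0 <= nz < mask.shape[2]
                and mask[nx, ny, nz]
                and not visited[nx, ny, nz]
            ):
                visited[nx, ny, nz] = True
                queue.append((nx, ny, nz))
    return mask & ~visited


def pooled_t_scores(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature |t| with pooled variance, computed feature-by-feature."""
    scores = []
    for j in range(features.shape[1]):
        x0 = features[labels == 0, j]
        x1 = features[labels == 1, j]
        n0, n1 = len(x0), len(x1)
        s2 = (
            ((x0 - x0.mean()) ** 2).sum() + ((x1 - x1.mean()) ** 2).sum()
        ) / max(n0 + n1 - 2, 1)
        denom = np.sqrt(s2 * (1 / n0 + 1 / n1))
        diff = abs(x1.mean() - x0.mean())
        if denom == 0:
            scores.append(np.inf if diff > 0 else 0.0)
        else:
            scores.append(diff / denom)
    return np.array(scores)


def spanning_id_count(groups_by_subset: list[list[str]]) -> int:
    """Number of identifiers present in more than one subset (set arithmetic)."""
    sets = [set(g) for g in groups_by_subset]
    spanning = set()
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            spanning |= sets[i] & sets[j]
    return len(spanning)
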