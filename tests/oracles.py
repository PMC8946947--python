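"""Independent brute-force reference computations used as test oracles.

Everything here is written as plain nested loops straight from the textbook
definitions, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

NEIGHBORS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def masked_mean(data: np.ndarray, mask: np.ndarray) -> float:
    total = 0.0
    count = 0
    for idx in np.ndindex(data.shape):
        if mask[idx]:
            total += float(data[idx])
            count += 1
    return total / count


def glcm_pairs(levels: np.ndarray, ng: int, delta: int, angle) -> np.ndarray:
    """Symmetrized co-occurrence counts by exhaustive pair enumeration."""
    mat = np.zeros((ng, ng))
    off = tuple(delta * a for a in angle)
    shape = levels.shape
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        jdx = tuple(i + o for i, o in zip(idx, off))
        if all(0 <= j < n for j, n in zip(jdx, shape)) and levels[jdx] > 0:
            mat[levels[idx] - 1, levels[jdx] - 1] += 1
            mat[levels[jdx] - 1, levels[idx] - 1] += 1
    return mat


def glrlm_runs(levels: np.ndarray, ng: int, angle) -> np.ndarray:
    """Run-length counts: walk every maximal run along ``angle``."""
    shape = levels.shape
    runs = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        prev = tuple(i - a for i, a in zip(idx, angle))
        if (
            all(0 <= p < n for p, n in zip(prev, shape))
            and levels[prev] == levels[idx]
        ):
            continue  # not the start of a run
        length = 1
        cur = idx
        while True:
            nxt = tuple(c + a for c, a in zip(cur, angle))
            if all(0 <= x < n for x, n in zip(nxt, shape)) and levels[nxt] == levels[idx]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((levels[idx], length))
    max_len = max((r for _, r in runs), default=1)
    mat = np.zeros((ng, max_len))
    for level, length in runs:
        mat[level - 1, length - 1] += 1
    return mat


def glszm_zones(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone sizes via explicit 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0 or seen[idx]:
            continue
        level = levels[idx]
        stack = [idx]
        seen[idx] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for d in NEIGHBORS_26:
                nxt = tuple(c + o for c, o in zip(cur, d))
                if (
                    all(0 <= x < n for x, n in zip(nxt, shape))
                    and not seen[nxt]
                    and levels[nxt] == level
                ):
                    seen[nxt] = True
                    stack.append(nxt)
        zones.append((level, size))
    max_size = max((s for _, s in zones), default=1)
    mat = np.zeros((ng, max_size))
    for level, size in zones:
        mat[level - 1, size - 1] += 1
    return mat


def gldm_counts(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts by explicit neighborhood scanning (center excluded)."""
    shape = levels.shape
    entries = []
    for idx in np.ndindex(shape):
        if levels[idx] == 0:
            continue
        dep = 0
        for d in NEIGHBORS_26:
            nxt = tuple(c + o for c, o in zip(idx, d))
            if (
                all(0 <= x < n for x, n in zip(nxt, shape))
                and levels[nxt] > 0
                and abs(int(levels[nxt]) - int(levels[idx])) <= alpha
            ):
                dep += 1
        entries.append((levels[idx], dep))
    max_dep = max((d for _, d in entries), default=0)
    mat = np.zeros((ng, max_dep + 1))
    for level, dep in entries:
        mat[level - 1, dep] += 1
    return mat


def ngtdm_table(levels: np.ndarray, ng: int, delta: int) -> np.ndarray:
    """(n_i, p_i, s_i) by exhaustive enumeration of every Chebyshev offset.

    Accumulates neighbor sums and counts one explicit offset at a time
    (padded-array shifts), then reduces per level — a different algorithm
    from any separable-filter implementation.
    """
    shape = levels.shape
    pad = delta
    padded = np.pad(levels, pad)
    neigh_sum = np.zeros(shape, dtype=float)
    neigh_cnt = np.zeros(shape, dtype=int)
    for d in itertools.product(range(-delta, delta + 1), repeat=3):
        if d == (0, 0, 0):
            continue
        sl = tuple(slice(pad + o, pad + o + n) for o, n in zip(d, shape))
        shifted = padded[sl]
        inroi = shifted > 0
        neigh_sum += shifted * inroi
        neigh_cnt += inroi
    n = np.zeros(ng)
    s = np.zeros(ng)
    for idx in np.ndindex(shape):
        i = levels[idx]
        if i == 0 or neigh_cnt[idx] == 0:
            continue
        n[i - 1] += 1
        s[i - 1] += abs(float(i) - neigh_sum[idx] / neigh_cnt[idx])
    table = np.zeros((ng, 3))
    table[:, 0] = n
    if n.sum() > 0:
        table[:, 1] = n / n.sum()
    table[:, 2] = s
    return table


def pairwise_auc(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U by exhaustive pair counting."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def fisher_scores_direct(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fisher criterion per feature, straight from the weighted-variance formula."""
    classes = sorted(set(y))
    n, p = x.shape
    out = np.zeros(p)
    for r in range(p):
        mu = x[:, r].mean()
        num = 0.0
        den = 0.0
        for c in classes:
            xc = x[y == c, r]
            num += len(xc) * (xc.mean() - mu) ** 2
            den += len(xc) * xc.var()
        if den == 0:
            out[r] = np.inf if num > 0 else 0.0
        else:
            out[r] = num / den
    return out


def moments(x: np.ndarray) -> dict:
    """Population skewness/kurtosis by direct summation."""
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    return {
        "skewness": 0.0 if m2 == 0 else m3 / m2**1.5,
        "kurtosis": 0.0 if m2 == 0 else m4 / m2**2,
    }
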