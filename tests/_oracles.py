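"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive between-class-variance maximizer over all 256 levels."""
    g = np.round(gray).astype(int).ravel()
    best_t, best_v = 0, -1.0
    for t in range(256):
        lo, hi = g[g <= t], g[g > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / g.size, hi.size / g.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v + 1e-12:
            best_v, best_t = v, t
    return best_t


def brute_force_apoz(act: np.ndarray) -> np.ndarray:
    """Element-wise zero counting per channel (axis 1)."""
    out = []
    for c in range(act.shape[1]):
        vals = act[:, c].ravel()
        out.append(sum(1 for v in vals if v <= 0) / vals.size)
    return np.array(out)


def pair_counting_roc_auc(y, s):
    """O(n^2) concordant-pair oracle; ties count one half."""
    y, s = np.asarray(y), np.asarray(s)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exact_mwu_p(a, b):
    """Two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    n = len(pooled)
    mean_u = n_a * len(b) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n_a):
        grp = pooled[list(comb)]
        rest = np.delete(pooled, list(comb))
        u = sum(1 for x in grp for y in rest if x > y)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total
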