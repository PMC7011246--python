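"""Independent brute-force re-implementations used only as test oracles.

Everything here is written as plainly as possible — explicit pixel walks and
python loops — and stays independent of the vectorized implementations it
checks.
"""

from itertools import combinations

import numpy as np
from sklearn.svm import SVC

DIRS = {"0": (0, 1), "45": (-1, 1), "90": (-1, 0), "135": (-1, -1)}


def bf_glcm(levels, mask, n_levels, offset):
    """Symmetric normalized co-occurrence matrix by explicit pair walking."""
    dr, dc = offset
    nr, nc = levels.shape
    P = np.zeros((n_levels, n_levels), dtype=float)
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                P[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    P = P + P.T
    s = P.sum()
    return None if s == 0 else P / s


def bf_glcm_features(P):
    L = P.shape[0]
    feats = dict.fromkeys(
        ["contrast", "correlation", "energy", "homogeneity", "entropy", "dissimilarity"], 0.0
    )
    mu = sum((i + 1) * P[i, j] for i in range(L) for j in range(L))
    var = sum((i + 1 - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
    for i in range(L):
        for j in range(L):
            p = P[i, j]
            feats["contrast"] += p * (i - j) ** 2
            feats["energy"] += p * p
            feats["homogeneity"] += p / (1 + (i - j) ** 2)
            feats["dissimilarity"] += p * abs(i - j)
            if p > 0:
                feats["entropy"] -= p * np.log2(p)
            if var > 0:
                feats["correlation"] += (i + 1 - mu) * (j + 1 - mu) * p / var
    return feats


def _walk_runs(levels, mask, offset):
    """All maximal same-level masked runs along one direction, as (g, l) pairs."""
    dr, dc = offset
    nr, nc = levels.shape
    # starting points: cells whose predecessor along (dr, dc) is off-grid
    runs = []
    for r in range(nr):
        for c in range(nc):
            pr, pc = r - dr, c - dc
            if 0 <= pr < nr and 0 <= pc < nc:
                continue  # not a line start
            rr, cc = r, c
            cur, length = None, 0
            while 0 <= rr < nr and 0 <= cc < nc:
                g = levels[rr, cc] if mask[rr, cc] else 0
                if g == cur:
                    length += 1
                else:
                    if cur not in (None, 0):
                        runs.append((cur, length))
                    cur, length = g, 1
                rr += dr
                cc += dc
            if cur not in (None, 0):
                runs.append((cur, length))
    return runs


def bf_glrm_features(levels, mask, n_pixels, offset):
    runs = _walk_runs(levels, mask, offset)
    if not runs:
        return None
    n_r = len(runs)
    by_g, by_l = {}, {}
    for g, l in runs:
        by_g[g] = by_g.get(g, 0) + 1
        by_l[l] = by_l.get(l, 0) + 1
    return {
        "sre": sum(1 / l**2 for _, l in runs) / n_r,
        "lre": sum(l**2 for _, l in runs) / n_r,
        "gln": sum(v**2 for v in by_g.values()) / n_r,
        "rln": sum(v**2 for v in by_l.values()) / n_r,
        "rp": n_r / n_pixels,
        "lgre": sum(1 / g**2 for g, _ in runs) / n_r,
        "hgre": sum(g**2 for g, _ in runs) / n_r,
        "srlge": sum(1 / (g**2 * l**2) for g, l in runs) / n_r,
        "srhge": sum(g**2 / l**2 for g, l in runs) / n_r,
        "lrlge": sum(l**2 / g**2 for g, l in runs) / n_r,
        "lrhge": sum(g**2 * l**2 for g, l in runs) / n_r,
    }


def bf_avg(dicts):
    dicts = [d for d in dicts if d is not None]
    return {k: float(np.mean([d[k] for d in dicts])) for k in dicts[0]}


def bf_loo_accuracy(X, y, C=1.0):
    """Fold-wise-standardized LOO accuracy of an RBF SVM, written independently."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    hits = 0
    for i in range(n):
        idx = [j for j in range(n) if j != i]
        Xtr, ytr = X[idx], y[idx]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        clf = SVC(kernel="rbf", C=C, gamma="scale")
        clf.fit((Xtr - mu) / sd, ytr)
        if clf.predict(((X[i] - mu) / sd).reshape(1, -1))[0] == y[i]:
            hits += 1
    return hits / n


def bf_exhaustive_search(cols, X, y, tol=1e-3, max_k=3):
    """Brute-force subset search with the improvement-threshold stopping rule."""
    best_prev = 0.0
    levels = []
    selected, selected_acc = [], 0.0
    for k in range(1, max_k + 1):
        if best_prev >= 1.0:
            levels.append((k, None, None))
            break
        scored = []
        for subset in combinations(range(len(cols)), k):
            scored.append((bf_loo_accuracy(X[:, subset], y), subset))
        best_acc = max(s for s, _ in scored)
        best_subset = min(sub for s, sub in scored if s == best_acc)
        levels.append((k, [cols[i] for i in best_subset], best_acc))
        if best_acc - best_prev > tol:
            selected, selected_acc = [cols[i] for i in best_subset], best_acc
            best_prev = best_acc
        else:
            break
    return levels, selected, selected_acc
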