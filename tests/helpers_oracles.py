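"""Independent brute-force oracles shared across test modules.

Deliberately naive, loop-based implementations that never touch the package's
vectorized counting code.
"""

import numpy as np

from mammofuse.select import discretize


def glcm_pairs_oracle(codes, offset, levels):
    """Count symmetric co-occurrences by scanning every pixel pair."""
    H, W = codes.shape
    dr, dc = offset
    M = np.zeros((levels, levels))
    for i in range(H):
        for j in range(W):
            ii, jj = i + dr, j + dc
            if 0 <= ii < H and 0 <= jj < W:
                M[codes[i, j], codes[ii, jj]] += 1
                M[codes[ii, jj], codes[i, j]] += 1
    return M


def runs_oracle(codes, direction):
    """Enumerate maximal constant runs along one scan direction."""
    H, W = codes.shape
    steps = {"d0": (0, 1), "d90": (1, 0), "d135": (1, 1), "d45": (-1, 1)}
    dr, dc = steps[direction]
    starts = []
    for i in range(H):
        for j in range(W):
            pi, pj = i - dr, j - dc
            if not (0 <= pi < H and 0 <= pj < W):
                starts.append((i, j))
    runs = []
    for i0, j0 in starts:
        i, j = i0, j0
        line = []
        while 0 <= i < H and 0 <= j < W:
            line.append(codes[i, j])
            i, j = i + dr, j + dc
        k = 0
        while k < len(line):
            m = k
            while m < len(line) and line[m] == line[k]:
                m += 1
            runs.append((line[k], m - k))
            k = m
    return runs


def mi_oracle(a_codes, b_codes):
    """Plug-in MI in bits from the raw contingency table, term by term."""
    a_codes = np.asarray(a_codes)
    b_codes = np.asarray(b_codes)
    mi = 0.0
    for av in np.unique(a_codes):
        for bv in np.unique(b_codes):
            pab = np.mean((a_codes == av) & (b_codes == bv))
            if pab > 0:
                pa, pb = np.mean(a_codes == av), np.mean(b_codes == bv)
                mi += pab * np.log2(pab / (pa * pb))
    return mi


def mrmr_oracle(X, y, k, bins=4):
    """Exhaustive greedy search recomputing every mRMR objective from scratch."""
    n_feat = X.shape[1]
    codes = [discretize(X[:, j], bins) for j in range(n_feat)]
    ycodes = np.asarray(y)
    selected = []
    for step in range(k):
        best, best_val = None, -np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            rel = mi_oracle(codes[j], ycodes)
            if step == 0:
                val = rel
            else:
                val = rel - np.mean([mi_oracle(codes[j], codes[s]) for s in selected])
            if val > best_val:
                best, best_val = j, val
        selected.append(best)
    return selected
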