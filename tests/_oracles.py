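"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: plain loops, a naive
DP edit distance, and manually computed ranks.
"""

import numpy as np


def naive_levenshtein(a, b):
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[n]


def reference_denoise(uniques, minampsize, alpha):
    """Exhaustive re-implementation of the abundance-skew centroid rule."""
    centroids = []   # (seq, founder, size)
    for seq, a in uniques:
        eligible = []
        for ci, (cseq, founder, _) in enumerate(centroids):
            d = naive_levenshtein(seq, cseq)
            if d > 0 and a / founder <= 2.0 ** (-(alpha * d + 1)):
                eligible.append((d, -founder, ci))
        if eligible:
            ci = min(eligible)[2]
            cseq, founder, size = centroids[ci]
            centroids[ci] = (cseq, founder, size + a)
        elif a >= minampsize:
            centroids.append((seq, a, a))
    return sorted(((s, size) for s, _, size in centroids),
                  key=lambda kv: (-kv[1], kv[0]))


def reference_tmm(counts: np.ndarray) -> np.ndarray:
    """Independently coded textbook TMM (loops, manual average ranks)."""
    counts = counts[[i for i in range(counts.shape[0])
                     if counts[i].sum() > 0]]
    ncol = counts.shape[1]
    lib = counts.sum(axis=0).astype(float)
    uq = np.array([np.quantile(counts[:, j], 0.75) / lib[j]
                   for j in range(ncol)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    def avg_rank(values):
        order = np.argsort(values, kind="stable")
        ranks = np.empty(len(values), float)
        i = 0
        sorted_v = values[order]
        while i < len(values):
            j = i
            while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    factors = []
    for j in range(ncol):
        obs, refc = counts[:, j].astype(float), counts[:, ref].astype(float)
        both = (obs > 0) & (refc > 0)
        o, r = obs[both], refc[both]
        logr = np.log2((o / lib[j]) / (r / lib[ref]))
        abse = 0.5 * (np.log2(o / lib[j]) + np.log2(r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        if logr.size == 0 or np.max(np.abs(logr)) < 1e-6:
            factors.append(1.0)
            continue
        n = logr.size
        lo_l = np.floor(n * 0.3) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * 0.05) + 1
        hi_s = n + 1 - lo_s
        rr, re = avg_rank(logr), avg_rank(abse)
        keep = (rr >= lo_l) & (rr <= hi_l) & (re >= lo_s) & (re <= hi_s)
        if not keep.any():
            factors.append(1.0)
            continue
        factors.append(2.0 ** (np.sum(logr[keep] / w[keep])
                               / np.sum(1.0 / w[keep])))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))
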