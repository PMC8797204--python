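"""Independent oracles used by the test suite (never by the implementation)."""

import itertools

import numpy as np
from scipy import stats


def tmm_oracle(counts, logratio_trim=0.3, abs_trim=0.05):
    """Direct-formula TMM factors with sort-based trimming."""
    y = np.asarray(counts, dtype=float)
    lib = y.sum(axis=0)
    uq = np.array([np.percentile(col[col > 0], 75) for col in y.T]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    fs = []
    for k in range(y.shape[1]):
        o, r = y[:, k], y[:, ref]
        ok = (o > 0) & (r > 0)
        o, r = o[ok], r[ok]
        m = np.log2((o / lib[k]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[k]) * (r / lib[ref]))
        w = (lib[k] - o) / (lib[k] * o) + (lib[ref] - r) / (lib[ref] * r)
        if np.all(np.abs(m - m[0]) < 1e-10):
            fs.append(2 ** m[0])
            continue
        n = len(m)
        keep = np.ones(n, bool)
        for v, trim in ((m, logratio_trim), (a, abs_trim)):
            cut = int(np.floor(n * trim))
            order = np.argsort(v, kind="stable")
            keep[order[:cut]] = False
            keep[order[n - cut:]] = False
        fs.append(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep])))
    fs = np.asarray(fs)
    return fs / np.exp(np.mean(np.log(fs)))


def exact_rank_sum_p(a, b):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    ws = np.asarray(
        [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n1)]
    )
    p_lo = np.mean(ws <= w_obs + 1e-9)
    p_hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(p_lo, p_hi))


def union_find_stitch(spans, d):
    """Connected components of the gap graph (quadratic union-find)."""
    spans = sorted(spans)
    parent = list(range(len(spans)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(spans)):
        for j in range(i + 1, len(spans)):
            gap = max(spans[i][0], spans[j][0]) - min(spans[i][1], spans[j][1])
            if gap <= d:
                parent[find(i)] = find(j)
    comps = {}
    for i, (s, e) in enumerate(spans):
        comps.setdefault(find(i), []).append((s, e))
    return sorted((min(s for s, _ in c), max(e for _, e in c)) for c in comps.values())
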