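"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity by direct enumeration or
quadratic scanning, sharing no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_brute(p: np.ndarray) -> np.ndarray:
    """BH adjusted p by explicit min over all tail ratios."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for out_rank, idx in enumerate(order, start=1):
        # q_i = min over j >= rank(i) of m*p_(j)/j
        candidates = []
        for j_rank, j_idx in enumerate(order, start=1):
            if j_rank >= out_rank:
                candidates.append(m * p[j_idx] / j_rank)
        adj[idx] = min(1.0, min(candidates))
    return adj


def hypergeom_enum_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(n, col1)
    p = 0.0
    for k in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        if k >= a:
            p += comb(row1, k) * comb(n - row1, col1 - k) / denom
    return p


def wilcoxon_enum_p(x: np.ndarray, y: np.ndarray, alternative: str = "two-sided") -> float:
    """Exact rank-sum p by enumerating all C(n+m, n) rank assignments."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    assert len(np.unique(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = pooled.argsort().argsort() + 1.0
    w_obs = ranks[: len(x)].sum()
    n, m = len(x), len(y)
    ws = [
        sum(c)
        for c in itertools.combinations(range(1, n + m + 1), n)
    ]
    total = len(ws)
    ge = sum(w >= w_obs for w in ws) / total
    le = sum(w <= w_obs for w in ws) / total
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def scan_brute(matrix: np.ndarray, background: np.ndarray, seq: str, threshold: float):
    """Per-offset brute-force PWM scan of both strands.

    Returns a set of (start0, strand, rounded score) for hits >= threshold.
    """
    comp = str.maketrans("ACGT", "TGCA")
    L = matrix.shape[0]

    def score(window: str) -> float:
        s = 0.0
        for i, base in enumerate(window):
            if base not in "ACGT":
                return -np.inf
            s += np.log2(max(matrix[i, "ACGT".index(base)], 1e-9) / background["ACGT".index(base)])
        return s

    hits = set()
    for o in range(len(seq) - L + 1):
        w = seq[o : o + L].upper()
        for strand, ww in (("+", w), ("-", w.translate(comp)[::-1])):
            sc = score(ww)
            if sc >= threshold:
                hits.add((o, strand, round(sc, 6)))
    return hits


def threshold_enum(matrix: np.ndarray, background: np.ndarray, fpr: float, step: float = 0.01) -> float:
    """FPR threshold by full 4^L enumeration on the same score grid."""
    L = matrix.shape[0]
    lo = np.log2(np.maximum(matrix, 1e-9) / background[None, :])
    q = np.rint(lo / step).astype(int)
    probs: dict[int, float] = {}
    for word in itertools.product(range(4), repeat=L):
        s = sum(q[i, b] for i, b in enumerate(word))
        p = float(np.prod([background[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    lo_g, hi_g = min(probs), max(probs)
    for g in range(lo_g, hi_g + 2):
        tail = sum(p for k, p in probs.items() if k >= g)
        if tail <= fpr + 1e-12:
            return g * step
    raise AssertionError("unreachable")


def classify_oracle(me1, me3, pu1):
    """All-pairs O(n^2) promoter/enhancer labels for PU.1 intervals."""

    def any_overlap(iv, others):
        return any(
            iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end
            for o in others
        )

    labels = []
    for iv in pu1:
        a = any_overlap(iv, me1)
        b = any_overlap(iv, me3)
        labels.append("active_promoter" if (a and b) else "enhancer" if a else "neither")
    return labels


def assign_oracle(peaks, genes, window):
    """All-pairs distance-based peak -> gene assignment."""
    out = []
    for iv in peaks:
        hit = []
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            ws, we = g.tss - window, g.tss + window
            if iv.start < we and ws < iv.end:
                hit.append(g.gene_id)
        out.append(sorted(hit))
    return out


def overlap_fraction_oracle(a, b) -> float:
    if not list(a):
        return float("nan")
    n = 0
    for iv in a:
        if any(
            iv.chrom == o.chrom and iv.start < o.end and o.start < iv.end for o in b
        ):
            n += 1
    return n / len(list(a))


def simple_cycles_oracle(edges: set[tuple[str, str]], max_length: int):
    """All simple directed cycles up to max_length via DFS enumeration."""
    nodes = sorted({n for e in edges for n in e})
    succ = {n: sorted({t for s, t in edges if s == n}) for n in nodes}
    found = set()

    def dfs(path):
        last = path[-1]
        for nxt in succ[last]:
            if nxt == path[0]:
                cyc = tuple(path)
                i = min(range(len(cyc)), key=lambda k: cyc[k])
                found.add(cyc[i:] + cyc[:i])
            elif nxt not in path and len(path) < max_length:
                dfs(path + [nxt])

    for n in nodes:
        dfs([n])
    return sorted(found, key=lambda c: (len(c), c))
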