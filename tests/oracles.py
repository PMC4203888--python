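"""Independent brute-force oracles the unit tests check the pipeline against.

These deliberately re-derive results by direct enumeration rather than by
calling the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def brute_force_best_hit(hits, query, evalue_max):
    """Best subject for one query by full enumeration of the documented rule."""
    cand = {}
    for h in hits:
        if h.query_id != query or h.evalue > evalue_max:
            continue
        key = (h.evalue, -h.bitscore)
        if h.subject_id not in cand or key < cand[h.subject_id]:
            cand[h.subject_id] = key
    if not cand:
        return None
    best_key = min(cand.values())
    winners = [s for s, k in cand.items() if k == best_key]
    return winners[0] if len(winners) == 1 else None


def brute_force_rbh(hits_ab, hits_ba, evalue_max):
    queries_a = {h.query_id for h in hits_ab}
    queries_b = {h.query_id for h in hits_ba}
    pairs = []
    for a in queries_a:
        b = brute_force_best_hit(hits_ab, a, evalue_max)
        if b is not None and b in queries_b:
            if brute_force_best_hit(hits_ba, b, evalue_max) == a:
                pairs.append((a, b))
    return sorted(pairs)


class DisjointSet:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def union_find_components(rbh_pairs, links_a, links_b):
    """Cross-species components as (frozenset members_A, frozenset members_B) pairs."""
    dsu = DisjointSet()
    for ps, t in links_a.items():
        dsu.union(("psA", ps), ("tA", t))
    for ps, t in links_b.items():
        dsu.union(("psB", ps), ("tB", t))
    for a, b in rbh_pairs:
        dsu.union(("tA", a), ("tB", b))
    groups = {}
    for node in list(dsu.parent):
        groups.setdefault(dsu.find(node), []).append(node)
    out = set()
    for members in groups.values():
        mem_a = frozenset(n[1] for n in members if n[0] == "psA")
        mem_b = frozenset(n[1] for n in members if n[0] == "psB")
        if mem_a and mem_b:
            out.add((mem_a, mem_b))
    return out


def welch_direct(a, b):
    """Welch t statistic and two-sided p by the direct formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def bh_stepup(p_values, q):
    """Benjamini–Hochberg step-up by explicit enumeration."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


def median_rank_top_brute(values_by_replicate, fraction):
    """Top set by sorting hand-computed median fractional ranks.

    ``values_by_replicate`` is an (n_genes, n_reps) array.
    """
    vals = np.asarray(values_by_replicate, float)
    ranks = np.column_stack(
        [stats.rankdata(-vals[:, j], method="average") for j in range(vals.shape[1])]
    )
    med = np.median(ranks, axis=1)
    n_top = int(np.floor(fraction * len(med)))
    cutoff = np.sort(med)[n_top - 1]
    return {i for i in range(len(med)) if med[i] <= cutoff}
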