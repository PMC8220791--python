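"""Independent brute-force oracles used by the test suite.

These are deliberately naive (explicit loops, sort-based trimming, library
re-implementations) and share no code with the package, so agreement is
evidence of correctness rather than of consistency.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def oneway_icc_bruteforce(y):
    """ICC(1) via explicit double-loop sums of squares."""
    y = [list(map(float, row)) for row in y]
    n = len(y)
    k = len(y[0])
    grand = sum(sum(row) for row in y) / (n * k)
    ss_between = 0.0
    ss_within = 0.0
    for row in y:
        rm = sum(row) / k
        ss_between += k * (rm - grand) ** 2
        for v in row:
            ss_within += (v - rm) ** 2
    ms_between = ss_between / (n - 1)
    ms_error = ss_within / (n * (k - 1))
    icc = (ms_between - ms_error) / (ms_between + (k - 1) * ms_error)
    return ms_between, ms_error, icc


def median_ratio_factors_bruteforce(columns):
    """Size factors per sample from explicit per-gene geometric means.

    ``columns`` is a list of per-sample count lists (already rounded).
    """
    n_genes = len(columns[0])
    geomeans = []
    for g in range(n_genes):
        vals = [col[g] for col in columns]
        if all(v > 0 for v in vals):
            geomeans.append(math.exp(sum(math.log(v) for v in vals) / len(vals)))
        else:
            geomeans.append(0.0)
    factors = []
    for col in columns:
        ratios = [
            col[g] / geomeans[g] for g in range(n_genes) if geomeans[g] > 0
        ]
        factors.append(statistics.median(ratios))
    return factors


def _rank_with_ties(values):
    """Average ranks (1-based) computed by pairwise counting."""
    n = len(values)
    ranks = []
    for i in range(n):
        less = sum(1 for j in range(n) if values[j] < values[i])
        equal = sum(1 for j in range(n) if values[j] == values[i])
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def tmm_factor_bruteforce(
    qs, qr, ns=None, nr=None, logratio_trim=0.30, abs_trim=0.05, weighted=True
):
    """One TMM factor (sample vs reference), no rescaling, explicit loops."""
    qs = list(map(float, qs))
    qr = list(map(float, qr))
    ns = sum(qs) if ns is None else float(ns)
    nr = sum(qr) if nr is None else float(nr)
    idx = [i for i in range(len(qs)) if qs[i] > 0 and qr[i] > 0]
    M = [math.log2((qs[i] / ns) / (qr[i] / nr)) for i in idx]
    A = [0.5 * math.log2((qs[i] / ns) * (qr[i] / nr)) for i in idx]
    n = len(idx)
    lo_m = math.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = _rank_with_ties(M)
    ra = _rank_with_ties(A)
    num = 0.0
    den = 0.0
    kept = 0
    for pos, i in enumerate(idx):
        if lo_m <= rm[pos] <= hi_m and lo_a <= ra[pos] <= hi_a:
            if weighted:
                w = 1.0 / (
                    (ns - qs[i]) / (ns * qs[i]) + (nr - qr[i]) / (nr * qr[i])
                )
            else:
                w = 1.0
            num += w * M[pos]
            den += w
            kept += 1
    assert kept > 0, "oracle: trim removed everything"
    return 2.0 ** (num / den)


def scipy_ward_leafsets(d, leaf_ids):
    """Leaf sets and heights of every internal node via scipy linkage."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(d, checks=False), method="ward")
    n = len(leaf_ids)
    sets = {i: frozenset([leaf_ids[i]]) for i in range(n)}
    out = []
    for t, (a, b, h, _sz) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + t] = s
        out.append((s, float(h)))
    return out


def exclusive_clade_discordance(d, leaf_ids, groups):
    """Discordant-group count via scipy's tree traversal (independent path)."""
    from scipy.cluster.hierarchy import linkage, to_tree
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(d, checks=False), method="ward")
    root = to_tree(Z)
    clades = set()

    def collect(node):
        leaves = frozenset(leaf_ids[i] for i in node.pre_order(lambda x: x.id))
        clades.add(leaves)
        if not node.is_leaf():
            collect(node.left)
            collect(node.right)

    collect(root)
    return sum(
        1 for _m, samples in groups.items() if frozenset(samples) not in clades
    )
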