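"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, no shared code with the package) so the
fast implementations can be validated against them on small fixtures.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Phylogenetic references (trees given as skbio TreeNode, but traversed
# generically through parent pointers)
# ---------------------------------------------------------------------------

def cophenetic_brute(tree):
    """Tip-to-tip patristic distances via explicit root paths.

    For each tip, record the path of nodes to the root; the distance between
    two tips is the sum of branch lengths of both root paths minus twice the
    shared prefix (the path through the lowest common ancestor).
    """
    tips = list(tree.tips())
    paths = {}
    for tip in tips:
        path = []
        node = tip
        while node.parent is not None:
            path.append(node)
            node = node.parent
        paths[tip.name] = path
    names = [t.name for t in tips]
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = paths[names[i]]
            pj = paths[names[j]]
            si = {id(x) for x in pi}
            sj = {id(x) for x in pj}
            d = sum(x.length for x in pi if id(x) not in sj)
            d += sum(x.length for x in pj if id(x) not in si)
            out[i, j] = out[j, i] = d
    return names, out


def beta_mntd_brute(counts_a: dict, counts_b: dict, names, dmat, weighted=True):
    """Double-loop nearest-taxon scan."""
    idx = {t: k for k, t in enumerate(names)}
    a = {t: c for t, c in counts_a.items() if c > 0}
    b = {t: c for t, c in counts_b.items() if c > 0}
    tot_a = sum(a.values())
    tot_b = sum(b.values())
    s1 = 0.0
    for t, c in a.items():
        nn = min(dmat[idx[t], idx[u]] for u in b)
        w = c / tot_a if weighted else 1.0 / len(a)
        s1 += w * nn
    s2 = 0.0
    for t, c in b.items():
        nn = min(dmat[idx[t], idx[u]] for u in a)
        w = c / tot_b if weighted else 1.0 / len(b)
        s2 += w * nn
    return 0.5 * (s1 + s2)


def unifrac_brute(present_a: set, present_b: set, tree):
    """Per-branch descendant-set accounting of unweighted UniFrac."""
    unique = 0.0
    shared_total = 0.0
    for node in tree.traverse(include_self=False):
        tipset = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        in_a = bool(tipset & present_a)
        in_b = bool(tipset & present_b)
        if not in_a and not in_b:
            continue
        shared_total += node.length
        if in_a != in_b:
            unique += node.length
    return unique / shared_total


# ---------------------------------------------------------------------------
# Compositional references
# ---------------------------------------------------------------------------

def bray_curtis_brute(x, y):
    num = sum(abs(a - b) for a, b in zip(x, y))
    den = sum(a + b for a, b in zip(x, y))
    return num / den


def interaction_profile_brute(counts, S, weighted=True):
    """Per-sample interaction profiles u_A = sum_i w_iA S_i. via loops."""
    n, d = counts.shape
    U = np.zeros((n, d))
    for s in range(n):
        row = counts[s]
        if weighted:
            tot = row.sum()
            w = row / tot
        else:
            pres = (row > 0).astype(float)
            w = pres / pres.sum()
        for i in range(d):
            for j in range(d):
                U[s, j] += w[i] * S[i, j]
    return U


def interaction_dissimilarity_brute(counts, S, weighted=True):
    U = interaction_profile_brute(counts, S, weighted)
    n = counts.shape[0]
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            na = math.sqrt(sum(v * v for v in U[a]))
            nb = math.sqrt(sum(v * v for v in U[b]))
            cos = sum(x * y for x, y in zip(U[a], U[b])) / (na * nb)
            out[a, b] = 1.0 - min(1.0, cos)
    return out


# ---------------------------------------------------------------------------
# Abundance filter reference
# ---------------------------------------------------------------------------

def abundance_filter_brute(counts: np.ndarray, global_min=1e-5,
                           c1_samples=2, c1_abund=0.01,
                           c2_fraction=0.02, c2_abund=0.001,
                           c3_fraction=0.05):
    """Direct clause evaluation; returns the boolean keep mask per column."""
    n_samples, n_asvs = counts.shape
    total = counts.sum()
    keep = []
    for j in range(n_asvs):
        col = counts[:, j]
        if total == 0 or col.sum() / total <= global_min:
            keep.append(False)
            continue
        c1 = c2 = c3 = 0
        for i in range(n_samples):
            row_sum = counts[i].sum()
            rel = col[i] / row_sum if row_sum else 0.0
            if rel > c1_abund:
                c1 += 1
            if rel > c2_abund:
                c2 += 1
            if col[i] > 0:
                c3 += 1
        ok = (c1 >= c1_samples
              or c2 >= math.ceil(c2_fraction * n_samples)
              or c3 >= math.ceil(c3_fraction * n_samples))
        keep.append(ok)
    return np.array(keep)


# ---------------------------------------------------------------------------
# RC_bray enumeration oracle (tiny pools only)
# ---------------------------------------------------------------------------

def rc_null_distribution_exact(pool_occupancy, pool_mean_relab, richness_a,
                               reads_a, richness_b, reads_b, n_mc, rng):
    """Monte-Carlo reference for the RC reassembly null using naive loops.

    Returns the list of null Bray-Curtis values; intended for 3-4 taxon toys
    where a very large n_mc approximates the exact distribution.
    """
    pool = len(pool_occupancy)
    occ = np.asarray(pool_occupancy, dtype=float)
    mra = np.asarray(pool_mean_relab, dtype=float)
    vals = []
    for _ in range(n_mc):
        def draw(rich, reads):
            chosen = []
            avail = list(range(pool))
            weights = occ.copy()
            for _ in range(rich):
                p = weights[avail] / weights[avail].sum()
                k = rng.choice(len(avail), p=p)
                chosen.append(avail.pop(k))
            p = mra[chosen] / mra[chosen].sum()
            counts = np.zeros(pool)
            counts[chosen] = rng.multinomial(reads, p)
            return counts
        a = draw(richness_a, reads_a)
        b = draw(richness_b, reads_b)
        vals.append(bray_curtis_brute(a, b))
    return vals


# ---------------------------------------------------------------------------
# PERMANOVA exact enumeration (tiny n)
# ---------------------------------------------------------------------------

def permanova_f_brute(dmat: np.ndarray, x: np.ndarray):
    """Pseudo-F for one numeric/dummy predictor via explicit matrices."""
    n = len(x)
    D2 = dmat ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * C @ D2 @ C
    X = np.column_stack([np.ones(n), x])
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    ss_model = np.trace(H @ G @ H)
    ss_total = np.trace(G)
    p = np.linalg.matrix_rank(X)
    return (ss_model / (p - 1)) / ((ss_total - ss_model) / (n - p))
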