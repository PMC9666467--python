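"""Phylogenetic distances and phylogenetic-signal diagnostics.

Covers the tree-derived quantities the assembly framework rests on: patristic
(cophenetic) tip-to-tip distances, abundance-weighted beta mean nearest taxon
distance (βMNTD), unweighted UniFrac, per-ASV environmental niches, and the
Mantel correlogram used to establish phylogenetic signal — the precondition
for reading βNTI as evidence of selection.

Trees are :class:`skbio.TreeNode` objects (rooted, with branch lengths);
distance matrices are :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.beta import unweighted_unifrac as _skbio_unweighted_unifrac

from .table import CountTable, SampleMetadata, relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "cophenetic_distances",
    "beta_mntd",
    "beta_mntd_matrix",
    "unweighted_unifrac",
    "asv_niche",
    "phylo_signal_asv",
    "mantel_correlogram",
]


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return tree


def cophenetic_distances(tree: TreeNode) -> DistanceMatrix:
    """Patristic distance between every pair of tips (sum of branch lengths).

    Every non-root edge must carry a branch length; a missing length raises
    with the offending edge named.
    """
    for node in tree.traverse(include_self=False):
        if node.length is None:
            parent = node.parent.name or "<unnamed>"
            child = node.name or "<internal>"
            raise ValueError(f"missing branch length on edge {parent} -> {child}")
    dm = tree.tip_tip_distances()
    return DistanceMatrix(dm.data, ids=dm.ids)


def _present(row) -> pd.Series:
    row = pd.Series(row, dtype=float)
    return row[row > 0]


def beta_mntd(row_a, row_b, coph: DistanceMatrix, weighted: bool = True) -> float:
    """βMNTD between two samples.

    The mean phylogenetic distance from each ASV in one sample to its nearest
    relative in the other, averaged over both directions:

        0.5 * [ Σ_{i∈A} f_iA · min_{j∈B} d_ij  +  Σ_{j∈B} f_jB · min_{i∈A} d_ij ]

    with f the within-sample relative abundances when ``weighted`` else
    uniform 1/richness weights.

    ``row_a``/``row_b`` map ASV IDs to counts (pandas Series or dict).
    """
    a = _present(row_a)
    b = _present(row_b)
    if a.empty or b.empty:
        raise ValueError("both samples must contain at least one ASV")
    idx = {t: k for k, t in enumerate(coph.ids)}
    try:
        ia = np.array([idx[t] for t in a.index])
        ib = np.array([idx[t] for t in b.index])
    except KeyError as exc:
        raise ValueError(f"ASV {exc.args[0]!r} absent from cophenetic matrix") from exc
    D = coph.data[np.ix_(ia, ib)]
    if weighted:
        fa = a.to_numpy() / a.sum()
        fb = b.to_numpy() / b.sum()
    else:
        fa = np.full(len(a), 1.0 / len(a))
        fb = np.full(len(b), 1.0 / len(b))
    return float(0.5 * (fa @ D.min(axis=1) + fb @ D.min(axis=0)))


def beta_mntd_matrix(table: CountTable, coph: DistanceMatrix,
                     weighted: bool = True) -> DistanceMatrix:
    """Pairwise βMNTD among all samples of a table."""
    n = table.shape[0]
    out = np.zeros((n, n))
    rows = [table.data.iloc[i] for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = beta_mntd(rows[i], rows[j], coph, weighted=weighted)
    return DistanceMatrix(out, ids=[str(s) for s in table.sample_ids])


def unweighted_unifrac(row_a, row_b, tree: TreeNode) -> float:
    """Unweighted UniFrac: fraction of observed branch length unique to one
    of the two communities.  Presence/absence is taken from counts > 0."""
    a = _present(row_a)
    b = _present(row_b)
    if a.empty and b.empty:
        raise ValueError("both samples are empty; UniFrac undefined")
    taxa = sorted(set(a.index) | set(b.index))
    ua = np.array([1 if t in a.index else 0 for t in taxa])
    ub = np.array([1 if t in b.index else 0 for t in taxa])
    return float(_skbio_unweighted_unifrac(ua, ub, taxa=taxa, tree=tree, validate=True))


def asv_niche(table: CountTable, meta: SampleMetadata, variables=None,
              pca_axes: int = 0) -> pd.DataFrame:
    """Realised environmental niche of each ASV.

    The niche along a variable is the mean of that variable over the samples
    where the ASV occurs, weighted by the ASV's relative abundances:

        niche_iv = Σ_s f_is · env_sv / Σ_s f_is

    Optionally, ``pca_axes`` leading principal components of the standardised
    environmental variables are appended as additional axes (columns
    ``PC1`` ...), each summarised by the same weighted mean.

    ASVs absent from every sample are excluded (and logged).
    """
    meta = meta.aligned_to(table.sample_ids)
    if variables is None:
        variables = meta.env_variables()
    env = meta.data[list(variables)].astype(float)
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"environmental variable(s) with missing values: {bad}")

    rel = relative_abundance(table)
    weights = rel.to_numpy()  # samples x asvs
    col_w = weights.sum(axis=0)
    absent = np.asarray(table.asv_ids)[col_w == 0]
    if absent.size:
        logger.info("asv_niche: %d ASV(s) absent everywhere, excluded", absent.size)

    axes = env.copy()
    if pca_axes:
        from sklearn.decomposition import PCA

        std = (env - env.mean()) / env.std(ddof=0).replace(0, np.nan)
        std = std.dropna(axis=1)
        scores = PCA(n_components=pca_axes).fit_transform(std.to_numpy())
        for k in range(pca_axes):
            axes[f"PC{k + 1}"] = scores[:, k]

    keep = col_w > 0
    w = weights[:, keep]
    niche = (w.T @ axes.to_numpy()) / w.sum(axis=0)[:, None]
    return pd.DataFrame(niche, index=np.asarray(table.asv_ids)[keep], columns=axes.columns)


def phylo_signal_asv(coph: DistanceMatrix, niches: pd.Series | pd.DataFrame,
                     variable: str | None = None, n_bins: int = 100) -> pd.DataFrame:
    """Mean absolute niche difference between ASV pairs, binned by
    phylogenetic distance.

    Pairs are assigned to ``n_bins`` equal-width bins of cophenetic distance;
    the output reports per-bin centre, mean \\|Δniche\\| and pair count.  Under
    phylogenetically conserved niches the means rise over the smallest bins.
    """
    if isinstance(niches, pd.DataFrame):
        if variable is None:
            raise ValueError("variable must be named when niches is a DataFrame")
        niche = niches[variable]
    else:
        niche = niches
    ids = [t for t in coph.ids if t in niche.index]
    if len(ids) < 2:
        raise ValueError("need at least two ASVs with niches on the tree")
    sub = coph.filter(ids)
    z = niche.loc[list(sub.ids)].to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    d = sub.data[iu]
    if d.size < n_bins:
        raise ValueError(
            f"only {d.size} ASV pairs for {n_bins} bins; reduce n_bins"
        )
    dz = np.abs(z[iu[0]] - z[iu[1]])
    edges = np.linspace(d.min(), d.max(), n_bins + 1)
    which = np.clip(np.digitize(d, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        mask = which == k
        rows.append({
            "bin": k,
            "distance_center": 0.5 * (edges[k] + edges[k + 1]),
            "mean_abs_niche_diff": float(dz[mask].mean()) if mask.any() else np.nan,
            "n_pairs": int(mask.sum()),
        })
    return pd.DataFrame(rows)


def _condensed(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_correlogram(d_phylo: DistanceMatrix, d_habitat: DistanceMatrix,
                       n_bins: int = 40, n_perm: int = 999, seed=None,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Mantel correlogram of habitat distance against distance classes.

    The first (phylogenetic or otherwise) matrix is cut into ``n_bins``
    equal-frequency distance classes.  For class *k* the Mantel statistic is
    the negative Pearson correlation between the class-membership indicator
    and the habitat distances, so that positive values mean pairs in that
    class are more similar in habitat than average.  P-values come from
    permuting sample identities of the habitat matrix, one-tailed for
    positive autocorrelation (the correlogram's question over the
    short-distance classes), with progressive Holm correction:
    the statistic of class *k* is corrected within the family of classes
    1..k.

    Returns a DataFrame with one row per class: centre, number of pairs,
    ``mantel_r``, ``p_value``, ``p_corrected`` and ``significant``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if list(d_phylo.ids) != list(d_habitat.ids):
        d_habitat = d_habitat.filter(d_phylo.ids)
    n = d_phylo.shape[0]
    iu = np.triu_indices(n, k=1)
    dp = d_phylo.data[iu]
    dh_mat = d_habitat.data

    # equal-frequency class edges over the pair distances
    qs = np.quantile(dp, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(qs[1:-1], dp, side="right"), 0, n_bins - 1)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    dh_obs = dh_mat[iu]
    dh_c = dh_obs - dh_obs.mean()
    dh_ss = float(np.sqrt((dh_c ** 2).sum()))

    # permuted condensed habitat distances, shape (n_perm, n_pairs)
    dh_perm = np.stack([dh_mat[np.ix_(p, p)][iu] for p in perms])
    dh_perm_c = dh_perm - dh_perm.mean(axis=1, keepdims=True)
    dh_perm_ss = np.sqrt((dh_perm_c ** 2).sum(axis=1))

    rows = []
    for k in range(n_bins):
        ind = (which == k).astype(float)
        n_pairs = int(ind.sum())
        if n_pairs == 0 or n_pairs == len(dp):
            rows.append({"bin": k, "distance_center": float(np.mean(qs[k:k + 2])),
                         "n_pairs": n_pairs, "mantel_r": np.nan, "p_value": np.nan})
            continue
        ind_c = ind - ind.mean()
        ind_ss = float(np.sqrt((ind_c ** 2).sum()))
        r_obs = -float(ind_c @ dh_c) / (ind_ss * dh_ss)
        r_perm = -(dh_perm_c @ ind_c) / (ind_ss * dh_perm_ss)
        p = (int((r_perm >= r_obs).sum()) + 1) / (n_perm + 1)
        rows.append({"bin": k, "distance_center": float(0.5 * (qs[k] + qs[k + 1])),
                     "n_pairs": n_pairs, "mantel_r": r_obs, "p_value": p})
    out = pd.DataFrame(rows)

    # progressive Holm: class k corrected within classes 1..k
    p_corr = np.full(len(out), np.nan)
    for k in range(len(out)):
        fam = out["p_value"].to_numpy()[: k + 1]
        valid = ~np.isnan(fam)
        if not valid[k]:
            continue
        pv = fam[valid]
        order = np.argsort(pv)
        m = len(pv)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * pv[idx])
            adj[idx] = min(1.0, running)
        p_corr[k] = adj[np.flatnonzero(valid).tolist().index(k)]
    out["p_corrected"] = p_corr
    out["significant"] = out["p_corrected"] < alpha
    return out
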