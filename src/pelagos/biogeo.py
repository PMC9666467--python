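"""Compositional beta diversity, geographic distance-decay, and the
variance-partitioning statistics used for basin-scale biogeography.

Distance decay — the change of community dissimilarity with geographic
separation — is summarised with loess-style local regression so that
non-monotone (e.g. bell-shaped) patterns along a latitudinal transect are
captured without committing to a parametric form.  Families' decay curves
are grouped by hierarchical clustering with the number of clusters chosen
by the average-silhouette method.  Per-variable PERMANOVA (pseudo-F on
partitioned sums of squared dissimilarities, permutation p-values,
Benjamini–Hochberg correction across variables) quantifies how much
community variance each environmental variable explains under different
dissimilarity indices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import anosim as _skbio_anosim
from sklearn.metrics import silhouette_score

from .table import CountTable, SampleMetadata, relative_abundance

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "bray_curtis_matrix",
    "haversine_km",
    "geographic_distance_matrix",
    "loess_fit",
    "DecayCurve",
    "distance_decay_curve",
    "cluster_decay_curves",
    "family_unifrac_decay_clusters",
    "PermanovaResult",
    "permanova_single_variable",
    "permanova_table",
    "anosim",
    "oligotype_zscore_clusters",
]


# ---------------------------------------------------------------------------
# Dissimilarity and geography
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: CountTable, transform: str = "none") -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity, BC(A,B) = Σ|a−b| / Σ(a+b).

    ``transform="total_sum_sqrt"`` first total-sum normalises each sample
    and square-roots the proportions (the standard pre-ordination
    transform); ``"none"`` works on raw counts.
    """
    if transform not in ("none", "total_sum_sqrt"):
        raise ValueError("transform must be 'none' or 'total_sum_sqrt'")
    X = table.counts().astype(float)
    row = X.sum(axis=1)
    if (row == 0).any():
        bad = [table.sample_ids[k] for k in np.flatnonzero(row == 0)]
        raise ValueError(f"zero-sum sample(s): {bad}")
    if transform == "total_sum_sqrt":
        X = np.sqrt(X / row[:, None])
    n = X.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        out[i, i + 1:] = out[i + 1:, i] = diff / tot
    return DistanceMatrix(out, ids=[str(s) for s in table.sample_ids])


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) on a sphere of radius 6371 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2) - math.radians(lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def geographic_distance_matrix(meta: SampleMetadata, sample_ids=None) -> DistanceMatrix:
    """Pairwise great-circle distances between samples' station coordinates
    (depth is ignored: distance is horizontal)."""
    ids = list(sample_ids) if sample_ids is not None else meta.sample_ids
    sub = meta.aligned_to(ids).data
    lat = sub["latitude"].to_numpy(dtype=float)
    lon = sub["longitude"].to_numpy(dtype=float)
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(out, ids=[str(s) for s in ids])


# ---------------------------------------------------------------------------
# Loess-style local regression and decay curves
# ---------------------------------------------------------------------------

def loess_fit(x, y, x_eval, span: float = 0.75) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated at ``x_eval``.

    For each evaluation point the nearest ``ceil(span·n)`` observations get
    tricube weights over their maximal distance and a degree-1 weighted
    least-squares fit supplies the prediction — classical loess with
    degree 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    if x.size != y.size or x.size < 2:
        raise ValueError("need at least two (x, y) observations")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = max(2, int(np.ceil(span * x.size)))
    out = np.empty(x_eval.size)
    for k, x0 in enumerate(x_eval):
        dist = np.abs(x - x0)
        idx = np.argsort(dist, kind="stable")[:q]
        h = dist[idx].max()
        if h == 0:
            out[k] = y[idx].mean()
            continue
        w = (1 - (dist[idx] / h) ** 3) ** 3
        w = np.maximum(w, 0)
        if w.sum() == 0:
            out[k] = y[idx].mean()
            continue
        xc = x[idx] - x0
        sw, swx = w.sum(), w @ xc
        swxx, swy, swxy = w @ (xc * xc), w @ y[idx], w @ (xc * y[idx])
        denom = sw * swxx - swx * swx
        if abs(denom) < 1e-12 * max(1.0, sw * swxx):
            out[k] = swy / sw
        else:
            # intercept of the local fit at x0
            out[k] = (swxx * swy - swx * swxy) / denom
    return out


@dataclass
class DecayCurve:
    """A fitted distance-decay curve on an equidistant geographic grid."""

    curve_id: str
    grid_km: np.ndarray
    fitted: np.ndarray
    span: float = 0.75
    n_pairs: int = 0

    def __post_init__(self):
        self.grid_km = np.asarray(self.grid_km, dtype=float)
        self.fitted = np.asarray(self.fitted, dtype=float)
        if self.grid_km.size != self.fitted.size:
            raise ValueError("grid and fitted values differ in length")
        if np.any(np.diff(self.grid_km) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("fitted values must be finite")


def distance_decay_curve(d_comm: DistanceMatrix, d_geo: DistanceMatrix,
                         span: float = 0.75, grid_size: int = 100,
                         curve_id: str = "community") -> DecayCurve:
    """Loess fit of community dissimilarity against geographic distance,
    evaluated at ``grid_size`` equidistant points over the observed range."""
    if list(d_comm.ids) != list(d_geo.ids):
        d_geo = d_geo.filter(d_comm.ids)
    iu = np.triu_indices(d_comm.shape[0], k=1)
    x = d_geo.data[iu]
    y = d_comm.data[iu]
    if x.size < 10:
        raise ValueError("need at least 10 sample pairs for a decay curve")
    if np.ptp(x) == 0:
        raise ValueError("all pairs lie at the same geographic distance")
    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = loess_fit(x, y, grid, span=span)
    return DecayCurve(curve_id, grid, fitted, span=span, n_pairs=int(x.size))


def _silhouette_hclust(dist_condensed: np.ndarray, square: np.ndarray,
                       k_range) -> tuple[int, np.ndarray, float]:
    """Average-linkage hierarchical clustering with the average-silhouette
    method for choosing k.  Returns (k, labels, best silhouette)."""
    Z = linkage(dist_condensed, method="average")
    n = square.shape[0]
    best = (None, None, -np.inf)
    for k in k_range:
        if not 2 <= k <= n - 1:
            continue
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(square, labels, metric="precomputed")
        if s > best[2]:
            best = (k, labels, s)
    if best[0] is None:
        raise ValueError("no k in k_range produced a valid clustering")
    return best


def cluster_decay_curves(curves: pd.DataFrame, k_range=range(2, 11)) -> pd.DataFrame:
    """Cluster fitted decay curves (rows = curve IDs, columns = grid points).

    Euclidean distances between curves, average-linkage hierarchical
    clustering, k chosen by maximum average silhouette width over
    ``k_range``.  Returns a DataFrame with cluster label and silhouette
    width per curve; the chosen k is in ``result.attrs["k"]``.
    """
    X = curves.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 curves to cluster")
    cond = squareform(_euclidean_square(X), checks=False)
    k, labels, sil = _silhouette_hclust(cond, _euclidean_square(X), k_range)
    from sklearn.metrics import silhouette_samples

    widths = silhouette_samples(_euclidean_square(X), labels, metric="precomputed")
    out = pd.DataFrame({"cluster": labels, "silhouette_width": widths},
                       index=curves.index)
    out.attrs["k"] = int(k)
    out.attrs["mean_silhouette"] = float(sil)
    return out


def _euclidean_square(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return squareform(pdist(X, metric="euclidean"))


def family_unifrac_decay_clusters(
    table: CountTable,
    taxonomy: pd.Series,
    tree: TreeNode,
    meta: SampleMetadata,
    min_asvs: int = 10,
    min_span_km: float = 10_000.0,
    k_range=range(2, 11),
    span: float = 0.75,
    grid_size: int = 30,
    depth_group: str = "layer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster taxonomic families by the shape of their phylogenetic
    distance-decay curves.

    Families qualify when they hold more than ``min_asvs`` ASVs and occur
    sequentially (consecutive occupied stations, ordered by latitude) over
    at least ``min_span_km`` of the transect.  For each family, unweighted
    UniFrac is computed between sample pairs from the same size fraction
    and the same depth group whose family ASV overlap is strictly between
    0% and 100%; the values are z-scored within the family (so clustering
    responds to curve *shape*, not mean level), loess-fitted against
    geographic distance and evaluated on a common equidistant grid.  The
    curve matrix is clustered as in :func:`cluster_decay_curves`.

    Returns ``(assignments, curves)``: per-family cluster label and
    silhouette width, and the fitted z-scored curves on the common grid.
    """
    from .phylo import unweighted_unifrac

    mdf = meta.aligned_to(table.sample_ids).data
    if depth_group not in mdf.columns:
        raise ValueError(f"metadata lacks depth-group column {depth_group!r}")
    fam_of = taxonomy.dropna()
    families = [f for f in fam_of.unique()
                if (fam_of == f).sum() > min_asvs]
    if not families:
        raise ValueError("no family passes the ASV-count filter")

    # station table ordered by latitude for the sequential-span filter
    stations = mdf[["latitude", "longitude"]].drop_duplicates().sort_values("latitude")

    geo = geographic_distance_matrix(meta, table.sample_ids)
    geo_df = pd.DataFrame(geo.data, index=table.sample_ids, columns=table.sample_ids)

    curves = {}
    for fam in families:
        asvs = [a for a in fam_of.index[fam_of == fam] if a in table.data.columns]
        if len(asvs) <= min_asvs:
            continue
        sub = table.data[asvs]
        present_samples = sub.index[sub.sum(axis=1) > 0]

        # sequential span: longest run of consecutive latitude-ordered
        # stations in which the family occurs, measured end to end
        occ_station = set(map(tuple, mdf.loc[present_samples, ["latitude", "longitude"]]
                              .to_numpy()))
        run_best, run_cur = [], []
        for st in stations.itertuples(index=False):
            if (st.latitude, st.longitude) in occ_station:
                run_cur.append(st)
                if len(run_cur) > len(run_best):
                    run_best = list(run_cur)
            else:
                run_cur = []
        if len(run_best) < 2:
            continue
        extent = haversine_km(run_best[0].latitude, run_best[0].longitude,
                              run_best[-1].latitude, run_best[-1].longitude)
        if extent < min_span_km:
            logger.info("family %r spans only %.0f km sequentially, excluded", fam, extent)
            continue

        xs, ys = [], []
        ps = list(present_samples)
        for i in range(len(ps)):
            for j in range(i + 1, len(ps)):
                a, b = ps[i], ps[j]
                if "size_fraction" in mdf.columns and \
                        mdf.loc[a, "size_fraction"] != mdf.loc[b, "size_fraction"]:
                    continue
                if mdf.loc[a, depth_group] != mdf.loc[b, depth_group]:
                    continue
                pa = set(sub.columns[sub.loc[a] > 0])
                pb = set(sub.columns[sub.loc[b] > 0])
                shared = len(pa & pb)
                union = len(pa | pb)
                if shared == 0 or shared == union:
                    continue  # overlap must be strictly between 0% and 100%
                xs.append(float(geo_df.loc[a, b]))
                ys.append(unweighted_unifrac(sub.loc[a], sub.loc[b], tree))
        if len(xs) < 10:
            continue
        y = np.asarray(ys)
        if y.std(ddof=0) == 0:
            logger.info("family %r has zero UniFrac variance, dropped", fam)
            continue
        z = (y - y.mean()) / y.std(ddof=0)
        curves[fam] = (np.asarray(xs), z)

    if len(curves) < 2:
        raise ValueError("fewer than 2 eligible families after filtering")

    lo = min(x.min() for x, _ in curves.values())
    hi = max(x.max() for x, _ in curves.values())
    grid = np.linspace(lo, hi, grid_size)
    fitted = pd.DataFrame(
        {fam: loess_fit(x, z, grid, span=span) for fam, (x, z) in curves.items()},
        index=grid,
    ).T
    assignments = cluster_decay_curves(fitted, k_range=k_range)
    return assignments, fitted


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    variable: str
    r_squared: float
    pseudo_f: float
    p_value: float
    p_adjusted: float | None = None
    n_perm: int = 999

    def __post_init__(self):
        if not 0 <= self.r_squared <= 1:
            raise ValueError("R² outside [0, 1]")


def _design_matrix(values: pd.Series | np.ndarray) -> np.ndarray:
    v = pd.Series(values)
    if v.nunique() < 2:
        raise ValueError("variable is constant; PERMANOVA undefined")
    if pd.api.types.is_numeric_dtype(v):
        x = v.to_numpy(dtype=float)
        return np.column_stack([np.ones(len(v)), x])
    dummies = pd.get_dummies(v.astype("category"), drop_first=True).to_numpy(dtype=float)
    return np.column_stack([np.ones(len(v)), dummies])


def permanova_single_variable(d: DistanceMatrix, values, variable: str = "x",
                              n_perm: int = 999, seed=None) -> PermanovaResult:
    """One-variable PERMANOVA (adonis-style) on a distance matrix.

    The Gower-centred matrix G = −½ C D² C partitions total sum of squares
    into a model part tr(HGH) under the hat matrix of [1, x] (numeric x) or
    group dummies (categorical x).  The permutation p-value shuffles sample
    labels of the variable.
    """
    vals = pd.Series(values)
    if len(vals) != d.shape[0]:
        raise ValueError("variable length does not match distance matrix")
    X = _design_matrix(vals)
    n = d.shape[0]
    D2 = d.data ** 2
    C = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * C @ D2 @ C
    ss_total = np.trace(G)
    p_rank = np.linalg.matrix_rank(X)
    df_model = p_rank - 1
    df_resid = n - p_rank
    if df_model < 1 or df_resid < 1:
        raise ValueError("insufficient degrees of freedom")

    eps = 1e-10 * max(1.0, abs(ss_total))

    def _f(ss):
        # clamp: with a perfect fit the residual SS is zero up to round-off
        ss = np.minimum(ss, ss_total)
        resid = np.maximum(ss_total - ss, 0.0)
        with np.errstate(divide="ignore"):
            return np.where(resid < eps, np.inf,
                            (ss / df_model) / (resid / df_resid))

    rng = np.random.default_rng(seed)
    if pd.api.types.is_numeric_dtype(vals) and X.shape[1] == 2:
        # single numeric predictor: tr(HG) = x̃'Gx̃ / x̃'x̃ since G is
        # double-centred (the intercept part vanishes); permutations become
        # one quadratic form each
        xc = X[:, 1] - X[:, 1].mean()
        denom = float(xc @ xc)
        ss_model = float(xc @ G @ xc) / denom
        P = np.stack([rng.permutation(xc) for _ in range(n_perm)])
        ss_perm = np.einsum("pi,ij,pj->p", P, G, P) / denom
        f_obs = float(_f(ss_model))
        count = int((_f(ss_perm) >= f_obs).sum())
    else:
        def model_ss(perm):
            Xp = X[perm]
            H = Xp @ np.linalg.pinv(Xp.T @ Xp) @ Xp.T
            return float(np.sum(H * G))  # tr(HG), H symmetric

        ss_model = model_ss(np.arange(n))
        f_obs = float(_f(ss_model))
        count = 0
        for _ in range(n_perm):
            if float(_f(model_ss(rng.permutation(n)))) >= f_obs:
                count += 1
    p = (count + 1) / (n_perm + 1)
    r2 = float(np.clip(ss_model / ss_total, 0.0, 1.0))
    return PermanovaResult(variable, r2, float(f_obs), float(p), n_perm=n_perm)


def permanova_table(d: DistanceMatrix, meta: SampleMetadata, variables,
                    n_perm: int = 999, seed=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable PERMANOVA with Benjamini–Hochberg correction.

    Variables whose BH-adjusted p exceeds ``alpha`` are flagged
    ``retained=False`` (the convention of dropping non-significant terms
    from downstream interpretation).
    """
    from statsmodels.stats.multitest import multipletests

    sub = meta.aligned_to(list(d.ids)).data
    rng = np.random.default_rng(seed)
    results = []
    for v in variables:
        res = permanova_single_variable(
            d, sub[v], variable=v, n_perm=n_perm,
            seed=int(rng.integers(2 ** 31)))
        results.append(res)
    pvals = [r.p_value for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    rows = []
    for r, pa in zip(results, p_adj):
        rows.append({"variable": r.variable, "r_squared": r.r_squared,
                     "pseudo_f": r.pseudo_f, "p_value": r.p_value,
                     "p_bh": float(pa), "retained": bool(pa <= alpha)})
    return pd.DataFrame(rows)


def anosim(d: DistanceMatrix, grouping, n_perm: int = 999, seed=None) -> tuple[float, float]:
    """ANOSIM: R = (mean between-group rank − mean within-group rank) /
    (n_pairs / 2), with a permutation p-value."""
    g = pd.Series(grouping)
    sizes = g.value_counts()
    if (sizes >= 2).sum() < 2:
        raise ValueError("ANOSIM needs at least two groups with two members")
    if seed is not None:
        np.random.seed(int(seed) % (2 ** 31))
    res = _skbio_anosim(d, g.to_numpy(), permutations=n_perm)
    return float(res["test statistic"]), float(res["p-value"])


# ---------------------------------------------------------------------------
# Oligotype profiles
# ---------------------------------------------------------------------------

def oligotype_zscore_clusters(table: CountTable, k_range=range(2, 11),
                              seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each ASV's abundance profile across samples and cluster.

    Intended for a table restricted to one lineage's oligotypes along a
    transect.  Constant-profile ASVs are dropped (logged).  Clustering is
    hierarchical on Bray–Curtis distances between the ASVs' relative
    profiles, with k chosen by average silhouette.

    Returns ``(zscores, assignments)``: the z-scored profiles (ASVs × samples)
    and per-ASV cluster labels with silhouette widths.
    """
    prof = table.data.T.astype(float)  # ASVs x samples
    keep = prof.std(axis=1, ddof=0) > 0
    dropped = prof.index[~keep].tolist()
    if dropped:
        logger.info("oligotype_zscore_clusters: dropped constant ASVs %s", dropped[:5])
    prof = prof.loc[keep]
    if prof.shape[0] < 2:
        raise ValueError("need at least 2 ASVs with variable profiles")
    z = prof.sub(prof.mean(axis=1), axis=0).div(prof.std(axis=1, ddof=0), axis=0)

    rel = prof.div(prof.sum(axis=1), axis=0)
    n = rel.shape[0]
    bc = np.zeros((n, n))
    X = rel.to_numpy()
    for i in range(n):
        diff = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        tot = (X[i] + X[i + 1:]).sum(axis=1)
        bc[i, i + 1:] = bc[i + 1:, i] = diff / tot
    k, labels, _ = _silhouette_hclust(squareform(bc, checks=False), bc, k_range)
    from sklearn.metrics import silhouette_samples

    widths = silhouette_samples(bc, labels, metric="precomputed")
    assignments = pd.DataFrame({"cluster": labels, "silhouette_width": widths},
                               index=prof.index)
    assignments.attrs["k"] = int(k)
    return z, assignments
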