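"""Null-model quantification of community-assembly mechanisms.

For every pair of samples two standardised null-model statistics are
computed and combined into a mechanism call:

* **βNTI** — the beta nearest taxon index: the observed abundance-weighted
  βMNTD expressed as a standard deviate against a null distribution obtained
  by shuffling taxon identities (with their abundances) across the tips of
  the phylogeny.  \\|βNTI\\| > 2 indicates that phylogenetic turnover deviates
  significantly from chance: βNTI > +2 heterogeneous selection, βNTI < −2
  homogeneous selection.

* **RC_bray** — the abundance-adjusted Raup–Crick index: observed Bray–Curtis
  dissimilarity ranked within a null distribution of probabilistically
  reassembled community pairs that preserve each sample's richness and read
  total, with taxon selection weighted by occupancy and read filling by mean
  relative abundance.  Scaled to [−1, +1]; RC > +0.95 indicates dispersal
  limitation, RC < −0.95 homogenizing dispersal.

Pairs exceeding neither threshold are attributed to ecological drift.
Selection takes precedence: RC_bray is only consulted when \\|βNTI\\| ≤ 2.

The public surface is the :class:`AssemblyModel` / :class:`AssemblyResults`
pair; the underlying matrix routines (:func:`bnti_matrix`,
:func:`rcbray_matrix`) are exposed for direct use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .phylo import beta_mntd, cophenetic_distances
from .table import CountTable, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "NullConfig",
    "MECHANISM_LABELS",
    "AssemblyModel",
    "AssemblyResults",
    "bnti_matrix",
    "rcbray_matrix",
    "classify_mechanism",
    "mechanism_table",
    "mechanism_fractions",
    "fractions_by_temperature_difference",
]

MECHANISM_LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


@dataclass(frozen=True)
class NullConfig:
    """Null-model settings.

    ``n_null`` randomisations per pair (999 by default, matching common
    practice); ``pool_scope`` controls the taxon pool for the βNTI tip
    shuffle: ``"whole_matrix"`` (default: all tips of the cophenetic matrix,
    the canonical regional-pool shuffle) or ``"pairwise"`` (union of the
    pair's taxa only — a much weaker null that cannot detect clustering
    relative to the wider phylogeny; provided for sensitivity analyses).
    """

    n_null: int = 999
    seed: int | None = None
    pool_scope: str = "whole_matrix"

    def __post_init__(self):
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.pool_scope not in ("pairwise", "whole_matrix"):
            raise ValueError("pool_scope must be 'pairwise' or 'whole_matrix'")


# ---------------------------------------------------------------------------
# βNTI
# ---------------------------------------------------------------------------

def _beta_mntd_arrays(fa, fb, D) -> float:
    return float(0.5 * (fa @ D.min(axis=1) + fb @ D.min(axis=0)))


def bnti_matrix(table: CountTable, coph: DistanceMatrix, cfg: NullConfig = NullConfig(),
                weighted: bool = True, signal_checked: bool = False,
                _max_chunk_elems: int = 2 ** 25) -> pd.DataFrame:
    """Pairwise βNTI for all samples of a table.

    The null shuffles taxon identities (abundances travel with their labels)
    across the tips of the pool, recomputing βMNTD ``cfg.n_null`` times;
    βNTI = (observed − null mean) / null SD.  Pairs whose null SD is zero are
    returned as NaN and logged.

    Returns a symmetric DataFrame (NaN-friendly, hence not a strict
    DistanceMatrix).
    """
    if table.shape[0] < 2:
        raise ValueError("need at least two samples")
    if not signal_checked:
        logger.warning(
            "bnti_matrix: phylogenetic signal has not been verified for this "
            "dataset; βNTI assumes niches are phylogenetically conserved"
        )
    idx = {t: k for k, t in enumerate(coph.ids)}
    missing = [t for t in table.asv_ids if t not in idx]
    if missing:
        raise ValueError(f"ASVs absent from cophenetic matrix: {missing[:5]}")
    D = np.ascontiguousarray(coph.data)
    counts = table.counts().astype(float)
    n = counts.shape[0]
    col_idx = np.array([idx[t] for t in table.asv_ids])

    rng = np.random.default_rng(cfg.seed)
    samples = table.sample_ids
    out = np.full((n, n), 0.0)
    present = [np.flatnonzero(counts[i] > 0) for i in range(n)]

    for i in range(n):
        for j in range(i + 1, n):
            pa, pb = present[i], present[j]
            if pa.size == 0 or pb.size == 0:
                raise ValueError(
                    f"sample {samples[i] if pa.size == 0 else samples[j]!r} is empty"
                )
            if weighted:
                fa = counts[i, pa] / counts[i, pa].sum()
                fb = counts[j, pb] / counts[j, pb].sum()
            else:
                fa = np.full(pa.size, 1.0 / pa.size)
                fb = np.full(pb.size, 1.0 / pb.size)
            if cfg.pool_scope == "pairwise":
                pool = np.union1d(pa, pb)
                gpool = col_idx[pool]
                pos = {p: k for k, p in enumerate(pool)}
                la = np.array([pos[p] for p in pa])
                lb = np.array([pos[p] for p in pb])
            else:
                # all tips of the cophenetic matrix, including taxa absent
                # from this table: the regional pool is the whole phylogeny
                gpool = np.arange(D.shape[0])
                la = col_idx[pa]
                lb = col_idx[pb]
            obs = _beta_mntd_arrays(fa, fb, D[np.ix_(col_idx[pa], col_idx[pb])])

            u = gpool.size
            chunk = max(1, _max_chunk_elems // max(1, pa.size * pb.size))
            nulls = np.empty(cfg.n_null)
            done = 0
            while done < cfg.n_null:
                m = min(chunk, cfg.n_null - done)
                # one permutation of the pool's tip identities per null
                # replicate, applied to both samples: abundances follow
                # their labels, so shared taxa remain shared under the null
                # (co-occurrence structure is preserved; only the placement
                # on the tree is randomised)
                P = gpool[np.argsort(rng.random((m, u)), axis=1)]
                Dn = D[P[:, la][:, :, None], P[:, lb][:, None, :]]
                nulls[done:done + m] = 0.5 * (Dn.min(axis=2) @ fa + Dn.min(axis=1) @ fb)
                done += m
            mu = nulls.mean()
            sd = nulls.std(ddof=0)
            if sd == 0:
                logger.warning(
                    "bnti_matrix: zero null SD for pair (%s, %s); βNTI undefined",
                    samples[i], samples[j],
                )
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = (obs - mu) / sd
    return pd.DataFrame(out, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# RC_bray
# ---------------------------------------------------------------------------

def _bray_curtis(a: np.ndarray, b: np.ndarray) -> float:
    denom = (a + b).sum()
    return float(np.abs(a - b).sum() / denom) if denom else 0.0


def rcbray_matrix(table: CountTable, cfg: NullConfig = NullConfig()) -> pd.DataFrame:
    """Pairwise abundance-adjusted Raup–Crick (RC_bray) for all samples.

    Each null replicate reassembles both communities of a pair from the
    table-wide taxon pool: a sample first draws its observed richness of
    taxa without replacement with probability proportional to occupancy
    (number of samples a taxon occurs in), then distributes its observed
    read total over the drawn taxa with probability proportional to the
    taxon's mean relative abundance.  The observed Bray–Curtis dissimilarity
    is ranked within the null Bray–Curtis values (ties count half):

        RC = 2 · [ #(null < obs) + 0.5 · #(null = obs) ] / n_null − 1
    """
    counts = table.counts().astype(np.int64)
    n, m = counts.shape
    if n < 2:
        raise ValueError("need at least two samples")
    occupancy = (counts > 0).sum(axis=0).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    if pool.size == 0:
        raise ValueError("empty table")
    occ_w = occupancy[pool]
    row_tot = counts.sum(axis=1).astype(float)
    relab = counts / row_tot[:, None]
    mean_relab = relab.mean(axis=0)[pool]
    mean_relab = mean_relab / mean_relab.sum()
    log_occ = np.log(occ_w)

    richness = (counts > 0).sum(axis=1)
    reads = counts.sum(axis=1)
    too_rich = np.flatnonzero(richness > pool.size)
    if too_rich.size:
        raise ValueError(
            f"sample richness exceeds taxon pool for {table.sample_ids[too_rich[0]]!r}"
        )

    rng = np.random.default_rng(cfg.seed)
    samples = table.sample_ids
    out = np.zeros((n, n))

    def _null_community(k: int) -> np.ndarray:
        """One reassembly of sample k: counts over the pool indices."""
        # weighted sampling without replacement via exponential keys
        keys = log_occ + rng.gumbel(size=pool.size)
        chosen = np.argpartition(-keys, richness[k] - 1)[: richness[k]]
        p = mean_relab[chosen]
        vec = np.zeros(pool.size)
        vec[chosen] = rng.multinomial(reads[k], p / p.sum())
        return vec

    for i in range(n):
        for j in range(i + 1, n):
            obs = _bray_curtis(counts[i].astype(float), counts[j].astype(float))
            less = ties = 0
            for _ in range(cfg.n_null):
                null_bc = _bray_curtis(_null_community(i), _null_community(j))
                if abs(null_bc - obs) <= 1e-12:
                    ties += 1
                elif null_bc < obs:
                    less += 1
            rc = 2.0 * (less + 0.5 * ties) / cfg.n_null - 1.0
            out[i, j] = out[j, i] = rc
    return pd.DataFrame(out, index=samples, columns=samples)


# ---------------------------------------------------------------------------
# Classification and aggregation
# ---------------------------------------------------------------------------

def classify_mechanism(bnti: float, rc_bray: float) -> str:
    """Assign a pair its assembly mechanism from (βNTI, RC_bray).

    Selection is evaluated first (|βNTI| > 2); only when it is absent is the
    compositional null consulted (|RC_bray| > 0.95); otherwise drift.
    Undefined inputs yield ``"undefined"``.
    """
    if bnti is None or rc_bray is None or np.isnan(bnti) or np.isnan(rc_bray):
        return "undefined"
    if bnti > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_bray > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_bray < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def mechanism_table(bnti: pd.DataFrame, rc: pd.DataFrame) -> pd.DataFrame:
    """Long-format per-pair table: sample_a, sample_b, bnti, rc_bray, label."""
    if list(bnti.index) != list(rc.index):
        raise ValueError("βNTI and RC_bray matrices have different samples")
    samples = list(bnti.index)
    rows = []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            b = float(bnti.iloc[i, j])
            r = float(rc.iloc[i, j])
            rows.append({
                "sample_a": samples[i],
                "sample_b": samples[j],
                "bnti": b,
                "rc_bray": r,
                "label": classify_mechanism(b, r),
            })
    return pd.DataFrame(rows)


def _fraction_series(labels: pd.Series) -> pd.Series:
    defined = labels[labels != "undefined"]
    frac = defined.value_counts(normalize=True)
    return frac.reindex(MECHANISM_LABELS, fill_value=0.0)


def mechanism_fractions(mech: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Fraction of pairs per mechanism, optionally per group.

    ``groups`` maps sample IDs to a grouping value (depth, size fraction,
    layer ...); a pair belongs to a group only when both its samples share
    the value, otherwise it is excluded.  Undefined pairs are excluded from
    denominators.  Empty groups are omitted with a warning.
    """
    if mech.empty:
        raise ValueError("empty mechanism table")
    if groups is None:
        frac = _fraction_series(mech["label"])
        out = frac.to_frame().T
        out.index = ["all"]
        out["n_pairs"] = int((mech["label"] != "undefined").sum())
        return out
    ga = mech["sample_a"].map(groups)
    gb = mech["sample_b"].map(groups)
    same = ga == gb
    rows, index = [], []
    for g in pd.unique(groups.dropna()):
        sel = mech.loc[same & (ga == g)]
        sel = sel[sel["label"] != "undefined"]
        if sel.empty:
            logger.warning("mechanism_fractions: group %r has no classified pairs", g)
            continue
        frac = _fraction_series(sel["label"])
        frac["n_pairs"] = len(sel)
        rows.append(frac)
        index.append(g)
    if not rows:
        raise ValueError("no group contains a classified pair")
    out = pd.DataFrame(rows, index=index)
    out["n_pairs"] = out["n_pairs"].astype(int)
    return out


def fractions_by_temperature_difference(mech: pd.DataFrame, meta: SampleMetadata,
                                        bin_width_C: float = 4.0,
                                        variable: str = "temperature") -> pd.DataFrame:
    """Mechanism fractions binned by pairwise temperature difference \\|ΔT\\|.

    Pairs missing a temperature are excluded (and logged).  Bins of width
    ``bin_width_C`` °C span 0 to the maximum observed difference; empty bins
    are reported with ``n_pairs`` 0 and NaN fractions.
    """
    temp = meta.variable(variable).astype(float)
    ta = mech["sample_a"].map(temp)
    tb = mech["sample_b"].map(temp)
    ok = ta.notna() & tb.notna()
    if (~ok).any():
        logger.warning(
            "fractions_by_temperature_difference: %d pair(s) lack %s, excluded",
            int((~ok).sum()), variable,
        )
    sub = mech.loc[ok].copy()
    if sub.empty:
        raise ValueError("no pair has temperature on both samples")
    dt = (ta - tb).abs().loc[sub.index]
    n_bins = max(1, int(np.ceil((dt.max() + 1e-12) / bin_width_C)))
    rows = []
    for k in range(n_bins):
        lo, hi = k * bin_width_C, (k + 1) * bin_width_C
        mask = (dt >= lo) & (dt < hi) if k < n_bins - 1 else (dt >= lo) & (dt <= hi)
        sel = sub.loc[mask]
        sel = sel[sel["label"] != "undefined"]
        row = {"dt_low": lo, "dt_high": hi, "n_pairs": len(sel)}
        if len(sel):
            row.update(_fraction_series(sel["label"]).to_dict())
        else:
            row.update({lab: np.nan for lab in MECHANISM_LABELS})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class AssemblyModel:
    """Null-model inference of assembly mechanisms for one count table.

    Parameters
    ----------
    table : CountTable
        Samples × ASVs integer counts (raw or rarefied; record which).
    tree : skbio.TreeNode, optional
        Rooted phylogeny covering the table's ASVs.  Either ``tree`` or
        ``coph`` must be given.
    coph : skbio.DistanceMatrix, optional
        Precomputed cophenetic (patristic) distances.
    metadata : SampleMetadata, optional
        Needed only for metadata-based aggregations on the results.
    config : NullConfig
        Number of null randomisations, seed, and tip-shuffle pool scope.
    """

    def __init__(self, table: CountTable, tree: TreeNode | None = None,
                 coph: DistanceMatrix | None = None,
                 metadata: SampleMetadata | None = None,
                 config: NullConfig = NullConfig()):
        if coph is None:
            if tree is None:
                raise ValueError("provide a tree or a cophenetic matrix")
            coph = cophenetic_distances(tree)
        self.table = table
        self.coph = coph
        self.metadata = metadata
        self.config = config
        self.signal_checked = False

    @classmethod
    def from_files(cls, counts_path, tree_path, metadata_path=None,
                   config: NullConfig = NullConfig(),
                   orientation: str = "samples") -> "AssemblyModel":
        from .phylo import read_tree
        from .table import read_count_table, read_sample_metadata

        table = read_count_table(counts_path, orientation=orientation)
        tree = read_tree(tree_path)
        meta = read_sample_metadata(metadata_path) if metadata_path else None
        return cls(table, tree=tree, metadata=meta, config=config)

    def check_phylogenetic_signal(self, variable: str = "temperature",
                                  n_bins: int = 40, n_perm: int = 999,
                                  seed=None) -> pd.DataFrame:
        """Mantel correlogram of βMNTD against habitat (|Δvariable|) distance.

        Marks the model as signal-checked; returns the correlogram table.
        """
        from .phylo import beta_mntd_matrix, mantel_correlogram

        if self.metadata is None:
            raise ValueError("metadata required for the phylogenetic-signal check")
        meta = self.metadata.aligned_to(self.table.sample_ids)
        d_phylo = beta_mntd_matrix(self.table, self.coph)
        v = meta.variable(variable).astype(float).to_numpy()
        d_hab = DistanceMatrix(np.abs(v[:, None] - v[None, :]),
                               ids=[str(s) for s in self.table.sample_ids])
        out = mantel_correlogram(d_phylo, d_hab, n_bins=n_bins, n_perm=n_perm, seed=seed)
        self.signal_checked = True
        return out

    def fit(self, seed=None) -> "AssemblyResults":
        """Run both null models and classify every sample pair."""
        cfg = self.config
        if seed is not None:
            cfg = NullConfig(n_null=cfg.n_null, seed=seed, pool_scope=cfg.pool_scope)
        ss = np.random.SeedSequence(cfg.seed) if cfg.seed is not None else np.random.SeedSequence()
        s_bnti, s_rc = ss.spawn(2)
        bnti = bnti_matrix(
            self.table, self.coph,
            NullConfig(cfg.n_null, seed=s_bnti.generate_state(1)[0] % (2 ** 31),
                       pool_scope=cfg.pool_scope),
            signal_checked=self.signal_checked,
        )
        rc = rcbray_matrix(
            self.table,
            NullConfig(cfg.n_null, seed=s_rc.generate_state(1)[0] % (2 ** 31)),
        )
        mech = mechanism_table(bnti, rc)
        return AssemblyResults(self, bnti, rc, mech)


class AssemblyResults:
    """Fitted per-pair statistics and mechanism calls.

    Attributes
    ----------
    bnti : DataFrame
        Symmetric βNTI matrix (NaN where the null SD was zero).
    rc_bray : DataFrame
        Symmetric RC_bray matrix in [−1, 1].
    mechanisms : DataFrame
        Long format, one row per unordered pair with the mechanism label.
    """

    def __init__(self, model: AssemblyModel, bnti: pd.DataFrame,
                 rc: pd.DataFrame, mechanisms: pd.DataFrame):
        self.model = model
        self.bnti = bnti
        self.rc_bray = rc
        self.mechanisms = mechanisms

    def fractions(self, by: str | None = None) -> pd.DataFrame:
        """Mechanism fractions, overall or grouped by a metadata column."""
        groups = None
        if by is not None:
            if self.model.metadata is None:
                raise ValueError("model has no metadata to group by")
            groups = self.model.metadata.variable(by)
        return mechanism_fractions(self.mechanisms, groups)

    def fractions_by_temperature_difference(self, bin_width_C: float = 4.0,
                                            variable: str = "temperature") -> pd.DataFrame:
        if self.model.metadata is None:
            raise ValueError("model has no metadata")
        return fractions_by_temperature_difference(
            self.mechanisms, self.model.metadata, bin_width_C, variable)

    def summary(self) -> str:
        """Human-readable summary of the fitted mechanism partition."""
        frac = self.fractions().iloc[0]
        n_total = len(self.mechanisms)
        n_undef = int((self.mechanisms["label"] == "undefined").sum())
        lines = [
            "Assembly mechanism inference",
            "=" * 44,
            f"samples:            {self.model.table.shape[0]}",
            f"ASVs:               {self.model.table.shape[1]}",
            f"pairs classified:   {n_total - n_undef} (of {n_total})",
            f"null replicates:    {self.model.config.n_null}",
            f"pool scope:         {self.model.config.pool_scope}",
            "-" * 44,
        ]
        for lab in MECHANISM_LABELS:
            lines.append(f"{lab:<24s} {frac[lab]:6.1%}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.mechanisms.to_csv(path, sep="\t", index=False)
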