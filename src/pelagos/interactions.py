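"""Compositional co-occurrence inference (SparCC) and interaction-adjusted
beta diversity (TINA/PINA).

SparCC estimates pairwise correlations between the *basis* (absolute)
abundances underlying compositional count data.  For fractions x_i it uses
the log-ratio variances t_ij = var(log(x_i / x_j)), which relate to basis
variances ω² and correlations ρ through

    t_ij = ω_i² + ω_j² − 2 ρ_ij ω_i ω_j .

Assuming correlations are sparse, summing over j gives a linear system for
the ω² which is solved and refined by iteratively excluding the most
strongly correlated pairs; correlations follow as
ρ_ij = (ω_i² + ω_j² − t_ij) / (2 ω_i ω_j).  Count uncertainty is handled by
averaging (median) over Dirichlet posterior resamples of the fractions.

TINA and PINA replace the taxon-identity overlap of classical beta
diversity with the overlap of *interaction profiles*: every sample is
projected to u_A = Σ_i w_iA · S_i· through a taxon × taxon similarity matrix
S (co-occurrence-derived for TINA, phylogenetic for PINA) and pairs of
samples are compared by cosine dissimilarity of those profiles.  Two
samples sharing no taxa but whose taxa strongly co-occur are thereby close
— the property that lets these indices capture the turnover of interacting
groups rather than of individual taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .table import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "SparccConfig",
    "sparcc_correlations",
    "tina_dissimilarity",
    "pina_dissimilarity",
]


@dataclass(frozen=True)
class SparccConfig:
    """SparCC estimation settings (defaults follow the original algorithm:
    20 Dirichlet resamples, up to 10 exclusion rounds at |ρ| > 0.1)."""

    n_resamples: int = 20
    n_exclusion_rounds: int = 10
    exclusion_threshold: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.exclusion_threshold < 1:
            raise ValueError("exclusion_threshold must lie in (0, 1)")


def _variation_matrix(frac: np.ndarray) -> np.ndarray:
    """t_ij = var(log(x_i/x_j)) over samples, for fractions (samples x taxa)."""
    logf = np.log(frac)
    # var(a - b) = var a + var b - 2 cov(a, b)
    cov = np.cov(logf, rowvar=False, ddof=1)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2 * cov


def _basis_correlations(t: np.ndarray, n_rounds: int, threshold: float) -> np.ndarray:
    """One SparCC estimate from a variation matrix, with iterative exclusion."""
    d = t.shape[0]
    excluded = np.zeros_like(t, dtype=bool)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        # M @ omega2 = t_row_sums, with excluded pairs removed from both sides
        active = ~excluded
        np.fill_diagonal(active, False)
        M = np.ones((d, d))
        M[excluded] = 0.0
        # t_i = (d-1-e_i)·ω_i² + Σ_{active j≠i} ω_j², e_i = excluded partners
        np.fill_diagonal(M, d - 1 - excluded.sum(axis=1))
        # keep the system solvable when a taxon lost too many partners
        np.fill_diagonal(M, np.maximum(np.diag(M), 1.0))
        trow = np.where(active, t, 0.0).sum(axis=1)
        omega2 = np.linalg.solve(M, trow)
        omega2 = np.maximum(omega2, 1e-12)
        om = np.sqrt(omega2)
        rho = (omega2[:, None] + omega2[None, :] - t) / (2 * np.outer(om, om))
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0), om

    rho, _ = solve()
    for _ in range(n_rounds):
        mag = np.abs(np.where(excluded, 0.0, rho))
        np.fill_diagonal(mag, 0.0)
        i, j = np.unravel_index(np.argmax(mag), mag.shape)
        if mag[i, j] <= threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        rho, _ = solve()
    return rho


def sparcc_correlations(table: CountTable, cfg: SparccConfig = SparccConfig()) -> pd.DataFrame:
    """Estimate basis correlations between ASVs from compositional counts.

    Each Dirichlet resample draws posterior fractions (counts + 1 pseudo
    prior), computes the log-ratio variation matrix and solves for basis
    correlations; the reported matrix is the element-wise median over
    resamples, clamped to [−1, 1] with unit diagonal.

    Requires ≥ 4 ASVs (the basis-variance system is underdetermined below
    that); fewer than 10 samples triggers a warning.
    """
    counts = table.counts()
    n, d = counts.shape
    if d < 4:
        raise ValueError(f"SparCC needs at least 4 ASVs, got {d}")
    if n < 10:
        logger.warning("sparcc_correlations: only %d samples; estimates will be noisy", n)
    empty = np.flatnonzero(counts.sum(axis=0) == 0)
    if empty.size:
        names = [table.asv_ids[k] for k in empty[:5]]
        raise ValueError(f"ASV(s) with no reads anywhere: {names}")

    rng = np.random.default_rng(cfg.seed)
    estimates = np.empty((cfg.n_resamples, d, d))
    alpha = counts + 1.0
    for r in range(cfg.n_resamples):
        frac = np.vstack([rng.dirichlet(alpha[s]) for s in range(n)])
        t = _variation_matrix(frac)
        estimates[r] = _basis_correlations(t, cfg.n_exclusion_rounds, cfg.exclusion_threshold)
    rho = np.median(estimates, axis=0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=table.asv_ids, columns=table.asv_ids)


def _interaction_dissimilarity(table: CountTable, S: pd.DataFrame,
                               weighted: bool) -> DistanceMatrix:
    ids = list(table.asv_ids)
    missing = [t for t in ids if t not in S.index]
    if missing:
        raise ValueError(f"ASVs absent from similarity matrix: {missing[:5]}")
    Sm = S.loc[ids, ids].to_numpy(dtype=float)
    counts = table.counts().astype(float)
    if weighted:
        row = counts.sum(axis=1)
        if (row == 0).any():
            bad = [table.sample_ids[k] for k in np.flatnonzero(row == 0)]
            raise ValueError(f"sample(s) with no ASVs: {bad}")
        W = counts / row[:, None]
    else:
        pres = (counts > 0).astype(float)
        rich = pres.sum(axis=1)
        if (rich == 0).any():
            bad = [table.sample_ids[k] for k in np.flatnonzero(rich == 0)]
            raise ValueError(f"sample(s) with no ASVs: {bad}")
        W = pres / rich[:, None]
    U = W @ Sm  # interaction profiles, samples x taxa
    norms = np.linalg.norm(U, axis=1)
    if (norms == 0).any():
        bad = [table.sample_ids[k] for k in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero interaction profile for sample(s): {bad}")
    cos = (U @ U.T) / np.outer(norms, norms)
    dis = 1.0 - np.clip(cos, -1.0, 1.0)
    dis = np.clip((dis + dis.T) / 2, 0.0, None)
    np.fill_diagonal(dis, 0.0)
    return DistanceMatrix(dis, ids=[str(s) for s in table.sample_ids])


def tina_dissimilarity(table: CountTable, assoc: pd.DataFrame,
                       weighted: bool = True) -> DistanceMatrix:
    """Taxon interaction-adjusted (TINA) dissimilarity.

    Correlations are rescaled to similarities S = (ρ + 1)/2 (keeping
    profiles non-negative), samples are projected through S with relative-
    abundance weights (``weighted``) or richness-normalised presence
    weights, and compared by 1 − cosine similarity.  Values lie in [0, 1].
    """
    S = (assoc + 1.0) / 2.0
    return _interaction_dissimilarity(table, S, weighted)


def pina_dissimilarity(table: CountTable, coph: DistanceMatrix,
                       weighted: bool = True) -> DistanceMatrix:
    """Phylogenetic interaction-adjusted (PINA) dissimilarity.

    Identical machinery to TINA with phylogenetic similarity
    S_ij = 1 − d_ij / max(d) in place of the co-occurrence similarity.
    """
    d = coph.data
    mx = d.max()
    if mx == 0:
        raise ValueError("cophenetic matrix has no variation")
    S = pd.DataFrame(1.0 - d / mx, index=coph.ids, columns=coph.ids)
    return _interaction_dissimilarity(table, S, weighted)
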