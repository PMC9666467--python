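"""Count tables, sample metadata, and the standard amplicon preprocessing steps.

The central carrier is :class:`CountTable`, a thin validated wrapper around a
pandas DataFrame holding non-negative integer read counts with samples in rows
and ASVs (amplicon sequence variants) in columns.  Everything downstream —
dissimilarity matrices, null models, interaction-adjusted indices — consumes
this one container, so the samples-in-rows convention is enforced here once.

Preprocessing mirrors common practice for marker-gene surveys: a prevalence/
abundance filter against spurious rare sequences, rarefaction to a common
sequencing depth, total-sum normalisation, and inverse-Simpson alpha
diversity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "SampleMetadata",
    "FilterRule",
    "read_count_table",
    "write_count_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "abundance_filter",
    "rarefy",
    "relative_abundance",
    "inverse_simpson",
]

SIZE_FRACTIONS = ("FL_0.2_3", "PA_3_8", "PA_gt8")


class CountTable:
    """Samples × ASVs matrix of non-negative integer read counts.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are ASVs.  Values must be non-negative
        integers; duplicate sample or ASV identifiers are rejected.
    """

    def __init__(self, counts: pd.DataFrame):
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV IDs: {dups}")
        values = counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values), atol=0):
                bad = np.argwhere(values != np.round(values))[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{counts.index[bad[0]]!r}, ASV {counts.columns[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if values.size and (counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        self._df = counts.astype(np.int64, copy=False)

    # -- container protocol -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        """The underlying samples × ASVs DataFrame (do not mutate)."""
        return self._df

    @property
    def sample_ids(self) -> list:
        return list(self._df.index)

    @property
    def asv_ids(self) -> list:
        return list(self._df.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def counts(self) -> np.ndarray:
        return self._df.to_numpy()

    def sample(self, sample_id) -> pd.Series:
        return self._df.loc[sample_id]

    def subset_samples(self, sample_ids) -> "CountTable":
        return CountTable(self._df.loc[list(sample_ids)])

    def subset_asvs(self, asv_ids) -> "CountTable":
        return CountTable(self._df.loc[:, list(asv_ids)])

    def drop_empty_asvs(self) -> "CountTable":
        keep = self._df.sum(axis=0) > 0
        return CountTable(self._df.loc[:, keep])

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self._df.equals(other._df)

    def __repr__(self) -> str:
        n, m = self._df.shape
        return f"CountTable({n} samples x {m} ASVs, {int(self._df.to_numpy().sum())} reads)"


class SampleMetadata:
    """Per-sample metadata: position, depth, size fraction and environment.

    Wraps a DataFrame indexed by sample ID.  Recognised columns are
    ``latitude`` (degrees, [-90, 90]), ``longitude`` (degrees, (-180, 180]),
    ``depth`` (m, > 0), ``size_fraction`` (one of ``FL_0.2_3``, ``PA_3_8``,
    ``PA_gt8``), ``layer`` (``epipelagic``/``mesopelagic``; derived from depth
    when absent: ≤100 m epipelagic, ≥200 m mesopelagic) and ``province``.
    All remaining numeric columns are treated as environmental variables
    (temperature in °C, nutrients, oxygen, ...).
    """

    CORE_COLUMNS = ("latitude", "longitude", "depth", "size_fraction", "layer", "province")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs in metadata: {dups}")
        frame = frame.copy()
        if "latitude" in frame:
            lat = frame["latitude"].astype(float)
            if ((lat < -90) | (lat > 90)).any():
                raise ValueError("latitude outside [-90, 90]")
        if "longitude" in frame:
            lon = frame["longitude"].astype(float)
            if ((lon <= -180) | (lon > 180)).any():
                raise ValueError("longitude outside (-180, 180]")
        if "depth" in frame:
            depth = frame["depth"].astype(float)
            if (depth <= 0).any():
                raise ValueError("depth must be positive (metres below surface)")
            if "layer" not in frame:
                frame["layer"] = np.where(depth <= 100, "epipelagic", "mesopelagic")
        if "size_fraction" in frame:
            bad = set(frame["size_fraction"].dropna()) - set(SIZE_FRACTIONS)
            if bad:
                raise ValueError(f"unknown size fractions: {sorted(bad)}")
        self._df = frame

    @property
    def data(self) -> pd.DataFrame:
        return self._df

    @property
    def sample_ids(self) -> list:
        return list(self._df.index)

    def env_variables(self) -> list[str]:
        """Names of the numeric environmental columns (non-core numerics)."""
        num = self._df.select_dtypes(include=[np.number]).columns
        return [c for c in num if c not in ("latitude", "longitude", "depth")]

    def variable(self, name: str) -> pd.Series:
        if name not in self._df:
            raise KeyError(f"metadata has no variable {name!r}")
        return self._df[name]

    def aligned_to(self, sample_ids) -> "SampleMetadata":
        missing = [s for s in sample_ids if s not in self._df.index]
        if missing:
            raise KeyError(f"metadata missing samples: {missing}")
        return SampleMetadata(self._df.loc[list(sample_ids)])

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self._df)} samples, columns={list(self._df.columns)})"


@dataclass(frozen=True)
class FilterRule:
    """Three-clause prevalence/abundance filter for ASVs.

    An ASV is retained when its whole-dataset relative abundance exceeds
    ``global_min_fraction`` AND it satisfies at least one clause:

    1. present in ≥ ``clause1_min_samples`` samples at relative abundance
       > ``clause1_min_rel_abund`` (default: 2 samples above 1%);
    2. present in ≥ ``clause2_min_sample_fraction`` of all samples at relative
       abundance > ``clause2_min_rel_abund`` (default: 2% of samples above 0.1%);
    3. present (any abundance) in ≥ ``clause3_min_sample_fraction`` of all
       samples (default: 5% of samples).

    Sample-fraction thresholds convert to counts with a ceiling, preserving
    their "at least" reading.
    """

    global_min_fraction: float = 1e-5
    clause1_min_samples: int = 2
    clause1_min_rel_abund: float = 0.01
    clause2_min_sample_fraction: float = 0.02
    clause2_min_rel_abund: float = 0.001
    clause3_min_sample_fraction: float = 0.05

    def __post_init__(self):
        for name in (
            "global_min_fraction",
            "clause1_min_rel_abund",
            "clause2_min_sample_fraction",
            "clause2_min_rel_abund",
            "clause3_min_sample_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _write_provenance(path: Path, **params) -> None:
    """Emit a small YAML sidecar recording how a file was produced."""
    from . import __version__

    sidecar = Path(str(path) + ".prov.yaml")
    record = {"file": Path(path).name, "pelagos_version": __version__, **params}
    sidecar.write_text(yaml.safe_dump(record, sort_keys=False))


def read_count_table(path, orientation: str = "samples") -> CountTable:
    """Read a TSV count table.

    Parameters
    ----------
    path : str or Path
        TSV file with one header row and the first column holding IDs.
    orientation : {"samples", "asvs"}
        Whether rows of the file are samples or ASVs.  The returned table is
        always samples × ASVs.
    """
    if orientation not in ("samples", "asvs"):
        raise ValueError("orientation must be 'samples' or 'asvs'")
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric count in column {col!r}, row(s) {list(bad[:3])}"
            )
    if orientation == "asvs":
        df = df.T
    return CountTable(df)


def write_count_table(table: CountTable, path, orientation: str = "samples",
                      provenance: dict | None = None) -> None:
    """Write a count table as TSV (with a YAML provenance sidecar)."""
    if orientation not in ("samples", "asvs"):
        raise ValueError("orientation must be 'samples' or 'asvs'")
    df = table.data if orientation == "samples" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")
    _write_provenance(Path(path), orientation=orientation, **(provenance or {}))


def read_sample_metadata(path) -> SampleMetadata:
    """Read sample metadata from a TSV keyed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_sample_metadata(meta: SampleMetadata, path, provenance: dict | None = None) -> None:
    meta.data.to_csv(path, sep="\t", index_label="sample_id")
    _write_provenance(Path(path), **(provenance or {}))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def abundance_filter(table: CountTable, rule: FilterRule = FilterRule()) -> CountTable:
    """Apply the three-clause prevalence/abundance filter to the ASV set.

    Samples are left untouched; only ASV columns failing the rule are removed.
    Raises on an empty table.
    """
    counts = table.data
    if counts.size == 0:
        raise ValueError("cannot filter an empty count table")
    total = counts.to_numpy().sum()
    if total == 0:
        raise ValueError("count table contains no reads")
    n_samples = counts.shape[0]

    global_frac = counts.sum(axis=0) / total
    keep_global = global_frac > rule.global_min_fraction

    row_sums = counts.sum(axis=1).to_numpy().astype(float)
    row_sums[row_sums == 0] = np.nan  # empty samples contribute nothing
    rel = counts.to_numpy() / row_sums[:, None]

    c1 = (rel > rule.clause1_min_rel_abund).sum(axis=0) >= rule.clause1_min_samples
    c2_min = math.ceil(rule.clause2_min_sample_fraction * n_samples)
    c2 = (rel > rule.clause2_min_rel_abund).sum(axis=0) >= c2_min
    c3_min = math.ceil(rule.clause3_min_sample_fraction * n_samples)
    c3 = (counts.to_numpy() > 0).sum(axis=0) >= c3_min

    keep = keep_global.to_numpy() & (c1 | c2 | c3)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("abundance_filter removed %d of %d ASVs", dropped, counts.shape[1])
    return CountTable(counts.loc[:, keep])


def rarefy(table: CountTable, depth: int, seed=None) -> CountTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (and logged).
    Sampling is multivariate hypergeometric, i.e. classical rarefaction.
    """
    if depth is None or int(depth) <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    depth = int(depth)
    rng = np.random.default_rng(seed)
    counts = table.data
    totals = counts.sum(axis=1)
    kept = totals.index[totals >= depth]
    dropped = totals.index[totals < depth].tolist()
    if dropped:
        logger.warning(
            "rarefy(depth=%d) dropped %d samples below depth: %s",
            depth, len(dropped), dropped,
        )
    out = np.empty((len(kept), counts.shape[1]), dtype=np.int64)
    for i, s in enumerate(kept):
        row = counts.loc[s].to_numpy()
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(pd.DataFrame(out, index=kept, columns=counts.columns))


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Total-sum normalise each sample; rows sum to 1."""
    counts = table.data
    row_sums = counts.sum(axis=1)
    zero = row_sums.index[row_sums == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s): {zero}")
    return counts.div(row_sums, axis=0)


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1/Σp², the effective number of species."""
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("inverse_simpson expects a single sample vector")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    p = x / total
    return float(1.0 / np.sum(p * p))
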