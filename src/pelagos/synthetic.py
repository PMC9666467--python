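"""Synthetic latitudinal-transect datasets with known assembly regimes.

The generator emulates the sampling design of a basin-scale marine transect:
stations evenly spaced along a latitudinal gradient, a tropical-peaked
temperature field decaying with depth, three plankton size fractions, and
integer ASV read counts at realistic sequencing depths.  Ground truth is
explicit: an ultrametric phylogeny, Brownian-motion thermal niches on that
phylogeny (so niches are phylogenetically conserved, satisfying the
phylogenetic-signal precondition of the null-model framework), and a known
assembly *regime* controlling which ecological mechanism dominates:

* ``selection`` — narrow Gaussian environmental filter (small σ_w), free
  dispersal, large communities: temperature sorts taxa deterministically.
* ``dispersal_limitation`` — no filter, but regional metacommunity pools
  perturbed independently and mixed with an exponential distance kernel:
  compositional turnover without phylogenetic turnover.
* ``neutral_drift`` — no filter, free dispersal, small local communities
  (small J): sampling noise dominates.
* ``mixed`` — intermediate values of all three.

Communities assemble per station/depth as a multinomial draw of J
individuals with weight m_i · exp(−(z_i − E_s)² / (2σ_w²)) · k(distance),
and sequencing draws ``read_depth`` reads from the realised community.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skbio import TreeNode

from .table import CountTable, SampleMetadata, write_count_table, write_sample_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_traits",
    "assemble_communities",
    "generate_dataset",
]

REGIMES = ("selection", "dispersal_limitation", "neutral_drift", "mixed")
DEPTH_LEVELS = (20.0, 40.0, 60.0, 100.0, 130.0, 200.0, 300.0, 500.0)
SIZE_FRACTION_LEVELS = ("FL_0.2_3", "PA_3_8", "PA_gt8")

# regime presets: (selection width sigma_w [°C], dispersal e-folding [km],
# local community size J, local pool-perturbation log-SD, transect peak
# temperature [°C], metacommunity lognormal SD); None = unlimited / keep
# the config value.
# The selection scenario samples a subpolar transect (2-10 °C) out of a
# basin-wide pool whose thermal niches centre far warmer, so every station
# filters the phylogenetically clustered cold flank of the niche
# distribution; moderate J and local pool perturbation supply the
# species-level turnover against which the clade-level filter is visible.
_REGIME_PRESETS = {
    "selection": (2.0, None, 300, 0.7, 10.0, 0.5),
    "dispersal_limitation": (None, 1500.0, 100_000, 0.0, None, 1.5),
    "neutral_drift": (None, None, 500, 0.0, None, 1.5),
    "mixed": (4.0, 3000.0, 10_000, 0.5, None, 1.0),
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic transect scenario.

    ``sigma_w``, ``dispersal_scale`` and ``community_size`` default to the
    regime's preset when left ``None``.  ``None`` for the first two means
    "unlimited" (no filter / perfect mixing).
    """

    regime: str = "selection"
    n_stations: int = 26
    n_depths: int = 1
    n_size_fractions: int = 1
    lat_range: tuple = (-52.1, 58.9)
    longitude: float = 180.0
    temperature_peak: float | None = None  # °C at the equator (regime preset or 29)
    temperature_polar_min: float = 2.0  # °C floor towards the poles
    temperature_width: float = 20.0     # Gaussian width in degrees latitude
    n_taxa: int = 200
    metacommunity_mean: float = 0.0     # lognormal log-mean of regional abundances
    metacommunity_sd: float | None = None  # lognormal log-sd (regime preset)
    brownian_rate: float = 64.0         # trait variance per unit branch length (°C²)
    trait_root: float = 15.5            # root niche optimum, °C
    sigma_w: float | None = None
    dispersal_scale: float | None = None
    community_size: int | None = None   # J, individuals per local community
    local_noise_sd: float | None = None  # per-sample lognormal pool perturbation
    read_depth: int = 8000
    n_regions: int = 5                  # regional pools for dispersal limitation
    region_pool_sd: float = 2.0         # log-perturbation SD of regional pools
    birth_rate: float = 1.0
    death_rate: float = 0.8             # high turnover: clumpy, clade-rich trees
    seed: int | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        for name in ("n_stations", "n_depths", "n_size_fractions", "n_taxa",
                     "read_depth", "n_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        preset = _REGIME_PRESETS[self.regime]
        if self.sigma_w is None:
            self.sigma_w = preset[0]
        if self.dispersal_scale is None:
            self.dispersal_scale = preset[1]
        if self.community_size is None:
            self.community_size = preset[2]
        if self.local_noise_sd is None:
            self.local_noise_sd = preset[3]
        if self.temperature_peak is None:
            self.temperature_peak = preset[4] if preset[4] is not None else 29.0
        if self.metacommunity_sd is None:
            self.metacommunity_sd = preset[5]
        if self.sigma_w is not None and self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive (or None for unlimited)")
        if self.community_size < 1:
            raise ValueError("community_size must be >= 1")
        if self.community_size < self.read_depth:
            logger.info(
                "community_size J=%d below read_depth=%d; reads resample individuals",
                self.community_size, self.read_depth,
            )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "lat_range" in raw:
            raw["lat_range"] = tuple(raw["lat_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lat_range"] = list(d["lat_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class SyntheticDataset:
    """A generated transect: counts, metadata, tree, true niches, regime."""

    table: CountTable
    metadata: SampleMetadata
    tree: TreeNode
    traits: pd.Series  # true thermal niche optimum per tip, °C
    regime: str
    config: ScenarioConfig

    def write(self, outdir) -> dict:
        """Write all fixture files (TSV / Newick / YAML) under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "metadata": outdir / "metadata.tsv",
            "tree": outdir / "tree.nwk",
            "traits": outdir / "traits.tsv",
            "config": outdir / "scenario.yaml",
        }
        prov = {"regime": self.regime, "seed": self.config.seed}
        write_count_table(self.table, paths["counts"], provenance=prov)
        write_sample_metadata(self.metadata, paths["metadata"], provenance=prov)
        self.tree.write(str(paths["tree"]), format="newick")
        self.traits.rename("thermal_niche_C").to_csv(paths["traits"], sep="\t",
                                                     index_label="asv_id")
        self.config.to_yaml(paths["config"])
        return paths


# ---------------------------------------------------------------------------
# Tree and trait simulation
# ---------------------------------------------------------------------------

def simulate_tree(n_taxa: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed=None) -> TreeNode:
    """Simulate an ultrametric birth–death tree with ``n_taxa`` extant tips.

    Forward Gillespie simulation; lineages going extinct are pruned and the
    run restarts if everything dies.  After the last speciation an
    exponential tail is appended so pendant edges are strictly positive.
    Branch lengths are rescaled to unit crown depth.  Tips are named
    ``ASV_0001`` ... in simulation order.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if birth_rate <= death_rate or death_rate < 0 or birth_rate <= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = np.random.default_rng(seed)
    total_rate = birth_rate + death_rate
    p_birth = birth_rate / total_rate

    for _ in range(10_000):
        root = TreeNode()
        starts = {id(root): 0.0}
        active = [root]
        t = 0.0
        while active and len(active) < n_taxa:
            t += rng.exponential(1.0 / (len(active) * total_rate))
            k = int(rng.integers(len(active)))
            node = active.pop(k)
            if rng.random() < p_birth:
                c1, c2 = TreeNode(), TreeNode()
                node.extend([c1, c2])
                node.length = t - starts[id(node)] if node.parent else None
                starts[id(c1)] = starts[id(c2)] = t
                active.extend([c1, c2])
            else:
                node.length = t - starts[id(node)]
                node.name = "__dead__"
        if not active:
            continue
        t_end = t + rng.exponential(1.0 / (len(active) * total_rate))
        for i, node in enumerate(active):
            node.length = (t_end - starts[id(node)]) if node.parent else None
            node.name = f"ASV_{i + 1:04d}"

        # prune extinct lineages, then drop unifurcations
        dead = [tip for tip in root.tips() if tip.name == "__dead__"]
        if dead:
            keep = [tip.name for tip in root.tips() if tip.name != "__dead__"]
            if len(keep) < n_taxa:
                continue
            root = root.shear(keep)
        root.prune()
        depth = max(root.distance(tip) for tip in root.tips())
        if depth <= 0:
            continue
        for node in root.traverse(include_self=False):
            node.length = (node.length or 0.0) / depth
        root.length = None
        return root
    raise RuntimeError("tree simulation failed to reach the requested tip count")


def simulate_traits(tree: TreeNode, brownian_rate: float, root_value: float = 0.0,
                    seed=None) -> pd.Series:
    """Brownian-motion trait evolution along the tree.

    Each branch adds a Normal(0, brownian_rate · length) increment, so
    closely related tips end near each other — phylogenetically conserved
    niches by construction.  Returns the tip values (°C).
    """
    if brownian_rate < 0:
        raise ValueError("brownian_rate must be >= 0")
    rng = np.random.default_rng(seed)
    values = {id(tree): float(root_value)}
    for node in tree.preorder(include_self=False):
        if node.length is None:
            raise ValueError("tree has a branch without length")
        step = rng.normal(0.0, np.sqrt(brownian_rate * node.length)) if brownian_rate else 0.0
        values[id(node)] = values[id(node.parent)] + step
    return pd.Series({tip.name: values[id(tip)] for tip in tree.tips()},
                     name="thermal_niche_C")


# ---------------------------------------------------------------------------
# Community assembly
# ---------------------------------------------------------------------------

def _temperature(lat: np.ndarray, depth: float, cfg: ScenarioConfig) -> np.ndarray:
    surf = cfg.temperature_polar_min + (cfg.temperature_peak - cfg.temperature_polar_min) \
        * np.exp(-lat ** 2 / (2 * cfg.temperature_width ** 2))
    # exponential cooling with depth towards the polar floor
    atten = np.exp(-max(0.0, depth - DEPTH_LEVELS[0]) / 250.0)
    return cfg.temperature_polar_min + (surf - cfg.temperature_polar_min) * atten


def _province(lat: float) -> str:
    a = abs(lat)
    if a < 23.5:
        return "TROP"
    if a < 40.0:
        return "SUBT"
    if a < 52.0:
        return "TEMP"
    return "SUBP"


def assemble_communities(cfg: ScenarioConfig, tree: TreeNode,
                         traits: pd.Series, seed=None) -> SyntheticDataset:
    """Assemble local communities and sequencing reads for every sample.

    Station sampling weight of taxon i at temperature E_s is
    m_i · exp(−(z_i − E_s)²/(2σ_w²)) · (distance-kernel mixture of regional
    pools); the local community is a multinomial draw of J individuals and
    the reads a multinomial draw of ``read_depth`` from the community.
    """
    tips = [t.name for t in tree.tips()]
    if set(traits.index) != set(tips):
        raise ValueError("traits and tree tips are inconsistent")
    if cfg.n_taxa != len(tips):
        raise ValueError(f"config expects {cfg.n_taxa} taxa, tree has {len(tips)}")
    z = traits.loc[tips].to_numpy(dtype=float)
    rng = np.random.default_rng(seed if seed is not None else cfg.seed)

    m = rng.lognormal(cfg.metacommunity_mean, cfg.metacommunity_sd, size=len(tips))

    lats = np.linspace(cfg.lat_range[0], cfg.lat_range[1], cfg.n_stations)
    # positions along the transect in km (meridional spacing, 111.19 km/deg)
    km_per_deg = 2 * np.pi * 6371.0 / 360.0
    station_km = (lats - lats[0]) * km_per_deg

    # regional pools (used only when dispersal is limited)
    if cfg.dispersal_scale is not None:
        centers_km = np.linspace(station_km[0], station_km[-1], cfg.n_regions)
        region_pools = m[None, :] * np.exp(
            rng.normal(0.0, cfg.region_pool_sd, size=(cfg.n_regions, len(tips))))
    else:
        centers_km = None
        region_pools = None

    depths = DEPTH_LEVELS[: cfg.n_depths]
    fractions = SIZE_FRACTION_LEVELS[: cfg.n_size_fractions]

    rows, meta_rows, sample_ids = [], [], []
    for si, lat in enumerate(lats):
        for depth in depths:
            temp = float(_temperature(np.array([lat]), depth, cfg)[0])
            if cfg.dispersal_scale is not None:
                kernel = np.exp(-np.abs(station_km[si] - centers_km) / cfg.dispersal_scale)
                pool = kernel @ region_pools
            else:
                pool = m
            if cfg.sigma_w is not None:
                filt = np.exp(-((z - temp) ** 2) / (2 * cfg.sigma_w ** 2))
            else:
                filt = 1.0
            w = pool * filt
            if cfg.local_noise_sd:
                # fine-scale patchiness: independent lognormal perturbation of
                # each station's effective pool (species-level turnover that a
                # clade-level filter leaves intact)
                w = w * np.exp(rng.normal(0.0, cfg.local_noise_sd, size=len(tips)))
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                raise ValueError(
                    f"degenerate sampling weights at station {si + 1}, depth {depth}")
            w = w / total
            for frac in fractions:
                community = rng.multinomial(cfg.community_size, w)
                reads = rng.multinomial(cfg.read_depth, community / cfg.community_size)
                sid = f"S{si + 1:02d}_D{int(depth):03d}_{frac}"
                sample_ids.append(sid)
                rows.append(reads)
                meta_rows.append({
                    "sample_id": sid,
                    "latitude": float(lat),
                    "longitude": cfg.longitude,
                    "depth": float(depth),
                    "size_fraction": frac,
                    "province": _province(lat),
                    "temperature": temp,
                })
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64),
                          index=sample_ids, columns=tips)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return SyntheticDataset(CountTable(counts), SampleMetadata(meta), tree,
                            traits, cfg.regime, cfg)


def generate_dataset(cfg: ScenarioConfig, outdir=None) -> SyntheticDataset:
    """Generate a complete scenario (tree + traits + communities) from one
    config; deterministic under ``cfg.seed``.  Writes fixture files when
    ``outdir`` is given."""
    ss = np.random.SeedSequence(cfg.seed if cfg.seed is not None else None)
    s_tree, s_traits, s_comm = (int(s.generate_state(1)[0] % (2 ** 31))
                                for s in ss.spawn(3))
    tree = simulate_tree(cfg.n_taxa, cfg.birth_rate, cfg.death_rate, seed=s_tree)
    traits = simulate_traits(tree, cfg.brownian_rate, cfg.trait_root, seed=s_traits)
    ds = assemble_communities(cfg, tree, traits, seed=s_comm)
    if outdir is not None:
        ds.write(outdir)
    return ds
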