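"""Synthetic Visium-like tissue/organoid samples and single-cell datasets.

The generator emulates the statistical structure the downstream stages
assume, so the whole pipeline is exercisable without any download:

* hexagonal spot lattices (Visium-style doubled array coordinates) for
  tissue sections at several gestational timepoints, and disc-shaped
  organoid sections;
* spatially structured cell-type mixtures: a ventricular-zone-like
  progenitor pole grading into a mature pole along a maturation axis,
  with older tissues globally shifted toward mature types;
* negative-binomial counts whose means are mixture-weighted cell-type
  signatures, with module genes co-varying with maturation/pseudotime;
* organoid samples whose expected niche composition interpolates between
  two tissue timepoints with a known mixing weight ``mix_alpha``.

Every stochastic draw flows from one :class:`numpy.random.Generator`
seeded by ``SyntheticConfig.seed``, so entire runs are replayable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._exceptions import ParameterError
from .io_core import (
    ORGANOID,
    TISSUE,
    CountMatrix,
    SampleMeta,
    SpotGrid,
    write_mtx_counts,
    write_spot_positions,
    write_table,
)

logger = logging.getLogger("mbstage.synthetic_data")

import scipy.sparse as sp


@dataclass
class ModuleSpec:
    """One co-regulated gene module: ids of member genes and the log-scale
    effect size with which their expression follows pseudotime/maturation."""

    module_id: str
    genes: list[str]
    effect: float


def _default_timepoints() -> list[SampleMeta]:
    return [
        SampleMeta("tissue_7pcw", TISSUE, 7.0),
        SampleMeta("tissue_11pcw", TISSUE, 11.0),
        SampleMeta("tissue_17pcw", TISSUE, 17.0),
    ]


@dataclass
class SyntheticConfig:
    """Knobs of the generator. Defaults are the package's study conditions.

    ``gradient_strength`` tilts per-spot type mixtures along the maturation
    axis (progenitor types enriched at the ventricular pole); an equal
    ``timepoint_strength`` shifts whole samples toward mature types with
    gestational age, which is what makes timepoints distinguishable and
    temporal alignment a recoverable quantity.
    """

    seed: int = 0
    n_types: int = 5
    grid_radius: int = 5
    dirichlet_alpha: float | Sequence[float] = 2.0
    gradient_strength: float = 3.0
    timepoint_strength: float = 3.0
    n_genes: int = 200
    nb_mean: float = 5.0
    nb_dispersion: float = 2.0
    module_spec: list[ModuleSpec] = field(default_factory=list)
    mix_alpha: float = 0.5
    timepoints: list[SampleMeta] = field(default_factory=_default_timepoints)
    # single-cell settings
    n_cells: int = 1000
    sc_cell_types: tuple[str, ...] = ("progenitor", "intermediate", "mature")
    sc_timepoints: tuple[float, ...] = (10.0, 16.0)
    sc_replicates: tuple[str, ...] = ("r1", "r2")
    n_clusters: int = 6

    def __post_init__(self) -> None:
        alpha = np.broadcast_to(np.asarray(self.dirichlet_alpha, dtype=float), (self.n_types,))
        if np.any(alpha <= 0):
            raise ParameterError("dirichlet_alpha must all be > 0")
        self.dirichlet_alpha = np.array(alpha)
        if not self.nb_dispersion > 0:
            raise ParameterError("nb_dispersion must be > 0")
        if not 0.0 <= self.mix_alpha <= 1.0:
            raise ParameterError("mix_alpha must be in [0, 1]")
        if not self.module_spec:
            self.module_spec = default_module_spec(self.n_genes)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def type_names(self) -> list[str]:
        return [f"type{k}" for k in range(self.n_types)]

    def type_scores(self) -> np.ndarray:
        """Maturity score per type in [-1, 1]: type0 most progenitor-like."""
        return np.linspace(-1.0, 1.0, self.n_types)

    def timepoint_range(self) -> tuple[float, float]:
        vals = [m.timepoint_value for m in self.timepoints]
        return min(vals), max(vals)


def default_module_spec(n_genes: int) -> list[ModuleSpec]:
    """Three 10-gene modules: maturation-up, maturation-down and null."""
    if n_genes < 30:
        raise ParameterError("need >= 30 genes for the default module spec")
    g = [f"gene{i}" for i in range(n_genes)]
    return [
        ModuleSpec("module_up", g[0:10], 2.0),
        ModuleSpec("module_down", g[10:20], -2.0),
        ModuleSpec("module_null", g[20:30], 0.0),
    ]


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    mixtures: np.ndarray | None = None  # (n_spots, K), rows sum to 1
    maturation: np.ndarray | None = None  # (n_spots,) in [0, 1]
    pseudotime: np.ndarray | None = None  # (n_cells,) in [0, 1]
    mix_alpha: float | None = None
    implied_timepoint: float | None = None
    meta: SampleMeta | None = None
    t_norm: float | None = None  # normalized timepoint over the reference range


# ---------------------------------------------------------------------------
# Hex lattice geometry (Visium doubled-column array coordinates)
# ---------------------------------------------------------------------------

def hex_disc(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Axial hex disc of the given ring radius.

    Returns (array_coords, phys_coords). Array coordinates use the doubled
    column convention (array_col = 2q + r), so the six lattice neighbors
    differ by (±1, ±1) and (0, ±2) — the Visium array layout.
    """
    if radius < 1:
        raise ParameterError("grid radius must be >= 1")
    arr, phys = [], []
    for q in range(-radius, radius + 1):
        for r in range(-radius, radius + 1):
            if max(abs(q), abs(r), abs(q + r)) > radius:
                continue
            row = r + radius
            col = 2 * q + r + 3 * radius  # shift to nonnegative
            x = q + r / 2.0
            y = r * np.sqrt(3.0) / 2.0
            arr.append((row, col))
            phys.append((x, y))
    return np.array(arr, dtype=int), np.array(phys, dtype=float)


def _make_grid(radius: int, meta: SampleMeta, prefix: str) -> SpotGrid:
    arr, phys = hex_disc(radius)
    spots = [f"{prefix}_s{i:04d}" for i in range(len(arr))]
    return SpotGrid(spots=spots, array_coords=arr, phys_coords=phys, meta=meta)


# ---------------------------------------------------------------------------
# Mixtures, signatures and counts
# ---------------------------------------------------------------------------

def expected_mixture(cfg: SyntheticConfig, maturation: np.ndarray, t_norm: float) -> np.ndarray:
    """Expected type mixture at maturation coordinate m for a sample whose
    normalized timepoint is ``t_norm`` (0 = youngest, 1 = oldest reference).

    mixture_k(m) ∝ alpha_k * exp(s_k * [g*(m-1/2) + gt*(t_norm-1/2)])
    with s_k the per-type maturity score. At zero gradient and centered
    timepoint this reduces to the Dirichlet mean alpha / sum(alpha).
    """
    m = np.atleast_1d(np.asarray(maturation, dtype=float))
    scores = cfg.type_scores()
    tilt = (
        cfg.gradient_strength * (m[:, None] - 0.5)
        + cfg.timepoint_strength * (t_norm - 0.5)
    ) * scores[None, :]
    w = cfg.dirichlet_alpha[None, :] * np.exp(tilt)
    return w / w.sum(axis=1, keepdims=True)


def _draw_mixtures(rng: np.random.Generator, expected: np.ndarray, concentration: float) -> np.ndarray:
    return np.vstack([rng.dirichlet(np.maximum(concentration * p, 1e-8)) for p in expected])


def type_signatures(cfg: SyntheticConfig) -> np.ndarray:
    """(K, G) per-type mean expression signatures, deterministic given seed.

    Each gene gets a baseline mean around ``nb_mean`` and is a marker of one
    type (cyclically assigned) with an 8-fold boost, so argmax labeling and
    HVG selection have real signal to find. Derived from a child seed so
    tissues, organoids and readers of GroundTruth all share one signature set.
    """
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 7])
    base = rng.gamma(shape=2.0, scale=cfg.nb_mean / 2.0, size=cfg.n_genes)
    sig = np.tile(base, (cfg.n_types, 1))
    marker_type = np.arange(cfg.n_genes) % cfg.n_types
    for k in range(cfg.n_types):
        sig[k, marker_type == k] *= 8.0
    return sig


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson draw: variance = mu + mu^2 / dispersion."""
    mean = np.maximum(mean, 1e-12)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def _counts_from_mixtures(
    cfg: SyntheticConfig, rng: np.random.Generator, mixtures: np.ndarray, maturation: np.ndarray
) -> np.ndarray:
    sig = type_signatures(cfg)
    mu = mixtures @ sig
    # module genes additionally follow the maturation coordinate
    gene_index = {g: i for i, g in enumerate(f"gene{i}" for i in range(cfg.n_genes))}
    for mod in cfg.module_spec:
        idx = [gene_index[g] for g in mod.genes if g in gene_index]
        mu[:, idx] = mu[:, idx] * np.exp(mod.effect * (maturation[:, None] - 0.5))
    return _nb_counts(rng, mu, cfg.nb_dispersion)


def _package_sample(
    cfg: SyntheticConfig, grid: SpotGrid, mixtures: np.ndarray, counts: np.ndarray
):
    from .niche_similarity import AbundanceMatrix

    ab = AbundanceMatrix(spots=list(grid.spots), types=cfg.type_names, values=mixtures.copy())
    gene_ids = [f"gene{i}" for i in range(cfg.n_genes)]
    cm = CountMatrix(entities=list(grid.spots), genes=gene_ids, counts=sp.csr_matrix(counts))
    return ab, cm


# ---------------------------------------------------------------------------
# Sample generators
# ---------------------------------------------------------------------------

def generate_tissue_sample(
    cfg: SyntheticConfig, meta: SampleMeta, rng: np.random.Generator | None = None
):
    """One hex tissue section: 1 + 3r(r+1) spots on a hex disc of ring radius r.

    The maturation coordinate runs along the physical y-axis from the
    ventricular (progenitor-rich) edge (m = 0) to the mature edge (m = 1).
    Per-spot mixtures are Dirichlet draws centered on
    :func:`expected_mixture`; counts are negative-binomial around
    mixture-weighted type signatures. Deterministic given the seed.
    """
    if meta.kind != TISSUE:
        raise ParameterError("generate_tissue_sample expects meta.kind == 'tissue'")
    rng = cfg.rng() if rng is None else rng
    grid = _make_grid(cfg.grid_radius, meta, meta.sample_id)
    y = grid.phys_coords[:, 1]
    maturation = (y - y.min()) / (y.max() - y.min())
    tmin, tmax = cfg.timepoint_range()
    t_norm = 0.5 if tmax == tmin else (meta.timepoint_value - tmin) / (tmax - tmin)
    expected = expected_mixture(cfg, maturation, t_norm)
    concentration = float(np.sum(cfg.dirichlet_alpha))
    mixtures = _draw_mixtures(rng, expected, concentration)
    counts = _counts_from_mixtures(cfg, rng, mixtures, maturation)
    ab, cm = _package_sample(cfg, grid, mixtures, counts)
    gt = GroundTruth(mixtures=mixtures, maturation=maturation, meta=meta, t_norm=t_norm)
    return grid, ab, cm, gt


def generate_organoid_sample(
    cfg: SyntheticConfig,
    tissue_a: GroundTruth,
    tissue_b: GroundTruth,
    mix_alpha: float | None = None,
    meta: SampleMeta | None = None,
    rng: np.random.Generator | None = None,
):
    """Disc organoid whose expected niche composition interpolates two tissues.

    The organoid's maturation coordinate is radial (progenitor core at the
    center, mature periphery). At matched coordinate m the expected mixture
    is (1 - a) * p_A(m) + a * p_B(m); the implied gestational timepoint is
    (1 - a) * t_A + a * t_B.
    """
    alpha = cfg.mix_alpha if mix_alpha is None else float(mix_alpha)
    if not 0.0 <= alpha <= 1.0:
        raise ParameterError("mix_alpha must be in [0, 1]")
    rng = cfg.rng() if rng is None else rng
    t_a, t_b = tissue_a.meta.timepoint_value, tissue_b.meta.timepoint_value
    implied = (1.0 - alpha) * t_a + alpha * t_b
    if meta is None:
        meta = SampleMeta(f"organoid_a{alpha:.2f}", ORGANOID, max(implied, 1e-6))
    grid = _make_grid(cfg.grid_radius, meta, meta.sample_id)
    r = np.linalg.norm(grid.phys_coords - grid.phys_coords.mean(axis=0), axis=1)
    maturation = r / r.max()
    pa = expected_mixture(cfg, maturation, tissue_a.t_norm)
    pb = expected_mixture(cfg, maturation, tissue_b.t_norm)
    expected = (1.0 - alpha) * pa + alpha * pb
    concentration = float(np.sum(cfg.dirichlet_alpha))
    mixtures = _draw_mixtures(rng, expected, concentration)
    counts = _counts_from_mixtures(cfg, rng, mixtures, maturation)
    ab, cm = _package_sample(cfg, grid, mixtures, counts)
    gt = GroundTruth(
        mixtures=mixtures,
        maturation=maturation,
        mix_alpha=alpha,
        implied_timepoint=implied,
        meta=meta,
    )
    return grid, ab, cm, gt


def generate_single_cell_dataset(cfg: SyntheticConfig, rng: np.random.Generator | None = None):
    """Cells on a latent pseudotime in [0, 1] with lineage structure.

    Cell types switch root -> intermediate -> terminal along pseudotime;
    finer cluster labels (``n_clusters`` equal pseudotime bins) support the
    cluster-graph lineage stage; module genes co-vary with pseudotime with
    the configured effect sizes; timepoint/replicate labels make the HVG
    intersect/union scheme and the permutation comparisons exercisable.

    Returns ``(CountMatrix, metadata DataFrame, GroundTruth)``.
    """
    if len(cfg.sc_cell_types) < 2:
        raise ParameterError("need >= 2 cell types including a root type")
    if len(cfg.sc_timepoints) < 2:
        raise ParameterError("HVG scheme needs >= 2 timepoints")
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_cells
    tps = np.asarray(cfg.sc_timepoints, dtype=float)
    centers = np.linspace(0.3, 0.7, len(tps))
    tp_idx = rng.integers(0, len(tps), size=n)
    pseudotime = np.clip(centers[tp_idx] + rng.normal(0.0, 0.22, size=n), 0.0, 1.0)

    k_types = len(cfg.sc_cell_types)
    type_idx = np.minimum((pseudotime * k_types).astype(int), k_types - 1)
    cell_types = np.array(cfg.sc_cell_types)[type_idx]
    cluster_idx = np.minimum((pseudotime * cfg.n_clusters).astype(int), cfg.n_clusters - 1)
    clusters = np.array([f"c{i}" for i in cluster_idx])
    replicates = np.array(cfg.sc_replicates)[rng.integers(0, len(cfg.sc_replicates), size=n)]

    # expression: type markers switch smoothly along pseudotime (labels stay
    # discrete) so the lineage is a connected continuum, plus module genes
    rng_sig = np.random.default_rng([int(cfg.seed) % (2**31), 13])
    base = rng_sig.gamma(shape=2.0, scale=cfg.nb_mean / 2.0, size=cfg.n_genes)
    marker_type = np.arange(cfg.n_genes) % k_types
    centers_t = (np.arange(k_types) + 0.5) / k_types
    w = np.exp(-(((pseudotime[:, None] - centers_t[None, :]) / 0.3) ** 2))
    w = w / w.sum(axis=1, keepdims=True)
    boost = 1.0 + 7.0 * w[:, marker_type]
    gene_ids = [f"gene{i}" for i in range(cfg.n_genes)]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    # module genes carry only their stated pseudotime effect — never type
    # markers, so a zero-effect module really is null w.r.t. time and type
    module_gene_idx = sorted(
        {gene_index[g] for mod in cfg.module_spec for g in mod.genes if g in gene_index}
    )
    boost[:, module_gene_idx] = 1.0
    mu = base[None, :] * boost
    for mod in cfg.module_spec:
        idx = [gene_index[g] for g in mod.genes if g in gene_index]
        mu[:, idx] = mu[:, idx] * np.exp(mod.effect * (pseudotime[:, None] - 0.5))
    # hold expected sequencing depth constant per cell, so scale-factor
    # normalization leaves zero-effect genes flat in expectation
    mu = mu / mu.sum(axis=1, keepdims=True) * base.sum()
    counts = _nb_counts(rng, mu, cfg.nb_dispersion)

    cells = [f"cell{i:05d}" for i in range(n)]
    cm = CountMatrix(entities=cells, genes=gene_ids, counts=sp.csr_matrix(counts))
    meta = pd.DataFrame(
        {
            "cell": cells,
            "donor": replicates,
            "model": "fetal",
            "timepoint": tps[tp_idx],
            "replicate": replicates,
            "cell_type": cell_types,
            "cluster": clusters,
        }
    )
    gt = GroundTruth(pseudotime=pseudotime)
    return cm, meta, gt


# ---------------------------------------------------------------------------
# Field fixtures for spatial statistics
# ---------------------------------------------------------------------------

FIELD_PATTERNS = ("constant", "checkerboard", "smooth_gradient", "iid_noise")


def generate_field(grid: SpotGrid, pattern: str, seed: int = 0) -> np.ndarray:
    """Per-spot scalar fixture fields for autocorrelation tests.

    checkerboard parity is (array_row + array_col) % 2; on doubled-column
    hex lattices, where that sum has constant parity, the axial parity
    (row + (col - row) // 2) % 2 is used instead (a hex lattice has odd
    cycles, so no exact two-coloring exists).
    """
    if grid.n_spots == 0:
        raise ParameterError("empty grid")
    if pattern == "constant":
        return np.ones(grid.n_spots)
    if pattern == "checkerboard":
        rows = grid.array_coords[:, 0]
        cols = grid.array_coords[:, 1]
        parity = (rows + cols) % 2
        if len(np.unique(parity)) == 1:
            parity = (rows + (cols - rows) // 2) % 2
        return np.where(parity == 0, 1.0, -1.0)
    if pattern == "smooth_gradient":
        x = grid.phys_coords[:, 0]
        span = x.max() - x.min()
        return (x - x.min()) / (span if span > 0 else 1.0)
    if pattern == "iid_noise":
        return np.random.default_rng(seed).standard_normal(grid.n_spots)
    raise ParameterError(f"unknown pattern {pattern!r}; expected one of {FIELD_PATTERNS}")


# ---------------------------------------------------------------------------
# On-disk round trip (same formats io_core reads)
# ---------------------------------------------------------------------------

def write_sample(outdir: str | Path, grid: SpotGrid, abundance, cm: CountMatrix) -> Path:
    """Write one sample in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spot_positions(grid, outdir / "tissue_positions.csv")
    write_mtx_counts(cm, outdir / "matrix.mtx", outdir / "barcodes.tsv", outdir / "features.tsv")
    df = pd.DataFrame(abundance.values, columns=abundance.types)
    df.insert(0, "barcode", abundance.spots)
    write_table(df, outdir / "abundance.tsv")
    return outdir
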