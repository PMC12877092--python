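"""Gene-module activation scores and resampled permutation comparisons.

A module's activation score in a cell is the mean log-normalized expression
of its member genes. Group comparisons use a two-sided one-way permutation
test (|difference of group means|, 10,000 label permutations by default);
because compared groups usually differ in size, the larger group is
resampled without replacement to match the smaller one (100 times by
default) and the mean p-value over resamplings is reported, followed by
Benjamini-Hochberg correction across modules with the usual significance
tiers (pAdj < 0.001 / 0.01 / 0.05).
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import ParameterError, ValidationError
from .io_core import CountMatrix

logger = logging.getLogger("mbstage.module_scores")

DEFAULT_N_PERM = 10_000
DEFAULT_N_RESAMPLE = 100
EXHAUSTIVE_MAX_TOTAL = 10


@dataclass
class GeneModule:
    module_id: str
    genes: list[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"module {self.module_id!r} is empty")


@dataclass
class ModuleScoreTable:
    cells: list[str]
    modules: list[str]
    scores: pd.DataFrame  # cells x modules
    groups: pd.DataFrame | None = None  # per-cell labels (dataset, timepoint, cell type)

    def column(self, module_id: str) -> np.ndarray:
        return self.scores[module_id].to_numpy(dtype=float)


@dataclass
class PermTestResult:
    module_id: str
    statistic: float  # |mean_a - mean_b| on the full groups
    mean_p: float
    p_per_resample: list[float]
    p_adj: float = math.nan
    tier: str = ""


def modules_from_frame(df: pd.DataFrame) -> list[GeneModule]:
    """Two-column (module_id, gene) table -> list of GeneModule."""
    return [
        GeneModule(mid, list(sub["gene"]))
        for mid, sub in df.groupby("module_id", sort=False)
    ]


def activation_score(
    cm: CountMatrix, modules: list[GeneModule], groups: pd.DataFrame | None = None
) -> ModuleScoreTable:
    """Mean lognorm expression over each module's retained genes, per cell.

    Genes absent from the matrix are dropped with a warning; a module with
    no retained genes is dropped entirely.
    """
    if "lognorm" not in cm.layers:
        raise ValidationError("lognorm layer missing; run lognormalize first")
    X = cm.dense_layer("lognorm")
    gidx = {g: i for i, g in enumerate(cm.genes)}
    cols: dict[str, np.ndarray] = {}
    for mod in modules:
        present = [gidx[g] for g in mod.genes if g in gidx]
        absent = len(mod.genes) - len(present)
        if absent:
            logger.warning("activation_score: %d genes of %s absent", absent, mod.module_id)
        if not present:
            logger.warning("activation_score: module %s dropped (no retained genes)", mod.module_id)
            continue
        cols[mod.module_id] = X[:, present].mean(axis=1)
    scores = pd.DataFrame(cols, index=cm.entities)
    return ModuleScoreTable(cells=list(cm.entities), modules=list(scores.columns), scores=scores, groups=groups)


# ---------------------------------------------------------------------------
# Resampled permutation test
# ---------------------------------------------------------------------------

def _perm_p_two_sided(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for T = |mean(a) - mean(b)|.

    Exhaustive over all C(n, n_a) label splits when total <= 10 (with the
    split count as the +1-corrected denominator's n_perm); Monte Carlo
    otherwise. The combined values are sorted first so the p-value depends
    only on the multiset of values, not the input order.
    """
    na, nb = a.size, b.size
    t_obs = abs(a.mean() - b.mean())
    v = np.sort(np.concatenate([a, b]))
    n = na + nb
    tot = v.sum()
    if n <= EXHAUSTIVE_MAX_TOTAL:
        count = total = 0
        for comb in itertools.combinations(range(n), na):
            sa = v[list(comb)].sum()
            t = abs(sa / na - (tot - sa) / nb)
            if t >= t_obs - 1e-12:
                count += 1
            total += 1
        return (1 + count) / (1 + total)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        sa = v[perm[:na]].sum()
        t = abs(sa / na - (tot - sa) / nb)
        if t >= t_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def resampled_permutation_test(
    scores: ModuleScoreTable | pd.DataFrame,
    group_a,
    group_b,
    n_perm: int = DEFAULT_N_PERM,
    n_resample: int = DEFAULT_N_RESAMPLE,
    seed: int = 0,
) -> list[PermTestResult]:
    """Per-module two-sided permutation test with larger-group resampling.

    ``group_a``/``group_b`` are boolean masks or index arrays over cells.
    For each of ``n_resample`` rounds the larger group is subsampled without
    replacement to the smaller group's size and a permutation p computed;
    the mean p over rounds is reported per module and BH-adjusted across
    modules. Equal group sizes skip resampling (one round, logged). The
    result is symmetric in the group labels.
    """
    table = scores.scores if isinstance(scores, ModuleScoreTable) else scores
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    mask_a = np.asarray(group_a)
    mask_b = np.asarray(group_b)
    if mask_a.dtype == bool:
        idx_a = np.flatnonzero(mask_a)
    else:
        idx_a = mask_a.astype(int)
    if mask_b.dtype == bool:
        idx_b = np.flatnonzero(mask_b)
    else:
        idx_b = mask_b.astype(int)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ParameterError("both groups must be non-empty")
    if min(idx_a.size, idx_b.size) < 2:
        raise ParameterError("smaller group must have >= 2 cells")
    # canonical orientation: 'small' is the smaller group regardless of naming
    if idx_a.size <= idx_b.size:
        idx_small, idx_large = idx_a, idx_b
    else:
        idx_small, idx_large = idx_b, idx_a
    m = idx_small.size
    equal = idx_large.size == m
    if equal:
        logger.info("resampled_permutation_test: equal group sizes, single round (no subsampling)")
        rounds = 1
    else:
        rounds = n_resample

    results = []
    master = np.random.default_rng(seed)
    round_seeds = master.integers(0, 2**31 - 1, size=rounds)
    for module_id in table.columns:
        vals = table[module_id].to_numpy(dtype=float)
        a_full, b_full = vals[idx_small], vals[idx_large]
        t_full = abs(a_full.mean() - b_full.mean())
        ps = []
        for r in range(rounds):
            rng = np.random.default_rng(
                [int(round_seeds[r]), zlib.crc32(str(module_id).encode()) % (2**31)]
            )
            sub = idx_large if equal else rng.choice(idx_large, size=m, replace=False)
            ps.append(_perm_p_two_sided(vals[idx_small], vals[sub], n_perm, rng))
        results.append(
            PermTestResult(
                module_id=module_id,
                statistic=float(t_full),
                mean_p=float(np.mean(ps)),
                p_per_resample=[float(p) for p in ps],
            )
        )
    p_adj = multipletests([r.mean_p for r in results], method="fdr_bh")[1]
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
        r.tier = significance_tier(pa)
    return results


def significance_tier(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "ns"


def results_frame(results: list[PermTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "module": [r.module_id for r in results],
            "statistic": [r.statistic for r in results],
            "mean_p": [r.mean_p for r in results],
            "p_adj": [r.p_adj for r in results],
            "tier": [r.tier for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------------

def timepoint_profile(
    values: pd.Series | np.ndarray,
    groups: pd.DataFrame,
    by: tuple[str, ...] = ("dataset", "timepoint"),
    grid_size: int = 256,
):
    """Per-(dataset, timepoint) mean +/- sd and Gaussian kernel densities.

    Densities use Silverman's bandwidth on a fixed evaluation grid spanning
    all groups and integrate to 1 (trapezoid, tolerance 1e-3). A group with
    a single cell reports sd 0 with a warning; a zero-variance group gets a
    narrow Gaussian bump instead of a KDE.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) != len(groups):
        raise ValidationError("values and groups must align")
    df = groups.copy()
    df["_value"] = vals
    span = vals.max() - vals.min()
    pad = 0.5 * span if span > 0 else 1.0
    xgrid = np.linspace(vals.min() - pad, vals.max() + pad, grid_size)
    rows, densities = [], {}
    for key, sub in df.groupby(list(by), sort=True):
        x = sub["_value"].to_numpy()
        if x.size == 1:
            logger.warning("timepoint_profile: group %s has a single cell; sd = 0", key)
            sd = 0.0
        else:
            sd = float(np.std(x, ddof=1))
        rows.append({**dict(zip(by, key if isinstance(key, tuple) else (key,))),
                     "n": x.size, "mean": float(x.mean()), "sd": sd})
        if x.size > 1 and np.ptp(x) > 0:
            kde = stats.gaussian_kde(x, bw_method="silverman")
            dens = kde(xgrid)
        else:
            bw = max(1e-3, 1e-3 * max(abs(float(x[0])), 1.0))
            dens = stats.norm.pdf(xgrid, loc=float(x.mean()), scale=bw)
        densities[key] = dens
    return pd.DataFrame(rows), xgrid, densities


def ranksum_compare(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact when the smaller sample has <= 8 observations and there are no
    ties; otherwise the normal approximation with tie correction (no
    continuity correction, so identical samples give exactly p = 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = len(np.unique(combined)) < combined.size
    if min(a.size, b.size) <= 8 and not has_ties:
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    return float(
        stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        ).pvalue
    )
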