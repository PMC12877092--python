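"""Moran's I spatial autocorrelation with a permutation null, and a simple
neighbor ligand-receptor co-expression score.

Moran's I here uses binary adjacency weights (1 for lattice neighbors, no
row standardization):

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = x - mean(x)

with E[I] = -1/(n-1) under no autocorrelation. Significance comes from
random relabeling of the values over the spots, two-sided around E[I].
The neighbor ligand-receptor score — ligand expression at a spot times the
mean receptor expression over its lattice neighbors — is a transparent
per-spot signaling proxy whose spatial structure can then be ranked by
Moran's I; it makes no claim of equivalence to optimal-transport signaling
inference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.stats.multitest import multipletests

from ._exceptions import DegenerateInputError, ParameterError, ValidationError
from .io_core import SpotGrid

logger = logging.getLogger("mbstage.spatial_stats")


@dataclass
class MoranResult:
    I: float
    n: int
    S0: float
    expected_I: float
    p_perm: float
    n_perm: int


def _weights(grid: SpotGrid) -> sp.csr_matrix:
    if grid.adjacency is None:
        raise ValidationError("adjacency not built")
    n = grid.n_spots
    edges = grid.adjacency_indices()
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    data = np.ones(2 * len(edges))
    return sp.csr_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))


def _moran_stat(z: np.ndarray, W: sp.csr_matrix, S0: float) -> float:
    n = z.size
    return float(n / S0 * (z @ (W @ z)) / (z @ z))


def morans_i(
    grid: SpotGrid,
    values,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "auto",
) -> MoranResult:
    """Moran's I with a two-sided permutation p centered at E[I] = -1/(n-1).

    ``method='exact'`` (automatic for n <= 7) enumerates all n! relabelings
    and reports p = count / n!; otherwise ``n_perm`` Monte Carlo relabelings
    with the +1-corrected estimator.
    """
    x = np.asarray(values, dtype=float)
    n = grid.n_spots
    if x.size != n:
        raise ValidationError("values must be defined on all spots")
    if n < 3:
        raise ParameterError("need >= 3 spots")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant field: Moran's I undefined")
    W = _weights(grid)
    S0 = float(W.sum())
    if S0 == 0:
        raise DegenerateInputError("no adjacency edges")
    z = x - x.mean()
    i_obs = _moran_stat(z, W, S0)
    e_i = -1.0 / (n - 1)
    t_obs = abs(i_obs - e_i)

    if method == "auto":
        method = "exact" if n <= 7 else "mc"
    if method == "exact":
        count = total = 0
        for perm in itertools.permutations(range(n)):
            zp = z[list(perm)]
            if abs(_moran_stat(zp, W, S0) - e_i) >= t_obs - 1e-12:
                count += 1
            total += 1
        return MoranResult(i_obs, n, S0, e_i, count / total, total)
    if method != "mc":
        raise ParameterError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    denom = float(z @ z)  # invariant under permutation
    count = 0
    for _ in range(n_perm):
        zp = z[rng.permutation(n)]
        i_p = float(n / S0 * (zp @ (W @ zp)) / denom)
        if abs(i_p - e_i) >= t_obs - 1e-12:
            count += 1
    return MoranResult(i_obs, n, S0, e_i, (1 + count) / (1 + n_perm), n_perm)


def neighbor_lr_score(grid: SpotGrid, ligand, receptor) -> np.ndarray:
    """score(s) = ligand(s) x mean receptor over s's lattice neighbors.

    Isolated spots score 0.
    """
    lig = np.asarray(ligand, dtype=float)
    rec = np.asarray(receptor, dtype=float)
    if lig.size != grid.n_spots or rec.size != grid.n_spots:
        raise ValidationError("ligand/receptor vectors must cover all spots")
    W = _weights(grid)
    deg = np.asarray(W.sum(axis=1)).ravel()
    mean_rec = np.zeros_like(rec)
    nz = deg > 0
    mean_rec[nz] = (W @ rec)[nz] / deg[nz]
    return lig * mean_rec


def rank_pairs_by_moran(
    grid: SpotGrid,
    score_table: pd.DataFrame | dict,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank per-spot score fields (e.g. ligand-receptor pair scores) by
    Moran's I, with Benjamini-Hochberg-adjusted permutation p-values.

    Constant fields are dropped with a warning. Returns a table with columns
    pair, I, p, p_adj sorted by I descending.
    """
    if isinstance(score_table, dict):
        score_table = pd.DataFrame(score_table)
    if score_table.shape[1] < 1:
        raise ParameterError("need >= 1 score field")
    rows = []
    rng = np.random.default_rng(seed)
    for pair in score_table.columns:
        vals = score_table[pair].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            logger.warning("rank_pairs_by_moran: %r constant, dropped", pair)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = morans_i(grid, vals, n_perm=n_perm, seed=sub_seed, method="mc")
        rows.append({"pair": pair, "I": res.I, "p": res.p_perm})
    if not rows:
        logger.warning("rank_pairs_by_moran: all score fields constant; empty result")
        return pd.DataFrame(columns=["pair", "I", "p", "p_adj"])
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values("I", ascending=False, ignore_index=True)
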