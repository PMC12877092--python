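"""Expression trends along manually annotated maturation paths.

A maturation path is an ordered list of spots (or a drawn polyline with an
assignment radius) running from an immature, ventricular-zone-like region
to a mature region of a section. Expression of genes of interest is
smoothed with a running average (window of 50 spots by default), and a
permutation trend test on the Spearman correlation with path rank provides
a simple monotone-trend call. The trend test is a documented substitute
for cell-type-decomposed differential expression along the path, which is
out of this package's scope.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from ._exceptions import DegenerateInputError, ParameterError
from .io_core import SpotGrid

logger = logging.getLogger("mbstage.maturation_path")

DEFAULT_WINDOW = 50


@dataclass
class MaturationPath:
    sample_id: str
    ordered_spots: list[str]
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if len(set(self.ordered_spots)) != len(self.ordered_spots):
            raise ParameterError("ordered_spots must be unique")
        if self.window < 1:
            raise ParameterError("window must be >= 1")


def _project_to_polyline(point: np.ndarray, polyline: np.ndarray) -> tuple[float, float]:
    """(arc length of closest orthogonal projection, distance to the polyline)."""
    best = (math.inf, math.inf)
    arc0 = 0.0
    for a, b in zip(polyline[:-1], polyline[1:]):
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            continue
        t = float(np.clip(np.dot(point - a, seg) / seg_len**2, 0.0, 1.0))
        proj = a + t * seg
        dist = float(np.linalg.norm(point - proj))
        cand = (dist, arc0 + t * seg_len)
        if cand[0] < best[0]:
            best = (cand[0], cand[1])
        arc0 += seg_len
    return best[1], best[0]


def order_spots_on_polyline(
    grid: SpotGrid, polyline: np.ndarray, radius: float
) -> list[str]:
    """Order the spots within ``radius`` of a drawn polyline by the arc length
    of their orthogonal projection; ties by distance to the line, then spot id."""
    polyline = np.asarray(polyline, dtype=float)
    if polyline.ndim != 2 or len(polyline) < 2:
        raise ParameterError("polyline needs >= 2 vertices")
    if not radius > 0:
        raise ParameterError("radius must be > 0")
    keyed = []
    for spot, xy in zip(grid.spots, grid.phys_coords):
        arc, dist = _project_to_polyline(np.asarray(xy, dtype=float), polyline)
        if dist <= radius:
            keyed.append((arc, dist, spot))
    if not keyed:
        raise DegenerateInputError("no spot within radius of the polyline: empty path")
    keyed.sort()
    return [spot for _, _, spot in keyed]


def moving_average(values, window: int) -> np.ndarray:
    """Centered running mean, truncated (never padded) at the path ends.

    Position i averages indices max(0, i - w//2) .. min(n-1, i + w//2).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ParameterError("values must be a non-empty 1-D sequence")
    if window < 1:
        raise ParameterError("window must be >= 1")
    half = window // 2
    n = v.size
    csum = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def path_trend_test(
    values, positions=None, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """Spearman trend of expression with path rank, permutation-calibrated.

    Two-sided p over permutations of position; exhaustive enumeration of all
    n! orderings when n <= 7 (p = count / n!), otherwise Monte Carlo with the
    +1-corrected estimator. Constant values have no defined trend; by
    convention (statistic NaN, p = 1) with a logged warning.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 5:
        raise ParameterError("need >= 5 spots on the path")
    if n_perm < 99:
        raise ParameterError("n_perm must be >= 99")
    pos = np.arange(n, dtype=float) if positions is None else np.asarray(positions, dtype=float)
    if pos.size != n:
        raise ParameterError("positions must match values")
    if np.ptp(v) == 0:
        logger.warning("path_trend_test: constant values; trend undefined, p = 1")
        return math.nan, 1.0
    rho_obs = spearmanr(v, pos).statistic
    if n <= 7:
        count, total = 0, 0
        for perm in itertools.permutations(range(n)):
            rho = spearmanr(v, pos[list(perm)]).statistic
            if abs(rho) >= abs(rho_obs) - 1e-12:
                count += 1
            total += 1
        return float(rho_obs), count / total
    rng = np.random.default_rng(seed)
    # Spearman is Pearson on (average) ranks; permute position ranks directly.
    from scipy.stats import rankdata

    vr = rankdata(v)
    pr = rankdata(pos)
    vz = (vr - vr.mean()) / vr.std()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        prp = pr[perm]
        rho = float(np.mean(vz * (prp - prp.mean()) / prp.std()))
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return float(rho_obs), (1 + count) / (1 + n_perm)
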