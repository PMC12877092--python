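"""Lineage reconstruction on a pruned cluster graph, PC1-proxy pseudotime,
HVG selection by the intersect-then-union scheme, and trimmed five-bin
expression profiles with start-vs-end change calls.

The lineage is a path on a cluster-abstraction graph built from a kNN cell
graph: clusters are nodes, and the connectivity between two clusters is the
observed number of inter-cluster edges over the smaller cluster's total
degree (a transparent, bounded [0, 1] statistic; it is not the PAGA
connectivity, but is monotone in the same signal). Edges with weight below
0.05 are pruned (strictly: w = 0.05 is kept) and the lineage is the
hop-count shortest path from root to endpoint, optionally forced through a
waypoint cluster. Pseudotime along the lineage is the min-max-rescaled
first principal component of standardized log-normalized expression over
the HVG set, oriented so the root cluster sits at the low end, with an
adjusted R-squared check of how much PC1 variance the cell-type labels
explain. Gene trends are summarized as mean expression in five equal-width
pseudotime bins after trimming the 1st/99th pseudotime percentiles, and a
start-vs-end permutation test (a stated substitute for GAM-based
start-vs-end testing) calls genes up/down at p < 0.001 and |logFC| > 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._exceptions import (
    DegenerateInputError,
    DisconnectedLineageError,
    ParameterError,
    ValidationError,
)
from .io_core import CountMatrix

logger = logging.getLogger("mbstage.lineage")

PRUNE_THRESHOLD = 0.05
DEFAULT_N_HVG = 2000
DEFAULT_KNN = 10
TRIM_PERCENTILES = (1.0, 99.0)
N_BINS = 5
CALL_P = 0.001
CALL_LFC = 2.0


# ---------------------------------------------------------------------------
# Cell graph and cluster abstraction
# ---------------------------------------------------------------------------

def build_knn_graph(embedding: np.ndarray, k: int = DEFAULT_KNN) -> nx.Graph:
    """Undirected union-of-kNN graph on Euclidean distances.

    An edge exists when either cell lists the other among its k nearest
    neighbors; distance ties are broken deterministically by cell index
    (stable argsort on the full distance matrix).
    """
    X = np.asarray(embedding, dtype=float)
    if X.ndim != 2:
        raise ParameterError("embedding must be 2-D")
    n = X.shape[0]
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k >= n:
        raise ParameterError("k must be < number of cells")
    if not np.all(np.isfinite(X)):
        raise ValidationError("embedding must be finite")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    # chunked brute force keeps the tie-break exact and memory bounded
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = np.linalg.norm(X[start:stop, None, :] - X[None, :, :], axis=2)
        for ii in range(stop - start):
            i = start + ii
            row = d[ii].copy()
            row[i] = np.inf
            order = np.argsort(row, kind="stable")
            for j in order[:k]:
                g.add_edge(i, int(j))
    return g


@dataclass
class ClusterGraph:
    clusters: dict[str, int]  # cluster id -> size
    edges: dict[tuple[str, str], float]  # sorted pair -> weight in [0, 1]
    prune_threshold: float = PRUNE_THRESHOLD

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValidationError("self-edge in cluster graph")
            if not 0.0 <= w <= 1.0:
                raise ValidationError(f"weight {w} outside [0, 1] for edge ({a}, {b})")

    def pruned(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.clusters)
        for (a, b), w in self.edges.items():
            if w >= self.prune_threshold:  # strict '<' prune: w == threshold kept
                g.add_edge(a, b, weight=w)
        return g


def cluster_connectivity(cell_graph: nx.Graph, labels) -> ClusterGraph:
    """Cluster-abstraction weights: inter-cluster edge count over the smaller
    cluster's total degree, clipped to [0, 1]; 0 when no inter edges."""
    labels = list(labels)
    if len(labels) != cell_graph.number_of_nodes():
        raise ValidationError("every cell must be labeled")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ParameterError("need >= 2 clusters")
    sizes = {c: labels.count(c) for c in uniq}
    degree_total = {c: 0 for c in uniq}
    inter: dict[tuple[str, str], int] = {}
    deg = dict(cell_graph.degree())
    for node, d in deg.items():
        degree_total[labels[node]] += d
    for u, v in cell_graph.edges():
        cu, cv = labels[u], labels[v]
        if cu == cv:
            continue
        key = tuple(sorted((cu, cv)))
        inter[key] = inter.get(key, 0) + 1
    edges = {}
    for (a, b), cnt in inter.items():
        denom = min(degree_total[a], degree_total[b])
        edges[(a, b)] = min(cnt / denom, 1.0) if denom > 0 else 0.0
    return ClusterGraph(clusters=sizes, edges=edges)


@dataclass
class LineagePath:
    clusters: list[str]
    waypoint: str | None = None
    member_cells: list[str] = field(default_factory=list)
    pseudotime: np.ndarray | None = None
    adjusted_r2: float | None = None


def _best_shortest_path(g: nx.Graph, src: str, dst: str) -> list[str]:
    """Hop-count shortest path; ties broken by larger minimum edge weight
    along the path, then lexicographically smaller cluster-id sequence."""
    paths = list(nx.all_shortest_paths(g, src, dst))
    def key(p):
        min_w = min((g[a][b]["weight"] for a, b in zip(p[:-1], p[1:])), default=math.inf)
        return (-min_w, tuple(p))
    return sorted(paths, key=key)[0]


def _collapse_duplicates(path: list[str]) -> list[str]:
    """Remove loops: whenever a cluster reappears, cut back to its first visit."""
    out: list[str] = []
    for c in path:
        if c in out:
            out = out[: out.index(c) + 1]
        else:
            out.append(c)
    return out


def prune_and_path(
    cg: ClusterGraph, root: str, endpoint: str, waypoint: str | None = None
) -> LineagePath:
    """Shortest root-to-endpoint path on the pruned cluster graph.

    With a waypoint, the path is shortest(root -> waypoint) followed by
    shortest(waypoint -> endpoint), with duplicate clusters collapsed.
    """
    for name, node in (("root", root), ("endpoint", endpoint), ("waypoint", waypoint)):
        if node is not None and node not in cg.clusters:
            raise ParameterError(f"{name} cluster {node!r} not in graph")
    g = cg.pruned()
    if root == endpoint and waypoint is None:
        return LineagePath(clusters=[root])
    legs = [(root, endpoint)] if waypoint is None else [(root, waypoint), (waypoint, endpoint)]
    full: list[str] = []
    for src, dst in legs:
        if src == dst:
            seg = [src]
        else:
            if not nx.has_path(g, src, dst):
                comps = [sorted(c) for c in nx.connected_components(g)]
                raise DisconnectedLineageError(
                    f"no path {src} -> {dst} in the pruned graph; components: {comps}",
                    components=comps,
                )
            seg = _best_shortest_path(g, src, dst)
        full.extend(seg if not full else seg[1:])
    return LineagePath(clusters=_collapse_duplicates(full), waypoint=waypoint)


# ---------------------------------------------------------------------------
# HVG selection: per-replicate top-n, intersect per timepoint, union
# ---------------------------------------------------------------------------

@dataclass
class HVGSelection:
    per_replicate: dict[tuple, list[str]]  # (timepoint, replicate) -> ranked HVG list
    per_timepoint: dict = field(init=False)
    final: list[str] = field(init=False)

    def __post_init__(self) -> None:
        by_tp: dict = {}
        for (tp, _rep), genes in self.per_replicate.items():
            by_tp.setdefault(tp, []).append(set(genes))
        self.per_timepoint = {tp: set.intersection(*sets) for tp, sets in by_tp.items()}
        union: set = set().union(*self.per_timepoint.values()) if self.per_timepoint else set()
        self.final = sorted(union)


def hvg_rank(cm: CountMatrix, cell_mask: np.ndarray, n_hvg: int, n_bins: int = 20) -> list[str]:
    """Top-``n_hvg`` genes by binned-dispersion ranking of lognorm values.

    Dispersion (variance / mean) of the lognorm values is z-scored within 20
    gene-mean bins; ranking is by standardized dispersion descending with a
    deterministic tie-break by gene id.
    """
    if "lognorm" not in cm.layers:
        raise ValidationError("lognorm layer missing")
    X = cm.dense_layer("lognorm")[np.asarray(cell_mask)]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    order = np.argsort(mean, kind="stable")
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / sd if sd > 0 else 0.0
    if n_hvg > len(cm.genes):
        logger.warning("hvg_rank: n_hvg > gene count; returning all genes")
        n_hvg = len(cm.genes)
    ranked = sorted(range(len(cm.genes)), key=lambda i: (-z[i], cm.genes[i]))
    return [cm.genes[i] for i in ranked[:n_hvg]]


def select_hvg(
    cm: CountMatrix,
    cell_groups: pd.DataFrame,
    n_hvg: int = DEFAULT_N_HVG,
    timepoint_col: str = "timepoint",
    replicate_col: str = "replicate",
) -> HVGSelection:
    """Per-replicate HVG -> per-timepoint intersection -> union across timepoints.

    A timepoint with a single replicate contributes its own HVG set.
    """
    if len(cell_groups) != len(cm.entities):
        raise ValidationError("cell_groups must align with entities")
    per_rep: dict[tuple, list[str]] = {}
    for (tp, rep), sub in cell_groups.groupby([timepoint_col, replicate_col], sort=True):
        mask = np.zeros(len(cm.entities), dtype=bool)
        mask[sub.index.to_numpy()] = True
        per_rep[(tp, rep)] = hvg_rank(cm, mask, n_hvg)
    return HVGSelection(per_replicate=per_rep)


# ---------------------------------------------------------------------------
# PC1 pseudotime
# ---------------------------------------------------------------------------

def pc1_pseudotime(
    cm: CountMatrix,
    hvg: HVGSelection | list[str],
    cell_types,
    root_type: str,
    cell_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """PC1 of standardized lognorm over the HVG set as a pseudotime proxy.

    The component's sign is oriented so the root cluster's mean score is
    minimal; scores are min-max rescaled to [0, 1]. Also returns the
    adjusted R-squared of regressing the PC1 score on cell-type indicators
    (a sanity check that the axis tracks the annotated progression).
    """
    genes = hvg.final if isinstance(hvg, HVGSelection) else list(hvg)
    gidx = [cm.genes.index(g) for g in genes if g in cm.genes]
    if len(gidx) < 2:
        raise ParameterError("need >= 2 HVGs present in the matrix")
    X = cm.dense_layer("lognorm")
    if cell_mask is not None:
        X = X[np.asarray(cell_mask)]
        cell_types = np.asarray(cell_types)[np.asarray(cell_mask)]
    cell_types = np.asarray(cell_types)
    if X.shape[0] < 3:
        raise ParameterError("need >= 3 cells")
    X = X[:, gidx]
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        raise DegenerateInputError("fewer than 2 HVGs with nonzero variance")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    if np.allclose(Z, Z[0]):
        raise DegenerateInputError("all cells identical: PCA degenerate")
    from sklearn.decomposition import PCA

    score = PCA(n_components=1, svd_solver="full").fit_transform(Z).ravel()
    root_mask = cell_types == root_type
    if not root_mask.any():
        raise ParameterError(f"root type {root_type!r} has no cells")
    if (~root_mask).any() and score[root_mask].mean() > score[~root_mask].mean():
        score = -score
    span = score.max() - score.min()
    pt = (score - score.min()) / (span if span > 0 else 1.0)

    # adjusted R^2 of PC1 score on cell-type indicators (group-mean model)
    n = score.size
    groups = pd.Series(score).groupby(pd.Series(cell_types)).transform("mean").to_numpy()
    sst = float(((score - score.mean()) ** 2).sum())
    sse = float(((score - groups) ** 2).sum())
    k = len(np.unique(cell_types)) - 1
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else math.nan
    return pt, float(adj_r2)


# ---------------------------------------------------------------------------
# Binned profiles and start-vs-end calls
# ---------------------------------------------------------------------------

@dataclass
class BinProfile:
    gene: str
    bin_means: np.ndarray  # NaN where a bin is empty
    bin_edges: np.ndarray
    start_end_call: str  # up / down / none
    log_fc: float
    p: float


def bin_profiles(
    pseudotime: np.ndarray,
    cm: CountMatrix,
    genes: list[str],
    trim: tuple[float, float] = TRIM_PERCENTILES,
    n_bins: int = N_BINS,
    n_perm: int = 9999,
    seed: int = 0,
    p_threshold: float = CALL_P,
    lfc_threshold: float = CALL_LFC,
) -> list[BinProfile]:
    """Per-gene mean expression in equal-width pseudotime bins, with a
    start-vs-end change call.

    Cells below the ``trim[0]``-th or above the ``trim[1]``-th pseudotime
    percentile are dropped, the remaining pseudotime range is split into
    ``n_bins`` equal-width bins, and per-bin mean lognorm expression is
    reported (empty bins as NaN, logged). The start-vs-end statistic is the
    difference of last-bin and first-bin means on log values (a logFC); its
    two-sided permutation p (+1-corrected, permuting first/last-bin
    membership) and the thresholds p < 0.001, |logFC| > 2 drive the
    up/down/none call.
    """
    pt = np.asarray(pseudotime, dtype=float)
    X = cm.dense_layer("lognorm")
    if pt.size != X.shape[0]:
        raise ValidationError("pseudotime must cover all cells")
    lo, hi = np.percentile(pt, trim)
    keep = (pt >= lo) & (pt <= hi)
    if keep.sum() < n_bins:
        raise ParameterError("fewer cells than bins after trimming")
    pt_k = pt[keep]
    X = X[keep]
    edges = np.linspace(pt_k.min(), pt_k.max(), n_bins + 1)
    which = np.clip(np.digitize(pt_k, edges[1:-1], right=False), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    gidx = {g: i for i, g in enumerate(cm.genes)}
    out = []
    for gene in genes:
        if gene not in gidx:
            logger.warning("bin_profiles: gene %r absent, skipped", gene)
            continue
        v = X[:, gidx[gene]]
        means = np.full(n_bins, np.nan)
        for b in range(n_bins):
            m = which == b
            if m.any():
                means[b] = v[m].mean()
            else:
                logger.warning("bin_profiles: empty bin %d for gene %s", b, gene)
        first, last = which == 0, which == n_bins - 1
        if not (first.any() and last.any()) or math.isnan(means[0]) or math.isnan(means[-1]):
            out.append(BinProfile(gene, means, edges, "none", math.nan, math.nan))
            continue
        a, b_ = v[first], v[last]
        lfc = float(b_.mean() - a.mean())
        combined = np.concatenate([a, b_])
        na = a.size
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(combined.size)
            t = abs(combined[perm[na:]].mean() - combined[perm[:na]].mean())
            if t >= abs(lfc) - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        call = "none"
        if p < p_threshold and abs(lfc) > lfc_threshold:
            call = "up" if lfc > 0 else "down"
        out.append(BinProfile(gene, means, edges, call, lfc, p))
    return out


def bin_profiles_frame(profiles: list[BinProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for b, m in enumerate(p.bin_means):
            rows.append(
                {"gene": p.gene, "bin": b, "mean": m, "call": p.start_end_call,
                 "log_fc": p.log_fc, "p": p.p, "test": "permutation start-vs-end"}
            )
    return pd.DataFrame(rows)
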