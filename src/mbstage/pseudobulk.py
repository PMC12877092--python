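"""Pseudobulk staging: per-group mean expression over the HVG set and the
pairwise Pearson correlation matrix used to stage in-vitro samples against
fetal timepoints."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import ParameterError, ValidationError
from .io_core import CountMatrix

logger = logging.getLogger("mbstage.pseudobulk")


@dataclass
class PseudobulkTable:
    groups: list[str]
    genes: list[str]
    means: np.ndarray  # groups x genes
    n_cells: list[int]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.groups, columns=self.genes)


def pseudobulk_means(
    cm: CountMatrix,
    group_labels,
    gene_set: list[str],
    layer: str = "lognorm",
) -> PseudobulkTable:
    """Mean per-cell values per (dataset x timepoint) group over ``gene_set``.

    Any per-cell value layer may be supplied (the analysis is agnostic to
    whether values are log-normalized or batch-corrected); which layer was
    used is recorded in the log. Groups keep their first-appearance order;
    empty groups are impossible by construction of the labels.
    """
    if not gene_set:
        raise ParameterError("gene set must be non-empty")
    labels = list(group_labels)
    if len(labels) != len(cm.entities):
        raise ValidationError("group labels must align with entities")
    gidx = [cm.genes.index(g) for g in gene_set if g in cm.genes]
    if not gidx:
        raise ParameterError("no gene of the set present in the matrix")
    if len(gidx) < len(gene_set):
        logger.warning("pseudobulk_means: %d genes absent", len(gene_set) - len(gidx))
    X = cm.dense_layer(layer)[:, gidx]
    logger.info("pseudobulk_means: using layer %r", layer)
    order = list(dict.fromkeys(labels))
    lab_arr = np.asarray(labels)
    means, ns = [], []
    for g in order:
        m = lab_arr == g
        means.append(X[m].mean(axis=0))
        ns.append(int(m.sum()))
    return PseudobulkTable(
        groups=order,
        genes=[cm.genes[i] for i in gidx],
        means=np.vstack(means),
        n_cells=ns,
    )


def correlation_matrix(pb: PseudobulkTable) -> pd.DataFrame:
    """Pairwise Pearson correlations between group profiles.

    Constant profiles are dropped with a warning; fewer than two valid
    groups is an error. Symmetric, diagonal 1, entries in [-1, 1].
    """
    sds = pb.means.std(axis=1)
    keep = sds > 0
    if keep.sum() < len(pb.groups):
        dropped = [g for g, k in zip(pb.groups, keep) if not k]
        logger.warning("correlation_matrix: constant profiles dropped: %s", dropped)
    if keep.sum() < 2:
        raise ParameterError("need >= 2 groups with non-constant profiles")
    groups = [g for g, k in zip(pb.groups, keep) if k]
    R = np.corrcoef(pb.means[keep])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=groups, columns=groups)


def average_linkage_order(corr: pd.DataFrame) -> list[str]:
    """Optional presentation helper: leaf order of average-linkage clustering
    on correlation distance (1 - r)."""
    from scipy.cluster.hierarchy import average, leaves_list
    from scipy.spatial.distance import squareform

    d = 1.0 - corr.to_numpy()
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    return [corr.index[i] for i in leaves_list(link)]
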