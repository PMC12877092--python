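"""Readers/writers for the spatial and single-cell formats the pipeline touches,
scale-factor log-normalization, and shared configuration.

Formats handled
---------------
* Visium ``tissue_positions`` CSV dialect: six columns
  (barcode, in_tissue, array_row, array_col, pxl_row, pxl_col), with or
  without a header row (auto-detected).
* MatrixMarket coordinate-integer count matrices plus plain-text barcode and
  feature lists (features in rows, barcodes in columns, as emitted by the
  10x pipelines; transposed on read to entity-major).
* Delimited abundance / metadata tables via pandas.

Normalization follows the common single-cell convention: counts are scaled
to a fixed total per entity (default 10,000) and log1p-transformed.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
import yaml

from ._exceptions import FormatError, ParameterError, ValidationError

logger = logging.getLogger("mbstage.io_core")

DEFAULT_SCALE_FACTOR = 10_000.0

DEFAULT_CONFIG: dict = {
    "scale_factor": DEFAULT_SCALE_FACTOR,
    "adjacency_scale_tolerance": 1.05,
    "include_out_of_tissue": False,
    "hvg_n": 2000,
    "prune_threshold": 0.05,
    "knn_neighbors": 10,
    "n_permutations": 10_000,
    "n_resamplings": 100,
    "moving_average_window": 50,
    "pseudotime_trim_percentiles": [1, 99],
    "pseudotime_bins": 5,
}


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML/JSON config file and merge it over the package defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        text = Path(path).read_text()
        loaded = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if loaded:
            cfg.update(loaded)
    return cfg


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

TISSUE = "tissue"
ORGANOID = "organoid"


@dataclass
class SampleMeta:
    """Identity and timepoint of one sample.

    ``timepoint_value`` is in post-conceptional weeks for tissue samples and
    in differentiation days for organoids; ``kind`` determines the unit.
    """

    sample_id: str
    kind: str
    timepoint_value: float
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.kind not in (TISSUE, ORGANOID):
            raise ValidationError(f"kind must be 'tissue' or 'organoid', got {self.kind!r}")
        if not self.timepoint_value > 0:
            raise ValidationError("timepoint_value must be > 0")


@dataclass
class SpotGrid:
    """Spots of one sample: ids, lattice + physical coordinates, adjacency.

    ``adjacency`` is a set of unordered spot-id pairs stored as sorted tuples;
    it is ``None`` until built (see :func:`mbstage.niche_similarity.build_adjacency`).
    """

    spots: list[str]
    array_coords: np.ndarray  # (n, 2) int: array_row, array_col
    phys_coords: np.ndarray  # (n, 2) float: x, y in arbitrary length units
    adjacency: set[tuple[str, str]] | None = None
    meta: SampleMeta | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(set(self.spots)) != len(self.spots):
            raise ValidationError("duplicate spot ids")
        self.array_coords = np.asarray(self.array_coords)
        self.phys_coords = np.asarray(self.phys_coords, dtype=float)
        if self.array_coords.shape != (len(self.spots), 2):
            raise ValidationError("array_coords shape must be (n_spots, 2)")
        if self.phys_coords.shape != (len(self.spots), 2):
            raise ValidationError("phys_coords shape must be (n_spots, 2)")
        if self.adjacency is not None:
            self._check_adjacency()
        self._index = {s: i for i, s in enumerate(self.spots)}

    def _check_adjacency(self) -> None:
        known = set(self.spots)
        for a, b in self.adjacency:
            if a == b:
                raise ValidationError(f"self-adjacency for spot {a}")
            if a not in known or b not in known:
                raise ValidationError(f"adjacency references unknown spot in ({a}, {b})")

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def index_of(self, spot: str) -> int:
        return self._index[spot]

    def adjacency_indices(self) -> np.ndarray:
        """Adjacency as an (E, 2) array of spot indices (requires adjacency)."""
        if self.adjacency is None:
            raise ValidationError("adjacency not built")
        if not self.adjacency:
            return np.empty((0, 2), dtype=int)
        return np.array(
            sorted((self._index[a], self._index[b]) for a, b in self.adjacency), dtype=int
        )

    def neighbors_of(self, spot: str) -> list[str]:
        if self.adjacency is None:
            raise ValidationError("adjacency not built")
        out = []
        for a, b in self.adjacency:
            if a == spot:
                out.append(b)
            elif b == spot:
                out.append(a)
        return sorted(out)


@dataclass
class CountMatrix:
    """Entity (cell/spot) x gene integer counts with optional derived layers."""

    entities: list[str]
    genes: list[str]
    counts: sp.csr_matrix
    layers: dict[str, sp.csr_matrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.entities)) != len(self.entities):
            raise ValidationError("duplicate entity ids")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate gene ids")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.entities), len(self.genes)):
            raise ValidationError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.entities)}, {len(self.genes)})"
            )
        data = self.counts.data
        if data.size:
            if np.any(data < 0):
                raise ValidationError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValidationError("fractional counts")
        for name, layer in self.layers.items():
            if layer.shape != self.counts.shape:
                raise ValidationError(f"layer {name!r} shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def dense_layer(self, name: str = "lognorm") -> np.ndarray:
        layer = self.layers[name]
        return layer.toarray() if sp.issparse(layer) else np.asarray(layer)


# ---------------------------------------------------------------------------
# Spot positions (Visium tissue_positions dialect)
# ---------------------------------------------------------------------------

_POSITION_COLUMNS = ("barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col")


def _looks_like_header(row: Sequence[str]) -> bool:
    # Header auto-detection: in a data row field 2 (in_tissue) parses as int.
    try:
        int(row[1])
        return False
    except (ValueError, IndexError):
        return True


def read_spot_positions(
    path: str | Path,
    include_out_of_tissue: bool = False,
    meta: SampleMeta | None = None,
) -> SpotGrid:
    """Parse a ``tissue_positions`` CSV into a :class:`SpotGrid` (no adjacency).

    Both the headered and headerless generations of the dialect are accepted;
    a header is detected by attempting an integer parse of the second field.
    File row order is preserved. When ``include_out_of_tissue`` is false,
    rows with ``in_tissue == 0`` are dropped (and the drop is logged).
    """
    rows = [r for r in csv.reader(Path(path).open()) if r]
    if not rows:
        raise FormatError(f"{path}: empty spot-position file")
    if _looks_like_header(rows[0]):
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: header only, no spot rows")

    spots: list[str] = []
    array_coords: list[tuple[int, int]] = []
    phys_coords: list[tuple[float, float]] = []
    seen: set[str] = set()
    n_read = len(rows)
    n_filtered = 0
    for lineno, row in enumerate(rows, start=1):
        if len(row) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(row)}")
        barcode, in_tissue_s, ar, ac, pr, pc = (f.strip() for f in row)
        try:
            in_tissue = int(in_tissue_s)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: in_tissue not an integer") from e
        if in_tissue not in (0, 1):
            raise FormatError(f"{path}:{lineno}: in_tissue must be 0 or 1")
        try:
            arow, acol = int(ar), int(ac)
        except ValueError as e:
            raise FormatError(f"{path}:{lineno}: non-integer array coordinates") from e
        if barcode in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate barcode {barcode!r}")
        seen.add(barcode)
        if in_tissue == 0 and not include_out_of_tissue:
            n_filtered += 1
            continue
        spots.append(barcode)
        array_coords.append((arow, acol))
        # Visium pixel coordinates are (row, col); store as (x, y) = (col, row).
        phys_coords.append((float(pc), float(pr)))
    logger.info(
        "read_spot_positions: %d read, %d kept, %d filtered (in + filtered = read)",
        n_read, len(spots), n_filtered,
    )
    return SpotGrid(
        spots=spots,
        array_coords=np.array(array_coords, dtype=int).reshape(len(spots), 2),
        phys_coords=np.array(phys_coords, dtype=float).reshape(len(spots), 2),
        meta=meta,
    )


def write_spot_positions(grid: SpotGrid, path: str | Path, header: bool = True) -> None:
    """Write a grid back to the ``tissue_positions`` dialect (all in_tissue=1)."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            writer.writerow(_POSITION_COLUMNS)
        for spot, (ar, ac), (x, y) in zip(grid.spots, grid.array_coords, grid.phys_coords):
            writer.writerow([spot, 1, int(ar), int(ac), y, x])


# ---------------------------------------------------------------------------
# MTX counts
# ---------------------------------------------------------------------------

def _read_id_list(path: str | Path) -> list[str]:
    ids = [line.split("\t")[0].strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return ids


def read_mtx_counts(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket triplet count matrix with its barcode/feature lists.

    The matrix is expected feature-major (rows = features, columns =
    barcodes, the 10x convention) and is transposed to entity-major.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as e:  # scipy raises ValueError on malformed headers
        raise FormatError(f"{matrix_path}: not a readable MatrixMarket file: {e}") from e
    barcodes = _read_id_list(barcodes_path)
    features = _read_id_list(features_path)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{matrix_path}: declared shape {mat.shape} inconsistent with "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    coo = sp.coo_matrix(mat)
    if coo.data.size and (np.any(coo.data < 0) or not np.allclose(coo.data, np.round(coo.data))):
        raise ValidationError(f"{matrix_path}: counts must be nonnegative integers")
    return CountMatrix(entities=barcodes, genes=features, counts=sp.csr_matrix(coo.T))


def write_mtx_counts(
    cm: CountMatrix,
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write counts feature-major as MatrixMarket integer plus id lists."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(cm.counts.T.astype(int)), field="integer")
    Path(barcodes_path).write_text("\n".join(cm.entities) + "\n")
    Path(features_path).write_text("\n".join(cm.genes) + "\n")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def lognormalize(cm: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> CountMatrix:
    """Attach a ``lognorm`` layer: log1p(count / entity_total * scale_factor).

    Entities with zero total get all-zero rows (kept, with a warning);
    dropping them is downstream QC, not the normalizer's job.
    """
    if not scale_factor > 0:
        raise ParameterError("scale_factor must be > 0")
    totals = np.asarray(cm.counts.sum(axis=1)).ravel()
    if not np.any(totals > 0):
        raise ValidationError("all entities have zero total count")
    n_zero = int(np.sum(totals == 0))
    if n_zero:
        logger.warning("lognormalize: %d entities with zero total count (rows left zero)", n_zero)
    safe = np.where(totals > 0, totals, 1.0)
    norm = sp.csr_matrix(cm.counts, dtype=float)
    scale = scale_factor / safe
    norm = sp.diags(scale) @ norm
    norm.data = np.log1p(norm.data)
    cm.layers["lognorm"] = sp.csr_matrix(norm)
    return cm


# ---------------------------------------------------------------------------
# Delimited tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, **kwargs):
    """Read a delimited table with header (TSV by default)."""
    import pandas as pd

    sep = kwargs.pop("sep", "\t")
    return pd.read_csv(path, sep=sep, **kwargs)


def write_table(df, path: str | Path, **kwargs) -> None:
    sep = kwargs.pop("sep", "\t")
    df.to_csv(path, sep=sep, index=kwargs.pop("index", False), **kwargs)
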