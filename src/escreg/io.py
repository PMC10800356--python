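"""Expression-matrix containers, standard-format I/O, cell QC and normalization.

The central container is :class:`ExpressionMatrix`, a genes×cells grid with a
``layer`` tag distinguishing raw counts from log-normalized values.  Readers
accept the 10x-style Matrix Market triplet (matrix.mtx + features.tsv +
barcodes.tsv) and dense CSV/TSV with gene rows; gene-set collections come in
as GMT.  QC implements detected-gene and mitochondrial-fraction gates, and
normalization is the per-cell log transform
``ln(1 + count * scale_factor / cell_total)`` with scale factor 10 000.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "QCParams",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "filter_cells",
    "log_normalize",
    "mito_fraction",
]

DEFAULT_SCALE_FACTOR = 10_000.0


class FormatError(ValueError):
    """Malformed input file (dimension mismatch, duplicates, bad values)."""


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids)):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise FormatError(f"duplicate {what} identifier: {x!r}")
            seen.add(x)


@dataclass
class ExpressionMatrix:
    """Genes × cells expression grid with identifiers and a layer tag.

    Parameters
    ----------
    values
        Dense ``(n_genes, n_cells)`` array. The ``counts`` layer must hold
        non-negative integers; the ``lognorm`` layer non-negative floats.
    gene_ids, cell_ids
        Ordered, unique identifiers for rows and columns.
    layer
        Either ``"counts"`` or ``"lognorm"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise FormatError("expression values must be 2-dimensional")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        _check_unique(np.asarray(self.gene_ids), "gene")
        _check_unique(np.asarray(self.cell_ids), "cell")
        if self.layer not in ("counts", "lognorm"):
            raise ValueError(f"unknown layer tag {self.layer!r}")
        if np.any(self.values < 0):
            raise FormatError("negative expression values")
        if self.layer == "counts" and not np.allclose(
            self.values, np.round(self.values)
        ):
            bad = np.argwhere(~np.isclose(self.values, np.round(self.values)))[0]
            raise FormatError(
                "non-integer value in counts layer at gene "
                f"{self.gene_ids[bad[0]]!r}, cell {self.cell_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cell_ids], dtype=int)
        return ExpressionMatrix(
            self.values[:, idx], list(self.gene_ids), [self.cell_ids[i] for i in idx], self.layer
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.gene_index(gene_ids)
        return ExpressionMatrix(
            self.values[idx, :], [self.gene_ids[i] for i in idx], list(self.cell_ids), self.layer
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (signatures) with optional free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


@dataclass
class QCParams:
    """Cell-level quality-control gates.

    ``peripheral_blood`` mode uses at least 500 detected genes and at most
    10% mitochondrial counts; ``pdx`` mode relaxes to 200 genes / 20%.
    """

    min_genes_per_cell: int = 500
    max_mito_fraction: float = 0.10
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must be in [0, 1]")

    @classmethod
    def peripheral_blood(cls) -> "QCParams":
        return cls(min_genes_per_cell=500, max_mito_fraction=0.10)

    @classmethod
    def pdx(cls) -> "QCParams":
        return cls(min_genes_per_cell=200, max_mito_fraction=0.20)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_id_column(path: Path, what: str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    _check_unique(np.asarray(ids), what)
    return ids


def read_expression(path, format: str = "mtx") -> ExpressionMatrix:
    """Read a counts matrix from MTX triplet or dense CSV/TSV.

    For ``format="mtx"``, *path* is the directory holding ``matrix.mtx``,
    ``features.tsv`` and ``barcodes.tsv`` (genes as matrix rows, 1-based
    coordinate indices per the Matrix Market standard).  For ``format="csv"``,
    *path* is a dense file with gene rows and cell columns; a ``.tsv``
    suffix switches the separator to tabs.
    """
    path = Path(path)
    if format == "mtx":
        mtx_path = path / "matrix.mtx" if path.is_dir() else path
        base = mtx_path.parent
        try:
            mat = scipy.io.mmread(mtx_path)
        except Exception as exc:  # scipy raises bare ValueError on bad indices
            raise FormatError(f"cannot parse Matrix Market file {mtx_path}: {exc}") from exc
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        genes = _read_id_column(base / "features.tsv", "gene")
        cells = _read_id_column(base / "barcodes.tsv", "cell")
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix dims {mat.shape} do not match sidecars "
                f"({len(genes)} features, {len(cells)} barcodes)"
            )
        return ExpressionMatrix(mat, genes, cells, layer="counts")
    if format == "csv":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = df.index.astype(str).tolist()
        _check_unique(np.asarray(genes), "gene")
        cells = df.columns.astype(str).tolist()
        _check_unique(np.asarray(cells), "cell")
        return ExpressionMatrix(df.to_numpy(), genes, cells, layer="counts")
    raise ValueError(f"unknown format {format!r}")


def write_expression(m: ExpressionMatrix, path, format: str = "mtx") -> None:
    """Write *m* as an MTX triplet directory or a dense CSV/TSV file."""
    path = Path(path)
    if format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        sparse = scipy.sparse.coo_matrix(m.values)
        field_kind = "integer" if m.layer == "counts" else "real"
        scipy.io.mmwrite(path / "matrix.mtx", sparse, field=field_kind)
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif format == "csv":
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = m.to_frame()
        if m.layer == "counts":
            df = df.astype(int)
        df.to_csv(path, sep=sep)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, fields name, description, genes..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"GMT line {lineno}: fewer than 3 tab-separated fields")
            name, desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# QC and normalization


def mito_fraction(m: ExpressionMatrix, mito_prefix: str = "MT-") -> pd.Series:
    """Per-cell fraction of counts on genes whose id starts with *mito_prefix*."""
    if m.layer != "counts":
        raise ValueError("mito_fraction operates on the counts layer")
    mask = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
    totals = m.values.sum(axis=0)
    if not mask.any():
        warnings.warn(f"no gene matches mitochondrial prefix {mito_prefix!r}")
        return pd.Series(np.zeros(m.n_cells), index=m.cell_ids, name="mito_fraction")
    mito = m.values[mask, :].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / totals, 0.0)
    return pd.Series(frac, index=m.cell_ids, name="mito_fraction")


def filter_cells(m: ExpressionMatrix, qc: QCParams) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove cells with too few detected genes or too high mito content.

    A cell is retained iff its detected-gene count is at least
    ``min_genes_per_cell`` AND its mitochondrial fraction is at most
    ``max_mito_fraction`` (both bounds inclusive for retention — the
    exclusions "fewer than" / "greater than" are strict).  Returns the
    filtered matrix and a per-cell report (n_genes, mito_fraction, kept,
    reason).
    """
    if m.layer != "counts":
        raise ValueError("filter_cells operates on the counts layer")
    n_genes = (m.values > 0).sum(axis=0)
    mito = mito_fraction(m, qc.mito_prefix).to_numpy()
    keep = (n_genes >= qc.min_genes_per_cell) & (mito <= qc.max_mito_fraction)
    reasons = []
    for i in range(m.n_cells):
        r = []
        if n_genes[i] < qc.min_genes_per_cell:
            r.append(f"fewer than {qc.min_genes_per_cell} genes")
        if mito[i] > qc.max_mito_fraction:
            r.append(f"mito fraction above {qc.max_mito_fraction:g}")
        reasons.append("; ".join(r))
    report = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "n_genes": n_genes,
            "mito_fraction": mito,
            "kept": keep,
            "reason": reasons,
        }
    ).set_index("cell_id")
    kept_ids = [c for c, k in zip(m.cell_ids, keep) if k]
    return m.subset_cells(kept_ids), report


def log_normalize(
    m: ExpressionMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR
) -> ExpressionMatrix:
    """Per-cell log normalization: ``ln(1 + count * scale_factor / cell_total)``.

    This is the standard single-cell "LogNormalize" transform at scale factor
    10 000; zeros map to zero exactly and the transform is strictly monotone
    in the count within each cell.
    """
    if m.layer != "counts":
        raise ValueError("log_normalize operates on the counts layer")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.values.sum(axis=0)
    if np.any(totals == 0):
        bad = m.cell_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"cell {bad!r} has zero total counts")
    vals = np.log1p(m.values * (scale_factor / totals)[np.newaxis, :])
    return ExpressionMatrix(vals, list(m.gene_ids), list(m.cell_ids), layer="lognorm")
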