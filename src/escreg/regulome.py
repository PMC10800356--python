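"""Co-expression regulome construction by pairwise Pearson correlation.

The regulome is built in three steps: (1) candidate genes are the
intersection of pooled signature genes with the union of significant
differentially expressed genes; (2) all candidate gene pairs are scored by
the Pearson correlation of their log-normalized expression across cells;
(3) a gene joins the regulome when it shows a correlation above the
threshold (default 0.4, strict) with at least ``min_partners`` other
candidates.  Zero-variance genes are excluded and reported rather than
carried as undefined correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "PCCMatrix",
    "RegulomeResult",
    "select_candidates",
    "pairwise_pcc",
    "regulome_membership",
    "pcc_summary",
]


@dataclass
class PCCMatrix:
    """Symmetric Pearson-correlation grid over an ordered gene list."""

    genes: list[str]
    values: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.genes)):
            raise ValueError("PCC grid shape does not match gene list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("PCC grid is not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PCC grid contains non-finite values")
        if np.any(np.abs(self.values) > 1 + 1e-12):
            raise ValueError("PCC values outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def off_diagonal(self) -> np.ndarray:
        """Strict upper-triangle values (each unordered pair once)."""
        iu = np.triu_indices(len(self.genes), k=1)
        return self.values[iu]


@dataclass
class RegulomeResult:
    """Outcome of threshold-based regulome membership calling."""

    candidates: set[str]
    members: set[str]
    threshold: float
    pcc: PCCMatrix
    dropped_degenerate: set[str] = field(default_factory=set)
    min_partners: int = 1

    def to_dict(self) -> dict:
        return {
            "candidates": sorted(self.candidates),
            "members": sorted(self.members),
            "threshold": self.threshold,
            "min_partners": self.min_partners,
            "dropped_degenerate": sorted(self.dropped_degenerate),
        }


def select_candidates(
    signatures: GeneSetCollection,
    deg_tables: list[pd.DataFrame],
    padj_cut: float = 0.05,
    lfc_cut: float = 0.5,
) -> list[str]:
    """Candidate regulome genes: pooled signatures ∩ union of significant DEGs.

    Each DEG table needs columns ``gene``, ``log2fc``, ``padj``; a gene passes
    with ``padj <= padj_cut`` and ``|log2fc| >= lfc_cut``.  The result is
    sorted for determinism; an empty intersection warns rather than fails.
    """
    if not signatures.sets or not deg_tables:
        raise ValueError("need at least one signature and one DEG table")
    sig_genes = signatures.all_genes()
    deg_union: set[str] = set()
    for table in deg_tables:
        passing = table[
            (table["padj"] <= padj_cut) & (table["log2fc"].abs() >= lfc_cut)
        ]
        deg_union.update(passing["gene"].astype(str))
    result = sorted(sig_genes & deg_union)
    if not result:
        warnings.warn("candidate selection produced an empty gene set")
    return result


def pairwise_pcc(
    m: ExpressionMatrix,
    genes,
    cell_subset=None,
) -> tuple[PCCMatrix, set[str]]:
    """All-pairs Pearson correlation of the given genes across cells.

    Genes absent from the matrix are skipped with a warning; genes with zero
    variance over the (optional) cell subset are excluded from the grid and
    returned as the second element.  Requires at least 3 observations.
    """
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in set(m.gene_ids)]
    missing = [g for g in genes if g not in set(m.gene_ids)]
    if missing:
        warnings.warn(f"{len(missing)} requested genes absent from matrix: {missing[:5]}...")
    if cell_subset is not None:
        m = m.subset_cells(list(cell_subset))
    if m.n_cells < 3:
        raise ValueError(f"need at least 3 cells, got {m.n_cells}")
    if not present:
        raise ValueError("none of the requested genes are present")
    sub = m.values[m.gene_index(present), :].astype(float)
    variances = sub.var(axis=1)
    degenerate = {g for g, v in zip(present, variances) if v == 0.0}
    kept = [g for g in present if g not in degenerate]
    if not kept:
        raise ValueError("all requested genes are degenerate (zero variance)")
    sub = sub[[present.index(g) for g in kept], :]
    grid = np.corrcoef(sub)
    grid = np.clip((grid + grid.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(grid, 1.0)
    return PCCMatrix(kept, grid, n_obs=m.n_cells), degenerate


def regulome_membership(
    pcc: PCCMatrix,
    threshold: float = 0.4,
    min_partners: int = 1,
    dropped_degenerate: set[str] | None = None,
) -> RegulomeResult:
    """Call regulome members: genes with >= min_partners correlations above threshold.

    The comparison is strict (``PCC > threshold``), with the default
    threshold 0.4.  ``min_partners`` interpolates between "correlated with at
    least one other candidate" (1, the default) and "correlated with every
    other candidate" (``len(genes) - 1``).
    """
    if not -1.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly inside (-1, 1)")
    if min_partners < 1:
        raise ValueError("min_partners must be >= 1")
    off = pcc.values.copy()
    np.fill_diagonal(off, -np.inf)
    n_above = (off > threshold).sum(axis=1)
    members = {g for g, n in zip(pcc.genes, n_above) if n >= min_partners}
    return RegulomeResult(
        candidates=set(pcc.genes) | set(dropped_degenerate or set()),
        members=members,
        threshold=threshold,
        pcc=pcc,
        dropped_degenerate=set(dropped_degenerate or set()),
        min_partners=min_partners,
    )


def pcc_summary(
    pcc_by_condition: dict[str, PCCMatrix], bins: int = 50
) -> pd.DataFrame:
    """Per-condition mean off-diagonal PCC and a shared-edge histogram.

    Returns one row per condition with the mean over the strict upper
    triangle, the number of gene pairs, and the histogram counts over
    ``bins`` equal-width bins spanning [-1, 1] (edges identical across
    conditions so distributions are directly comparable).
    """
    if not pcc_by_condition:
        raise ValueError("need at least one condition")
    edges = np.linspace(-1.0, 1.0, bins + 1)
    rows = []
    for cond, pcc in pcc_by_condition.items():
        off = pcc.off_diagonal()
        if off.size == 0:
            raise ValueError(f"condition {cond!r} has no gene pairs")
        hist, _ = np.histogram(off, bins=edges)
        rows.append(
            {
                "condition": cond,
                "mean_pcc": float(off.mean()),
                "n_pairs": int(off.size),
                "histogram": hist.tolist(),
            }
        )
    out = pd.DataFrame(rows).set_index("condition")
    out.attrs["bin_edges"] = edges.tolist()
    return out


def heatmap_order(pcc: PCCMatrix) -> list[str]:
    """Average-linkage leaf order on (1 - PCC) distance, for reproducible export."""
    if len(pcc.genes) < 3:
        return sorted(pcc.genes)
    order = np.argsort(pcc.genes, kind="stable")  # lexicographic tie-break
    dist = 1.0 - pcc.values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    linkage = scipy.cluster.hierarchy.average(condensed)
    leaves = scipy.cluster.hierarchy.leaves_list(linkage)
    sorted_genes = [pcc.genes[i] for i in order]
    return [sorted_genes[i] for i in leaves]
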