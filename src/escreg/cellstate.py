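"""Per-cell signature scoring, cell-cycle phases, quiescence gating and DE.

Signature scores are the arithmetic mean of log-normalized expression over
the signature genes present in the matrix.  Cell-cycle assignment follows
the standard expression-matched control construction: each phase score is
the mean of the phase genes minus the mean of control genes drawn from
mean-expression bins; a cell takes the phase of its largest positive score,
defaults to G1 otherwise, and G1 cells with no detectable MKI67 are
relabeled G0 (quiescent).  The quiescence classifier combines a low
regulome-score gate with per-marker quantile gates (MKI67/CD38/TP53 below
the 95th quantile among expressing cells by default).  Differential
expression between cell groups uses the two-sided Wilcoxon rank-sum test
with Benjamini–Hochberg correction and a log2 fold change computed on
de-logged means.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

__all__ = [
    "QuiescenceGate",
    "score_signature",
    "cluster_high_call",
    "assign_cell_cycle",
    "select_exemplars",
    "classify_quiescent",
    "rank_sum_de",
]

PHASE_ORDER = ("G0", "G1", "S", "G2M")


@dataclass
class QuiescenceGate:
    """Quantile gates defining the quiescent (regulome-low) cell state.

    A cell is quiescent when its regulome score falls below the
    ``escreg_quantile`` quantile of all cells' scores and each marker's
    expression falls below the marker's quantile computed among expressing
    cells (``among_expressing=True``) or among all cells.
    """

    escreg_quantile: float = 0.5
    marker_gates: list[tuple[str, float, bool]] = field(
        default_factory=lambda: [
            ("MKI67", 0.95, True),
            ("CD38", 0.95, True),
            ("TP53", 0.95, True),
        ]
    )

    def __post_init__(self) -> None:
        for q in [self.escreg_quantile] + [q for _, q, _ in self.marker_gates]:
            if not 0.0 < q <= 1.0:
                raise ValueError(f"gate quantile must be in (0, 1], got {q!r}")


def score_signature(m: ExpressionMatrix, genes) -> pd.Series:
    """Mean log-normalized expression of the signature genes, per cell."""
    if m.layer != "lognorm":
        raise ValueError("score_signature expects log-normalized values")
    genes = [str(g) for g in genes]
    present = [g for g in genes if g in set(m.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the matrix")
    if len(present) < len(genes):
        warnings.warn(
            f"{len(genes) - len(present)} signature genes absent from the matrix"
        )
    scores = m.values[m.gene_index(present), :].mean(axis=0)
    return pd.Series(scores, index=m.cell_ids, name="signature_score")


def cluster_high_call(
    scores: pd.Series, clusters: pd.Series, threshold: float | None = None
) -> tuple[pd.DataFrame, float]:
    """Flag high-scoring clusters and the overall fraction of cells in them.

    A cluster is "high" when its mean score strictly exceeds the median of
    cluster means (or a caller-supplied absolute *threshold*).  Returns the
    per-cluster table (mean score, cell count, high flag) and the fraction of
    all cells that sit in high clusters.
    """
    clusters = clusters.reindex(scores.index)
    if clusters.isna().any():
        raise ValueError("every cell must carry a cluster label")
    if len(clusters) == 0:
        raise ValueError("empty cluster label set")
    table = pd.DataFrame({"score": scores, "cluster": clusters})
    means = table.groupby("cluster")["score"].mean()
    counts = table.groupby("cluster")["score"].size()
    cut = float(np.median(means.to_numpy())) if threshold is None else float(threshold)
    high = means > cut
    out = pd.DataFrame({"mean_score": means, "n_cells": counts, "high": high})
    fraction = float(counts[high].sum() / counts.sum()) if high.any() else 0.0
    return out, fraction


def _expression_bins(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin label per gene, by rank of mean expression."""
    order = scipy.stats.rankdata(gene_means, method="ordinal") - 1
    return (order * n_bins // len(gene_means)).astype(int)


def _control_score(
    values: np.ndarray,
    gene_ids: list[str],
    sig_genes: list[str],
    bins: np.ndarray,
    n_ctrl: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Phase-gene mean minus mean of bin-matched control genes, per cell."""
    idx = {g: i for i, g in enumerate(gene_ids)}
    sig_idx = np.array([idx[g] for g in sig_genes])
    control: set[int] = set()
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        pool = pool[~np.isin(pool, sig_idx)]
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    if not control:
        raise ValueError("no control genes available for signature scoring")
    ctrl_idx = np.array(sorted(control))
    return values[sig_idx, :].mean(axis=0) - values[ctrl_idx, :].mean(axis=0)


def assign_cell_cycle(
    m: ExpressionMatrix,
    s_genes,
    g2m_genes,
    mki67_gene: str = "MKI67",
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Score S and G2M programs and assign each cell a cycle phase.

    Scores are control-matched: mean(phase genes) − mean(control genes drawn
    from the phase genes' mean-expression bins, ``n_ctrl`` per gene, seeded).
    Phase is the argmax of (s_score, g2m_score) when that max is positive,
    else G1; G1 cells with zero MKI67 are relabeled G0.  Returns a per-cell
    frame with columns ``s_score``, ``g2m_score``, ``phase``.
    """
    if m.layer != "lognorm":
        raise ValueError("assign_cell_cycle expects log-normalized values")
    universe = set(m.gene_ids)
    if mki67_gene not in universe:
        raise ValueError(f"proliferation marker {mki67_gene!r} absent from the matrix")
    s_present = [g for g in map(str, s_genes) if g in universe]
    g2m_present = [g for g in map(str, g2m_genes) if g in universe]
    if not s_present or not g2m_present:
        raise ValueError("phase gene sets are empty after intersection with the matrix")
    rng = np.random.default_rng(seed)
    gene_means = m.values.mean(axis=1)
    bins = _expression_bins(gene_means, n_bins)
    s_score = _control_score(m.values, m.gene_ids, s_present, bins, n_ctrl, rng)
    g2m_score = _control_score(m.values, m.gene_ids, g2m_present, bins, n_ctrl, rng)
    best = np.where(s_score >= g2m_score, "S", "G2M")
    phase = np.where(np.maximum(s_score, g2m_score) > 0, best, "G1")
    mki67 = m.values[m.gene_index([mki67_gene])[0], :]
    phase = np.where((phase == "G1") & (mki67 == 0), "G0", phase)
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase},
        index=m.cell_ids,
    )


def select_exemplars(table: pd.DataFrame, n_per_phase: int = 500) -> dict[str, list[str]]:
    """Pick up to ``n_per_phase`` exemplar cells per cell-cycle phase.

    S and G2M exemplars are the cells with the highest phase score; G1 and G0
    exemplars are the cells with the lowest maximum cycle score (the most
    convincingly non-cycling).  Ties break lexicographically on cell id so
    repeated runs return the same cells.  Shortfalls warn rather than fail.
    """
    required = {"s_score", "g2m_score", "phase"}
    if not required <= set(table.columns):
        raise ValueError(f"table must carry columns {sorted(required)}")
    out: dict[str, list[str]] = {}
    max_score = table[["s_score", "g2m_score"]].max(axis=1)
    for phase in PHASE_ORDER:
        cells = table[table["phase"] == phase]
        if phase == "S":
            rank_key = -cells["s_score"]
        elif phase == "G2M":
            rank_key = -cells["g2m_score"]
        else:  # G1 / G0: most negative cycle score first
            rank_key = max_score.loc[cells.index]
        order = sorted(cells.index.astype(str), key=lambda c: (rank_key.loc[c], c))
        chosen = order[:n_per_phase]
        if len(chosen) < n_per_phase:
            warnings.warn(
                f"phase {phase}: only {len(chosen)} cells available "
                f"(requested {n_per_phase})"
            )
        out[phase] = chosen
    return out


def classify_quiescent(
    m: ExpressionMatrix,
    escreg_genes,
    gate: QuiescenceGate | None = None,
) -> tuple[pd.Series, dict]:
    """Flag quiescent cells by low regulome score and low marker expression.

    Returns the per-cell boolean series and a report with the thresholds
    actually applied.  Marker gates with ``among_expressing=True`` compute
    their quantile over cells with nonzero expression of that marker; a
    marker with no expressing cell is an error.
    """
    if m.layer != "lognorm":
        raise ValueError("classify_quiescent expects log-normalized values")
    gate = gate or QuiescenceGate()
    scores = score_signature(m, escreg_genes)
    score_cut = float(np.quantile(scores.to_numpy(), gate.escreg_quantile))
    quiescent = scores.to_numpy() < score_cut
    report: dict = {
        "escreg_quantile": gate.escreg_quantile,
        "escreg_threshold": score_cut,
        "marker_thresholds": {},
    }
    universe = set(m.gene_ids)
    for gene, q, among_expressing in gate.marker_gates:
        if gene not in universe:
            raise ValueError(f"gate gene {gene!r} absent from the matrix")
        expr = m.values[m.gene_index([gene])[0], :]
        pool = expr[expr > 0] if among_expressing else expr
        if pool.size == 0:
            raise ValueError(f"gate gene {gene!r} has no expressing cells")
        cut = float(np.quantile(pool, q))
        quiescent &= expr < cut
        report["marker_thresholds"][gene] = {
            "quantile": q,
            "among_expressing": among_expressing,
            "threshold": cut,
        }
    return pd.Series(quiescent, index=m.cell_ids, name="quiescent"), report


# ---------------------------------------------------------------------------
# Rank-sum differential expression

_EXACT_MAX = 8


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group labelings.

    Handles ties exactly: p = P(|S - E[S]| >= |S_obs - E[S]|) over all
    C(n, n_x) assignments of the pooled (tie-averaged) ranks.
    """
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n, n_x = len(pooled), len(x)
    s_obs = ranks[:n_x].sum()
    mu = n_x * (n + 1) / 2.0
    d_obs = abs(s_obs - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_x):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def _asymptotic_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided normal-approximation rank-sum p with tie correction."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n, n_x = len(pooled), len(x)
    n_y = n - n_x
    s = ranks[:n_x].sum()
    mu = n_x * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / ((n) * (n - 1))
    var = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (s - mu) / math.sqrt(var)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def rank_sum_de(
    m: ExpressionMatrix,
    group_a,
    group_b,
    lfc_cut: float = 0.5,
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Per gene: a two-sided rank-sum p (exact enumeration when both groups
    have at most 8 cells, else normal approximation with tie correction),
    Benjamini–Hochberg adjustment over all tested genes, and
    ``log2fc = log2(mean(expm1(a)) + 1) - log2(mean(expm1(b)) + 1)``.
    Returns a frame with columns gene, log2fc, p, padj, significant — the
    ``significant`` genes are those with ``padj <= padj_cut`` and
    ``|log2fc| >= lfc_cut``.
    """
    if m.layer != "lognorm":
        raise ValueError("rank_sum_de expects log-normalized values")
    group_a, group_b = list(map(str, group_a)), list(map(str, group_b))
    if set(group_a) & set(group_b):
        raise ValueError("cell groups must be disjoint")
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("each group needs at least 3 cells")
    a = m.subset_cells(group_a).values
    b = m.subset_cells(group_b).values
    exact = len(group_a) <= _EXACT_MAX and len(group_b) <= _EXACT_MAX
    pvals = np.empty(m.n_genes)
    for i in range(m.n_genes):
        xa, xb = a[i], b[i]
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            pvals[i] = 1.0
        elif exact:
            pvals[i] = _exact_ranksum_p(xa, xb)
        else:
            pvals[i] = _asymptotic_ranksum_p(xa, xb)
    lfc = np.log2(np.expm1(a).mean(axis=1) + 1.0) - np.log2(
        np.expm1(b).mean(axis=1) + 1.0
    )
    padj = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "log2fc": lfc,
            "p": pvals,
            "padj": padj,
            "significant": (padj <= padj_cut) & (np.abs(lfc) >= lfc_cut),
        }
    )
    return out
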