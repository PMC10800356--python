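"""Factor–factor co-occupancy correlation on regulome genes.

A binding matrix is a binary genes×factors grid (TF or histone-mark bound /
unbound at each gene).  Restricted to regulome genes, the Pearson correlation
between two factors' 0/1 occupancy columns equals the phi coefficient of
their 2×2 co-occupancy table; blocks of high correlation reveal factors that
co-occupy regulome genes as a complex.  ``cooccupancy_contrast`` makes
"over-represented on the regulome" testable by comparing the regulome grid
to the average grid over size-matched random background gene draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["BindingMatrix", "CooccupancyResult", "factor_cooccupancy", "cooccupancy_contrast"]


@dataclass
class BindingMatrix:
    """Binary genes×factors occupancy grid."""

    values: pd.DataFrame  # index = genes, columns = factors, entries 0/1

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binding matrix entries must be 0/1")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene labels in binding matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate factor labels in binding matrix")

    @classmethod
    def read_tsv(cls, path) -> "BindingMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.values.astype(int).to_csv(path, sep="\t")

    @property
    def genes(self) -> list[str]:
        return self.values.index.astype(str).tolist()

    @property
    def factors(self) -> list[str]:
        return self.values.columns.astype(str).tolist()


@dataclass
class CooccupancyResult:
    """Factor correlation grids on regulome genes and (optionally) background."""

    factor_pcc: pd.DataFrame
    background_pcc: pd.DataFrame | None = None
    delta: pd.DataFrame | None = None
    excluded_factors: set[str] = field(default_factory=set)


def _factor_corr(occupancy: np.ndarray, factors: list[str]) -> tuple[pd.DataFrame, set[str]]:
    """Correlate factor columns of a genes×factors 0/1 block; drop constants."""
    variances = occupancy.var(axis=0)
    keep = variances > 0
    excluded = {f for f, k in zip(factors, keep) if not k}
    kept = [f for f, k in zip(factors, keep) if k]
    if not kept:
        raise ValueError("all factors have constant occupancy on the gene subset")
    grid = np.corrcoef(occupancy[:, keep], rowvar=False)
    grid = np.atleast_2d(grid)
    grid = np.clip((grid + grid.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(grid, 1.0)
    return pd.DataFrame(grid, index=kept, columns=kept), excluded


def factor_cooccupancy(b: BindingMatrix, regulome_genes) -> CooccupancyResult:
    """Pearson (phi) correlation of every factor pair on regulome genes.

    Factors whose occupancy is constant (all bound or all unbound) across the
    regulome genes are excluded and reported; requires at least 3 usable
    genes.
    """
    genes = sorted(set(map(str, regulome_genes)) & set(b.genes))
    if len(genes) < 3:
        raise ValueError(
            f"need at least 3 regulome genes present in the binding matrix, got {len(genes)}"
        )
    occ = b.values.loc[genes].to_numpy(dtype=float)
    grid, excluded = _factor_corr(occ, b.factors)
    return CooccupancyResult(factor_pcc=grid, excluded_factors=excluded)


def cooccupancy_contrast(
    b: BindingMatrix,
    regulome_genes,
    background_genes,
    n_background_draws: int = 100,
    seed: int = 0,
) -> CooccupancyResult:
    """Regulome co-occupancy grid contrasted with size-matched background draws.

    ``background_pcc`` is the elementwise mean of the factor correlation grid
    over ``n_background_draws`` random background samples of the same size as
    the regulome set (a factor constant within one draw contributes no value
    for that draw); ``delta`` is regulome minus background.  Background must
    be disjoint from and at least as large as the regulome set.
    """
    reg = sorted(set(map(str, regulome_genes)) & set(b.genes))
    bg = sorted(set(map(str, background_genes)) & set(b.genes))
    overlap = set(reg) & set(bg)
    identity_mode = set(reg) == set(bg)  # self-contrast sanity check
    if overlap and not identity_mode:
        raise ValueError("background genes must be disjoint from regulome genes")
    if len(reg) < 3 or len(bg) < 3:
        raise ValueError("regulome and background sets need at least 3 genes each")
    if len(bg) < len(reg) and not identity_mode:
        raise ValueError(
            f"background ({len(bg)}) smaller than regulome ({len(reg)}); "
            "cannot draw size-matched samples"
        )
    result = factor_cooccupancy(b, reg)
    factors = result.factor_pcc.index.tolist()
    rng = np.random.default_rng(seed)
    stack = np.full((n_background_draws, len(factors), len(factors)), np.nan)
    for d in range(n_background_draws):
        draw = bg if identity_mode else list(
            rng.choice(bg, size=len(reg), replace=False)
        )
        occ = b.values.loc[draw, factors].to_numpy(dtype=float)
        var = occ.var(axis=0)
        usable = var > 0
        if usable.sum() < 2:
            continue
        sub = np.corrcoef(occ[:, usable], rowvar=False)
        idx = np.flatnonzero(usable)
        stack[np.ix_([d], idx, idx)] = np.clip(sub, -1.0, 1.0)
        stack[d][np.diag_indices(len(factors))] = 1.0
    with np.errstate(invalid="ignore"):
        bg_grid = np.nanmean(stack, axis=0)
    background = pd.DataFrame(bg_grid, index=factors, columns=factors)
    delta = result.factor_pcc - background
    return CooccupancyResult(
        factor_pcc=result.factor_pcc,
        background_pcc=background,
        delta=delta,
        excluded_factors=result.excluded_factors,
    )
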