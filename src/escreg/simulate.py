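"""Synthetic single-cell, binding and bulk data with known planted structure.

The generator plants exactly the statistical features the downstream analysis
assumes, so every stage can be validated against ground truth without any
external download:

* a correlated gene module driven by one per-cell lognormal latent activity
  (the stand-in for the stem-cell-like regulome);
* cell-cycle phase programs (S and G2M gene sets elevated in their phase) and
  a quiescent G0 subpopulation with low module activity and near-zero counts
  for the MKI67 / CD38 / TP53 marker genes;
* mitochondrial genes (``MT-`` prefix) with a high-mito cell band;
* binary genes×factors occupancy matrices whose factors fall into
  "complexes" sharing occupancy on regulome genes;
* two-condition bulk counts with planted differentially expressed genes.

Counts are negative binomial (gene-level dispersion, Poisson in the
zero-dispersion limit) with multiplicative Bernoulli dropout.  All draws flow
from a single seed; identical configuration implies identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_cells",
    "simulate_binding",
    "simulate_bulk",
    "emit_candidate_inputs",
    "write_truth",
]

MARKER_GENES = ("MKI67", "CD38", "TP53")
PHASES = ("G0", "G1", "S", "G2M")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


def _default_phase_fractions() -> dict[str, float]:
    # Quiescence-dominated stem-cell compartment: half the cells in G0.
    return {"G0": 0.5, "G1": 0.2, "S": 0.15, "G2M": 0.15}


@dataclass
class SimConfig:
    """Parameters of the single-cell simulation.

    ``module_strength`` is the standard deviation of the latent log-activity
    shared by module genes; ``quiescent_module_factor`` scales module
    activity in quiescent cells (low), and ``marker_quiescent_factor`` scales
    MKI67/CD38/TP53 in quiescent cells (near-zero counts).
    """

    n_cells: int = 500
    n_genes: int = 2000
    module_size: int = 50
    module_strength: float = 0.5
    phase_fractions: dict[str, float] = field(default_factory=_default_phase_fractions)
    quiescent_fraction: float = 0.5
    mito_genes: int = 10
    mito_high_fraction: float = 0.2
    library_size_mean: float = 5000.0
    dropout_rate: float = 0.1
    dispersion: float = 0.3
    seed: int = 0
    mito_prefix: str = "MT-"
    s_program_size: int = 40
    g2m_program_size: int = 40
    phase_program_fold: float = 5.0
    phase_program_baseline: float = 0.3
    quiescent_module_factor: float = 0.02
    marker_quiescent_factor: float = 0.01

    def validate(self) -> None:
        for name in ("n_cells", "n_genes", "module_size", "mito_genes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        total = sum(self.phase_fractions.get(p, 0.0) for p in PHASES)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"phase_fractions must sum to 1 (got {total!r})"
            )
        for name in ("quiescent_fraction", "mito_high_fraction", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1] (got {v!r})")
        reserved = (
            self.module_size
            + self.mito_genes
            + len(MARKER_GENES)
            + self.s_program_size
            + self.g2m_program_size
        )
        if reserved > self.n_genes:
            raise ConfigurationError(
                f"module, mito, marker and phase-program genes ({reserved}) "
                f"exceed n_genes ({self.n_genes})"
            )
        if self.quiescent_fraction > self.phase_fractions.get("G0", 0.0) + 1e-9:
            raise ConfigurationError(
                "quiescent_fraction cannot exceed the G0 phase fraction "
                "(quiescent cells are a subset of G0)"
            )


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    module_genes: set[str] = field(default_factory=set)
    phase_of_cell: dict[str, str] = field(default_factory=dict)
    quiescent_cells: set[str] = field(default_factory=set)
    complex_of_factor: dict[str, str] = field(default_factory=dict)
    deg_genes: set[str] = field(default_factory=set)
    s_genes: list[str] = field(default_factory=list)
    g2m_genes: list[str] = field(default_factory=list)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2; Poisson at 0."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def gene_universe(config: SimConfig) -> dict[str, list[str]]:
    """Deterministic gene naming: markers, mito, phase programs, module, background."""
    n_named = (
        len(MARKER_GENES)
        + config.mito_genes
        + config.s_program_size
        + config.g2m_program_size
        + config.module_size
    )
    return {
        "markers": list(MARKER_GENES),
        "mito": [f"{config.mito_prefix}{i + 1}" for i in range(config.mito_genes)],
        "s_program": [f"SP{i + 1:03d}" for i in range(config.s_program_size)],
        "g2m_program": [f"GM{i + 1:03d}" for i in range(config.g2m_program_size)],
        "module": [f"RG{i + 1:03d}" for i in range(config.module_size)],
        "background": [f"BG{i + 1:04d}" for i in range(config.n_genes - n_named)],
    }


def simulate_cells(
    config: SimConfig,
) -> tuple[ExpressionMatrix, GroundTruth, pd.DataFrame]:
    """Simulate a single-cell counts matrix with planted module, phases and G0.

    Returns the counts matrix (genes × cells), the ground truth, and a
    per-cell label table (phase, quiescent flag, high-mito flag, cluster —
    ``"quiescent"`` vs ``"cycling"``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = gene_universe(config)
    genes = [g for grp in groups.values() for g in grp]
    n_genes = len(genes)
    cells = [f"CELL{i + 1:05d}" for i in range(config.n_cells)]

    # --- per-cell state ------------------------------------------------
    # exact phase composition (largest remainder), randomly assigned to cells
    probs = np.array([config.phase_fractions.get(p, 0.0) for p in PHASES])
    quota = probs * config.n_cells
    n_phase = np.floor(quota).astype(int)
    remainder = np.argsort(-(quota - n_phase), kind="stable")
    for i in remainder[: config.n_cells - n_phase.sum()]:
        n_phase[i] += 1
    phase = np.repeat(PHASES, n_phase)
    rng.shuffle(phase)
    g0_idx = np.flatnonzero(phase == "G0")
    n_quiescent = int(round(config.quiescent_fraction * config.n_cells))
    n_quiescent = min(n_quiescent, g0_idx.size)
    quiescent = np.zeros(config.n_cells, dtype=bool)
    quiescent[rng.choice(g0_idx, size=n_quiescent, replace=False)] = True

    high_mito = rng.random(config.n_cells) < config.mito_high_fraction
    lib = rng.lognormal(np.log(config.library_size_mean), 0.3, config.n_cells)
    latent = np.exp(config.module_strength * rng.standard_normal(config.n_cells))
    module_activity = np.where(
        quiescent, config.quiescent_module_factor * latent, latent
    )

    # --- per-gene base abundance ---------------------------------------
    base = rng.lognormal(0.0, 1.0, n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    # module genes kept away from the low-abundance tail so the planted
    # correlation is observable at realistic depth
    for g in groups["module"]:
        base[idx[g]] = rng.lognormal(0.5, 0.5)
    for g in groups["mito"]:
        base[idx[g]] = 3.0
    base[idx["MKI67"]] = 4.0
    base[idx["CD38"]] = 2.5
    base[idx["TP53"]] = 2.5

    # --- cell-specific multipliers -------------------------------------
    mult = np.ones((n_genes, config.n_cells))
    mod_rows = [idx[g] for g in groups["module"]]
    mult[mod_rows, :] = module_activity[np.newaxis, :]
    # cycle programs are on in their phase and repressed elsewhere, so that
    # control-matched scoring sees genuinely negative scores in non-cycling cells
    s_rows = [idx[g] for g in groups["s_program"]]
    g2m_rows = [idx[g] for g in groups["g2m_program"]]
    mult[s_rows, :] = config.phase_program_baseline
    mult[g2m_rows, :] = config.phase_program_baseline
    mult[np.ix_(s_rows, phase == "S")] = config.phase_program_fold
    mult[np.ix_(g2m_rows, phase == "G2M")] = config.phase_program_fold
    marker_rows = [idx[g] for g in MARKER_GENES]
    mult[np.ix_(marker_rows, quiescent)] = config.marker_quiescent_factor
    mito_rows = [idx[g] for g in groups["mito"]]
    mult[np.ix_(mito_rows, high_mito)] = 8.0

    rate = base[:, np.newaxis] * mult
    rate = rate / rate.sum(axis=0, keepdims=True) * lib[np.newaxis, :]
    counts = _nb_draw(rng, rate, config.dispersion)
    if config.dropout_rate > 0:
        counts = counts * (rng.random(counts.shape) >= config.dropout_rate)

    truth = GroundTruth(
        module_genes=set(groups["module"]),
        phase_of_cell={c: str(p) for c, p in zip(cells, phase)},
        quiescent_cells={c for c, q in zip(cells, quiescent) if q},
        s_genes=list(groups["s_program"]),
        g2m_genes=list(groups["g2m_program"]),
    )
    labels = pd.DataFrame(
        {
            "cell_id": cells,
            "phase": phase,
            "quiescent": quiescent,
            "high_mito": high_mito,
            "cluster": np.where(quiescent, "quiescent", "cycling"),
        }
    ).set_index("cell_id")
    em = ExpressionMatrix(counts.astype(np.int64), genes, cells, layer="counts")
    return em, truth, labels


def simulate_binding(
    n_factors: int,
    n_complexes: int,
    regulome_genes,
    background_genes,
    cooccupancy_prob: float = 0.9,
    background_prob: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a binary genes×factors occupancy matrix with planted complexes.

    Factors are assigned round-robin to ``n_complexes`` complexes.  On
    regulome genes, each complex carries a shared per-gene occupancy
    indicator (Bernoulli 0.5); a member factor copies that indicator with
    probability ``cooccupancy_prob`` and otherwise binds independently with
    probability ``background_prob``.  Off the regulome, all factors bind
    independently with ``background_prob``.
    """
    regulome_genes = sorted(set(map(str, regulome_genes)))
    background_genes = sorted(set(map(str, background_genes)))
    if not regulome_genes or not background_genes:
        raise ValueError("regulome and background gene sets must be non-empty")
    if n_factors < n_complexes or n_complexes < 1:
        raise ValueError("need n_factors >= n_complexes >= 1")
    for name, p in (("cooccupancy_prob", cooccupancy_prob), ("background_prob", background_prob)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    factors = [f"TF{i + 1:02d}" for i in range(n_factors)]
    complex_of = {f: f"complex{(i % n_complexes) + 1}" for i, f in enumerate(factors)}
    genes = regulome_genes + [g for g in background_genes if g not in set(regulome_genes)]
    n_reg = len(regulome_genes)
    values = (rng.random((len(genes), n_factors)) < background_prob).astype(np.int8)
    shared = rng.random((n_reg, n_complexes)) < 0.5
    copy = rng.random((n_reg, n_factors)) < cooccupancy_prob
    for j, f in enumerate(factors):
        k = int(complex_of[f].removeprefix("complex")) - 1
        col = values[:n_reg, j].astype(bool)
        values[:n_reg, j] = np.where(copy[:, j], shared[:, k], col).astype(np.int8)
    binding = pd.DataFrame(values, index=genes, columns=factors)
    truth = GroundTruth(module_genes=set(regulome_genes), complex_of_factor=complex_of)
    return binding, truth


def simulate_bulk(
    n_per_group: int = 20,
    n_genes: int = 1000,
    deg_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, GroundTruth, pd.Series]:
    """Two-condition bulk counts with planted DEGs at a fixed log2 fold change.

    DEGs alternate direction (up/down in the second group).  Returns the
    counts matrix (genes × samples), truth (``deg_genes``) and per-sample
    group labels.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if not 0.0 <= deg_fraction <= 1.0:
        raise ValueError("deg_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"S{g}_{i + 1:02d}" for g in ("A", "B") for i in range(n_per_group)]
    group = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group, index=samples, name="group"
    )
    base = rng.lognormal(0.0, 1.0, n_genes)
    n_deg = int(round(deg_fraction * n_genes)) if effect_log2fc != 0 else 0
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False) if n_deg else np.array([], int)
    sign = np.where(np.arange(n_deg) % 2 == 0, 1.0, -1.0)
    fold = np.ones(n_genes)
    fold[deg_idx] = 2.0 ** (effect_log2fc * sign)
    lib = rng.lognormal(np.log(5e5), 0.1, 2 * n_per_group)
    rate = np.tile(base[:, np.newaxis], (1, 2 * n_per_group))
    rate[:, n_per_group:] *= fold[:, np.newaxis]
    rate = rate / rate.sum(axis=0, keepdims=True) * lib[np.newaxis, :]
    counts = _nb_draw(rng, rate, 0.1)
    em = ExpressionMatrix(counts.astype(np.int64), genes, samples, layer="counts")
    truth = GroundTruth(deg_genes={genes[i] for i in deg_idx})
    return em, truth, group


def emit_candidate_inputs(
    truth: GroundTruth, background_genes, seed: int = 0
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Signature sets and a DEG table whose intersection plants the candidates.

    Builds the two inputs the candidate-selection step consumes: a stem-like
    signature containing the planted module plus decoy genes, a second
    unrelated signature, and a DEG table in which the module and a subset of
    the decoys pass the significance cutoffs.  The resulting candidate set is
    the module plus correlated-noise-free decoys, so membership calling has
    genuine negatives to reject.
    """
    rng = np.random.default_rng(seed)
    module = sorted(truth.module_genes)
    background = sorted(set(map(str, background_genes)) - truth.module_genes)
    n_decoy = min(60, len(background))
    decoys = list(rng.choice(background, size=n_decoy, replace=False))
    half = n_decoy // 2
    sig_sets = {
        "STEMLIKE_SIGNATURE": module + decoys[:half],
        "UNRELATED_SIGNATURE": decoys[half:],
    }
    deg_rows = []
    for g in module:
        deg_rows.append((g, float(rng.uniform(1.0, 2.5) * rng.choice([-1, 1])), 1e-5))
    for g in decoys[: half // 2]:  # significant decoys -> candidate negatives
        deg_rows.append((g, float(rng.uniform(0.8, 1.5)), 1e-4))
    for g in decoys[half // 2 : half]:  # non-significant decoys
        deg_rows.append((g, float(rng.uniform(-0.2, 0.2)), 0.8))
    deg = pd.DataFrame(deg_rows, columns=["gene", "log2fc", "padj"])
    return sig_sets, deg


def write_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth to YAML (sets as sorted lists)."""
    payload = {
        "module_genes": sorted(truth.module_genes),
        "phase_of_cell": dict(sorted(truth.phase_of_cell.items())),
        "quiescent_cells": sorted(truth.quiescent_cells),
        "complex_of_factor": dict(sorted(truth.complex_of_factor.items())),
        "deg_genes": sorted(truth.deg_genes),
        "s_genes": list(truth.s_genes),
        "g2m_genes": list(truth.g2m_genes),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
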