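"""End-to-end orchestration: simulate/read → QC → normalize → regulome →
co-occupancy → cell states → differential expression → enrichment.

A single :class:`PipelineConfig` drives the run.  One global seed
deterministically derives a per-stage seed from the stage name, so a rerun
with the same configuration produces byte-identical artifacts and report.
The JSON report records the thresholds actually applied, per-stage record
counts, artifact hashes and — for simulated inputs — recovery metrics
against the planted ground truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cellstate, cooccupancy, io, regulome, simulate, stats

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("escreg")

QC_MODES = {
    "peripheral_blood": io.QCParams.peripheral_blood,
    "pdx": io.QCParams.pdx,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Run-level configuration.

    Exactly one of ``simulate`` (a :class:`~escreg.simulate.SimConfig`) or
    ``expression_path`` must be given.  File inputs: ``gmt_path`` for
    signatures, ``deg_paths`` for DEG tables, ``binding_path`` for a binary
    occupancy matrix, ``labels_path`` for per-cell cluster labels.
    """

    out_dir: str = "escreg_run"
    seed: int = 0
    simulate: simulate.SimConfig | None = None
    expression_path: str | None = None
    expression_format: str = "mtx"
    gmt_path: str | None = None
    deg_paths: list[str] = field(default_factory=list)
    binding_path: str | None = None
    labels_path: str | None = None
    qc_mode: str = "peripheral_blood"
    scale_factor: float = 10_000.0
    candidate_padj_cut: float = 0.05
    candidate_lfc_cut: float = 0.5
    pcc_threshold: float = 0.4
    min_partners: int = 1
    exemplar_n: int = 500
    de_lfc_cut: float = 0.5
    de_padj_cut: float = 0.05
    quiescence_gate: cellstate.QuiescenceGate = field(
        default_factory=cellstate.QuiescenceGate
    )

    def validate(self) -> None:
        if (self.simulate is None) == (self.expression_path is None):
            raise ValueError(
                "config must provide exactly one of a simulate block or an expression path"
            )
        if self.qc_mode not in QC_MODES:
            raise ValueError(f"unknown qc_mode {self.qc_mode!r}")
        for path in [
            self.expression_path,
            self.gmt_path,
            self.binding_path,
            self.labels_path,
            *self.deg_paths,
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = simulate.SimConfig(**raw["simulate"])
        if "quiescence_gate" in raw and raw["quiescence_gate"] is not None:
            gate = raw["quiescence_gate"]
            gate["marker_gates"] = [tuple(g) for g in gate.get("marker_gates", [])]
            raw["quiescence_gate"] = cellstate.QuiescenceGate(**gate)
        return cls(**raw)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write artifacts + report JSON.

    Returns the report dictionary (also written to ``report.json`` in the
    output directory).  Stage failures raise with the stage name; artifacts
    written before the failure are kept alongside a ``FAILED`` marker.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    stage = "init"
    try:
        # --- input / simulation ----------------------------------------
        truth = None
        labels = None
        signatures = None
        deg_tables: list[pd.DataFrame] = []
        binding = None
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            counts, truth, labels = simulate.simulate_cells(sim)
            io.write_expression(counts, out / "counts_mtx", format="mtx")
            labels.to_csv(out / "cell_labels.tsv", sep="\t")
            simulate.write_truth(truth, out / "ground_truth.yaml")
            groups = simulate.gene_universe(sim)
            sig_sets, deg = simulate.emit_candidate_inputs(
                truth, groups["background"], seed=stage_seed(config.seed, "candidates")
            )
            signatures = io.GeneSetCollection(sig_sets)
            io.write_gmt(signatures, out / "signatures.gmt")
            deg.to_csv(out / "deg_input.tsv", sep="\t", index=False)
            deg_tables = [deg]
            bind_df, bind_truth = simulate.simulate_binding(
                n_factors=12,
                n_complexes=2,
                regulome_genes=truth.module_genes,
                background_genes=groups["background"],
                seed=stage_seed(config.seed, "binding"),
            )
            binding = cooccupancy.BindingMatrix(bind_df)
            binding.write_tsv(out / "binding.tsv")
            truth.complex_of_factor = bind_truth.complex_of_factor
            report["stages"]["simulate"] = {
                "n_cells": counts.n_cells,
                "n_genes": counts.n_genes,
                "n_module_genes": len(truth.module_genes),
            }
        else:
            stage = "read"
            counts = io.read_expression(config.expression_path, config.expression_format)
            if config.gmt_path:
                signatures = io.read_gmt(config.gmt_path)
            for p in config.deg_paths:
                deg_tables.append(pd.read_csv(p, sep="\t"))
            if config.binding_path:
                binding = cooccupancy.BindingMatrix.read_tsv(config.binding_path)
            if config.labels_path:
                labels = pd.read_csv(config.labels_path, sep="\t", index_col=0)
            report["stages"]["read"] = {
                "n_cells": counts.n_cells,
                "n_genes": counts.n_genes,
            }

        # --- QC + normalization ----------------------------------------
        stage = "qc"
        qc = QC_MODES[config.qc_mode]()
        filtered, qc_report = io.filter_cells(counts, qc)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t")
        report["stages"]["qc"] = {
            "mode": config.qc_mode,
            "min_genes_per_cell": qc.min_genes_per_cell,
            "max_mito_fraction": qc.max_mito_fraction,
            "cells_in": counts.n_cells,
            "cells_kept": filtered.n_cells,
        }
        stage = "normalize"
        lognorm = io.log_normalize(filtered, config.scale_factor)
        report["stages"]["normalize"] = {"scale_factor": config.scale_factor}
        mito = io.mito_fraction(filtered, qc.mito_prefix)

        # --- regulome ---------------------------------------------------
        members: set[str] = set()
        if signatures is not None and deg_tables:
            stage = "regulome"
            candidates = regulome.select_candidates(
                signatures, deg_tables, config.candidate_padj_cut, config.candidate_lfc_cut
            )
            pcc, degenerate = regulome.pairwise_pcc(lognorm, candidates)
            result = regulome.regulome_membership(
                pcc, config.pcc_threshold, config.min_partners, degenerate
            )
            members = result.members
            pcc.to_frame().to_csv(out / "pcc_matrix.tsv", sep="\t")
            (out / "regulome.json").write_text(json.dumps(result.to_dict(), indent=2))
            report["stages"]["regulome"] = {
                "threshold": config.pcc_threshold,
                "min_partners": config.min_partners,
                "n_candidates": len(result.candidates),
                "n_members": len(members),
            }
            if truth is not None:
                planted = truth.module_genes
                non_module = set(result.candidates) - planted
                sens = len(members & planted) / len(planted) if planted else float("nan")
                admit = (
                    len(members & non_module) / len(non_module) if non_module else 0.0
                )
                report["stages"]["regulome"]["membership_sensitivity"] = sens
                report["stages"]["regulome"]["background_admission"] = admit

        # --- co-occupancy ------------------------------------------------
        if binding is not None and len(members) >= 3:
            stage = "cooccupancy"
            background = sorted(set(binding.genes) - members)
            contrast = cooccupancy.cooccupancy_contrast(
                binding,
                members & set(binding.genes),
                background,
                n_background_draws=50,
                seed=stage_seed(config.seed, "cooccupancy"),
            )
            contrast.factor_pcc.to_csv(out / "cooccupancy_pcc.tsv", sep="\t")
            contrast.delta.to_csv(out / "cooccupancy_delta.tsv", sep="\t")
            report["stages"]["cooccupancy"] = {
                "n_factors": contrast.factor_pcc.shape[0],
                "excluded_factors": sorted(contrast.excluded_factors),
            }

        # --- cell states --------------------------------------------------
        stage = "cellstate"
        score_genes = sorted(members) if members else sorted(
            truth.module_genes if truth else lognorm.gene_ids[:50]
        )
        escreg_score = cellstate.score_signature(lognorm, score_genes)
        s_genes = truth.s_genes if truth is not None else []
        g2m_genes = truth.g2m_genes if truth is not None else []
        state = pd.DataFrame({"escreg_score": escreg_score, "mito_fraction": mito})
        if s_genes and g2m_genes:
            cycle = cellstate.assign_cell_cycle(
                lognorm, s_genes, g2m_genes, seed=stage_seed(config.seed, "cellcycle")
            )
            state = state.join(cycle)
            exemplars = cellstate.select_exemplars(cycle, config.exemplar_n)
            (out / "exemplars.json").write_text(json.dumps(exemplars, indent=2))
            report["stages"]["cellstate"] = {
                "exemplar_n": config.exemplar_n,
                "exemplars_per_phase": {p: len(v) for p, v in exemplars.items()},
            }
            if truth is not None:
                planted_phase = pd.Series(truth.phase_of_cell).reindex(cycle.index)
                accuracy = float((cycle["phase"] == planted_phase).mean())
                report["stages"]["cellstate"]["phase_accuracy"] = accuracy
        quiescent, gate_report = cellstate.classify_quiescent(
            lognorm, score_genes, config.quiescence_gate
        )
        state["quiescent"] = quiescent
        if labels is not None and "cluster" in getattr(labels, "columns", []):
            state["cluster"] = labels["cluster"].reindex(state.index)
        state.to_csv(out / "cell_state.tsv", sep="\t")
        report["stages"]["quiescence"] = {"gate": gate_report}
        if truth is not None and truth.quiescent_cells:
            called = set(state.index[state["quiescent"]])
            planted_q = truth.quiescent_cells & set(state.index)
            tp = len(called & planted_q)
            report["stages"]["quiescence"]["precision"] = (
                tp / len(called) if called else float("nan")
            )
            report["stages"]["quiescence"]["recall"] = (
                tp / len(planted_q) if planted_q else float("nan")
            )

        # --- differential expression + enrichment -------------------------
        if state["quiescent"].any() and (~state["quiescent"]).sum() >= 3:
            stage = "de"
            de = cellstate.rank_sum_de(
                lognorm,
                state.index[state["quiescent"]],
                state.index[~state["quiescent"]],
                lfc_cut=config.de_lfc_cut,
                padj_cut=config.de_padj_cut,
            )
            de.to_csv(out / "de_quiescent_vs_cycling.tsv", sep="\t", index=False)
            report["stages"]["de"] = {
                "lfc_cut": config.de_lfc_cut,
                "padj_cut": config.de_padj_cut,
                "n_significant": int(de["significant"].sum()),
            }
            if signatures is not None:
                stage = "enrich"
                sig_genes = de.loc[de["significant"], "gene"].tolist()
                if sig_genes:
                    enrichment = stats.hypergeometric_ora(
                        sig_genes, signatures, lognorm.gene_ids
                    )
                    enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    report["stages"]["enrich"] = {
                        "n_sets_tested": len(enrichment),
                        "top_set": enrichment.iloc[0]["set_name"]
                        if len(enrichment)
                        else None,
                    }

        stage = "report"
        for artifact in sorted(out.iterdir()):
            if artifact.name not in ("report.json", "run.log") and artifact.is_file():
                report["artifacts"][artifact.name] = _hash_file(artifact)
            elif artifact.is_dir():
                for sub in sorted(artifact.iterdir()):
                    report["artifacts"][f"{artifact.name}/{sub.name}"] = _hash_file(sub)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        return report
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
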