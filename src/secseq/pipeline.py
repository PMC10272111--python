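"""End-to-end orchestration: preprocess -> gate -> secretion -> association.

Stages communicate through on-disk TSV/MTX/YAML artifacts inside the run
directory, so any stage's output can be inspected or reused. A run manifest
records the config snapshot, seed, per-stage cell counts and a content hash
of every output file; re-running with the same inputs reproduces identical
artifacts (the manifest's timestamps aside).
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association, gating, mixing, preprocess, secretion
from .config import PipelineConfig
from .io_formats import (
    FeatureCounts,
    GeneCountMatrix,
    read_cell_table,
    read_counts,
    write_cell_table,
)
from .synthetic import GeneratorConfig, generate_dataset, write_fixture

__all__ = ["PipelineError", "RunResult", "run_pipeline", "report"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunResult:
    """In-memory view of a pipeline run's outputs."""

    cells: pd.DataFrame
    thresholds: secretion.SecretionThresholds | None
    gates: dict[str, gating.GateSpec]
    correlation: pd.DataFrame | None
    de: pd.DataFrame | None
    compositions: dict[str, pd.DataFrame]
    pseudotime_profile: pd.DataFrame | None
    manifest: dict[str, Any]
    out_dir: Path


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    data_dir: str | Path | None = None,
    out_dir: str | Path = "secseq_run",
    demo: bool = False,
    generator_config: GeneratorConfig | None = None,
) -> RunResult:
    """Run the full SEC-seq analysis.

    With ``demo=True`` (or no ``data_dir``) a synthetic fixture is generated
    from ``generator_config`` (default conditions, seeded by
    ``config.seed``) and written next to the outputs, then analyzed exactly
    as an on-disk dataset would be.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    _write_manifest()
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    def _write_manifest() -> None:
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=str) + "\n"
        )

    def _save_table(name: str, table: pd.DataFrame) -> None:
        path = out_dir / name
        write_cell_table(table, path)
        manifest["outputs"][name] = _hash_file(path)

    # ---- load / generate -------------------------------------------------
    with _stage("load"):
        if demo or data_dir is None:
            gen_cfg = generator_config or GeneratorConfig(seed=config.seed)
            genes, feats, cells, truth = generate_dataset(gen_cfg)
            fixture_dir = out_dir / "fixture"
            write_fixture(genes, feats, cells, truth, fixture_dir)
            manifest["input"] = {"demo": True, "generator_seed": gen_cfg.seed}
        else:
            data_dir = Path(data_dir)
            genes, feats = read_counts(data_dir)
            cells_path = data_dir / "cells.tsv"
            if cells_path.exists():
                cells = read_cell_table(cells_path, barcodes=genes.cell_barcodes)
            else:
                cells = pd.DataFrame({"barcode": genes.cell_barcodes,
                                      "donor": "donor1", "timepoint": "na"})
            manifest["input"] = {
                "demo": False,
                "data_dir": str(data_dir),
                "matrix_hash": _hash_file(
                    next(p for p in (data_dir / "matrix.mtx",
                                     data_dir / "matrix.mtx.gz") if p.exists())
                ),
            }
        if config.sec_feature not in feats.feature_names:
            raise ValueError(
                f"secretion feature {config.sec_feature!r} not among capture "
                f"features {feats.feature_names}"
            )
        manifest["stages"]["load"] = {"n_cells": genes.n_cells,
                                      "n_genes": genes.n_genes}

    # ---- QC --------------------------------------------------------------
    with _stage("qc_filter"):
        genes_qc, qc_report = preprocess.qc_filter(
            genes, config.min_genes_per_cell, config.min_counts_per_cell
        )
        kept = np.flatnonzero(
            (qc_report.reasons["reason"] == "kept").to_numpy()
        )
        feats_qc = feats.subset_cells(kept)
        cells_qc = cells.iloc[kept].reset_index(drop=True)
        _save_table("qc_report.tsv", qc_report.reasons)
        manifest["stages"]["qc_filter"] = {
            "n_input": qc_report.n_input,
            "n_kept": qc_report.n_kept,
            "n_excluded_lowq": qc_report.n_excluded_lowq,
        }

    # ---- normalize -------------------------------------------------------
    with _stage("normalize"):
        norm = preprocess.normalize_log(genes_qc, config.target_sum)

    # ---- gates -----------------------------------------------------------
    with _stage("gates"):
        gates: dict[str, gating.GateSpec] = {}
        for channel in preprocess.HEAVY_CHANNELS + preprocess.LIGHT_CHANNELS:
            vals = norm.channel_values(channel)
            gates[channel] = gating.find_bimodal_gate(
                vals, channel=channel,
                fallback_quantile=config.fallback_gate_quantile,
            )
        gates_path = out_dir / "gates.yaml"
        gates_path.write_text(
            yaml.safe_dump({c: g.to_dict() for c, g in gates.items()},
                           sort_keys=True)
        )
        manifest["outputs"]["gates.yaml"] = _hash_file(gates_path)

    # ---- chain exclusivity ----------------------------------------------
    with _stage("chain_exclusivity"):
        kept_idx, chain_report = preprocess.chain_exclusivity_filter(norm, gates)
        excluded_mask = np.ones(norm.n_cells, dtype=bool)
        excluded_mask[kept_idx] = False
        _save_table("chain_report.tsv", chain_report.reasons)
        manifest["stages"]["chain_exclusivity"] = {
            "n_input": chain_report.n_input,
            "n_kept": chain_report.n_kept,
            "n_excluded_multichain": chain_report.n_excluded_multichain,
        }

    # ---- isotype assignment ---------------------------------------------
    with _stage("isotype"):
        iso = gating.assign_isotypes(norm, gates, genes_qc, excluded_mask)
        cells_qc = cells_qc.assign(
            isotype_call=iso["isotype_call"].to_numpy(),
            subclass_call=iso["subclass_call"].to_numpy(),
        )
        manifest["stages"]["isotype"] = (
            iso["isotype_call"].value_counts().to_dict()
        )

    # ---- secretion thresholds & classes ----------------------------------
    with _stage("secretion"):
        sec_counts = feats_qc.feature_vector(config.sec_feature)
        sec_values = secretion.transform_barcode(sec_counts)
        null_mask = cells_qc["isotype_call"].isin(["IGHM_pos", "IGHA_pos"])
        thresholds = secretion.compute_sec_thresholds(
            sec_values[null_mask.to_numpy()],
            quantile=config.quantile,
            min_null_cells=config.min_null_cells,
        )
        cells_qc["sec_value"] = sec_values
        cells_qc["sec_class"] = secretion.classify_secretion(sec_values, thresholds)
        thr_path = out_dir / "thresholds.yaml"
        thr_path.write_text(yaml.safe_dump(thresholds.to_dict(), sort_keys=True))
        manifest["outputs"]["thresholds.yaml"] = _hash_file(thr_path)
        manifest["stages"]["secretion"] = {
            "null_n": thresholds.null_n,
            "t_hi": thresholds.t_hi,
            "t_lo": thresholds.t_lo,
        }

    # ---- composition tables ----------------------------------------------
    with _stage("composition"):
        compositions: dict[str, pd.DataFrame] = {}
        for key in ("isotype_call", "subclass_call", "donor", "cluster"):
            if key in cells_qc.columns:
                comp = secretion.group_secretion_composition(cells_qc, key)
                compositions[key] = comp
                _save_table(f"composition_{key}.tsv", comp)

    # ---- pseudotime profile ----------------------------------------------
    with _stage("pseudotime_profile"):
        profile = None
        if "pseudotime" in cells_qc.columns and cells_qc["pseudotime"].notna().any():
            profile = secretion.pseudotime_secretor_profile(
                cells_qc, bin_width=config.bin_width,
                min_bin_cells=config.min_bin_cells,
            )
            _save_table("pseudotime_profile.tsv", profile)

    # ---- correlation & consensus markers ---------------------------------
    with _stage("markers"):
        correlation = None
        donors = sorted(cells_qc["donor"].unique())
        analysis_mask = ~excluded_mask
        tables = {}
        for donor in donors:
            subset = np.flatnonzero(
                analysis_mask & (cells_qc["donor"] == donor).to_numpy()
            )
            if subset.size >= 3:
                tables[donor] = association.gene_secretion_correlation(
                    norm, sec_values, cell_subset=subset
                )
        if tables:
            correlation = association.consensus_markers(
                tables, r_min=config.r_min, top_k=config.top_k
            )
            _save_table("consensus_markers.tsv", correlation)

    # ---- differential expression -----------------------------------------
    with _stage("de"):
        de = None
        igg = (cells_qc["isotype_call"] == "IgG").to_numpy()
        hi = np.flatnonzero(igg & (cells_qc["sec_class"] == "sec_hi").to_numpy())
        lo = np.flatnonzero(igg & (cells_qc["sec_class"] == "sec_lo").to_numpy())
        if hi.size >= 3 and lo.size >= 3:
            de = association.rank_sum_de(norm, hi, lo, fdr_alpha=config.fdr_alpha)
            _save_table("de_results.tsv", de)
        manifest["stages"]["de"] = {"n_hi": int(hi.size), "n_lo": int(lo.size)}

    # ---- outputs ----------------------------------------------------------
    with _stage("write"):
        _save_table("cells_annotated.tsv", cells_qc)
        result = RunResult(
            cells=cells_qc,
            thresholds=thresholds,
            gates=gates,
            correlation=correlation,
            de=de,
            compositions=compositions,
            pseudotime_profile=profile,
            manifest=manifest,
            out_dir=out_dir,
        )
        text = report(result, top_k=config.top_k)
        (out_dir / "report.md").write_text(text)
        manifest["outputs"]["report.md"] = _hash_file(out_dir / "report.md")
        _make_figures(result)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        # cell-count conservation check across stages
        qc_s = manifest["stages"]["qc_filter"]
        assert qc_s["n_input"] == qc_s["n_kept"] + qc_s["n_excluded_lowq"]
        _write_manifest()
    return result


def _make_figures(result: RunResult) -> None:
    """Diagnostic figures: SEC histogram with cutoffs, pseudotime profile."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = result.cells
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for iso, color in (("IGHM_pos", "tab:blue"), ("IGHA_pos", "tab:cyan"),
                       ("IgG", "tab:red")):
        vals = cells.loc[cells["isotype_call"] == iso, "sec_value"]
        if len(vals):
            ax.hist(vals, bins=40, alpha=0.5, label=iso, color=color)
    if result.thresholds is not None:
        ax.axvline(result.thresholds.t_hi, ls="--", c="k")
        ax.axvline(result.thresholds.t_lo, ls="--", c="gray")
    ax.set_xlabel("log10(1 + secretion barcode)")
    ax.set_ylabel("cells")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(result.out_dir / "sec_histogram.png", dpi=110)
    plt.close(fig)

    if result.pseudotime_profile is not None:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for donor, sub in result.pseudotime_profile.groupby("group"):
            ok = sub["frac_hi"].notna()
            ax.plot(sub.loc[ok, "bin_mid"], 100 * sub.loc[ok, "frac_hi"],
                    marker="o", label=str(donor))
        ax.set_xlabel("pseudotime")
        ax.set_ylabel("% SEC-hi")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(result.out_dir / "pseudotime_profile.png", dpi=110)
        plt.close(fig)


def report(result: RunResult, top_k: int = 40) -> str:
    """Human-readable markdown summary of a run."""
    lines = ["# SEC-seq run report", ""]
    thr = result.thresholds
    if thr is not None:
        lines += [
            "## Secretion thresholds (log10(1+count) scale)",
            "",
            f"- SEC-hi cutoff (t_hi): {thr.t_hi:.4f} "
            f"(nearest-rank {thr.quantile:.0%} quantile of the IGHM/A null)",
            f"- SEC-lo cutoff (t_lo): {thr.t_lo:.4f} "
            "(null mean minus the t_hi excess)",
            f"- null mean {thr.null_mean:.4f} over {thr.null_n} IGHM/A+ cells",
            "",
        ]
    lines += ["## Gates", ""]
    for channel, gate in sorted(result.gates.items()):
        lines.append(
            f"- {channel}: threshold {gate.threshold:.4f} ({gate.method})"
        )
    lines.append("")

    n_igg = int((result.cells["isotype_call"] == "IgG").sum())
    if n_igg == 0:
        lines += [
            "## SEC classes",
            "",
            "No IgG cells in this cohort: SEC-hi/lo composition and "
            "differential expression for the IgG subset are not computable.",
            "",
        ]
    for key, comp in result.compositions.items():
        lines += [f"## SEC class composition by {key}", "",
                  comp.to_string(index=False,
                                 float_format=lambda v: f"{v:.2f}"), ""]

    lines += ["## Consensus surrogate markers", ""]
    if result.correlation is None:
        lines.append("Not computed (no donor had enough cells).")
    else:
        hits = result.correlation[result.correlation["consensus"]]
        shown = hits.head(top_k)
        lines.append(
            f"{len(hits)} genes pass the consensus criterion; showing top "
            f"{len(shown)} by mean r."
        )
        lines += ["", shown.to_string(index=False,
                                      float_format=lambda v: f"{v:.3f}"), ""]

    lines += ["## Differential expression (SEC-hi vs SEC-lo, IgG cells)", ""]
    if result.de is None:
        lines.append("Not computed (SEC-hi or SEC-lo group below 3 cells).")
    else:
        lines += [result.de.head(15).to_string(
            index=False, float_format=lambda v: f"{v:.3g}"), ""]

    lines += ["## Pseudotime secretor profile", ""]
    if result.pseudotime_profile is None:
        lines.append("Pseudotime not provided.")
    else:
        shown = result.pseudotime_profile[result.pseudotime_profile["n"] > 0]
        lines += [shown.to_string(index=False,
                                  float_format=lambda v: f"{v:.3f}"), ""]
    return "\n".join(lines) + "\n"
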