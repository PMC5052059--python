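"""End-to-end pipeline: I/O or simulation -> XCI state -> allelic patterns
-> association analyses, driven by a single YAML-able config with all
thresholds surfaced and seeded reproducibility. Every stage writes TSVs
plus a machine-readable run manifest."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as xio
from . import allelic, association, state as xstate
from .simulate import SimConfig, ConditionSpec, generate_dataset, preset_paper_conditions

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("xcipipe")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # input: either a directory with the five-TSV layout, or a simulate block
    input_dir: str | None = None
    simulate: dict | None = None
    simulate_preset: bool = False
    out_dir: str = "xci_out"
    seed: int = 0
    # stage toggles
    run_qc: bool = False
    run_state: bool = True
    run_allelic: bool = True
    run_association: bool = True
    # thresholds (study defaults)
    completed_upper: float = 1.2
    ongoing_upper: float = 1.8
    window_genes: int = 10
    min_informative_reads: int = 50
    min_allele_reads: int = 2
    tau_set: tuple[float, ...] = (5.0, 10.0, 20.0)
    escapee_min_ratio: float = 0.1
    escapee_min_cell_fraction: float = 0.25
    fc_cut: float = 4.0
    alpha: float = 0.01
    min_genes_detected: int = 2000
    qc_marker_genes: tuple[str, ...] | None = None
    qc_marker_conditions: tuple[str, ...] | None = None
    xist_min_rpkm: float = 1.0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 1.0 < self.completed_upper < self.ongoing_upper < 2.0:
            raise ValueError(
                "XCI group bounds must satisfy 1 < completed_upper < ongoing_upper < 2 "
                f"(got {self.completed_upper}, {self.ongoing_upper})"
            )
        if self.input_dir is None and self.simulate is None and not self.simulate_preset:
            raise ValueError("config needs input_dir, a simulate block, or simulate_preset")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("tau_set", "qc_marker_genes", "qc_marker_conditions"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _build_sim_config(config: PipelineConfig) -> SimConfig:
    if config.simulate_preset:
        overrides = dict(config.simulate or {})
        overrides.setdefault("seed", config.seed)
        n = overrides.pop("n_cells_per_condition", 50)
        return preset_paper_conditions(n_cells_per_condition=n, **overrides)
    block = dict(config.simulate or {})
    block.setdefault("seed", config.seed)
    conds = [ConditionSpec(**c) if isinstance(c, dict) else c
             for c in block.pop("conditions", [])]
    return SimConfig(conditions=conds, **block)


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                manifest["stages"].append(dict(stage=name, status="failed",
                                               seconds=round(dt, 3), error=str(exc)))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(dict(stage=name, status="ok", seconds=round(dt, 3)))
            log.info("stage %s: done in %.2fs", name, dt)
            return False
    return _Timer()


def _write(df: pd.DataFrame, path: Path, index: bool = False, index_label=None):
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {k: v for k, v in asdict(config).items()
                       if k not in ("input_dir", "simulate", "out_dir")},
        "stages": [],
        "counts": {},
    }

    with _stage(manifest, "load"):
        if config.input_dir is not None:
            acs = xio.read_allelic_counts_dir(config.input_dir)
            truth = None
        else:
            sim = _build_sim_config(config)
            acs, truth = generate_dataset(sim)
            xio.write_allelic_counts(acs, out / "input")
            truth.write(out / "truth.tsv")
        expr = xio.rpkm_for(acs)
        manifest["counts"]["load"] = dict(n_genes=int(len(acs.gene_ids)),
                                          n_cells=int(len(acs.cell_ids)))

    if config.run_qc:
        with _stage(manifest, "qc"):
            acs = xio.qc_filter_cells(
                acs, expr, min_genes_detected=config.min_genes_detected,
                marker_genes=config.qc_marker_genes,
                marker_conditions=config.qc_marker_conditions,
            )
            n_fail = int((~acs.cells["qc_pass"].astype(bool)).sum())
            acs = acs.passing_cells()
            expr = expr[acs.cell_ids]
            manifest["counts"]["qc"] = dict(n_cells=int(len(acs.cell_ids)),
                                            n_failed=n_fail)
    else:
        manifest["counts"]["qc"] = dict(n_cells=int(len(acs.cell_ids)), n_failed=0)

    bounds = (config.completed_upper, config.ongoing_upper)
    state_res = None
    if config.run_state:
        with _stage(manifest, "state"):
            state_res = xstate.xci_state_table(
                acs, min_informative_reads=config.min_informative_reads, bounds=bounds
            )
            _write(state_res.cells, out / "xci_state.tsv", index=True,
                   index_label="cell_id")
            _write(state_res.condition_summary, out / "condition_summary.tsv")
            _write(state_res.skew_tests, out / "skew_tests.tsv")
            for group in ("uninitiated", "ongoing", "completed"):
                cells = state_res.cells.index[state_res.cells["xci_group"] == group]
                if len(cells) == 0:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    prof = xstate.window_ratio_profile(
                        acs, state_res, cells, window_genes=config.window_genes
                    )
                _write(prof, out / f"window_profile_{group}.tsv")
            n_completed = int((state_res.cells["xci_group"] == "completed").sum())
            if n_completed:
                esc = xstate.detect_escapees(
                    acs, state_res, min_ratio=config.escapee_min_ratio,
                    min_cell_fraction=config.escapee_min_cell_fraction,
                )
                _write(esc, out / "escapees.tsv", index=True, index_label="gene_id")
            manifest["counts"]["state"] = dict(
                n_female=int(len(state_res.cells)),
                n_insufficient=int((state_res.cells["xci_group"] == "insufficient").sum()),
                n_completed=n_completed,
            )
            if config.make_plots:
                _plot_profiles(out)

    if config.run_allelic:
        with _stage(manifest, "allelic"):
            calls = allelic.build_call_matrix(acs, config.min_allele_reads)
            long = calls.stack().rename("call").reset_index()
            long.columns = ["gene_id", "cell_id", "call"]
            _write(long[long["call"] != "undetected"], out / "allelic_calls.tsv")
            conditions = acs.cells.loc[acs.cell_ids, "condition"]
            names = acs.gene_names()
            profile_genes = [g for g in names.index
                             if names[g] in association.PLURIPOTENCY_SCORE_GENES]
            summary = allelic.allelic_profile_report(
                calls, expr, conditions, gene_ids=profile_genes,
                tau_set=config.tau_set,
            )
            _write(summary, out / "allelic_summary.tsv")
            auto = acs.autosomal_genes()
            bi_mono = allelic.biallelic_vs_mono_expression_test(
                calls, expr, conditions, gene_ids=auto, tau=max(config.tau_set)
            )
            _write(bi_mono, out / "biallelic_vs_mono.tsv")
            manifest["counts"]["allelic"] = dict(
                n_calls=int((calls.to_numpy() != "undetected").sum()),
                n_bi_mono_tests=int(len(bi_mono)),
            )

    if config.run_association and state_res is not None:
        with _stage(manifest, "association"):
            names = acs.gene_names()
            score = association.pluripotency_score(expr, gene_names=names)
            female = state_res.cells.index
            score_table = pd.DataFrame({"pluripotency_score": score})
            _write(score_table, out / "pluripotency_score.tsv", index=True,
                   index_label="cell_id")
            module_names = list(association.PLURIPOTENCY_SCORE_GENES)
            module_ids = [g for g in names.index if names[g] in module_names]
            corr = association.correlate_with_activity(expr, state_res,
                                                       gene_ids=module_ids)
            corr["gene_name"] = corr["gene_id"].map(names)
            _write(corr, out / "correlations.tsv")
            group_rows = []
            try:
                res = association.group_expression_test(
                    score.loc[female], state_res.cells["xci_group"]
                )
                group_rows.append(dict(scope="all_female", **res))
            except ValueError as exc:
                log.warning("group test skipped: %s", exc)
            for cond, cdf in state_res.cells.groupby("condition", sort=False):
                try:
                    res = association.group_expression_test(
                        score.loc[cdf.index], cdf["xci_group"]
                    )
                    group_rows.append(dict(scope=cond, **res))
                except ValueError:
                    continue
            _write(pd.DataFrame(group_rows), out / "group_tests.tsv")
            markers = association.marker_enrichment(
                expr, acs.cells.loc[acs.cell_ids, "condition"],
                fc_cut=config.fc_cut, alpha=config.alpha,
            )
            markers["gene_name"] = markers["gene_id"].map(names)
            _write(markers[markers["enriched_condition"].notna()],
                   out / "markers.tsv")
            try:
                xist = association.xist_tsix_report(
                    expr, state_res, acs.cells.loc[acs.cell_ids],
                    gene_names=names, min_xist_rpkm=config.xist_min_rpkm,
                )
                _write(xist, out / "xist_report.tsv")
            except ValueError as exc:
                log.warning("Xist/Tsix report skipped: %s", exc)
            manifest["counts"]["association"] = dict(
                n_correlations=int(len(corr)), n_group_tests=len(group_rows),
                n_markers=int(markers["enriched_condition"].notna().sum()),
            )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _plot_profiles(out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    colors = {"uninitiated": "tab:red", "ongoing": "tab:green", "completed": "tab:purple"}
    for group, color in colors.items():
        path = out / f"window_profile_{group}.tsv"
        if not path.exists():
            continue
        prof = pd.read_csv(path, sep="\t")
        ax.plot(prof["midpoint_bp"] / 1e6, prof["ratio"], color=color, label=group)
    ax.set_xlabel("X position (Mb)")
    ax.set_ylabel("inactive / active X expression ratio")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "window_profiles.png", dpi=150)
    plt.close(fig)
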