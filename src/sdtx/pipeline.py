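"""End-to-end orchestration: ingest (or simulate) -> quantile-normalize ->
per-gene contrasts M1-M3 -> baseline models -> circadian-panel screen +
Monte-Carlo test -> preranked GSEA -> time-course gene-set analysis ->
summary report.

Every stage writes a TSV under the output directory, all dropped entities
(missing panel genes, non-converged sets) are recorded machine-readably, a
run manifest captures the seed, package version and config hash, and the
whole run is deterministic given the seed.  A stage failure halts the run,
leaving partial outputs plus a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__

from .deg import (
    ContrastSpec,
    baseline_differences,
    results_frame,
    run_transcriptome,
    summarize_counts,
)
from .enrichment import (
    enrichment_frame,
    gsea_preranked,
    make_ranked_list,
    montecarlo_set_test,
    screen_panel,
)
from .io import load_circadian_panel, read_expression, read_gmt, read_panel
from .plots import render_trend_heatmap
from .tcgsa import run_tcgsa_collection, trajectory_frame

log = logging.getLogger("sdtx.pipeline")

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run (YAML-serializable)."""

    expr_path: str
    meta_path: str
    gmt_path: str
    outdir: str
    panel_path: str | None = None  # None = packaged circadian panel
    fdr_alpha: float = 0.05
    alpha_unc: float = 0.05
    n_perm: int = 1000
    b_draws: int = 10000
    seed: int = 0
    gsea_weight: float = 1.0
    tcgsa_reference: str = "mixture"
    tcgsa_cohorts: tuple[str, ...] = (
        "patients",
        "controls",
        "responders",
        "non_responders",
    )
    exclude_gene_sets: tuple[str, ...] = ("HALLMARK_HEME_METABOLISM",)
    exclude_from_heatmap: tuple[str, ...] = ()
    normalize: bool = True

    def __post_init__(self) -> None:
        for name in ("fdr_alpha", "alpha_unc"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("expr_path", "meta_path", "gmt_path"):
            if not Path(getattr(self, name)).exists():
                raise FileNotFoundError(f"{name}: {getattr(self, name)} not found")
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise FileNotFoundError(f"panel_path: {self.panel_path} not found")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("tcgsa_cohorts", "exclude_gene_sets", "exclude_from_heatmap"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a manifest dict (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": asdict(config),
        "stages": {},
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        study = read_expression(config.expr_path, config.meta_path)
        collection = read_gmt(config.gmt_path).exclude(config.exclude_gene_sets)
        panel = (
            read_panel(config.panel_path)
            if config.panel_path
            else load_circadian_panel()
        )
        _stage_done(manifest, "load", t0, rows=study.n_samples)

        if config.normalize:
            stage = "normalize"
            t0 = time.perf_counter()
            from .normalize import quantile_normalize

            study = quantile_normalize(study)
            _stage_done(manifest, "normalize", t0, rows=study.n_samples)

        stage = "fit"
        t0 = time.perf_counter()
        results_by_contrast = {}
        for name in ("M1", "M2", "M3"):
            res = run_transcriptome(study, ContrastSpec(name))
            results_by_contrast[name] = res
            _write(results_frame(res), outdir / f"deg_{name}.tsv")
        _stage_done(manifest, "fit", t0, rows=sum(map(len, results_by_contrast.values())))

        stage = "baseline"
        t0 = time.perf_counter()
        for comparison in ("response", "case"):
            base = baseline_differences(study, comparison)
            _write(results_frame(base), outdir / f"baseline_{comparison}.tsv")
        _stage_done(manifest, "baseline", t0)

        stage = "panel"
        t0 = time.perf_counter()
        mc_rows = []
        for name, res in results_by_contrast.items():
            table, missing = screen_panel(res, panel, alpha=config.fdr_alpha)
            table.insert(0, "contrast", name)
            _write(table, outdir / f"panel_{name}.tsv")
            if missing:
                log.warning("panel genes missing from %s results: %s", name, missing)
            mc = montecarlo_set_test(
                res,
                panel,
                b_draws=config.b_draws,
                alpha_unc=config.alpha_unc,
                seed=config.seed,
            )
            mc_rows.append(
                {
                    "contrast": name,
                    "panel_size": mc.panel_size,
                    "observed": mc.observed,
                    "b_draws": mc.b_draws,
                    "p_emp": mc.p_emp,
                    "analytic_p": mc.analytic_p,
                    "n_missing": len(mc.missing),
                }
            )
        _write(pd.DataFrame(mc_rows), outdir / "panel_montecarlo.tsv")
        _stage_done(manifest, "panel", t0)

        stage = "gsea"
        t0 = time.perf_counter()
        for name, res in results_by_contrast.items():
            ranked = make_ranked_list(res)
            enr = gsea_preranked(
                ranked,
                collection,
                n_perm=config.n_perm,
                weight=config.gsea_weight,
                seed=config.seed,
            )
            _write(enrichment_frame(enr), outdir / f"gsea_{name}.tsv")
        _stage_done(manifest, "gsea", t0)

        stage = "tcgsa"
        t0 = time.perf_counter()
        tc = run_tcgsa_collection(
            study,
            collection,
            cohorts=list(config.tcgsa_cohorts),
            reference=config.tcgsa_reference,
            alpha=config.fdr_alpha,
            seed=config.seed,
        )
        for cohort, res in tc.items():
            _write(trajectory_frame(res), outdir / f"tcgsa_{cohort}.tsv")
            render_trend_heatmap(
                res,
                outdir / f"tcgsa_{cohort}.png",
                alpha=config.fdr_alpha,
                exclude_sets=list(config.exclude_from_heatmap),
                title=cohort,
            )
        _stage_done(manifest, "tcgsa", t0)

        stage = "report"
        t0 = time.perf_counter()
        summary = summarize_counts(results_by_contrast, alpha=config.fdr_alpha)
        assert (summary["n_up"] + summary["n_down"]).equals(summary["n_sig"])
        tc_summary = pd.DataFrame(
            {
                "cohort": list(tc),
                "n_sets": [len(r) for r in tc.values()],
                "n_converged": [sum(x.converged for x in r) for r in tc.values()],
                "n_significant": [
                    sum(
                        x.converged and np.isfinite(x.q) and x.q < config.fdr_alpha
                        for x in r
                    )
                    for r in tc.values()
                ],
            }
        )
        _write(summary, outdir / "summary_counts.tsv")
        _write(tc_summary, outdir / "summary_tcgsa.tsv")
        _stage_done(manifest, "report", t0)
    except Exception as exc:
        failed_marker.write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(_stable(manifest), indent=2, sort_keys=True))
    return manifest


def _stage_done(manifest: dict, stage: str, t0: float, rows: int | None = None) -> None:
    elapsed = time.perf_counter() - t0
    log.info("stage %-10s done in %.2fs%s", stage, elapsed,
             f" ({rows} rows)" if rows is not None else "")
    manifest["stages"][stage] = {"rows": rows}


def _stable(manifest: dict) -> dict:
    """Manifest without wall-clock content so identical runs hash identically."""
    return manifest
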