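"""End-to-end analysis pipeline: traits -> isotopes -> statistics -> report.

Given a root-observation table and a tissue-sample table (e.g. from
:mod:`rhizotrace.simulate` or from file), the pipeline

1. computes per-row deep-rooting traits (DeepRoot40, sigmoid inflection,
   interval root lengths) for the configured imaging session of each year;
2. computes excess-15N and percent tracer recovery per row and the log
   transforms ln(delta15N) and ln(delta2H + 90);
3. applies the replication filter, estimates genotype means of DeepRoot40
   with design covariates, and computes cultivar-mean Pearson correlations of
   DeepRoot40 with ln delta15N, ln(delta2H + 90) and delta13C within each
   year, plus year-by-year correlation matrices;
4. writes tidy CSV outputs and a human-readable text report.

Any stage failure is re-raised as :class:`PipelineError` naming the stage.
Results are deterministic functions of the inputs and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import root_traits, stats
from .io import RunConfig, read_observations, read_tissue, write_csv
from .isotopes import facility_recovery, tissue_excess_table, transform_for_model
from .root_traits import interval_column

__all__ = ["PipelineError", "PipelineResult", "run_pipeline", "run_pipeline_files"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineResult:
    traits: pd.DataFrame
    isotope_results: pd.DataFrame
    genotype_means: pd.DataFrame
    correlations: pd.DataFrame
    year_matrices: pd.DataFrame
    report_text: str


def _year_of(traits: pd.DataFrame) -> pd.Series:
    if "year" in traits.columns:
        return traits["year"]
    return traits["session"].astype(str).str.slice(0, 4).astype(int)


def run_pipeline(
    observations: pd.DataFrame,
    tissue: pd.DataFrame,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory tables; optionally write outputs."""
    cfg = config or RunConfig()
    ana = cfg.analysis

    # ---- stage: traits ----------------------------------------------------
    try:
        month = f"-{ana.session_month:02d}"
        obs = observations[observations["session"].astype(str).str.endswith(month)]
        if obs.shape[0] == 0:
            obs = observations  # no session matches the configured month: use all
        traits = root_traits.traits_table(
            obs,
            cfg.geometry,
            intervals=ana.intervals,
            target_cm=ana.deeproot_target_cm,
            fit_sigmoid=ana.fit_sigmoid,
        )
        traits["year"] = _year_of(traits)
    except Exception as exc:  # noqa: BLE001 - stage contract
        raise PipelineError("traits", exc) from exc

    # ---- stage: isotopes --------------------------------------------------
    try:
        iso = tissue_excess_table(tissue, cfg.constants)
        recov = facility_recovery(tissue, cfg.dose, cfg.constants)
        grain = iso[iso["tissue"] == "grain"].copy()
        grain["ln_delta15n"] = transform_for_model(grain["delta15N"], "15N")
        grain["ln_delta2h_p90"] = transform_for_model(grain["delta2H"], "2H")
        iso_results = grain.merge(recov, on="row_id", how="left")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("isotopes", exc) from exc

    # ---- stage: stats -----------------------------------------------------
    try:
        merged = traits.merge(
            iso_results[
                ["row_id", "ln_delta15n", "ln_delta2h_p90", "delta13C", "recovery_pct_total"]
            ],
            on="row_id",
            how="left",
        )
        filtered, kept = stats.replication_filter(merged, min_reps=ana.min_reps, scope="per-year")

        means = stats.estimate_genotype_means(
            _core_subset(filtered, ana.min_reps), "deep_root40_cm", alpha=ana.alpha
        )

        corr_rows = []
        deep_iv = interval_column(*ana.intervals[-1]) if ana.intervals else None
        pairs = [
            ("deep_root40_cm", "ln_delta15n"),
            ("deep_root40_cm", "ln_delta2h_p90"),
            ("deep_root40_cm", "delta13C"),
        ]
        if ana.fit_sigmoid:
            pairs.append(("si_cm", "ln_delta15n"))
        by_year_means: dict[int, pd.Series] = {}
        for year, sub in filtered.groupby("year"):
            cmeans = sub.groupby("genotype").mean(numeric_only=True)
            by_year_means[int(year)] = cmeans["deep_root40_cm"]
            for xv, yv in pairs:
                try:
                    res = stats.cultivar_mean_correlation(cmeans[xv], cmeans[yv], xv, yv)
                    corr_rows.append(
                        {
                            "year": year,
                            "var_x": xv,
                            "var_y": yv,
                            "r": res.r,
                            "p": res.p,
                            "n": res.n,
                            "flag": res.flag,
                        }
                    )
                except stats.StatsError as err:
                    log.warning("correlation %s x %s in %s skipped: %s", xv, yv, year, err)
        correlations = pd.DataFrame(corr_rows)
        if len(by_year_means) >= 2:
            year_matrices = stats.correlation_matrix(by_year_means)
            year_matrices.insert(0, "variable", "deep_root40_cm")
        else:
            year_matrices = pd.DataFrame(
                columns=["variable", "year_x", "year_y", "r", "p", "n", "flag"]
            )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stats", exc) from exc

    report = _render_report(means, correlations, year_matrices, kept)
    result = PipelineResult(traits, iso_results, means, correlations, year_matrices, report)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _core_subset(filtered: pd.DataFrame, min_reps: int) -> pd.DataFrame:
    """Genotypes replicated in every year, for the genotype-mean model."""
    try:
        core, _ = stats.replication_filter(filtered, min_reps=min_reps, scope="all-years")
        if core["genotype"].nunique() >= 2:
            return core
    except stats.StatsError:
        pass
    return filtered


def _render_report(means, correlations, year_matrices, kept) -> str:
    lines = ["rhizotrace run report", "=====================", ""]
    lines.append(f"genotypes passing replication filter: {len(kept)}")
    lines.append("")
    lines.append("Genotype means, DeepRoot40 (cm)")
    lines.append(means.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    lines.append("")
    lines.append("Cultivar-mean correlations within year")
    if correlations.shape[0]:
        lines.append(correlations.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    else:
        lines.append("(none)")
    lines.append("")
    lines.append("Year x year correlations of DeepRoot40 cultivar means")
    if year_matrices.shape[0]:
        lines.append(year_matrices.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    else:
        lines.append("(single year)")
    lines.append("")
    lines.append(
        "model note: genotype means from OLS with genotype + year + bed + "
        "quadratic along-bed position (simplified surrogate for a "
        "spatial-correlation GLS)"
    )
    return "\n".join(lines) + "\n"


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_csv(result.traits, outdir / "traits.csv")
    write_csv(result.isotope_results, outdir / "isotope_results.csv")
    write_csv(result.genotype_means, outdir / "genotype_means.csv")
    write_csv(result.correlations, outdir / "correlations.csv")
    write_csv(result.year_matrices, outdir / "year_correlations.csv")
    (outdir / "report.txt").write_text(result.report_text)


def run_pipeline_files(
    roots_path: str | Path,
    tissue_path: str | Path,
    outdir: str | Path,
    config: RunConfig | None = None,
) -> PipelineResult:
    """File-based entry point: read, validate, analyse, write."""
    cfg = config or RunConfig()
    try:
        observations = read_observations(roots_path, px_per_cm=cfg.geometry.px_per_cm)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("read-observations", exc) from exc
    try:
        tissue = read_tissue(tissue_path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("isotopes", exc) from exc
    return run_pipeline(observations, tissue, cfg, outdir=outdir)
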