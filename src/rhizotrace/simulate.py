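"""Synthetic semi-field trial generator.

Emulates the structure of a multi-year minirhizotron + isotope-tracer trial so
that every pipeline stage is testable without field data:

* **Design.**  A core set of genotypes replicated ten times per year plus a
  larger set replicated four times (default 9 x 10 + 39 x 4 = 246 crop rows
  per year), randomised over two beds with an along-bed position index.
* **Root profiles.**  Expected root length per image follows a decreasing
  logistic in depth, ``A / (1 + exp(k (d - m)))``, with a genotype midpoint
  shift ``b_g ~ N(0, sigma_b)`` shared across years (plus year-specific
  perturbations), a row-level shift, and a smooth along-bed spatial trend.
  Observed lengths multiply the expectation by LogNormal(0, sigma_obs) noise
  and add a half-normal detection-noise floor that dominates where roots are
  sparse (deep images), mimicking spurious/missed detections.
* **Isotope coupling.**  Grain/straw delta15N and grain delta2H increase
  linearly with the genotype's expected root length in the tracer-injection
  interval (1.6-1.8 m); delta13C *decreases* with expected DeepRoot40, with a
  year-severity multiplier so the water-stress coupling strengthens in a dry
  year.  Per-row tracer uptake fractions are back-computed from the drawn
  delta15N values and recorded in the ground-truth table, so aggregate
  recovery computed downstream must conserve the planted total.

Everything is reproducible bit-for-bit from ``(config, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TubeGeometry
from .isotopes import TracerDose
from .root_traits import RootProfile, deep_root_threshold

__all__ = ["SimulationConfig", "SimulatedTrial", "simulate_trial", "write_trial", "planted_effect_check"]

_VERSION = "0.1.0"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic trial; defaults define the study conditions.

    Depth/length units: cm for the profile model, m for depth intervals,
    per-mil for isotope values, g for masses.
    """

    # design
    n_core_genotypes: int = 9
    core_reps: int = 10
    n_extra_genotypes: int = 39
    extra_reps: int = 4
    n_beds: int = 2
    years: tuple[int, ...] = (2021, 2022, 2023)
    geometry: TubeGeometry = field(default_factory=TubeGeometry)
    dose: TracerDose = field(default_factory=TracerDose)

    # logistic root-profile model (cm)
    surface_length_cm: float = 2.0          # A: per-image length in dense shallow soil
    midpoint_depth_cm: float = 120.0        # m0: depth of the shallow->sparse transition
    steepness_per_cm: float = 0.05          # k
    genotype_shift_sd_cm: float = 10.0      # sigma_b: genotype midpoint SD
    genotype_shifts: tuple[float, ...] | None = None  # explicit b_g, overrides sigma_b
    year_shift_sd_cm: float = 4.0           # genotype x year perturbation SD
    year_midpoint_offset_cm: dict = field(
        default_factory=lambda: {2021: 5.0, 2022: -17.0, 2023: 0.0}
    )
    row_shift_sd_cm: float = 6.0            # row-level midpoint SD
    spatial_trend_cm: float = 3.0           # linear along-bed midpoint gradient (+-)
    obs_lognormal_sd: float = 0.3           # multiplicative observation noise (CV ~ 0.3)
    detection_noise_cm: float = 0.02        # additive half-normal per-image noise floor

    # isotope coupling (per mil); L = expected root length (cm) in deep_interval
    deep_interval_m: tuple[float, float] = (1.6, 1.8)
    delta15n_grain_intercept: float = 20.0
    delta15n_grain_slope: float = 3.0
    delta15n_grain_sd: float = 4.0
    delta15n_straw_intercept: float = 8.0
    delta15n_straw_slope: float = 2.0
    delta15n_straw_sd: float = 3.0
    delta2h_intercept: float = -60.0
    delta2h_slope: float = 4.0
    delta2h_sd: float = 6.0
    delta13c_year_intercept: dict = field(
        default_factory=lambda: {2021: -25.0, 2022: -24.3, 2023: -23.3}
    )
    delta13c_slope_per_cm: float = 0.012    # beta3: per cm of expected DeepRoot40
    delta13c_sd: float = 0.3
    delta13c_straw_offset: float = -2.0
    year_severity: dict = field(
        default_factory=lambda: {2021: 1.0, 2022: 0.6, 2023: 1.8}
    )

    # tissue masses (whole-row dry matter) and N content
    grain_mass_mean_g: float = 1400.0
    grain_mass_sd_g: float = 150.0
    grain_n_pct_mean: float = 2.2
    grain_n_pct_sd: float = 0.15
    straw_mass_mean_g: float = 1800.0
    straw_mass_sd_g: float = 250.0
    straw_n_pct_mean: float = 0.5
    straw_n_pct_sd: float = 0.05
    straw_rows_per_year: int = 60

    @property
    def n_genotypes(self) -> int:
        return self.n_core_genotypes + self.n_extra_genotypes

    @property
    def rows_per_year(self) -> int:
        return self.n_core_genotypes * self.core_reps + self.n_extra_genotypes * self.extra_reps

    def genotype_labels(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.n_genotypes)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["dose"] = dataclasses.asdict(self.dose)
        return d


@dataclass(frozen=True)
class SimulatedTrial:
    roots: pd.DataFrame
    tissue: pd.DataFrame
    truth_genotypes: pd.DataFrame
    truth_rows: pd.DataFrame
    provenance: dict


def _expected_profile(depths_cm: np.ndarray, A: float, k: float, m) -> np.ndarray:
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))[:, None]
    return A / (1.0 + np.exp(np.clip(k * (depths_cm[None, :] - m_arr), -500.0, 500.0)))


def simulate_trial(config: SimulationConfig, seed: int) -> SimulatedTrial:
    """Generate one complete synthetic trial (all configured years).

    Returns root observations and tissue samples in the exact input schemas of
    the trait and isotope modules, plus genotype- and row-level ground truth.
    Identical (config, seed) give identical outputs.
    """
    cfg = config
    rng = np.random.default_rng(seed)
    geom = cfg.geometry
    genotypes = cfg.genotype_labels()
    nG = cfg.n_genotypes

    if cfg.genotype_shifts is not None:
        if len(cfg.genotype_shifts) != nG:
            raise ValueError(
                f"genotype_shifts has {len(cfg.genotype_shifts)} entries for {nG} genotypes"
            )
        b_g = np.asarray(cfg.genotype_shifts, dtype=float)
    else:
        b_g = rng.normal(0.0, cfg.genotype_shift_sd_cm, nG)

    depths_m = geom.image_depths_m()
    depths_cm = depths_m * 100.0
    deep_lo, deep_hi = cfg.deep_interval_m
    deep_mask = (depths_m >= deep_lo) & (depths_m < deep_hi)

    reps = np.array(
        [cfg.core_reps] * cfg.n_core_genotypes + [cfg.extra_reps] * cfg.n_extra_genotypes
    )
    geno_idx_year = np.repeat(np.arange(nG), reps)
    n_rows = geno_idx_year.size
    rows_per_bed = int(np.ceil(n_rows / cfg.n_beds))

    # atom-fraction arithmetic kept inline: the generator's bookkeeping must
    # not depend on the module it is used to test
    r_std = 0.0036765
    af0 = r_std / (1.0 + r_std)

    def af(delta):
        r = (np.asarray(delta, float) / 1000.0 + 1.0) * r_std
        return r / (1.0 + r)

    roots_parts, tissue_parts, truth_g_parts, truth_r_parts = [], [], [], []
    for year in cfg.years:
        jitter = rng.normal(0.0, cfg.year_shift_sd_cm, nG)
        year_off = cfg.year_midpoint_offset_cm.get(year, 0.0)
        m_gy = cfg.midpoint_depth_cm + b_g + jitter + year_off

        # genotype-year expectations (noiseless)
        exp_prof = _expected_profile(depths_cm, cfg.surface_length_cm, cfg.steepness_per_cm, m_gy)
        L_gy = exp_prof[:, deep_mask].sum(axis=1)
        dr40_gy = np.array(
            [
                deep_root_threshold(
                    RootProfile(g, str(year), depths_m, exp_prof[i]), target_cm=40.0
                )
                for i, g in enumerate(genotypes)
            ]
        )
        sev = cfg.year_severity.get(year, 1.0)
        c13_int = cfg.delta13c_year_intercept.get(year, -24.5)
        truth_g_parts.append(
            pd.DataFrame(
                {
                    "genotype": genotypes,
                    "year": year,
                    "shift_cm": b_g,
                    "midpoint_cm": m_gy,
                    "expected_deeproot40_cm": dr40_gy,
                    "expected_deep_length_cm": L_gy,
                    "expected_delta15n_grain": cfg.delta15n_grain_intercept
                    + cfg.delta15n_grain_slope * L_gy,
                    "expected_delta2h_grain": cfg.delta2h_intercept + cfg.delta2h_slope * L_gy,
                    "expected_delta13c_grain": c13_int
                    - cfg.delta13c_slope_per_cm * sev * dr40_gy,
                }
            )
        )

        # randomised layout over beds
        order = rng.permutation(n_rows)
        gidx = geno_idx_year[order]
        bed = 1 + np.arange(n_rows) // rows_per_bed
        pos = 1 + np.arange(n_rows) % rows_per_bed
        row_ids = np.array(
            [f"Y{year}-B{b}-R{p:03d}" for b, p in zip(bed, pos)]
        )
        pos_frac = (pos - 1) / max(rows_per_bed - 1, 1)
        m_row = (
            m_gy[gidx]
            + cfg.spatial_trend_cm * (2.0 * pos_frac - 1.0)
            + rng.normal(0.0, cfg.row_shift_sd_cm, n_rows)
        )

        expected = _expected_profile(
            depths_cm, cfg.surface_length_cm, cfg.steepness_per_cm, m_row
        )
        noise = rng.lognormal(0.0, cfg.obs_lognormal_sd, expected.shape) if cfg.obs_lognormal_sd > 0 else 1.0
        floor = (
            np.abs(rng.normal(0.0, cfg.detection_noise_cm, expected.shape))
            if cfg.detection_noise_cm > 0
            else 0.0
        )
        observed = expected * noise + floor

        n_img = depths_m.size
        roots_parts.append(
            pd.DataFrame(
                {
                    "row_id": np.repeat(row_ids, n_img),
                    "genotype": np.repeat(np.array(genotypes)[gidx], n_img),
                    "session": f"{year}-06",
                    "year": year,
                    "bed": np.repeat(bed, n_img),
                    "row_pos": np.repeat(pos, n_img),
                    "position_mm": np.tile(geom.image_positions_mm(), n_rows),
                    "root_length_cm": observed.ravel(),
                }
            )
        )

        # tissue samples: grain for every row, straw for a random subset
        L_row = L_gy[gidx]
        dr40_row = dr40_gy[gidx]
        d15n_grain = np.maximum(
            cfg.delta15n_grain_intercept
            + cfg.delta15n_grain_slope * L_row
            + rng.normal(0.0, cfg.delta15n_grain_sd, n_rows),
            0.5,
        )
        d13c_grain = (
            c13_int
            - cfg.delta13c_slope_per_cm * sev * dr40_row
            + rng.normal(0.0, cfg.delta13c_sd, n_rows)
        )
        d2h_grain = np.maximum(
            cfg.delta2h_intercept
            + cfg.delta2h_slope * L_row
            + rng.normal(0.0, cfg.delta2h_sd, n_rows),
            -85.0,
        )
        grain_mass = np.maximum(rng.normal(cfg.grain_mass_mean_g, cfg.grain_mass_sd_g, n_rows), 200.0)
        grain_npct = np.maximum(rng.normal(cfg.grain_n_pct_mean, cfg.grain_n_pct_sd, n_rows), 0.5)

        n_straw = min(cfg.straw_rows_per_year, n_rows)
        straw_sel = np.sort(rng.choice(n_rows, size=n_straw, replace=False))
        d15n_straw = np.maximum(
            cfg.delta15n_straw_intercept
            + cfg.delta15n_straw_slope * L_row[straw_sel]
            + rng.normal(0.0, cfg.delta15n_straw_sd, n_straw),
            0.2,
        )
        d13c_straw = (
            c13_int
            + cfg.delta13c_straw_offset
            - cfg.delta13c_slope_per_cm * sev * dr40_row[straw_sel]
            + rng.normal(0.0, cfg.delta13c_sd, n_straw)
        )
        straw_mass = np.maximum(
            rng.normal(cfg.straw_mass_mean_g, cfg.straw_mass_sd_g, n_straw), 200.0
        )
        straw_npct = np.maximum(
            rng.normal(cfg.straw_n_pct_mean, cfg.straw_n_pct_sd, n_straw), 0.05
        )

        grain_df = pd.DataFrame(
            {
                "row_id": row_ids,
                "genotype": np.array(genotypes)[gidx],
                "tissue": "grain",
                "year": year,
                "bed": bed,
                "row_pos": pos,
                "dry_mass_g": grain_mass,
                "n_pct": grain_npct,
                "delta15N": d15n_grain,
                "delta13C": d13c_grain,
                "delta2H": d2h_grain,
            }
        )
        straw_df = pd.DataFrame(
            {
                "row_id": row_ids[straw_sel],
                "genotype": np.array(genotypes)[gidx[straw_sel]],
                "tissue": "straw",
                "year": year,
                "bed": bed[straw_sel],
                "row_pos": pos[straw_sel],
                "dry_mass_g": straw_mass,
                "n_pct": straw_npct,
                "delta15N": d15n_straw,
                "delta13C": d13c_straw,
                "delta2H": np.nan,
            }
        )
        tissue_parts.append(pd.concat([grain_df, straw_df], ignore_index=True))

        # ground-truth tracer bookkeeping (inline atom-fraction arithmetic)
        excess_grain = grain_mass * grain_npct / 100.0 * (af(d15n_grain) - af0)
        excess_straw_full = np.zeros(n_rows)
        excess_straw_full[straw_sel] = (
            straw_mass * straw_npct / 100.0 * (af(d15n_straw) - af0)
        )
        per_row_dose = cfg.dose.per_row_applied_15n_g
        uptake = (excess_grain + excess_straw_full) / per_row_dose
        truth_r_parts.append(
            pd.DataFrame(
                {
                    "row_id": row_ids,
                    "genotype": np.array(genotypes)[gidx],
                    "year": year,
                    "bed": bed,
                    "row_pos": pos,
                    "midpoint_cm": m_row,
                    "uptake_fraction_15n": uptake,
                }
            )
        )

    provenance = {
        "generator": "rhizotrace.simulate",
        "version": _VERSION,
        "seed": int(seed),
        "config": cfg.to_dict(),
    }
    return SimulatedTrial(
        roots=pd.concat(roots_parts, ignore_index=True),
        tissue=pd.concat(tissue_parts, ignore_index=True),
        truth_genotypes=pd.concat(truth_g_parts, ignore_index=True),
        truth_rows=pd.concat(truth_r_parts, ignore_index=True),
        provenance=provenance,
    )


def write_trial(trial: SimulatedTrial, outdir: str | Path) -> dict[str, Path]:
    """Write roots.csv, tissue.csv, truth(.csv/_rows.csv) and provenance.json.

    CSV output is deterministic (fixed float format, LF line endings, empty
    fields for missing values) so identical trials give identical bytes.
    """
    from .io import write_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "roots": outdir / "roots.csv",
        "tissue": outdir / "tissue.csv",
        "truth": outdir / "truth.csv",
        "truth_rows": outdir / "truth_rows.csv",
        "provenance": outdir / "provenance.json",
    }
    write_csv(trial.roots, paths["roots"])
    write_csv(trial.tissue, paths["tissue"])
    write_csv(trial.truth_genotypes, paths["truth"])
    write_csv(trial.truth_rows, paths["truth_rows"])
    paths["provenance"].write_text(json.dumps(trial.provenance, indent=2, default=str) + "\n")
    return paths


def planted_effect_check(
    truth_genotypes: pd.DataFrame, estimates: pd.DataFrame
) -> pd.DataFrame:
    """Compare planted genotype effects with pipeline estimates.

    ``estimates`` needs columns ``genotype, year, deep_root40_cm`` (cultivar
    means).  Returns one row per year with the Spearman rank correlation of
    the planted midpoint shift ``b_g`` with estimated DeepRoot40.  Raises on a
    genotype-label mismatch.
    """
    from scipy.stats import spearmanr

    rows = []
    for year, est in estimates.groupby("year"):
        truth = truth_genotypes[truth_genotypes["year"] == year]
        missing = set(est["genotype"]) - set(truth["genotype"])
        if missing:
            raise ValueError(f"estimate genotypes absent from truth table: {sorted(missing)}")
        merged = truth.merge(est, on="genotype").dropna(subset=["deep_root40_cm"])
        rho = spearmanr(merged["shift_cm"], merged["deep_root40_cm"]).statistic
        rows.append({"year": year, "n": merged.shape[0], "spearman_rho": float(rho)})
    return pd.DataFrame(rows)
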