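"""Validated CSV readers/writers and structured run configuration.

Schemas (extra columns are passed through untouched):

* root observations — ``row_id, genotype, session, position_mm,
  root_length_cm`` (or ``root_length_px`` plus a pixel calibration in the
  geometry config); the generator adds ``year, bed, row_pos``.
* tissue samples — ``row_id, genotype, tissue, dry_mass_g, n_pct, delta15N,
  delta13C, delta2H``.

Schema violations are reported with 1-based file line numbers (header is
line 1).  All writers emit deterministic RFC-4180 CSV: fixed float format, LF
line endings, missing values as empty fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import TubeGeometry
from .isotopes import IsotopeConstants, TracerDose

__all__ = [
    "SchemaError",
    "AnalysisConfig",
    "RunConfig",
    "read_observations",
    "read_tissue",
    "write_csv",
    "load_config",
]

OBSERVATION_COLUMNS = ("row_id", "genotype", "session", "position_mm")
TISSUE_COLUMNS = ("row_id", "genotype", "tissue", "dry_mass_g", "n_pct", "delta15N")


class SchemaError(ValueError):
    """A CSV file violates its expected schema."""


def _lines(idx) -> list[int]:
    # DataFrame index -> 1-based file line numbers (header is line 1)
    return [int(i) + 2 for i in idx]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
    if bad.any():
        raise SchemaError(f"{path}: non-numeric {col!r} on line(s) {_lines(df.index[bad])}")
    return coerced


def read_observations(path: str | Path, px_per_cm: float | None = None) -> pd.DataFrame:
    """Read and validate a root-observation CSV.

    Requires ``row_id, genotype, session, position_mm`` and one of
    ``root_length_cm`` / ``root_length_px`` (pixel lengths are converted using
    ``px_per_cm``).  Negative lengths and non-numeric fields raise
    :class:`SchemaError` naming the offending line(s).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    if "root_length_cm" not in df.columns:
        if "root_length_px" not in df.columns:
            raise SchemaError(f"{path}: need root_length_cm or root_length_px column")
        if px_per_cm is None or px_per_cm <= 0:
            raise SchemaError(f"{path}: root_length_px given but no px_per_cm calibration")
        df["root_length_cm"] = _numeric(df, "root_length_px", path) / px_per_cm
    df["position_mm"] = _numeric(df, "position_mm", path)
    df["root_length_cm"] = _numeric(df, "root_length_cm", path)
    neg = df["root_length_cm"] < 0
    if neg.any():
        raise SchemaError(f"{path}: negative root length on line(s) {_lines(df.index[neg])}")
    if df["position_mm"].isna().any() or df["root_length_cm"].isna().any():
        bad = df.index[df["position_mm"].isna() | df["root_length_cm"].isna()]
        raise SchemaError(f"{path}: empty numeric field on line(s) {_lines(bad)}")
    return df


def read_tissue(path: str | Path) -> pd.DataFrame:
    """Read and validate a tissue-sample CSV (grain/straw isotope data)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TISSUE_COLUMNS, path)
    bad_tissue = ~df["tissue"].isin(["grain", "straw"])
    if bad_tissue.any():
        raise SchemaError(
            f"{path}: tissue must be grain|straw on line(s) {_lines(df.index[bad_tissue])}"
        )
    for col in ("dry_mass_g", "n_pct", "delta15N", "delta13C", "delta2H"):
        if col in df.columns:
            df[col] = _numeric(df, col, path)
    neg = df["dry_mass_g"] < 0
    if neg.any():
        raise SchemaError(f"{path}: negative dry mass on line(s) {_lines(df.index[neg])}")
    out_of_range = (df["n_pct"] < 0) | (df["n_pct"] > 100)
    if out_of_range.any():
        raise SchemaError(
            f"{path}: n_pct outside [0, 100] on line(s) {_lines(df.index[out_of_range])}"
        )
    return df


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV output (fixed float format, LF endings, empty NA)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n", na_rep="")
    return path


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters: binning, DeepRoot target, screening grid, tests."""

    bin_width_m: float = 0.30
    deeproot_target_cm: float = 40.0
    intervals: tuple[tuple[float, float], ...] = ((1.0, 1.3), (1.3, 1.6), (1.6, 1.9), (1.9, 2.2))
    alpha: float = 0.05
    min_reps: int = 4
    fit_sigmoid: bool = True
    session_month: int = 6  # imaging session used for trait-isotope correlation

    def __post_init__(self) -> None:
        if self.deeproot_target_cm <= 0:
            raise ValueError("deeproot_target_cm must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    geometry: TubeGeometry = field(default_factory=TubeGeometry)
    dose: TracerDose = field(default_factory=TracerDose)
    constants: IsotopeConstants = field(default_factory=IsotopeConstants)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _build(cls, block: dict | None):
    if not block:
        return cls()
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - fields
    if unknown:
        raise SchemaError(f"unknown {cls.__name__} key(s): {sorted(unknown)}")
    if "intervals" in block:
        block = dict(block, intervals=tuple(tuple(iv) for iv in block["intervals"]))
    if "injection_depth_m" in block:
        block = dict(block, injection_depth_m=tuple(block["injection_depth_m"]))
    return cls(**block)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a nested YAML run configuration (any block may be omitted)."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        geometry=_build(TubeGeometry, raw.get("geometry")),
        dose=_build(TracerDose, raw.get("dose")),
        constants=_build(IsotopeConstants, raw.get("constants")),
        analysis=_build(AnalysisConfig, raw.get("analysis")),
        seed=int(raw.get("seed", 0)),
    )
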