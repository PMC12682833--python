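"""Depth-resolved root profiles and deep-rooting traits.

Builds per-tube root profiles from per-image observations and computes the
deep-rooting statistics used to phenotype semi-field trials:

* **pRLD profiles** — planar root length density (cm of root per cm^2 of image
  surface) in fixed depth bins (default 0.30 m).
* **DeepRoot40** — the soil depth below which 40 cm of cumulative root length
  is observed along the tube.  Writing ``C(d)`` for the total root length at
  depths >= ``d``, DeepRoot40 is the greatest depth ``d*`` with
  ``C(d*) >= 40`` cm; larger values mean deeper rooting.  The crossing is
  linearly interpolated between adjacent image depths to avoid quantisation at
  the image spacing.
* **sigmoid inflection (SI)** — the inflection depth ``m`` of a decreasing
  logistic curve ``y(d) = A / (1 + exp(k (d - m)))`` fitted to per-image root
  length against depth, a proxy for rooting depth marking the transition from
  dense shallow to sparse deep roots.
* **interval root lengths** — total root length within arbitrary half-open
  depth intervals, and a screening routine correlating cultivar-mean interval
  lengths with cultivar-mean isotope values to locate the soil depths that
  matter for deep tracer uptake.

Trait values that cannot be computed (total root length below the DeepRoot40
target, a profile with no depth transition, a non-convergent sigmoid fit) are
returned as ``NaN`` with a logged diagnostic and propagate as missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .geometry import TubeGeometry, _count_images_in, depth_at_position

__all__ = [
    "ProfileError",
    "RootProfile",
    "BinnedProfile",
    "build_profile",
    "bin_profile",
    "deep_root_threshold",
    "sigmoid_inflection",
    "interval_root_length",
    "traits_table",
    "interval_screen",
]

log = logging.getLogger(__name__)

DEFAULT_TARGET_CM = 40.0
DEFAULT_BIN_WIDTH_M = 0.30
DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = (
    (1.0, 1.3),
    (1.3, 1.6),
    (1.6, 1.9),
    (1.9, 2.2),
)


class ProfileError(ValueError):
    """Invalid root profile or trait query."""


@dataclass(frozen=True)
class RootProfile:
    """Depth-ordered root length observations for one tube and session."""

    row_id: str
    session: str
    depths_m: np.ndarray
    lengths_cm: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_m, dtype=float)
        y = np.asarray(self.lengths_cm, dtype=float)
        if d.size == 0:
            raise ProfileError(f"empty profile for row {self.row_id!r}")
        if d.shape != y.shape:
            raise ProfileError("depths and lengths differ in shape")
        if np.any(np.diff(d) <= 0):
            raise ProfileError(f"depths not strictly increasing for row {self.row_id!r}")
        if np.any(y < 0):
            raise ProfileError(f"negative root length in row {self.row_id!r}")
        object.__setattr__(self, "depths_m", d)
        object.__setattr__(self, "lengths_cm", y)

    @property
    def total_length_cm(self) -> float:
        return float(self.lengths_cm.sum())

    def __len__(self) -> int:
        return int(self.depths_m.size)


@dataclass(frozen=True)
class BinnedProfile:
    """pRLD and total root length per half-open depth bin.

    ``prld_cm_per_cm2`` is NaN for bins containing no image position (the
    density is undefined there, not zero).
    """

    row_id: str
    session: str
    bin_edges_m: np.ndarray
    lengths_cm: np.ndarray
    areas_cm2: np.ndarray
    prld_cm_per_cm2: np.ndarray


def build_profile(
    observations: pd.DataFrame,
    geom: TubeGeometry,
    row_id: str | None = None,
    session: str | None = None,
) -> RootProfile:
    """Assemble a :class:`RootProfile` from per-image observation rows.

    ``observations`` needs columns ``position_mm`` and ``root_length_cm`` (and
    ``row_id`` / ``session`` if not passed explicitly); all rows must belong to
    one tube and session, and positions must be unique.  Rows are sorted by
    soil depth via the geometry's depth registration.
    """
    obs = observations
    if obs.shape[0] == 0:
        raise ProfileError("no observations supplied")
    if row_id is None:
        ids = obs["row_id"].unique()
        if len(ids) != 1:
            raise ProfileError(f"observations mix row_ids {sorted(map(str, ids))}")
        row_id = str(ids[0])
    if session is None and "session" in obs.columns:
        sessions = obs["session"].unique()
        if len(sessions) != 1:
            raise ProfileError(f"observations mix sessions {sorted(map(str, sessions))}")
        session = str(sessions[0])
    session = session or ""

    pos = obs["position_mm"].to_numpy(dtype=float)
    dup = pd.Series(pos).duplicated(keep=False)
    if dup.any():
        dupes = sorted(set(pos[dup.to_numpy()]))
        raise ProfileError(f"duplicate tube positions for row {row_id!r}: {dupes}")
    depths = depth_at_position(pos, geom)
    order = np.argsort(depths)
    return RootProfile(
        row_id=row_id,
        session=session,
        depths_m=depths[order],
        lengths_cm=obs["root_length_cm"].to_numpy(dtype=float)[order],
    )


def bin_profile(
    profile: RootProfile,
    geom: TubeGeometry,
    bin_width_m: float = DEFAULT_BIN_WIDTH_M,
) -> BinnedProfile:
    """Aggregate a profile into half-open depth bins of ``bin_width_m``.

    Per-bin total root length is the sum over images whose depth falls in the
    bin; pRLD divides by the bin's observation area in cm^2.  Bin edges start
    at the first imaged depth and cover the whole imaged range, so summed bin
    lengths conserve the profile total exactly.
    """
    if bin_width_m <= 0:
        raise ProfileError(f"bin_width_m must be > 0 (got {bin_width_m})")
    lo = geom.first_image_depth_m
    deepest = geom.image_depths_m()[-1]
    n_bins = max(int(np.ceil((geom.last_image_depth_m - lo) / bin_width_m - 1e-9)), 1)
    # widen by one bin if the deepest image would otherwise fall on the last edge
    if deepest >= lo + n_bins * bin_width_m - 1e-12:
        n_bins += 1
    edges = lo + bin_width_m * np.arange(n_bins + 1)

    idx = np.clip(((profile.depths_m - lo) / bin_width_m).astype(int), 0, n_bins - 1)
    lengths = np.bincount(idx, weights=profile.lengths_cm, minlength=n_bins)
    areas = np.array(
        [
            _count_images_in(edges[i], edges[i + 1], geom) * geom.per_image_area_cm2
            for i in range(n_bins)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        prld = np.where(areas > 0, lengths / np.where(areas > 0, areas, 1.0), np.nan)
    return BinnedProfile(
        row_id=profile.row_id,
        session=profile.session,
        bin_edges_m=edges,
        lengths_cm=lengths,
        areas_cm2=areas,
        prld_cm_per_cm2=prld,
    )


def deep_root_threshold(profile: RootProfile, target_cm: float = DEFAULT_TARGET_CM) -> float:
    """DeepRoot_target: deepest soil depth (cm) below which ``target_cm`` of
    cumulative root length is observed.

    Let ``C(d)`` be the total root length at depths >= ``d``.  Returns the
    greatest ``d*`` with ``C(d*) >= target_cm``, linearly interpolating the
    bottom-up cumulative curve within the image interval where it crosses the
    target.  Returns ``NaN`` (with a logged shortfall) when the whole tube
    holds less than ``target_cm`` of root.
    """
    if target_cm <= 0:
        raise ProfileError(f"target_cm must be > 0 (got {target_cm})")
    d = profile.depths_m * 100.0  # cm
    y = profile.lengths_cm
    # bottom-up cumulative: S[j] = sum of lengths at depths >= d[j]
    S = np.cumsum(y[::-1])[::-1]
    total = S[0]
    if total < target_cm:
        log.info(
            "row %s session %s: total root length %.3f cm < target %.1f cm; "
            "DeepRoot undefined",
            profile.row_id,
            profile.session,
            total,
            target_cm,
        )
        return float("nan")
    # deepest image index whose bottom-up cumulative still reaches the target
    idx = int(np.flatnonzero(S >= target_cm - 1e-12)[-1])
    if idx == len(y) - 1:
        return float(d[idx])
    shallower_needed = target_cm - S[idx + 1]  # length needed from image idx
    frac = shallower_needed / y[idx]
    return float(d[idx] + (1.0 - frac) * (d[idx + 1] - d[idx]))


def _logistic(d: np.ndarray, A: float, k: float, m: float) -> np.ndarray:
    return A / (1.0 + np.exp(np.clip(k * (d - m), -500.0, 500.0)))


def _logistic_jac(d: np.ndarray, A: float, k: float, m: float) -> np.ndarray:
    z = np.clip(k * (d - m), -500.0, 500.0)
    e = np.exp(z)
    denom = (1.0 + e) ** 2
    return np.column_stack(
        [1.0 / (1.0 + e), -A * (d - m) * e / denom, A * k * e / denom]
    )


def sigmoid_inflection(
    profile: RootProfile,
    min_observations: int = 8,
    min_span_m: float = 0.5,
    cv_floor: float = 0.05,
) -> float:
    """Sigmoid-inflection rooting-depth proxy (cm).

    Fits ``y(d) = A / (1 + exp(k (d - m)))`` (A > 0, k > 0, ``m`` within the
    observed depth range) to per-image root length against depth by least
    squares and returns the inflection depth ``m``.  Returns NaN with a logged
    diagnostic for near-constant profiles (coefficient of variation below
    ``cv_floor``: no depth transition), non-convergence, or a fitted ``m``
    pinned at a depth bound.
    """
    d = profile.depths_m * 100.0
    y = profile.lengths_cm
    if len(profile) < min_observations:
        raise ProfileError(
            f"sigmoid fit needs >= {min_observations} observations (got {len(profile)})"
        )
    span = d.max() - d.min()
    if span < min_span_m * 100.0:
        raise ProfileError(
            f"sigmoid fit needs >= {min_span_m} m depth span (got {span / 100:.2f} m)"
        )
    mean = y.mean()
    if mean <= 0 or y.std() / mean < cv_floor:
        log.info("row %s: near-constant profile, no depth transition", profile.row_id)
        return float("nan")

    A0 = float(np.percentile(y, 95))
    cum = np.cumsum(y)
    m0 = float(d[np.searchsorted(cum, cum[-1] / 2.0)])  # length-weighted median depth
    k0 = 4.0 / span
    lo = (1e-9, 1e-4, d.min())
    hi = (10.0 * max(y.max(), 1e-9), 5.0, d.max())
    p0 = (max(A0, 1e-6), min(max(k0, 1e-3), 4.9), m0)
    try:
        popt, _ = curve_fit(
            _logistic, d, y, p0=p0, bounds=(lo, hi), jac=_logistic_jac, maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        log.info("row %s: sigmoid fit failed to converge (%s)", profile.row_id, exc)
        return float("nan")
    m_hat = float(popt[2])
    tol = 1e-6 * max(span, 1.0)
    if m_hat - d.min() < tol or d.max() - m_hat < tol:
        log.info("row %s: fitted inflection pinned at depth bound (%.2f cm)", profile.row_id, m_hat)
        return float("nan")
    return m_hat


def interval_root_length(profile: RootProfile, d_lo: float, d_hi: float) -> float:
    """Total root length (cm) at depths in the half-open interval [d_lo, d_hi) m."""
    if not d_lo < d_hi:
        raise ProfileError(f"inverted depth interval [{d_lo}, {d_hi})")
    mask = (profile.depths_m >= d_lo) & (profile.depths_m < d_hi)
    return float(profile.lengths_cm[mask].sum())


def traits_table(
    observations: pd.DataFrame,
    geom: TubeGeometry,
    intervals: Sequence[tuple[float, float]] = DEFAULT_INTERVALS,
    target_cm: float = DEFAULT_TARGET_CM,
    fit_sigmoid: bool = True,
) -> pd.DataFrame:
    """Compute per-row, per-session deep-rooting traits.

    Groups an observation table (columns ``row_id, genotype, session,
    position_mm, root_length_cm``, optionally ``year``/``bed``/``row_pos``) by
    tube and session and returns one row per group with ``deep_root40_cm``,
    ``si_cm`` (if ``fit_sigmoid``) and one ``len_<lo>_<hi>_cm`` column per
    requested depth interval.  Undefined traits are NaN.
    """
    carry = [c for c in ("genotype", "year", "bed", "row_pos") if c in observations.columns]
    records: list[dict] = []
    for (row_id, session), grp in observations.groupby(["row_id", "session"], sort=True):
        profile = build_profile(grp, geom, row_id=str(row_id), session=str(session))
        rec: dict = {"row_id": row_id, "session": session}
        for c in carry:
            rec[c] = grp[c].iloc[0]
        rec["deep_root40_cm"] = deep_root_threshold(profile, target_cm=target_cm)
        if fit_sigmoid:
            rec["si_cm"] = sigmoid_inflection(profile)
        for lo, hi in intervals:
            rec[interval_column(lo, hi)] = interval_root_length(profile, lo, hi)
        records.append(rec)
    return pd.DataFrame.from_records(records)


def interval_column(d_lo: float, d_hi: float) -> str:
    return f"len_{d_lo:g}_{d_hi:g}_cm"


def interval_screen(
    observations: pd.DataFrame,
    geom: TubeGeometry,
    isotope_by_row: pd.DataFrame,
    interval_grid: Iterable[tuple[float, float]],
    isotope_col: str = "delta15N",
) -> pd.DataFrame:
    """Screen depth intervals for association with deep tracer uptake.

    For each half-open interval in ``interval_grid``, computes cultivar-mean
    interval root length across rows, pairs it with cultivar-mean isotope
    values from ``isotope_by_row`` (columns ``row_id, genotype, <isotope_col>``)
    and reports the Pearson correlation.  Returns a table with columns
    ``d_lo, d_hi, r, p, n, flag``; a zero-variance isotope vector flags every
    interval rather than propagating NaN silently.
    """
    from .stats import StatsError, cultivar_mean_correlation

    iso_means = isotope_by_row.groupby("genotype")[isotope_col].mean()
    if iso_means.size < 3:
        raise StatsError(f"interval screen needs >= 3 cultivar means (got {iso_means.size})")

    obs = observations.copy()
    obs["_depth_m"] = depth_at_position(obs["position_mm"].to_numpy(dtype=float), geom)
    rows = []
    for d_lo, d_hi in interval_grid:
        mask = (obs["_depth_m"] >= d_lo) & (obs["_depth_m"] < d_hi)
        per_row = (
            obs[mask].groupby("row_id")["root_length_cm"].sum()
            .reindex(obs["row_id"].unique(), fill_value=0.0)
        )
        geno = obs.drop_duplicates("row_id").set_index("row_id")["genotype"]
        cultivar = per_row.groupby(geno).mean()
        res = cultivar_mean_correlation(cultivar, iso_means)
        rows.append(
            {"d_lo": d_lo, "d_hi": d_hi, "r": res.r, "p": res.p, "n": res.n, "flag": res.flag}
        )
    return pd.DataFrame(rows)
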