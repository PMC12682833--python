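"""Genotype-mean estimation and cultivar-mean correlation analyses.

Field-trial traits are analysed at two levels:

* **Genotype means.**  Row-level trait values are fitted with a linear model
  with genotype and year fixed effects plus bed and a quadratic along-bed
  position covariate — a deliberately simplified surrogate for a generalized
  least squares fit with a spatial correlation structure (which requires the
  original facility layout).  Marginal genotype means average the fitted
  surface over years and beds at the mean position.  Pairwise genotype
  differences use the studentized range (Tukey) when the design is balanced
  and Holm-adjusted t-tests otherwise, summarised as a compact letter display:
  genotypes sharing a letter are not significantly different at alpha.
* **Cultivar-mean correlations.**  Associations between traits and isotope
  values (and of either across years) are Pearson correlations of cultivar
  means, with two-sided p-values from the t-distribution with n - 2 degrees of
  freedom and pairwise deletion of missing genotypes.

A replication filter selects the genotypes entering each analysis: genotypes
with at least ``min_reps`` rows within a year for correlations, or in every
year for the multi-year models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatsError",
    "CorrelationResult",
    "GenotypeMeanEstimate",
    "replication_filter",
    "estimate_genotype_means",
    "cultivar_mean_correlation",
    "correlation_matrix",
    "compact_letters",
]


class StatsError(ValueError):
    """Invalid statistical analysis input."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation over cultivar means."""

    x_label: str
    y_label: str
    r: float
    p: float
    n: int
    flag: str = ""


@dataclass(frozen=True)
class GenotypeMeanEstimate:
    genotype: str
    trait: str
    mean: float
    se: float
    letters: str


def replication_filter(
    data: pd.DataFrame,
    min_reps: int = 4,
    scope: str = "per-year",
) -> tuple[pd.DataFrame, list[str]]:
    """Retain genotypes meeting a replication threshold.

    ``scope='per-year'`` keeps, within each year, the genotypes with at least
    ``min_reps`` rows in that year; ``scope='all-years'`` keeps genotypes with
    at least ``min_reps`` rows in every year present in the data.  Returns the
    filtered table and the sorted list of retained genotypes.
    """
    if scope not in ("per-year", "all-years"):
        raise StatsError(f"unknown scope {scope!r}")
    counts = data.groupby(["genotype", "year"]).size()
    if scope == "per-year":
        ok = counts[counts >= min_reps].index
        mask = data.set_index(["genotype", "year"]).index.isin(ok)
        filtered = data[mask]
    else:
        n_years = data["year"].nunique()
        per_geno = counts[counts >= min_reps].groupby("genotype").size()
        keep = set(per_geno[per_geno == n_years].index)
        filtered = data[data["genotype"].isin(keep)]
    if filtered.shape[0] == 0:
        raise StatsError(
            f"no genotypes meet min_reps={min_reps} ({scope}); relax the threshold"
        )
    return filtered, sorted(filtered["genotype"].unique())


def _design_matrix(
    data: pd.DataFrame,
    genotypes: list,
    years: list,
    beds: list,
    pos_mean: float,
    use_pos: bool,
) -> tuple[np.ndarray, list[str]]:
    n = data.shape[0]
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for g in genotypes[1:]:
        cols.append((data["genotype"] == g).to_numpy(float))
        names.append(f"geno[{g}]")
    for yy in years[1:]:
        cols.append((data["year"] == yy).to_numpy(float))
        names.append(f"year[{yy}]")
    for b in beds[1:]:
        cols.append((data["bed"] == b).to_numpy(float))
        names.append(f"bed[{b}]")
    if use_pos:
        p = data["row_pos"].to_numpy(float) - pos_mean
        cols.append(p)
        cols.append(p**2)
        names.extend(["pos", "pos2"])
    return np.column_stack(cols), names


def estimate_genotype_means(
    data: pd.DataFrame,
    trait: str,
    alpha: float = 0.05,
    adjust: str = "auto",
) -> pd.DataFrame:
    """Estimate marginal genotype means with design covariates.

    ``data`` needs columns ``genotype`` and ``trait``; ``year``, ``bed`` and
    ``row_pos`` are used as covariates when present.  Returns a tidy table
    (``genotype, trait, mean, se, letters``) sorted by descending mean.
    Missing trait values are dropped pairwise.  Raises on a rank-deficient
    design (e.g. a genotype confounded with a bed), naming the aliased terms.
    """
    df = data.dropna(subset=[trait]).copy()
    genotypes = sorted(df["genotype"].unique())
    if len(genotypes) < 2:
        raise StatsError("need >= 2 genotypes to estimate genotype means")
    counts = df.groupby("genotype").size()
    if (counts < 2).any():
        raise StatsError(
            f"genotypes with < 2 replicates after filtering: "
            f"{sorted(counts[counts < 2].index)}"
        )
    years = sorted(df["year"].unique()) if "year" in df.columns else [None]
    beds = sorted(df["bed"].unique()) if "bed" in df.columns else [None]
    use_pos = "row_pos" in df.columns and df["row_pos"].nunique() > 2
    if "year" not in df.columns:
        df["year"] = 0
    if "bed" not in df.columns:
        df["bed"] = 0
    years = sorted(df["year"].unique())
    beds = sorted(df["bed"].unique())
    pos_mean = float(df["row_pos"].mean()) if use_pos else 0.0

    X, names = _design_matrix(df, genotypes, years, beds, pos_mean, use_pos)
    y = df[trait].to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise StatsError(f"rank-deficient design; aliased terms: {aliased}")

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise StatsError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv

    # marginal-mean contrast: genotype dummy at 1, years/beds averaged,
    # position at its mean (centred covariates -> 0; pos2 at mean of squares)
    p2_mean = float(((df["row_pos"] - pos_mean) ** 2).mean()) if use_pos else 0.0

    def contrast(g: str) -> np.ndarray:
        c = np.zeros(len(names))
        c[names.index("intercept")] = 1.0
        if g != genotypes[0]:
            c[names.index(f"geno[{g}]")] = 1.0
        for yy in years[1:]:
            c[names.index(f"year[{yy}]")] = 1.0 / len(years)
        for b in beds[1:]:
            c[names.index(f"bed[{b}]")] = 1.0 / len(beds)
        if use_pos:
            c[names.index("pos2")] = p2_mean
        return c

    means, ses, cons = {}, {}, {}
    for g in genotypes:
        c = contrast(g)
        means[g] = float(c @ beta)
        ses[g] = float(np.sqrt(max(c @ cov @ c, 0.0)))
        cons[g] = c

    balanced = counts.nunique() == 1
    if adjust == "auto":
        adjust = "tukey" if balanced else "holm"
    k = len(genotypes)
    pairs = [(genotypes[i], genotypes[j]) for i in range(k) for j in range(i + 1, k)]
    p_adj: dict[tuple[str, str], float] = {}
    raw_t = {}
    for a, b in pairs:
        d = cons[a] - cons[b]
        se_d = float(np.sqrt(max(d @ cov @ d, 0.0)))
        t = np.inf if se_d == 0 else (means[a] - means[b]) / se_d
        raw_t[(a, b)] = t
    if adjust == "tukey":
        for pair, t in raw_t.items():
            p_adj[pair] = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, dof))
    elif adjust == "holm":
        raw_p = [2.0 * sps.t.sf(abs(t), dof) for t in raw_t.values()]
        adj = multipletests(raw_p, method="holm")[1]
        p_adj = dict(zip(raw_t.keys(), adj))
    else:
        raise StatsError(f"unknown adjustment {adjust!r}")

    significant = {pair for pair, p in p_adj.items() if p < alpha}
    order = sorted(genotypes, key=lambda g: -means[g])
    letters = compact_letters(order, significant)

    out = pd.DataFrame(
        {
            "genotype": order,
            "trait": trait,
            "mean": [means[g] for g in order],
            "se": [ses[g] for g in order],
            "letters": [letters[g] for g in order],
        }
    )
    out.attrs["adjustment"] = adjust
    out.attrs["model"] = (
        "OLS: genotype + year + bed + quadratic along-bed position "
        "(simplified surrogate for a spatial-correlation GLS)"
    )
    out.attrs["pairwise_p"] = {f"{a}|{b}": p for (a, b), p in p_adj.items()}
    return out


def compact_letters(order: Sequence, significant: set[tuple]) -> dict:
    """Compact letter display by insert-and-absorb.

    ``order`` lists the groups (best mean first); ``significant`` holds the
    unordered pairs whose difference is significant.  Two groups share a
    letter iff their pair is not in ``significant``.
    """
    rank = {g: i for i, g in enumerate(order)}
    # process widely separated pairs first: keeps the working set small
    def _span(pr: frozenset) -> int:
        ra, rb = (rank[g] for g in pr)
        return abs(ra - rb)

    sig_pairs = sorted({frozenset(p) for p in significant}, key=_span, reverse=True)
    sets: set[frozenset] = {frozenset(order)}
    for pair in sig_pairs:
        a, b = tuple(pair)
        to_split = [s for s in sets if a in s and b in s]
        if not to_split:
            continue
        for s in to_split:
            sets.discard(s)
            sets.add(s - {a})
            sets.add(s - {b})
        # absorb: drop empty sets and sets contained in another
        sets = {s for s in sets if s and not any(s < t for t in sets)}
    # order letter groups by the best-ranked member so 'a' goes to the top mean
    letter_sets = sorted(sets, key=lambda s: (min(rank[g] for g in s), -len(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for i, s in enumerate(letter_sets):
        letter = alphabet[i] if i < len(alphabet) else f"({i})"
        for g in s:
            out[g] += letter
    return {g: "".join(sorted(v)) for g, v in out.items()}


def cultivar_mean_correlation(
    x: pd.Series,
    y: pd.Series,
    x_label: str = "x",
    y_label: str = "y",
) -> CorrelationResult:
    """Pearson correlation of two per-genotype mean series.

    Genotypes are matched by index label with pairwise deletion of missing
    values; the p-value is two-sided from the t-distribution with n - 2
    degrees of freedom.  Zero variance in either series yields a flagged
    undefined result rather than NaN propagation.
    """
    joined = pd.concat([x.rename("x"), y.rename("y")], axis=1, join="inner").dropna()
    n = joined.shape[0]
    if n < 3:
        raise StatsError(f"Pearson correlation needs >= 3 paired cultivar means (got {n})")
    xv = joined["x"].to_numpy(float)
    yv = joined["y"].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return CorrelationResult(x_label, y_label, np.nan, np.nan, n, flag="zero-variance")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(x_label, y_label, float(r), float(p), n)


def correlation_matrix(series_by_year: Mapping) -> pd.DataFrame:
    """All pairwise year-by-year correlations of per-genotype means.

    Returns a long table ``year_x, year_y, r, p, n, flag`` for year pairs
    (x < y); a pair with no overlapping genotypes is flagged ``no-overlap``.
    """
    years = sorted(series_by_year)
    if len(years) < 2:
        raise StatsError("correlation matrix needs >= 2 years")
    rows = []
    for i, ya in enumerate(years):
        for yb in years[i + 1 :]:
            try:
                res = cultivar_mean_correlation(
                    series_by_year[ya], series_by_year[yb], str(ya), str(yb)
                )
                rows.append(
                    {"year_x": ya, "year_y": yb, "r": res.r, "p": res.p, "n": res.n, "flag": res.flag}
                )
            except StatsError:
                rows.append(
                    {"year_x": ya, "year_y": yb, "r": np.nan, "p": np.nan, "n": 0, "flag": "no-overlap"}
                )
    return pd.DataFrame(rows)
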