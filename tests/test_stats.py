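"""Genotype means, compact letters, replication filter, Pearson correlations."""

import numpy as np
import pandas as pd
import pytest

from rhizotrace.stats import (
    StatsError,
    compact_letters,
    correlation_matrix,
    cultivar_mean_correlation,
    estimate_genotype_means,
    replication_filter,
)


def balanced_trial(offsets: dict, reps=10, noise_sd=0.0, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for geno, off in offsets.items():
        for r in range(reps):
            rows.append(
                {
                    "genotype": geno,
                    "year": 2021 + r % 2,
                    "bed": 1 + (r // 2) % 2,
                    "row_pos": 1 + (7 * i) % 50,
                    "trait": 100.0 + off + rng.normal(0, noise_sd),
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestReplicationFilter:
    @staticmethod
    def _table(counts: dict) -> pd.DataFrame:
        rows = []
        for (geno, year), n in counts.items():
            rows += [{"genotype": geno, "year": year, "row_id": f"{geno}-{year}-{i}"} for i in range(n)]
        return pd.DataFrame(rows)

    def test_per_year_counting(self):
        df = self._table({("A", 2021): 5, ("B", 2021): 3, ("A", 2022): 2, ("B", 2022): 4})
        filtered, kept = replication_filter(df, min_reps=4, scope="per-year")
        pairs = set(map(tuple, filtered[["genotype", "year"]].drop_duplicates().to_numpy()))
        assert pairs == {("A", 2021), ("B", 2022)}
        assert kept == ["A", "B"]

    def test_min_reps_one_is_identity(self):
        df = self._table({("A", 2021): 1, ("B", 2021): 2})
        filtered, _ = replication_filter(df, min_reps=1)
        assert filtered.shape[0] == df.shape[0]

    def test_all_years_excludes_partial_genotype(self):
        df = self._table(
            {("A", y): 4 for y in (2021, 2022, 2023)}
            | {("B", 2021): 4, ("B", 2022): 4, ("B", 2023): 3}
        )
        filtered, kept = replication_filter(df, min_reps=4, scope="all-years")
        assert kept == ["A"]

    def test_empty_result_advises(self):
        df = self._table({("A", 2021): 1})
        with pytest.raises(StatsError, match="relax"):
            replication_filter(df, min_reps=4)


class TestGenotypeMeans:
    def test_exact_recovery_noiseless(self):
        offsets = {"A": 0.0, "B": 10.0, "C": -5.0}
        out = estimate_genotype_means(balanced_trial(offsets), "trait")
        for geno, off in offsets.items():
            est = out.loc[out["genotype"] == geno, "mean"].iloc[0]
            assert est == pytest.approx(100.0 + off, abs=1e-8)

    def test_shift_equivariance(self):
        df = balanced_trial({"A": 0.0, "B": 10.0, "C": -5.0}, noise_sd=3.0, seed=5)
        out1 = estimate_genotype_means(df, "trait")
        df2 = df.assign(trait=df["trait"] + 42.0)
        out2 = estimate_genotype_means(df2, "trait")
        np.testing.assert_allclose(out2["mean"], out1["mean"] + 42.0, rtol=1e-10)
        assert list(out1["letters"]) == list(out2["letters"])

    def test_rank_deficiency_identified(self):
        # genotype B occurs only in bed 2 -> aliased with the bed effect
        df = balanced_trial({"A": 0.0, "B": 5.0}, reps=6, noise_sd=1.0)
        df.loc[df["genotype"] == "A", "bed"] = 1
        df.loc[df["genotype"] == "B", "bed"] = 2
        with pytest.raises(StatsError, match="alias"):
            estimate_genotype_means(df, "trait")

    def test_separated_genotypes_get_distinct_letters(self):
        df = balanced_trial({"A": 0.0, "B": 50.0, "C": 100.0}, noise_sd=1.0, seed=2)
        out = estimate_genotype_means(df, "trait").set_index("genotype")
        letters = out["letters"]
        assert not set(letters["A"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["B"])


class TestCompactLetters:
    def test_clique_cover_property(self, rng):
        # letters must encode exactly the non-significance graph
        for _ in range(20):
            k = int(rng.integers(3, 9))
            groups = [f"g{i}" for i in range(k)]
            sig = {
                (a, b)
                for i, a in enumerate(groups)
                for b in groups[i + 1 :]
                if rng.random() < 0.4
            }
            letters = compact_letters(groups, sig)
            for i, a in enumerate(groups):
                for b in groups[i + 1 :]:
                    share = bool(set(letters[a]) & set(letters[b]))
                    assert share == ((a, b) not in sig), (a, b, letters, sig)

    def test_all_same_single_letter(self):
        letters = compact_letters(["a", "b", "c"], set())
        assert set(letters.values()) == {"a"}


class TestCultivarCorrelation:
    def test_identity_and_reflection(self):
        x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        res = cultivar_mean_correlation(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10
        assert cultivar_mean_correlation(x, -x).r == pytest.approx(-1.0)

    def test_formula_oracle(self):
        # from-scratch sum-based Pearson r and t-distribution p-value
        import scipy.stats as sps

        xv = np.array([3.0, 1, 4, 1, 5, 9, 2, 6, 5, 3])
        yv = np.array([2.0, 7, 1, 8, 2, 8, 1, 8, 2, 8])
        n = len(xv)
        sx, sy = xv.sum(), yv.sum()
        sxx, syy, sxy = (xv**2).sum(), (yv**2).sum(), (xv * yv).sum()
        r_exp = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
        t = r_exp * np.sqrt((n - 2) / (1 - r_exp**2))
        p_exp = 2 * sps.t.sf(abs(t), n - 2)
        res = cultivar_mean_correlation(
            pd.Series(xv, index=range(n)), pd.Series(yv, index=range(n))
        )
        assert res.r == pytest.approx(r_exp, abs=1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_affine_invariance_and_sign_flip(self, rng):
        x = pd.Series(rng.normal(size=20))
        y = pd.Series(rng.normal(size=20))
        base = cultivar_mean_correlation(x, y).r
        assert cultivar_mean_correlation(2.5 * x + 7, y).r == pytest.approx(base, rel=1e-10)
        assert cultivar_mean_correlation(-2.5 * x + 7, y).r == pytest.approx(-base, rel=1e-10)

    def test_pairwise_deletion_and_n(self):
        x = pd.Series([1.0, 2, 3, np.nan, 5], index=list("abcde"))
        y = pd.Series([2.0, 4, 6, 8, np.nan], index=list("abcde"))
        res = cultivar_mean_correlation(x, y)
        assert res.n == 3

    def test_zero_variance_flagged(self):
        x = pd.Series([1.0, 1, 1, 1], index=list("abcd"))
        y = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        res = cultivar_mean_correlation(x, y)
        assert res.flag == "zero-variance"
        assert np.isnan(res.r)

    def test_too_few_pairs_rejected(self):
        x = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(StatsError):
            cultivar_mean_correlation(x, x)


class TestCorrelationMatrix:
    def test_identical_years_give_unit_r(self):
        s = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        out = correlation_matrix({2021: s, 2022: s.copy(), 2023: s.copy()})
        assert out.shape[0] == 3
        np.testing.assert_allclose(out["r"], 1.0)

    def test_disjoint_years_flagged(self):
        a = pd.Series([1.0, 2, 3], index=list("abc"))
        b = pd.Series([1.0, 2, 3], index=list("xyz"))
        out = correlation_matrix({2021: a, 2022: b})
        assert out["flag"].iloc[0] == "no-overlap"

    def test_persistent_effects_give_positive_r(self, rng):
        base = rng.normal(0, 2, 30)
        years = {
            y: pd.Series(base + rng.normal(0, 0.5, 30), index=range(30))
            for y in (2021, 2022, 2023)
        }
        out = correlation_matrix(years)
        assert (out["r"] > 0).all()
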