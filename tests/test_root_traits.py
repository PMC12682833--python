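"""Root profiles and deep-rooting traits: DeepRoot40, SI, intervals, pRLD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizotrace.geometry import TubeGeometry
from rhizotrace.root_traits import (
    ProfileError,
    RootProfile,
    bin_profile,
    build_profile,
    deep_root_threshold,
    interval_root_length,
    interval_screen,
    sigmoid_inflection,
    traits_table,
)

from conftest import logistic_profile, observations_frame, random_profile


def grid_scan_deeproot(profile: RootProfile, target_cm: float = 40.0) -> float:
    """Independent oracle: scan a 1-mm depth grid of the linearly interpolated
    bottom-up cumulative root-length curve for max{d : C(d) >= target}."""
    d_cm = profile.depths_m * 100.0
    S = np.cumsum(profile.lengths_cm[::-1])[::-1]  # C at each image depth
    if S[0] < target_cm:
        return float("nan")
    grid = np.arange(d_cm[0], d_cm[-1] + 0.05, 0.1)
    C = np.interp(grid, d_cm, S)  # C is non-increasing in depth -> interp of S
    ok = grid[C >= target_cm]
    return float(ok[-1]) if ok.size else float("nan")


class TestBuildProfile:
    def test_sorted_by_depth(self, geom):
        df = pd.DataFrame(
            {
                "row_id": "R1",
                "session": "s",
                "position_mm": [70.0, 0.0, 35.0],
                "root_length_cm": [3.0, 1.0, 2.0],
            }
        )
        p = build_profile(df, geom)
        assert len(p) == 3
        assert np.all(np.diff(p.depths_m) > 0)
        assert list(p.lengths_cm) == [1.0, 2.0, 3.0]

    def test_permutation_invariance(self, geom, rng):
        df = observations_frame(random_profile(rng, geom), geom)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        p1, p2 = build_profile(df, geom), build_profile(shuffled, geom)
        np.testing.assert_array_equal(p1.depths_m, p2.depths_m)
        np.testing.assert_array_equal(p1.lengths_cm, p2.lengths_cm)

    def test_duplicate_positions_listed(self, geom):
        df = pd.DataFrame(
            {
                "row_id": "R1",
                "session": "s",
                "position_mm": [35.0, 35.0, 70.0],
                "root_length_cm": [1.0, 1.0, 1.0],
            }
        )
        with pytest.raises(ProfileError, match="35"):
            build_profile(df, geom)

    def test_empty_rejected(self, geom):
        with pytest.raises(ProfileError):
            build_profile(pd.DataFrame(columns=["position_mm", "root_length_cm"]), geom)

    def test_full_tube_gives_one_observation_per_image(self, geom, rng):
        df = observations_frame(random_profile(rng, geom), geom)
        assert len(build_profile(df, geom)) == geom.n_images


class TestBinProfile:
    def test_zero_profile_zero_prld(self, geom):
        d = geom.image_depths_m()
        b = bin_profile(RootProfile("R1", "s", d, np.zeros(d.size)), geom)
        nonempty = b.areas_cm2 > 0
        assert np.all(b.prld_cm_per_cm2[nonempty] == 0.0)
        assert np.all(np.isnan(b.prld_cm_per_cm2[~nonempty]))

    def test_single_bin_aggregates_everything(self, geom, rng):
        p = random_profile(rng, geom)
        b = bin_profile(p, geom, bin_width_m=geom.depth_span_m + 0.01)
        assert b.lengths_cm[0] == pytest.approx(p.total_length_cm)
        assert b.prld_cm_per_cm2[0] == pytest.approx(
            p.total_length_cm / (geom.n_images * geom.per_image_area_cm2)
        )

    def test_binned_lengths_conserve_total(self, geom, rng):
        for _ in range(5):
            p = random_profile(rng, geom)
            b = bin_profile(p, geom)
            assert b.lengths_cm.sum() == pytest.approx(p.total_length_cm, rel=1e-12)

    def test_per_bin_length_equals_prld_times_area(self, geom, rng):
        b = bin_profile(random_profile(rng, geom), geom)
        mask = b.areas_cm2 > 0
        np.testing.assert_allclose(
            b.lengths_cm[mask], b.prld_cm_per_cm2[mask] * b.areas_cm2[mask]
        )


class TestDeepRootThreshold:
    def test_point_mass_at_150cm(self, geom):
        d = geom.image_depths_m()
        y = np.zeros(d.size)
        i = int(np.argmin(np.abs(d - 1.5)))
        y[i] = 40.0
        p = RootProfile("R1", "s", d, y)
        assert deep_root_threshold(p) == pytest.approx(d[i] * 100.0)

    def test_shortfall_is_undefined(self, geom):
        d = geom.image_depths_m()
        y = np.full(d.size, 39.0 / d.size)
        assert np.isnan(deep_root_threshold(RootProfile("R1", "s", d, y)))

    def test_matches_grid_scan_oracle(self, geom, rng):
        for _ in range(25):
            p = random_profile(rng, geom)
            est = deep_root_threshold(p)
            oracle = grid_scan_deeproot(p)
            assert est == pytest.approx(oracle, abs=0.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1), st.floats(0.7, 2.9), st.floats(1.0, 30.0))
    def test_monotone_under_added_deep_root(self, seed, add_depth_m, add_len):
        # appending root length below the current threshold never decreases it
        geom = TubeGeometry()
        p = random_profile(np.random.default_rng(seed), geom)
        base = deep_root_threshold(p)
        if np.isnan(base) or add_depth_m * 100.0 <= base:
            return
        d = p.depths_m
        i = int(np.argmin(np.abs(d - add_depth_m)))
        if d[i] * 100.0 <= base:
            return
        y = p.lengths_cm.copy()
        y[i] += add_len
        deeper = deep_root_threshold(RootProfile("R1", "s", d, y))
        assert deeper >= base - 1e-9

    def test_scaling_never_shallows(self, geom, rng):
        for c in (1.0, 1.5, 3.0):
            p = random_profile(rng, geom)
            base = deep_root_threshold(p)
            scaled = deep_root_threshold(
                RootProfile(p.row_id, p.session, p.depths_m, c * p.lengths_cm)
            )
            if not np.isnan(base):
                assert scaled >= base - 1e-9


class TestSigmoidInflection:
    def test_exact_model_recovery(self, geom):
        p = logistic_profile(geom, A=2.0, k=0.05, m_cm=120.0)
        assert sigmoid_inflection(p) == pytest.approx(120.0, abs=0.1)

    def test_exact_recovery_well_conditioned_parameters(self, geom):
        for m in (100.0, 150.0, 200.0):
            p = logistic_profile(geom, A=1.5, k=0.08, m_cm=m)
            assert sigmoid_inflection(p) == pytest.approx(m, rel=1e-3)

    def test_constant_profile_undefined(self, geom):
        d = geom.image_depths_m()
        p = RootProfile("R1", "s", d, np.full(d.size, 2.0))
        assert np.isnan(sigmoid_inflection(p))

    def test_too_few_observations_rejected(self, geom):
        d = geom.image_depths_m()[:5]
        with pytest.raises(ProfileError):
            sigmoid_inflection(RootProfile("R1", "s", d, np.ones(5)))

    def test_noisy_recovery_median_error(self, geom):
        # multiplicative noise CV 0.3, full image grid: median error < 10 cm
        rng = np.random.default_rng(99)
        errors = []
        for _ in range(20):
            p = logistic_profile(geom, m_cm=120.0)
            noisy = RootProfile(
                "R1", "s", p.depths_m, p.lengths_cm * rng.lognormal(0.0, 0.3, len(p))
            )
            errors.append(abs(sigmoid_inflection(noisy) - 120.0))
        assert np.median(errors) < 10.0


class TestIntervalRootLength:
    def test_totality_and_empty(self, geom, rng):
        p = random_profile(rng, geom)
        assert interval_root_length(p, 0.0, 10.0) == pytest.approx(p.total_length_cm)
        d = p.depths_m
        mid = (d[3] + d[4]) / 2
        assert interval_root_length(p, mid, mid + 1e-5) == 0.0

    def test_disjoint_additivity(self, geom, rng):
        p = random_profile(rng, geom)
        for b in (1.0, 1.7, 2.4):
            assert interval_root_length(p, 0.6, b) + interval_root_length(
                p, b, 3.01
            ) == pytest.approx(interval_root_length(p, 0.6, 3.01))

    def test_inverted_interval_rejected(self, geom, rng):
        with pytest.raises(ProfileError):
            interval_root_length(random_profile(rng, geom), 2.0, 1.0)


class TestTraitsTable:
    def test_one_row_per_tube_session(self, geom, rng):
        frames = []
        for rid in ("R1", "R2"):
            p = random_profile(rng, geom)
            df = observations_frame(p, geom)
            df["row_id"] = rid
            frames.append(df)
        table = traits_table(pd.concat(frames), geom, fit_sigmoid=False)
        assert table.shape[0] == 2
        assert {"deep_root40_cm", "len_1.6_1.9_cm"} <= set(table.columns)


class TestIntervalScreen:
    @staticmethod
    def _screen_inputs(rng, geom, couple=True):
        from rhizotrace.simulate import SimulationConfig, simulate_trial

        cfg = SimulationConfig(years=(2021,), delta15n_grain_slope=3.0 if couple else 0.0)
        trial = simulate_trial(cfg, int(rng.integers(2**31)))
        iso = trial.tissue[trial.tissue["tissue"] == "grain"][
            ["row_id", "genotype", "delta15N"]
        ]
        return trial.roots, iso

    def test_zero_variance_isotope_flagged(self, geom, rng):
        roots, iso = self._screen_inputs(rng, geom)
        iso = iso.copy()
        iso["delta15N"] = 5.0
        out = interval_screen(roots, geom, iso, [(1.0, 1.3), (1.6, 1.9)])
        assert (out["flag"] == "zero-variance").all()
        assert out["r"].isna().all()

    def test_coupled_interval_is_detected(self, geom, rng):
        # uptake is coupled to 1.6-1.8 m root length: the best-correlated
        # window should overlap [1.5, 1.9] m
        grid = [(lo, lo + 0.3) for lo in np.arange(0.6, 2.5, 0.1)]
        roots, iso = self._screen_inputs(rng, geom)
        out = interval_screen(roots, geom, iso, grid)
        best = out.loc[out["r"].idxmax()]
        assert best["d_hi"] > 1.5 and best["d_lo"] < 1.9

    def test_label_permutation_destroys_association(self, geom, rng):
        roots, iso = self._screen_inputs(rng, geom)
        genos = iso["genotype"].unique()
        perm = dict(zip(genos, rng.permutation(genos)))
        shuffled = iso.assign(genotype=iso["genotype"].map(perm))
        grid = [(1.6, 1.9)]
        r_true = interval_screen(roots, geom, iso, grid)["r"].iloc[0]
        r_perm = interval_screen(roots, geom, shuffled, grid)["r"].iloc[0]
        assert abs(r_perm) < abs(r_true)
        assert abs(r_perm) < 0.3
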