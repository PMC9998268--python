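import numpy as np
import pytest

from upslope import (
    NullConfig,
    SpeciesRangeRecord,
    build_envelope,
    candidate_elevations,
    compare_to_null,
    generate_null_dataset,
    resample_placements,
    truncate_candidates,
)
from upslope.nullmodel import observed_fit_for_region, region_rng
from upslope.wls import WeightedFit, weighted_least_squares


def rec(species, limit1, shift, weight=2, region="A"):
    w1 = weight // 2
    return SpeciesRangeRecord(
        species=species, region=region, limit_t1=limit1, limit_tlast=limit1 + shift,
        shift=shift, annual_shift=shift / 10, freq_t1=w1, freq_tlast=weight - w1,
        weight=weight,
    )


BOUNDS = (500.0, 2000.0)


@pytest.fixture
def eight_species():
    rng = np.random.default_rng(0)
    out = []
    for i in range(8):
        x = float(rng.uniform(*BOUNDS))
        d = float(np.clip(rng.normal(0, 200), BOUNDS[0] - x, BOUNDS[1] - x))
        out.append(rec(f"s{i}", x, d, weight=int(rng.integers(2, 12))))
    return out


class TestCandidates:
    def test_grid200_spacing(self):
        cfg = NullConfig(variant="grid200", bounds=BOUNDS)
        cands = candidate_elevations(cfg, None, [])
        assert len(cands) == 200
        assert cands[0] == 500.0 and cands[-1] == 2000.0
        assert np.allclose(np.diff(cands), 1500.0 / 199)

    def test_observed_initials_identity(self, eight_species):
        cfg = NullConfig(variant="observed_initials", bounds=BOUNDS)
        cands = candidate_elevations(cfg, None, eight_species)
        assert np.array_equal(cands, [r.limit_t1 for r in eight_species])

    def test_surveyed_uses_design(self, toy_design):
        cfg = NullConfig(variant="surveyed")
        cands = candidate_elevations(cfg, toy_design, [], region="R01")
        assert len(cands) == 40

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            NullConfig(variant="shuffled")


class TestTruncation:
    def test_upward_shift_drops_top(self):
        cands = [500.0, 1000.0, 1500.0, 2000.0]
        assert list(truncate_candidates(cands, 600.0, BOUNDS)) == [500.0, 1000.0]

    def test_zero_shift_keeps_all(self):
        cands = [500.0, 1000.0, 1500.0, 2000.0]
        assert list(truncate_candidates(cands, 0.0, BOUNDS)) == cands

    def test_downward_shift_drops_bottom(self):
        cands = [500.0, 1000.0, 1500.0, 2000.0]
        assert list(truncate_candidates(cands, -700.0, BOUNDS)) == [1500.0, 2000.0]

    def test_infeasible_shift_raises(self):
        with pytest.raises(ValueError, match="feasible"):
            truncate_candidates([600.0], 1600.0, BOUNDS)


class TestResampling:
    def test_placements_respect_bounds(self, eight_species, toy_design):
        cands = toy_design["R01"].elevations
        rng = np.random.default_rng(3)
        initials, shifts, weights = resample_placements(
            eight_species, cands, BOUNDS, rng, size=200
        )
        assert initials.shape == (8, 200)
        final = initials + shifts[:, None]
        assert final.min() >= BOUNDS[0] - 1e-9
        assert final.max() <= BOUNDS[1] + 1e-9

    def test_shift_weight_pairing_preserved(self, eight_species, toy_design):
        cands = toy_design["R01"].elevations
        _, shifts, weights = resample_placements(
            eight_species, cands, BOUNDS, np.random.default_rng(1), size=5
        )
        assert list(shifts) == [r.shift for r in eight_species]
        assert list(weights) == [r.weight for r in eight_species]

    def test_single_candidate_is_deterministic(self):
        r = rec("s", 600.0, 1400.0)  # only 500 remains feasible
        initials, _, _ = resample_placements(
            [r], [500.0, 1200.0, 2000.0], BOUNDS, np.random.default_rng(0), size=50
        )
        assert np.all(initials == 500.0)

    def test_reproducible_under_fixed_seed(self, eight_species, toy_design):
        cands = toy_design["R01"].elevations
        a, _, _ = resample_placements(eight_species, cands, BOUNDS, region_rng(5, "A"), size=20)
        b, _, _ = resample_placements(eight_species, cands, BOUNDS, region_rng(5, "A"), size=20)
        assert np.array_equal(a, b)


class TestEnvelope:
    def test_bounds_ordered_and_slope_negative(self, eight_species, toy_design):
        cfg = NullConfig(n_boot=2000, seed=1, bounds=BOUNDS)
        env = build_envelope(eight_species, cfg, design=toy_design, region="R01")
        assert np.all(env.lower <= env.upper)
        assert np.all(env.lower <= env.mean_expected + 1e-9)
        assert np.all(env.mean_expected <= env.upper + 1e-9)
        # geometric constraint + regression to the mean -> negative expected slope
        assert env.mean_slope < 0

    def test_zero_shifts_collapse_envelope(self, toy_design):
        records = [rec(f"s{i}", 500.0 + 150 * i, 0.0) for i in range(8)]
        cfg = NullConfig(n_boot=500, seed=2, bounds=BOUNDS)
        env = build_envelope(records, cfg, design=toy_design, region="R01")
        assert np.allclose(env.lower, 0.0, atol=1e-9)
        assert np.allclose(env.upper, 0.0, atol=1e-9)

    def test_lower_confidence_never_widens(self, eight_species, toy_design):
        wide = build_envelope(
            eight_species, NullConfig(n_boot=2000, seed=3, confidence=0.95, bounds=BOUNDS),
            design=toy_design, region="R01",
        )
        narrow = build_envelope(
            eight_species, NullConfig(n_boot=2000, seed=3, confidence=0.80, bounds=BOUNDS),
            design=toy_design, region="R01",
        )
        assert np.all(narrow.upper - narrow.lower <= wide.upper - wide.lower + 1e-9)

    def test_small_n_boot_warns(self, eight_species, toy_design):
        with pytest.warns(RuntimeWarning, match="n_boot"):
            build_envelope(
                eight_species, NullConfig(n_boot=50, seed=1, bounds=BOUNDS),
                design=toy_design, region="R01",
            )

    def test_grid200_narrower_than_observed_initials(self, toy_design):
        # the 200-point grid is the less conservative variant, the observed
        # initials the more conservative one
        rng = np.random.default_rng(8)
        widths = {"grid200": [], "observed_initials": []}
        records = []
        for i in range(12):
            x = float(rng.uniform(*BOUNDS))
            d = float(np.clip(rng.normal(0, 150), BOUNDS[0] - x, BOUNDS[1] - x))
            records.append(rec(f"s{i}", x, d, weight=int(rng.integers(2, 10))))
        for variant in widths:
            cfg = NullConfig(variant=variant, n_boot=3000, seed=4, bounds=BOUNDS)
            env = build_envelope(records, cfg, design=toy_design, region="R01")
            widths[variant] = np.mean(env.upper - env.lower)
        assert widths["grid200"] <= widths["observed_initials"]

    def test_region_substreams_independent(self, eight_species, toy_design):
        cfg = NullConfig(n_boot=200, seed=9, bounds=BOUNDS)
        recs_a = eight_species
        recs_b = [rec(r.species, r.limit_t1, r.shift, r.weight, region="B") for r in recs_a]
        env_a1 = build_envelope(recs_a, cfg, design=toy_design, region="R01")
        # interleave another region's computation; R01 must be unaffected
        build_envelope(recs_b, cfg, design=toy_design, region="R01",
                       rng=region_rng(9, "B"))
        env_a2 = build_envelope(recs_a, cfg, design=toy_design, region="R01")
        assert np.array_equal(env_a1.lower, env_a2.lower)
        assert np.array_equal(env_a1.upper, env_a2.upper)


class TestComparison:
    def _flat_envelope(self, lo, hi, n=100):
        grid = np.linspace(500, 2000, n)
        from upslope.nullmodel import NullEnvelope

        return NullEnvelope(
            grid=grid,
            lower=np.full(n, lo),
            upper=np.full(n, hi),
            mean_expected=np.full(n, (lo + hi) / 2),
            slopes=np.zeros(3),
        )

    def _fit(self, intercept, slope):
        x = np.array([500.0, 1250.0, 2000.0])
        y = intercept + slope * x
        return weighted_least_squares(x, y, None)

    def test_inside_everywhere_not_significant(self):
        comp = compare_to_null(self._fit(0.0, 0.0), self._flat_envelope(-50, 50))
        assert comp.prop_above == 0.0 and comp.prop_below == 0.0
        assert not comp.significant

    def test_partial_exceedance_fraction(self):
        # line rises through the upper bound at x = 1250 -> above at ~half the grid
        fit = self._fit(-0.04 * 1250.0, 0.04)
        comp = compare_to_null(fit, self._flat_envelope(-50, 0))
        assert comp.significant
        assert comp.prop_above == pytest.approx(0.5, abs=0.02)
        (lo_x, hi_x), = comp.above_ranges
        assert lo_x > 1250 - 30 and hi_x == 2000.0

    def test_below_at_high_elevation_reported(self):
        fit = self._fit(100.0, -0.1)  # drops below -50 beyond x = 1500
        comp = compare_to_null(fit, self._flat_envelope(-50, 200))
        assert comp.prop_below > 0 and comp.prop_above == 0.0
        (lo_x, hi_x), = comp.below_ranges
        assert lo_x > 1500 - 30 and hi_x == 2000.0


class TestNullDatasetRoundtrip:
    def test_realized_shifts_equal_supplied(self, toy_design):
        from upslope import compute_shifts

        rng = np.random.default_rng(21)
        shifts = np.clip(rng.normal(0, 150, 30), -1400, 1400)
        first, last, truth = generate_null_dataset(toy_design, shifts, rng=rng)
        recs = compute_shifts(first, last, 10)
        assert len(recs) == 30
        got = {r.species: r.shift for r in recs}
        for sp, d in zip(truth["species"], truth["shift"]):
            assert got[sp] == pytest.approx(d, abs=1e-9)

    def test_placements_respect_constraint(self, toy_design):
        rng = np.random.default_rng(22)
        shifts = np.clip(rng.normal(0, 300, 50), -1400, 1400)
        first, last, truth = generate_null_dataset(toy_design, shifts, rng=rng)
        lo, hi = toy_design["R01"].bounds
        assert first.occupancy["elevation"].between(lo, hi).all()
        assert last.occupancy["elevation"].between(lo, hi).all()
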