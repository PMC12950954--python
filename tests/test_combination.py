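import numpy as np
import pytest

from fragsense.combination import (
    DoseResponseMatrix,
    HormesisError,
    PlateError,
    compare_groups,
    detect_hormesis,
    dose_sparing,
    enhancement_delta,
    normalize_viability,
    significance_stars,
    vehicle_dilution_percent,
)


def make_matrix(values, doses_a=(0.0, 0.1, 1.0), doses_b=(0.0, 10.0), reps=None):
    """values: dict (a, b) -> list of replicates; missing cells get [1.0]."""
    signals = {}
    for a in doses_a:
        for b in doses_b:
            signals[(a, b)] = values.get((a, b), reps or [1.0])
    return DoseResponseMatrix(doses_a, doses_b, signals, cell_line="test")


class TestNormalize:
    def test_treated_cell_halved(self):
        m = make_matrix({(0.0, 0.0): [1.0, 1.0], (1.0, 10.0): [0.5, 0.5]})
        v = normalize_viability(m)
        assert v.mean_percent.loc[1.0, 10.0] == pytest.approx(50.0)
        assert v.mean_percent.loc[0.0, 0.0] == 100.0

    def test_uniform_plate_all_hundred(self):
        v = normalize_viability(make_matrix({}, reps=[2.0, 2.0]))
        assert (v.mean_percent.to_numpy() == 100.0).all()

    def test_simple_ratio(self):
        m = make_matrix({(0.0, 0.0): [2.0], (0.1, 0.0): [1.76]})
        v = normalize_viability(m)
        assert v.mean_percent.loc[0.1, 0.0] == pytest.approx(88.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        base = {
            (a, b): rng.uniform(0.5, 2.0, 4)
            for a in (0.0, 0.1, 1.0) for b in (0.0, 10.0)
        }
        v1 = normalize_viability(make_matrix(base))
        scaled = {k: 7.3 * np.asarray(vv) for k, vv in base.items()}
        v2 = normalize_viability(make_matrix(scaled))
        assert np.allclose(v1.mean_percent.to_numpy(), v2.mean_percent.to_numpy())
        assert np.allclose(v1.sem_percent.to_numpy(), v2.sem_percent.to_numpy())

    def test_nonpositive_control_rejected(self):
        m = make_matrix({(0.0, 0.0): [0.0]})
        with pytest.raises(PlateError):
            normalize_viability(m)

    def test_missing_control_cell_rejected(self):
        signals = {
            (a, b): [1.0] for a in (0.0, 0.1, 1.0) for b in (0.0, 10.0)
        }
        del signals[(0.0, 0.0)]
        with pytest.raises(PlateError):
            DoseResponseMatrix((0.0, 0.1, 1.0), (0.0, 10.0), signals)


class TestEnhancement:
    @pytest.fixture()
    def summary(self):
        return normalize_viability(
            make_matrix({(0.1, 0.0): [0.70], (0.1, 10.0): [0.58]})
        )

    def test_headline_style_delta(self, summary):
        # drug alone 70%, combination 58% -> 12-point sensitisation
        assert enhancement_delta(summary, 0.1, 10.0) == pytest.approx(12.0)

    def test_zero_sensitiser_dose_is_exactly_zero(self, summary):
        assert enhancement_delta(summary, 0.1, 0.0) == 0.0

    def test_antagonism_reported_negative(self):
        v = normalize_viability(
            make_matrix({(0.1, 0.0): [0.58], (0.1, 10.0): [0.70]})
        )
        assert enhancement_delta(v, 0.1, 10.0) == pytest.approx(-12.0)

    def test_missing_cell_rejected(self, summary):
        with pytest.raises(PlateError):
            enhancement_delta(summary, 0.25, 10.0)


def column_matrix(alone, combo, doses):
    """Two-column plate with deterministic single-replicate signals."""
    signals = {(0.0, 0.0): [100.0], (0.0, 10.0): [100.0]}
    for dose, va, vc in zip(doses, alone, combo):
        signals[(dose, 0.0)] = [va]
        signals[(dose, 10.0)] = [vc]
    return DoseResponseMatrix((0.0, *doses), (0.0, 10.0), signals)


class TestDoseSparing:
    DOSES = (0.01, 0.03, 0.1, 0.3, 1.0)

    def test_identical_columns_spare_nothing(self):
        curve = [95.0, 85.0, 60.0, 40.0, 30.0]
        v = normalize_viability(column_matrix(curve, curve, self.DOSES))
        assert dose_sparing(v, 10.0, 70.0) == pytest.approx(0.0, abs=1e-12)

    def test_left_shifted_copy_gives_the_shift(self):
        """A combination curve equal to the drug-alone curve at 0.9x dose
        yields sparing 0.10 exactly.  The curve is linear in log10 dose, so
        the 0.9x rescaling is a uniform shift and the piecewise-linear
        inversion reproduces it without discretisation error."""
        slope = 25.0
        alone = [90.0 - slope * (np.log10(d) + 2) for d in self.DOSES]
        shift = slope * np.log10(1 / 0.9)
        combo = [v - shift for v in alone]
        v = normalize_viability(column_matrix(alone, combo, self.DOSES))
        assert dose_sparing(v, 10.0, 70.0) == pytest.approx(0.10, abs=1e-9)

    def test_target_outside_range_names_interval(self):
        curve = [95.0, 85.0, 60.0, 40.0, 30.0]
        v = normalize_viability(column_matrix(curve, curve, self.DOSES))
        with pytest.raises(PlateError, match="achievable interval"):
            dose_sparing(v, 10.0, 10.0)

    def test_biphasic_column_raises_hormesis_error(self):
        alone = [95.0, 60.0, 40.0, 60.0, 30.0]  # re-crosses 50%
        v = normalize_viability(column_matrix(alone, alone, self.DOSES))
        with pytest.raises(HormesisError):
            dose_sparing(v, 10.0, 50.0)

    def test_sparing_monotone_in_potency_shift(self):
        """Stronger simulated potency shifts yield larger estimated sparing."""
        from fragsense.synthetic_data import HillParams, generate_dose_response

        estimates = []
        for rho in (0.0, 0.1, 0.2, 0.4):
            p = HillParams(noise_sd=0.0, rho=rho)
            v = normalize_viability(generate_dose_response(p=p))
            estimates.append(dose_sparing(v, 10.0, 57.5))
        assert estimates == sorted(estimates)
        assert estimates[0] == pytest.approx(0.0, abs=1e-12)


class TestHormesis:
    def build(self, means, sems=1.0, n=4):
        rng = np.random.default_rng(0)
        doses = (0.0, *[0.01 * 3 ** i for i in range(len(means) - 1)])
        signals = {}
        for dose, mean in zip(doses, means):
            # replicates with the requested SEM, mean exact
            sd = sems * np.sqrt(n)
            reps = rng.normal(0, 1, n)
            reps = (reps - reps.mean()) / reps.std(ddof=1) * sd + mean
            signals[(dose, 0.0)] = reps
        m = DoseResponseMatrix(doses, (0.0,), signals)
        return normalize_viability(m)

    def test_strictly_decreasing_curve_not_flagged(self):
        v = self.build([100.0, 90.0, 80.0, 70.0, 60.0])
        flag, locations = detect_hormesis(v, 0.0)
        assert (flag, locations) == (False, [])

    def test_rebound_flagged_at_the_offending_pair(self):
        v = self.build([100.0, 80.0, 60.0, 75.0])
        flag, locations = detect_hormesis(v, 0.0)
        assert flag
        doses = list(v.mean_percent.index)
        assert (doses[2], doses[3]) in locations

    def test_needs_three_points(self):
        v = self.build([100.0, 90.0])
        with pytest.raises(PlateError):
            detect_hormesis(v, 0.0)


class TestCompareGroups:
    def test_identical_constant_groups_degenerate_to_p_one(self):
        res = compare_groups([[5.0, 5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert res.f_statistic == 0.0 and res.p_value == 1.0
        assert (res.pairwise["p_adj"] == 1.0).all()

    def test_well_separated_groups_are_significant(self):
        rng = np.random.default_rng(1)
        res = compare_groups([rng.normal(0, 0.1, 10), rng.normal(10, 0.1, 10)])
        assert res.p_value < 1e-6
        assert res.pairwise["stars"].iloc[0] == "****"

    def test_f_statistic_matches_hand_computed_sums_of_squares(self):
        groups = [[6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]]
        # independent arithmetic: F = (SSB/(k-1)) / (SSW/(N-k))
        means = [np.mean(g) for g in groups]
        grand = np.mean(np.concatenate(groups))
        ssb = sum(len(g) * (m - grand) ** 2 for g, m in zip(groups, means))
        ssw = sum(((np.asarray(g) - m) ** 2).sum() for g, m in zip(groups, means))
        f_ref = (ssb / 2) / (ssw / 15)
        res = compare_groups(groups)
        assert res.f_statistic == pytest.approx(f_ref, abs=1e-6)

    def test_underpowered_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1.0], [1.0, 2.0]])

    @pytest.mark.parametrize(
        "p, stars",
        [(0.2, "ns"), (0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.00004, "****")],
    )
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars


def test_vehicle_dilution_arithmetic():
    # a 5000-fold dilution of neat DMSO leaves 0.02% v/v
    assert vehicle_dilution_percent(5000) == 0.02
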