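"""Shift calling: matching oracle, Welch test, rule fidelity, coefficients."""

import itertools

import numpy as np
import pytest
from scipy import stats

from rdeep.fitting import fit_mixture
from rdeep.shifts import (
    PeakPairing,
    ShiftConfig,
    call_shift,
    call_shifts_for_protein,
    classify_dependence,
    match_peaks,
    shifting_coefficient,
    summarize_screen,
)
from rdeep.shifts import test_amplitude_difference as amplitude_difference
from rdeep.simulate import GaussianPeak, ShiftScenario, gaussian_curve
from tests.conftest import make_fit, peak_with_grid_area, replicate_curves


def two_sided_fit(mus, areas=None, condition="CTRL", width=1.5):
    areas = areas or [100.0 / len(mus)] * len(mus)
    peaks = [peak_with_grid_area(a, m, width) for a, m in zip(areas, mus)]
    return make_fit(peaks, condition=condition)


class TestMatchPeaks:
    def test_single_pair_distance(self):
        pairs = match_peaks(two_sided_fit([12.0]), two_sided_fit([9.0], condition="RNASE"))
        assert len(pairs) == 1
        assert pairs[0].distance == pytest.approx(-3.0)

    def test_lost_peak_becomes_one_sided(self):
        pairs = match_peaks(two_sided_fit([10.0, 22.0]), two_sided_fit([10.0], condition="RNASE"))
        paired = [p for p in pairs if p.control_peak and p.rnase_peak]
        lost = [p for p in pairs if p.rnase_peak is None]
        assert len(paired) == 1 and paired[0].control_peak.position == pytest.approx(10.0)
        assert len(lost) == 1 and lost[0].control_peak.position == pytest.approx(22.0)

    def test_uncrossed_assignment_preferred(self):
        pairs = match_peaks(two_sided_fit([5.0, 15.0]), two_sided_fit([6.0, 14.0], condition="RNASE"))
        ds = sorted(round(p.distance, 6) for p in pairs)
        assert ds == [-1.0, 1.0]  # (5,6) and (15,14), total 2, not the crossed 20

    @pytest.mark.parametrize("n_ctrl,n_rnase", [(2, 2), (3, 3), (3, 2)])
    def test_exhaustive_assignment_oracle(self, n_ctrl, n_rnase):
        """Optimal assignment equals brute force over all injections."""
        rng = np.random.default_rng(n_ctrl * 10 + n_rnase)
        for _ in range(10):
            cmu = np.sort(rng.uniform(2, 24, n_ctrl))
            rmu = np.sort(rng.uniform(2, 24, n_rnase))
            cfit = two_sided_fit(list(cmu))
            rfit = two_sided_fit(list(rmu), condition="RNASE")
            pairs = match_peaks(cfit, rfit, ShiftConfig(max_match_distance=30))
            got = sum(abs(p.distance) for p in pairs if p.distance is not None)
            k = min(n_ctrl, n_rnase)
            best = min(
                sum(abs(rmu[j] - cmu[i]) for i, j in zip(ci, rj))
                for ci in itertools.permutations(range(n_ctrl), k)
                for rj in [range(k)]
                for rj in itertools.combinations(range(n_rnase), k)
            ) if n_ctrl <= n_rnase else min(
                sum(abs(rmu[list(rj)[t]] - cmu[list(ci)[t]]) for t in range(k))
                for ci in itertools.combinations(range(n_ctrl), k)
                for rj in itertools.permutations(range(n_rnase), k)
            )
            assert got == pytest.approx(best, abs=1e-9)


class TestAmplitudeTest:
    def test_identical_replicates_p_one(self):
        reps = replicate_curves(gaussian_curve([GaussianPeak(10, 12, 1.5)]))
        assert amplitude_difference(reps, reps, 12.0) == 1.0

    def test_clear_separation_small_p(self):
        a = np.zeros((3, 25)); a[:, 11] = [10.0, 10.0, 10.0]
        b = np.zeros((3, 25)); b[:, 11] = [0.001, 0.002, 0.0015]
        p = amplitude_difference(a, b, 12.0)
        assert p < 0.001

    def test_matches_welch_closed_form(self):
        a = np.zeros((3, 25)); a[:, 5] = [9.8, 10.1, 10.4]
        b = np.zeros((3, 25)); b[:, 5] = [5.2, 5.5, 4.9]
        p = amplitude_difference(a, b, 6.0)
        expected = stats.ttest_ind(a[:, 5], b[:, 5], equal_var=False).pvalue
        assert p == pytest.approx(expected, rel=1e-12)

    def test_label_swap_symmetry(self):
        a = replicate_curves(gaussian_curve([GaussianPeak(10, 12, 1.5)]), jitter=0.1, seed=1)
        b = replicate_curves(gaussian_curve([GaussianPeak(6, 12, 1.5)]), jitter=0.1, seed=2)
        assert amplitude_difference(a, b, 12.0) == pytest.approx(
            amplitude_difference(b, a, 12.0), rel=1e-12
        )

    def test_single_replicate_untestable(self):
        a = np.zeros((1, 25)); b = np.zeros((3, 25))
        assert np.isnan(amplitude_difference(a, b, 5))


class CallFixture:
    """A control/RNase fit pair with replicate curves carrying tiny jitter."""

    def __init__(self, ctrl_fit, rnase_fit, jitter=0.02):
        self.ctrl = ctrl_fit
        self.rnase = rnase_fit
        self.ctrl_reps = replicate_curves(ctrl_fit.fitted_curve, jitter=jitter, seed=5)
        self.rnase_reps = replicate_curves(rnase_fit.fitted_curve, jitter=jitter, seed=6)

    def call_all(self, cfg=None):
        return call_shifts_for_protein(
            "P", self.ctrl, self.rnase, self.ctrl_reps, self.rnase_reps, cfg
        ).shift_calls


class TestCallShift:
    def test_three_fraction_left_shift_called(self):
        fx = CallFixture(two_sided_fit([12.0]), two_sided_fit([9.0], condition="RNASE"))
        calls = fx.call_all()
        assert len(calls) == 1
        c = calls[0]
        assert c.significant and c.direction == "left"
        assert min(c.p_control_max, c.p_rnase_max) < 0.001

    def test_sub_fraction_distance_never_called(self):
        """|distance| = 0.8 fails the rule regardless of p-value."""
        fx = CallFixture(two_sided_fit([12.0]), two_sided_fit([11.2], condition="RNASE"))
        calls = fx.call_all()
        assert not any(c.significant for c in calls)
        assert all(c.direction == "none" for c in calls)

    def test_distance_exactly_one_not_called(self):
        fx = CallFixture(two_sided_fit([12.0]), two_sided_fit([11.0], condition="RNASE"))
        assert not any(c.significant for c in fx.call_all())

    def test_gained_peak_past_boundary_is_precipitation(self):
        ctrl = two_sided_fit([12.0])
        rnase = make_fit(
            [peak_with_grid_area(60.0, 12.0, 1.5), peak_with_grid_area(40.0, 24.2, 1.0)],
            condition="RNASE",
        )
        fx = CallFixture(ctrl, rnase)
        calls = fx.call_all()
        prec = [c for c in calls if c.direction == "precipitation"]
        assert len(prec) == 1 and prec[0].significant

    def test_insignificant_amplitude_blocks_call(self):
        # same curves in both conditions but shifted fits would need distance;
        # identical replicate data at maxima -> p = 1 -> no call
        ctrl = two_sided_fit([12.0])
        rnase = two_sided_fit([9.0], condition="RNASE")
        reps = replicate_curves(ctrl.fitted_curve)  # identical in both conditions
        call = call_shift(match_peaks(ctrl, rnase)[0], ctrl, rnase, reps, reps)
        assert not call.significant

    def test_label_swap_inverts_direction(self):
        ctrl = two_sided_fit([12.0])
        rnase = two_sided_fit([8.0], condition="RNASE")
        fx = CallFixture(ctrl, rnase)
        fwd = fx.call_all()[0]
        swapped = call_shifts_for_protein(
            "P", fx.rnase, fx.ctrl, fx.rnase_reps, fx.ctrl_reps
        ).shift_calls[0]
        assert fwd.significant == swapped.significant
        assert (fwd.direction, swapped.direction) == ("left", "right")


class TestShiftingCoefficient:
    def test_identical_curves_sc_zero(self):
        f1 = two_sided_fit([12.0])
        f2 = two_sided_fit([12.0], condition="RNASE")
        sc = shifting_coefficient(match_peaks(f1, f2)[0], f1, f2)
        assert sc == 0.0

    def test_complete_shift_sc_one(self):
        ctrl = two_sided_fit([20.0], width=1.0)
        rnase = two_sided_fit([5.0], condition="RNASE", width=1.0)
        pairing = PeakPairing(ctrl.peaks[0], rnase.peaks[0])
        assert shifting_coefficient(pairing, ctrl, rnase) == pytest.approx(1.0, abs=1e-9)

    def test_half_amount_half_amplitude_gives_quarter(self):
        """A peak holding 50% of the protein whose maximum drops to half:
        SC = 0.5 x 0.5 = 0.25."""
        p1 = peak_with_grid_area(50.0, 8.0, 1.0)
        p2 = peak_with_grid_area(50.0, 20.0, 1.0)
        ctrl = make_fit([p1, p2])
        rnase = make_fit(
            [GaussianPeak(p1.amplitude / 2, 8.0, 1.0), p2, peak_with_grid_area(25.0, 3.0, 1.0)],
            condition="RNASE",
        )
        pairing = PeakPairing(p1, rnase.peaks[1])  # the halved peak at mu=8
        assert shifting_coefficient(pairing, ctrl, rnase) == pytest.approx(0.25, abs=1e-6)

    def test_sc_monotone_in_moved_amount_noiseless(self):
        scs = []
        for m in [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]:
            if m == 0:
                scen = ShiftScenario("none", [(1.0, 15, 1.5)], [(1.0, 15, 1.5)], 0.0)
            elif m == 1:
                scen = ShiftScenario("left_complete", [(1.0, 15, 1.5)], [(1.0, 8, 1.5)], 1.0)
            else:
                scen = ShiftScenario(
                    "left_partial", [(1.0, 15, 1.5)],
                    [(round(1 - m, 3), 15, 1.5), (m, 8, 1.5)], m,
                )
            ctrl = fit_mixture(gaussian_curve(scen.peaks_for("CTRL")))
            rnase = fit_mixture(gaussian_curve(scen.peaks_for("RNASE")))
            rnase.condition = "RNASE"
            pairing = next(
                p for p in match_peaks(ctrl, rnase)
                if p.control_peak is not None
            )
            scs.append(shifting_coefficient(pairing, ctrl, rnase))
        assert all(b >= a - 1e-9 for a, b in zip(scs, scs[1:]))
        assert scs[0] == pytest.approx(0.0, abs=1e-6)
        assert scs[-1] == pytest.approx(1.0, abs=1e-3)
        # on noiseless data SC tracks the moved amount itself
        assert np.allclose(scs[1:-1], [0.2, 0.4, 0.6, 0.8], atol=0.02)


class TestClassification:
    def _call(self, sc, significant=True):
        pairing = PeakPairing(GaussianPeak(1, 10, 1), GaussianPeak(1, 5, 1))
        from rdeep.shifts import ShiftCall

        return ShiftCall(pairing, 0.01, 0.01, significant, "left", sc, 1.0)

    def test_no_significant_shift_independent(self):
        assert classify_dependence([self._call(0.9, significant=False)]) == "independent"
        assert classify_dependence([]) == "independent"

    def test_sc_one_complete(self):
        assert classify_dependence([self._call(1.0)]) == "complete"

    def test_sc_quarter_partial(self):
        assert classify_dependence([self._call(0.25)]) == "partial"

    def test_threshold_boundary(self):
        assert classify_dependence([self._call(0.75)]) == "complete"
        assert classify_dependence([self._call(0.7499)]) == "partial"


class TestSummarize:
    def _result(self, pid, directions, significant=True):
        from rdeep.shifts import ProteinResult, ShiftCall

        calls = [
            ShiftCall(
                PeakPairing(GaussianPeak(1, 10, 1), GaussianPeak(1, 5, 1)),
                0.01, 0.01, significant, d, 0.5, 1.0,
            )
            for d in directions
        ]
        r = ProteinResult(protein_id=pid, shift_calls=calls)
        r.n_left = directions.count("left")
        r.n_right = directions.count("right")
        r.n_precipitated = directions.count("precipitation")
        return r

    def test_counts_and_novelty(self):
        import pandas as pd

        results = [
            self._result("A", ["left"]),
            self._result("B", ["left"]),
            self._result("C", [], significant=False),
            self._result("D", [], significant=False),
            self._result("E", [], significant=False),
        ]
        ann = pd.DataFrame(
            {"protein_id": list("ABCDE"),
             "rbp_listed": [True, False, True, False, False],
             "rbp2go_score": [30.0, 5.0, 12.0, 1.0, 2.0]}
        ).set_index("protein_id", drop=False)
        s = summarize_screen(results, ann)
        assert s["n_shifting"] == 2
        assert s["n_novel_candidates"] == 1  # B shifts but is not listed
        assert s["mean_rbp2go_shifting"] == pytest.approx(30.0)
        assert s["mean_rbp2go_nonshifting"] == pytest.approx(12.0)

    def test_multi_direction_protein_counts_in_each_category(self):
        s = summarize_screen([self._result("A", ["left", "precipitation"])])
        assert s["n_left_shifts"] == 1 and s["n_precipitations"] == 1
        assert s["n_shifting"] == 1

    def test_without_annotations_novelty_unknown(self):
        results = [self._result("A", ["left"])]
        s = summarize_screen(results)
        assert s["n_novel_candidates"] is None
        assert results[0].novelty == "unknown"
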