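import math
import random

import pytest

from cqscreen import (
    HitCall,
    HitStatus,
    ScreenError,
    WellRecord,
    WellRole,
    call_hits,
    confirm_hits,
    counter_screen_filter,
    deconvolution_plan,
    delta_cq_table,
    qc_metrics,
    round_sig,
    screen_summary,
    threshold_from_sd,
)


def _neg(plate, well, cq):
    return WellRecord(plate, well, WellRole.NEGATIVE_CONTROL, cq=cq)


def _inhib(plate, well, cq):
    return WellRecord(
        plate, well, WellRole.INHIBITED_CONTROL, content=("REF",), i_tot=2500.0, cq=cq
    )


def _test(plate, well, cq, content=("C1",), pool=None):
    return WellRecord(
        plate, well, WellRole.TEST, content=content, i_tot=9000.0, pool_id=pool, cq=cq
    )


class TestWellRecord:
    def test_bad_label(self):
        with pytest.raises(ValueError):
            WellRecord("p1", "Z1", WellRole.TEST, content=("C1",), i_tot=1.0)
        with pytest.raises(ValueError):
            WellRecord("p1", "A25", WellRole.TEST, content=("C1",), i_tot=1.0)

    def test_role_content_invariants(self):
        with pytest.raises(ValueError):
            WellRecord("p1", "A1", WellRole.NEGATIVE_CONTROL, content=("C1",))
        with pytest.raises(ValueError):
            WellRecord("p1", "A1", WellRole.TEST, content=())
        with pytest.raises(ValueError):
            WellRecord("p1", "A1", WellRole.POSITIVE_CONTROL, content=("REF",))


class TestDeltaCqTable:
    def test_simple_arithmetic(self):
        wells = [_neg("p1", "A1", 9.8), _neg("p1", "A2", 10.0), _test("p1", "B1", 10.7)]
        dcq = delta_cq_table(wells)
        assert dcq["p1:B1"] == pytest.approx(0.8)

    def test_equal_to_mean_gives_zero(self):
        wells = [_neg("p1", "A1", 9.8), _neg("p1", "A2", 10.0), _test("p1", "B1", 9.9)]
        assert delta_cq_table(wells)["p1:B1"] == pytest.approx(0.0)

    def test_full_window_shift(self):
        wells = [_neg("p1", "A1", 9.89), _neg("p1", "A2", 9.89), _test("p1", "B1", 22.92)]
        assert delta_cq_table(wells)["p1:B1"] == pytest.approx(13.03)

    def test_negative_controls_average_to_zero(self):
        wells = [_neg("p1", "A1", 9.7), _neg("p1", "A2", 10.1), _neg("p1", "A3", 9.9)]
        dcq = delta_cq_table(wells)
        assert sum(dcq.values()) == pytest.approx(0.0, abs=1e-12)

    def test_censored_propagates(self):
        wells = [_neg("p1", "A1", 9.8), _neg("p1", "A2", 10.0), _test("p1", "B1", None)]
        assert delta_cq_table(wells)["p1:B1"] is None

    def test_requires_negative_controls(self):
        with pytest.raises(ScreenError):
            delta_cq_table([_test("p1", "B1", 10.0)])
        with pytest.raises(ScreenError):
            delta_cq_table([_neg("p1", "A1", 9.8), _test("p1", "B1", 10.0)])

    def test_per_plate_baselines(self):
        wells = [
            _neg("p1", "A1", 9.0), _neg("p1", "A2", 9.0), _test("p1", "B1", 10.0),
            _neg("p2", "A1", 11.0), _neg("p2", "A2", 11.0), _test("p2", "B1", 12.0),
        ]
        dcq = delta_cq_table(wells)
        assert dcq["p1:B1"] == pytest.approx(1.0)
        assert dcq["p2:B1"] == pytest.approx(1.0)


def _controls(neg_mean, neg_sd, pos_mean, pos_sd, n=4):
    """Control wells whose sample mean/SD exactly match the requested values."""
    half = n // 2
    wells = []
    for i in range(n):
        delta = neg_sd * math.sqrt((n - 1) / n) if i < half else -neg_sd * math.sqrt((n - 1) / n)
        wells.append(_neg("p1", f"A{i + 1}", neg_mean + delta))
    for i in range(n):
        delta = pos_sd * math.sqrt((n - 1) / n) if i < half else -pos_sd * math.sqrt((n - 1) / n)
        wells.append(_inhib("p1", f"B{i + 1}", pos_mean + delta))
    return wells


class TestQcMetrics:
    def test_pooled_screen_statistics(self):
        qc = qc_metrics(_controls(9.89, 0.14, 22.92, 0.11))
        assert qc.neg_mean == pytest.approx(9.89)
        assert qc.neg_sd == pytest.approx(0.14)
        assert round(qc.assay_window, 2) == 13.03
        assert round(qc.z_prime, 2) == 0.94

    def test_individual_screen_statistics(self):
        qc = qc_metrics(_controls(10.22, 0.18, 22.85, 0.18))
        assert round(qc.assay_window, 2) == 12.63
        # formula applied to these controls yields 0.91 (see notes)
        assert round(qc.z_prime, 2) == 0.91

    def test_noiseless_z_prime_is_one(self):
        qc = qc_metrics(_controls(10.0, 0.0, 23.0, 0.0))
        assert qc.z_prime == 1.0

    def test_fold_range(self):
        qc = qc_metrics(_controls(10.0, 0.0, 23.0, 0.0))
        assert qc.fold_range(1.0) == pytest.approx(2**13)

    def test_insufficient_controls(self):
        with pytest.raises(ScreenError):
            qc_metrics([_neg("p1", "A1", 9.9), _inhib("p1", "B1", 22.9)])


class TestThresholdFromSd:
    def test_pooled_multiplier(self):
        assert threshold_from_sd(0.09, 8.0) == pytest.approx(0.72)

    def test_individual_multiplier(self):
        assert threshold_from_sd(0.18, 3.0) == pytest.approx(0.54)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_sd(0.09, 0.0)
        with pytest.raises(ValueError):
            threshold_from_sd(0.0, 3.0)


class TestCallHits:
    def test_threshold_classification(self):
        calls = call_hits({"p1:A1": 0.85, "p1:A2": 0.30}, 0.80)
        by = {c.subject: c.status for c in calls}
        assert by["p1:A1"] is HitStatus.INITIAL_HIT
        assert by["p1:A2"] is HitStatus.INACTIVE

    def test_threshold_is_inclusive(self):
        calls = call_hits({"p1:A1": 0.80}, 0.80)
        assert calls[0].status is HitStatus.INITIAL_HIT

    def test_empty_table(self):
        assert call_hits({}, 0.80) == []

    def test_censored_is_hit(self):
        calls = call_hits({"p1:A1": None}, 0.80)
        assert calls[0].status is HitStatus.INITIAL_HIT
        assert math.isinf(calls[0].delta_cq)

    def test_order_independent(self):
        dcq = {f"p1:A{i + 1}": 0.1 * i for i in range(10)}
        shuffled = list(dcq.items())
        random.Random(3).shuffle(shuffled)
        assert call_hits(dict(shuffled), 0.5) == call_hits(dcq, 0.5)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            call_hits({"p1:A1": 1.0}, 0.0)


class TestCounterScreenFilter:
    def _hit(self, subject, dcq=1.0, pool="P1"):
        return HitCall(subject=subject, delta_cq=dcq, status=HitStatus.INITIAL_HIT, pool_id=pool)

    def test_reactive_hit_becomes_interferer(self):
        out = counter_screen_filter([self._hit("p1:A1")], {"p1:A1": 1.2}, 0.5)
        assert out[0].status is HitStatus.INTERFERER
        assert out[0].counter_delta_cq == pytest.approx(1.2)

    def test_quiet_hit_retained(self):
        out = counter_screen_filter([self._hit("p1:A1")], {"p1:A1": 0.05}, 0.5)
        assert out[0].status is HitStatus.INITIAL_HIT
        assert out[0].counter_delta_cq == pytest.approx(0.05)

    def test_missing_counter_measurement_retained_with_note(self):
        out = counter_screen_filter([self._hit("p1:A1")], {}, 0.5)
        assert out[0].status is HitStatus.INITIAL_HIT
        assert "unresolved" in out[0].note

    def test_non_hits_untouched(self):
        inactive = HitCall(subject="p1:A2", delta_cq=0.1, status=HitStatus.INACTIVE)
        out = counter_screen_filter([inactive], {"p1:A2": 5.0}, 0.5)
        assert out[0] == inactive

    def test_status_never_upgrades(self):
        # pipeline is monotone: filtering can only demote initial hits
        hits = [self._hit("p1:A1"), HitCall("p1:A2", 0.2, HitStatus.INACTIVE)]
        out = counter_screen_filter(hits, {"p1:A1": 9.9, "p1:A2": 9.9}, 0.5)
        assert out[0].status is HitStatus.INTERFERER
        assert out[1].status is HitStatus.INACTIVE


class TestDeconvolutionPlan:
    def test_single_pool_expands_fully(self):
        hits = [HitCall("p1:C5", 1.0, HitStatus.INITIAL_HIT, pool_id="P1")]
        pool_map = {"P1": tuple(f"C{i}" for i in range(11))}
        plan = deconvolution_plan(hits, pool_map)
        assert len(plan) == 11
        assert all(conc == 10_000.0 for _, conc in plan)

    def test_no_hits_empty_plan(self):
        assert deconvolution_plan([], {"P1": ("C1",)}) == []

    def test_disjoint_pools_union(self):
        hits = [
            HitCall("p1:A1", 1.0, HitStatus.INITIAL_HIT, pool_id="P1"),
            HitCall("p1:A2", 1.0, HitStatus.INITIAL_HIT, pool_id="P2"),
        ]
        pool_map = {
            "P1": tuple(f"C{i}" for i in range(11)),
            "P2": tuple(f"D{i}" for i in range(11)),
        }
        assert len(deconvolution_plan(hits, pool_map)) == 22

    def test_shared_compound_listed_once(self):
        hits = [
            HitCall("p1:A1", 1.0, HitStatus.INITIAL_HIT, pool_id="P1"),
            HitCall("p1:A2", 1.0, HitStatus.INITIAL_HIT, pool_id="P2"),
        ]
        plan = deconvolution_plan(hits, {"P1": ("C1", "C2"), "P2": ("C2", "C3")})
        assert [cid for cid, _ in plan] == ["C1", "C2", "C3"]

    def test_interferers_not_retested(self):
        hits = [HitCall("p1:A1", 1.0, HitStatus.INTERFERER, pool_id="P1")]
        assert deconvolution_plan(hits, {"P1": ("C1",)}) == []

    def test_unknown_pool_named_in_error(self):
        hits = [HitCall("p1:A1", 1.0, HitStatus.INITIAL_HIT, pool_id="P9")]
        with pytest.raises(ScreenError, match="P9"):
            deconvolution_plan(hits, {"P1": ("C1",)})


class TestConfirmHits:
    def test_two_confirmed_from_one_pool(self):
        dcq = {"C1": 1.1, "C2": 0.9, "C3": 0.1, "C4": 0.2}
        calls = confirm_hits(dcq, 0.8)
        confirmed = [c.subject for c in calls if c.status is HitStatus.CONFIRMED_HIT]
        assert confirmed == ["C1", "C2"]

    def test_none_confirmed(self):
        calls = confirm_hits({"C1": 0.1, "C2": 0.2}, 0.8)
        assert all(c.status is HitStatus.NOT_CONFIRMED for c in calls)


class TestScreenSummary:
    def _initial(self, n):
        return [
            HitCall(f"p1:A{i + 1}", 1.0, HitStatus.INITIAL_HIT, pool_id=f"P{i}")
            for i in range(n)
        ]

    def test_predeconvolution_rate(self):
        summary = screen_summary(self._initial(24), 5280)
        assert summary.initial_hit_rate_pct == 0.45

    def test_postcounter_rate(self):
        calls = self._initial(4) + [
            HitCall(f"p1:B{i + 1}", 1.0, HitStatus.INTERFERER) for i in range(20)
        ]
        summary = screen_summary(calls, 5280)
        assert summary.n_initial_hits == 24
        assert summary.n_surviving_hits == 4
        assert summary.surviving_hit_rate_pct == 0.076

    def test_zero_hits(self):
        summary = screen_summary([], 5280)
        assert summary.initial_hit_rate_pct == 0.0
        assert summary.n_initial_hits == 0

    def test_invalid_library_size(self):
        with pytest.raises(ValueError):
            screen_summary([], 0)


class TestRoundSig:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.4545, 0.45), (0.07576, 0.076), (0.0, 0.0), (13.03, 13.0), (123.4, 120.0)],
    )
    def test_two_significant_figures(self, value, expected):
        assert round_sig(value, 2) == expected
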