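"""Coincidence matching, outcome routes, ordering, correlations, rates."""

import numpy as np
import pytest

from splicekin import (AcquisitionConfig, EventInterval, Outcome,
                       background_rate, classify_outcomes, dwell_correlation,
                       make_fixture, match_coincident, multi_binding_summary,
                       ordering_offsets, preset_scheme, randomized_control,
                       rebinding_analysis, simulate_molecules)
from splicekin.io import truths_to_events


def _ev(mol, chan, t0, t1, censored=False):
    return EventInterval(mol, chan, t0, t1, censored)


class TestMatchCoincident:
    def test_identical_starts_all_paired(self):
        a = [_ev(0, "U5", 10.0, 50.0), _ev(0, "U5", 100.0, 130.0)]
        b = [_ev(0, "U4", 10.0, 40.0), _ev(0, "U4", 100.0, 120.0)]
        pairs, oa, ob = match_coincident(a, b, 3.0)
        assert len(pairs) == 2 and not oa and not ob

    def test_offset_beyond_tolerance_unpaired(self):
        a = [_ev(0, "U5", 10.0, 50.0)]
        b = [_ev(0, "U4", 16.0, 40.0)]  # two frames late, tolerance one
        pairs, oa, ob = match_coincident(a, b, 3.0)
        assert not pairs and len(oa) == 1 and len(ob) == 1

    def test_symmetric_under_channel_swap(self):
        # generic channels exercise the positional transposition
        a = [_ev(0, "A", 10.0, 50.0), _ev(0, "A", 11.0, 90.0)]
        b = [_ev(0, "B", 9.0, 40.0)]
        p1, _, _ = match_coincident(a, b, 3.0)
        p2, _, _ = match_coincident(b, a, 3.0)
        assert [(p.u4.t_start, p.u5.t_start) for p in p1] == \
            [(p.u5.t_start, p.u4.t_start) for p in p2]

    def test_intervals_used_at_most_once(self):
        a = [_ev(0, "U5", 10.0, 50.0), _ev(0, "U5", 12.0, 60.0)]
        b = [_ev(0, "U4", 11.0, 40.0)]
        pairs, oa, _ = match_coincident(a, b, 3.0)
        assert len(pairs) == 1 and len(oa) == 1
        # equidistant candidates: stream order breaks the tie
        assert pairs[0].u5.t_start == 10.0

    def test_printed_coincident_fraction(self):
        fx = make_fixture("coincidence",
                          {"paired": 551, "only_a": 325, "only_b": 465})
        pairs, only_u5, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        frac = len(pairs) / (len(pairs) + len(only_u5))
        assert round(100 * frac) == 63  # 551 of 876 U5 arrivals


class TestClassifyOutcomes:
    def test_route_rules(self):
        pairs, _, _ = match_coincident(
            [_ev(0, "U5", 10.0, 500.0), _ev(1, "U5", 10.0, 100.0),
             _ev(2, "U5", 10.0, 3600.0, True), _ev(3, "U5", 10.0, 99.0)],
            [_ev(0, "U4", 10.0, 100.0), _ev(1, "U4", 10.0, 500.0),
             _ev(2, "U4", 10.0, 3600.0, True), _ev(3, "U4", 10.0, 100.0)],
            3.0)
        tally = classify_outcomes(pairs, 3.0)
        by_mol = {p.molecule_id: p.outcome for p in pairs}
        assert by_mol[0] == Outcome.U4_FIRST
        assert by_mol[1] == Outcome.U5_FIRST
        assert by_mol[2] == Outcome.PERSIST
        assert by_mol[3] == Outcome.SIMULTANEOUS_LOSS
        assert sum(tally.counts.values()) == tally.total == 4

    def test_printed_2mM_routes(self):
        fx = make_fixture("routes", {"U4_FIRST": 79,
                                     "SIMULTANEOUS_LOSS": 46,
                                     "U5_FIRST": 3, "total": 128})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        tally = classify_outcomes(pairs, 3.0)
        assert tally.total == 128
        assert round(tally.percentages["U4_FIRST"]) == 62

    def test_printed_50uM_routes(self):
        fx = make_fixture("routes", {"U4_FIRST": 19,
                                     "SIMULTANEOUS_LOSS": 157,
                                     "U5_FIRST": 12, "PERSIST": 19})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        tally = classify_outcomes(pairs, 3.0)
        assert tally.total == 207
        assert round(tally.percentages["U4_FIRST"]) == 9

    def test_ground_truth_classification_is_exact(self):
        # on simulator truth with tolerance >= 1 frame and no detection
        # noise the outcome of every pair follows the generative route
        truths = simulate_molecules(preset_scheme("2mM"), 150,
                                    AcquisitionConfig(), seed=11)
        events = truths_to_events(truths)
        pairs, oa, ob = match_coincident(
            [e for e in events if e.channel == "U5"],
            [e for e in events if e.channel == "U4"], 3.0)
        assert not oa  # every U5 interval starts with a tri-snRNP arrival
        tally = classify_outcomes(pairs, 3.0)
        assert tally.counts["U5_FIRST"] == 0
        resolved = tally.total - tally.counts["PERSIST"]
        frac = tally.counts["U4_FIRST"] / resolved
        assert abs(frac - 0.62) < 3 * np.sqrt(0.62 * 0.38 / resolved)


class TestMultiBindingAndRebinding:
    def test_printed_repeat_activation_fraction(self):
        fx = make_fixture("repeats", {"total": 481, "repeat": 49})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        classify_outcomes(pairs, 3.0)
        summary = multi_binding_summary(pairs, fx["n_molecules"])
        assert summary["n_repeat_activation"] == 49
        assert summary["repeat_activation_percent"] == pytest.approx(
            10.2, abs=0.1)

    def test_single_event_molecules_have_no_repeats(self):
        fx = make_fixture("routes", {"U4_FIRST": 5})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        classify_outcomes(pairs, 3.0)
        assert multi_binding_summary(pairs)["n_repeat_activation"] == 0

    def test_printed_rebinding_fraction(self):
        fx = make_fixture("rebinding", {"eligible": 260, "rebind": 15})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        classify_outcomes(pairs, 3.0)
        res = rebinding_analysis(pairs, fx["events"]["U4"], 3.0,
                                 background_rate_per_min=2.3e-3)
        assert res.n_eligible == 260 and res.n_rebinding == 15
        assert res.percent == pytest.approx(5.7, abs=0.1)

    def test_no_reappearance_counts_zero(self):
        fx = make_fixture("rebinding", {"eligible": 30, "rebind": 0})
        pairs, _, _ = match_coincident(
            fx["events"]["U5"], fx["events"]["U4"], 3.0)
        classify_outcomes(pairs, 3.0)
        res = rebinding_analysis(pairs, fx["events"]["U4"], 3.0, 0.0)
        assert res.n_rebinding == 0 and res.percent == 0.0

    def test_rebinding_rate_recovers_injected_poisson_rate(self, rng):
        # inject background-style U4 reappearances at a known rate and
        # check the measured per-minute rate against it
        rate_per_min = 0.02
        window = (400.0, 3400.0)  # 50 eligible minutes per molecule
        u4_events, u5_events = [], []
        for mol in range(300):
            u4_events.append(_ev(mol, "U4", 100.0, 220.0))
            u5_events.append(_ev(mol, "U5", 100.0, window[1]))
            n = rng.poisson(rate_per_min * 50.0)
            for t0 in rng.uniform(*window, size=n):
                u4_events.append(_ev(mol, "U4", t0, t0 + 10.0))
        pairs, _, _ = match_coincident(u5_events, u4_events, 3.0)
        classify_outcomes(pairs, 3.0)
        res = rebinding_analysis(pairs, u4_events, 3.0, rate_per_min)
        # instances are molecules with >= 1 reappearance; at low rate the
        # per-minute instance rate approximates the event rate
        expected = (1 - np.exp(-rate_per_min * 50.0)) / 50.0
        assert res.rate_per_min == pytest.approx(expected, rel=0.25)


class TestOrdering:
    def test_sign_convention(self):
        u4 = [_ev(0, "U4", 10.0, 100.0), _ev(1, "U4", 10.0, 100.0)]
        ntc = [_ev(0, "NTC", 130.0, 500.0),  # NTC 30 s after release
               _ev(1, "NTC", 95.0, 500.0)]   # NTC 5 s before release
        rec = ordering_offsets(u4, ntc)
        assert rec.deltas[0] == pytest.approx(-30.0)
        assert rec.deltas[1] == pytest.approx(5.0)
        assert rec.fraction_negative == 0.5

    def test_molecules_missing_a_channel_are_excluded(self):
        u4 = [_ev(0, "U4", 10.0, 100.0), _ev(1, "U4", 10.0, 100.0)]
        ntc = [_ev(1, "NTC", 130.0, 500.0), _ev(2, "NTC", 10.0, 50.0)]
        rec = ordering_offsets(u4, ntc)
        assert rec.deltas.size == 1 and rec.n_excluded == 2

    def test_sequential_scheme_gives_negative_offsets(self):
        truths = simulate_molecules(preset_scheme("2mM"), 200,
                                    AcquisitionConfig(), seed=13)
        events = truths_to_events(truths)
        rec = ordering_offsets([e for e in events if e.channel == "U4"],
                               [e for e in events if e.channel == "NTC"])
        assert rec.deltas.size > 50
        assert rec.fraction_negative > 0.9

    def test_randomized_control_deterministic_and_flat_for_iid(self, rng):
        u4, ntc = [], []
        for mol in range(400):
            rel = rng.uniform(200.0, 3400.0)
            arr = rng.uniform(200.0, 3400.0)
            u4.append(_ev(mol, "U4", rel - 50.0, rel))
            ntc.append(_ev(mol, "NTC", arr, arr + 100.0))
        obs = ordering_offsets(u4, ntc)
        ctrl = randomized_control(u4, ntc, n_shuffles=40, seed=5)
        again = randomized_control(u4, ntc, n_shuffles=40, seed=5)
        np.testing.assert_array_equal(ctrl.histogram, again.histogram)
        # exchangeable case: control and observed histograms agree up to
        # sampling noise (total-variation distance)
        tv = 0.5 * np.abs(obs.histogram / obs.deltas.size
                          - ctrl.histogram / ctrl.histogram.sum()).sum()
        assert tv < 0.15

    def test_sequential_scheme_excess_over_control_near_zero(self):
        truths = simulate_molecules(preset_scheme("2mM"), 200,
                                    AcquisitionConfig(), seed=17)
        events = truths_to_events(truths)
        u4 = [e for e in events if e.channel == "U4"]
        ntc = [e for e in events if e.channel == "NTC"]
        obs = ordering_offsets(u4, ntc)
        ctrl = randomized_control(u4, ntc, n_shuffles=20, seed=3)
        edges = obs.bin_edges
        near = (edges[:-1] >= -200) & (edges[1:] <= 0)
        obs_mass = obs.histogram[near].sum() / obs.deltas.size
        ctrl_mass = ctrl.histogram[near].sum() / ctrl.histogram.sum()
        assert obs_mass > 2 * ctrl_mass


class TestCorrelationAndBackground:
    def test_perfect_monotone_correlations(self):
        x = np.arange(1.0, 21.0)
        rho, _ = dwell_correlation(x, x, n_perm=200, seed=0)
        assert rho == pytest.approx(1.0)
        rho, _ = dwell_correlation(x, -x, n_perm=200, seed=0)
        assert rho == pytest.approx(-1.0)

    def test_independent_pairs_show_no_correlation(self, rng):
        x = rng.exponential(100.0, 200)
        y = rng.exponential(300.0, 200)
        rho, p = dwell_correlation(x, y, n_perm=500, seed=1)
        assert abs(rho) < 0.15 and p > 0.05

    def test_all_tied_input_rejected(self):
        with pytest.raises(ValueError):
            dwell_correlation([1.0] * 10, list(range(10)))

    def test_background_rate_arithmetic(self):
        res = background_rate(90, 500, 60.0)
        assert res.rate_per_aoi_min == pytest.approx(3.0e-3)
        assert background_rate(0, 500, 60.0).rate_per_aoi_min == 0.0

    def test_background_ci_coverage(self, rng):
        true_rate = 1.0e-3
        n_aois, minutes = 500, 60.0
        covered = 0
        for _ in range(100):
            n = rng.poisson(true_rate * n_aois * minutes)
            res = background_rate(n, n_aois, minutes)
            covered += res.ci_low <= true_rate <= res.ci_high
        assert covered >= 90
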