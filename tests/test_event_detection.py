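import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scicpms import (
    NoBackgroundError,
    TimeTrace,
    extract_events,
    iterative_threshold,
    max_intensity,
    read_event_table,
    write_event_table,
)

from _oracles import brute_force_threshold

WORKED = [10, 12, 11, 9, 10, 500, 11, 10, 490, 12]


def trace_of(counts, dwell=0.003):
    return TimeTrace(np.asarray(counts), dwell)


class TestIterativeThreshold:
    def test_worked_example_background(self):
        """Two spikes rejected in two passes; the 8 clean dwells average 10.625."""
        bg = iterative_threshold(trace_of(WORKED))
        assert bg.mean_counts == pytest.approx(10.625)
        assert bg.n_iterations == 2
        assert sorted(set(range(10)) - set(bg.background_indices)) == [5, 8]
        assert bg.threshold_counts == pytest.approx(
            bg.mean_counts + 3 * bg.sd_counts
        )

    def test_worked_example_matches_brute_force(self):
        bg = iterative_threshold(trace_of(WORKED))
        oracle_bg, mean, sd, iters = brute_force_threshold(WORKED)
        assert set(bg.background_indices) == oracle_bg
        assert bg.mean_counts == pytest.approx(mean)
        assert bg.sd_counts == pytest.approx(sd)
        assert bg.n_iterations == iters

    def test_constant_trace_flags_nothing(self):
        bg = iterative_threshold(trace_of([5] * 12))
        assert bg.mean_counts == 5.0
        assert bg.n_iterations == 1
        assert bg.n_background == 12

    def test_sample_sd_mode_matches_its_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(50, 300)
        counts[[10, 200]] = 5000
        bg = iterative_threshold(trace_of(counts), sd_mode="sample")
        oracle_bg, mean, sd, iters = brute_force_threshold(
            list(counts), sd_mode="sample"
        )
        assert set(bg.background_indices) == oracle_bg
        assert bg.sd_counts == pytest.approx(sd)
        assert bg.n_iterations == iters

    @pytest.mark.parametrize("lam", [10.0, 100.0])
    def test_pure_poisson_false_positive_rate(self, lam):
        """On spike-free Poisson background the 3-sigma cut flags well under
        0.5% of dwells (Monte Carlo over 20 seeds)."""
        flagged = 0
        total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tr = trace_of(rng.poisson(lam, 6000))
            bg = iterative_threshold(tr)
            flagged += tr.n_dwells - bg.n_background
            total += tr.n_dwells
        assert flagged / total <= 0.005

    def test_short_trace_and_bad_k_rejected(self):
        with pytest.raises(ValueError, match="10 dwells"):
            iterative_threshold(trace_of([1] * 9))
        with pytest.raises(ValueError, match="k_sigma"):
            iterative_threshold(trace_of([1] * 20), k_sigma=0)

    def test_no_background_error(self):
        # explosive growth: every iteration peels the top until <2 remain
        counts = [10 ** (2 * i) for i in range(10)]
        with pytest.raises(NoBackgroundError):
            iterative_threshold(trace_of(counts))

    def test_idempotent_on_background_set(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(30, 500)
        counts[::50] += 400
        bg = iterative_threshold(trace_of(counts))
        sub = trace_of(counts[bg.background_indices])
        bg2 = iterative_threshold(sub)
        assert bg2.n_iterations == 1
        assert bg2.n_background == bg.n_background

    def test_events_nonincreasing_in_k_sigma(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(20, 2000)
        counts[rng.integers(0, 2000, 15)] += 300
        tr = trace_of(counts)
        n_prev = None
        for k in [2.0, 3.0, 4.0, 5.0, 8.0]:
            n = len(extract_events(tr, iterative_threshold(tr, k)).events)
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestOracleEquivalence:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**20),
        lam=st.floats(1.0, 200.0),
        n=st.integers(50, 500),
        n_spikes=st.integers(0, 10),
    )
    def test_matches_brute_force_loop(self, seed, lam, n, n_spikes):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(lam, n)
        if n_spikes:
            idx = rng.integers(0, n, n_spikes)
            counts[idx] += rng.integers(
                int(10 * np.sqrt(lam)), int(100 * lam) + 50, n_spikes
            )
        try:
            bg = iterative_threshold(trace_of(counts))
        except NoBackgroundError:
            with pytest.raises(ValueError):
                brute_force_threshold(list(counts))
            return
        oracle_bg, mean, sd, iters = brute_force_threshold(list(counts))
        assert set(bg.background_indices) == oracle_bg
        assert bg.mean_counts == pytest.approx(mean)
        assert bg.sd_counts == pytest.approx(sd)
        assert bg.n_iterations == iters


class TestExtractEvents:
    def test_worked_example_two_events(self):
        tr = trace_of(WORKED)
        table = extract_events(tr, iterative_threshold(tr))
        assert table.n_events == 2
        nets = sorted(e.net_counts for e in table.events)
        assert nets == pytest.approx([490 - 10.625, 500 - 10.625])

    def test_isolated_spike_net_counts(self):
        counts = [10] * 30
        counts[15] = 500
        tr = trace_of(counts)
        table = extract_events(tr, iterative_threshold(tr))
        assert table.n_events == 1
        ev = table.events[0]
        assert ev.start_index == 15
        assert ev.n_dwells_spanned == 1
        assert ev.net_counts == pytest.approx(500 - table.background.mean_counts)

    def test_adjacent_dwells_merge_into_one_event(self):
        counts = [10] * 30
        counts[15] = 400
        counts[16] = 350
        tr = trace_of(counts)
        table = extract_events(tr, iterative_threshold(tr), merge_gap=0)
        assert table.n_events == 1
        assert table.events[0].n_dwells_spanned == 2

    def test_merge_gap_bridges_a_below_threshold_dwell(self):
        counts = [10] * 30
        counts[15] = 400
        counts[17] = 350
        tr = trace_of(counts)
        assert extract_events(tr, iterative_threshold(tr), merge_gap=0).n_events == 2
        table = extract_events(tr, iterative_threshold(tr), merge_gap=1)
        assert table.n_events == 1
        assert table.events[0].n_dwells_spanned == 3

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(25, 1000)
        counts[rng.integers(0, 1000, 8)] += 500
        tr = trace_of(counts)
        bg = iterative_threshold(tr)
        table = extract_events(tr, bg, merge_gap=1)
        event_dwells = sum(e.n_dwells_spanned for e in table.events)
        above = int((tr.counts > bg.threshold_counts).sum())
        merged_inside = event_dwells - above
        assert bg.n_background + above + merged_inside == tr.n_dwells

    def test_length_mismatch_rejected(self):
        bg = iterative_threshold(trace_of([10] * 30))
        with pytest.raises(ValueError, match="different length"):
            extract_events(trace_of([10] * 29), bg)

    def test_detection_is_deterministic(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(40, 3000)
        counts[rng.integers(0, 3000, 12)] += 600
        tr = trace_of(counts)
        t1 = extract_events(tr, iterative_threshold(tr))
        t2 = extract_events(tr, iterative_threshold(tr))
        assert t1.events == t2.events


class TestMaxIntensity:
    def test_basic_and_constant(self):
        assert max_intensity(trace_of([1, 9, 3])) == 9
        assert max_intensity(trace_of([7] * 5)) == 7

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            max_intensity(TimeTrace(np.array([], dtype=int), 0.003))


class TestEventTableIO:
    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        counts = rng.poisson(30, 800)
        counts[[100, 400, 401]] += 700
        tr = trace_of(counts)
        table = extract_events(tr, iterative_threshold(tr))
        p = tmp_path / "events.csv"
        write_event_table(table, p)
        back = read_event_table(p)
        assert back.n_events == table.n_events
        assert back.background.mean_counts == pytest.approx(
            table.background.mean_counts
        )
        for a, b in zip(back.events, table.events):
            assert a.start_index == b.start_index
            assert a.net_counts == pytest.approx(b.net_counts)
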