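"""Next time-bin / next place sequence construction and user filtering."""

import numpy as np
import pytest

from mobipred._util import from_epoch_seconds
from mobipred.sequences import (
    PlaceSequence,
    RegionVisitSequence,
    TimeBinSequence,
    build_next_place_sequence,
    build_time_bin_sequence,
    compute_q,
    delta_t_sweep_values,
    filter_users,
    sequence_stats,
)
from mobipred.staypoints import Trajectory

DAY0 = 1_600_041_600  # midnight UTC


def visits(entries, uid="u"):
    return RegionVisitSequence(
        uid,
        [(r, from_epoch_seconds(DAY0 + s), from_epoch_seconds(DAY0 + e)) for r, s, e in entries],
    )


class TestTimeBin:
    def test_majority_time_rule(self):
        # in one hour bin: A for 40 min then B for 20 min -> A
        seq = build_time_bin_sequence(visits([(1, 0, 2400), (2, 2400, 3600)]), 3600.0)
        assert seq.symbols == [1]

    def test_empty_bin_is_null(self):
        seq = build_time_bin_sequence(visits([(1, 0, 3600), (1, 7200, 10800)]), 3600.0)
        assert seq.symbols == [1, None, 1]

    def test_frequency_tie_break(self):
        # bin 3: A and B 30 min each; A visited 3 times overall vs B once -> A
        seq = build_time_bin_sequence(
            visits(
                [
                    (1, 0, 3600),
                    (2, 3600, 7200),
                    (1, 7200, 9000),
                    (2, 9000, 10800),
                    (1, 10800, 14400),
                ]
            ),
            3600.0,
        )
        assert seq.symbols[2] == 1

    def test_final_tie_break_is_smallest_region_id(self):
        seq = build_time_bin_sequence(visits([(7, 0, 1800), (3, 1800, 3600)]), 3600.0)
        assert seq.symbols == [3]

    def test_origin_floored_to_midnight_multiples(self):
        # first visit starts 10:30; hourly bins must start on the hour
        seq = build_time_bin_sequence(visits([(1, 37_800, 41_400)]), 3600.0)
        assert (np.datetime64(seq.origin) - from_epoch_seconds(DAY0)) / np.timedelta64(
            1, "h"
        ) == 10.0

    def test_bin_count_matches_span(self):
        # visits spanning 10h from the origin, delta_t 3h -> ceil(10/3) = 4 bins
        seq = build_time_bin_sequence(visits([(1, 0, 7200), (2, 28_800, 36_000)]), 3 * 3600.0)
        assert len(seq) == 4

    def test_halving_delta_t_does_not_lose_records(self):
        vs = visits([(1, 0, 5400), (2, 9000, 12_600), (1, 14_400, 21_600)])
        coarse = build_time_bin_sequence(vs, 7200.0)
        fine = build_time_bin_sequence(vs, 3600.0)
        n_coarse = sum(s is not None for s in coarse.symbols)
        n_fine = sum(s is not None for s in fine.symbols)
        assert n_fine >= n_coarse

    def test_empty_visits_rejected(self):
        with pytest.raises(ValueError):
            build_time_bin_sequence(visits([]), 3600.0)


class TestNextPlace:
    def test_consecutive_duplicates_collapse(self):
        assert build_next_place_sequence(
            visits([(1, 0, 1), (1, 2, 3), (2, 4, 5), (2, 6, 7), (1, 8, 9)])
        ).symbols == [1, 2, 1]

    def test_constant_sequence_truncates_to_one(self):
        assert build_next_place_sequence(
            visits([(1, 0, 1), (1, 2, 3), (1, 4, 5)])
        ).symbols == [1]

    def test_single_visit(self):
        assert build_next_place_sequence(visits([(4, 0, 1)])).symbols == [4]

    def test_round_trip_with_time_bins(self):
        # visits each spanning >= one full bin: collapsing the time-bin
        # sequence recovers the next place sequence
        vs = visits([(1, 0, 7200), (2, 7200, 14_400), (1, 14_400, 25_200), (3, 25_200, 32_400)])
        tb = build_time_bin_sequence(vs, 3600.0)
        non_null = [s for s in tb.symbols if s is not None]
        collapsed = [non_null[0]] + [b for a, b in zip(non_null, non_null[1:]) if a != b]
        assert collapsed == build_next_place_sequence(vs).symbols


class TestStats:
    def make_tb(self, symbols):
        return TimeBinSequence("u", 3600.0, from_epoch_seconds(DAY0), list(symbols))

    def test_q_and_stats_examples(self):
        assert compute_q(self.make_tb([1, None, 1] + [2] * 7)) == pytest.approx(0.1)
        assert compute_q(self.make_tb([1, 2])) == 0.0
        assert compute_q(self.make_tb([None, None])) == 1.0
        assert sequence_stats(self.make_tb([1, 1, 2])) == (3, 2, 1)
        # a null breaks adjacency
        assert sequence_stats(self.make_tb([1, None, 1])) == (2, 1, 0)

    def test_place_sequences_have_no_self_transitions(self):
        n, L, st = sequence_stats(PlaceSequence("u", [1, 2, 1, 3]))
        assert (n, L, st) == (4, 3, 0)

    def test_q_complements_non_null_fraction(self, rng):
        syms = [int(s) if s >= 0 else None for s in rng.integers(-2, 5, 400)]
        tb = self.make_tb(syms)
        n_records, _, n_self = sequence_stats(tb)
        assert compute_q(tb) + n_records / len(tb) == pytest.approx(1.0)
        assert n_self <= max(n_records - 1, 0)

    def test_zero_length_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_q(self.make_tb([]))


class TestFiltering:
    def make_user(self, n_days, missing_hours, uid):
        hours = np.arange(n_days * 24)
        keep = ~np.isin(hours, missing_hours)
        t = from_epoch_seconds(DAY0 + hours[keep] * 3600.0)
        return Trajectory(uid, np.zeros(keep.sum()), np.zeros(keep.sum()), t)

    def test_filter_rules(self):
        pop = {
            "ok": self.make_user(30, np.arange(100, 128), "ok"),  # q ~ 0.04, 30 d
            "gappy": self.make_user(30, np.arange(100, 244), "gappy"),  # q = 0.2
            "short": self.make_user(27, [], "short"),  # 27 days
        }
        kept = filter_users(pop, q_max=0.15, d_min_days=28)
        assert set(kept) == {"ok"}


def test_delta_t_sweep_list():
    v = delta_t_sweep_values()
    assert v[0] == 300.0  # 5 min
    assert v[-1] == 144 * 3600.0  # 144 h
    assert len(v) == 12  # 60 min and 1 h deduplicated
    assert all(b > a for a, b in zip(v, v[1:]))
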