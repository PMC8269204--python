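import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from halomotif.seqio import MultipleAlignment
from halomotif.motif_discovery import (
    AmbiguityError, ConservedRegion, column_conservation, entropy_track,
    find_conserved_regions, label_sites, load_anchor_table, window_entropy,
)


def msa_from_windows(windows):
    """Rows consisting of exactly one 3-column window each."""
    return MultipleAlignment([f"r{i}" for i in range(len(windows))], list(windows))


class TestWindowEntropy:
    def test_invariant_window_zero_bits(self):
        msa = msa_from_windows(["TIP"] * 5)
        e, g = window_entropy(msa, 1)
        assert e == 0.0 and g == 0.0

    def test_two_species_mixture_closed_form(self):
        """{PSL x2, PNL x3}: H = -(0.4 log2 0.4 + 0.6 log2 0.6) = 0.971 bits."""
        msa = msa_from_windows(["PSL", "PSL", "PNL", "PNL", "PNL"])
        e, _ = window_entropy(msa, 1)
        expected = -(0.4 * math.log2(0.4) + 0.6 * math.log2(0.6))
        assert e == pytest.approx(expected, abs=1e-12)
        assert e == pytest.approx(0.971, abs=5e-4)

    @pytest.mark.parametrize("n", [2, 4, 8])
    def test_distinct_rows_reach_log2_n(self, n):
        rows = ["ACD", "CDE", "DEF", "EFG", "FGH", "GHI", "HIK", "IKL"][:n]
        e, _ = window_entropy(msa_from_windows(rows), 1)
        assert e == pytest.approx(math.log2(n), abs=1e-12)

    def test_gapped_rows_excluded_and_counted(self):
        msa = msa_from_windows(["TIP", "T-P", "TIP", "TIP"])
        e, g = window_entropy(msa, 1)
        assert e == 0.0 and g == pytest.approx(0.25)

    def test_all_gapped_flagged_missing(self):
        msa = msa_from_windows(["-----", "-----"])
        e, g = window_entropy(msa, 2)
        assert math.isnan(e) and g == 1.0

    def test_entropy_bounded_by_log2_rows(self):
        rnd = random.Random(0)
        for _ in range(20):
            n = rnd.randint(2, 6)
            rows = ["".join(rnd.choice("ACDE") for _ in range(5)) for _ in range(n)]
            msa = MultipleAlignment([f"r{i}" for i in range(n)], rows)
            for start in range(1, 4):
                e, _ = window_entropy(msa, start)
                assert 0.0 <= e <= math.log2(n) + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.text(alphabet="ACDE", min_size=4, max_size=4), min_size=2, max_size=6),
       st.randoms(use_true_random=False))
def test_entropy_row_permutation_and_duplication_invariance(rows, rnd):
    msa = MultipleAlignment([f"r{i}" for i in range(len(rows))], rows)
    shuffled = list(rows)
    rnd.shuffle(shuffled)
    msa_shuf = MultipleAlignment([f"s{i}" for i in range(len(rows))], shuffled)
    msa_dup = MultipleAlignment([f"d{i}" for i in range(2 * len(rows))], rows + rows)
    for start in (1, 2):
        e, _ = window_entropy(msa, start)
        assert window_entropy(msa_shuf, start)[0] == pytest.approx(e)
        assert window_entropy(msa_dup, start)[0] == pytest.approx(e)


class TestFindConservedRegions:
    def track(self, entropies, gaps=None):
        from halomotif.motif_discovery import EntropyTrack
        gaps = gaps or [0.0] * len(entropies)
        return EntropyTrack(list(map(float, entropies)), gaps, len(entropies) + 2)

    def test_constant_zero_spans_everything(self):
        regions = find_conserved_regions(self.track([0.0] * 8))
        assert len(regions) == 1
        assert (regions[0].start_col, regions[0].end_col) == (1, 10)

    def test_high_entropy_window_splits_runs(self):
        regions = find_conserved_regions(self.track([0, 0, 5, 0, 0]), min_len=1)
        assert [(r.start_col, r.end_col) for r in regions] == [(1, 4), (4, 7)]

    def test_min_len_discards_short_spans(self):
        regions = find_conserved_regions(self.track([0, 5, 5, 5, 5]), min_len=4)
        assert regions == []

    def test_gap_fraction_vetoes_windows(self):
        regions = find_conserved_regions(
            self.track([0, 0, 0], gaps=[0.0, 0.9, 0.0]), min_len=1)
        assert [(r.start_col, r.end_col) for r in regions] == [(1, 3), (3, 5)]

    def test_raising_tau_never_shrinks_spans(self):
        rng = np.random.default_rng(1)
        ents = rng.uniform(0, 3, 40)
        lo = find_conserved_regions(self.track(ents), tau=0.8, min_len=1)
        hi = find_conserved_regions(self.track(ents), tau=1.6, min_len=1)
        for r in lo:
            assert any(h.start_col <= r.start_col and h.end_col >= r.end_col
                       for h in hi)

    def test_planted_invariant_blocks_recovered(self):
        """Two invariant width-6 blocks amid random columns, 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            aas = list("ACDEFGHIKLMNPQRSTVWY")
            n_rows, n_cols = 10, 60
            cols = rng.choice(aas, size=(n_rows, n_cols))
            for start in (15, 40):  # 1-based block starts
                block = rng.choice(aas, size=6)
                cols[:, start - 1 : start + 5] = block
            msa = MultipleAlignment(
                [f"r{i}" for i in range(n_rows)],
                ["".join(row) for row in cols])
            regions = find_conserved_regions(entropy_track(msa), tau=1.0)
            found = sorted((r.start_col, r.end_col) for r in regions)
            assert len(found) == 2
            for (s, e), want_s in zip(found, (15, 40)):
                assert abs(s - want_s) <= 1 and abs(e - (want_s + 5)) <= 1


class TestColumnConservation:
    def test_direct_count(self):
        msa = MultipleAlignment(["r1", "r2", "r3", "r4"], ["I", "I", "V", "F"])
        out = column_conservation(msa, 1)
        assert out == [("I", 50.0), ("F", 25.0), ("V", 25.0)]

    def test_single_residue_is_100(self):
        msa = MultipleAlignment(["r1", "r2"], ["W", "W"])
        assert column_conservation(msa, 1) == [("W", 100.0)]

    def test_percentages_sum_to_100(self):
        rnd = random.Random(5)
        rows = ["".join(rnd.choice("ACDEFG-") for _ in range(6)) for _ in range(10)]
        msa = MultipleAlignment([f"r{i}" for i in range(10)], rows)
        for col in range(1, 7):
            out = column_conservation(msa, col)
            if out:
                assert sum(p for _, p in out) == pytest.approx(100.0, abs=0.1)

    def test_fully_gapped_column_empty(self):
        msa = MultipleAlignment(["r1", "r2"], ["-A", "-A"])
        assert column_conservation(msa, 1) == []


class TestLabelSites:
    def test_trp1_rows_labelled(self):
        rows = ["ATIPSL", "ATVPNL", "ATFSTV"] * 2
        msa = MultipleAlignment([f"r{i}" for i in range(6)], rows)
        regions = [ConservedRegion(1, 6, 0.5, 0.0)]
        out = label_sites(regions, msa)
        assert out[0].label == "Trp1"

    def test_trp3_rows_labelled(self):
        rows = ["QRAQX", "QGKTQ"] * 2
        msa = MultipleAlignment([f"r{i}" for i in range(4)], rows)
        out = label_sites([ConservedRegion(1, 5, 0.5, 0.0)], msa)
        assert out[0].label == "Trp3"

    def test_random_region_unlabeled(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("DEKRMN"), 8)) for _ in range(5)]
        msa = MultipleAlignment([f"r{i}" for i in range(5)], rows)
        out = label_sites([ConservedRegion(1, 8, 2.0, 0.0)], msa)
        assert out[0].label == "unlabeled"

    def test_duplicate_best_regions_ambiguous(self):
        rows = ["ATIPSLXXATIPSL"] * 4
        msa = MultipleAlignment([f"r{i}" for i in range(4)], rows)
        regions = [ConservedRegion(1, 6, 0.0, 0.0), ConservedRegion(9, 14, 0.0, 0.0)]
        with pytest.raises(AmbiguityError, match="Trp1"):
            label_sites(regions, msa)

    def test_anchor_table_loads(self):
        anchors = load_anchor_table()
        for site in ("FAD1", "Trp1", "Trp2", "Trp3", "Trp4", "halide", "K"):
            assert anchors[site]
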