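import math
import random

import numpy as np
import pytest

from _oracle import enumerate_path_odds
from halomotif.seqio import MultipleAlignment, SequenceRecord
from halomotif.profile_hmm import (
    CalibrationError, GumbelCalibration, ModelError, ProfileHMM, ScanHit,
    build_phmm, calibrate_evalue, filter_hits, forward_score, scan_proteome,
    viterbi_align,
)


def toy_models(n_models=25, seed=0):
    """Random small MSAs over a reduced 3-letter alphabet -> profile models."""
    rnd = random.Random(seed)
    models = []
    while len(models) < n_models:
        n_rows = rnd.randint(2, 4)
        n_cols = rnd.randint(1, 4)
        rows = ["".join(rnd.choice("ACD-") for _ in range(n_cols))
                for _ in range(n_rows)]
        try:
            msa = MultipleAlignment([f"r{i}" for i in range(n_rows)], rows)
            models.append(build_phmm(msa))
        except (ModelError, ValueError):
            continue
    return models


class TestBuild:
    def test_single_column_emission_formula(self):
        """(count + 1) / (n_observed + 20) for a 2-row invariant column."""
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["A", "A"]))
        assert model.match_emissions[0, 0] == pytest.approx(3 / 22)
        assert model.match_emissions[0, 1] == pytest.approx(1 / 22)

    def test_gappy_column_not_match_state(self):
        msa = MultipleAlignment(["r1", "r2", "r3", "r4"], ["AC", "-C", "-C", "-C"])
        model = build_phmm(msa, gap_threshold=0.5)
        assert model.n_match_states == 1
        assert list(model.column_map) == [2]

    def test_rows_and_transitions_normalized(self):
        msa = MultipleAlignment(["r1", "r2", "r3"], ["ACD-E", "A-DFE", "ACDF-"])
        model = build_phmm(msa)
        model.validate()  # raises on any distribution not summing to 1

    def test_all_gap_columns_rejected(self):
        msa = MultipleAlignment(["r1", "r2", "r3"], ["A-", "--", "--"])
        with pytest.raises(ModelError):
            build_phmm(msa, gap_threshold=0.5)

    def test_too_few_rows(self):
        with pytest.raises(ModelError):
            build_phmm(MultipleAlignment(["r1"], ["ACD"]))

    def test_json_round_trip(self):
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["ACD", "AC-"]))
        back = ProfileHMM.from_json(model.to_json())
        np.testing.assert_allclose(back.match_emissions, model.match_emissions)
        assert list(back.column_map) == list(model.column_map)


class TestForward:
    def test_single_match_state_closed_form(self):
        """log2((3/22)/0.05) for query 'A' against the {'A','A'} profile."""
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["A", "A"]))
        score = forward_score(model, SequenceRecord("q", "A"))
        assert score == pytest.approx(math.log2((3 / 22) / 0.05), abs=1e-12)

    def test_background_scores_below_consensus(self):
        model = build_phmm(MultipleAlignment(
            ["r1", "r2", "r3"], ["ACDEFGHIKL"] * 3))
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        bg_scores = [
            forward_score(model, SequenceRecord("q", "".join(rng.choice(aas, 10))))
            for _ in range(30)
        ]
        cons = forward_score(model, SequenceRecord("c", model.consensus()))
        assert np.mean(bg_scores) < cons

    def test_score_ignores_id_and_description(self):
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["ACD", "ACD"]))
        a = forward_score(model, SequenceRecord("x", "ACD", "one"))
        b = forward_score(model, SequenceRecord("y", "ACD", "two"))
        assert a == b


class TestOracleEquivalence:
    """Forward sum and Viterbi max against exhaustive path enumeration."""

    @pytest.mark.parametrize("qlen", [1, 2, 4, 6])
    def test_forward_and_viterbi_match_enumeration(self, qlen):
        rnd = random.Random(qlen)
        for model in toy_models(12, seed=qlen):
            q = "".join(rnd.choice("ACD") for _ in range(qlen))
            total, best = enumerate_path_odds(model, q)
            fwd = 2.0 ** forward_score(model, SequenceRecord("q", q))
            vit = 2.0 ** viterbi_align(model, SequenceRecord("q", q)).score_bits
            assert fwd == pytest.approx(total, rel=1e-9)
            assert vit == pytest.approx(best, rel=1e-9)

    def test_forward_at_least_viterbi(self):
        rnd = random.Random(99)
        for model in toy_models(10, seed=7):
            q = "".join(rnd.choice("ACDEF") for _ in range(rnd.randint(1, 6)))
            f = forward_score(model, SequenceRecord("q", q))
            v = viterbi_align(model, SequenceRecord("q", q)).score_bits
            assert f >= v - 1e-9


class TestViterbi:
    def test_consensus_full_coverage(self):
        msa = MultipleAlignment(["r1", "r2", "r3"], ["ACDEFGHIKL"] * 3)
        model = build_phmm(msa)
        aln = viterbi_align(model, SequenceRecord("q", model.consensus()))
        assert aln.model_coverage == 1.0
        assert aln.aligned_interval == (1, 10)
        assert aln.match_map == {i: i for i in range(1, 11)}

    def test_prefix_alignment_coverage_fraction(self):
        """A query matching only the first k of L match states covers k/L."""
        msa = MultipleAlignment(["r1", "r2", "r3"], ["ACDEFGHIKL"] * 3)
        model = build_phmm(msa)
        aln = viterbi_align(model, SequenceRecord("q", "ACDEF"))
        assert aln.model_coverage == pytest.approx(5 / 10)
        assert set(aln.match_map) == {1, 2, 3, 4, 5}


class TestCalibration:
    def test_deterministic_given_seed(self):
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["ACDEFG", "ACDEFG"]))
        c1 = calibrate_evalue(model, n_shuffles=60, seed=5)
        c2 = calibrate_evalue(model, n_shuffles=60, seed=5)
        assert (c1.mu, c1.lam) == (c2.mu, c2.lam)

    def test_location_equivariance(self):
        """Shifting all scores by +c shifts mu by +c and keeps lambda."""
        rng = np.random.default_rng(0)
        scores = rng.gumbel(loc=3.0, scale=1.5, size=400)
        from scipy import stats
        loc1, scale1 = stats.gumbel_r.fit(scores)
        loc2, scale2 = stats.gumbel_r.fit(scores + 10.0)
        assert loc2 == pytest.approx(loc1 + 10.0, abs=1e-6)
        assert scale2 == pytest.approx(scale1, abs=1e-6)

    def test_too_few_shuffles_rejected(self):
        model = build_phmm(MultipleAlignment(["r1", "r2"], ["ACD", "ACD"]))
        with pytest.raises(CalibrationError):
            calibrate_evalue(model, n_shuffles=10, seed=0)

    def test_tail_evalue_of_maximum_shuffled_score(self):
        """E-value of the max of n null scores is ~N/n (within a factor 3)."""
        rng = np.random.default_rng(42)
        scores = rng.gumbel(loc=0.0, scale=1.0, size=500)
        from scipy import stats
        loc, scale = stats.gumbel_r.fit(scores)
        calib = GumbelCalibration(mu=loc, lam=1.0 / scale, n_shuffles=500, length=100)
        N = 1000
        expected = N / 500
        observed = calib.e_value(float(scores.max()), N)
        assert expected / 3 < observed < expected * 3


class TestFilterSemantics:
    def hit(self, qid, e, cov):
        return ScanHit(qid, 100.0, e, cov, (1, 50))

    def test_strong_hit_retained(self):
        kept = filter_hits([self.hit("q", 1e-140, 0.6)])
        assert len(kept) == 1

    def test_weak_evalue_rejected_despite_coverage(self):
        assert filter_hits([self.hit("q", 1e-120, 0.9)]) == []

    def test_exact_coverage_boundary_rejected(self):
        """Coverage must strictly exceed the threshold ('covered >50%')."""
        assert filter_hits([self.hit("q", 1e-140, 0.5)]) == []

    def test_whitelist_bypasses_filter(self):
        kept = filter_hits([self.hit("q", 1.0, 0.1)], whitelist={"q"})
        assert len(kept) == 1

    def test_filter_monotonicity(self):
        """Raising e_max or lowering cov_min never drops a retained hit."""
        rng = np.random.default_rng(3)
        hits = [self.hit(f"q{i}", float(10.0 ** rng.uniform(-150, 0)),
                         float(rng.uniform(0, 1))) for i in range(50)]
        base = {h.query_id for h in filter_hits(hits, e_max=1e-100, cov_min=0.5)}
        wider_e = {h.query_id for h in filter_hits(hits, e_max=1e-50, cov_min=0.5)}
        wider_c = {h.query_id for h in filter_hits(hits, e_max=1e-100, cov_min=0.2)}
        assert base <= wider_e and base <= wider_c

    def test_sorted_by_evalue(self):
        hits = [self.hit("a", 1e-135, 0.9), self.hit("b", 1e-150, 0.9)]
        assert [h.query_id for h in filter_hits(hits)] == ["b", "a"]


def test_scan_empty_query_list():
    model = build_phmm(MultipleAlignment(["r1", "r2"], ["ACD", "ACD"]))
    calib = GumbelCalibration(mu=0.0, lam=1.0, n_shuffles=100, length=3)
    assert scan_proteome(model, [], calib) == []
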