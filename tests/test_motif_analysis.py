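import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexorient.io_formats import Pfm
from hexorient.motif_analysis import (
    AsymmetryResult,
    MotifHit,
    _tail_prob,
    binomial_asymmetry,
    classify_motif,
    count_halves,
    make_scoring_matrix,
    null_distribution,
    pvalue_threshold,
    scan_window,
)
from hexorient.position_stats import revcomp


class TestScoringMatrix:
    def test_sharp_column_scores(self):
        sm = make_scoring_matrix(Pfm("m", np.array([[1.0, 0, 0, 0]])))
        # A: log2((1 + 0.001*0.25) / (1.001*0.25)) ~ 2 bits
        assert sm.scores[0, 0] == pytest.approx(2.0, abs=0.01)
        assert np.all(np.isfinite(sm.scores))
        assert np.all(sm.scores[0, 1:] < -8)

    def test_background_equal_pfm_scores_zero(self):
        sm = make_scoring_matrix(Pfm("m", np.full((3, 4), 0.25)))
        assert np.allclose(sm.scores, 0.0)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            make_scoring_matrix(
                Pfm("m", np.full((2, 4), 0.25)), background=np.array([0.5, 0.5, 0, 0])
            )


def brute_force_scores(sm) -> np.ndarray:
    return np.array(
        [
            sum(sm.scores[i, b] for i, b in enumerate(word))
            for word in itertools.product(range(4), repeat=sm.width)
        ]
    )


class TestNullDistribution:
    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_dp_matches_exhaustive_enumeration(self, width):
        rng = np.random.default_rng(width)
        sm = make_scoring_matrix(Pfm("m", rng.dirichlet(np.ones(4), size=width)))
        scores = brute_force_scores(sm)
        values, probs = null_distribution(sm)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        for s in np.unique(np.round(scores, 9)):
            bf_tail = (scores >= s - 1e-6).mean()
            assert _tail_prob(sm, float(s)) == pytest.approx(bf_tail, abs=1e-9)

    def test_nonuniform_background(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        rng = np.random.default_rng(9)
        sm = make_scoring_matrix(Pfm("m", rng.dirichlet(np.ones(4), size=3)), bg)
        scores = brute_force_scores(sm)
        word_probs = np.array(
            [
                np.prod([bg[b] for b in word])
                for word in itertools.product(range(4), repeat=3)
            ]
        )
        for s in np.unique(np.round(scores, 9)):
            bf_tail = word_probs[scores >= s - 1e-6].sum()
            assert _tail_prob(sm, float(s)) == pytest.approx(bf_tail, abs=1e-9)


class TestPvalueThreshold:
    def test_width_one_quartile(self):
        sm = make_scoring_matrix(Pfm("m", np.array([[1.0, 0, 0, 0]])))
        thr = pvalue_threshold(sm, 0.25)
        assert thr == pytest.approx(sm.scores.max(), abs=1e-6)
        assert _tail_prob(sm, thr) == pytest.approx(0.25)

    def test_alpha_one_gives_min_score(self):
        sm = make_scoring_matrix(Pfm("m", np.array([[1.0, 0, 0, 0]])))
        assert pvalue_threshold(sm, 1.0) == pytest.approx(sm.scores.min(), abs=1e-6)

    def test_unattainable_alpha_warns(self):
        sm = make_scoring_matrix(Pfm("m", np.array([[1.0, 0, 0, 0]])))
        with pytest.warns(UserWarning, match="minimum attainable"):
            thr = pvalue_threshold(sm, 1e-9)
        assert thr == pytest.approx(sm.scores.max(), abs=1e-6)


class TestScanWindow:
    def test_consensus_window_hits_at_zero(self, consensus_pfm):
        sm = make_scoring_matrix(consensus_pfm)
        hits = scan_window("ACGTAC", sm, alpha=1e-3)
        assert [h.start for h in hits] == [0]
        assert hits[0].pvalue <= 1e-3

    def test_planted_site_recovered(self, consensus_pfm, rng):
        sm = make_scoring_matrix(consensus_pfm)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        win = flank[:23] + "ACGTAC" + flank[23:]
        hits = scan_window(win, sm, alpha=1e-3)
        assert 23 in {h.start for h in hits}

    def test_all_n_window_empty(self, consensus_pfm):
        sm = make_scoring_matrix(consensus_pfm)
        assert scan_window("N" * 30, sm) == []

    def test_short_window_empty(self, consensus_pfm):
        sm = make_scoring_matrix(consensus_pfm)
        assert scan_window("ACG", sm) == []

    def test_alpha_monotonicity(self, consensus_pfm, rng):
        sm = make_scoring_matrix(consensus_pfm)
        win = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        n_hits = [len(scan_window(win, sm, alpha=a)) for a in (0.1, 0.01, 1e-3)]
        assert n_hits == sorted(n_hits, reverse=True)

    def test_reverse_strand_mirror(self, consensus_pfm, rng):
        sm = make_scoring_matrix(consensus_pfm)
        win = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        fwd = scan_window(win, sm, alpha=0.01, scan_reverse=True)
        rev = scan_window(revcomp(win), sm, alpha=0.01, scan_reverse=True)
        L, w = len(win), sm.width
        mirrored = {(L - w - h.start, {"+": "-", "-": "+"}[h.strand]) for h in rev}
        assert {(h.start, h.strand) for h in fwd} == mirrored


def _hit(start, width=4):
    return MotifHit("s", start, "+", width, 1.0, 0.001)


class TestCountHalves:
    def test_left_hit(self):
        counts = count_halves([_hit(0)], 21)
        assert (counts.n_up, counts.n_down) == (1, 0)

    def test_mirrored_hits_balance(self):
        # window length 21, centre 10; hits at 2 and 15 have midpoints 4 and 17
        counts = count_halves([_hit(2), _hit(15)], 21)
        assert counts.n_up == counts.n_down == 1

    def test_center_hit_dropped_but_counted(self):
        counts = count_halves([_hit(8)], 21)  # midpoint 10 == centre
        assert (counts.n_up, counts.n_down, counts.n_center) == (0, 0, 1)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            count_halves([], 20)


class TestBinomialAsymmetry:
    @pytest.mark.parametrize(
        "n_up, n_down, expected",
        [(5, 5, 1.0), (10, 0, 2 * 0.5**10), (7, 3, 0.34375)],
    )
    def test_closed_forms(self, n_up, n_down, expected):
        assert binomial_asymmetry(n_up, n_down) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.integers(0, 200), b=st.integers(0, 200))
    def test_symmetry(self, a, b):
        if a + b == 0:
            return
        assert binomial_asymmetry(a, b) == pytest.approx(binomial_asymmetry(b, a))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            binomial_asymmetry(0, 0)


class TestClassifyMotif:
    def test_upstream_enrichment_in_down_biased_is_weak(self):
        asym = AsymmetryResult("m", 40, 10, binomial_asymmetry(40, 10))
        assert classify_motif(asym, "HEX_DOWN") == "weak_binding"

    def test_downstream_enrichment_in_down_biased_is_strong(self):
        asym = AsymmetryResult("m", 10, 40, binomial_asymmetry(10, 40))
        assert classify_motif(asym, "HEX_DOWN") == "strong_binding"

    def test_upstream_enrichment_in_up_biased_is_strong(self):
        asym = AsymmetryResult("m", 40, 10, binomial_asymmetry(40, 10))
        assert classify_motif(asym, "HEX_UP") == "strong_binding"

    def test_insignificant_is_unclassified(self):
        asym = AsymmetryResult("m", 6, 4, binomial_asymmetry(6, 4))
        assert classify_motif(asym, "HEX_DOWN") == "unclassified"

    def test_bonferroni_over_motifs_applies(self):
        asym = AsymmetryResult("m", 17, 5, binomial_asymmetry(17, 5))  # p ~ 0.017
        assert classify_motif(asym, "HEX_DOWN", n_motifs=1) != "unclassified"
        assert classify_motif(asym, "HEX_DOWN", n_motifs=5) == "unclassified"

    def test_unknown_class_rejected(self):
        asym = AsymmetryResult("m", 40, 10, 1e-6)
        with pytest.raises(ValueError):
            classify_motif(asym, "NUCLEOSOME")
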