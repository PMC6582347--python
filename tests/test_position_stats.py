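import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexorient.io_formats import GenomeSeq
from hexorient.position_stats import (
    RatioProfile,
    adjacent_orientation_test,
    contingency_chisq,
    extract_window,
    grouped_ratio_test,
    orientation_position_test,
    positional_distribution,
    ratio_profile,
    revcomp,
)

from conftest import make_particle


class TestExtractWindow:
    def test_watson(self, toy_genome):
        p = make_particle(strand="+", dyad=4)
        assert extract_window(toy_genome, p, 2) == "ACGTT"

    def test_crick_is_reverse_complement(self, toy_genome):
        p = make_particle(strand="-", dyad=4)
        assert extract_window(toy_genome, p, 2) == "AACGT"

    def test_out_of_bounds(self, toy_genome):
        p = make_particle(strand="+", dyad=1)
        with pytest.raises(IndexError):
            extract_window(toy_genome, p, 2)


class TestPositionalDistribution:
    def test_mononucleotide_counts(self):
        d = positional_distribution(["AAA", "AAC"])
        assert d.probs.loc[-1, "A"] == 1.0
        assert d.probs.loc[1, "A"] == 0.5
        assert d.probs.loc[1, "C"] == 0.5
        assert d.n_sequences == 2

    def test_dinucleotide_counts(self):
        d = positional_distribution(["AAA", "AAC"], alphabet="di")
        assert list(d.probs.index) == [-1, 0]
        assert d.probs.loc[-1, "AA"] == 1.0
        assert d.probs.loc[0, "AA"] == 0.5
        assert d.probs.loc[0, "AC"] == 0.5

    def test_uniform_sampling_bound(self, rng):
        bases = np.array(list("ACGT"))
        windows = ["".join(bases[rng.integers(0, 4, 21)]) for _ in range(1000)]
        d = positional_distribution(windows)
        assert np.all(np.abs(d.probs.to_numpy() - 0.25) < 0.05)

    def test_windows_with_n_dropped(self):
        d = positional_distribution(["AAA", "ANA", "CCC"])
        assert d.n_sequences == 2 and d.n_dropped == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            positional_distribution([])

    def test_probabilities_sum_to_one(self, rng):
        bases = np.array(list("ACGT"))
        windows = ["".join(bases[rng.integers(0, 4, 15)]) for _ in range(50)]
        for alphabet in ("mono", "di"):
            d = positional_distribution(windows, alphabet)
            assert np.allclose(d.probs.sum(axis=1), 1.0)

    def test_revcomp_mirror_maps_a_profile_to_t_profile(self, rng):
        bases = np.array(list("ACGT"))
        windows = ["".join(bases[rng.integers(0, 4, 21, )]) for _ in range(200)]
        fwd = positional_distribution(windows)
        rev = positional_distribution([revcomp(w) for w in windows])
        for a, b in (("A", "T"), ("C", "G")):
            np.testing.assert_allclose(
                fwd.probs[a].to_numpy(), rev.probs[b].to_numpy()[::-1]
            )


class TestRatioProfile:
    def test_self_ratio_is_one(self, rng):
        bases = np.array(list("ACGT"))
        windows = ["".join(bases[rng.integers(0, 4, 11)]) for _ in range(40)]
        d = positional_distribution(windows)
        prof = ratio_profile(d, d)
        finite = prof.ratios.to_numpy()[~prof.undefined.to_numpy()]
        assert np.allclose(finite, 1.0)

    def test_plain_ratio(self):
        up = positional_distribution(["A", "A", "C", "G"])
        down = positional_distribution(["A", "C", "G", "T"])
        prof = ratio_profile(up, down)
        assert prof.ratios.loc[0, "A"] == pytest.approx(2.0)

    def test_zero_denominator_flags(self):
        up = positional_distribution(["A", "C"])
        down = positional_distribution(["C", "C"])
        prof = ratio_profile(up, down)
        assert np.isinf(prof.ratios.loc[0, "A"])
        assert prof.infinite.loc[0, "A"]
        assert np.isnan(prof.ratios.loc[0, "G"])
        assert prof.undefined.loc[0, "G"]

    def test_shape_mismatch_rejected(self):
        a = positional_distribution(["ACG"])
        b = positional_distribution(["ACGTA"])
        with pytest.raises(ValueError):
            ratio_profile(a, b)


def profile_from_values(values: dict[int, float], symbol: str = "A") -> RatioProfile:
    pos = np.arange(-70, 71)
    data = {s: np.ones(len(pos)) for s in "ACGT"}
    df = pd.DataFrame(data, index=pos)
    for p, v in values.items():
        df.loc[p, symbol] = v
    df.index.name = "position"
    mask = pd.DataFrame(False, index=df.index, columns=df.columns)
    return RatioProfile(df, mask.copy(), mask.copy())


class TestGroupedRatioTest:
    def test_alternating_block_gives_zero_t(self):
        values = {p: (0.9 if i % 2 else 1.1) for i, p in enumerate(range(1, 11))}
        out = grouped_ratio_test(profile_from_values(values))
        row = out[(out.group_id == 7) & (out.symbol == "A")].iloc[0]
        assert row["t"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)
        assert not row["degenerate"]

    def test_constant_block_flagged_degenerate(self):
        values = {p: 1.1 for p in range(1, 11)}
        out = grouped_ratio_test(profile_from_values(values))
        row = out[(out.group_id == 7) & (out.symbol == "A")].iloc[0]
        assert row["degenerate"] and row["p"] == 0.0

    def test_t_statistic_matches_closed_form(self):
        block = [1.2, 1.1, 1.3, 1.0, 1.2, 1.1, 1.25, 1.15, 1.2, 1.1]
        values = dict(zip(range(1, 11), block))
        out = grouped_ratio_test(profile_from_values(values))
        row = out[(out.group_id == 7) & (out.symbol == "A")].iloc[0]
        x = np.asarray(block)
        t_expected = (x.mean() - 1.0) / (x.std(ddof=1) / np.sqrt(len(x)))
        assert row["t"] == pytest.approx(t_expected)
        assert row["p"] == pytest.approx(2 * stats.t.sf(abs(t_expected), len(x) - 1))

    def test_bonferroni_factor_and_bound(self):
        out = grouped_ratio_test(profile_from_values({1: 1.05}))
        assert out.attrs["bonferroni_factor"] == 56
        assert (out["p_bonferroni"] >= out["p"]).all()
        assert (out["p_bonferroni"] <= 1.0).all()

    def test_grid_tiles_140_positions(self):
        out = grouped_ratio_test(profile_from_values({}))
        assert len(out) == 14 * 4
        covered = set()
        for _, row in out[out.symbol == "A"].iterrows():
            covered.update(range(row.pos_start, row.pos_end + 1))
        assert covered == set(range(-70, 0)) | set(range(1, 71))

    def test_type_i_error_controlled_on_null(self, rng):
        """Finite-sample noise only: Bonferroni keeps the family error small."""
        bases = np.array(list("ACGT"))
        n_reject = 0
        for rep in range(5):
            wins_a = ["".join(bases[rng.integers(0, 4, 149)]) for _ in range(200)]
            wins_b = ["".join(bases[rng.integers(0, 4, 149)]) for _ in range(200)]
            prof = ratio_profile(
                positional_distribution(wins_a), positional_distribution(wins_b)
            )
            out = grouped_ratio_test(prof)
            n_reject += int((out.loc[~out.degenerate, "p_bonferroni"] < 0.05).any())
        assert n_reject <= 1


class TestContingency:
    def test_uniform_table(self):
        chi2, dof, p = contingency_chisq([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_hand_computed(self):
        chi2, dof, p = contingency_chisq([[20, 0], [0, 20]])
        assert chi2 == pytest.approx(40.0)
        assert dof == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            contingency_chisq([[0, 0], [5, 5]])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            contingency_chisq([[1, 2]])


class TestOrientationPositionTest:
    def test_identical_proportions_give_p_one(self):
        summary = pd.DataFrame(
            {"HEX_UP": [10, 20, 30], "HEX_DOWN": [10, 20, 30], "NUCLEOSOME": [20, 40, 60]},
            index=[1, 2, 3],
        )
        pvals = orientation_position_test(summary)
        assert np.allclose(pvals, 1.0)

    def test_planted_excess_detected(self, rng):
        # +1 particles enriched for HEX_DOWN relative to the pooled mix
        base = np.array([1 / 3, 1 / 3, 1 / 3])
        skew = np.array([0.2, 0.5, 0.3])
        rows = [rng.multinomial(700, skew), rng.multinomial(700, base),
                rng.multinomial(700, base)]
        summary = pd.DataFrame(rows, index=[1, 2, 3],
                               columns=["HEX_UP", "HEX_DOWN", "NUCLEOSOME"])
        pvals = orientation_position_test(summary)
        assert pvals[1] < 0.01
        assert pvals[1] < pvals[2]  # the unskewed indices sit closer to the pool

    def test_all_zero_rejected(self):
        summary = pd.DataFrame(0, index=[1, 2, 3],
                               columns=["HEX_UP", "HEX_DOWN", "NUCLEOSOME"])
        with pytest.raises(ValueError):
            orientation_position_test(summary)

    def test_independence_test_type_i_calibration(self, rng):
        """Orientation independent of gene index: chi-squared p ~ uniform."""
        pvals = []
        for _ in range(300):
            orient = rng.integers(0, 3, 900)
            index = rng.integers(0, 3, 900)
            table = np.zeros((3, 3), dtype=int)
            np.add.at(table, (orient, index), 1)
            pvals.append(contingency_chisq(table)[2])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


def _calls_frame(labels_by_gene: dict[str, dict[int, str]]) -> pd.DataFrame:
    rows = [
        {"gene_id": g, "gene_index": i, "label": lab}
        for g, by_idx in labels_by_gene.items()
        for i, lab in by_idx.items()
    ]
    return pd.DataFrame(rows)


class TestAdjacentOrientationTest:
    def test_coupled_orientations_highly_significant(self, rng):
        labels = ["HEX_UP", "HEX_DOWN", "NUCLEOSOME"]
        genes = {}
        for g in range(500):
            lab = labels[rng.integers(0, 3)]
            genes[f"g{g}"] = {1: lab, 2: lab, 3: lab}
        out = adjacent_orientation_test(_calls_frame(genes))
        assert (out["p"] < 1e-6).all()

    def test_independent_orientations_calibrated(self, rng):
        labels = np.array(["HEX_UP", "HEX_DOWN", "NUCLEOSOME"])
        pvals = []
        for _ in range(200):
            genes = {
                f"g{g}": {i: labels[rng.integers(0, 3)] for i in (1, 2, 3)}
                for g in range(150)
            }
            out = adjacent_orientation_test(_calls_frame(genes))
            pvals.extend(out["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            adjacent_orientation_test(
                _calls_frame({"g": {1: "HEX_UP", 2: "HEX_UP", 3: "HEX_UP"}})
            )
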