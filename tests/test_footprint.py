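"""Terminal cleavage-signal matrices, KL logos, and matrix comparison."""
import numpy as np
import pytest

from mhc2lig.alphabet import RESIDUES, RESIDUE_INDEX
from mhc2lig.encoding import PeptideInstance
from mhc2lig.footprint import (
    PFRAnnotation,
    annotate_pfr,
    background_frequencies,
    kl_logo_matrix,
    matrix_pcc,
    pcc_permutation_test,
    pfr_grouped_logos,
    terminal_matrix,
)

UNIFORM = np.full(20, 1 / 20)


def make_annotation(seq, offset, up="GGG", down="GGG"):
    p = PeptideInstance(seq, target=1.0, data_type="EL",
                        context_up=up, context_down=down)
    return PFRAnnotation(ligand=p, core_offset=offset,
                         context_up=up, context_down=down)


def synthetic_annotations(rng, n, proline_prob=0.0, length=15, offset=3):
    """Background-uniform ligands, optionally planting P at the second
    position from both termini (both PFRs have length 3 here)."""
    out = []
    for _ in range(n):
        codes = rng.integers(0, 20, size=length)
        if proline_prob and rng.random() < proline_prob:
            codes[1] = RESIDUE_INDEX["P"]
        if proline_prob and rng.random() < proline_prob:
            codes[-2] = RESIDUE_INDEX["P"]
        seq = "".join(RESIDUES[c] for c in codes)
        up = "".join(rng.choice(list(RESIDUES), size=3))
        down = "".join(rng.choice(list(RESIDUES), size=3))
        out.append(make_annotation(seq, offset, up, down))
    return out


class TestAnnotatePFR:
    def test_pfr_lengths_from_offset(self):
        a = make_annotation("A" * 15, 3)
        assert a.n_pfr_len == 3 and a.c_pfr_len == 3

    def test_core_at_start_of_11mer(self):
        a = make_annotation("A" * 11, 0)
        assert a.n_pfr_len == 0 and a.c_pfr_len == 2

    def test_pfr_arithmetic_identity(self, rng):
        for _ in range(30):
            L = int(rng.integers(11, 20))
            off = int(rng.integers(0, L - 8))
            a = make_annotation("A" * L, off)
            assert a.n_pfr_len + 9 + a.c_pfr_len == L

    def test_context_lookup_pads_x_at_protein_terminus(self):
        lig = PeptideInstance("ACDEFGHIKLM", target=1.0, data_type="EL",
                              source_protein_id="p1")
        proteome = {"p1": "ACDEFGHIKLMWW"}  # ligand at the very N terminus
        (a,) = annotate_pfr([lig], [0], proteome)
        assert a.context_up == "XXX" and a.context_down == "WWX"

    def test_ligand_missing_from_protein_excluded(self):
        lig = PeptideInstance("ACDEFGHIKLM", target=1.0, data_type="EL",
                              source_protein_id="p1")
        assert annotate_pfr([lig], [0], {"p1": "W" * 30}) == []

    def test_bad_offset_rejected(self):
        lig = PeptideInstance("ACDEFGHIKLM", target=1.0, data_type="EL")
        with pytest.raises(ValueError, match="offset"):
            annotate_pfr([lig], [5])


class TestTerminalMatrix:
    def test_short_pfr_ligands_are_excluded_exactly(self, rng):
        keep = synthetic_annotations(rng, 20, length=15, offset=3)
        drop = [make_annotation("A" * 15, off) for off in (0, 1, 2)] * 4
        m = terminal_matrix(keep + drop, "upstream", background=UNIFORM)
        assert m.n_ligands == 20

    def test_all_short_pfr_rejected_as_empty(self):
        short = [make_annotation("A" * 15, off) for off in (0, 1, 2)]
        with pytest.raises(ValueError, match="empty"):
            terminal_matrix(short, "upstream", background=UNIFORM)

    def test_forced_proline_position_has_frequency_near_one(self, rng):
        ann = synthetic_annotations(rng, 50, proline_prob=1.0)
        m = terminal_matrix(ann, "upstream", background=UNIFORM)
        # upstream positions: 3 context + p1 p2 p3; the planted P sits at p2
        p_col = RESIDUE_INDEX["P"]
        assert m.counts[4, p_col] == 50  # every ligand contributes a proline
        assert m.frequencies[4, p_col] == pytest.approx(51 / 70)  # add-one
        m2 = terminal_matrix(ann, "downstream", background=UNIFORM)
        # downstream positions: p-3 p-2 p-1 + 3 context; planted P at p-2
        assert m2.counts[1, p_col] == 50

    def test_counts_columns_sum_to_contributing_ligands(self, rng):
        ann = synthetic_annotations(rng, 25)
        m = terminal_matrix(ann, "upstream", background=UNIFORM)
        np.testing.assert_array_equal(m.counts.sum(axis=1), [25] * 6)

    def test_x_padding_excluded_from_counts(self, rng):
        ann = synthetic_annotations(rng, 10)
        ann.append(make_annotation("A" * 15, 3, up="XXA", down="GGG"))
        m = terminal_matrix(ann, "upstream", background=UNIFORM)
        assert m.counts[0].sum() == 10 and m.counts[1].sum() == 10
        assert m.counts[2].sum() == 11

    def test_frequency_rows_sum_to_one(self, rng):
        ann = synthetic_annotations(rng, 25)
        m = terminal_matrix(ann, "downstream", background=UNIFORM)
        np.testing.assert_allclose(m.frequencies.sum(axis=1), 1.0, atol=1e-12)

    def test_background_from_source_proteins(self, rng):
        proteome = {"p1": "ACD" * 50, "p2": "WYA" * 40}
        bg = background_frequencies(proteome)
        assert bg.sum() == pytest.approx(1.0)
        assert bg[RESIDUE_INDEX["A"]] > bg[RESIDUE_INDEX["G"]] > 0


class TestKLLogo:
    def test_frequencies_equal_to_background_give_zero_heights(self):
        logo = kl_logo_matrix(np.tile(UNIFORM, (4, 1)), UNIFORM)
        np.testing.assert_allclose(logo.heights, 0.0, atol=1e-12)
        np.testing.assert_allclose(logo.information, 0.0, atol=1e-12)

    def test_concentrated_column_reaches_log2_20(self):
        f = np.zeros((1, 20))
        f[0, 3] = 1.0
        logo = kl_logo_matrix(f, UNIFORM)
        assert logo.information[0] == pytest.approx(np.log2(20))

    def test_matches_direct_formula_on_random_input(self, rng):
        f = rng.dirichlet(np.ones(20), size=6)
        q = rng.dirichlet(np.full(20, 5.0))
        logo = kl_logo_matrix(f, q)
        expected = f * np.log2(f / q)
        np.testing.assert_allclose(logo.heights, expected, atol=1e-12)
        np.testing.assert_allclose(logo.information, expected.sum(axis=1), atol=1e-12)

    def test_zero_background_rejected(self):
        q = UNIFORM.copy()
        q[0] = 0.0
        with pytest.raises(ValueError, match="background"):
            kl_logo_matrix(np.tile(UNIFORM, (2, 1)), q)

    def test_grouped_logos_have_three_plus_pfr_positions(self):
        anns = [make_annotation("A" * 11, 1)] * 5 + \
               [make_annotation("A" * 15, 6)] * 5
        logos = pfr_grouped_logos(anns, "upstream", UNIFORM)
        assert logos[1].n_positions == 4
        assert logos[6].n_positions == 9
        assert set(logos) == {1, 6}


class TestMatrixPCC:
    def test_self_correlation_is_exactly_one(self, rng):
        m = terminal_matrix(synthetic_annotations(rng, 30), "upstream",
                            background=UNIFORM)
        assert matrix_pcc(m, m) == pytest.approx(1.0, abs=1e-12)

    def test_negated_matrix_gives_minus_one(self, rng):
        m = terminal_matrix(synthetic_annotations(rng, 30), "upstream",
                            background=UNIFORM)
        neg = terminal_matrix(synthetic_annotations(rng, 30), "upstream",
                              background=UNIFORM)
        neg.log_odds = -m.log_odds
        assert matrix_pcc(m, neg) == pytest.approx(-1.0, abs=1e-12)

    def test_symmetric(self, rng):
        a = terminal_matrix(synthetic_annotations(rng, 40, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        b = terminal_matrix(synthetic_annotations(rng, 40, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        assert matrix_pcc(a, b) == pytest.approx(matrix_pcc(b, a))

    def test_different_sides_rejected(self, rng):
        ann = synthetic_annotations(rng, 20)
        a = terminal_matrix(ann, "upstream", background=UNIFORM)
        b = terminal_matrix(ann, "downstream", background=UNIFORM)
        with pytest.raises(ValueError, match="termini"):
            matrix_pcc(a, b)

    def test_replicates_with_same_planted_signal_correlate(self):
        r1 = np.random.default_rng(11)
        r2 = np.random.default_rng(22)
        a = terminal_matrix(synthetic_annotations(r1, 1000, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        b = terminal_matrix(synthetic_annotations(r2, 1000, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        assert matrix_pcc(a, b) > 0.7

    def test_cysteine_removal_changes_replicate_pcc_little(self):
        r1 = np.random.default_rng(11)
        r2 = np.random.default_rng(22)
        a = terminal_matrix(synthetic_annotations(r1, 1000, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        b = terminal_matrix(synthetic_annotations(r2, 1000, proline_prob=0.4),
                            "upstream", background=UNIFORM)
        full = matrix_pcc(a, b)
        c = RESIDUE_INDEX["C"]
        keep = [i for i in range(20) if i != c]
        va = a.log_odds[:, keep].ravel()
        vb = b.log_odds[:, keep].ravel()
        no_cys = float(np.corrcoef(va, vb)[0, 1])
        assert abs(full - no_cys) < 0.1


class TestPermutationTest:
    def test_shared_strong_signal_is_significant(self):
        r1 = np.random.default_rng(31)
        r2 = np.random.default_rng(32)
        a = synthetic_annotations(r1, 800, proline_prob=0.4)
        b = synthetic_annotations(r2, 800, proline_prob=0.4)
        obs, p = pcc_permutation_test(a, b, "upstream", n_perm=999,
                                      background=UNIFORM, rng=5)
        assert obs > 0.5
        assert p <= 0.01

    def test_p_value_extremes_follow_estimator_definition(self, rng):
        # observed above every permuted value -> 1/(1+n); below all -> 1
        a = synthetic_annotations(np.random.default_rng(41), 500, proline_prob=0.5)
        b = synthetic_annotations(np.random.default_rng(42), 500, proline_prob=0.5)
        _, p = pcc_permutation_test(a, b, "upstream", n_perm=19,
                                    background=UNIFORM, rng=1)
        assert p == pytest.approx(1 / 20)

    def test_membership_null_calibrated_on_one_pool(self):
        """Sets drawn from one signal-free pool: rejection at alpha=0.05
        stays within binomial noise over repeated experiments."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 60
        for _ in range(reps):
            pool = synthetic_annotations(rng, 80)
            a, b = pool[:40], pool[40:]
            _, p = pcc_permutation_test(a, b, "upstream", n_perm=39,
                                        background=UNIFORM,
                                        null="membership", rng=rng)
            if p <= 0.05:
                rejections += 1
        # binomial(60, 0.05): mean 3, sd 1.7; stay within ~4 sigma
        assert rejections <= 10

    def test_invalid_n_perm_rejected(self, rng):
        a = synthetic_annotations(rng, 20)
        with pytest.raises(ValueError, match="n_perm"):
            pcc_permutation_test(a, a, "upstream", n_perm=0, background=UNIFORM)


class TestPlantedSignalRecovery:
    def test_proline_log_odds_exceeds_one_bit_at_n_1000(self):
        rng = np.random.default_rng(99)
        ann = synthetic_annotations(rng, 1000, proline_prob=0.4)
        m = terminal_matrix(ann, "upstream", background=UNIFORM)
        assert m.log_odds[4, RESIDUE_INDEX["P"]] > 1.0
        md = terminal_matrix(ann, "downstream", background=UNIFORM)
        assert md.log_odds[1, RESIDUE_INDEX["P"]] > 1.0
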