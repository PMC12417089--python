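"""Codon-usage statistics: RSCU, neutral-usage distance, CAI, Fop, E."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nfembed.codon import (
    CODON_TO_AA,
    SENSE_CODONS,
    SYNONYMOUS_FAMILIES,
    ReferenceUsage,
    compute_bias_E,
    compute_cai,
    compute_fop,
    compute_rscu,
    default_reference_usage,
    euclidean_codon_distance,
    expression_block,
)
from nfembed.data_model import CodingSequence

IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


def make_ref(optimal_first: bool = True) -> ReferenceUsage:
    """Reference where each family's lexicographically first codon is optimal
    with weight 1 and the rest carry weight 0.25."""
    weights, optimal = {}, {}
    for aa, fam in SYNONYMOUS_FAMILIES.items():
        optimal[aa] = fam[0]
        for i, c in enumerate(fam):
            weights[c] = 1.0 if i == 0 else 0.25
    return ReferenceUsage(weights=weights, optimal=optimal)


random_cds = st.lists(
    st.sampled_from(SENSE_CODONS), min_size=2, max_size=40
).map(lambda cods: CodingSequence("".join(cods)))


class TestRscu:
    def test_equal_use_of_two_codon_family(self):
        r = compute_rscu(CodingSequence("TTTTTC"))
        assert r[IDX["TTT"]] == 1.0 and r[IDX["TTC"]] == 1.0
        assert np.all(np.delete(r, [IDX["TTT"], IDX["TTC"]]) == 0.0)

    def test_exclusive_use_of_one_family_member(self):
        r = compute_rscu(CodingSequence("TTTTTT"))
        assert r[IDX["TTT"]] == 2.0 and r[IDX["TTC"]] == 0.0

    def test_singleton_family(self):
        assert compute_rscu(CodingSequence("ATG"))[IDX["ATG"]] == 1.0

    def test_neutral_fill_option(self):
        r = compute_rscu(CodingSequence("ATG"), fill=1.0)
        assert r[IDX["TTT"]] == 1.0

    @given(random_cds)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_observed_family_sums_equal_family_size(self, cds):
        r = compute_rscu(cds)
        used = set(cds.codons)
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if used & set(fam):
                assert sum(r[IDX[c]] for c in fam) == pytest.approx(len(fam))


class TestEuclideanDistance:
    def test_neutral_vector_has_zero_distance(self):
        assert euclidean_codon_distance(np.ones(61)) == 0.0

    def test_single_unit_deviation(self):
        v = np.ones(61)
        v[10] = 2.0
        assert euclidean_codon_distance(v) == pytest.approx(1.0)

    def test_zero_vector_closed_form(self):
        assert euclidean_codon_distance(np.zeros(61)) == pytest.approx(np.sqrt(61))

    def test_permutation_invariance(self, rng):
        v = rng.uniform(0, 3, 61)
        assert euclidean_codon_distance(v) == pytest.approx(
            euclidean_codon_distance(rng.permutation(v))
        )

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            euclidean_codon_distance(np.ones(60))


class TestCai:
    def test_all_optimal_codons_give_one(self):
        ref = make_ref()
        cds = CodingSequence("TTC" + "GCA" + "TTC")  # TTC, GCA are family-first
        assert compute_cai(cds, ref) == pytest.approx(1.0)

    def test_geometric_mean_of_two_weights(self):
        ref = make_ref()
        # TTC weight 1, TTT weight 0.25 -> sqrt(0.25) = 0.5
        assert compute_cai(CodingSequence("TTTTTC"), ref) == pytest.approx(0.5)

    def test_only_singleton_families_is_an_error(self):
        with pytest.raises(ValueError):
            compute_cai(CodingSequence("ATGTGG"), make_ref())

    @given(random_cds)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bounded_in_unit_interval(self, cds):
        ref = default_reference_usage()
        try:
            cai = compute_cai(cds, ref)
        except ValueError:
            return  # all codons from singleton families
        assert 0 < cai <= 1 + 1e-12


class TestFop:
    def test_all_optimal(self):
        assert compute_fop(CodingSequence("TTCTTC"), make_ref()) == 1.0

    def test_none_optimal(self):
        assert compute_fop(CodingSequence("TTTTTT"), make_ref()) == 0.0

    def test_half_optimal(self):
        cds = CodingSequence("TTCTTTTTCTTT")
        assert compute_fop(cds, make_ref()) == 0.5

    def test_no_eligible_codons_is_an_error(self):
        with pytest.raises(ValueError):
            compute_fop(CodingSequence("ATGTGG"), make_ref())


class TestBiasE:
    def test_uniform_family_usage_gives_zero(self):
        assert compute_bias_E(CodingSequence("TTTTTC")) == pytest.approx(0.0)

    def test_single_family_fully_biased(self):
        # Phe family size 2 used as TTT only: |1-0.5| + |0-0.5| = 1
        assert compute_bias_E(CodingSequence("TTT")) == pytest.approx(1.0)

    def test_length_invariance_at_fixed_proportions(self):
        cds1 = CodingSequence("TTTTTTTTC")
        cds2 = CodingSequence(cds1.bases * 3)
        assert compute_bias_E(cds1) == pytest.approx(compute_bias_E(cds2))


class TestExpressionBlock:
    def test_full_block_shape_and_finiteness(self, small_dataset):
        dataset, _ = small_dataset
        ref = default_reference_usage()
        block = expression_block(dataset.samples[0], ref)
        assert block.shape == (24,)
        assert np.all(np.isfinite(block))

    def test_missing_gene_zero_filled(self, small_dataset):
        dataset, _ = small_dataset
        import copy

        s = copy.deepcopy(dataset.samples[0])
        del s.cds["nifX"]
        block = expression_block(s, default_reference_usage())
        assert np.all(block[21:24] == 0)
        assert np.any(block[:21] != 0)

    def test_deterministic_for_identical_cds(self, small_dataset):
        dataset, _ = small_dataset
        ref = default_reference_usage()
        s = dataset.samples[0]
        np.testing.assert_array_equal(expression_block(s, ref), expression_block(s, ref))


class TestReferenceUsage:
    def test_family_maxima_are_one(self):
        ref = default_reference_usage()
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            assert max(ref.weights[c] for c in fam) == pytest.approx(1.0)
            assert ref.optimal[aa] in fam

    def test_tsv_round_trip(self, tmp_path):
        ref = default_reference_usage()
        path = tmp_path / "ref.tsv"
        ref.to_tsv(path)
        back = ReferenceUsage.from_tsv(path)
        for c in SENSE_CODONS:
            assert back.weights[c] == pytest.approx(ref.weights[c], rel=1e-5)

    def test_invalid_family_max_rejected(self):
        weights = {c: 0.5 for c in SENSE_CODONS}
        with pytest.raises(ValueError):
            ReferenceUsage(weights=weights, optimal={aa: fam[0] for aa, fam in SYNONYMOUS_FAMILIES.items()})
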