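import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgt_evidence.datasets import GC_FOLD_EXAMPLES
from hgt_evidence.gc_profile import (DONOR_CONSISTENT, HOST_CONSISTENT, TIE,
                                     fold_ratio, gc_affinity, gc_content,
                                     gene_gc, sliding_window_gc)
from hgt_evidence.io_formats import GenomicFeature, SequenceRecord

COMPLEMENT = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")

#: expected G+C contribution per IUPAC code (independent tally oracle)
GC_WEIGHT = {"G": 1, "C": 1, "S": 1, "A": 0, "T": 0, "U": 0, "W": 0,
             "R": 0.5, "Y": 0.5, "K": 0.5, "M": 0.5, "N": 0.5,
             "B": 2 / 3, "V": 2 / 3, "D": 1 / 3, "H": 1 / 3}


def oracle_mol_percent(seq):
    return 100 * sum(GC_WEIGHT[c] for c in seq) / len(seq)


class TestGCContent:
    def test_direct_count(self):
        assert gc_content("ATGC").mol_percent == 50.0

    def test_strong_ambiguity_code_counts_fully(self):
        assert gc_content("GGCCSS").mol_percent == 100.0

    def test_fractional_ambiguity_codes(self):
        assert gc_content("RN").mol_percent == pytest.approx(50.0)
        assert gc_content("W").mol_percent == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_non_iupac_character_rejected(self):
        with pytest.raises(Exception):
            gc_content("ACGZ")

    def test_matches_tally_oracle_on_random_sequences(self, rng):
        alphabet = "ACGTURYSWKMBDHVN"
        for _ in range(30):
            seq = "".join(rng.choice(alphabet) for _ in range(rng.randrange(1, 2000)))
            assert gc_content(seq).mol_percent == pytest.approx(
                oracle_mol_percent(seq))

    def test_long_random_sequence_oracle(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(10_000))
        assert gc_content(seq).mol_percent == pytest.approx(
            oracle_mol_percent(seq))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=300))
    def test_strand_invariance(self, seq):
        revcomp = seq.translate(COMPLEMENT)[::-1]
        assert gc_content(seq).mol_percent == pytest.approx(
            gc_content(revcomp).mol_percent)

    def test_partition_weighted_mean(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(997))
        cut1, cut2 = 311, 700
        whole = gc_content(seq)
        parts = [gc_content(seq[:cut1]), gc_content(seq[cut1:cut2]),
                 gc_content(seq[cut2:])]
        weighted = sum(p.gc_count for p in parts)
        assert whole.gc_count == pytest.approx(weighted)


class TestGCAffinity:
    def test_published_empedobacter_like_case(self):
        aff = gc_affinity(71.3, 32.7, 71.3)
        assert aff.verdict == DONOR_CONSISTENT
        assert aff.delta_donor == 0.0

    def test_published_campylobacter_like_case(self):
        aff = gc_affinity(56.7, 30.4, 56.3)
        assert aff.verdict == DONOR_CONSISTENT
        assert aff.delta_donor == pytest.approx(0.4)
        assert aff.delta_host == pytest.approx(26.3)

    def test_exact_tie(self):
        assert gc_affinity(50, 50, 50).verdict == TIE

    def test_host_consistent(self):
        assert gc_affinity(33, 32, 70).verdict == HOST_CONSISTENT

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(gene=st.floats(0, 100), host=st.floats(0, 100),
           donor=st.floats(0, 100))
    def test_label_exchange_symmetry(self, gene, host, donor):
        """Swapping host and donor relabels the verdict accordingly."""
        fwd = gc_affinity(gene, host, donor).verdict
        swp = gc_affinity(gene, donor, host).verdict
        expected = {DONOR_CONSISTENT: HOST_CONSISTENT,
                    HOST_CONSISTENT: DONOR_CONSISTENT, TIE: TIE}[fwd]
        assert swp == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gc_affinity(101, 50, 50)


class TestFoldRatio:
    @pytest.mark.parametrize("mge, genome, published", GC_FOLD_EXAMPLES)
    def test_published_ratios(self, mge, genome, published):
        assert round(fold_ratio(mge, genome), 1) == published

    def test_identity(self):
        assert fold_ratio(42.0, 42.0) == 1.0

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            fold_ratio(50, 0)


class TestSlidingWindow:
    def test_uniform_sequence_uniform_windows(self):
        out = sliding_window_gc("GCGCGCGCGC", window=4, step=2)
        assert all(stats.mol_percent == 100.0 for _, stats, _ in out)

    def test_partial_final_window_flagged(self):
        out = sliding_window_gc("GCGCGCGCG", window=4, step=4)
        assert [t[0] for t in out] == [1, 5, 9]
        assert [t[2] for t in out] == [False, False, True]

    def test_insert_deviates_in_known_direction(self, rng):
        host = "".join(rng.choice("AATT" + "GC") for _ in range(3000))
        insert = "GC" * 300
        seq = host[:1500] + insert + host[1500 + 600:]
        out = sliding_window_gc(seq, window=300, step=300)
        inside = [s.mol_percent for start, s, _ in out
                  if 1500 < start <= 1800]
        outside = [s.mol_percent for start, s, _ in out if start <= 1200]
        assert min(inside) > max(outside)

    def test_concatenation_invariance(self, rng):
        seq = "".join(rng.choice("ACGT") for _ in range(1200))
        out = sliding_window_gc(seq, window=100, step=100)
        weighted = sum(s.gc_count for _, s, _ in out)
        assert gc_content(seq).gc_count == pytest.approx(weighted)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_gc("ACGT", window=0, step=1)
        with pytest.raises(ValueError):
            sliding_window_gc("ACGT", window=2, step=0)
        with pytest.raises(ValueError):
            sliding_window_gc("ACGT", window=10, step=1)


class TestGeneGC:
    def test_span_is_one_based_inclusive(self):
        genome = SequenceRecord(id="g", residues="AAGGCCAA", alphabet="nt")
        feat = GenomicFeature("g", "gene", 3, 6)
        assert gene_gc(genome, feat).mol_percent == 100.0

    def test_feature_beyond_sequence_rejected(self):
        genome = SequenceRecord(id="g", residues="ACGT", alphabet="nt")
        with pytest.raises(ValueError):
            gene_gc(genome, GenomicFeature("g", "gene", 2, 10))
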