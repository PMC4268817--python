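"""Sequence features: SRE counting, permutation z-scores, splice-site
models, group statistics, flank lengths."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ejcsplice.catalog import CassetteEvent
from ejcsplice.features import (ACCEPTOR_LENGTH, DONOR_LENGTH, MotifSet,
                                SequenceError, SpliceSiteModel,
                                acceptor_site_seq, compare_groups,
                                default_acceptor_model, default_donor_model,
                                donor_site_seq, encode, flank_lengths,
                                kmer_codes, length_expression_correlation,
                                load_site_models, motif_zscore, score_site,
                                sre_count, sre_frequency, train_site_model,
                                _dinuc_shuffle)


class TestSreFrequency:
    def test_no_occurrence_gives_zero(self):
        assert sre_frequency("ACGTACGT", MotifSet("m", "ESE", ("GAAGAA",))) == 0.0

    def test_overlapping_occurrences_all_counted(self):
        # GAAGAAGAA: matches at offsets 0 and 3 -> 2/9
        ms = MotifSet("m", "ESE", ("GAAGAA",))
        assert sre_frequency("GAAGAAGAA", ms) == pytest.approx(2 / 9)

    def test_frequency_halves_when_length_doubles(self):
        ms = MotifSet("m", "ESE", ("GAAGAA",))
        seq = "GAAGAAGAA"
        padded = seq + "C" * len(seq)
        assert sre_count(seq, ms) == sre_count(padded, ms)
        assert sre_frequency(padded, ms) == pytest.approx(sre_frequency(seq, ms) / 2)

    def test_short_sequence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert sre_frequency("ACG", MotifSet("m", "ESE", ("GAAGAA",))) == 0.0

    def test_reverse_complement_invariance_only_for_closed_sets(self):
        from ejcsplice.annotation import revcomp

        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(30)]
        open_set = MotifSet("open", "ESE", ("GAAGAA",))
        closed = MotifSet("closed", "ESE", ("GAAGAA", "TTCTTC"))
        closed_same = sum(sre_count(s, closed) == sre_count(revcomp(s), closed)
                          for s in seqs)
        open_same = sum(sre_count(s, open_set) == sre_count(revcomp(s), open_set)
                        for s in seqs)
        assert closed_same == len(seqs)
        assert open_same < len(seqs)

    def test_non_acgt_symbol_rejected(self):
        with pytest.raises(SequenceError, match="non-ACGT"):
            encode("ACGN")

    def test_motif_set_length_enforced(self):
        with pytest.raises(SequenceError, match="6-mer"):
            MotifSet("m", "ESE", ("GAAGA",))


class TestMotifZscore:
    def test_homopolymer_gives_nan_sentinel(self):
        z = motif_zscore("A" * 200, MotifSet("m", "ESE", ("GAAGAA",)), seed=1)
        assert math.isnan(z)

    def test_zscore_matches_independent_reimplementation(self):
        ms = MotifSet("m", "ESE", ("GAAGAA", "AAGAAG"))
        rng = np.random.default_rng(5)
        seq = "".join(np.random.default_rng(77).choice(list("ACGT"), size=200))
        z = motif_zscore(seq, ms, n_shuffles=100, rng=np.random.default_rng(5))
        # independent shuffle+count with the same seeded stream
        def count(s):
            return sum(s[i:i + 6] in ms.motifs for i in range(len(s) - 5)) / len(s)
        f_obs = count(seq)
        freqs = []
        arr = np.array(list(seq))
        for _ in range(100):
            freqs.append(count("".join(rng.permutation(arr))))
        freqs = np.array(freqs)
        expected = (f_obs - freqs.mean()) / freqs.std(ddof=1)
        assert z == pytest.approx(expected, rel=1e-12)

    def test_too_few_shuffles_is_an_error(self):
        with pytest.raises(SequenceError):
            motif_zscore("ACGT" * 50, MotifSet("m", "ESE", ("GAAGAA",)),
                         n_shuffles=1, seed=1)

    def test_dinucleotide_shuffle_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(4)
        codes = encode("".join(rng.choice(list("ACGT"), size=300)))
        shuffled = _dinuc_shuffle(codes, rng)
        assert len(shuffled) == len(codes)

        def dinucs(c):
            vals, counts = np.unique(c[:-1] * 4 + c[1:], return_counts=True)
            return dict(zip(vals.tolist(), counts.tolist()))
        assert dinucs(codes) == dinucs(shuffled)


class TestSpliceSiteModel:
    def test_background_model_scores_zero(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        model = SpliceSiteModel("donor", np.tile(bg, (DONOR_LENGTH, 1)), bg)
        rng = np.random.default_rng(0)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGT"), size=DONOR_LENGTH))
            assert abs(model.score(s)) < 1e-12

    def test_two_informative_positions_hand_computed(self):
        probs = np.tile([0.25, 0.25, 0.25, 0.25], (DONOR_LENGTH, 1)).astype(float)
        probs[3] = [0.8, 0.2 / 3, 0.2 / 3, 0.2 / 3]
        probs[4] = [0.8, 0.2 / 3, 0.2 / 3, 0.2 / 3]
        model = SpliceSiteModel("donor", probs, np.full(4, 0.25))
        assert model.score("CCCAACCCC") == pytest.approx(2 * math.log2(0.8 / 0.25))

    def test_wrong_length_input_is_an_error(self):
        with pytest.raises(SequenceError, match="9-mer"):
            default_donor_model().score("ACGTACGT")
        with pytest.raises(SequenceError, match="23-mer"):
            default_acceptor_model().score("A" * 22)

    def test_training_on_identical_sequences_is_degenerate(self):
        model = train_site_model(["CAGGTAAGT"] * 5, "donor", pseudocount=0.0)
        codes = encode("CAGGTAAGT")
        assert np.allclose(model.probs[np.arange(DONOR_LENGTH), codes], 1.0)

    def test_empty_training_set_is_an_error(self):
        with pytest.raises(SequenceError):
            train_site_model([], "donor")

    def test_sampling_recovery(self):
        """train -> sample -> train round trip: per-position probabilities
        recovered within a small total-variation distance."""
        truth = default_acceptor_model()
        rng = np.random.default_rng(11)
        model = train_site_model(truth.sample(10_000, rng), "acceptor",
                                 pseudocount=0.0)
        tv = 0.5 * np.abs(model.probs - truth.probs).sum(axis=1)
        assert tv.max() < 0.02

    def test_score_additive_and_column_permutation_invariant(self):
        m = default_donor_model()
        s = "CAGGTAAGT"
        per_pos = [math.log2(m.probs[i, encode(s)[i]] / m.background[encode(s)[i]])
                   for i in range(DONOR_LENGTH)]
        assert m.score(s) == pytest.approx(sum(per_pos))
        # swapping two identical-probability columns leaves scores unchanged
        probs = np.tile([0.4, 0.3, 0.2, 0.1], (DONOR_LENGTH, 1)).astype(float)
        m1 = SpliceSiteModel("donor", probs, np.full(4, 0.25))
        probs2 = probs.copy()
        probs2[[2, 5]] = probs2[[5, 2]]
        m2 = SpliceSiteModel("donor", probs2, np.full(4, 0.25))
        rng = np.random.default_rng(1)
        for _ in range(5):
            s = "".join(rng.choice(list("ACGT"), size=DONOR_LENGTH))
            assert m1.score(s) == pytest.approx(m2.score(s))

    def test_save_load_round_trip(self, tmp_path):
        m = default_donor_model()
        (tmp_path / "models").mkdir()
        m.save(tmp_path / "models" / "donor.tsv")
        default_acceptor_model().save(tmp_path / "models" / "acceptor.tsv")
        loaded = load_site_models(tmp_path / "models")
        for _ in range(3):
            s = m.sample(1, np.random.default_rng(2))[0]
            assert loaded["donor"].score(s) == pytest.approx(m.score(s))

    def test_missing_tables_error_suggests_trainable_model(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="train_site_model"):
            load_site_models(tmp_path)

    def test_invalid_probabilities_rejected(self):
        probs = np.tile([0.5, 0.5, 0.5, 0.5], (DONOR_LENGTH, 1))
        with pytest.raises(SequenceError, match="sum to 1"):
            SpliceSiteModel("donor", probs, np.full(4, 0.25))


class TestSiteExtraction:
    def test_donor_and_acceptor_windows(self):
        genome = {"c": "".join(np.random.default_rng(3).choice(list("ACGT"), size=400))}
        d = donor_site_seq(genome, "c", "+", 100, 200)
        a = acceptor_site_seq(genome, "c", "+", 100, 200)
        assert d == genome["c"][197:206] and len(d) == DONOR_LENGTH
        assert a == genome["c"][80:103] and len(a) == ACCEPTOR_LENGTH

    def test_minus_strand_is_reverse_complement(self):
        from ejcsplice.annotation import revcomp

        genome = {"c": "".join(np.random.default_rng(3).choice(list("ACGT"), size=400))}
        d = donor_site_seq(genome, "c", "-", 100, 200)
        assert d == revcomp(genome["c"][94:103])


class TestFlankLengths:
    def _event(self, strand):
        # transcript-ordered trio; on the minus strand the upstream exon has
        # larger genomic coordinates
        if strand == "+":
            return CassetteEvent("e", "c", "+", 100, 200, 500, 600, 900, 1000)
        return CassetteEvent("e", "c", "-", 900, 1000, 500, 600, 100, 200)

    def test_plus_strand_lengths(self):
        fl = flank_lengths(self._event("+"))
        assert fl.upstream_intron == 300 and fl.downstream_intron == 300
        assert fl.cassette_exon == 100 and fl.valid

    def test_minus_strand_flips_up_and_down(self):
        ev = CassetteEvent("e", "c", "-", 900, 1000, 500, 600, 100, 200)
        fl = flank_lengths(ev)
        assert fl.upstream_intron == 300  # gap between [900,1000) and [500,600)
        assert fl.valid

    def test_asymmetric_gaps_assigned_by_strand(self):
        # exons [100,200) and [500,600) with a 300 nt gap: on the minus
        # strand that gap is the downstream intron
        ev = CassetteEvent("e", "c", "-", 700, 800, 500, 600, 100, 200)
        fl = flank_lengths(ev)
        assert fl.upstream_intron == 100 and fl.downstream_intron == 300

    def test_abutting_exons_flagged_invalid(self):
        ev = CassetteEvent("e", "c", "+", 100, 500, 500, 600, 900, 1000)
        assert not flank_lengths(ev).valid


class TestGroupStats:
    def test_identical_groups_give_p_near_one(self):
        _, p = compare_groups([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.85

    def test_exact_small_sample_enumeration(self):
        u, p = compare_groups([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_p_decreases_monotonically_with_shift(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=200)
        ps = [compare_groups(base, base + shift)[1] for shift in (0.0, 0.5, 1.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_group_is_an_error(self):
        with pytest.raises(SequenceError):
            compare_groups([], [1.0])

    def test_monotone_pairing_gives_rho_one(self):
        rho, _ = length_expression_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)

    def test_constant_vector_gives_nan_sentinel(self):
        rho, p = length_expression_correlation([1, 2, 3], [5, 5, 5])
        assert math.isnan(rho) and math.isnan(p)

    def test_independent_draws_have_small_correlation(self):
        rng = np.random.default_rng(12)
        rho, _ = length_expression_correlation(rng.normal(size=1000),
                                               rng.normal(size=1000))
        assert abs(rho) < 0.08


@settings(deadline=None, max_examples=30)
@given(st.text(alphabet="ACGT", min_size=6, max_size=60))
def test_kmer_count_matches_naive_scan(seq):
    ms = MotifSet("m", "ESE", ("GAAGAA", "TTTTTT", "ACGTAC"))
    naive = sum(seq[i:i + 6] in ms.motifs for i in range(len(seq) - 5))
    assert sre_count(seq, ms) == naive


def test_bundled_synthetic_motif_sets_load():
    sizes = {"ESE": 238, "ESS": 176, "ISE": 199, "ISS": 102}
    for kind, n in sizes.items():
        ms = MotifSet.bundled_synthetic(kind)
        assert len(ms) == n
        assert ms.k == (10 if kind == "ISS" else 6)
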