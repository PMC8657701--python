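"""Read-processing chain: merging, EE filtering, dereplication, denoising,
identity search, and the assembled pipeline."""

import math

import numpy as np
import pytest

from _oracles import reference_denoise
from amplindel._seq import revcomp
from amplindel.readproc import (Amp, DenoiseParams, FilterParams, MergeParams,
                                SearchParams, beta_skew, denoise, dereplicate,
                                filter_maxee, global_identity, merge_pairs,
                                posterior_error_probs, run_chain, search_assign)


def q(qchar, n):
    return qchar * n


class TestMerge:
    AMP = ("ACGTTGCAACGGTGCATTGCAACCGGTTAACCGTACGATCGATCGGCTA"
           "GCTTAGCGTACCGGAATTCCGGATCGATCCGGTTAACCGGCATGCATGC")

    def _pair(self, read_len=60):
        r1 = self.AMP[:read_len]
        r2 = revcomp(self.AMP)[:read_len]
        return ("p", r1, q("I", read_len)), ("p", r2, q("I", read_len))

    def test_error_free_pair_reconstructs_amplicon(self):
        a, b = self._pair()
        merged, stats = merge_pairs([a], [b], MergeParams())
        assert stats["merged"] == 1
        assert merged[0][1] == self.AMP

    def test_mismatch_cap_rejects(self):
        a, b = self._pair()
        seq = list(b[1])
        # R2 position i maps to overlap position 59-i on the plus strand;
        # these three all land inside the 22-base overlap
        for i in (45, 50, 55):
            seq[i] = {"A": "C"}.get(seq[i], "A")
        b = (b[0], "".join(seq), b[2])
        _, stats = merge_pairs([a], [b], MergeParams(maxdiffs=2))
        assert stats["merged"] == 0
        merged, stats = merge_pairs([a], [b], MergeParams(maxdiffs=3))
        assert stats["merged"] == 1

    def test_short_overlap_rejected(self):
        a, b = self._pair(read_len=52)   # overlap 6 < min_overlap 16
        _, stats = merge_pairs([a], [b], MergeParams(min_overlap=16))
        assert stats["merged"] == 0

    def test_posterior_quality_exceeds_inputs_when_agreeing(self):
        a, b = self._pair()
        a = (a[0], a[1], q("5", 60))   # Q20
        b = (b[0], b[1], q("5", 60))
        merged, _ = merge_pairs([a], [b], MergeParams())
        quals = np.frombuffer(merged[0][2].encode(), np.uint8) - 33
        overlap = slice(len(self.AMP) - 60, 60)
        assert (quals[overlap] > 20).all()
        # oracle: direct posterior computation p1*p2/3 normalization,
        # clamped at the configured Qmax
        p = 10 ** (-20 / 10)
        post = (p * p / 3) / (1 - 2 * p + 4 * p * p / 3)
        assert quals[overlap][0] == min(round(-10 * math.log10(post)), 41)

    def test_disagreement_keeps_higher_quality_base(self):
        a, b = self._pair()
        seq = list(b[1])
        seq[49] = {"A": "C"}.get(seq[49], "A")  # overlap position 10
        qual = list(b[2])
        qual[49] = "$"                          # Q3 << Q40
        b = (b[0], "".join(seq), "".join(qual))
        merged, _ = merge_pairs([a], [b], MergeParams())
        assert merged[0][1] == self.AMP        # R1's base wins

    def test_unpaired_inputs_raise(self):
        a, b = self._pair()
        with pytest.raises(ValueError, match="unpaired"):
            merge_pairs([a, a], [b], MergeParams())

    def test_posterior_probability_symmetry(self):
        p1 = np.array([0.01, 0.1])
        p2 = np.array([0.001, 0.01])
        agree = np.array([True, False])
        ab = posterior_error_probs(p1, p2, agree)
        ba = posterior_error_probs(p2, p1, agree)
        np.testing.assert_allclose(ab, ba)
        assert (ab[0] < p2[0]) and (ab[1] > p2[1])


class TestFilter:
    def test_maxee_closed_forms(self):
        # all-Q20 reads: EE = n * 0.01
        keep, _ = filter_maxee([("a", "A" * 100, q("5", 100))],
                               FilterParams(maxee=1.13))
        assert len(keep) == 1
        keep, _ = filter_maxee([("b", "A" * 150, q("5", 150))],
                               FilterParams(maxee=1.13))
        assert len(keep) == 0

    def test_empty_read_kept(self):
        keep, _ = filter_maxee([("a", "", "")], FilterParams(maxee=0.01))
        assert len(keep) == 1

    def test_malformed_quality_names_record(self):
        with pytest.raises(ValueError, match="bad_rec"):
            filter_maxee([("bad_rec", "AC", "I")], FilterParams())

    def test_raising_maxee_is_monotone(self):
        rng = np.random.default_rng(0)
        reads = [(f"r{i}", "A" * 80,
                  "".join(chr(33 + c) for c in rng.integers(10, 40, 80)))
                 for i in range(50)]
        kept = [len(filter_maxee(reads, FilterParams(maxee=m))[0])
                for m in (0.3, 0.6, 1.0, 2.0)]
        assert kept == sorted(kept)


class TestDereplicate:
    def test_counts_and_order(self):
        assert dereplicate(["AAA", "AAA", "AAT"]) == [("AAA", 2), ("AAT", 1)]

    def test_empty(self):
        assert dereplicate([]) == []

    def test_abundance_ties_break_lexicographically(self):
        assert dereplicate(["TTT", "AAA"]) == [("AAA", 1), ("TTT", 1)]

    def test_total_conserved(self):
        rng = np.random.default_rng(1)
        seqs = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(200)]
        assert sum(c for _, c in dereplicate(seqs)) == 200


class TestDenoise:
    def test_beta_rule_hand_cases(self):
        # centroid 100; variant d=1 size 10: skew 0.10 <= beta(1)=0.125
        assert beta_skew(1, 2.0) == pytest.approx(1 / 8)
        uniques = [("AAAAAAAAAA", 100), ("AAAAAAAAAT", 10)]
        out = denoise(uniques, DenoiseParams(minampsize=2, chimera=False))
        assert out == [("AAAAAAAAAA", 110)]
        # size 20: skew 0.20 > 0.125 -> its own centroid
        uniques = [("AAAAAAAAAA", 100), ("AAAAAAAAAT", 20)]
        out = denoise(uniques, DenoiseParams(minampsize=2, chimera=False))
        assert out == [("AAAAAAAAAA", 100), ("AAAAAAAAAT", 20)]

    def test_single_unique_above_minampsize(self):
        assert denoise([("ACGT", 30)], DenoiseParams(minampsize=22.47)) \
            == [("ACGT", 30)]
        assert denoise([("ACGT", 10)], DenoiseParams(minampsize=22.47)) == []

    def test_greedy_equals_exhaustive_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 21))
            seqs = set()
            while len(seqs) < n:
                seqs.add("".join(rng.choice(list("ACGT"),
                                            int(rng.integers(8, 14)))))
            uniques = sorted(((s, int(rng.integers(1, 200))) for s in seqs),
                             key=lambda kv: (-kv[1], kv[0]))
            params = DenoiseParams(minampsize=int(rng.integers(1, 5)),
                                   alpha=float(rng.choice([1.0, 2.0])),
                                   chimera=False)
            assert denoise(uniques, params) == reference_denoise(
                uniques, math.floor(params.minampsize), params.alpha)

    def test_chimera_concatenation_removed(self):
        a = "AAAACCCCGGGGTTTTAAAACCCC"
        b = "TTTTGGGGCCCCAAAATTTTGGGG"
        chim = a[:12] + b[12:]
        uniques = [(a, 100), (b, 90), (chim, 5)]
        out = denoise(uniques, DenoiseParams(minampsize=1, chimera=True))
        assert chim not in [s for s, _ in out]
        out = denoise(uniques, DenoiseParams(minampsize=1, chimera=False))
        assert chim in [s for s, _ in out]


class TestSearch:
    DB = [("db1", "ACGT" * 25), ("db2", "TTTT" * 25)]

    def test_identical_query_hits_at_identity_one(self):
        hits, counts = search_assign([("q", "ACGT" * 25)], self.DB,
                                     SearchParams(identity=0.99))
        assert hits["q"] == ("db1", 1.0)
        assert counts["db1"] == 1

    def test_single_substitution_is_identity_099(self):
        qseq = "C" + ("ACGT" * 25)[1:]
        hits, _ = search_assign([("q", qseq)], self.DB,
                                SearchParams(identity=0.99))
        hit, ident = hits["q"]
        assert hit == "db1"
        assert ident == pytest.approx(0.99)

    def test_distant_query_unassigned(self):
        hits, _ = search_assign([("q", "ACGG" * 25)], self.DB,
                                SearchParams(identity=0.99))
        assert hits["q"] == (None, 0.0)

    def test_terminal_gaps_excluded_from_identity(self):
        # query carries extra flanking bases; interior identical
        hits, _ = search_assign([("q", "GGGGG" + "ACGT" * 25 + "GGGGG")],
                                self.DB, SearchParams(identity=0.99))
        assert hits["q"][0] == "db1"

    def test_exact_mode_requires_equality(self):
        qseq = "C" + ("ACGT" * 25)[1:]
        hits, _ = search_assign([("q", qseq)], self.DB,
                                SearchParams(identity=1.0, mode="exact"))
        assert hits["q"] == (None, 0.0)

    def test_raising_identity_never_gains_matches(self):
        rng = np.random.default_rng(3)
        qs = []
        for i in range(40):
            s = list("ACGT" * 25)
            for j in rng.choice(100, size=rng.integers(0, 4), replace=False):
                s[j] = "T" if s[j] != "T" else "A"
            qs.append((f"q{i}", "".join(s)))
        matched = []
        for ident in (0.95, 0.97, 0.99, 1.0):
            hits, _ = search_assign(qs, self.DB, SearchParams(identity=ident))
            matched.append(sum(1 for h, _ in hits.values() if h))
        assert matched == sorted(matched, reverse=True)

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            search_assign([("q", "ACGT")], [], SearchParams())

    def test_identity_mode_exact_consistency_enforced(self):
        with pytest.raises(ValueError):
            SearchParams(identity=0.99, mode="exact")


class TestChain:
    def test_error_free_fixture_fully_recovered(self, small_dataset):
        from amplindel.simulate import ReadSimSpec, pcr_amplify, simulate_reads
        amps = pcr_amplify(small_dataset["wt_molecules"]).head(5)
        r1, r2 = simulate_reads(amps, ReadSimSpec(
            depth=60, substitution_error_rate=0.0, seed=13))
        res = run_chain([("L1", r1, r2)],
                        denoise_params=DenoiseParams(minampsize=2))
        assert res.stats["merged"] == res.stats["pairs"]
        assert len(res.amps) == amps["amplicon"].nunique()
        assert res.stats["assigned_reads"] == res.stats["pairs"]

    def test_sample_order_does_not_change_amp_set(self, small_reads):
        s = [("WT", *small_reads["WT"]), ("CR", *small_reads["CR"])]
        a = run_chain(s)
        b = run_chain(s[::-1])
        assert {x.sequence for x in a.amps} == {x.sequence for x in b.amps}
        assert a.counts.loc[:, ["WT", "CR"]].sort_index().equals(
            b.counts.loc[:, ["WT", "CR"]].sort_index())

    def test_read_conservation_at_each_stage(self, small_chain):
        st = small_chain.stats
        assert st["merged"] <= st["pairs"]
        assert st["filtered"] <= st["merged"]
        assert st["denoised_reads"] <= st["filtered"]
        assert st["assigned_reads"] <= st["merged"]

    def test_counts_match_amp_sample_counts(self, small_chain):
        for amp in small_chain.amps:
            for line, c in amp.sample_counts.items():
                assert small_chain.counts.loc[amp.id, line] == c
            assert amp.sample_counts and sum(amp.sample_counts.values()) >= 0

    def test_no_samples_raises(self):
        with pytest.raises(ValueError):
            run_chain([])
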