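import math

import numpy as np
import pytest

import oracles
from icekit.seqio import FastqRead, read_fastq
from icekit.simulate import (
    make_barcode_table,
    random_reference,
    simulate_amplicon_run,
)
from icekit.spectrum import (
    AlignmentScoring,
    align_read,
    average_summaries,
    background_subtract,
    call_mutations,
    clopper_pearson,
    demultiplex,
    merge_pairs,
    per_read_histogram,
    run_pipeline,
    summarize_sample,
)
from icekit.types import BarcodeEntry, BarcodeTable, MutationCall


def revcomp(s):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
    return "".join(comp[c] for c in reversed(s))


def qstr(q, n):
    return chr(q + 33) * n


class TestClopperPearson:
    def test_zero_successes(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(0.3085, abs=2e-4)

    def test_all_successes_upper_is_one(self):
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_forty_three_of_forty_nine(self):
        lo, hi = clopper_pearson(43, 49)
        assert lo == pytest.approx(0.752, abs=2e-3)
        assert hi == pytest.approx(0.953, abs=2e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)
        with pytest.raises(ValueError):
            clopper_pearson(-1, 4)

    @pytest.mark.parametrize("n", [1, 7, 19])
    def test_matches_tail_inversion(self, n):
        for k in range(n + 1):
            lo, hi = clopper_pearson(k, n)
            olo, ohi = oracles.clopper_pearson_by_inversion(k, n)
            assert lo == pytest.approx(olo, abs=1e-9)
            assert hi == pytest.approx(ohi, abs=1e-9)


class TestMergePairs:
    def make_pair(self, template, read_len, q1=30, q2=30, pid="p"):
        r1 = FastqRead(pid, template[:read_len], qstr(q1, read_len))
        r2 = FastqRead(pid, revcomp(template[-read_len:]),
                       qstr(q2, read_len))
        return r1, r2

    def test_error_free_pair_reconstructs_template(self):
        template = random_reference(80, seed=1)
        r1, r2 = self.make_pair(template, 50)
        merged, rejects = merge_pairs([r1], [r2], min_overlap=10)
        assert not rejects
        assert merged[0].seq == template

    def test_disagreement_resolved_to_higher_quality(self):
        template = random_reference(80, seed=2)
        r1, r2 = self.make_pair(template, 50, q1=40, q2=10)
        # corrupt one overlap base on the low-quality mate (R2)
        mid = 40  # template position inside the 20-base overlap
        alt = "A" if template[mid] != "A" else "C"
        r2seq = list(revcomp(template[-50:]))
        r2pos = len(template) - 1 - mid
        r2seq[r2pos] = revcomp(alt)
        r2 = FastqRead("p", "".join(r2seq), qstr(10, 50))
        merged, rejects = merge_pairs([r1], [r2], min_overlap=10)
        assert not rejects
        assert merged[0].seq == template  # Q40 base retained
        # merged quality is the max of the two mates
        assert merged[0].qual[mid] == chr(40 + 33)

    def test_low_agreement_pair_rejected(self):
        template = random_reference(80, seed=3)
        r1, _ = self.make_pair(template, 50)
        junk = FastqRead("p", random_reference(50, seed=99), qstr(30, 50))
        merged, rejects = merge_pairs([r1], [junk], min_overlap=10,
                                      quality_threshold=0.95)
        assert merged == [] and len(rejects) == 1

    def test_unpaired_input_rejected(self):
        r = FastqRead("p", "ACGT", qstr(30, 4))
        with pytest.raises(ValueError, match="unpaired"):
            merge_pairs([r, r], [r])

    def test_merged_positions_match_simulator_truth(
        self, tmp_path, ty1_profile
    ):
        """On ~1e3 simulated pairs the merged sequences equal the true
        templates whenever no sequencing error hit the pair."""
        refs = {"cargo": random_reference(380, 1),
                "control": random_reference(380, 2)}
        bt = make_barcode_table(1, 1, seed=3)
        run = simulate_amplicon_run(refs, bt, 500, ty1_profile,
                                    seq_error_rate=0.0,
                                    indel_error_rate=0.0, seed=4,
                                    out_dir=tmp_path)
        merged, rejects = merge_pairs(
            list(read_fastq(run.r1_path)), list(read_fastq(run.r2_path))
        )
        assert not rejects
        truth = dict(zip(run.truth.read_id, run.truth.n_events))
        by_sample = run.barcodes.by_sample()
        n_checked = 0
        for m in merged:
            if truth[m.id] == 0:
                sid = m.id.rsplit(".", 1)[0]
                e = by_sample[sid]
                assert m.seq == e.barcode + refs[e.reference]
                n_checked += 1
        assert n_checked > 400


class TestDemultiplex:
    def table(self):
        return BarcodeTable([
            BarcodeEntry("s1", "AAACCC", "cargo", "ref"),
            BarcodeEntry("s2", "GGGTTT", "cargo", "ref"),
            BarcodeEntry("s3", "ACACAC", "control", "ref"),
        ])

    def test_exact_match_assigned_and_trimmed(self):
        reads = [FastqRead("r1", "AAACCC" + "ACGTACGT", qstr(30, 14))]
        assigned, un = demultiplex(reads, self.table())
        assert [r.seq for r in assigned["s1"]] == ["ACGTACGT"]
        assert len(assigned["s1"][0].qual) == 8
        assert not un

    def test_single_mismatch_still_unique(self):
        reads = [FastqRead("r1", "AATCCC" + "ACGT", qstr(30, 10))]
        assigned, un = demultiplex(reads, self.table())
        assert len(assigned["s1"]) == 1 and not un

    def test_ambiguous_read_unassigned(self):
        # equidistant (1,1) between s1 and s3
        reads = [FastqRead("r1", "AAACAC" + "ACGT", qstr(30, 10))]
        assigned, un = demultiplex(reads, self.table())
        assert all(not v for v in assigned.values())
        assert len(un) == 1

    def test_distance_invariant_enforced_up_front(self):
        with pytest.raises(ValueError, match="Hamming"):
            BarcodeTable([
                BarcodeEntry("a", "AAAAAA", "cargo", "r"),
                BarcodeEntry("b", "AAAAAT", "cargo", "r"),
            ])

    def test_simulated_run_assignment_rate(self, tmp_path, ty1_profile):
        """With 1% per-base errors, assignment is essentially error-free
        (the >=2 bp barcode distance makes <=1-mismatch matches unique) and
        only the ~2% of reads with 2+ barcode errors drop out."""
        refs = {"cargo": random_reference(380, 1),
                "control": random_reference(380, 2)}
        bt = make_barcode_table(3, 1, seed=3)
        run = simulate_amplicon_run(refs, bt, 400, ty1_profile,
                                    seq_error_rate=0.01, seed=5,
                                    out_dir=tmp_path)
        merged, _ = merge_pairs(
            list(read_fastq(run.r1_path)), list(read_fastq(run.r2_path))
        )
        assigned, un = demultiplex(merged, bt)
        n_assigned = sum(len(v) for v in assigned.values())
        n_correct = sum(
            1 for sid, reads in assigned.items()
            for r in reads if r.id.rsplit(".", 1)[0] == sid
        )
        assert n_correct / n_assigned >= 0.999
        assert n_assigned / len(merged) >= 0.95


class TestAlignment:
    def test_identity_scores_full_length(self):
        ref = random_reference(40, seed=1)
        aln = align_read(ref, ref)
        assert aln.score == 40.0
        assert call_mutations(aln) == []

    def test_single_deletion_leftmost_in_homopolymer(self):
        ref = "GGC" + "AAAA" + "CGGTT"
        read = "GGC" + "AAA" + "CGGTT"
        calls = call_mutations(align_read(read, ref))
        assert len(calls) == 1
        c = calls[0]
        assert c.kind == "deletion" and c.position == 3

    def test_multibase_indel_is_one_event(self):
        ref = random_reference(60, seed=2)
        read = ref[:20] + ref[23:]  # 3-base deletion
        calls = call_mutations(align_read(read, ref))
        assert len(calls) == 1
        assert calls[0].kind == "deletion"
        assert len(calls[0].ref_allele) == 3

    def test_substitution_classification(self):
        ref = random_reference(30, seed=3)
        pos = 10
        alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref[pos]]
        read = ref[:pos] + alt + ref[pos + 1:]
        calls = call_mutations(align_read(read, ref))
        assert calls == [MutationCall(pos, ref[pos], alt, "transition")]

    def test_n_positions_ignored(self):
        ref = random_reference(30, seed=4)
        read = ref[:10] + "N" + ref[11:]
        assert call_mutations(align_read(read, ref)) == []

    def test_overlong_read_rejected(self):
        with pytest.raises(ValueError, match="artefact"):
            align_read("A" * 100, "ACGT" * 10)

    @pytest.mark.parametrize("case", range(50))
    def test_score_matches_full_dp_oracle(self, case):
        rng = np.random.default_rng(case)
        n = int(rng.integers(5, 30))
        ref = random_reference(n, seed=1000 + case)
        # random edit of the reference
        read = list(ref)
        for _ in range(int(rng.integers(0, 4))):
            op = rng.integers(0, 3)
            p = int(rng.integers(0, len(read)))
            if op == 0:
                read[p] = "ACGT"[rng.integers(0, 4)]
            elif op == 1 and len(read) > 3:
                del read[p]
            else:
                read.insert(p, "ACGT"[rng.integers(0, 4)])
        read = "".join(read)
        aln = align_read(read, ref, AlignmentScoring(band=30))
        expected = oracles.full_affine_dp_score(read, ref)
        assert aln.score == pytest.approx(expected)


class TestSummaries:
    def test_hand_tally(self):
        """3 transitions + 2 transversions + 1 deletion over 10 reads of
        1 kb: 0.6 mutations/kb, Ts/Tv 1.5, deletions 16.7% of events."""
        ref = random_reference(1000, seed=1)
        calls = [
            MutationCall(1, "A", "G", "transition", "r1"),
            MutationCall(2, "G", "A", "transition", "r1"),
            MutationCall(3, "C", "T", "transition", "r2"),
            MutationCall(4, "A", "C", "transversion", "r3"),
            MutationCall(5, "G", "T", "transversion", "r4"),
            MutationCall(6, "AC", "", "deletion", "r5"),
        ]
        s, prof = summarize_sample(calls, 10, ref)
        assert s.mut_per_kb == pytest.approx(0.6)
        assert s.ts_tv == pytest.approx(1.5)
        assert s.del_pct == pytest.approx(100 / 6, rel=1e-6)
        assert s.at_to_n_pct + s.gc_to_n_pct + s.ins_pct + s.del_pct == (
            pytest.approx(100.0)
        )
        assert prof.counts.sum() == 6
        hist = per_read_histogram(calls, 10)
        assert hist[0] == 5 and hist[1] == 4 and hist[2] == 1

    def test_no_calls(self):
        s, _ = summarize_sample([], 10, random_reference(100, seed=2))
        assert s.mut_per_kb == 0.0
        assert s.at_to_n_pct == s.del_pct == 0.0
        assert math.isinf(s.ts_tv)

    def test_class_ci_contains_rate(self):
        ref = random_reference(100, seed=3)
        calls = [MutationCall(1, "A", "G", "transition", "r")] * 5
        s, _ = summarize_sample(calls, 50, ref)
        lo, hi = s.class_ci("A>G")
        assert lo <= s.class_rates["A>G"] <= hi


class TestBackgroundSubtract:
    def make_summary(self, n_events_per_class, n_reads=100, L=1000):
        ref = random_reference(L, seed=1)
        calls = []
        for cls, n in n_events_per_class.items():
            for i in range(n):
                if cls == "del":
                    calls.append(MutationCall(i, ref[i], "", "deletion"))
                elif cls == "ins":
                    calls.append(MutationCall(i, "", "A", "insertion"))
                else:
                    r, a = cls.split(">")
                    kind = ("transition"
                            if {r, a} in ({"A", "G"}, {"C", "T"})
                            else "transversion")
                    calls.append(MutationCall(i, r, a, kind))
        return summarize_sample(calls, n_reads, ref)[0]

    def test_control_equal_sample_gives_zero(self):
        s = self.make_summary({"A>G": 5, "del": 2})
        corr = background_subtract(s, s)
        assert corr.total_rate == 0.0

    def test_zero_control_is_identity(self):
        s = self.make_summary({"A>G": 5, "C>A": 3})
        zero = self.make_summary({})
        corr = background_subtract(s, zero)
        assert corr.class_rates == pytest.approx(s.class_rates)

    def test_flooring_flagged(self):
        s = self.make_summary({"A>G": 1})
        c = self.make_summary({"A>G": 5, "del": 1})
        corr = background_subtract(s, c)
        assert "A>G" in corr.floored and "del" in corr.floored
        assert corr.class_rates["A>G"] == 0.0

    def test_average_summaries_unweighted(self):
        a = self.make_summary({"A>G": 10}, n_reads=100)
        b = self.make_summary({"A>G": 1}, n_reads=10)
        avg = average_summaries([a, b])
        assert avg.class_rates["A>G"] == pytest.approx(
            (a.class_rates["A>G"] + b.class_rates["A>G"]) / 2
        )


class TestPipeline:
    def run_small(self, tmp_path, profile, templates=300, seed=6, **kw):
        refs = {"cargo": random_reference(380, 1),
                "control": random_reference(380, 2)}
        bt = make_barcode_table(2, 1, seed=3)
        run = simulate_amplicon_run(refs, bt, templates, profile,
                                    seed=seed, out_dir=tmp_path, **kw)
        res = run_pipeline(run.r1_path, run.r2_path, refs, bt)
        return run, res

    def test_zero_input_pipeline_reports_exactly_zero(self, tmp_path):
        from icekit.types import SpectrumProfile

        prof = SpectrumProfile.uniform(mut_per_kb=0.0)
        _, res = self.run_small(tmp_path, prof, seq_error_rate=0.0,
                                indel_error_rate=0.0)
        assert res.corrected.mut_per_kb == 0.0
        assert res.cargo_summary.mut_per_kb == 0.0
        for s in res.samples.values():
            assert not s.calls

    def test_calls_match_sidecar_truth_without_errors(
        self, tmp_path, ty1_profile
    ):
        """With sequencing errors off, pipeline calls equal simulator ground
        truth (indels compared after leftmost normalisation)."""
        from icekit.simulate import normalize_call, parse_truth_calls

        run, res = self.run_small(
            tmp_path, ty1_profile, templates=4000,
            seq_error_rate=0.0, indel_error_rate=0.0,
        )
        truth_keys = []
        for _, row in run.truth.iterrows():
            if row.sample_id.startswith("cargo"):
                for c in parse_truth_calls(row.calls):
                    truth_keys.append(
                        normalize_call(c, run.refs["cargo"]).key()
                    )
        called_keys = []
        for s in res.samples.values():
            if s.role == "cargo":
                called_keys.extend(c.key() for c in s.calls)
        assert sorted(called_keys) == sorted(truth_keys)

    def test_read_order_invariance(self, tmp_path, ty1_profile):
        refs = {"cargo": random_reference(380, 1),
                "control": random_reference(380, 2)}
        bt = make_barcode_table(2, 1, seed=3)
        run = simulate_amplicon_run(refs, bt, 200, ty1_profile, seed=8,
                                    out_dir=tmp_path)
        res1 = run_pipeline(run.r1_path, run.r2_path, refs, bt)

        from icekit.seqio import write_fastq

        r1 = list(read_fastq(run.r1_path))
        r2 = list(read_fastq(run.r2_path))
        rng = np.random.default_rng(0)
        order = rng.permutation(len(r1))
        write_fastq([r1[i] for i in order], tmp_path / "s1.fastq")
        write_fastq([r2[i] for i in order], tmp_path / "s2.fastq")
        res2 = run_pipeline(tmp_path / "s1.fastq", tmp_path / "s2.fastq",
                            refs, bt)
        assert res1.corrected.class_rates == pytest.approx(
            res2.corrected.class_rates
        )

    def test_class_percentages_sum_to_100(self, tmp_path, ty1_profile):
        _, res = self.run_small(tmp_path, ty1_profile, templates=3000)
        s = res.cargo_summary
        assert s.at_to_n_pct + s.gc_to_n_pct + s.ins_pct + s.del_pct == (
            pytest.approx(100.0)
        )
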