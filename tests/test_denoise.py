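import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mycobarcode._dna import revcomp
from mycobarcode._seqio import ReadPair, phred_to_qual, read_fastq_pairs
from mycobarcode.denoise import (
    VariantTable,
    denoise_reads,
    expected_errors,
    filter_reads,
    merge_pairs,
    remove_bimeras,
)
from mycobarcode.simulate import SimConfig, make_chimera, simulate_run
from mycobarcode.trimdemux import trim_pairs

phred_lists = st.lists(st.integers(0, 41), max_size=60)


class TestExpectedErrors:
    def test_ten_q20_bases(self):
        assert expected_errors([20] * 10) == pytest.approx(0.1)

    def test_empty_read(self):
        assert expected_errors("") == 0.0

    def test_mixed_closed_form(self):
        assert expected_errors([10, 20, 30]) == pytest.approx(0.111)

    def test_ascii_and_integer_forms_agree(self):
        phred = [2, 11, 25, 40, 38]
        assert expected_errors(phred_to_qual(phred)) == pytest.approx(
            expected_errors(phred)
        )

    @given(x=phred_lists, y=phred_lists)
    def test_additivity(self, x, y):
        assert expected_errors(x + y) == pytest.approx(
            expected_errors(x) + expected_errors(y)
        )

    @given(x=st.lists(st.integers(1, 41), min_size=1, max_size=60), data=st.data())
    def test_monotone_under_quality_decrease(self, x, data):
        i = data.draw(st.integers(0, len(x) - 1))
        worse = list(x)
        worse[i] -= 1
        assert expected_errors(worse) > expected_errors(x)


def _pair_with_ee(read_id, fwd_ee_tenths, rev_ee_tenths):
    """Pair whose mates carry `n` Q10 bases (EE = n * 0.1) padded with Q40."""

    def mate(tenths):
        phred = [10] * tenths + [40] * 10
        return "A" * len(phred), phred_to_qual(phred)

    fs, fq = mate(fwd_ee_tenths)
    rs, rq = mate(rev_ee_tenths)
    return ReadPair(read_id, fs, fq, rs, rq)


class TestFilterReads:
    def test_threshold_behaviour_at_max_ee_three(self):
        near = _pair_with_ee("keep", 28, 28)  # EE ~2.9 per mate
        over = _pair_with_ee("drop", 31, 0)  # forward EE ~3.2
        kept = filter_reads([near, over], max_ee=3.0)
        assert [p.read_id for p in kept] == ["keep"]

    def test_all_q40_kept(self):
        pairs = [
            ReadPair(f"r{i}", "ACGT" * 50, "I" * 200, "ACGT" * 50, "I" * 200)
            for i in range(5)
        ]
        assert len(filter_reads(pairs)) == 5

    def test_truncation_at_low_quality_base(self):
        phred = [40] * 30 + [1] + [40] * 10
        p = ReadPair("t", "A" * 41, phred_to_qual(phred), "C" * 41, phred_to_qual([40] * 41))
        (kept,) = filter_reads([p], truncq=2)
        assert len(kept.fwd_seq) == 30
        assert kept.rev_seq == "C" * 41

    def test_infinite_max_ee_is_identity_on_content(self):
        pairs = [_pair_with_ee(f"r{i}", i * 10, 5) for i in range(6)]
        kept = filter_reads(pairs, max_ee=float("inf"), truncq=0)
        assert [(p.fwd_seq, p.rev_seq) for p in kept] == [
            (p.fwd_seq, p.rev_seq) for p in pairs
        ]


def _reads(*groups):
    """groups of (sequence, count) -> [(read_id, sequence), ...]"""
    out = []
    i = 0
    for seq, count in groups:
        for _ in range(count):
            out.append((f"r{i}", seq))
            i += 1
    return out


SEQ = "ACGTACGTACGTACGTACGT"
SEQ1 = "T" + SEQ[1:]  # one substitution


class TestDenoise:
    def test_error_child_absorbed(self):
        table, assignment = denoise_reads(_reads((SEQ, 99), (SEQ1, 1)))
        assert table.variants == [(SEQ, 100)]
        assert set(assignment.values()) == {0}

    def test_abundance_ratio_keeps_real_variant(self):
        table, _ = denoise_reads(_reads((SEQ, 60), (SEQ1, 40)))
        assert table.variants == [(SEQ, 60), (SEQ1, 40)]

    def test_indel_variants_stay_distinct(self):
        short = SEQ[:-1]
        table, _ = denoise_reads(_reads((SEQ, 99), (short, 1)))
        assert len(table) == 2

    @given(
        counts=st.lists(st.integers(1, 50), min_size=1, max_size=6),
        seed=st.integers(0, 10),
    )
    def test_count_conservation(self, counts, seed):
        rng = np.random.default_rng(seed)
        groups = [
            ("".join("ACGT"[b] for b in rng.integers(0, 4, 30)), c) for c in counts
        ]
        table, assignment = denoise_reads(_reads(*groups))
        assert table.total_count == sum(counts)
        assert len(assignment) == sum(counts)

    def test_simulated_specimen_recovers_template(self, scheme, tmp_path):
        cfg = SimConfig(n_specimens=1, depth_mean=200, chimera_rate=0.0,
                        contamination_rate=0.0, no_band_fraction=0.0, seed=13)
        run = simulate_run(scheme, cfg, tmp_path)
        (cid,) = run.truth.templates
        template = run.truth.templates[cid]
        pairs = read_fastq_pairs(*run.specimen_fastqs[cid])
        trimmed, _ = trim_pairs(pairs, scheme)
        table, _ = denoise_reads([(p.read_id, p.fwd_seq) for p in trimmed], cid)
        assert table.total_count == len(trimmed)
        assert table.variants[0][0] == template[: len(table.variants[0][0])]


class TestMergePairs:
    def _tables(self, fwd, rev, n=20):
        ft, fa = denoise_reads([(f"r{i}", fwd) for i in range(n)])
        rt, ra = denoise_reads([(f"r{i}", rev) for i in range(n)])
        return ft, rt, fa, ra

    def test_exact_overlap_merge(self):
        fwd = "AAAATTTTCCCCGGGG"
        rev_rc = "TTTTCCCCGGGGAAAA"  # 12-base true overlap with fwd
        res = merge_pairs(*self._tables(fwd, revcomp(rev_rc)))
        assert res.table.variants == [("AAAATTTTCCCCGGGGAAAA", 20)]
        assert res.n_unmerged_reads == 0

    def test_overlap_below_minimum_unmerged(self):
        fwd = "AAAATTTTCCCCGGGG"
        rev_rc = fwd[8:] + "ACGTACGTAC"  # true overlap is only 8 bases
        res = merge_pairs(*self._tables(fwd, revcomp(rev_rc)))
        assert len(res.table) == 0
        assert res.n_unmerged_reads == 20

    def test_error_free_pairs_reconstruct_template(self, scheme, zero_noise_run):
        truth = zero_noise_run.truth
        for cid in list(truth.templates)[:4]:
            template = truth.templates[cid]
            pairs = read_fastq_pairs(*zero_noise_run.specimen_fastqs[cid])
            trimmed, _ = trim_pairs(pairs, scheme)
            ft, fa = denoise_reads([(p.read_id, p.fwd_seq) for p in trimmed], cid)
            rt, ra = denoise_reads([(p.read_id, p.rev_seq) for p in trimmed], cid)
            res = merge_pairs(ft, rt, fa, ra)
            assert res.table.variants[0][0] == template


CHIM_A = "ACGTAG" * 40
CHIM_B = "TTGCAA" * 40


class TestRemoveBimeras:
    def test_constructed_bimera_removed(self):
        chim = make_chimera(CHIM_A, CHIM_B, 100)
        table = VariantTable("s", "merged", [(CHIM_A, 100), (CHIM_B, 100), (chim, 10)])
        clean, flagged = remove_bimeras(table)
        assert flagged == [chim]
        assert clean.sequences() == [CHIM_A, CHIM_B]

    def test_low_abundance_parent_not_sufficient(self):
        chim = make_chimera(CHIM_A, CHIM_B, 100)
        table = VariantTable("s", "merged", [(CHIM_A, 100), (chim, 60), (CHIM_B, 50)])
        clean, flagged = remove_bimeras(table)
        assert flagged == []
        assert len(clean) == 3

    def test_single_variant_unchanged(self):
        table = VariantTable("s", "merged", [(CHIM_A, 7)])
        clean, flagged = remove_bimeras(table)
        assert clean.variants == table.variants
        assert flagged == []

    def test_simulated_chimeric_variants_flagged(self, scheme, tmp_path):
        """>=80% of truth-labelled chimeric variants removed, and no true
        template ever flagged."""
        from mycobarcode.pipeline import run_specimen_pipeline
        from mycobarcode.denoise import filter_reads

        cfg = SimConfig(n_specimens=16, depth_mean=150, chimera_rate=0.05,
                        contamination_rate=0.6, seed=11)
        run = simulate_run(scheme, cfg, tmp_path)
        chim_reads = run.truth.reads[run.truth.reads.provenance == "chimera"]
        n_present = n_flagged = n_template_flagged = 0
        for cid in run.truth.templates:
            pairs = read_fastq_pairs(*run.specimen_fastqs[cid])
            trimmed, _ = trim_pairs(pairs, scheme)
            filtered = filter_reads(trimmed)
            ft, fa = denoise_reads([(p.read_id, p.fwd_seq) for p in filtered], cid)
            rt, ra = denoise_reads([(p.read_id, p.rev_seq) for p in filtered], cid)
            merged = merge_pairs(ft, rt, fa, ra)
            clean, flagged = remove_bimeras(merged.table)
            cores = {
                make_chimera(
                    run.truth.templates[row.source.split("+")[0]],
                    run.truth.templates[row.source.split("+")[1]],
                    int(row.breakpoint),
                )
                for row in chim_reads[chim_reads.specimen == cid].itertuples()
            }
            present = [s for s in merged.table.sequences() if s in cores]
            n_present += len(present)
            n_flagged += sum(s in flagged for s in present)
            truths = {run.truth.templates[cid]}
            if cid in run.truth.contaminated:
                truths.add(run.truth.templates[run.truth.contaminated[cid][0]])
            n_template_flagged += sum(s in truths for s in flagged)
        assert n_present >= 10
        assert n_flagged / n_present >= 0.8
        assert n_template_flagged == 0


def test_pipeline_counts_never_increase(default_results):
    summary, results = default_results
    df = summary.rows
    assert (df.raw_pairs >= df.trimmed_pairs).all()
    assert (df.trimmed_pairs >= df.filtered_pairs).all()
    assert (df.filtered_pairs >= df.merged_pairs).all()
    for res in results.values():
        assert res.table.total_count <= res.counts["merged_pairs"]
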