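import pytest

from mycobarcode._dna import revcomp
from mycobarcode._seqio import ReadPair, read_fastq_pairs
from mycobarcode.scheme import PrimerScheme
from mycobarcode.simulate import SimConfig, simulate_run
from mycobarcode.trimdemux import demux_pool, demux_read, trim_pairs, trim_readthrough

from tests.oracles import demux_oracle


def _read_for(scheme, barcode_id, spacer="", template="ACGT" * 40):
    return spacer + scheme.barcode(barcode_id) + scheme.reverse_primer + template


class TestDemuxRead:
    def test_exact_read_assigned(self, scheme):
        call = demux_read(_read_for(scheme, 3), scheme)
        assert call.barcode_id == 3
        assert call.mismatches == 0
        assert call.spacer_len == 0

    def test_spacer_shift_found(self, scheme):
        call = demux_read(_read_for(scheme, 5, spacer="CGAT"), scheme)
        assert call.barcode_id == 5
        assert call.spacer_len == 4

    def test_one_barcode_mismatch_tolerated(self, scheme):
        bc = list(scheme.barcode(2))
        bc[1] = "A" if bc[1] != "A" else "C"
        read = "".join(bc) + scheme.reverse_primer + "ACGT" * 30
        call = demux_read(read, scheme)
        assert call.barcode_id == 2
        assert call.mismatches == 1

    def test_distant_barcode_unassigned(self, scheme):
        # barcode region equally far (>=2) from every pool barcode
        read = _read_for(scheme, 1)
        for candidate in ("AAAAA", "GGGGG", "ACACA", "GTGTG"):
            probe = candidate + read[5:]
            mm = [sum(a != b for a, b in zip(candidate, b2)) for b2 in scheme.barcodes]
            if min(mm) > 1:
                call = demux_read(probe, scheme)
                assert call.reason == "no_barcode"
                return
        pytest.fail("no suitably distant probe barcode found")

    def test_short_read_is_no_primer(self, scheme):
        call = demux_read("ACGTACG", scheme)
        assert call.reason == "no_primer"

    def test_primer_mismatch_over_budget_is_no_primer(self, scheme):
        primer = list(scheme.reverse_primer)
        for i in (2, 5, 9):
            primer[i] = "A" if primer[i] != "A" else "C"
        read = scheme.barcode(1) + "".join(primer) + "ACGT" * 30
        call = demux_read(read, scheme)
        assert call.reason == "no_primer"

    def test_equidistant_barcodes_are_ambiguous(self):
        with pytest.warns(UserWarning):
            s = PrimerScheme(
                forward_primer="GGGGGGGG",
                reverse_primer="TTTTTTTT",
                cs1_tag="CC",
                cs2_tag="TT",
                forward_spacers=("",),
                reverse_spacers=("",),
                barcodes=("AAAAA", "AAGGG"),
            )
        # observed AAGCA is Hamming 2 from both barcodes
        call = demux_read("AAGCA" + "TTTTTTTT" + "ACGT" * 10, s, barcode_mismatches=2)
        assert call.reason == "ambiguous_barcode"


class TestDemuxAgainstOracle:
    def test_brute_force_agreement_and_truth_accuracy(self, scheme, tmp_path):
        """Demux matches exhaustive enumeration on every read and the truth
        assignment on >=99% of ~5,000 reads at ~0.5% error."""
        cfg = SimConfig(
            n_specimens=8, pool_size=8, depth_mean=850,
            mean_phred=23.0, phred_jitter_sd=0.0, phred_decay=0.0,
            chimera_rate=0.0, contamination_rate=0.0, seed=3,
        )
        run = simulate_run(scheme, cfg, tmp_path)
        truth_bc = dict(zip(run.truth.reads.read_id, run.truth.reads.barcode_id))
        pool_ids = list(range(1, 9))
        n = agree_truth = 0
        (r1p, r2p) = next(iter(run.pool_fastqs.values()))
        for p in read_fastq_pairs(r1p, r2p):
            call = demux_read(p.rev_seq, scheme, pool_ids)
            mine = (
                call.barcode_id
                if call.assigned
                else ("ambiguous" if call.reason == "ambiguous_barcode" else "none")
            )
            oracle = demux_oracle(p.rev_seq, scheme, pool_ids)
            assert mine == oracle, f"{p.read_id}: {mine} != oracle {oracle}"
            n += 1
            agree_truth += call.barcode_id == truth_bc[p.read_id]
        assert n >= 4000
        assert agree_truth / n >= 0.99

    def test_zero_error_demux_is_perfect(self, scheme, zero_noise_run):
        truth = zero_noise_run.truth
        for pid, (r1p, r2p) in zero_noise_run.pool_fastqs.items():
            members = truth.reads[truth.reads.pool_id == pid]
            pool_bcs = sorted(members.barcode_id.unique())
            truth_bc = dict(zip(members.read_id, members.barcode_id))
            for p in read_fastq_pairs(r1p, r2p):
                call = demux_read(p.rev_seq, scheme, pool_bcs)
                assert call.barcode_id == truth_bc[p.read_id]


class TestDemuxPool:
    def test_partition_invariant(self, scheme, default_run):
        pid, (r1, r2) = next(iter(default_run.pool_fastqs.items()))
        members = {
            s.barcode_id: s.catalog_id
            for s in default_run.specimens
            if s.pool_id == pid
        }
        result, buffers = demux_pool(r1, r2, scheme, members)
        result.check_partition()
        assert result.n_assigned > 0
        assert sum(len(b) for b in buffers.values()) == result.n_assigned


def _qual(n):
    return "I" * n  # Q40


def _pair(read_id, fwd, rev):
    return ReadPair(read_id, fwd, _qual(len(fwd)), rev, _qual(len(rev)))


class TestTrimReadthrough:
    def _construct_pair(self, scheme, template, read_length=250):
        """Per-specimen-style pair: template plus 3' read-through."""
        bc = scheme.barcode(1)
        r1 = (template + revcomp(scheme.reverse_primer) + revcomp(bc)
              + revcomp(scheme.cs2_tag))[:read_length]
        r2 = (revcomp(template) + revcomp(scheme.forward_primer)
              + revcomp(scheme.cs1_tag))[:read_length]
        return _pair("r1", r1, r2)

    def test_short_template_pair_discarded(self, scheme):
        template = "ACGTA" * 30  # 150 bp < 200 bp floor
        pair = self._construct_pair(scheme, template)
        assert trim_readthrough(pair, scheme) is None

    def test_long_template_unchanged(self, scheme):
        import numpy as np

        rng = np.random.default_rng(0)
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        pair = self._construct_pair(scheme, template)
        out = trim_readthrough(pair, scheme)
        assert out is not None
        assert out.fwd_seq == pair.fwd_seq
        assert out.rev_seq == pair.rev_seq

    def test_midlength_template_trimmed_and_retained(self, scheme):
        import numpy as np

        rng = np.random.default_rng(1)
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 220))
        bc = scheme.barcode(1)
        r1 = template + revcomp(scheme.reverse_primer) + "ACGTACGTAC"
        pair = _pair("x", r1, revcomp(template) + revcomp(scheme.forward_primer) + "TTTTTTTTTT")
        out = trim_readthrough(pair, scheme)
        assert out is not None
        assert out.fwd_seq == template
        assert out.rev_seq == revcomp(template)

    def test_terminal_partial_adapter_trimmed(self, scheme):
        import numpy as np

        rng = np.random.default_rng(2)
        template = "".join("ACGT"[i] for i in rng.integers(0, 4, 240))
        r1 = template + revcomp(scheme.reverse_primer)[:10]
        pair = _pair("y", r1, revcomp(template))
        out = trim_readthrough(pair, scheme)
        assert out is not None
        assert out.fwd_seq == template

    def test_never_lengthens_and_idempotent(self, scheme, default_run):
        cid = next(iter(default_run.specimen_fastqs))
        pairs = read_fastq_pairs(*default_run.specimen_fastqs[cid])[:50]
        kept, report = trim_pairs(pairs, scheme)
        assert report.n_in == len(pairs)
        for before, after in zip(
            [p for p in pairs if trim_readthrough(p, scheme) is not None], kept
        ):
            assert len(after.fwd_seq) <= len(before.fwd_seq)
            assert len(after.rev_seq) <= len(before.rev_seq)
        twice, _ = trim_pairs(kept, scheme)
        assert [(p.fwd_seq, p.rev_seq) for p in twice] == [
            (p.fwd_seq, p.rev_seq) for p in kept
        ]
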