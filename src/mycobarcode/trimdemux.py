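"""Inline-barcode demultiplexing and 3' read-through trimming.

Demultiplexing re-implements the facility step: each R2 read begins with a
variable heterogeneity spacer (0–4 bp), a 5-bp inline barcode and the
reverse locus primer; reads are assigned by scanning every candidate spacer
length, matching the barcode within a mismatch tolerance and confirming the
primer (IUPAC-aware).  Because the barcode set enforces pairwise Hamming
distance ≥ 3, the default 1-mismatch tolerance can never produce a
same-score collision between barcodes on an error-free read.

Trimming removes 3' read-through: when the ITS2 fragment is shorter than the
read, the read runs into the reverse complement of the opposite construct
(opposite primer first, then barcode/spacer/CS tag).  The opposite primer is
located by approximate search (error rate 0.1); reads are truncated at the
hit, and pairs are discarded when either trimmed mate falls below the
scheme's minimum length (200 bp by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from mycobarcode._dna import IUPAC, hamming, iupac_mismatches, revcomp
from mycobarcode._seqio import ReadPair, read_fastq_pairs, write_fastq_pairs
from mycobarcode.scheme import BARCODE_LENGTH, MAX_FORWARD_SPACER, MAX_REVERSE_SPACER, PrimerScheme

__all__ = [
    "DemuxCall",
    "DemuxResult",
    "TrimReport",
    "demux_read",
    "demux_pool",
    "trim_readthrough",
    "trim_pairs",
]

DEFAULT_BARCODE_MISMATCHES = 1
DEFAULT_PRIMER_MISMATCHES = 2
DEFAULT_ADAPTER_ERROR_RATE = 0.1
MIN_PARTIAL_ADAPTER = 5

UNASSIGNED_REASONS = ("no_barcode", "ambiguous_barcode", "no_primer")

#: edlib equality pairs so IUPAC degeneracy codes in primers match any base
#: they cover.
_IUPAC_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC.items()
    if len(bases) > 1
    for base in sorted(bases)
]


@dataclass(frozen=True)
class DemuxCall:
    """Outcome of demultiplexing a single R2 read."""

    barcode_id: int | None
    reason: str | None = None  # set iff unassigned
    spacer_len: int | None = None
    mismatches: int | None = None

    @property
    def assigned(self) -> bool:
        return self.barcode_id is not None


def demux_read(
    read2_sequence: str,
    scheme: PrimerScheme,
    pool_barcodes: Sequence[int] | None = None,
    barcode_mismatches: int = DEFAULT_BARCODE_MISMATCHES,
    primer_mismatches: int = DEFAULT_PRIMER_MISMATCHES,
) -> DemuxCall:
    """Assign one R2 read to an inline barcode, or explain why not.

    For each candidate spacer length ``s`` (0 to the maximum reverse spacer),
    ``read[s:s+5]`` is compared against each pool barcode (≤
    ``barcode_mismatches``) and the following window against the reverse
    primer (≤ ``primer_mismatches``, IUPAC-aware).  The (spacer, barcode)
    candidate with minimum total mismatches wins; a tie between distinct
    barcodes is ``ambiguous_barcode``; no candidate is ``no_barcode`` (the
    barcode never matched) or ``no_primer`` (a barcode matched but the primer
    never confirmed, or the read is too short).
    """
    if pool_barcodes is None:
        pool_barcodes = list(range(1, scheme.n_barcodes + 1))
    primer = scheme.reverse_primer
    plen = len(primer)
    seq = read2_sequence.upper()
    if len(seq) < BARCODE_LENGTH + plen + 1:
        return DemuxCall(None, reason="no_primer")

    best: list[tuple[int, int, int]] = []  # (total_mm, spacer_len, barcode_id)
    best_mm: int | None = None
    barcode_hit = False
    primer_hit = False
    for s in range(0, MAX_REVERSE_SPACER + 1):
        bc_obs = seq[s : s + BARCODE_LENGTH]
        if len(bc_obs) < BARCODE_LENGTH:
            break
        primer_obs = seq[s + BARCODE_LENGTH : s + BARCODE_LENGTH + plen]
        for bc_id in pool_barcodes:
            d_bc = hamming(bc_obs, scheme.barcode(bc_id))
            if d_bc > barcode_mismatches:
                continue
            barcode_hit = True
            if len(primer_obs) < plen:
                continue
            d_pr = iupac_mismatches(primer_obs, primer)
            if d_pr > primer_mismatches:
                continue
            primer_hit = True
            total = d_bc + d_pr
            if best_mm is None or total < best_mm:
                best_mm = total
                best = [(total, s, bc_id)]
            elif total == best_mm:
                best.append((total, s, bc_id))
    if not best:
        if barcode_hit and not primer_hit:
            return DemuxCall(None, reason="no_primer")
        return DemuxCall(None, reason="no_barcode")
    distinct = {bc for _, _, bc in best}
    if len(distinct) > 1:
        return DemuxCall(None, reason="ambiguous_barcode")
    total, s, bc_id = min(best, key=lambda t: t[1])  # smallest spacer on same-barcode tie
    return DemuxCall(bc_id, spacer_len=s, mismatches=total)


def _locate_forward_primer(
    seq: str, scheme: PrimerScheme, primer_mismatches: int
) -> int | None:
    """Find end position of (spacer + forward primer) at a read's 5' end; None
    if the primer is not found at any admissible spacer offset."""
    primer = scheme.forward_primer
    plen = len(primer)
    best_end, best_mm = None, None
    for s in range(0, MAX_FORWARD_SPACER + 1):
        window = seq[s : s + plen]
        if len(window) < plen:
            break
        mm = iupac_mismatches(window, primer)
        if mm <= primer_mismatches and (best_mm is None or mm < best_mm):
            best_end, best_mm = s + plen, mm
    return best_end


@dataclass
class DemuxResult:
    """Partition of one pool's reads into specimens and an unassigned bin."""

    assigned: dict[str, list[str]]  # specimen -> read ids
    unassigned: dict[str, list[str]]  # reason -> read ids
    n_total: int
    n_strict_agree: int = 0  # reads where 0-mismatch demux gives the same call

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_unassigned(self) -> int:
        return sum(len(v) for v in self.unassigned.values())

    def check_partition(self) -> None:
        if self.n_assigned + self.n_unassigned != self.n_total:
            raise AssertionError("demux partition invariant violated")


def demux_pool(
    r1_path: str | Path,
    r2_path: str | Path,
    scheme: PrimerScheme,
    pool_members: Mapping[int, str],
    outdir: str | Path | None = None,
    barcode_mismatches: int = DEFAULT_BARCODE_MISMATCHES,
    primer_mismatches: int = DEFAULT_PRIMER_MISMATCHES,
) -> tuple[DemuxResult, dict[str, list[ReadPair]]]:
    """Demultiplex one pool's paired FASTQ into per-specimen read pairs.

    ``pool_members`` maps barcode id -> specimen id.  Assigned pairs have the
    5' construct stripped from both mates (R2 by the demux call's offset; R1
    by locating spacer + forward primer); pairs whose R1 primer cannot be
    located are unassigned with reason ``no_primer``.  When ``outdir`` is
    given, per-specimen FASTQ pairs are appended there.  Also tallies, for
    comparability, how many calls agree with a strict zero-mismatch demux.
    """
    pairs = read_fastq_pairs(r1_path, r2_path)
    barcodes = sorted(pool_members)
    result = DemuxResult(
        assigned={cid: [] for cid in pool_members.values()},
        unassigned={r: [] for r in UNASSIGNED_REASONS},
        n_total=len(pairs),
    )
    buffers: dict[str, list[ReadPair]] = {cid: [] for cid in pool_members.values()}
    plen_r = len(scheme.reverse_primer)
    for p in pairs:
        call = demux_read(
            p.rev_seq, scheme, barcodes, barcode_mismatches, primer_mismatches
        )
        strict = demux_read(p.rev_seq, scheme, barcodes, 0, 0)
        if strict.barcode_id == call.barcode_id:
            result.n_strict_agree += 1
        if not call.assigned:
            result.unassigned[call.reason].append(p.read_id)
            continue
        cut1 = _locate_forward_primer(p.fwd_seq, scheme, primer_mismatches)
        if cut1 is None:
            result.unassigned["no_primer"].append(p.read_id)
            continue
        cid = pool_members[call.barcode_id]
        cut2 = call.spacer_len + BARCODE_LENGTH + plen_r
        result.assigned[cid].append(p.read_id)
        buffers[cid].append(
            ReadPair(
                p.read_id,
                p.fwd_seq[cut1:],
                p.fwd_qual[cut1:],
                p.rev_seq[cut2:],
                p.rev_qual[cut2:],
            )
        )
    result.check_partition()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cid, buf in buffers.items():
            write_fastq_pairs(
                outdir / f"{cid}_R1.fastq.gz", outdir / f"{cid}_R2.fastq.gz", buf
            )
    return result, buffers


def _trim_one(seq: str, qual: str, adapter: str, error_rate: float) -> tuple[str, str]:
    """Truncate ``seq`` at the start of the best 3' read-through hit.

    Full-pattern hits anywhere in the read are found by approximate infix
    search (rightmost among best-scoring); if none, 3'-terminal partial
    occurrences of the adapter prefix (≥ 5 bp) are checked, longest first.
    """
    k = int(error_rate * len(adapter))
    res = edlib.align(adapter, seq, mode="HW", task="locations", k=k,
                      additionalEqualities=_IUPAC_EQUALITIES)
    if res["editDistance"] != -1 and res["locations"]:
        start = max(loc[0] for loc in res["locations"] if loc[0] is not None)
        return seq[:start], qual[:start]
    for L in range(min(len(adapter), len(seq)) - 1, MIN_PARTIAL_ADAPTER - 1, -1):
        allowed = int(error_rate * L)
        if iupac_mismatches(seq[-L:], adapter[:L]) <= allowed:
            return seq[: len(seq) - L], qual[: len(qual) - L]
    return seq, qual


def trim_readthrough(
    pair: ReadPair,
    scheme: PrimerScheme,
    error_rate: float = DEFAULT_ADAPTER_ERROR_RATE,
    min_length: int | None = None,
) -> ReadPair | None:
    """Trim 3' read-through from both mates; None if the pair is discarded.

    The forward mate is searched for the reverse complement of the reverse
    primer, the reverse mate for the reverse complement of the forward
    primer.  A pair survives only if both trimmed mates reach the scheme's
    ``min_trimmed_length`` (or ``min_length`` if given); discard is a
    recorded outcome, not an error.  Never lengthens a read; idempotent on
    its own output for construct-derived reads.
    """
    floor = scheme.min_trimmed_length if min_length is None else min_length
    f_seq, f_qual = _trim_one(
        pair.fwd_seq, pair.fwd_qual, revcomp(scheme.reverse_primer), error_rate
    )
    r_seq, r_qual = _trim_one(
        pair.rev_seq, pair.rev_qual, revcomp(scheme.forward_primer), error_rate
    )
    if len(f_seq) < floor or len(r_seq) < floor:
        return None
    return ReadPair(pair.read_id, f_seq, f_qual, r_seq, r_qual)


@dataclass
class TrimReport:
    n_in: int = 0
    n_trimmed: int = 0  # pairs where at least one mate was shortened
    n_discarded: int = 0

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_discarded


def trim_pairs(
    pairs: Iterable[ReadPair],
    scheme: PrimerScheme,
    error_rate: float = DEFAULT_ADAPTER_ERROR_RATE,
    min_length: int | None = None,
) -> tuple[list[ReadPair], TrimReport]:
    """Apply :func:`trim_readthrough` to a stream of pairs with counts."""
    kept: list[ReadPair] = []
    report = TrimReport()
    for p in pairs:
        report.n_in += 1
        trimmed = trim_readthrough(p, scheme, error_rate, min_length)
        if trimmed is None:
            report.n_discarded += 1
            continue
        if len(trimmed.fwd_seq) < len(p.fwd_seq) or len(trimmed.rev_seq) < len(p.rev_seq):
            report.n_trimmed += 1
        kept.append(trimmed)
    return kept, report
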