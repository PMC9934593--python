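"""Per-specimen read cleaning: expected-error filtering, variant denoising,
pair merging, and bimera removal.

The pipeline mirrors a DADA2-style amplicon workflow run per specimen rather
than per community sample: reads are quality-truncated and filtered by
expected errors (EE = Σ 10^(-Q/10), kept when EE ≤ 3), forward and reverse
mates are independently collapsed into denoised sequence variants, variants
are merged across mates into full-fragment contigs by exact overlap, and
two-parent chimeras (bimeras) are removed per specimen based on the abundance
of their putative parents.

The denoiser here replaces the published tool's learned error model with an
explicit, transparent collapse rule: in descending abundance, a sequence is
absorbed as an error child of the most abundant earlier equal-length sequence
within Hamming distance ``d_max`` whose (accumulated) count is at least
``r_min`` times its own.  The output contract — unique sequence variants,
each with the number of reads supporting it — is preserved.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mycobarcode._dna import hamming, revcomp
from mycobarcode._seqio import ReadPair, qual_to_phred

__all__ = [
    "VariantTable",
    "MergeResult",
    "expected_errors",
    "filter_reads",
    "denoise_reads",
    "merge_pairs",
    "remove_bimeras",
]

STAGES = ("filtered", "denoised", "merged", "bimera_free")

DEFAULT_MAX_EE = 3.0
DEFAULT_TRUNCQ = 2
DEFAULT_D_MAX = 2
DEFAULT_R_MIN = 4.0
DEFAULT_MIN_OVERLAP = 12
DEFAULT_MAX_MISMATCH = 0
DEFAULT_PARENT_RATIO = 2.0


@dataclass
class VariantTable:
    """Unique sequences with supporting read counts for one specimen.

    Variants are kept count-descending, ties in first-seen order; counts are
    positive and sequences unique.  ``stage`` records pipeline provenance.
    """

    specimen_id: str
    stage: str
    variants: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        seqs = [s for s, _ in self.variants]
        if len(set(seqs)) != len(seqs):
            raise ValueError(f"{self.specimen_id}: duplicate sequence in variant table")
        counts = [c for _, c in self.variants]
        if any(c < 1 for c in counts):
            raise ValueError(f"{self.specimen_id}: non-positive variant count")
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(f"{self.specimen_id}: variants not in descending count order")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def total_count(self) -> int:
        return sum(c for _, c in self.variants)

    def sequences(self) -> list[str]:
        return [s for s, _ in self.variants]


def expected_errors(quality: str | Sequence[int]) -> float:
    """Expected number of errors in a read: Σ_i 10^(-Q_i/10).

    ``quality`` is an ASCII offset-33 string or a sequence of Phred integers;
    an empty read has zero expected errors.
    """
    phred = qual_to_phred(quality) if isinstance(quality, str) else list(quality)
    if any(q < 0 for q in phred):
        raise ValueError("Phred scores must be >= 0")
    return float(sum(10.0 ** (-q / 10.0) for q in phred))


def _truncate_at_q(seq: str, qual: str, truncq: int) -> tuple[str, str]:
    """Truncate at the first base with quality below ``truncq``."""
    for i, c in enumerate(qual):
        if ord(c) - 33 < truncq:
            return seq[:i], qual[:i]
    return seq, qual


def filter_reads(
    pairs: Iterable[ReadPair],
    max_ee: float = DEFAULT_MAX_EE,
    truncq: int = DEFAULT_TRUNCQ,
) -> list[ReadPair]:
    """Quality-truncate and expected-error filter read pairs.

    Each mate is truncated at its first base with Q < ``truncq``; the pair is
    retained iff both truncated mates are non-empty with EE ≤ ``max_ee``.
    Input order is preserved.
    """
    kept: list[ReadPair] = []
    for p in pairs:
        fseq, fq = _truncate_at_q(p.fwd_seq, p.fwd_qual, truncq)
        rseq, rq = _truncate_at_q(p.rev_seq, p.rev_qual, truncq)
        if not fseq or not rseq:
            continue
        if expected_errors(fq) <= max_ee and expected_errors(rq) <= max_ee:
            kept.append(ReadPair(p.read_id, fseq, fq, rseq, rq))
    return kept


def denoise_reads(
    reads: Sequence[tuple[str, str]],
    specimen_id: str = "",
    d_max: int = DEFAULT_D_MAX,
    r_min: float = DEFAULT_R_MIN,
) -> tuple[VariantTable, dict[str, int]]:
    """Collapse one specimen's (single-direction) reads into denoised variants.

    ``reads`` are ``(read_id, sequence)`` pairs.  Returns the variant table
    (stage ``denoised``) and a map from read id to the index of the variant
    the read supports — needed downstream to pair forward with reverse
    variants.  Counts are conserved: table total equals the input read count.
    Comparison is equal-length Hamming only; indel variants stay distinct.
    """
    if not reads:
        return VariantTable(specimen_id, "denoised", []), {}

    counts: Counter[str] = Counter(seq for _, seq in reads)
    first_seen: dict[str, int] = {}
    for i, (_, seq) in enumerate(reads):
        first_seen.setdefault(seq, i)
    uniques = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))

    # surviving variants: [representative sequence, accumulated count, member set]
    survivors: list[list] = []
    member_of: dict[str, int] = {}
    for seq in uniques:
        c = counts[seq]
        best = -1
        best_count = 0
        for idx, (rep, acc, _) in enumerate(survivors):
            if len(rep) != len(seq) or acc < r_min * c:
                continue
            if hamming(rep, seq) <= d_max and acc > best_count:
                best, best_count = idx, acc
        if best >= 0:
            survivors[best][1] += c
            survivors[best][2].append(seq)
            member_of[seq] = best
        else:
            member_of[seq] = len(survivors)
            survivors.append([seq, c, [seq]])

    order = sorted(
        range(len(survivors)),
        key=lambda i: (-survivors[i][1], first_seen[survivors[i][0]]),
    )
    rank_of = {old: new for new, old in enumerate(order)}
    table = VariantTable(
        specimen_id,
        "denoised",
        [(survivors[i][0], survivors[i][1]) for i in order],
    )
    assignment = {rid: rank_of[member_of[seq]] for rid, seq in reads}
    return table, assignment


def _overlap_merge(
    fwd: str, rev_rc: str, min_overlap: int, max_mismatch: int
) -> str | None:
    """Merge by the longest end-gap-free overlap (no indels) within the
    mismatch budget; None if no overlap of at least ``min_overlap`` fits."""
    for ov in range(min(len(fwd), len(rev_rc)), min_overlap - 1, -1):
        mism = 0
        tail = fwd[len(fwd) - ov :]
        head = rev_rc[:ov]
        ok = True
        for a, b in zip(tail, head):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    ok = False
                    break
        if ok:
            return fwd + rev_rc[ov:]
    return None


@dataclass
class MergeResult:
    table: VariantTable
    n_merged_reads: int
    n_unmerged_reads: int


def merge_pairs(
    fwd_table: VariantTable,
    rev_table: VariantTable,
    fwd_assignment: Mapping[str, int],
    rev_assignment: Mapping[str, int],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> MergeResult:
    """Merge denoised forward/reverse variants into full-fragment contigs.

    Read pairs are grouped into (forward variant, reverse variant) classes
    via the denoising assignments; each class is merged by overlap alignment
    (reverse variant reverse-complemented first, no indels, overlap maximised
    under the mismatch budget).  Unmergeable classes are dropped with their
    read counts reported.
    """
    class_counts: Counter[tuple[int, int]] = Counter()
    for rid, fidx in fwd_assignment.items():
        ridx = rev_assignment.get(rid)
        if ridx is not None:
            class_counts[(fidx, ridx)] += 1

    merged: dict[str, int] = {}
    seen_order: dict[str, int] = {}
    n_merged = n_unmerged = 0
    for rank, ((fidx, ridx), c) in enumerate(
        sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ):
        fwd_seq = fwd_table.variants[fidx][0]
        rev_seq = rev_table.variants[ridx][0]
        contig = _overlap_merge(fwd_seq, revcomp(rev_seq), min_overlap, max_mismatch)
        if contig is None:
            n_unmerged += c
            continue
        n_merged += c
        merged[contig] = merged.get(contig, 0) + c
        seen_order.setdefault(contig, rank)

    variants = sorted(merged.items(), key=lambda kv: (-kv[1], seen_order[kv[0]]))
    table = VariantTable(fwd_table.specimen_id, "merged", variants)
    return MergeResult(table, n_merged, n_unmerged)


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def _lcs_suffix(a: str, b: str) -> int:
    n = 0
    for x, y in zip(reversed(a), reversed(b)):
        if x != y:
            break
        n += 1
    return n


def _is_bimera_of(child: str, left: str, right: str) -> bool:
    """True if ``child`` equals an exact left-prefix/right-suffix join at some
    interior breakpoint (prefixes aligned at the 5' end, suffixes at the 3')."""
    lcp = _lcp(child, left)
    lcs = _lcs_suffix(child, right)
    n = len(child)
    k_lo = max(1, n - lcs)
    k_hi = min(lcp, n - 1)
    return k_lo <= k_hi


def remove_bimeras(
    table: VariantTable,
    parent_ratio: float = DEFAULT_PARENT_RATIO,
) -> tuple[VariantTable, list[str]]:
    """Remove two-parent chimeras from one specimen's merged variant table.

    A variant C is flagged iff two distinct other variants A and B each have
    at least ``parent_ratio`` × count(C) reads and C is an exact two-part
    join of A's prefix and B's suffix at some interior breakpoint.  Parent
    abundance is judged on the input table (one pass, no cascading).
    Returns the bimera-free table and the flagged sequences.
    """
    flagged: list[str] = []
    for ci, (cseq, ccount) in enumerate(table.variants):
        parents = [
            (seq, cnt)
            for pi, (seq, cnt) in enumerate(table.variants)
            if pi != ci and cnt >= parent_ratio * ccount
        ]
        if len(parents) < 2:
            continue
        found = False
        for aseq, _ in parents:
            for bseq, _ in parents:
                if aseq is bseq:
                    continue
                if _is_bimera_of(cseq, aseq, bseq):
                    found = True
                    break
            if found:
                break
        if found:
            flagged.append(cseq)
    flagged_set = set(flagged)
    kept = [(s, c) for s, c in table.variants if s not in flagged_set]
    return VariantTable(table.specimen_id, "bimera_free", kept), flagged
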