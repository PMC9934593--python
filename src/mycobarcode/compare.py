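"""Concordance scoring of representative barcodes against Sanger/reference
sequences.

Pairwise comparison uses local (Smith–Waterman) alignment with affine gap
penalties under a megablast-like scoring scheme (match +2, mismatch −3, gap
open −5, gap extend −2; a gap of length L costs open + (L−1)·extend).
Percent identity is the fraction of matching columns among aligned columns
(gap columns included); percent coverage is the aligned subject span over
the subject length — with a specimen's Illumina representative as subject,
this reproduces how much of the Illumina sequence a trimmed Sanger read
covers.  Identities are reported in the standard similarity bins
97.5–100 / 95–97.5 / 90–95 / 85–90 / <85.

The reported alignment is deterministic and well-defined among co-optimal
local alignments: the optimisation is lexicographic on (score, matches,
−gap columns, −mismatches), followed by the alignment ending first in
row-major order of (query, subject) positions and a fixed within-cell move
preference (substitution, then gap-in-subject, then gap-in-query; opening
over extension).  The first four criteria are invariant under swapping
query and subject, which makes percent identity exactly symmetric; percent
coverage is not (its denominator is the subject length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from numba import njit

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "ConcordanceVerdict",
    "align_pair",
    "best_hit",
    "classify_concordance",
    "identity_bin",
    "IDENTITY_BINS",
]

NEG_INF = -(10**9)

IDENTITY_BINS = ("97.5-100", "95-97.5", "90-95", "85-90", "<85")
_HIGH_BINS = frozenset(("97.5-100", "95-97.5", "90-95"))  # identity >= 90

CONCORDANT = "concordant"
DISCORDANT_NOMENCLATURE = "discordant_nomenclature"
PUTATIVE_CONTAMINANT = "putative_contaminant"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5  # cost of the first base of a gap
    gap_extend: int = -2  # each additional gapped base


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment of a query against a subject."""

    score: int
    percent_identity: float
    percent_coverage: float
    aligned_length: int
    n_matches: int
    n_gaps: int
    query_start: int  # 0-based, half-open span of the query in the alignment
    query_end: int
    subject_start: int
    subject_end: int


@njit(cache=True)
def _lex_gt(a0, a1, a2, a3, b0, b1, b2, b3):  # pragma: no cover
    """a > b on (score, matches, -gap columns, -mismatches)."""
    if a0 != b0:
        return a0 > b0
    if a1 != b1:
        return a1 > b1
    if a2 != b2:
        return a2 > b2
    return a3 > b3


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = q.shape[0]
    m = s.shape[0]
    # Each DP state tracks the lexicographic objective
    # (score, matches, -gap columns, -mismatches); the latter three are
    # stored negated-free as counts with comparison handled in _lex_gt.
    H0 = np.zeros((n + 1, m + 1), np.int32)  # score
    H1 = np.zeros((n + 1, m + 1), np.int32)  # matches
    H2 = np.zeros((n + 1, m + 1), np.int32)  # -gap columns
    H3 = np.zeros((n + 1, m + 1), np.int32)  # -mismatches
    E0 = np.full((n + 1, m + 1), NEG_INF, np.int32)
    E1 = np.zeros((n + 1, m + 1), np.int32)
    E2 = np.zeros((n + 1, m + 1), np.int32)
    E3 = np.zeros((n + 1, m + 1), np.int32)
    F0 = np.full((n + 1, m + 1), NEG_INF, np.int32)
    F1 = np.zeros((n + 1, m + 1), np.int32)
    F2 = np.zeros((n + 1, m + 1), np.int32)
    F3 = np.zeros((n + 1, m + 1), np.int32)
    ptrH = np.zeros((n + 1, m + 1), np.int8)  # 0 stop, 1 diag, 2 from F (up), 3 from E (left)
    ptrE = np.zeros((n + 1, m + 1), np.int8)  # 1 open from H, 2 extend
    ptrF = np.zeros((n + 1, m + 1), np.int8)
    b0 = 0
    b1 = 0
    b2 = 0
    b3 = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # F: gap in subject (consumes a query base)
            if _lex_gt(
                F0[i - 1, j] + gap_extend, F1[i - 1, j], F2[i - 1, j] - 1, F3[i - 1, j],
                H0[i - 1, j] + gap_open, H1[i - 1, j], H2[i - 1, j] - 1, H3[i - 1, j],
            ):
                F0[i, j] = F0[i - 1, j] + gap_extend
                F1[i, j] = F1[i - 1, j]
                F2[i, j] = F2[i - 1, j] - 1
                F3[i, j] = F3[i - 1, j]
                ptrF[i, j] = 2
            else:
                F0[i, j] = H0[i - 1, j] + gap_open
                F1[i, j] = H1[i - 1, j]
                F2[i, j] = H2[i - 1, j] - 1
                F3[i, j] = H3[i - 1, j]
                ptrF[i, j] = 1
            # E: gap in query (consumes a subject base)
            if _lex_gt(
                E0[i, j - 1] + gap_extend, E1[i, j - 1], E2[i, j - 1] - 1, E3[i, j - 1],
                H0[i, j - 1] + gap_open, H1[i, j - 1], H2[i, j - 1] - 1, H3[i, j - 1],
            ):
                E0[i, j] = E0[i, j - 1] + gap_extend
                E1[i, j] = E1[i, j - 1]
                E2[i, j] = E2[i, j - 1] - 1
                E3[i, j] = E3[i, j - 1]
                ptrE[i, j] = 2
            else:
                E0[i, j] = H0[i, j - 1] + gap_open
                E1[i, j] = H1[i, j - 1]
                E2[i, j] = H2[i, j - 1] - 1
                E3[i, j] = H3[i, j - 1]
                ptrE[i, j] = 1
            # H: best of substitution, F, E, or a fresh start
            if q[i - 1] == s[j - 1]:
                h0 = H0[i - 1, j - 1] + match
                h1 = H1[i - 1, j - 1] + 1
                h2 = H2[i - 1, j - 1]
                h3 = H3[i - 1, j - 1]
            else:
                h0 = H0[i - 1, j - 1] + mismatch
                h1 = H1[i - 1, j - 1]
                h2 = H2[i - 1, j - 1]
                h3 = H3[i - 1, j - 1] - 1
            p = 1
            if _lex_gt(F0[i, j], F1[i, j], F2[i, j], F3[i, j], h0, h1, h2, h3):
                h0 = F0[i, j]
                h1 = F1[i, j]
                h2 = F2[i, j]
                h3 = F3[i, j]
                p = 2
            if _lex_gt(E0[i, j], E1[i, j], E2[i, j], E3[i, j], h0, h1, h2, h3):
                h0 = E0[i, j]
                h1 = E1[i, j]
                h2 = E2[i, j]
                h3 = E3[i, j]
                p = 3
            if h0 <= 0:
                ptrH[i, j] = 0
            else:
                H0[i, j] = h0
                H1[i, j] = h1
                H2[i, j] = h2
                H3[i, j] = h3
                ptrH[i, j] = p
                if _lex_gt(h0, h1, h2, h3, b0, b1, b2, b3):
                    b0 = h0
                    b1 = h1
                    b2 = h2
                    b3 = h3
                    bi = i
                    bj = j
    return b0, bi, bj, ptrH, ptrE, ptrF


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def align_pair(
    query: str, subject: str, scoring: ScoringScheme = ScoringScheme()
) -> AlignmentResult:
    """Best local affine-gap alignment of ``query`` against ``subject``.

    Characters match on exact equality (case-insensitive); IUPAC codes are
    compared literally.  Raises ValueError on empty input.  A pair with no
    positive-scoring local alignment yields an all-zero result.
    """
    if not query or not subject:
        raise ValueError("align_pair requires non-empty sequences")
    q = _encode(query)
    s = _encode(subject)
    best, bi, bj, ptrH, ptrE, ptrF = _sw_fill(
        q, s, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return AlignmentResult(0, 0.0, 0.0, 0, 0, 0, 0, 0, 0, 0)

    i, j = bi, bj
    n_matches = aligned = gaps = 0
    subj_cols = 0
    state = 0  # 0 = H, 1 = F (gap in subject, consumes query), 2 = E (gap in query)
    while True:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                aligned += 1
                subj_cols += 1
                if q[i - 1] == s[j - 1]:
                    n_matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            aligned += 1
            gaps += 1
            p = ptrF[i, j]
            i -= 1
            if p == 1:
                state = 0
        else:
            aligned += 1
            gaps += 1
            subj_cols += 1
            p = ptrE[i, j]
            j -= 1
            if p == 1:
                state = 0
    identity = 100.0 * n_matches / aligned
    coverage = 100.0 * subj_cols / len(subject)
    return AlignmentResult(
        score=int(best),
        percent_identity=identity,
        percent_coverage=coverage,
        aligned_length=aligned,
        n_matches=n_matches,
        n_gaps=gaps,
        query_start=i,
        query_end=bi,
        subject_start=j,
        subject_end=bj,
    )


def identity_bin(percent_identity: float) -> str:
    """Similarity bin for a percent identity in [0, 100]; half-open at the
    lower edges except the top bin, which is closed at 100."""
    if not 0.0 <= percent_identity <= 100.0:
        raise ValueError(f"percent identity {percent_identity} outside [0, 100]")
    if percent_identity >= 97.5:
        return "97.5-100"
    if percent_identity >= 95.0:
        return "95-97.5"
    if percent_identity >= 90.0:
        return "90-95"
    if percent_identity >= 85.0:
        return "85-90"
    return "<85"


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def best_hit(
    query: str,
    reference: Sequence[tuple[str, str]],
    scoring: ScoringScheme = ScoringScheme(),
    prefilter_k: int | None = None,
    prefilter_top: int = 25,
) -> tuple[str, AlignmentResult, str]:
    """Top local-alignment hit of ``query`` in a reference collection.

    ``reference`` is a sequence of (id, sequence) records (e.g. from
    :func:`mycobarcode._seqio.read_fasta`).  The top hit maximises score,
    ties broken by identity then input order.  With ``prefilter_k`` set,
    only the ``prefilter_top`` records sharing the most k-mers with the
    query are aligned — a speed optimisation that must not change the top
    hit on realistic inputs (verified in tests); it is off by default.
    Returns (hit id, alignment, identity bin).
    """
    if not reference:
        raise ValueError("best_hit requires a non-empty reference")
    candidates = list(enumerate(reference))
    if prefilter_k is not None and len(reference) > prefilter_top:
        qk = _kmer_set(query.upper(), prefilter_k)
        scored = [
            (len(qk & _kmer_set(seq.upper(), prefilter_k)), -idx, idx)
            for idx, (_, seq) in candidates
        ]
        scored.sort(reverse=True)
        keep = {idx for _, _, idx in scored[:prefilter_top]}
        candidates = [(i, rec) for i, rec in candidates if i in keep]
    best_rec: str | None = None
    best_aln: AlignmentResult | None = None
    for _, (rid, seq) in candidates:
        aln = align_pair(query, seq, scoring)
        if best_aln is None or (aln.score, aln.percent_identity) > (
            best_aln.score,
            best_aln.percent_identity,
        ):
            best_rec, best_aln = rid, aln
    assert best_rec is not None and best_aln is not None
    return best_rec, best_aln, identity_bin(best_aln.percent_identity)


@dataclass(frozen=True)
class ConcordanceVerdict:
    verdict: str  # one of the four concordance classes
    specimen_label: str
    hit_label: str
    bin: str
    note: str = ""


def _genus(label: str) -> str | None:
    token = label.strip().split()[0] if label.strip() else ""
    if token and token.replace("-", "").isalpha():
        return token.capitalize()
    return None


def classify_concordance(
    specimen_label: str,
    hit_label: str,
    bin: str,
    synonym_map: Mapping[str, str] | None = None,
) -> ConcordanceVerdict:
    """Classify a specimen's best hit against its labelled identity.

    Genus-level automated rule: same genus (directly or via the synonym map)
    is concordant; genera linked only through the synonym map are
    discordant_nomenclature; an unrelated genus at ≥90% identity is a
    putative contaminant; anything else — including unparseable labels — is
    unresolved.  Infraspecific parts of labels are ignored.
    """
    if bin not in IDENTITY_BINS:
        raise ValueError(f"unknown identity bin {bin!r}")
    g_spec = _genus(specimen_label)
    g_hit = _genus(hit_label)
    if g_spec is None or g_hit is None:
        return ConcordanceVerdict(
            UNRESOLVED, specimen_label, hit_label, bin, note="unparseable taxon label"
        )
    if g_spec == g_hit:
        return ConcordanceVerdict(CONCORDANT, specimen_label, hit_label, bin)
    if synonym_map:
        canon = {k.capitalize(): v.capitalize() for k, v in synonym_map.items()}
        if canon.get(g_spec, g_spec) == canon.get(g_hit, g_hit):
            return ConcordanceVerdict(
                DISCORDANT_NOMENCLATURE, specimen_label, hit_label, bin,
                note="genera linked by synonym map",
            )
    if bin in _HIGH_BINS:
        return ConcordanceVerdict(PUTATIVE_CONTAMINANT, specimen_label, hit_label, bin)
    return ConcordanceVerdict(UNRESOLVED, specimen_label, hit_label, bin)
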