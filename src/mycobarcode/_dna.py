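"""Small DNA sequence utilities shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

#: IUPAC nucleotide codes mapped to the set of unambiguous bases they cover.
IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

STRICT_ALPHABET = frozenset("ACGT")
IUPAC_ALPHABET = frozenset(IUPAC)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Count positions of ``observed`` not covered by the IUPAC ``pattern``.

    ``observed`` is read sequence (A/C/G/T/N); ``pattern`` may carry
    degeneracy codes.  An N in the read matches nothing but N in the pattern
    covers everything, mirroring primer-matching practice.
    """
    if len(observed) != len(pattern):
        raise ValueError("iupac_mismatches requires equal-length sequences")
    n = 0
    for obs, pat in zip(observed, pattern):
        allowed = IUPAC.get(pat)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {pat!r} in pattern")
        if obs not in allowed:
            n += 1
    return n


def check_alphabet(seq: str, *, degenerate_ok: bool = False, what: str = "sequence") -> None:
    """Raise ValueError if ``seq`` leaves the permitted alphabet."""
    allowed = IUPAC_ALPHABET if degenerate_ok else STRICT_ALPHABET
    bad = set(seq.upper()) - allowed
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)}: {seq!r}")
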