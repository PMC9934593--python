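"""Two-step PCR primer scheme: construct grammar, barcode set, pool layout.

The library design appends, in the first PCR (PCR1), a Fluidigm consensus (CS)
tag, a variable-length heterogeneity spacer and — on the reverse side — a 5-bp
inline barcode to the locus primers (fITS7 forward, ITS4 reverse, targeting
nrITS2).  A second PCR primes on the CS tags to add Illumina indices per pool
of up to eight barcoded specimens.  This module validates a scheme
configuration, emits PCR1 oligo sequences, assigns specimens to pools and
barcodes, and maps gel-electrophoresis categories to pooling volumes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from mycobarcode._dna import check_alphabet, hamming

__all__ = [
    "PrimerScheme",
    "PoolLayout",
    "SpecimenRecord",
    "SchemeError",
    "load_scheme",
    "build_pcr1_oligos",
    "assign_pools",
    "pooling_volume",
    "read_specimen_sheet",
    "write_pool_assignments",
]

GEL_CATEGORIES = ("strong", "weak", "none")
EXTRACTION_METHODS = ("simple", "kit")

#: Pooling volume (µL) per PCR1 gel assessment: strong bands are sampled
#: least, invisible bands most, to normalise products across a pool.
POOLING_VOLUMES_UL = {"strong": 3.0, "weak": 5.0, "none": 10.0}

BARCODE_LENGTH = 5
MIN_BARCODE_DISTANCE = 3
EXPECTED_BARCODE_COUNT = 8
MAX_FORWARD_SPACER = 6
MAX_REVERSE_SPACER = 4


class SchemeError(ValueError):
    """A primer-scheme configuration violates a structural invariant."""


@dataclass(frozen=True)
class PrimerScheme:
    """Validated two-step PCR construct definition.

    Forward PCR1 oligo: ``cs1_tag + forward_spacer + forward_primer``.
    Reverse PCR1 oligo: ``cs2_tag + reverse_spacer + barcode + reverse_primer``.
    Primers may contain IUPAC degeneracy codes; tags, spacers and barcodes are
    plain A/C/G/T.
    """

    forward_primer: str
    reverse_primer: str
    cs1_tag: str
    cs2_tag: str
    forward_spacers: tuple[str, ...]
    reverse_spacers: tuple[str, ...]
    barcodes: tuple[str, ...]
    min_trimmed_length: int = 200

    def __post_init__(self) -> None:
        check_alphabet(self.forward_primer, degenerate_ok=True, what="forward_primer")
        check_alphabet(self.reverse_primer, degenerate_ok=True, what="reverse_primer")
        for name in ("cs1_tag", "cs2_tag"):
            check_alphabet(getattr(self, name), what=name)
        for sp in self.forward_spacers:
            check_alphabet(sp, what="forward spacer")
            if not 0 <= len(sp) <= MAX_FORWARD_SPACER:
                raise SchemeError(
                    f"forward spacer {sp!r} has length {len(sp)}; allowed 0–{MAX_FORWARD_SPACER}"
                )
        for sp in self.reverse_spacers:
            check_alphabet(sp, what="reverse spacer")
            if not 0 <= len(sp) <= MAX_REVERSE_SPACER:
                raise SchemeError(
                    f"reverse spacer {sp!r} has length {len(sp)}; allowed 0–{MAX_REVERSE_SPACER}"
                )
        for bc in self.barcodes:
            check_alphabet(bc, what="barcode")
            if len(bc) != BARCODE_LENGTH:
                raise SchemeError(
                    f"barcode {bc!r} has length {len(bc)}; must be {BARCODE_LENGTH} bp"
                )
        if len(self.barcodes) != EXPECTED_BARCODE_COUNT:
            warnings.warn(
                f"scheme defines {len(self.barcodes)} barcodes "
                f"(the standard layout uses {EXPECTED_BARCODE_COUNT})",
                stacklevel=2,
            )
        for (i, a), (j, b) in itertools.combinations(enumerate(self.barcodes, 1), 2):
            d = hamming(a, b)
            if d < MIN_BARCODE_DISTANCE:
                raise SchemeError(
                    f"barcodes {i} ({a}) and {j} ({b}) are Hamming distance {d} apart; "
                    f"minimum {MIN_BARCODE_DISTANCE} is required for unambiguous "
                    "mismatch-tolerant demultiplexing"
                )
        if self.min_trimmed_length < 1:
            raise SchemeError("min_trimmed_length must be positive")

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    def barcode(self, barcode_id: int) -> str:
        """Barcode sequence for a 1-based barcode id."""
        if not 1 <= barcode_id <= self.n_barcodes:
            raise SchemeError(f"barcode_id {barcode_id} outside 1–{self.n_barcodes}")
        return self.barcodes[barcode_id - 1]


@dataclass(frozen=True)
class SpecimenRecord:
    """One fungarium specimen in a sequencing run."""

    catalog_id: str
    taxon_label: str
    year: int | None
    extraction_method: str
    gel_category: str
    pool_id: str | None = None
    barcode_id: int | None = None

    def __post_init__(self) -> None:
        if self.gel_category not in GEL_CATEGORIES:
            raise ValueError(
                f"specimen {self.catalog_id}: gel_category {self.gel_category!r} "
                f"not in {GEL_CATEGORIES}"
            )
        if self.extraction_method not in EXTRACTION_METHODS:
            raise ValueError(
                f"specimen {self.catalog_id}: extraction_method "
                f"{self.extraction_method!r} not in {EXTRACTION_METHODS}"
            )


@dataclass(frozen=True)
class PoolLayout:
    """Specimen-to-pool/barcode assignment; pools hold 1–8 specimens."""

    pools: tuple[tuple[str, tuple[tuple[str, int], ...]], ...]
    """Tuples ``(pool_id, ((catalog_id, barcode_id), ...))``."""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pool_id, members in self.pools:
            if not members:
                raise ValueError(f"pool {pool_id} is empty")
            bcs = [b for _, b in members]
            if len(set(bcs)) != len(bcs):
                raise ValueError(f"pool {pool_id} repeats a barcode id")
            for cid, _ in members:
                if cid in seen:
                    raise ValueError(f"specimen {cid} appears in more than one pool")
                seen.add(cid)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_specimens(self) -> int:
        return sum(len(m) for _, m in self.pools)

    def assignment(self) -> dict[str, tuple[str, int]]:
        """Map catalog_id -> (pool_id, barcode_id)."""
        return {
            cid: (pool_id, bc)
            for pool_id, members in self.pools
            for cid, bc in members
        }


def load_scheme(config_path: str | Path) -> PrimerScheme:
    """Load and validate a primer scheme from a YAML/JSON config file.

    Raises :class:`SchemeError` on structural violations (wrong barcode
    length, pairwise barcode distance < 3 with the offending pair named);
    a barcode count other than eight is a warning, since the set size is
    configurable.
    """
    path = Path(config_path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemeError(f"{path}: scheme config must be a mapping")
    required = {
        "forward_primer",
        "reverse_primer",
        "cs1_tag",
        "cs2_tag",
        "forward_spacers",
        "reverse_spacers",
        "barcodes",
    }
    missing = required - raw.keys()
    if missing:
        raise SchemeError(f"{path}: missing keys {sorted(missing)}")
    return PrimerScheme(
        forward_primer=str(raw["forward_primer"]).upper(),
        reverse_primer=str(raw["reverse_primer"]).upper(),
        cs1_tag=str(raw["cs1_tag"]).upper(),
        cs2_tag=str(raw["cs2_tag"]).upper(),
        forward_spacers=tuple(str(s).upper() for s in raw["forward_spacers"]),
        reverse_spacers=tuple(str(s).upper() for s in raw["reverse_spacers"]),
        barcodes=tuple(str(b).upper() for b in raw["barcodes"]),
        min_trimmed_length=int(raw.get("min_trimmed_length", 200)),
    )


def demo_scheme_path() -> Path:
    """Path of the bundled demonstration scheme (fixture data, not the
    published oligo set)."""
    return Path(__file__).parent / "data" / "demo_scheme.yaml"


def build_pcr1_oligos(
    scheme: PrimerScheme,
    barcode_id: int,
    f_spacer_len: int,
    r_spacer_len: int,
) -> tuple[str, str]:
    """PCR1 oligo pair (5'→3') for one barcode and spacer-length choice.

    Forward: ``cs1_tag + forward_spacer + forward_primer``.
    Reverse: ``cs2_tag + reverse_spacer + barcode + reverse_primer``.
    """
    f_sp = _spacer_of_length(scheme.forward_spacers, f_spacer_len, MAX_FORWARD_SPACER, "forward")
    r_sp = _spacer_of_length(scheme.reverse_spacers, r_spacer_len, MAX_REVERSE_SPACER, "reverse")
    bc = scheme.barcode(barcode_id)
    forward = scheme.cs1_tag + f_sp + scheme.forward_primer
    reverse = scheme.cs2_tag + r_sp + bc + scheme.reverse_primer
    return forward, reverse


def _spacer_of_length(
    spacers: Sequence[str], length: int, maximum: int, side: str
) -> str:
    if not 0 <= length <= maximum:
        raise SchemeError(
            f"{side} spacer length {length} outside allowed range 0–{maximum}"
        )
    for sp in spacers:
        if len(sp) == length:
            return sp
    raise SchemeError(f"scheme defines no {side} spacer of length {length}")


def assign_pools(
    specimens: Sequence[SpecimenRecord],
    pool_size: int = 8,
    *,
    policy: str = "balanced",
    pool_prefix: str = "P",
) -> PoolLayout:
    """Assign specimens to pools and inline barcodes, in input order.

    With the default ``balanced`` policy the remainder is spread so pool
    sizes differ by at most one (e.g. 766 specimens at pool size 8 give 94
    pools of 8 and 2 pools of 7); with ``greedy`` all pools but the last are
    full.  Barcode ids cycle 1..pool_size within each pool.
    """
    if not specimens:
        raise ValueError("cannot assign pools for zero specimens")
    if pool_size < 1:
        raise ValueError("pool_size must be positive")
    n = len(specimens)
    n_pools = -(-n // pool_size)  # ceil
    if policy == "balanced":
        base, extra = divmod(n, n_pools)
        sizes = [base + 1] * extra + [base] * (n_pools - extra)
    elif policy == "greedy":
        sizes = [pool_size] * (n_pools - 1) + [n - (n_pools - 1) * pool_size]
    else:
        raise ValueError(f"unknown pool fill policy {policy!r}")
    width = max(2, len(str(n_pools)))
    pools = []
    it = iter(specimens)
    for k, size in enumerate(sizes, 1):
        pool_id = f"{pool_prefix}{k:0{width}d}"
        members = tuple(
            (next(it).catalog_id, bc) for bc in range(1, size + 1)
        )
        pools.append((pool_id, members))
    return PoolLayout(pools=tuple(pools))


def apply_layout(
    specimens: Iterable[SpecimenRecord], layout: PoolLayout
) -> list[SpecimenRecord]:
    """Return specimen records with pool_id/barcode_id filled in from a layout."""
    assignment = layout.assignment()
    out = []
    for rec in specimens:
        pool_id, bc = assignment[rec.catalog_id]
        out.append(replace(rec, pool_id=pool_id, barcode_id=bc))
    return out


def pooling_volume(gel_category: str) -> float:
    """Pooling volume in µL for a PCR1 gel assessment (strong/weak/none →
    3/5/10)."""
    try:
        return POOLING_VOLUMES_UL[gel_category]
    except KeyError:
        raise ValueError(
            f"unknown gel category {gel_category!r}; expected one of {GEL_CATEGORIES}"
        ) from None


def read_specimen_sheet(path: str | Path) -> list[SpecimenRecord]:
    """Read a specimen sheet TSV.

    Required columns: catalog_id, taxon_label, year, extraction_method,
    gel_category; optional pool_id, barcode_id.  Empty year is allowed
    (missing collection date).  Schema violations report the offending row.
    """
    import csv

    path = Path(path)
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"catalog_id", "taxon_label", "year", "extraction_method", "gel_category"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: specimen sheet must have columns {sorted(required)}; "
                f"found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            cid = row["catalog_id"].strip()
            if cid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate catalog_id {cid!r}")
            seen.add(cid)
            year_raw = (row.get("year") or "").strip()
            try:
                rec = SpecimenRecord(
                    catalog_id=cid,
                    taxon_label=row["taxon_label"].strip(),
                    year=int(year_raw) if year_raw else None,
                    extraction_method=row["extraction_method"].strip(),
                    gel_category=row["gel_category"].strip(),
                    pool_id=(row.get("pool_id") or "").strip() or None,
                    barcode_id=int(row["barcode_id"]) if (row.get("barcode_id") or "").strip() else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            records.append(rec)
    if not records:
        raise ValueError(f"{path}: specimen sheet is empty")
    return records


def write_pool_assignments(
    specimens: Sequence[SpecimenRecord], layout: PoolLayout, path: str | Path
) -> None:
    """Emit the pooling TSV: catalog_id, pool_id, barcode_id,
    pooling_volume_ul."""
    assignment = layout.assignment()
    by_id = {s.catalog_id: s for s in specimens}
    with Path(path).open("w") as fh:
        fh.write("catalog_id\tpool_id\tbarcode_id\tpooling_volume_ul\n")
        for pool_id, members in layout.pools:
            for cid, bc in members:
                vol = pooling_volume(by_id[cid].gel_category)
                fh.write(f"{cid}\t{pool_id}\t{bc}\t{vol:g}\n")
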