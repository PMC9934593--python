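"""Representative barcode selection and run-level summary statistics.

Each specimen's representative nrITS2 barcode is the most read-supported
variant of its bimera-free merged table.  One sequence is expected to exceed
twice the reads of any other variant; when it does not, the representative
is kept but flagged ambiguous rather than dropped — intragenomic variants,
contaminants and residual errors all produce minor variants, and the caller
decides what to do with close calls.  Exact count ties are broken by table
order (first listed), recorded via ``tie_broken``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mycobarcode.denoise import VariantTable
from mycobarcode.scheme import SpecimenRecord

__all__ = [
    "RepresentativeBarcode",
    "RunSummary",
    "select_representative",
    "summarize_run",
    "write_representatives",
]

AMBIGUITY_FACTOR = 2.0  # representative expected to have > 2x the runner-up's reads


@dataclass(frozen=True)
class RepresentativeBarcode:
    specimen_id: str
    sequence: str
    support_count: int
    second_count: int
    ambiguous: bool
    tie_broken: bool

    def __post_init__(self) -> None:
        if self.support_count < self.second_count:
            raise ValueError("support_count must be >= second_count")


def select_representative(table: VariantTable) -> RepresentativeBarcode | None:
    """Pick the top-count variant as the specimen's barcode; None when the
    table is empty (a recorded sequencing failure)."""
    if len(table) == 0:
        return None
    seq, support = table.variants[0]
    second = table.variants[1][1] if len(table) > 1 else 0
    return RepresentativeBarcode(
        specimen_id=table.specimen_id,
        sequence=seq,
        support_count=support,
        second_count=second,
        ambiguous=second > 0 and support <= AMBIGUITY_FACTOR * second,
        tie_broken=second == support,
    )


@dataclass
class RunSummary:
    """Per-specimen stage counts plus recomputable run aggregates."""

    rows: pd.DataFrame
    aggregates: dict

    def to_json_dict(self) -> dict:
        return {
            "aggregates": self.aggregates,
            "n_specimens": int(len(self.rows)),
        }


def _grp_stats(series: pd.Series) -> dict:
    if len(series) == 0:
        return {"mean": None, "median": None, "n": 0}
    return {
        "mean": float(series.mean()),
        "median": float(series.median()),
        "n": int(len(series)),
    }


def summarize_run(
    stage_counts: Mapping[str, Mapping[str, int]],
    representatives: Mapping[str, RepresentativeBarcode | None],
    specimens: Sequence[SpecimenRecord],
) -> RunSummary:
    """Assemble the run summary the study reports.

    ``stage_counts`` maps specimen -> {raw_pairs, trimmed_pairs,
    filtered_pairs, merged_pairs}; ``representatives`` maps specimen ->
    barcode or None.  Emits per-specimen rows and aggregates: mean/median
    raw and filtered depth overall, grouped by amplification success
    (gel strong+weak vs none) and by collection decade; failure count and
    ids; mean/median representative support.  Specimen id mismatches are a
    hard error listing the orphans.
    """
    sheet_ids = {s.catalog_id for s in specimens}
    orphans = (set(stage_counts) | set(representatives)) - sheet_ids
    missing = sheet_ids - set(stage_counts)
    if orphans or missing:
        raise ValueError(
            f"specimen id mismatch: unknown ids {sorted(orphans)}, "
            f"ids without stage counts {sorted(missing)}"
        )

    rows = []
    for s in specimens:
        counts = stage_counts[s.catalog_id]
        rep = representatives.get(s.catalog_id)
        decade = (s.year // 10) * 10 if s.year is not None else None
        rows.append(
            {
                "catalog_id": s.catalog_id,
                "taxon_label": s.taxon_label,
                "year": s.year,
                "decade": decade,
                "gel_category": s.gel_category,
                "amplified": s.gel_category in ("strong", "weak"),
                "raw_pairs": int(counts.get("raw_pairs", 0)),
                "trimmed_pairs": int(counts.get("trimmed_pairs", 0)),
                "filtered_pairs": int(counts.get("filtered_pairs", 0)),
                "merged_pairs": int(counts.get("merged_pairs", 0)),
                "representative_support": rep.support_count if rep else 0,
                "ambiguous": bool(rep.ambiguous) if rep else False,
                "no_sequence": rep is None,
            }
        )
    df = pd.DataFrame(rows).set_index("catalog_id", drop=False)

    failures = df.index[df["no_sequence"]].tolist()
    with_rep = df.loc[~df["no_sequence"], "representative_support"]
    agg = {
        "raw_pairs": _grp_stats(df["raw_pairs"]),
        "filtered_pairs": _grp_stats(df["filtered_pairs"]),
        "merged_pairs": _grp_stats(df["merged_pairs"]),
        "raw_pairs_by_amplification": {
            "amplified": _grp_stats(df.loc[df["amplified"], "raw_pairs"]),
            "none": _grp_stats(df.loc[~df["amplified"], "raw_pairs"]),
        },
        "filtered_pairs_by_amplification": {
            "amplified": _grp_stats(df.loc[df["amplified"], "filtered_pairs"]),
            "none": _grp_stats(df.loc[~df["amplified"], "filtered_pairs"]),
        },
        "raw_pairs_by_decade": {
            str(dec): _grp_stats(grp["raw_pairs"])
            for dec, grp in df.dropna(subset=["decade"]).groupby("decade")
        },
        "representative_support": _grp_stats(with_rep),
        "failure_count": len(failures),
        "failure_ids": failures,
        "success_rate": float((len(df) - len(failures)) / len(df)) if len(df) else None,
    }
    return RunSummary(rows=df, aggregates=agg)


def write_representatives(
    representatives: Mapping[str, RepresentativeBarcode | None],
    fasta_path,
    tsv_path,
) -> None:
    """Write representatives as FASTA (header: catalog_id, support count) and
    a flat TSV including ambiguity/tie flags."""
    from mycobarcode._seqio import write_fasta

    recs = [
        (f"{cid} support={rep.support_count}", rep.sequence)
        for cid, rep in representatives.items()
        if rep is not None
    ]
    write_fasta(fasta_path, recs)
    with open(tsv_path, "w") as fh:
        fh.write(
            "specimen_id\tsupport_count\tsecond_count\tambiguous\ttie_broken\tsequence\n"
        )
        for cid, rep in representatives.items():
            if rep is None:
                fh.write(f"{cid}\t0\t0\tFalse\tFalse\t\n")
            else:
                fh.write(
                    f"{cid}\t{rep.support_count}\t{rep.second_count}\t"
                    f"{rep.ambiguous}\t{rep.tie_broken}\t{rep.sequence}\n"
                )
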