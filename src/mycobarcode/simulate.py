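"""Seeded simulator for nested-barcode two-step PCR sequencing runs.

Generates a complete synthetic MiSeq-style run with known ground truth:
random ITS2-like specimen templates, per-specimen read depths (log-normal
around a configurable mean, reduced for "no visible PCR band" specimens),
2x250 bp read pairs carrying the full PCR1 construct (CS-tag-adjacent
heterogeneity spacer, 5-bp inline barcode and locus primer on the reverse
side), quality-dependent substitution errors, two-parent chimeras, and
cross-specimen contamination.  Outputs come in two forms, mirroring what a
sequencing facility returns: per-pool FASTQ pairs (construct intact, for
demultiplexing) and per-specimen FASTQ pairs (5' spacer/barcode/primer
already removed).

Every random process consumes an independent substream spawned from the run
seed, so a fixed seed reproduces the run byte-for-byte and raising one noise
rate does not perturb the draws of another.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mycobarcode._dna import IUPAC, revcomp
from mycobarcode._seqio import ReadPair, phred_to_qual, write_fastq_pairs
from mycobarcode.scheme import (
    PoolLayout,
    PrimerScheme,
    SpecimenRecord,
    apply_layout,
    assign_pools,
    write_pool_assignments,
)

__all__ = ["SimConfig", "TruthTable", "SimRun", "simulate_run", "make_chimera"]

BASES = np.array(list("ACGT"))

# Round-robin taxon pool for synthetic specimen sheets: common macrofungal
# genera crossed with generic epithets.  Consecutive specimens get different
# genera, so cross-specimen contamination is almost always cross-genus.
GENERA = (
    "Lactarius", "Russula", "Amanita", "Boletus", "Cortinarius", "Agaricus",
    "Ramaria", "Morchella", "Suillus", "Tricholoma", "Hygrophorus",
    "Clitocybe", "Inocybe", "Hebeloma", "Entoloma", "Pholiota", "Pluteus",
    "Lepiota", "Coprinellus", "Lycoperdon", "Hydnum", "Cantharellus",
    "Gomphidius", "Peziza",
)
EPITHETS = (
    "montanus", "alpinus", "occidentalis", "sylvestris", "rubescens",
    "luteus", "fragilis", "robustus", "pallidus", "velutinus",
)


@dataclass
class SimConfig:
    """Synthetic run parameters.

    Defaults emulate the scale of a 766-specimen MiSeq Nano fungarium run:
    ~800 raw read pairs per specimen, mean Phred ≈ 36.5 with a mild 3' decay,
    ~18% of specimens with no visible PCR1 band (depth scaled by 0.85), 2%
    chimeric reads, and 8% of specimens contaminated by another specimen's
    template at a read fraction large enough to dominate the pool (observed
    contamination manifests as the wrong representative sequence).
    """

    n_specimens: int = 100
    pool_size: int = 8
    template_length_range: tuple[int, int] = (220, 400)
    depth_distribution: str = "lognormal"  # or "negative-binomial"
    depth_mean: float = 800.0
    depth_dispersion: float = 0.5  # lognormal sigma; NB size parameter if NB
    no_band_fraction: float = 0.18
    no_band_depth_multiplier: float = 0.85
    mean_phred: float = 36.5
    phred_decay: float = 0.02  # mean Phred drop per position toward the 3' end
    phred_jitter_sd: float = 3.0
    error_scale: float = 1.0  # multiplies per-base error prob 10^(-Q/10); 0 = error-free
    chimera_rate: float = 0.02
    contamination_rate: float = 0.08
    contaminant_fraction_range: tuple[float, float] = (0.5, 0.95)
    read_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be positive")
        lo, hi = self.template_length_range
        if lo < 1 or hi < lo:
            raise ValueError("template_length_range must be positive and ordered")
        for name in ("no_band_fraction", "chimera_rate", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        flo, fhi = self.contaminant_fraction_range
        if not (0.0 <= flo <= fhi <= 1.0):
            raise ValueError("contaminant_fraction_range must be within [0, 1] and ordered")
        if self.depth_distribution not in ("lognormal", "negative-binomial"):
            raise ValueError(f"unknown depth distribution {self.depth_distribution!r}")
        if self.depth_mean <= 0 or self.read_length < 1:
            raise ValueError("depth_mean and read_length must be positive")
        if self.error_scale < 0:
            raise ValueError("error_scale must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of a simulated run.

    ``templates`` maps specimen -> true ITS2 core sequence; ``reads`` has one
    row per emitted read pair (read_id, specimen, pool_id, barcode_id,
    provenance ∈ {template, contaminant, chimera}, source specimen(s),
    chimera breakpoint); ``contaminated`` maps each contaminated specimen to
    (source specimen, contaminant read fraction).
    """

    templates: dict[str, str]
    reads: pd.DataFrame
    contaminated: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        ids = self.reads["read_id"]
        if ids.duplicated().any():
            raise ValueError("truth table contains duplicate read ids")

    def reads_of(self, specimen: str) -> pd.DataFrame:
        return self.reads[self.reads["specimen"] == specimen]

    def n_reads(self, specimen: str | None = None) -> int:
        if specimen is None:
            return len(self.reads)
        return int((self.reads["specimen"] == specimen).sum())

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        with (outdir / "truth_templates.tsv").open("w") as fh:
            fh.write("specimen\ttemplate\n")
            for cid, tmpl in self.templates.items():
                fh.write(f"{cid}\t{tmpl}\n")
        with (outdir / "truth_contamination.tsv").open("w") as fh:
            fh.write("specimen\tsource\tfraction\n")
            for cid, (src, frac) in self.contaminated.items():
                fh.write(f"{cid}\t{src}\t{frac:.4f}\n")


@dataclass
class SimRun:
    """Handles to a simulated run on disk."""

    outdir: Path
    scheme: PrimerScheme
    config: SimConfig
    specimens: list[SpecimenRecord]
    layout: PoolLayout
    truth: TruthTable
    pool_fastqs: dict[str, tuple[Path, Path]]
    specimen_fastqs: dict[str, tuple[Path, Path]]

    @property
    def sheet_path(self) -> Path:
        return self.outdir / "specimen_sheet.tsv"


def make_chimera(template_a: str, template_b: str, breakpoint: int) -> str:
    """Two-parent (bimera) join: prefix of ``template_a`` up to ``breakpoint``
    plus suffix of ``template_b`` from ``breakpoint``."""
    if not 0 < breakpoint < min(len(template_a), len(template_b)):
        raise ValueError(
            f"breakpoint {breakpoint} outside open interval (0, "
            f"{min(len(template_a), len(template_b))})"
        )
    return template_a[:breakpoint] + template_b[breakpoint:]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _realize_primer(rng: np.random.Generator, primer: str) -> str:
    """Instantiate IUPAC degeneracy codes with concrete bases."""
    out = []
    for c in primer:
        opts = sorted(IUPAC[c])
        out.append(opts[0] if len(opts) == 1 else opts[rng.integers(0, len(opts))])
    return "".join(out)


def _draw_depth(rng: np.random.Generator, cfg: SimConfig, mean: float) -> int:
    if cfg.depth_distribution == "lognormal":
        sigma = cfg.depth_dispersion
        mu = np.log(mean) - sigma**2 / 2.0
        return max(1, int(round(rng.lognormal(mu, sigma))))
    size = cfg.depth_dispersion
    p = size / (size + mean)
    return max(1, int(rng.negative_binomial(size, p)))


def _quality_profile(rng: np.random.Generator, cfg: SimConfig, length: int) -> np.ndarray:
    pos = np.arange(length)
    centre = cfg.mean_phred + cfg.phred_decay * (length - 1) / 2.0
    mean = centre - cfg.phred_decay * pos
    q = mean + rng.normal(0.0, cfg.phred_jitter_sd, size=length)
    return np.clip(np.rint(q), 2, 40).astype(int)


def _apply_errors(
    rng: np.random.Generator, seq: str, quals: np.ndarray, scale: float
) -> str:
    if scale == 0.0:
        return seq
    p_err = scale * 10.0 ** (-quals / 10.0)
    hits = np.nonzero(rng.random(len(seq)) < p_err)[0]
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(0, 3)]
    return "".join(out)


def simulate_run(
    scheme: PrimerScheme, config: SimConfig, outdir: str | Path
) -> SimRun:
    """Simulate a full run; writes per-pool and per-specimen FASTQ pairs,
    specimen sheet, pool assignments, truth tables, and a config echo.

    Per-pool R2 reads begin with (reverse spacer + barcode + reverse
    primer); per-specimen reads have the 5' construct sliced off (emulating
    facility demultiplexing, which is truth-based and therefore error-free
    in the construct region).  Templates shorter than the read length
    produce 3' read-through into the opposite construct.
    """
    if config.pool_size > scheme.n_barcodes:
        raise ValueError(
            f"pool_size {config.pool_size} exceeds the scheme's "
            f"{scheme.n_barcodes} barcodes"
        )
    outdir = Path(outdir)
    (outdir / "pools").mkdir(parents=True, exist_ok=True)
    (outdir / "specimens").mkdir(parents=True, exist_ok=True)

    streams = np.random.SeedSequence(config.seed).spawn(8)
    rng_sheet = np.random.default_rng(streams[0])
    rng_template = np.random.default_rng(streams[1])
    rng_depth = np.random.default_rng(streams[2])
    rng_contam = np.random.default_rng(streams[3])
    rng_chimera_flag = np.random.default_rng(streams[4])
    rng_chimera_detail = np.random.default_rng(streams[5])
    rng_construct = np.random.default_rng(streams[6])
    rng_quality = np.random.default_rng(streams[7])

    n = config.n_specimens
    width = max(4, len(str(n)))
    catalog_ids = [f"FS{i + 1:0{width}d}" for i in range(n)]

    # --- specimen sheet -------------------------------------------------
    specimens: list[SpecimenRecord] = []
    for i, cid in enumerate(catalog_ids):
        genus = GENERA[i % len(GENERA)]
        epithet = EPITHETS[(i // len(GENERA)) % len(EPITHETS)]
        year = int(rng_sheet.integers(1900, 2021))
        u = rng_sheet.random()
        if u < config.no_band_fraction:
            gel = "none"
        elif u < config.no_band_fraction + 0.7 * (1 - config.no_band_fraction):
            gel = "strong"
        else:
            gel = "weak"
        specimens.append(
            SpecimenRecord(
                catalog_id=cid,
                taxon_label=f"{genus} {epithet}",
                year=year,
                extraction_method="simple" if i % 2 == 0 else "kit",
                gel_category=gel,
            )
        )
    layout = assign_pools(specimens, config.pool_size)
    specimens = apply_layout(specimens, layout)
    by_id = {s.catalog_id: s for s in specimens}

    # --- templates and contamination ------------------------------------
    lo, hi = config.template_length_range
    templates = {
        cid: _random_dna(rng_template, int(rng_template.integers(lo, hi + 1)))
        for cid in catalog_ids
    }
    fwd_primers = {cid: _realize_primer(rng_template, scheme.forward_primer) for cid in catalog_ids}
    rev_primers = {cid: _realize_primer(rng_template, scheme.reverse_primer) for cid in catalog_ids}

    contaminated: dict[str, tuple[str, float]] = {}
    if n > 1:
        for i, cid in enumerate(catalog_ids):
            if rng_contam.random() < config.contamination_rate:
                j = int(rng_contam.integers(0, n - 1))
                if j >= i:
                    j += 1
                flo, fhi = config.contaminant_fraction_range
                contaminated[cid] = (catalog_ids[j], flo + (fhi - flo) * rng_contam.random())

    # --- reads -----------------------------------------------------------
    depths = {}
    for cid in catalog_ids:
        mean = config.depth_mean
        if by_id[cid].gel_category == "none":
            mean *= config.no_band_depth_multiplier
        depths[cid] = _draw_depth(rng_depth, config, mean)

    f_spacers = scheme.forward_spacers
    r_spacers = scheme.reverse_spacers
    truth_rows: list[dict] = []
    pool_buffers: dict[str, list[ReadPair]] = {pid: [] for pid, _ in layout.pools}
    specimen_buffers: dict[str, list[ReadPair]] = {cid: [] for cid in catalog_ids}

    for cid in catalog_ids:
        rec = by_id[cid]
        pool_id, bc_id = rec.pool_id, rec.barcode_id
        barcode = scheme.barcode(bc_id)
        fP, rP = fwd_primers[cid], rev_primers[cid]
        own = templates[cid]
        contam = contaminated.get(cid)
        for j in range(depths[cid]):
            read_id = f"{cid}:{j:05d}"
            u_contam = rng_contam.random()
            u_chim = rng_chimera_flag.random()
            source_cid = cid
            if contam is not None and u_contam < contam[1]:
                source_cid = contam[0]
            sources = [cid] + ([contam[0]] if contam is not None else [])
            provenance, core, src_label, breakpoint = "template", templates[source_cid], source_cid, ""
            if source_cid != cid:
                provenance = "contaminant"
            if u_chim < config.chimera_rate and len(sources) >= 2:
                a, b = sources[:2]
                if rng_chimera_detail.random() < 0.5:
                    a, b = b, a
                bp = int(
                    rng_chimera_detail.integers(
                        1, min(len(templates[a]), len(templates[b]))
                    )
                )
                core = make_chimera(templates[a], templates[b], bp)
                provenance, src_label, breakpoint = "chimera", f"{a}+{b}", str(bp)

            f_sp = f_spacers[rng_construct.integers(0, len(f_spacers))]
            r_sp = r_spacers[rng_construct.integers(0, len(r_spacers))]
            r1_full = f_sp + fP + core + revcomp(rP) + revcomp(barcode) + revcomp(r_sp) + revcomp(scheme.cs2_tag)
            r2_full = r_sp + barcode + rP + revcomp(core) + revcomp(fP) + revcomp(f_sp) + revcomp(scheme.cs1_tag)
            r1 = r1_full[: config.read_length]
            r2 = r2_full[: config.read_length]
            q1 = _quality_profile(rng_quality, config, len(r1))
            q2 = _quality_profile(rng_quality, config, len(r2))
            r1 = _apply_errors(rng_quality, r1, q1, config.error_scale)
            r2 = _apply_errors(rng_quality, r2, q2, config.error_scale)
            pair = ReadPair(read_id, r1, phred_to_qual(q1), r2, phred_to_qual(q2))
            pool_buffers[pool_id].append(pair)
            cut1 = len(f_sp) + len(fP)
            cut2 = len(r_sp) + len(barcode) + len(rP)
            specimen_buffers[cid].append(
                ReadPair(
                    read_id,
                    r1[cut1:],
                    pair.fwd_qual[cut1:],
                    r2[cut2:],
                    pair.rev_qual[cut2:],
                )
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "specimen": cid,
                    "pool_id": pool_id,
                    "barcode_id": bc_id,
                    "provenance": provenance,
                    "source": src_label,
                    "breakpoint": breakpoint,
                }
            )

    truth = TruthTable(
        templates=templates,
        reads=pd.DataFrame(truth_rows),
        contaminated=contaminated,
    )

    # --- write artifacts -------------------------------------------------
    pool_fastqs: dict[str, tuple[Path, Path]] = {}
    for pid, pairs in pool_buffers.items():
        r1p = outdir / "pools" / f"{pid}_R1.fastq.gz"
        r2p = outdir / "pools" / f"{pid}_R2.fastq.gz"
        write_fastq_pairs(r1p, r2p, pairs)
        pool_fastqs[pid] = (r1p, r2p)
    specimen_fastqs: dict[str, tuple[Path, Path]] = {}
    for cid, pairs in specimen_buffers.items():
        r1p = outdir / "specimens" / f"{cid}_R1.fastq.gz"
        r2p = outdir / "specimens" / f"{cid}_R2.fastq.gz"
        write_fastq_pairs(r1p, r2p, pairs)
        specimen_fastqs[cid] = (r1p, r2p)

    truth.write(outdir)
    with (outdir / "specimen_sheet.tsv").open("w") as fh:
        fh.write("catalog_id\ttaxon_label\tyear\textraction_method\tgel_category\tpool_id\tbarcode_id\n")
        for s in specimens:
            fh.write(
                f"{s.catalog_id}\t{s.taxon_label}\t{s.year}\t{s.extraction_method}\t"
                f"{s.gel_category}\t{s.pool_id}\t{s.barcode_id}\n"
            )
    write_pool_assignments(specimens, layout, outdir / "pool_assignments.tsv")
    with (outdir / "config.json").open("w") as fh:
        json.dump(asdict(config), fh, indent=2, default=str)

    return SimRun(
        outdir=outdir,
        scheme=scheme,
        config=config,
        specimens=specimens,
        layout=layout,
        truth=truth,
        pool_fastqs=pool_fastqs,
        specimen_fastqs=specimen_fastqs,
    )
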