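"""Strand-separated, filtered, per-exon coverage from BAM/SAM alignments.

The engine turns one alignment file plus an :class:`~covasym.gene_model.ExonModel`
into an :class:`ExonCoverageProfile`: for every exon, the number of aligned
bases attributable to transcript-sense and transcript-antisense reads, the
RPKM-like normalized coverage

    norm = bases / exon_length / library_total_reads * 1e6,

the mean TK-domain depth (aligned bases per position over the configured TK
exons), and a library-level QC flag. Read filtering follows the published
protocol: mapping quality strictly above 100 (STAR unique mappers carry MAPQ
255) and at least 10 bp of aligned reference length; duplicate, secondary,
supplementary and unmapped records are excluded. Aligned length and coverage
both count only reference-consuming match bases (cigar M/=/X); deletions and
splice gaps (D/N) advance the reference without contributing coverage.

The library size used for normalization is the genome-wide number of primary,
mapped, non-duplicate records, without the MAPQ/length filters, which apply
only to the gene-coverage step.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import pysam

from .config import AssayConfig
from .gene_model import ExonModel

__all__ = [
    "Orientation", "ReadFilterParams", "ExonCoverageProfile",
    "read_passes_filters", "transcript_orientation", "aligned_ref_blocks",
    "aligned_ref_length", "count_exon_bases", "library_size",
    "normalize_profile", "tk_depth", "library_qc", "compute_profile",
]

# cigar op codes consuming the reference
_REF_COVERED = {0, 7, 8}   # M, =, X
_REF_SKIPPED = {2, 3}      # D, N


class Orientation(Enum):
    SENSE = "sense"
    ANTISENSE = "antisense"
    BOTH = "both"


@dataclass(frozen=True)
class ReadFilterParams:
    """Per-read filters applied during exon coverage counting."""

    min_mapq: int = 101
    min_aln_len: int = 10
    exclude_duplicates: bool = True
    exclude_secondary_supplementary: bool = True

    def __post_init__(self) -> None:
        if self.min_aln_len < 1:
            raise ValueError("min_aln_len must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")

    @classmethod
    def from_config(cls, config: AssayConfig) -> "ReadFilterParams":
        return cls(min_mapq=config.min_mapq, min_aln_len=config.min_aln_len)


@dataclass
class ExonCoverageProfile:
    """Per-exon strand-separated coverage plus library-level metrics.

    ``data`` is indexed by exon_number with columns chrom, start, end, length,
    sense_bases, antisense_bases and, once normalized, norm_sense and
    norm_antisense.
    """

    data: pd.DataFrame
    model: ExonModel
    library_total_reads: int | None = None
    tk_depth: float | None = None
    library_qc_pass: bool | None = None
    strandedness: str = "reverse"
    sample_id: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def is_normalized(self) -> bool:
        return "norm_sense" in self.data.columns

    def group_values(self, exon_numbers, column: str = "norm_sense") -> pd.Series:
        numbers = sorted(exon_numbers)
        missing = set(numbers) - set(self.data.index)
        if missing:
            raise ValueError(f"exons {sorted(missing)} missing from profile")
        return self.data.loc[numbers, column]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.10g")

    def sidecar(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "gene_id": self.model.gene_id,
            "transcript_id": self.model.transcript_id,
            "library_total_reads": self.library_total_reads,
            "tk_depth": self.tk_depth,
            "library_qc_pass": self.library_qc_pass,
            "strandedness": self.strandedness,
            **self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# pure per-read predicates


def aligned_ref_blocks(cigartuples) -> list[tuple[int, int]]:
    """Reference intervals covered by match bases, as offsets from pos 0.

    M/=/X extend the current covered block; D and N advance the reference
    without coverage (so a splice gap splits blocks); insertions and clips
    consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    ref = 0
    for op, length in cigartuples or ():
        if op in _REF_COVERED:
            if blocks and blocks[-1][1] == ref:
                blocks[-1] = (blocks[-1][0], ref + length)
            else:
                blocks.append((ref, ref + length))
            ref += length
        elif op in _REF_SKIPPED:
            ref += length
    return blocks


def aligned_ref_length(cigartuples) -> int:
    """Total reference-consuming match length (M/=/X bases)."""
    return sum(l for op, l in (cigartuples or ()) if op in _REF_COVERED)


def read_passes_filters(
    mapq: int,
    aligned_len: int,
    is_duplicate: bool,
    is_secondary_or_supp: bool,
    is_unmapped: bool,
    params: ReadFilterParams,
) -> bool:
    """Coverage-step read filter (pure predicate)."""
    if is_unmapped:
        return False
    if params.exclude_secondary_supplementary and is_secondary_or_supp:
        return False
    if params.exclude_duplicates and is_duplicate:
        return False
    if mapq < params.min_mapq:
        return False
    return aligned_len >= params.min_aln_len


def transcript_orientation(
    read_forward: bool, gene_strand: str, library: str
) -> Orientation:
    """Classify a read (or read-1 of a pair) relative to the transcript.

    For a ``reverse``-stranded library a read is transcript-SENSE iff its
    genomic alignment strand is opposite to the gene strand; for ``forward``
    iff equal; ``unstranded`` libraries cannot distinguish and return BOTH.
    Read-2 of a pair must be flipped to its fragment's strand before calling.
    """
    if library == "unstranded":
        return Orientation.BOTH
    read_strand = "+" if read_forward else "-"
    same = read_strand == gene_strand
    if library == "reverse":
        return Orientation.ANTISENSE if same else Orientation.SENSE
    if library == "forward":
        return Orientation.SENSE if same else Orientation.ANTISENSE
    raise ValueError(f"unknown library strandedness: {library!r}")


# ---------------------------------------------------------------------------
# file-level operations


def _open_alignments(path: str | Path) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), require_index=False)


def _resolve_contig(afile: pysam.AlignmentFile, chrom: str) -> str:
    refs = set(afile.references)
    if chrom in refs:
        return chrom
    alt = chrom[3:] if chrom.startswith("chr") else "chr" + chrom
    hint = f" (did you mean {alt!r}? check chr-prefix naming)" if alt in refs else ""
    raise ValueError(f"contig not found, check naming: {chrom!r}{hint}")


def _iter_region(afile: pysam.AlignmentFile, chrom: str, start: int, end: int):
    """Fetch via index when available, else full scan (plain SAM fixtures)."""
    try:
        yield from afile.fetch(chrom, start, end)
        return
    except ValueError:
        pass  # no index: fall through to a full scan
    for read in afile.fetch(until_eof=True):
        if read.reference_name != chrom or read.is_unmapped:
            continue
        if read.reference_start < end and read.reference_end > start:
            yield read


def count_exon_bases(
    alignments: str | Path | pysam.AlignmentFile,
    model: ExonModel,
    params: ReadFilterParams | None = None,
    library: str = "reverse",
) -> ExonCoverageProfile:
    """Count aligned bases per exon, separated by transcript orientation.

    Every passing read contributes, for each exon, the number of reference
    positions covered by its aligned (M/=/X) blocks intersected with the exon
    interval; spliced reads contribute nothing where their N gap spans an
    exon. Normalization is deferred to :func:`normalize_profile`.
    """
    params = params or ReadFilterParams()
    own = not isinstance(alignments, pysam.AlignmentFile)
    afile = _open_alignments(alignments) if own else alignments
    try:
        chrom = _resolve_contig(afile, model.chrom)
        span_start, span_end = model.span
        exons = [(e.number, e.start, e.end) for e in model.exons]
        sense = {n: 0 for n, _, _ in exons}
        anti = {n: 0 for n, _, _ in exons}
        for read in _iter_region(afile, chrom, span_start, span_end):
            cig = read.cigartuples
            if not read_passes_filters(
                read.mapping_quality,
                aligned_ref_length(cig),
                read.is_duplicate,
                read.is_secondary or read.is_supplementary,
                read.is_unmapped,
                params,
            ):
                continue
            forward = not read.is_reverse
            if read.is_paired and read.is_read2:
                forward = not forward  # flip read-2 to the fragment strand
            orient = transcript_orientation(forward, model.gene_strand, library)
            target = anti if orient is Orientation.ANTISENSE else sense
            pos = read.reference_start
            for boff, eoff in aligned_ref_blocks(cig):
                bstart, bend = pos + boff, pos + eoff
                for n, estart, eend in exons:
                    ov = min(bend, eend) - max(bstart, estart)
                    if ov > 0:
                        target[n] += ov
    finally:
        if own:
            afile.close()

    frame = model.to_frame()
    frame["sense_bases"] = pd.Series(sense)
    frame["antisense_bases"] = pd.Series(anti)
    return ExonCoverageProfile(
        data=frame, model=model, strandedness=library,
        meta={"read_filters": {
            "min_mapq": params.min_mapq, "min_aln_len": params.min_aln_len,
            "exclude_duplicates": params.exclude_duplicates,
        }},
    )


def library_size(
    alignments: str | Path, params: ReadFilterParams | None = None
) -> int:
    """Genome-wide count of primary, mapped, non-duplicate records.

    This is the "total number of reads" used for normalization and library
    QC; the MAPQ/length coverage filters are deliberately not applied here.
    """
    params = params or ReadFilterParams()
    n = 0
    with _open_alignments(alignments) as afile:
        for read in afile.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if params.exclude_duplicates and read.is_duplicate:
                continue
            n += 1
    if n == 0:
        warnings.warn("alignment file contains no usable reads", stacklevel=2)
    return n


def normalize_profile(
    profile: ExonCoverageProfile, library_total_reads: int
) -> ExonCoverageProfile:
    """Attach RPKM-like normalized coverage columns to a counts profile."""
    if library_total_reads <= 0:
        raise ValueError("cannot normalize empty library")
    d = profile.data
    d = d.assign(
        norm_sense=d["sense_bases"] / d["length"] / library_total_reads * 1e6,
        norm_antisense=(
            d["antisense_bases"] / d["length"] / library_total_reads * 1e6),
    )
    profile.data = d
    profile.library_total_reads = library_total_reads
    return profile


def tk_depth(
    profile: ExonCoverageProfile,
    tk_exons,
    both_strands: bool = False,
) -> float:
    """Mean aligned bases per position over the TK exon group.

    Sense-strand bases by default; ``both_strands=True`` additionally counts
    antisense bases.
    """
    numbers = sorted(tk_exons)
    sub = profile.data.loc[numbers]
    bases = sub["sense_bases"].sum()
    if both_strands:
        bases += sub["antisense_bases"].sum()
    return float(bases / sub["length"].sum())


def library_qc(library_total_reads: int, config: AssayConfig) -> bool:
    """Pass iff the library has at least ``min_library_reads`` unique reads."""
    return library_total_reads >= config.min_library_reads


def compute_profile(
    alignments: str | Path,
    model: ExonModel,
    config: AssayConfig | None = None,
    sample_id: str | None = None,
) -> ExonCoverageProfile:
    """Full coverage stage: count, size the library, normalize, QC."""
    config = config or AssayConfig()
    config.validate_against(model.exon_numbers)
    params = ReadFilterParams.from_config(config)
    profile = count_exon_bases(
        alignments, model, params, library=config.library_strandedness)
    total = library_size(alignments, params)
    profile = normalize_profile(profile, total)
    profile.tk_depth = tk_depth(
        profile, config.tk_exons, both_strands=config.depth_both_strands)
    profile.library_qc_pass = library_qc(total, config)
    profile.sample_id = sample_id or Path(str(alignments)).stem
    return profile
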