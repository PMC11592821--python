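"""Exon structure of a single transcript, in transcription order.

The assay reasons about exons the way a biologist numbers them: exon 1 is the
5' end of the transcript regardless of genomic strand, so "exons 20-24" always
means the kinase-proximal group even for a minus-strand gene like ALK.
Internally every interval is 0-based half-open (the BAM convention); GTF input
(1-based closed) is converted on load, BED is taken as-is.

A packaged ALK model for transcript ENST00000389048.8 (29 exons, chromosome 2,
minus strand) is available via :func:`builtin_alk`. Its per-exon coordinates
are a synthetic stand-in with realistic exon and intron lengths, generated
offline; exon count, chromosome and strand match the reference transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Exon", "ExonModel", "load_gene_model", "builtin_alk", "exon_lengths",
]

_ALK_DATA = "alk_exons_synthetic.tsv"


@dataclass(frozen=True)
class Exon:
    """One exon: transcription-order number plus a genomic interval."""

    number: int
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ExonModel:
    """Ordered, numbered exons of one transcript.

    Invariants (checked on construction): exon numbers are exactly 1..N,
    intervals are non-empty and pairwise non-overlapping, and numbering
    follows transcription order (for a '-' gene exon 1 has the largest
    genomic start).
    """

    gene_id: str
    transcript_id: str
    chrom: str
    gene_strand: str
    exons: tuple[Exon, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.gene_strand not in ("+", "-"):
            raise ValueError(f"gene_strand must be '+' or '-', got {self.gene_strand!r}")
        exons = tuple(sorted(self.exons, key=lambda e: e.number))
        object.__setattr__(self, "exons", exons)
        n = len(exons)
        if n == 0:
            raise ValueError("malformed model: no exons")
        if [e.number for e in exons] != list(range(1, n + 1)):
            raise ValueError("malformed model: exon numbers must be exactly 1..N")
        for e in exons:
            if e.end <= e.start:
                raise ValueError(f"malformed model: exon {e.number} has end <= start")
        by_pos = sorted(exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"malformed model: exons {a.number} and {b.number} overlap")
        # transcription order must match strand
        genomic = [e.start for e in exons]
        expected = sorted(genomic, reverse=self.gene_strand == "-")
        if genomic != expected:
            raise ValueError(
                "malformed model: exon numbering does not follow transcription "
                f"order for strand {self.gene_strand!r}")

    # -- basic accessors ------------------------------------------------

    def __len__(self) -> int:
        return len(self.exons)

    def __getitem__(self, number: int) -> Exon:
        if not 1 <= number <= len(self.exons):
            raise KeyError(f"exon {number} not in model (1..{len(self.exons)})")
        return self.exons[number - 1]

    @property
    def exon_numbers(self) -> list[int]:
        return [e.number for e in self.exons]

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons."""
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    def lengths(self, numbers=None) -> dict[int, int]:
        return exon_lengths(self, numbers)

    def reversed_strand(self) -> "ExonModel":
        """Same intervals on the opposite strand: exon k becomes N+1-k."""
        n = len(self.exons)
        flipped = tuple(
            Exon(n + 1 - e.number, e.start, e.end) for e in self.exons)
        strand = "+" if self.gene_strand == "-" else "-"
        return replace(self, gene_strand=strand, exons=flipped)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exon_number": [e.number for e in self.exons],
                "chrom": self.chrom,
                "start": [e.start for e in self.exons],
                "end": [e.end for e in self.exons],
                "length": [e.length for e in self.exons],
            }
        ).set_index("exon_number")

    # -- exon-table round trip ------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the simple 4-column exon-table format (see module docs)."""
        lines = [
            f"#gene_id={self.gene_id}\ttranscript_id={self.transcript_id}",
            f"#gene_strand={self.gene_strand}",
        ]
        for e in sorted(self.exons, key=lambda e: e.number):
            lines.append(f"{self.chrom}\t{e.start}\t{e.end}\t{e.number}")
        Path(path).write_text("\n".join(lines) + "\n")


def _exon_table_from_lines(lines: list[str]) -> ExonModel:
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int, int]] = []
    for raw in lines:
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            for kv in line.lstrip("#").split("\t"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise ValueError(f"malformed exon-table row: {line!r}")
        rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    if "gene_strand" not in meta:
        raise ValueError("exon table is missing a '#gene_strand=' header line")
    chroms = {r[0] for r in rows}
    if len(chroms) != 1:
        raise ValueError("exon table must describe a single chromosome")
    return ExonModel(
        gene_id=meta.get("gene_id", "unknown"),
        transcript_id=meta.get("transcript_id", "unknown"),
        chrom=chroms.pop(),
        gene_strand=meta["gene_strand"],
        exons=tuple(Exon(num, start, end) for _, start, end, num in rows),
    )


def _load_exon_table(path: str | Path) -> ExonModel:
    return _exon_table_from_lines(Path(path).read_text().splitlines())


def _load_gtf(path: str | Path, transcript_id: str) -> ExonModel:
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    if "transcript_id" not in df.columns:
        raise ValueError("GTF has no transcript_id attribute")
    sub = df[(df["Feature"] == "exon") & (df["transcript_id"] == transcript_id)]
    if sub.empty:
        raise ValueError(f"transcript not found: {transcript_id}")
    strands = set(sub["Strand"])
    if len(strands) != 1:
        raise ValueError(f"malformed model: mixed strands for {transcript_id}")
    strand = strands.pop()
    gene_id = str(sub["gene_id"].iloc[0]) if "gene_id" in sub.columns else "unknown"
    chroms = set(sub["Chromosome"].astype(str))
    if len(chroms) != 1:
        raise ValueError(f"malformed model: multiple chromosomes for {transcript_id}")
    # pyranges already converts GTF to 0-based half-open Start/End
    ivals = sorted(
        (int(s), int(e)) for s, e in zip(sub["Start"], sub["End"]))
    if strand == "-":
        ivals = ivals[::-1]
    exons = tuple(Exon(i + 1, s, e) for i, (s, e) in enumerate(ivals))
    return ExonModel(gene_id, transcript_id, chroms.pop(), strand, exons)


def _load_bed12(path: str | Path, transcript_id: str | None) -> ExonModel:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thick_start", "thick_end", "rgb", "block_count",
        "block_sizes", "block_starts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    if transcript_id is not None:
        df = df[df["name"] == transcript_id]
        if df.empty:
            raise ValueError(f"transcript not found: {transcript_id}")
    if len(df) != 1:
        raise ValueError("BED12 input must resolve to a single transcript row")
    row = df.iloc[0]
    sizes = [int(x) for x in str(row["block_sizes"]).rstrip(",").split(",")]
    offsets = [int(x) for x in str(row["block_starts"]).rstrip(",").split(",")]
    if len(sizes) != int(row["block_count"]) or len(offsets) != len(sizes):
        raise ValueError("malformed BED12 blocks")
    ivals = [
        (int(row["start"]) + off, int(row["start"]) + off + size)
        for off, size in zip(offsets, sizes)
    ]
    ivals.sort()
    if row["strand"] == "-":
        ivals = ivals[::-1]
    exons = tuple(Exon(i + 1, s, e) for i, (s, e) in enumerate(ivals))
    return ExonModel(
        gene_id=str(row["name"]), transcript_id=str(row["name"]),
        chrom=str(row["chrom"]), gene_strand=str(row["strand"]), exons=exons)


def load_gene_model(
    path: str | Path,
    format: str = "exon-table",
    transcript_id: str | None = None,
) -> ExonModel:
    """Load an :class:`ExonModel` from GTF, BED12 or the exon-table format.

    GTF coordinates (1-based closed) are converted to the internal 0-based
    half-open convention; exon numbering is recomputed from transcription
    order as determined by the strand.
    """
    fmt = format.lower()
    if fmt == "gtf":
        if transcript_id is None:
            raise ValueError("transcript_id is required for GTF input")
        return _load_gtf(path, transcript_id)
    if fmt == "bed12":
        return _load_bed12(path, transcript_id)
    if fmt in ("exon-table", "table", "tsv"):
        return _load_exon_table(path)
    raise ValueError(f"unknown gene-model format: {format!r}")


def builtin_alk() -> ExonModel:
    """The packaged ALK exon model (ENST00000389048.8-keyed).

    29 exons on the minus strand of chromosome 2, exon 1 at the 5' end of the
    transcript and the tyrosine-kinase domain beginning at exon 20. The
    packaged coordinates are a synthetic stand-in with realistic exon/intron
    lengths (see module docstring); no network access is needed or attempted.
    """
    text = (resources.files("covasym.data") / _ALK_DATA).read_text()
    return _exon_table_from_lines(text.splitlines())


def exon_lengths(model: ExonModel, numbers=None) -> dict[int, int]:
    """Map exon number -> length in bases for the requested exons.

    ``numbers=None`` returns all exons; unknown numbers raise ``KeyError``.
    """
    if numbers is None:
        return {e.number: e.length for e in model.exons}
    return {n: model[n].length for n in sorted(numbers)}
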