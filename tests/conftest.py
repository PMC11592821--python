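"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own code paths: the coverage
oracle parses SAM text by hand and counts covered positions one at a time,
and the rank-test oracle enumerates group reassignments with exact rational
arithmetic using a rank-sum formulation of U. Both exist so the fast
implementations can be checked against something slow and obviously correct.
"""

from __future__ import annotations

import re
from fractions import Fraction
from itertools import combinations

import pytest

from covasym import AssayConfig, Exon, ExonModel, builtin_alk

# ---------------------------------------------------------------------------
# gene-model fixtures


@pytest.fixture(scope="session")
def alk_model() -> ExonModel:
    return builtin_alk()


@pytest.fixture(scope="session")
def uniform_model() -> ExonModel:
    """29 equal-length exons on '+': exchangeable groups for null studies."""
    exons = tuple(
        Exon(i + 1, 1000 + i * 500, 1000 + i * 500 + 150) for i in range(29))
    return ExonModel("UNI", "UNI-T1", "2", "+", exons)


@pytest.fixture
def three_exon_model() -> ExonModel:
    """Tiny '+' model: exons 1..3 at (100,200), (300,400), (500,550)."""
    return ExonModel(
        "G1", "T1", "2", "+",
        (Exon(1, 100, 200), Exon(2, 300, 400), Exon(3, 500, 550)))


# ---------------------------------------------------------------------------
# SAM fixture helper


SAM_CONTIGS = {"2": 50_000_000, "decoy": 1_000_000}


def sam_text(records: list[str], contigs: dict[str, int] | None = None) -> str:
    contigs = contigs or SAM_CONTIGS
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    header += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in contigs.items()]
    return "\n".join(header + records) + "\n"


def sam_record(
    qname: str,
    chrom: str,
    pos1: int,
    cigar: str,
    flag: int = 0,
    mapq: int = 255,
) -> str:
    """One SAM line; pos1 is 1-based as in the format."""
    read_len = sum(
        int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
        if op in "MIS=X")
    seq = "A" * read_len if read_len else "*"
    return (
        f"{qname}\t{flag}\t{chrom}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*")


@pytest.fixture
def write_sam(tmp_path):
    def _write(records, name="fixture.sam", contigs=None):
        path = tmp_path / name
        path.write_text(sam_text(records, contigs))
        return path

    return _write


# ---------------------------------------------------------------------------
# brute-force per-position coverage oracle (independent of covasym.coverage)


def _oracle_covered_positions(pos0: int, cigar: str) -> set[int]:
    covered: set[int] = set()
    ref = pos0
    for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        n = int(n)
        if op in "M=X":
            covered.update(range(ref, ref + n))
            ref += n
        elif op in "DN":
            ref += n
    return covered


def oracle_exon_counts(
    sam_body: str,
    model: ExonModel,
    min_mapq: int = 101,
    min_aln_len: int = 10,
    library: str = "reverse",
) -> dict[int, dict[str, int]]:
    """Per-exon sense/antisense base counts by per-position enumeration."""
    out = {e.number: {"sense": 0, "antisense": 0} for e in model.exons}
    for line in sam_body.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag, chrom, pos1, mapq, cigar = (
            int(f[1]), f[2], int(f[3]), int(f[4]), f[5])
        if chrom != model.chrom:
            continue
        if flag & (0x4 | 0x100 | 0x400 | 0x800):
            continue
        if mapq < min_mapq:
            continue
        aln_len = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIDNSHP=X])", cigar)
            if op in "M=X")
        if aln_len < min_aln_len:
            continue
        covered = _oracle_covered_positions(pos1 - 1, cigar)
        read_strand = "-" if flag & 0x10 else "+"
        if flag & 0x1 and flag & 0x80:  # read-2: flip to fragment strand
            read_strand = "+" if read_strand == "-" else "-"
        if library == "unstranded":
            key = "sense"
        else:
            same = read_strand == model.gene_strand
            if library == "reverse":
                key = "antisense" if same else "sense"
            else:
                key = "sense" if same else "antisense"
        for e in model.exons:
            n = sum(1 for p in covered if e.start <= p < e.end)
            out[e.number][key] += n
    return out


# ---------------------------------------------------------------------------
# exact rank-test oracle (rank-sum formulation, rational arithmetic)


def _ranks(values):
    """Mid-ranks, computed by sort-and-average (1-based)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [Fraction(0)] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = Fraction(sum(range(i + 1, j + 2)), j - i + 1)
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_exact_p(control, tk) -> Fraction:
    """P(U >= U_obs) over all splits, via U = R_tk - n2(n2+1)/2 on mid-ranks."""
    pooled = list(control) + list(tk)
    n1, n2 = len(control), len(tk)
    ranks = _ranks(pooled)

    def u_of(tk_idx):
        r = sum(ranks[i] for i in tk_idx)
        return r - Fraction(n2 * (n2 + 1), 2)

    u_obs = u_of(range(n1, n1 + n2))
    hits = 0
    total = 0
    for tk_idx in combinations(range(n1 + n2), n2):
        total += 1
        if u_of(tk_idx) >= u_obs:
            hits += 1
    return Fraction(hits, total)


# ---------------------------------------------------------------------------
# a config whose library floor suits desk-scale simulated libraries


@pytest.fixture(scope="session")
def desk_config() -> AssayConfig:
    return AssayConfig(min_library_reads=1000)
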