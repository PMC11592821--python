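"""Synthetic stranded RNA-seq alignments with known truth, and the
sequencing-depth reliability experiment.

The generator emits syntactically valid SAM: on-target reads are placed
uniformly inside single exons of the target gene (no splice simulation, so
brute-force per-position oracles stay exact), drawn per exon proportionally
to expression weight x exon length; off-target background reads live on a
decoy contig and set the library size independently of on-target coverage.
Read strands follow the configured library convention so the coverage
engine's orientation truth table classifies each read as intended; an
``antisense_fraction`` emulates read-through transcription from a neighbour
gene on the opposite strand. MAPQ is 255 (unique mappers) throughout.

Three truth profiles mirror the biology the screen must distinguish:

``FUSION``
    5' exons silent (optionally a small leak), exons at and beyond the
    breakpoint (default exon 20) elevated ``fold``-fold — the signature of a
    rearrangement that replaces the gene's 5' portion but keeps the kinase
    domain under the partner's promoter.
``WILD_TYPE``
    uniform baseline expression over all exons.
``SILENT``
    no on-target transcription at all.

:func:`depth_reliability_experiment` reproduces, at desk scale, the
subsampling design used to calibrate the TK-depth reliability gate: a master
library is subsampled to a grid of total read counts in triplicate, and each
subsample is pushed through the full coverage + exact-test pipeline to give a
(depth, p-value) table and a per-depth power estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .asymmetry import classify
from .config import AssayConfig
from .coverage import compute_profile
from .gene_model import ExonModel, builtin_alk

__all__ = [
    "SimProfile", "SubsampleResult", "make_profile", "simulate_alignments",
    "subsample_reads", "depth_reliability_experiment",
    "default_reliability_profile", "DEFAULT_DEPTH_GRID",
]

DECOY_CONTIG = "decoy"
DECOY_LENGTH = 1_000_000

#: Desk-scale subsampling grid (total reads); the published experiment used
#: 1/2/5/10/20 million reads — the same 1/2/4/10/20 shape, three orders of
#: magnitude smaller.
DEFAULT_DEPTH_GRID = (5_000, 10_000, 20_000, 50_000, 100_000)


@dataclass
class SimProfile:
    """Ground truth for one simulated sample."""

    model: ExonModel
    exon_weights: dict[int, float]
    truth_label: str
    on_target_reads: int = 400
    background_reads: int = 199_600
    antisense_fraction: float = 0.0
    read_length: int = 50
    seed: int = 0
    library: str = "reverse"

    def __post_init__(self) -> None:
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError("antisense_fraction must be in [0, 1]")
        weights = {int(k): float(v) for k, v in self.exon_weights.items()}
        if any(w < 0 for w in weights.values()):
            raise ValueError("exon weights must be nonnegative")
        total = sum(weights.values())
        if total == 0 and self.truth_label != "SILENT":
            raise ValueError("non-SILENT profiles need positive total weight")
        self.exon_weights = weights

    def to_dict(self) -> dict:
        return {
            "truth_label": self.truth_label,
            "gene_id": self.model.gene_id,
            "exon_weights": {str(k): v for k, v in sorted(self.exon_weights.items())},
            "on_target_reads": self.on_target_reads,
            "background_reads": self.background_reads,
            "antisense_fraction": self.antisense_fraction,
            "read_length": self.read_length,
            "seed": self.seed,
            "library": self.library,
        }


def make_profile(
    kind: str,
    model: ExonModel | None = None,
    breakpoint_exon: int = 20,
    fold: float = 50.0,
    baseline: float = 1.0,
    leak: float = 0.0,
    **kwargs,
) -> SimProfile:
    """Build the truth profile for a FUSION, WILD_TYPE or SILENT sample.

    FUSION puts weight ``baseline * leak`` on exons before the breakpoint
    (default no leak: the 5' portion is lost entirely) and ``baseline * fold``
    on exons from the breakpoint on; WILD_TYPE is uniform ``baseline``;
    SILENT is all-zero.
    """
    model = model or builtin_alk()
    kind = kind.upper()
    if kind == "FUSION":
        if fold <= 0:
            raise ValueError("fold must be positive")
        if breakpoint_exon not in model.exon_numbers:
            raise ValueError(f"breakpoint exon {breakpoint_exon} not in model")
        weights = {
            n: baseline * (fold if n >= breakpoint_exon else leak)
            for n in model.exon_numbers
        }
    elif kind == "WILD_TYPE":
        weights = {n: baseline for n in model.exon_numbers}
    elif kind == "SILENT":
        weights = {n: 0.0 for n in model.exon_numbers}
    else:
        raise ValueError(f"unknown profile kind: {kind!r}")
    return SimProfile(model=model, exon_weights=weights, truth_label=kind,
                      **kwargs)


def _sam_header(model: ExonModel) -> dict:
    span_end = model.span[1]
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": model.chrom, "LN": span_end + 10_000},
            {"SN": DECOY_CONTIG, "LN": DECOY_LENGTH},
        ],
    }


def _sense_is_forward(gene_strand: str, library: str) -> bool:
    """Genomic strand on which a transcript-sense read aligns."""
    if library == "reverse":
        return gene_strand == "-"
    # forward-stranded (and unstranded, where the choice is arbitrary)
    return gene_strand == "+"


def simulate_alignments(
    profile: SimProfile, out_path: str | Path, truth_path: str | Path | None = None
) -> Path:
    """Write a SAM file realising ``profile``; deterministic given its seed.

    On-target reads are distributed over positive-weight exons with
    probability proportional to weight x length and placed uniformly so each
    read fits entirely inside its exon. The truth record is written next to
    the SAM (``<out>.truth.json``) unless a path is given.
    """
    out_path = Path(out_path)
    model = profile.model
    rng = np.random.default_rng(profile.seed)

    positive = [
        (n, model[n].start, model[n].end)
        for n in model.exon_numbers
        if profile.exon_weights.get(n, 0.0) > 0
    ]
    if profile.on_target_reads > 0 and positive:
        too_short = [n for n, s, e in positive if e - s < profile.read_length]
        if too_short:
            raise ValueError(
                f"read_length {profile.read_length} exceeds exon(s) "
                f"{too_short}; shrink read_length")
        w = np.array(
            [profile.exon_weights[n] * (e - s) for n, s, e in positive])
        counts = rng.multinomial(profile.on_target_reads, w / w.sum())
    else:
        counts = np.zeros(len(positive), dtype=int)

    sense_forward = _sense_is_forward(model.gene_strand, profile.library)
    header = _sam_header(model)
    with pysam.AlignmentFile(str(out_path), "w", header=header) as sam:
        serial = 0
        for (n, start, end), k in zip(positive, counts):
            if k == 0:
                continue
            starts = rng.integers(start, end - profile.read_length + 1, size=k)
            antisense = rng.random(k) < profile.antisense_fraction
            for pos, anti in zip(starts, antisense):
                serial += 1
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"ot{serial:07d}_ex{n}"
                a.reference_id = 0
                a.reference_start = int(pos)
                a.mapping_quality = 255
                a.cigarstring = f"{profile.read_length}M"
                forward = sense_forward ^ bool(anti)
                a.flag = 0 if forward else 16
                a.query_sequence = "A" * profile.read_length
                sam.write(a)
        if profile.background_reads > 0:
            starts = rng.integers(
                0, DECOY_LENGTH - profile.read_length,
                size=profile.background_reads)
            strands = rng.random(profile.background_reads) < 0.5
            for i, (pos, fwd) in enumerate(zip(starts, strands)):
                a = pysam.AlignedSegment(sam.header)
                a.query_name = f"bg{i + 1:07d}"
                a.reference_id = 1
                a.reference_start = int(pos)
                a.mapping_quality = 255
                a.cigarstring = f"{profile.read_length}M"
                a.flag = 0 if fwd else 16
                a.query_sequence = "A" * profile.read_length
                sam.write(a)

    truth_path = Path(truth_path) if truth_path else out_path.with_suffix(
        out_path.suffix + ".truth.json")
    truth_path.write_text(json.dumps(profile.to_dict(), indent=2) + "\n")
    return out_path


def subsample_reads(
    alignments: str | Path,
    target_read_count: int,
    seed: int,
    out_path: str | Path,
) -> Path:
    """Uniform sample (without replacement) of primary records, to SAM.

    Record order is preserved, so the same seed always yields a byte-stable
    subset. Raises when more reads are requested than exist.
    """
    with pysam.AlignmentFile(str(alignments)) as src:
        header = src.header.to_dict()
        records = [
            r for r in src.fetch(until_eof=True)
            if not (r.is_secondary or r.is_supplementary)
        ]
    if target_read_count > len(records):
        raise ValueError(
            f"requested {target_read_count} reads but only "
            f"{len(records)} available")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(records), target_read_count, replace=False))
    out_path = Path(out_path)
    with pysam.AlignmentFile(str(out_path), "w", header=header) as dst:
        for i in keep:
            dst.write(records[i])
    return out_path


@dataclass
class SubsampleResult:
    """Outcome of the depth-reliability (subsampling) experiment."""

    table: pd.DataFrame  # columns: target_reads, replicate, seed, tk_depth, p_value
    power: pd.Series     # per target_reads: fraction of replicates with p < alpha
    alpha: float
    base_seed: int
    profile: SimProfile | None = None
    seeds: list[int] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _grid_seed(base_seed: int, grid_index: int, replicate: int) -> int:
    # distinct, reproducible, < 2^31
    return (base_seed + 100_003 * (grid_index + 1) + replicate) % (2**31 - 1)


def depth_reliability_experiment(
    profile: SimProfile,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    replicates: int = 3,
    base_seed: int = 0,
    config: AssayConfig | None = None,
    workdir: str | Path | None = None,
) -> SubsampleResult:
    """Subsample a simulated library over a read-count grid, in replicate.

    For each replicate a fresh master library is simulated (seed
    ``base_seed + replicate``); each grid point is then drawn from it without
    replacement and pushed through coverage counting, normalization and the
    exact one-sided rank test. Returns the full (depth, p) table plus the
    fraction of significant replicates per grid point.
    """
    if not depth_grid:
        raise ValueError("depth_grid must be non-empty")
    config = config or AssayConfig()
    import tempfile

    rows = []
    seeds_used: list[int] = []
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir else Path(tmp)
        base.mkdir(parents=True, exist_ok=True)
        for rep in range(replicates):
            master_profile = replace(profile, seed=profile.seed + base_seed + rep)
            master = simulate_alignments(
                master_profile, base / f"master_rep{rep}.sam")
            for gi, target in enumerate(depth_grid):
                seed = _grid_seed(base_seed, gi, rep)
                seeds_used.append(seed)
                sub = subsample_reads(
                    master, target, seed, base / f"sub_{target}_r{rep}.sam")
                cov = compute_profile(
                    sub, profile.model, config,
                    sample_id=f"{profile.truth_label}_{target}_r{rep}")
                res = classify(cov, config)
                rows.append(
                    {
                        "target_reads": target,
                        "replicate": rep,
                        "seed": seed,
                        "tk_depth": cov.tk_depth,
                        "p_value": res.p_value,
                        "verdict": res.verdict,
                    }
                )
    table = pd.DataFrame(rows)
    power = (
        table.assign(sig=table["p_value"] < config.alpha)
        .groupby("target_reads")["sig"].mean()
        .rename("power")
    )
    return SubsampleResult(
        table=table, power=power, alpha=config.alpha,
        base_seed=base_seed, profile=profile, seeds=seeds_used)


def default_reliability_profile(
    model: ExonModel | None = None, seed: int = 0
) -> SimProfile:
    """Study-condition FUSION profile for the subsampling experiment.

    200k-read master library with an on-target fraction of 0.002 and 25 bp
    reads, chosen so the subsampling grid straddles the TK-depth reliability
    gate of 0.7 (see the methods note for the calibration).
    """
    return make_profile(
        "FUSION",
        model=model or builtin_alk(),
        on_target_reads=400,
        background_reads=199_600,
        read_length=25,
        seed=seed,
    )
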