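"""Model/Results front end for the coverage-asymmetry fusion predictor.

`CoverageAsymmetry` bundles the inputs of one assay run (a per-exon coverage
profile, the gene model it was computed against, and the assay
configuration); `fit()` runs the exact one-sided rank test and returns a
`CoverageAsymmetryResults` carrying the estimates, the verdict, and
presentation helpers (`summary()`, `plot()`), in the spirit of the
model/results split used by statistical modelling packages.
"""

from __future__ import annotations

from pathlib import Path

from .asymmetry import AsymmetryResult, classify
from .config import AssayConfig
from .coverage import ExonCoverageProfile, compute_profile
from .gene_model import ExonModel, builtin_alk

__all__ = ["CoverageAsymmetry", "CoverageAsymmetryResults"]


class CoverageAsymmetry:
    """Exon coverage-asymmetry model for one sample of one target gene."""

    def __init__(
        self,
        profile: ExonCoverageProfile,
        config: AssayConfig | None = None,
    ):
        self.profile = profile
        self.config = config or AssayConfig()
        self.config.validate_against(profile.model.exon_numbers)

    @classmethod
    def from_alignments(
        cls,
        alignments: str | Path,
        gene_model: ExonModel | None = None,
        config: AssayConfig | None = None,
        sample_id: str | None = None,
    ) -> "CoverageAsymmetry":
        """Build the model straight from a BAM/SAM file.

        Runs the full coverage stage (filtering, strand-aware per-exon base
        counting, library sizing, RPKM-like normalization, TK depth, library
        QC). The packaged ALK model is used when no gene model is given.
        """
        model = gene_model or builtin_alk()
        config = config or AssayConfig()
        profile = compute_profile(alignments, model, config, sample_id=sample_id)
        return cls(profile, config)

    def fit(self) -> "CoverageAsymmetryResults":
        """Run the exact test and classification; return the results object."""
        result = classify(self.profile, self.config)
        return CoverageAsymmetryResults(self, result)


class CoverageAsymmetryResults:
    """Fitted results: test statistics, verdict, and reporting helpers."""

    def __init__(self, model: CoverageAsymmetry, result: AsymmetryResult):
        self.model = model
        self.result = result

    # convenient scalar accessors, statsmodels-style
    @property
    def pvalue(self) -> float:
        return self.result.p_value

    @property
    def u_statistic(self) -> float:
        return self.result.u_statistic

    @property
    def verdict(self) -> str:
        return self.result.verdict

    @property
    def tk_depth(self) -> float | None:
        return self.result.tk_depth

    @property
    def flags(self) -> list[str]:
        return self.result.flags

    def summary(self) -> str:
        """Plain-text summary table of the run."""
        p = self.model.profile
        c = self.model.config
        r = self.result
        rows = [
            ("Sample", p.sample_id or "-"),
            ("Gene / transcript",
             f"{p.model.gene_id} / {p.model.transcript_id}"),
            ("Exons in model", str(len(p.model))),
            ("Library reads (unique)", f"{p.library_total_reads:,}"
             if p.library_total_reads is not None else "-"),
            ("Library QC (>= {:,})".format(c.min_library_reads),
             {True: "pass", False: "FAIL", None: "-"}[p.library_qc_pass]),
            ("Control exons", ",".join(map(str, sorted(c.control_exons)))),
            ("TK exons", ",".join(map(str, sorted(c.tk_exons)))),
            ("Control mean coverage", f"{r.control_mean:.4f}"),
            ("TK mean coverage", f"{r.tk_mean:.4f}"),
            ("TK depth (gate {:.2f})".format(c.min_tk_depth),
             "-" if r.tk_depth is None else f"{r.tk_depth:.3f}"),
            ("U statistic", f"{r.u_statistic:g}"),
            ("p-value (one-sided exact)", f"{r.p_value:.3f}"),
            ("Verdict", r.verdict),
            ("Flags", ",".join(r.flags) if r.flags else "none"),
        ]
        width = max(len(k) for k, _ in rows)
        title = "Exon Coverage Asymmetry Test"
        bar = "=" * (width + 30)
        body = "\n".join(f"{k:<{width}}  {v}" for k, v in rows)
        return f"{bar}\n{title:^{width + 30}}\n{bar}\n{body}\n{bar}"

    def plot(self, out_path: str | Path | None = None, ax=None):
        """Sense/antisense coverage bar plot (see report.plot_coverage)."""
        from .report import plot_coverage

        return plot_coverage(
            self.model.profile, self.result, out_path=out_path, ax=ax,
            config=self.model.config)

    def to_dict(self) -> dict:
        d = self.result.to_dict()
        d["library_total_reads"] = self.model.profile.library_total_reads
        d["library_qc_pass"] = self.model.profile.library_qc_pass
        return d
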