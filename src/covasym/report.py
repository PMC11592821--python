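"""Reports, coverage plots, and validation (confusion) metrics.

Per-sample outputs are a one-row TSV and a JSON report; the coverage plot
shows normalized sense coverage as positive bars and antisense coverage as
negative bars over exon number, with the TK exon group highlighted and the
test result annotated. The validation utility cross-tabulates
predicted-vs-confirmed fusion flags into accuracy / sensitivity /
specificity; a transcription of the published 50-sample targeted-NGS
validation cohort ships with the package (the 31 aggregate-reported negative
controls are synthetic placeholder rows, flagged in the fixture comments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .asymmetry import AsymmetryResult
from .config import AssayConfig
from .coverage import ExonCoverageProfile

__all__ = [
    "ConfusionMetrics", "confusion_metrics", "load_validation_table",
    "plot_coverage", "write_sample_report", "batch_screen",
]

_VALIDATION_DATA = "validation_cohort.tsv"

RESULT_COLUMNS = [
    "sample_id", "gene", "p_value", "u_statistic", "control_mean",
    "tk_mean", "tk_depth", "verdict", "flags",
]


# ---------------------------------------------------------------------------
# validation metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn) * 100

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ZeroDivisionError(
                "sensitivity undefined: no confirmed positives in the table")
        return self.tp / (self.tp + self.fn) * 100

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ZeroDivisionError(
                "specificity undefined: no confirmed negatives in the table")
        return self.tn / (self.tn + self.fp) * 100

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def __str__(self) -> str:  # one decimal for display
        return (
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} | "
            f"accuracy {self.accuracy:.1f}% sensitivity {self.sensitivity:.1f}% "
            f"specificity {self.specificity:.1f}%"
        )


def load_validation_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load a validation table (sample_id, predicted/confirmed flags).

    Without a path, returns the packaged 50-sample cohort.
    """
    if path is None:
        src = resources.files("covasym.data") / _VALIDATION_DATA
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "predicted_positive", "confirmed_positive"}
    if not required <= set(df.columns):
        raise ValueError(f"validation table needs columns {sorted(required)}")
    if df.empty:
        raise ValueError("validation table is empty")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in validation table")
    df["predicted_positive"] = df["predicted_positive"].astype(bool)
    df["confirmed_positive"] = df["confirmed_positive"].astype(bool)
    return df


def confusion_metrics(table: pd.DataFrame) -> ConfusionMetrics:
    """Cross-tabulate predicted vs confirmed fusion flags."""
    pred = table["predicted_positive"].astype(bool)
    conf = table["confirmed_positive"].astype(bool)
    return ConfusionMetrics(
        tp=int((pred & conf).sum()),
        fp=int((pred & ~conf).sum()),
        tn=int((~pred & ~conf).sum()),
        fn=int((~pred & conf).sum()),
    )


# ---------------------------------------------------------------------------
# plotting


def plot_coverage(
    profile: ExonCoverageProfile,
    result: AsymmetryResult | None = None,
    out_path: str | Path | None = None,
    ax=None,
    config: AssayConfig | None = None,
):
    """Bar chart of normalized coverage per exon, antisense mirrored below zero.

    TK-group exons are drawn in a distinct colour; the annotation reports the
    one-sided p-value and the non-TK/TK group mean coverages.
    """
    import matplotlib
    if out_path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    config = config or AssayConfig()
    if not profile.is_normalized:
        raise ValueError("profile must be normalized before plotting")

    d = profile.data
    exon_nums = d.index.to_numpy()
    tk = [n in config.tk_exons for n in exon_nums]
    ctrl = [n in config.control_exons for n in exon_nums]
    colors = [
        "#c0392b" if t else ("#2980b9" if c else "#95a5a6")
        for t, c in zip(tk, ctrl)
    ]

    created_fig = ax is None
    if created_fig:
        fig, ax = plt.subplots(figsize=(10, 4))
    else:
        fig = ax.figure

    ax.bar(exon_nums, d["norm_sense"], color=colors, label="sense")
    if (d["norm_antisense"] > 0).any():
        ax.bar(exon_nums, -d["norm_antisense"], color="#7f8c8d",
               alpha=0.7, label="antisense")
    ax.axhline(0.0, color="black", lw=0.8)
    ax.set_xlabel("exon number (transcription order)")
    ax.set_ylabel("normalized coverage\n(bases/pos/read x 1e6)")
    title = profile.sample_id or profile.model.gene_id
    if result is not None:
        title += (
            f"   p={result.p_value:.3f}   non-TK/TK coverage "
            f"{result.control_mean:.3f}/{result.tk_mean:.3f}"
        )
    ax.set_title(title)
    ax.legend(loc="upper left", frameon=False)

    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        if created_fig:
            plt.close(fig)
    return ax


# ---------------------------------------------------------------------------
# report writing and batch mode


def _result_row(result: AsymmetryResult) -> dict:
    return {
        "sample_id": result.sample_id,
        "gene": result.gene_id,
        "p_value": result.p_value,
        "u_statistic": result.u_statistic,
        "control_mean": result.control_mean,
        "tk_mean": result.tk_mean,
        "tk_depth": result.tk_depth,
        "verdict": result.verdict,
        "flags": ";".join(result.flags),
    }


def write_sample_report(
    profile: ExonCoverageProfile,
    result: AsymmetryResult,
    out_dir: str | Path,
    config: AssayConfig | None = None,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the per-sample TSV/JSON (and optional plot); return the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = result.sample_id or "sample"
    paths = {
        "coverage_tsv": out_dir / f"{stem}.coverage.tsv",
        "result_tsv": out_dir / f"{stem}.result.tsv",
        "report_json": out_dir / f"{stem}.report.json",
    }
    profile.to_tsv(paths["coverage_tsv"])
    pd.DataFrame([_result_row(result)], columns=RESULT_COLUMNS).to_csv(
        paths["result_tsv"], sep="\t", index=False, float_format="%.10g")
    report = {
        "result": result.to_dict(),
        "library": profile.sidecar(),
        "config": (config or AssayConfig()).to_dict(),
    }
    paths["report_json"].write_text(json.dumps(report, indent=2) + "\n")
    if plot:
        paths["plot"] = out_dir / f"{stem}.coverage.png"
        plot_coverage(profile, result, out_path=paths["plot"], config=config)
    return paths


def batch_screen(
    manifest: pd.DataFrame,
    gene_model,
    config: AssayConfig | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Screen a cohort: one result row per sample in the manifest.

    ``manifest`` needs columns ``sample_id`` and ``path``. Samples failing
    library QC are reported with verdict QC_FAIL and excluded from calls;
    per-sample failures are recorded in the ``error`` column and do not stop
    the batch. With ``bh_adjust`` a Benjamini-Hochberg ``q_value`` column is
    added over the successfully tested samples.
    """
    from .asymmetry import Verdict, classify
    from .coverage import compute_profile

    config = config or AssayConfig()
    if manifest.empty:
        import warnings

        warnings.warn("empty manifest: no samples to screen", stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS + ["error"])

    rows = []
    for rec in manifest.itertuples(index=False):
        sample_id = str(rec.sample_id)
        try:
            profile = compute_profile(
                rec.path, gene_model, config, sample_id=sample_id)
            result = classify(profile, config)
            row = _result_row(result)
            if not profile.library_qc_pass:
                row["verdict"] = Verdict.QC_FAIL
            row["error"] = ""
        except Exception as exc:  # per-sample failure: log, continue
            row = {c: None for c in RESULT_COLUMNS}
            row["sample_id"] = sample_id
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["error"])

    if bh_adjust:
        from scipy.stats import false_discovery_control

        mask = out["p_value"].notna() & (out["verdict"] != Verdict.QC_FAIL)
        out["q_value"] = pd.NA
        if mask.any():
            out.loc[mask, "q_value"] = false_discovery_control(
                out.loc[mask, "p_value"].to_numpy(), method="bh")
    return out
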