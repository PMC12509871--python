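"""Evaluation of fine-mapping output against simulation truth.

Three summaries are produced from a set of simulated replicates:

* PIP distributions for Signal / Proxy / Null factors, split by whether all
  causal factors in the replicate reached genome-wide significance
  (P < 5e-8) in the single-factor association tests;
* a PIP calibration table: factors binned by PIP into deciles, with the
  empirical causal fraction and Clopper-Pearson confidence interval per bin;
* a precision-recall curve over PIP thresholds with Signal as the positive
  class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .dapg import FineMapResult
from .simulate import GENOME_WIDE_ALPHA, TruthRecord


@dataclass
class EvaluationReport:
    """Joined per-factor table plus the three derived summaries."""

    pip_table: pd.DataFrame
    strata_summary: pd.DataFrame
    calibration: pd.DataFrame
    precision: Optional[np.ndarray]
    recall: Optional[np.ndarray]
    pr_thresholds: Optional[np.ndarray]
    average_precision: Optional[float]


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def pip_long_table(
    results: Sequence[FineMapResult],
    truths: Sequence[TruthRecord],
    fbat_tables: Sequence[pd.DataFrame],
    alpha_gw: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """One row per (replicate, factor in the analysis panel).

    ``fbat_tables`` are the per-replicate z tables (``zpanel_frame`` output);
    their p-values drive the genome-wide-significance stratification.  A
    causal factor dropped from the panel counts as not significant.
    """
    if not (len(results) == len(truths) == len(fbat_tables)):
        raise ValueError("results, truths and fbat tables must be aligned")
    rows = []
    for rep, (res, truth, ztab) in enumerate(zip(results, truths, fbat_tables)):
        pvals = dict(zip(ztab["factor_id"].astype(str), ztab["p"].astype(float)))
        all_gw = all(
            pvals.get(nm, 1.0) < alpha_gw for nm in truth.causal_factor_names
        )
        truth.all_causal_genomewide = all_gw
        for i, nm in enumerate(res.factor_names):
            rows.append(
                {
                    "replicate": rep,
                    "factor_id": nm,
                    "pip": float(res.pips[i]),
                    "label": truth.labels.get(nm, "Null"),
                    "r2_with_causal": truth.r2_with_causal.get(nm, np.nan),
                    "p_value": pvals.get(nm, np.nan),
                    "all_causal_genomewide": all_gw,
                }
            )
    return pd.DataFrame(rows)


def evaluate_pips(
    results: Sequence[FineMapResult],
    truths: Sequence[TruthRecord],
    fbat_tables: Sequence[pd.DataFrame],
    alpha_gw: float = GENOME_WIDE_ALPHA,
    n_bins: int = 10,
) -> EvaluationReport:
    """Stratified PIP summaries, calibration table and PR curve."""
    table = pip_long_table(results, truths, fbat_tables, alpha_gw)

    strata = (
        table.groupby(["all_causal_genomewide", "label"])["pip"]
        .agg(["count", "mean", "median", lambda s: float(np.quantile(s, 0.9))])
        .rename(columns={"<lambda_0>": "q90"})
        .reset_index()
    )

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    cal_rows = []
    which = np.clip(np.digitize(table["pip"], edges[1:-1]), 0, n_bins - 1)
    for b in range(n_bins):
        sub = table[which == b]
        n = len(sub)
        k = int((sub["label"] == "Signal").sum())
        lo, hi = _clopper_pearson(k, n)
        cal_rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n_factors": n,
                "mean_pip": float(sub["pip"].mean()) if n else np.nan,
                "causal_fraction": k / n if n else np.nan,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    calibration = pd.DataFrame(cal_rows)

    y_true = (table["label"] == "Signal").to_numpy(int)
    y_score = table["pip"].to_numpy(float)
    if y_true.sum() == 0:
        precision = recall = thresholds = None
        ap = None
    else:
        from sklearn.metrics import average_precision_score, precision_recall_curve

        precision, recall, thresholds = precision_recall_curve(y_true, y_score)
        ap = float(average_precision_score(y_true, y_score))

    return EvaluationReport(
        pip_table=table,
        strata_summary=strata,
        calibration=calibration,
        precision=precision,
        recall=recall,
        pr_thresholds=thresholds,
        average_precision=ap,
    )


def calibration_max_deviation(
    report: EvaluationReport, min_bin_count: int = 50
) -> float:
    """Largest |bin-mean PIP - empirical causal fraction| over occupied bins."""
    cal = report.calibration
    occ = cal[cal["n_factors"] >= min_bin_count]
    if occ.empty:
        return 0.0
    return float((occ["mean_pip"] - occ["causal_fraction"]).abs().max())


def plot_report(report: EvaluationReport, outdir: str | Path) -> list[Path]:
    """Calibration, precision-recall and PIP-by-stratum panels as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    cal = report.calibration.dropna(subset=["mean_pip"])
    ax.errorbar(
        cal["mean_pip"],
        cal["causal_fraction"],
        yerr=[
            cal["causal_fraction"] - cal["ci_low"],
            cal["ci_high"] - cal["causal_fraction"],
        ],
        fmt="o",
    )
    ax.plot([0, 1], [0, 1], "--", color="grey")
    ax.set_xlabel("mean PIP in bin")
    ax.set_ylabel("empirical causal fraction")
    ax.set_title("PIP calibration")
    path = outdir / "calibration.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)

    if report.precision is not None:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(report.recall, report.precision)
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_title(f"PR curve (AP = {report.average_precision:.3f})")
        path = outdir / "precision_recall.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    fig, ax = plt.subplots(figsize=(6.0, 4.5))
    table = report.pip_table
    groups, labels = [], []
    for gw in (True, False):
        for lab in ("Signal", "Proxy", "Null"):
            sub = table[
                (table["all_causal_genomewide"] == gw) & (table["label"] == lab)
            ]["pip"]
            if len(sub):
                groups.append(sub.to_numpy())
                labels.append(f"{lab}\n{'GW' if gw else 'non-GW'}")
    if groups:
        ax.boxplot(groups, tick_labels=labels)
        ax.set_ylabel("PIP")
        ax.set_title("PIP by factor class and significance stratum")
    path = outdir / "pip_by_stratum.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(path)
    return written
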