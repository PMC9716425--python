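"""Validation layer: OLS goodness of fit and Bland-Altman agreement.

Regression (unweighted OLS, free intercept) summarises how tightly
volume-path nutrient intake tracks the weighed-mass path; Bland-Altman
describes agreement through the bias mu = mean(A - B) and the limits of
agreement mu +- 1.96 * SD of the paired differences (sample SD, n-1).
Note on notation: some reports write sigma for the bias; here mu is always
the bias and sigma_d the SD of differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

LOA_MULTIPLIER = 1.96  # normal 95% limits of agreement


@dataclass(frozen=True)
class FitResult:
    slope: float
    intercept: float
    r2: float
    rmse: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    bias: float  # mu = mean(a - b)
    sd: float  # sigma_d, SD of differences (ddof=1)
    loa_lower: float
    loa_upper: float
    n: int

    @property
    def zero_within_loa(self) -> bool:
        return self.loa_lower <= 0.0 <= self.loa_upper


def linear_fit(x, y) -> FitResult:
    """Ordinary least squares of y on x with free intercept.

    r^2 = 1 - SS_res/SS_tot; RMSE over residuals (no dof correction).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    resid = y - res.fittedvalues
    return FitResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        n=len(x),
    )


def bland_altman(a, b) -> AgreementResult:
    """Agreement of paired measurements: d = a - b, mu = mean(d),
    limits mu +- 1.96 * sd(d)."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mu = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=mu, sd=sd,
                           loa_lower=mu - LOA_MULTIPLIER * sd,
                           loa_upper=mu + LOA_MULTIPLIER * sd,
                           n=len(a))


def agreement_plot(a, b, result: AgreementResult, path, title=""):
    """Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = (np.asarray(a, float) + np.asarray(b, float)) / 2.0
    diff = np.asarray(a, float) - np.asarray(b, float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(mean, diff, s=10, alpha=0.6)
    for yv, style in ((result.bias, "-"), (result.loa_lower, "--"),
                      (result.loa_upper, "--")):
        ax.axhline(yv, color="k", linestyle=style, linewidth=0.8)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A - B)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def regression_plot(x, y, fit: FitResult, path, title=""):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=10, alpha=0.6)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-", linewidth=0.8)
    ax.set_xlabel("mass-path intake")
    ax.set_ylabel("volume-path intake")
    ax.set_title(f"{title}  r2={fit.r2:.3f} RMSE={fit.rmse:.3g}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(out_dir, segmentation=None, classification=None,
                 intake_metrics=None, nutrient_results=None, n=None, seed=None,
                 plots=False, nutrient_pairs=None):
    """Assemble CSV tables + a JSON summary (+ optional figures).

    nutrient_results: dict nutrient -> (FitResult, AgreementResult);
    nutrient_pairs (optional, for plots): nutrient -> (volume_path, mass_path).
    Deterministic: same inputs produce byte-identical tables.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"n": n, "seed": seed}

    if segmentation is not None:
        pd.DataFrame(segmentation).to_csv(out_dir / "segmentation.csv", index=False)
        summary["segmentation"] = {
            "mean_iou": float(np.mean([r["iou"] for r in segmentation]))}
    if classification is not None:
        pd.DataFrame(classification).to_csv(out_dir / "classification.csv", index=False)
        summary["classification"] = {
            "mean_top1_pct": float(np.mean([r["top1_pct"] for r in classification]))}
    if intake_metrics is not None:
        rows = [{"metric": k, "mean": v[0], "sd": v[1]}
                for k, v in intake_metrics.items() if isinstance(v, tuple)]
        pd.DataFrame(rows).to_csv(out_dir / "intake_metrics.csv", index=False)
        summary["intake"] = {k: v for k, v in intake_metrics.items()}
    if nutrient_results:
        rows = []
        for nut, (fit, agr) in nutrient_results.items():
            rows.append({
                "nutrient": nut, "slope": fit.slope, "intercept": fit.intercept,
                "r2": fit.r2, "rmse": fit.rmse, "bias": agr.bias, "sd_diff": agr.sd,
                "loa_lower": agr.loa_lower, "loa_upper": agr.loa_upper,
                "zero_within_loa": agr.zero_within_loa, "n": fit.n,
            })
        pd.DataFrame(rows).to_csv(out_dir / "nutrient_agreement.csv", index=False)
        summary["nutrients"] = {
            "min_r2": float(min(r["r2"] for r in rows)),
            "max_abs_bias": float(max(abs(r["bias"]) for r in rows)),
            "all_zero_within_loa": bool(all(r["zero_within_loa"] for r in rows)),
        }
        if plots and nutrient_pairs:
            fig_dir = out_dir / "figures"
            fig_dir.mkdir(exist_ok=True)
            for nut, (vol, mass) in nutrient_pairs.items():
                fit, agr = nutrient_results[nut]
                regression_plot(mass, vol, fit, fig_dir / f"{nut}_fit.png", nut)
                agreement_plot(vol, mass, agr, fig_dir / f"{nut}_agreement.png", nut)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
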