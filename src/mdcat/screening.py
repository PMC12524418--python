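"""Clinical output layer: warnings, risk continua and criterion validity.

A domain triggers a warning when its estimated trait strictly exceeds 0,
the midpoint of the standard-normal latent metric (i.e. the respondent
falls in the upper half of the reference distribution).  The continuum
position is the normal CDF of theta-hat, giving a 0-1 coordinate for a
green-to-red risk display.  Criterion validity against a binary gold
standard uses the tie-corrected rank (Mann-Whitney) AUC and the 2x2 table
at a stated threshold (predicted positive = score > threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .bank import FACTOR_NAMES
from .scoring import LatentState

WARNING_THRESHOLD = 0.0


def is_positive(score: float, threshold: float = WARNING_THRESHOLD) -> bool:
    """The single shared predicted-positive predicate: strict ``>``."""
    return score > threshold


@dataclass
class ScreeningResult:
    """Per-domain estimates with warning flags and continuum positions."""

    theta: np.ndarray
    se: np.ndarray
    warnings: tuple[bool, bool, bool, bool]
    continuum: np.ndarray  # Phi(theta), in [0, 1]
    factor_names: tuple[str, ...] = FACTOR_NAMES

    def to_dict(self) -> dict:
        return {
            "domains": [
                {
                    "factor": name,
                    "theta": float(self.theta[f]),
                    "se": float(self.se[f]),
                    "warning": bool(self.warnings[f]),
                    "continuum": float(self.continuum[f]),
                }
                for f, name in enumerate(self.factor_names)
            ]
        }


def classify_domains(state: LatentState) -> ScreeningResult:
    """Screen the four domains of a final latent state."""
    theta = np.asarray(state.theta, dtype=float)
    return ScreeningResult(
        theta=theta,
        se=np.asarray(state.se, dtype=float),
        warnings=tuple(is_positive(t) for t in theta),
        continuum=norm.cdf(theta),
    )


@dataclass
class ValidityReport:
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "threshold": self.threshold,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


class SingleClassError(ValueError):
    """AUC undefined (labels contain one class); ``report`` has the 2x2 table."""

    def __init__(self, message: str, report: ValidityReport):
        super().__init__(message)
        self.report = report


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def criterion_validity(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = WARNING_THRESHOLD,
) -> ValidityReport:
    """Discrimination of continuous scores against a binary gold standard.

    AUC is the pairwise concordance probability with half-credit for ties
    (the Mann-Whitney construction); sensitivity, specificity, PPV and NPV
    come from the 2x2 table at ``threshold`` with predicted positive =
    score > threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if len(s) < 2:
        raise ValueError("need at least 2 observations")
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")

    pred = s > threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    n1, n0 = tp + fn, fp + tn

    table_kwargs = dict(
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        ppv=_safe_div(tp, tp + fp),
        npv=_safe_div(tn, tn + fn),
        threshold=float(threshold),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
    if n1 == 0 or n0 == 0:
        report = ValidityReport(auc=float("nan"), **table_kwargs)
        raise SingleClassError("AUC undefined: labels contain a single class", report)

    ranks = rankdata(s)  # midranks give the tie-corrected construction
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return ValidityReport(auc=float(auc), **table_kwargs)


def render_report(
    result: ScreeningResult, path: str | Path, plot: bool = True
) -> dict[str, Path]:
    """Write the screening report as JSON (and a continuum plot alongside).

    ``path`` is the JSON target; the figure, when requested, lands next to
    it with a ``.png`` suffix.  Returns the written paths.
    """
    path = Path(path)
    path.write_text(json.dumps(result.to_dict(), indent=2) + "\n")
    written = {"json": path}
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(len(result.factor_names), 1, figsize=(6, 4.5), sharex=True)
        grad = np.linspace(0, 1, 256)[None, :]
        for f, ax in enumerate(axes):
            ax.imshow(
                grad, aspect="auto", cmap="RdYlGn_r", extent=(0, 1, 0, 1), origin="lower"
            )
            ax.axvline(result.continuum[f], color="black", lw=2)
            flag = "  ⚠" if result.warnings[f] else ""
            ax.set_ylabel(result.factor_names[f][:5], rotation=0, ha="right", va="center")
            ax.set_yticks([])
            ax.set_title(
                f"{result.factor_names[f]}: θ={result.theta[f]:+.2f} "
                f"(SE {result.se[f]:.2f}){flag}",
                fontsize=9,
                loc="left",
            )
        axes[-1].set_xlabel("continuum position Φ(θ)")
        fig.tight_layout()
        png = path.with_suffix(".png")
        fig.savefig(png, dpi=120)
        plt.close(fig)
        written["plot"] = png
    return written


def render_text(result: ScreeningResult, width: int = 40) -> str:
    """Plain-text rendering of the four continua (for terminal display)."""
    lines = []
    for f, name in enumerate(result.factor_names):
        pos = int(round(result.continuum[f] * (width - 1)))
        bar = "".join("|" if i == pos else "-" for i in range(width))
        flag = " WARNING" if result.warnings[f] else ""
        lines.append(
            f"{name:>15} [{bar}] θ={result.theta[f]:+.2f} SE={result.se[f]:.2f}{flag}"
        )
    return "\n".join(lines)
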