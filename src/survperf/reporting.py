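"""Report and plot emission: TSV tables with provenance headers, rank plots.

Every table written by the CLI carries ``#``-prefixed header lines with the
tool version, the seed and a digest of the run configuration, so any output
file is reconstructible from its header alone.  Plots are optional artifacts;
every plotted quantity is first written as TSV so nothing downstream ever
parses an image.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .metrics import MetricReport, RocCurve, ThresholdScan
from .models import RiskScores

__all__ = [
    "config_digest",
    "header_lines",
    "write_table",
    "metric_table",
    "scan_table",
    "roc_table",
    "render_rank_plot",
    "rank_quadrants",
]


def config_digest(config: dict) -> str:
    """Stable short digest of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def header_lines(config: dict, seed: int | None = None) -> list[str]:
    lines = [f"survperf {__version__}", f"config_digest={config_digest(config)}",
             f"config={json.dumps(config, sort_keys=True, default=str)}"]
    if seed is not None:
        lines.insert(1, f"seed={seed}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path, config: dict, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines(config, seed):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def metric_table(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """One row per model, mirroring the standard hazard-ratio table layout."""
    return pd.DataFrame([r.to_row() for r in reports])


def scan_table(scan: ThresholdScan) -> pd.DataFrame:
    return pd.DataFrame({
        "n_low": scan.n_low, "n_high": scan.n_high, "logrank_p": scan.pvalues,
        "tied_cutoff": scan.tied_cutoff.astype(int), "degenerate": scan.degenerate.astype(int),
    })


def roc_table(curve: RocCurve) -> pd.DataFrame:
    return pd.DataFrame({
        "cutoff": curve.cutoffs,
        "sensitivity": curve.sensitivity,
        "specificity": curve.specificity,
    })


def rank_quadrants(scores: RiskScores | np.ndarray, times: np.ndarray,
                   t_marker: float, median_marker: float) -> dict:
    """Misclassification quadrants of the rank-vs-time display.

    High-risk side = score above the training median.  ``upper_left`` counts
    subjects called high risk who survived past the time marker;
    ``lower_right`` counts subjects called low risk with short survival.
    """
    s = scores.values if isinstance(scores, RiskScores) else np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    high = s > median_marker
    return {
        "upper_left": int(np.sum(high & (t > t_marker))),
        "lower_right": int(np.sum(~high & (t <= t_marker))),
        "n_high": int(high.sum()),
        "n_low": int((~high).sum()),
    }


def render_rank_plot(scores: RiskScores | np.ndarray, times: np.ndarray, events: np.ndarray,
                     t_marker: float, median_marker: float, path: str | Path,
                     sidecar_path: str | Path | None = None) -> dict:
    """Survival time versus risk-score rank, with threshold markers.

    Rank 1 is the highest estimated risk.  The vertical line sits at the
    boundary between scores above and below the training median; the
    horizontal line marks the survival threshold.  Returns (and optionally
    writes as TSV) the quadrant counts, the numbers a reader checks against
    the scatter.
    """
    s = scores.values if isinstance(scores, RiskScores) else np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(-s, kind="stable")  # rank 1 = highest risk
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, s.size + 1)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ranks[e == 1], t[e == 1], marker="o", color="tab:red", label="event")
    ax.scatter(ranks[e == 0], t[e == 0], marker="^", color="tab:blue", label="censored")
    n_high = int(np.sum(s > median_marker))
    ax.axvline(n_high + 0.5, color="grey", linestyle="--",
               label="training-median boundary")
    ax.axhline(t_marker, color="black", linestyle=":", label=f"t = {t_marker:g}")
    ax.set_xlabel("rank of estimated risk score (1 = highest risk)")
    ax.set_ylabel("survival time")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)

    counts = rank_quadrants(s, t, t_marker, median_marker)
    if sidecar_path is not None:
        pd.DataFrame([counts]).to_csv(sidecar_path, sep="\t", index=False)
    return counts
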