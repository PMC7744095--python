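"""Summary outputs: time-windowed FRET histograms and condition plots.

Histograms follow the comparability convention of the assay: every
dataset (condition x 15-min window) is binned on identical edges, with
the bin count set to floor(sqrt(N)) of the *smallest* dataset, and
counts normalized to fractions so datasets of different size are
directly comparable bin by bin.  The condition summary reproduces the
notBoxPlot-style display: replicate points, mean line, and a 95%
confidence-interval band centered on the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fretcore import E_SANITY_BOUNDS, t_interval
from .types import ParameterError, RateEstimate

__all__ = ["HistogramSet", "build_histograms", "summarize_conditions", "plot_condition_summary"]

log = logging.getLogger(__name__)


@dataclass
class HistogramSet:
    """Normalized histograms of several datasets on shared bin edges."""

    edges: np.ndarray
    fractions: dict[str, np.ndarray]  # per dataset, sums to 1
    n: dict[str, int]

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mode_center(self, label: str) -> float:
        """Center of the most populated bin of one dataset."""
        return float(self.centers[int(np.argmax(self.fractions[label]))])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, frac in self.fractions.items():
            for c, lo, hi, f in zip(self.centers, self.edges[:-1], self.edges[1:], frac):
                rows.append(
                    {"dataset": label, "bin_center": c, "bin_lo": lo, "bin_hi": hi,
                     "fraction": f, "n": self.n[label]}
                )
        return pd.DataFrame(rows)


def build_histograms(
    samples: Mapping[str, np.ndarray],
    n_bins: Optional[int] = None,
    hist_range: Optional[tuple[float, float]] = None,
) -> HistogramSet:
    """Bin FRET samples from several datasets on shared edges.

    ``n_bins`` defaults to floor(sqrt(N_min)) where N_min is the size
    of the smallest non-empty dataset; ``hist_range`` defaults to the
    min/max over all pooled samples, clipped to the FRET sanity bounds.
    Empty datasets are omitted with a logged warning.
    """
    clean: dict[str, np.ndarray] = {}
    for label, x in samples.items():
        x = np.asarray(x, float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            log.warning("histogram dataset %r is empty; omitted", label)
            continue
        clean[label] = x
    if not clean:
        raise ParameterError("no non-empty datasets to histogram")

    if n_bins is None:
        n_bins = max(1, math.floor(math.sqrt(min(x.size for x in clean.values()))))
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    if hist_range is None:
        pooled = np.concatenate(list(clean.values()))
        pooled = np.clip(pooled, *E_SANITY_BOUNDS)
        lo, hi = float(pooled.min()), float(pooled.max())
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        hist_range = (lo, hi)

    edges = np.linspace(hist_range[0], hist_range[1], n_bins + 1)
    fractions, ns = {}, {}
    for label, x in clean.items():
        counts, _ = np.histogram(np.clip(x, *hist_range), bins=edges)
        fractions[label] = counts / x.size
        ns[label] = int(x.size)
    return HistogramSet(edges=edges, fractions=fractions, n=ns)


def summarize_conditions(
    conditions: Union[Sequence[RateEstimate], Mapping[str, Sequence[float]]],
) -> pd.DataFrame:
    """Tidy per-condition summary: replicate values, mean, 95% t CI.

    Accepts either rate estimates (replicate rates are used) or a
    mapping of condition label to replicate values.  Single-replicate
    conditions get a mean but no interval (with a warning).
    """
    if isinstance(conditions, Mapping):
        items = [(label, list(v)) for label, v in conditions.items()]
    else:
        items = [(est.condition, est.replicate_rates) for est in conditions]
    if not items:
        raise ParameterError("no conditions to summarize")

    rows = []
    for label, values in items:
        if len(values) == 0:
            log.warning("condition %r has no replicates; omitted", label)
            continue
        ci = t_interval(values)
        if ci is None:
            log.warning("condition %r has a single replicate; CI omitted", label)
        rows.append(
            {
                "condition": label,
                "n_replicates": len(values),
                "replicates": values,
                "mean": float(np.mean(values)),
                "ci95_lo": ci[0] if ci else np.nan,
                "ci95_hi": ci[1] if ci else np.nan,
            }
        )
    return pd.DataFrame(rows)


def plot_condition_summary(summary: pd.DataFrame, path: Optional[str] = None):
    """notBoxPlot-style figure: gray replicate circles, dark red mean
    line, light red 95% CI rectangle centered on the mean."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(summary), 3.6))
    half_w = 0.28
    for i, row in summary.reset_index(drop=True).iterrows():
        if np.isfinite(row["ci95_lo"]):
            ax.add_patch(
                plt.Rectangle(
                    (i - half_w, row["ci95_lo"]),
                    2 * half_w,
                    row["ci95_hi"] - row["ci95_lo"],
                    facecolor="#f4b6b6",
                    edgecolor="none",
                    zorder=1,
                )
            )
        ax.hlines(row["mean"], i - half_w, i + half_w, color="#8b0000", lw=2, zorder=3)
        jitter = np.linspace(-0.12, 0.12, len(row["replicates"]))
        ax.plot(i + jitter, row["replicates"], "o", mfc="0.6", mec="0.4", zorder=2)
    ax.set_xticks(range(len(summary)))
    ax.set_xticklabels(summary["condition"], rotation=30, ha="right")
    ax.set_ylabel("SR formation rate (s$^{-1}$)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
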