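"""FRET efficiency, SR-event calling, and formation-rate estimation.

The central statistic of the pipeline is the short-range (SR) synaptic
complex formation rate: the number of observed formation events divided
by the total time during which formation was possible — time with both
dyes photoactive and the molecule not already synapsed or ligated,
summed over all tracked molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    FretTrace,
    ParameterError,
    RateEstimate,
    SREvent,
    SREventSet,
    Trajectory,
)

__all__ = [
    "compute_fret",
    "detect_sr_events",
    "observable_time",
    "estimate_rate",
    "fold_change",
    "FoldChange",
    "t_interval",
    "poisson_rate_ci",
    "E_SANITY_BOUNDS",
]

E_SANITY_BOUNDS = (-0.2, 1.2)


def compute_fret(
    trace: Trajectory,
    bg_donor: float = 0.0,
    bg_acceptor: float = 0.0,
    replicate: Optional[int] = None,
    acceptor_present_frac: float = 0.3,
) -> FretTrace:
    """Apparent FRET efficiency on donor-excitation frames.

    E = (I_A - bg_A) / ((I_A - bg_A) + (I_D - bg_D)), uncorrected
    (gamma = 1).  Frames with a non-positive denominator are masked.
    The acceptor-present mask comes from the direct-excitation frames
    (signal above ``acceptor_present_frac`` of the initial direct
    level) held forward to the interleaved donor frames.
    """
    donor_exc = trace.donor_excitation()
    idx_d = np.flatnonzero(donor_exc)
    if idx_d.size == 0:
        raise ParameterError(f"{trace.molecule_id}: no donor-excitation frames")
    i_d = trace.donor[idx_d] - bg_donor
    i_a = trace.acceptor[idx_d] - bg_acceptor
    denom = i_d + i_a
    valid = denom > 0
    eff = np.full(idx_d.size, np.nan)
    np.divide(i_a, denom, out=eff, where=valid)

    idx_a = np.flatnonzero(~donor_exc)
    if idx_a.size:
        direct = trace.acceptor[idx_a] - bg_acceptor
        level = float(np.median(direct[: min(5, direct.size)]))
        thr = acceptor_present_frac * max(level, 0.0)
        present_direct = direct > thr if level > 0 else np.zeros(idx_a.size, bool)
        # Hold the most recent direct-excitation reading forward.
        pos = np.searchsorted(idx_a, idx_d, side="right") - 1
        present = present_direct[np.clip(pos, 0, idx_a.size - 1)]
    else:
        present = np.ones(idx_d.size, bool)

    nd, na = trace.cycle
    quantum = trace.frame_period * (nd + na) / nd
    out_of_range = bool(
        np.any((eff[valid] < E_SANITY_BOUNDS[0]) | (eff[valid] > E_SANITY_BOUNDS[1]))
    )
    return FretTrace(
        molecule_id=trace.molecule_id,
        times=trace.time_s[idx_d].astype(float),
        efficiency=eff,
        acceptor_present=present,
        valid=valid,
        time_quantum_s=quantum,
        truncation_time_s=float(trace.n_frames) * trace.frame_period,
        replicate=trace.replicate if replicate is None else replicate,
        out_of_range=out_of_range,
    )


def detect_sr_events(
    ft: FretTrace, threshold: float = 0.25, min_frames: int = 5
) -> SREventSet:
    """Call SR formation events: maximal runs of at least ``min_frames``
    consecutive donor-excitation frames with E above ``threshold``.

    The event starts at the first frame of the qualifying run and ends
    at the first subsequent frame at or below threshold; a run that
    reaches the truncation point is censored and scored as ligated
    (the high-FRET state persisted to the end of the observation).  A
    run already in progress at the first analyzed frame is flagged
    ``preformed`` — the formation transition was not observed — and is
    excluded from the formation-event count.
    """
    if min_frames < 1:
        raise ParameterError("min_frames must be >= 1")
    if not (E_SANITY_BOUNDS[0] < threshold < E_SANITY_BOUNDS[1]):
        raise ParameterError(f"threshold outside sanity bounds {E_SANITY_BOUNDS}")
    hi = ft.valid & (ft.efficiency > threshold)
    events: list[SREvent] = []
    spans: list[tuple[int, int]] = []
    n = hi.size
    if n:
        padded = np.concatenate(([False], hi, [False])).astype(np.int8)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for a, b in zip(starts, ends):
            if b - a < min_frames:
                continue
            censored = b == n
            end_s = ft.truncation_time_s if censored else float(ft.times[b])
            events.append(
                SREvent(
                    molecule_id=ft.molecule_id,
                    start_s=float(ft.times[a]),
                    end_s=end_s,
                    censored=censored,
                    ligated=censored,
                    preformed=(a == 0),
                )
            )
            spans.append((int(a), int(b)))
    return SREventSet(
        molecule_id=ft.molecule_id,
        events=events,
        threshold=threshold,
        min_frames=min_frames,
        spans=spans,
    )


def observable_time(
    ft: FretTrace, events: SREventSet, mode: str = "exclude_events"
) -> float:
    """Total time (s) during which SR formation was possible.

    A donor-excitation frame qualifies when the acceptor is present and
    (in the default mode) the molecule is not inside a detected SR
    event — ends already synapsed or joined cannot form.  Each donor
    frame contributes its share of the excitation cycle
    (``frame_period x cycle_length / donor_frames_per_cycle``), so the
    qualifying frame count converts to wall-clock at-risk time.
    ``mode='total'`` keeps in-event time in the denominator (sensitivity
    switch).
    """
    if mode not in ("exclude_events", "total"):
        raise ParameterError(f"unknown denominator mode {mode!r}")
    at_risk = ft.acceptor_present.copy()
    if mode == "exclude_events":
        for a, b in events.spans:
            at_risk[a:b] = False
    return float(np.count_nonzero(at_risk)) * ft.time_quantum_s


def t_interval(values: Sequence[float], level: float = 0.95) -> Optional[tuple[float, float]]:
    """Mean +/- t_{(1+level)/2, n-1} * SD/sqrt(n); None for n < 2."""
    v = np.asarray(values, float)
    if v.size < 2:
        return None
    m = float(np.mean(v))
    half = float(stats.t.ppf(0.5 + level / 2, v.size - 1) * np.std(v, ddof=1) / np.sqrt(v.size))
    return (m - half, m + half)


def poisson_rate_ci(n_events: int, t_s: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson interval for a rate of ``n_events`` in
    ``t_s`` seconds.  Zero events: (0, -ln((1-level)/2)/T)."""
    if t_s <= 0:
        raise ParameterError("t_s must be > 0")
    alpha = 1.0 - level
    lo = 0.0 if n_events == 0 else stats.chi2.ppf(alpha / 2, 2 * n_events) / 2 / t_s
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (n_events + 1)) / 2 / t_s
    return (float(lo), float(hi))


@dataclass(frozen=True)
class MoleculeRecord:
    """Per-molecule event count and at-risk time with replicate label."""

    molecule_id: str
    replicate: int
    n_events: int
    t_observable_s: float


def estimate_rate(
    records: Iterable[MoleculeRecord], condition: str = ""
) -> RateEstimate:
    """Pooled SR formation rate with replicate-based 95% CI.

    Pooled rate = (sum of events) / (sum of at-risk time).  Replicate
    rates are computed the same way within each replicate; a replicate
    with zero events contributes rate 0 (it is not dropped).  The 95%
    CI is the t interval over replicate rates (absent with < 2
    replicates); an exact Poisson interval on the pooled count is also
    reported.
    """
    records = list(records)
    total_t = sum(r.t_observable_s for r in records)
    if total_t <= 0:
        raise ParameterError("total observable time must be > 0")
    total_n = sum(r.n_events for r in records)

    rep_stats: list[tuple[int, float, float]] = []
    for rep in sorted({r.replicate for r in records}):
        sub = [r for r in records if r.replicate == rep]
        n = sum(r.n_events for r in sub)
        t = sum(r.t_observable_s for r in sub)
        rep_stats.append((n, t, n / t if t > 0 else 0.0))

    ci = t_interval([r for _, _, r in rep_stats]) if len(rep_stats) >= 2 else None
    return RateEstimate(
        condition=condition,
        n_events=total_n,
        t_observable_s=total_t,
        rate_per_s=total_n / total_t,
        replicate_stats=rep_stats,
        ci95=ci,
        poisson_ci95=poisson_rate_ci(total_n, total_t),
        n_molecules=len(records),
    )


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two formation rates (a over b)."""

    ratio: float
    lower_bound95: float  # conservative Poisson bound a_low / b_high

    def __float__(self) -> float:
        return self.ratio


def fold_change(a: RateEstimate, b: RateEstimate) -> FoldChange:
    """Rate ratio a/b.  If b has zero events the ratio is infinite and
    the Poisson lower bound (a's lower limit over b's upper limit)
    quantifies how large the fold difference must at least be."""
    lower = a.poisson_ci95[0] / b.poisson_ci95[1] if b.poisson_ci95[1] > 0 else math.inf
    if b.rate_per_s == 0:
        return FoldChange(ratio=math.inf, lower_bound95=lower)
    return FoldChange(ratio=a.rate_per_s / b.rate_per_s, lower_bound95=lower)
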