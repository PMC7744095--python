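"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from synapsefret import AcquisitionConfig, KineticModel, Trajectory
from synapsefret.types import FretTrace


@pytest.fixture
def model():
    return KineticModel()


@pytest.fixture
def acq_small():
    return AcquisitionConfig(
        n_replicates=1, n_fovs_per_replicate=1, n_molecules_per_fov=10, seed=42
    )


def make_fret_trace(
    efficiencies,
    frame_period: float = 2.0,
    cycle=(4, 1),
    truncation_time_s: float | None = None,
    acceptor_present=None,
    molecule_id: str = "m0",
) -> FretTrace:
    """FretTrace from an explicit per-donor-frame efficiency sequence.

    Times follow the alternating-excitation layout: donor frames are
    the non-direct frames of a (4, 1) cycle at the given frame period.
    """
    e = np.asarray(efficiencies, float)
    nd, na = cycle
    n_needed = e.size
    frame_idx = []
    f = 0
    while len(frame_idx) < n_needed:
        if (f % (nd + na)) < nd:
            frame_idx.append(f)
        f += 1
    times = np.asarray(frame_idx, float) * frame_period
    if truncation_time_s is None:
        truncation_time_s = float(f * frame_period)
    present = (
        np.ones(e.size, bool)
        if acceptor_present is None
        else np.asarray(acceptor_present, bool)
    )
    return FretTrace(
        molecule_id=molecule_id,
        times=times,
        efficiency=e,
        acceptor_present=present,
        valid=np.isfinite(e),
        time_quantum_s=frame_period * (nd + na) / nd,
        truncation_time_s=truncation_time_s,
    )


def brute_force_event_spans(hi: np.ndarray, m: int) -> list[tuple[int, int]]:
    """Window-scan oracle for event calling.

    Marks every frame covered by *any* all-above-threshold window of
    length ``m``; maximal runs of covered frames are the events.  This
    is deliberately a different construction from the run-length
    detector it checks.
    """
    hi = np.asarray(hi, bool)
    n = hi.size
    covered = np.zeros(n, bool)
    for i in range(n - m + 1):
        if hi[i : i + m].all():
            covered[i : i + m] = True
    # extend each covered block through the remaining True frames
    spans = []
    i = 0
    while i < n:
        if covered[i]:
            j = i
            while j < n and hi[j]:
                j += 1
            spans.append((i, j))
            i = j
        else:
            i += 1
    return spans


def make_trajectory(
    donor,
    acceptor,
    cycle=(4, 1),
    frame_period: float = 2.0,
    molecule: int = 0,
) -> Trajectory:
    donor = np.asarray(donor, float)
    n = donor.size
    nd, na = cycle
    unit = np.array(["D"] * nd + ["A"] * na)
    exc = np.tile(unit, int(np.ceil(n / unit.size)))[:n]
    return Trajectory(
        replicate=0,
        fov=0,
        molecule=molecule,
        frame=np.arange(n),
        time_s=np.arange(n) * frame_period,
        excitation=exc,
        donor=donor,
        acceptor=np.asarray(acceptor, float),
        frame_period=frame_period,
        cycle=cycle,
    )
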