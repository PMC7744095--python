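"""Trajectory-table, ground-truth and result file formats.

The trajectory table is a plain CSV/TSV with one row per molecule per
frame and columns (replicate, fov, molecule, frame, time_s, excitation,
I_donor, I_acceptor) plus an optional window_start_s; this is both what
the simulator writes and what the analysis reads, so simulated and real
recordings flow through identical code.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Union

import numpy as np
import pandas as pd

from .types import GroundTruth, RateEstimate, SchemaError, State, StatePath, Trajectory

__all__ = [
    "trajectories_to_frame",
    "frame_to_trajectories",
    "write_trajectories",
    "read_trajectories",
    "write_ground_truth",
    "read_ground_truth",
    "rate_estimate_to_dict",
    "write_rate_estimates",
]

REQUIRED_COLUMNS = [
    "replicate", "fov", "molecule", "frame", "time_s", "excitation",
    "I_donor", "I_acceptor",
]


def trajectories_to_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    parts = []
    for t in trajectories:
        parts.append(
            pd.DataFrame(
                {
                    "replicate": t.replicate,
                    "fov": t.fov,
                    "molecule": t.molecule,
                    "frame": t.frame,
                    "time_s": t.time_s,
                    "excitation": t.excitation,
                    "I_donor": t.donor,
                    "I_acceptor": t.acceptor,
                    "window_start_s": t.window_start_s,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=REQUIRED_COLUMNS + ["window_start_s"])
    return pd.concat(parts, ignore_index=True)


def frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Validate a trajectory table and split it into Trajectory objects.

    Row order is normalized to (replicate, fov, molecule, frame); frames
    within a molecule must be consecutive from 0 with one shared frame
    period, and excitation labels must be 'D' or 'A'.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    bad = ~df["excitation"].isin(["D", "A"])
    if bad.any():
        raise SchemaError(f"invalid excitation label at row {int(np.flatnonzero(bad)[0])}")
    df = df.sort_values(["replicate", "fov", "molecule", "frame"], kind="mergesort")

    out: list[Trajectory] = []
    period = None
    for (rep, fov, mol), g in df.groupby(["replicate", "fov", "molecule"], sort=True):
        frames = g["frame"].to_numpy()
        if frames.size == 0:
            continue
        if frames[0] != 0 or np.any(np.diff(frames) != 1):
            raise SchemaError(
                f"non-contiguous frames for molecule r{rep}_f{fov}_m{mol} "
                f"(first offending row index {int(g.index[0])})"
            )
        times = g["time_s"].to_numpy(float)
        if frames.size > 1:
            dts = np.diff(times)
            p = float(np.median(dts))
            if np.any(np.abs(dts - p) > 1e-6):
                raise SchemaError(f"non-uniform frame period for r{rep}_f{fov}_m{mol}")
            if period is None:
                period = p
            elif abs(p - period) > 1e-6:
                raise SchemaError(f"mixed frame periods (molecule r{rep}_f{fov}_m{mol})")
        exc = g["excitation"].to_numpy(str)
        cycle = _infer_cycle(exc)
        out.append(
            Trajectory(
                replicate=int(rep),
                fov=int(fov),
                molecule=int(mol),
                frame=frames.astype(int),
                time_s=times,
                excitation=exc,
                donor=g["I_donor"].to_numpy(float),
                acceptor=g["I_acceptor"].to_numpy(float),
                window_start_s=float(g["window_start_s"].iloc[0])
                if "window_start_s" in g
                else 0.0,
                frame_period=period if period is not None else 2.0,
                cycle=cycle,
            )
        )
    return out


def _infer_cycle(exc: np.ndarray) -> tuple[int, int]:
    """Infer (n_donor, n_acceptor) per cycle from the label pattern."""
    a_pos = np.flatnonzero(exc == "A")
    if a_pos.size < 2:
        return (max(int((exc == "D").sum()), 1), 1)
    gaps = np.diff(a_pos)
    period = int(np.min(gaps))
    return (period - 1 if period > 1 else 1, 1)


def write_trajectories(path: Union[str, Path], trajectories: Iterable[Trajectory]) -> Path:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    trajectories_to_frame(trajectories).to_csv(path, sep=sep, index=False)
    return path


def read_trajectories(path: Union[str, Path]) -> list[Trajectory]:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    return frame_to_trajectories(df)


def write_ground_truth(path: Union[str, Path], truth: GroundTruth) -> Path:
    payload = {
        "paths": {
            mid: {
                "transitions": [[t, s.name] for t, s in p.transitions],
                "bleach_time_donor": p.bleach_time_donor,
                "bleach_time_acceptor": p.bleach_time_acceptor,
            }
            for mid, p in truth.paths.items()
        },
        "event_times": truth.event_times,
        "ligated": truth.ligated,
        "spot_xy": {k: list(v) for k, v in truth.spot_xy.items()},
        "crowded": sorted(truth.crowded),
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth(path: Union[str, Path]) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    paths = {
        mid: StatePath(
            molecule_id=mid,
            transitions=[(float(t), State[s]) for t, s in rec["transitions"]],
            bleach_time_donor=rec["bleach_time_donor"],
            bleach_time_acceptor=rec["bleach_time_acceptor"],
        )
        for mid, rec in payload["paths"].items()
    }
    return GroundTruth(
        paths=paths,
        event_times=payload["event_times"],
        ligated=payload["ligated"],
        spot_xy={k: tuple(v) for k, v in payload.get("spot_xy", {}).items()},
        crowded=set(payload.get("crowded", [])),
    )


def rate_estimate_to_dict(est: RateEstimate) -> dict:
    return {
        "condition": est.condition,
        "n_events": est.n_events,
        "t_observable_s": est.t_observable_s,
        "rate_per_s": est.rate_per_s,
        "replicates": [
            {"n_events": n, "t_observable_s": t, "rate_per_s": r}
            for n, t, r in est.replicate_stats
        ],
        "ci95": list(est.ci95) if est.ci95 else None,
        "poisson_ci95": list(est.poisson_ci95),
        "n_molecules": est.n_molecules,
    }


def write_rate_estimates(path: Union[str, Path], estimates: Iterable[RateEstimate]) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps([rate_estimate_to_dict(e) for e in estimates], indent=1)
    )
    return path
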