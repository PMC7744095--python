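"""Synthetic smFRET experiment generator.

Ground truth is produced by exact stochastic simulation (Gillespie) of a
two-state synapsis model: a tethered DNA substrate alternates between a
low-FRET state (unpaired ends or the long-range complex) and a
high-FRET short-range (SR) synaptic state, with each formation event
optionally absorbing (ligation).  Intensity trajectories are then
emitted under a 4:1 alternating-excitation cycle with photobleaching
and additive Gaussian noise, matching the schema the analysis stages
consume, so every downstream operation has a known-answer test surface.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .types import (
    AcquisitionConfig,
    GroundTruth,
    KineticModel,
    ParameterError,
    State,
    StatePath,
    Trajectory,
)

__all__ = [
    "simulate_state_path",
    "emit_trajectory",
    "simulate_experiment",
    "render_movie",
]


def simulate_state_path(
    model: KineticModel,
    duration: float,
    rng: np.random.Generator | int,
    molecule_id: str = "m0",
    duty_factor: float = 0.5,
) -> StatePath:
    """Simulate one molecule's synapsis state path for ``duration`` seconds.

    Exact simulation of LOW --k_form--> HIGH and HIGH --k_dissolve--> LOW,
    with each formation flagged absorbing (LIGATED) with probability
    ``p_ligate``.  Dye bleach times are independent exponentials in
    illuminated time; they are converted to wall-clock time with the
    acquisition duty factor (exposure/frame_period), since the dyes only
    accumulate photodamage while the lasers are on.
    """
    if not np.isfinite(duration) or duration <= 0:
        raise ParameterError(f"duration must be positive and finite, got {duration!r}")
    if not 0 < duty_factor <= 1:
        raise ParameterError("duty_factor must be in (0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    transitions: list[tuple[float, State]] = [(0.0, State.LOW)]
    t, state = 0.0, State.LOW
    while True:
        rate = model.k_form if state is State.LOW else model.k_dissolve
        if rate == 0.0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        if state is State.LOW:
            if rng.random() < model.p_ligate:
                transitions.append((t, State.LIGATED))
                break
            state = State.HIGH
        else:
            state = State.LOW
        transitions.append((t, state))

    def _bleach(hazard: float) -> Optional[float]:
        if hazard == 0.0:
            return None
        tb = rng.exponential(1.0 / hazard) / duty_factor
        return tb if tb < duration else None

    return StatePath(
        molecule_id=molecule_id,
        transitions=transitions,
        bleach_time_donor=_bleach(model.h_bleach_donor),
        bleach_time_acceptor=_bleach(model.h_bleach_acceptor),
    )


def _interval_overlap(starts: np.ndarray, ends: np.ndarray, a: float, b: float) -> np.ndarray:
    """Per-frame overlap of windows [starts, ends) with interval [a, b)."""
    return np.clip(np.minimum(ends, b) - np.maximum(starts, a), 0.0, None)


def emit_trajectory(
    path: StatePath,
    model: KineticModel,
    acq: AcquisitionConfig,
    rng: np.random.Generator | int,
    replicate: int = 0,
    fov: int = 0,
    molecule: int = 0,
    window_start_s: float = 0.0,
) -> Trajectory:
    """Render one intensity trajectory from a state path.

    Frame ``i`` opens its exposure at ``window_start_s + i*frame_period``
    (kinetic clock) and is reported at local time ``i*frame_period``.
    Donor-excitation frames split ``I_total`` between the channels
    according to the exposure-averaged FRET efficiency; direct
    acceptor-excitation frames report ``I_direct`` while the acceptor
    survives.  Bleaching is applied with sub-frame resolution: an
    exposure window straddling a bleach or state-change time uses the
    time-weighted mean emission.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = acq.n_frames
    frames = np.arange(n)
    t_local = frames * acq.frame_period
    t0 = window_start_s + t_local  # exposure window start on the kinetic clock
    t1 = t0 + acq.exposure
    exc = acq.excitation_labels(n)

    # Bleach clock starts when illumination starts (= window start).
    tb_d = np.inf if path.bleach_time_donor is None else window_start_s + path.bleach_time_donor
    tb_a = np.inf if path.bleach_time_acceptor is None else window_start_s + path.bleach_time_acceptor

    # Fraction of each exposure with the donor alive.
    f_on = _interval_overlap(t0, t1, -np.inf, tb_d) / acq.exposure
    # Fraction with donor alive, acceptor alive, and molecule high-FRET.
    both_until = min(tb_d, tb_a)
    f_high = np.zeros(n)
    for a, b in path.high_intervals(window_start_s + acq.fov_duration + acq.exposure):
        f_high += _interval_overlap(t0, t1, a, min(b, both_until)) / acq.exposure
    f_high = np.clip(f_high, 0.0, f_on)
    # Fraction with both dyes alive regardless of state.
    f_both = _interval_overlap(t0, t1, -np.inf, both_until) / acq.exposure
    f_low = np.clip(f_both - f_high, 0.0, None)

    mean_E = model.E_high * f_high + model.E_low * f_low  # already weighted by "on"
    donor_sig = model.I_total * (f_on - mean_E)
    acceptor_sig = model.I_total * mean_E

    # Direct acceptor excitation frames.
    f_acc_on = _interval_overlap(t0, t1, -np.inf, tb_a) / acq.exposure
    direct = exc == "A"
    donor = np.where(direct, 0.0, donor_sig) + model.bg_donor
    acceptor = np.where(direct, model.I_direct * f_acc_on, acceptor_sig) + model.bg_acceptor

    if model.noise_sd > 0:
        donor = donor + rng.normal(0.0, model.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, model.noise_sd, n)

    return Trajectory(
        replicate=replicate,
        fov=fov,
        molecule=molecule,
        frame=frames,
        time_s=t_local.astype(float),
        excitation=exc,
        donor=donor,
        acceptor=acceptor,
        window_start_s=window_start_s,
        frame_period=acq.frame_period,
        cycle=acq.cycle,
    )


def simulate_experiment(
    model: KineticModel,
    acq: AcquisitionConfig,
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate a full multi-replicate experiment.

    Each replicate images ``n_fovs_per_replicate`` distinct fields of
    view back to back (FOV k starts at ``k * fov_duration`` on the
    kinetic clock), with ``n_molecules_per_fov`` independent molecules
    per FOV.  Synapsis kinetics run from extract addition (t = 0), so
    molecules in later windows may already be synapsed or ligated when
    their imaging starts — as in the experiment.  Deterministic given
    ``acq.seed``: one master seed spawns an independent stream per
    molecule.
    """
    n_mol = acq.n_replicates * acq.n_fovs_per_replicate * acq.n_molecules_per_fov
    seeds = np.random.SeedSequence(acq.seed).spawn(n_mol)
    trajectories: list[Trajectory] = []
    truth = GroundTruth(paths={}, event_times={}, ligated={})

    i = 0
    for rep in range(acq.n_replicates):
        for fov in range(acq.n_fovs_per_replicate):
            window_start = fov * acq.fov_duration
            for mol in range(acq.n_molecules_per_fov):
                rng = np.random.default_rng(seeds[i])
                i += 1
                mol_id = f"r{rep}_f{fov}_m{mol}"
                path = simulate_state_path(
                    model,
                    duration=window_start + acq.fov_duration + acq.exposure,
                    rng=rng,
                    molecule_id=mol_id,
                    duty_factor=acq.duty_factor,
                )
                traj = emit_trajectory(
                    path, model, acq, rng,
                    replicate=rep, fov=fov, molecule=mol,
                    window_start_s=window_start,
                )
                trajectories.append(traj)
                truth.paths[mol_id] = path
                window_end = window_start + acq.fov_duration
                forms = path.formation_times()
                lig_flags = _ligation_flags(path)
                in_window = [window_start <= t < window_end for t in forms]
                truth.event_times[mol_id] = [t for t, ok in zip(forms, in_window) if ok]
                truth.ligated[mol_id] = [f for f, ok in zip(lig_flags, in_window) if ok]
    return trajectories, truth


def _ligation_flags(path: StatePath) -> list[bool]:
    flags = []
    prev = State.LOW
    for _, s in path.transitions[1:]:
        if prev is State.LOW and s in (State.HIGH, State.LIGATED):
            flags.append(s is State.LIGATED)
        prev = s
    return flags


def _psf_patch(x: float, y: float, radius: int, sigma: float) -> tuple[np.ndarray, int, int]:
    """Pixel-integrated unit-flux Gaussian patch around (x, y).

    Returns the patch and the (x0, y0) of its lower corner.  Pixel i
    covers [i - 0.5, i + 0.5] (0-based pixel-center convention).
    """
    from scipy.special import erf

    cx, cy = int(round(x)), int(round(y))
    xs = np.arange(cx - radius, cx + radius + 1)
    ys = np.arange(cy - radius, cy + radius + 1)
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    return np.outer(fy, fx), cx - radius, cy - radius


def render_movie(
    trajectories: list[Trajectory],
    truth: GroundTruth,
    optics=None,
    channel_map=None,
    rng: np.random.Generator | int = 0,
    margin: int = 8,
    patch_radius: int | None = None,
):
    """Render a dual-half-channel movie stack from intensity trajectories.

    Each molecule becomes a pixel-integrated Gaussian spot: its donor
    intensity lands at its donor-half position and its acceptor
    intensity at the channel-mapped acceptor-half position, per frame.
    A uniform camera background, Poisson shot noise and Gaussian read
    noise complete the camera model, and the result is a 16-bit stack.
    Trajectories should be emitted noiseless and background-free
    (``noise_sd = 0``, zero backgrounds): all movie-mode noise enters
    here, at the pixel level.

    Spot positions are drawn uniformly inside the donor half (with a
    ``margin``) unless ``truth.spot_xy`` already provides them; any two
    molecules closer than ``optics.min_separation`` are recorded in
    ``truth.crowded`` (they should trip the multi-peak QC rule).
    Returns ``(stack, sidecar)`` where the sidecar holds positions and
    the channel map.
    """
    from scipy.spatial import cKDTree

    from .localization import ChannelMap, OpticsConfig

    optics = optics or OpticsConfig()
    channel_map = channel_map or ChannelMap()
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if not trajectories:
        raise ParameterError("no trajectories to render")

    h, w = optics.image_shape
    half_w = optics.half_width
    n_frames = trajectories[0].n_frames
    if patch_radius is None:
        patch_radius = max(4, int(np.ceil(4 * optics.psf_sigma)))

    # Assign positions (donor-half local coordinates).
    for traj in trajectories:
        if traj.molecule_id not in truth.spot_xy:
            truth.spot_xy[traj.molecule_id] = (
                float(rng.uniform(margin, half_w - margin)),
                float(rng.uniform(margin, h - margin)),
            )
    ids = [t.molecule_id for t in trajectories]
    xy = np.array([truth.spot_xy[i] for i in ids])
    if len(ids) > 1:
        tree = cKDTree(xy)
        for i, j in tree.query_pairs(optics.min_separation):
            truth.crowded.add(ids[i])
            truth.crowded.add(ids[j])

    stack = np.zeros((n_frames, h, w), dtype=float)
    for traj, (x, y) in zip(trajectories, xy):
        ax, ay = channel_map.apply((x, y))[0]
        for (px, py, x_off, flux) in (
            (x, y, 0, np.clip(traj.donor, 0, None)),
            (ax, ay, half_w, np.clip(traj.acceptor, 0, None)),
        ):
            patch, x0, y0 = _psf_patch(px, py, patch_radius, optics.psf_sigma)
            x0 += x_off
            xs = slice(max(x0, x_off), min(x0 + patch.shape[1], x_off + half_w))
            ys = slice(max(y0, 0), min(y0 + patch.shape[0], h))
            sub = patch[ys.start - y0 : ys.stop - y0, xs.start - x0 : xs.stop - x0]
            stack[:, ys, xs] += flux[: n_frames, None, None] * sub

    stack += optics.bg_level
    if optics.shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(float)
    if optics.read_noise_sd > 0:
        stack += rng.normal(0.0, optics.read_noise_sd, stack.shape)
    stack = np.clip(stack, 0, 65535).round().astype(np.uint16)

    sidecar = {
        "positions": {i: list(truth.spot_xy[i]) for i in ids},
        "crowded": sorted(truth.crowded),
        "channel_map": {
            "matrix": channel_map.matrix.tolist(),
            "offset": channel_map.offset.tolist(),
        },
        "image_shape": [h, w],
        "psf_sigma": optics.psf_sigma,
    }
    return stack, sidecar
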