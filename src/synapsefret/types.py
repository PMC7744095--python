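"""Domain types shared across the pipeline.

The objects here mirror the stages of a single-molecule FRET synapsis
experiment: a kinetic model of DNA-end synapsis (:class:`KineticModel`),
the acquisition geometry of an alternating-excitation TIRF recording
(:class:`AcquisitionConfig`), simulated ground truth
(:class:`StatePath`, :class:`GroundTruth`), raw per-molecule intensity
trajectories (:class:`Trajectory`), quality-controlled FRET traces
(:class:`FretTrace`), detected short-range (SR) complex formation events
(:class:`SREvent`, :class:`SREventSet`) and the resulting rate estimate
(:class:`RateEstimate`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "State",
    "KineticModel",
    "AcquisitionConfig",
    "StatePath",
    "GroundTruth",
    "Trajectory",
    "QCReport",
    "FretTrace",
    "SREvent",
    "SREventSet",
    "RateEstimate",
    "ParameterError",
    "SchemaError",
]


class ParameterError(ValueError):
    """Invalid model or analysis parameter."""


class SchemaError(ValueError):
    """Malformed input table or configuration."""


class State(enum.IntEnum):
    """Synapsis state of one DNA substrate molecule.

    LOW covers both unpaired ends and the long-range (LR) complex:
    neither brings the dye pair within FRET range.  HIGH is the
    short-range (SR) synaptic complex; LIGATED is the covalently joined
    product, spectroscopically indistinguishable from HIGH and absorbing.
    """

    LOW = 0
    HIGH = 1
    LIGATED = 2


@dataclass(frozen=True)
class KineticModel:
    """Rates and emission parameters of the two-state synapsis model.

    Parameters
    ----------
    k_form : float
        SR-complex formation rate (s^-1) out of the low-FRET state.
    k_dissolve : float
        SR-complex dissolution rate (s^-1) back to the low-FRET state.
    p_ligate : float
        Probability that a formation event is absorbing (the ends are
        ligated and never separate again).
    h_bleach_donor, h_bleach_acceptor : float
        Photobleaching hazards (s^-1 of *illuminated* time) for the
        donor (Cy3) and acceptor (Cy5) dyes.  A single effective
        acceptor hazard subsumes FRET-mediated bleaching under donor
        excitation.
    E_low, E_high : float
        Apparent FRET efficiencies of the two states.
    I_total : float
        Mean total detected intensity per donor-excitation frame
        (counts); split between channels according to E.
    I_direct : float
        Mean acceptor intensity under direct acceptor excitation.
    noise_sd : float
        Additive Gaussian noise per channel per frame (counts).
    bg_donor, bg_acceptor : float
        Constant channel backgrounds (counts).
    """

    k_form: float = 1.7e-3
    k_dissolve: float = 2.0e-3
    p_ligate: float = 0.5
    h_bleach_donor: float = 5.0e-4
    h_bleach_acceptor: float = 1.0e-3
    E_low: float = 0.05
    E_high: float = 0.5
    I_total: float = 1000.0
    I_direct: float = 600.0
    noise_sd: float = 50.0
    bg_donor: float = 100.0
    bg_acceptor: float = 100.0

    def __post_init__(self) -> None:
        for name in ("k_form", "k_dissolve", "h_bleach_donor", "h_bleach_acceptor"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be finite and >= 0, got {v!r}")
        if not 0.0 <= self.p_ligate <= 1.0:
            raise ParameterError(f"p_ligate must be in [0, 1], got {self.p_ligate!r}")
        if not 0.0 <= self.E_low < self.E_high <= 1.0:
            raise ParameterError(
                f"need 0 <= E_low < E_high <= 1, got ({self.E_low!r}, {self.E_high!r})"
            )
        if not self.I_total > 0:
            raise ParameterError(f"I_total must be > 0, got {self.I_total!r}")
        if self.noise_sd < 0 or self.I_direct < 0:
            raise ParameterError("noise_sd and I_direct must be >= 0")

    def with_(self, **kw) -> "KineticModel":
        return replace(self, **kw)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Alternating-excitation acquisition settings.

    Defaults reproduce the experimental scheme: 1 s exposures every 2 s,
    four donor (532 nm) excitation frames followed by one direct
    acceptor (641 nm) excitation frame, three 15-min fields of view per
    replicate imaged back to back (0-15, 15-30 and 30-45 min).
    """

    exposure: float = 1.0
    frame_period: float = 2.0
    cycle: tuple[int, int] = (4, 1)
    fov_duration: float = 900.0
    n_fovs_per_replicate: int = 3
    n_replicates: int = 3
    n_molecules_per_fov: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure <= 0 or self.frame_period <= 0:
            raise ParameterError("exposure and frame_period must be > 0")
        if self.exposure > self.frame_period:
            raise ParameterError("exposure must not exceed frame_period")
        n = self.fov_duration / self.frame_period
        if self.fov_duration <= 0 or abs(n - round(n)) > 1e-9:
            raise ParameterError("fov_duration must be a positive multiple of frame_period")
        if self.cycle[0] < 1 or self.cycle[1] < 1:
            raise ParameterError("cycle counts must be >= 1")
        if min(self.n_fovs_per_replicate, self.n_replicates, self.n_molecules_per_fov) < 1:
            raise ParameterError("replicate/FOV/molecule counts must be >= 1")

    @property
    def n_frames(self) -> int:
        return int(round(self.fov_duration / self.frame_period))

    @property
    def duty_factor(self) -> float:
        """Fraction of wall time the sample is illuminated."""
        return self.exposure / self.frame_period

    def excitation_labels(self, n_frames: Optional[int] = None) -> np.ndarray:
        """Repeating 'D'/'A' labels for the first ``n_frames`` frames."""
        n = self.n_frames if n_frames is None else n_frames
        nd, na = self.cycle
        unit = np.array(["D"] * nd + ["A"] * na)
        reps = int(np.ceil(n / unit.size))
        return np.tile(unit, reps)[:n]

    @property
    def donor_frame_quantum(self) -> float:
        """Wall-clock time represented by one donor-excitation frame.

        Each donor frame stands for its share of the full excitation
        cycle, so that summing over donor frames recovers wall time.
        """
        nd, na = self.cycle
        return self.frame_period * (nd + na) / nd


@dataclass
class StatePath:
    """Continuous-time state path of one molecule plus its bleach times.

    ``transitions`` is an ordered list of ``(time_s, State)`` with the
    first entry ``(0.0, LOW)``.  Bleach times are wall-clock seconds
    from the start of illumination (``None`` = never bleached within
    the simulated horizon).
    """

    molecule_id: str
    transitions: list[tuple[float, State]]
    bleach_time_donor: Optional[float] = None
    bleach_time_acceptor: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.transitions or self.transitions[0] != (0.0, State.LOW):
            raise ParameterError("state path must start (0.0, LOW)")
        times = [t for t, _ in self.transitions]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ParameterError("transition times must be strictly increasing")
        seen_ligated = False
        for _, s in self.transitions:
            if seen_ligated:
                raise ParameterError("LIGATED is absorbing")
            seen_ligated = s is State.LIGATED

    def state_at(self, t: float) -> State:
        idx = np.searchsorted([tt for tt, _ in self.transitions], t, side="right") - 1
        return self.transitions[max(idx, 0)][1]

    def formation_times(self) -> list[float]:
        """Times of every LOW -> HIGH/LIGATED transition (one per event)."""
        out = []
        prev = State.LOW
        for t, s in self.transitions[1:]:
            if prev is State.LOW and s in (State.HIGH, State.LIGATED):
                out.append(t)
            prev = s
        return out

    def high_intervals(self, t_end: float) -> list[tuple[float, float]]:
        """Closed intervals during which the molecule is high-FRET."""
        out: list[tuple[float, float]] = []
        start: Optional[float] = None
        for t, s in self.transitions:
            if s in (State.HIGH, State.LIGATED):
                if start is None:
                    start = t
            elif start is not None:
                out.append((start, t))
                start = None
        if start is not None:
            out.append((start, t_end))
        return [(a, min(b, t_end)) for a, b in out if a < t_end]


@dataclass
class Trajectory:
    """Per-frame dual-channel intensities of one molecule.

    Times are seconds from the start of the molecule's own imaging
    window; ``window_start_s`` records where that window sits within
    the replicate (0, 900, 1800 s for the three FOVs).
    """

    replicate: int
    fov: int
    molecule: int
    frame: np.ndarray
    time_s: np.ndarray
    excitation: np.ndarray  # 'D' or 'A'
    donor: np.ndarray
    acceptor: np.ndarray
    window_start_s: float = 0.0
    frame_period: float = 2.0
    cycle: tuple[int, int] = (4, 1)

    @property
    def molecule_id(self) -> str:
        return f"r{self.replicate}_f{self.fov}_m{self.molecule}"

    @property
    def n_frames(self) -> int:
        return int(self.frame.size)

    def donor_excitation(self) -> np.ndarray:
        return self.excitation == "D"


@dataclass
class GroundTruth:
    """Known-answer sidecar for simulated data."""

    paths: dict[str, StatePath]
    event_times: dict[str, list[float]]  # formation times within the imaged window
    ligated: dict[str, list[bool]]
    spot_xy: dict[str, tuple[float, float]] = field(default_factory=dict)
    crowded: set[str] = field(default_factory=set)  # spots violating min separation

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.event_times.values())


@dataclass
class QCReport:
    """Per-molecule quality-control outcome."""

    molecule_id: str
    truncation_frame: int  # exclusive end, in trajectory frame index
    bleach_channel: str  # 'donor' | 'acceptor' | 'none'
    exclusion_flags: frozenset[str] = frozenset()

    VALID_FLAGS = frozenset(
        {"low_snr", "multistep_bleach", "non_fret_fluctuation", "multi_peak", "too_short"}
    )

    def __post_init__(self) -> None:
        unknown = set(self.exclusion_flags) - self.VALID_FLAGS
        if unknown:
            raise ParameterError(f"unknown QC flags: {sorted(unknown)}")
        self.exclusion_flags = frozenset(self.exclusion_flags)

    @property
    def included(self) -> bool:
        return not self.exclusion_flags


@dataclass
class FretTrace:
    """FRET-efficiency series on donor-excitation frames after QC.

    ``acceptor_present`` is interpolated from the direct-excitation
    frames; ``valid`` masks frames whose total signal was too low for a
    meaningful ratio.  ``time_quantum_s`` is the wall-clock time each
    donor frame represents (frame_period x cycle/donor-frames).
    """

    molecule_id: str
    times: np.ndarray
    efficiency: np.ndarray
    acceptor_present: np.ndarray
    valid: np.ndarray
    time_quantum_s: float
    truncation_time_s: float
    replicate: int = 0
    out_of_range: bool = False  # any E outside the sanity bound [-0.2, 1.2]

    def __post_init__(self) -> None:
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")


@dataclass(frozen=True)
class SREvent:
    """One SR-complex formation event."""

    molecule_id: str
    start_s: float
    end_s: float
    censored: bool  # run reached the truncation frame
    ligated: bool  # synonym of censored under the threshold rule
    preformed: bool = False  # run began at the first analyzed frame


@dataclass
class SREventSet:
    """Events detected in one FRET trace plus the detection parameters."""

    molecule_id: str
    events: list[SREvent]
    threshold: float
    min_frames: int
    spans: list[tuple[int, int]] = field(default_factory=list)  # donor-frame index runs

    @property
    def formation_events(self) -> list[SREvent]:
        """Events with an observed LOW -> HIGH transition."""
        return [e for e in self.events if not e.preformed]

    @property
    def n_events(self) -> int:
        return len(self.formation_events)


@dataclass
class RateEstimate:
    """SR-formation rate: pooled events over pooled at-risk time.

    ``ci95`` is the replicate-based t interval (mean of replicate rates
    +/- t_{0.975,n-1} * SD/sqrt(n)); ``poisson_ci95`` the exact Poisson
    interval on the pooled count.  With < 2 replicates the t interval
    is ``None``.
    """

    condition: str
    n_events: int
    t_observable_s: float
    rate_per_s: float
    replicate_stats: list[tuple[int, float, float]]  # (n_events, T_s, rate)
    ci95: Optional[tuple[float, float]]
    poisson_ci95: tuple[float, float]
    n_molecules: int

    def __post_init__(self) -> None:
        if self.t_observable_s <= 0:
            raise ParameterError("t_observable_s must be > 0")
        if self.rate_per_s < 0:
            raise ParameterError("rate must be >= 0")
        if self.replicate_stats and sum(n for n, _, _ in self.replicate_stats) != self.n_events:
            raise ParameterError("replicate event counts must sum to pooled count")

    @property
    def replicate_rates(self) -> list[float]:
        return [r for _, _, r in self.replicate_stats]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]
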