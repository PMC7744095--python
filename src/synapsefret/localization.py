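"""Spot localization and intensity extraction from dual-half-chip movies.

The emission path splits donor (Cy3) and acceptor (Cy5) light onto the
two halves of one camera chip: donor on columns [0, W/2), acceptor on
[W/2, W).  Coordinates are 0-based pixel centers *local to each half*;
an affine channel map relates donor-half coordinates to acceptor-half
coordinates.  Table-mode analyses bypass this module entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from skimage.filters import gaussian

from .types import ParameterError, Trajectory

__all__ = [
    "OpticsConfig",
    "ChannelMap",
    "SpotSet",
    "PairedMolecule",
    "detect_spots",
    "pair_channels",
    "extract_intensities",
]


@dataclass(frozen=True)
class OpticsConfig:
    """Camera/PSF model for rendering and localizing movies."""

    image_shape: tuple[int, int] = (64, 128)  # (height, full width)
    psf_sigma: float = 1.1  # px
    bg_level: float = 100.0  # counts per pixel
    read_noise_sd: float = 3.0  # counts
    shot_noise: bool = True
    min_separation: float = 4.0  # px, multi-peak exclusion radius

    @property
    def half_width(self) -> int:
        return self.image_shape[1] // 2


@dataclass
class ChannelMap:
    """Affine transform from donor-half to acceptor-half coordinates."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.offset = np.asarray(self.offset, float)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ParameterError("channel map must be invertible")
        if not np.isfinite(self.residual_rms):
            raise ParameterError("residual RMS must be finite")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, float))
        return xy @ self.matrix.T + self.offset

    @classmethod
    def fit(cls, donor_xy: np.ndarray, acceptor_xy: np.ndarray) -> "ChannelMap":
        """Least-squares affine fit from matched fiducial coordinates."""
        src = np.atleast_2d(np.asarray(donor_xy, float))
        dst = np.atleast_2d(np.asarray(acceptor_xy, float))
        if src.shape[0] < 3:
            raise ParameterError("need >= 3 fiducial pairs to fit an affine map")
        design = np.column_stack([src, np.ones(src.shape[0])])
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        matrix, offset = coef[:2].T, coef[2]
        pred = design @ coef
        rms = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
        return cls(matrix=matrix, offset=offset, residual_rms=rms)


@dataclass
class SpotSet:
    """Detected spots in one channel (half-local coordinates)."""

    xy: np.ndarray  # (n, 2) of (x, y)
    channel: str  # 'donor' | 'acceptor'
    scores: np.ndarray
    multipeak_xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def n(self) -> int:
        return int(self.xy.shape[0])


@dataclass
class PairedMolecule:
    """One molecule's ROI centers in both halves."""

    index: int
    donor_xy: tuple[float, float]
    acceptor_xy: tuple[float, float]
    mutual: bool  # True if matched to a detected acceptor spot


def _half_image(frame_stack: np.ndarray, channel: str, half_width: int) -> np.ndarray:
    if channel == "donor":
        return frame_stack[..., :half_width]
    if channel == "acceptor":
        return frame_stack[..., half_width:]
    raise ParameterError(f"unknown channel {channel!r}")


def detect_spots(
    movie: np.ndarray,
    channel: str,
    optics: OpticsConfig = OpticsConfig(),
    excitation: Optional[np.ndarray] = None,
    n_average: int = 10,
    threshold_mads: float = 5.0,
) -> SpotSet:
    """Detect spots on the time-average of early donor-excitation frames.

    Local maxima of the lightly smoothed average image above
    median + ``threshold_mads`` x MAD are kept, refined to sub-pixel
    precision by background-subtracted center of mass.  Any two spots
    closer than ``optics.min_separation`` px are *both* dropped and
    recorded as multi-peak candidates (they contaminate each other's
    ROI and feed the multi-peak QC exclusion).
    """
    movie = np.asarray(movie, float)
    if movie.ndim == 2:
        movie = movie[None]
    if movie.size == 0:
        raise ParameterError("empty movie")
    if excitation is not None:
        donor_frames = np.flatnonzero(np.asarray(excitation) == "D")[:n_average]
    else:
        donor_frames = np.arange(min(n_average, movie.shape[0]))
    avg = movie[donor_frames].mean(axis=0)
    half = _half_image(avg, channel, optics.half_width)
    if np.ptp(half) == 0:
        raise ParameterError("flat image: nothing to detect")

    smooth = gaussian(half, sigma=max(optics.psf_sigma / 2, 0.5), preserve_range=True)
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    thr = med + threshold_mads * max(mad, 1e-9)
    peaks = peak_local_max(smooth, min_distance=1, threshold_abs=thr, exclude_border=1)

    # Sub-pixel refinement: center of mass in a small window.
    r = 3
    xy, scores = [], []
    h, w = half.shape
    for py, px in peaks:
        y0, y1 = max(py - r, 0), min(py + r + 1, h)
        x0, x1 = max(px - r, 0), min(px + r + 1, w)
        patch = half[y0:y1, x0:x1] - med
        patch = np.clip(patch, 0, None)
        total = patch.sum()
        if total <= 0:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        xy.append(((xs * patch).sum() / total, (ys * patch).sum() / total))
        scores.append(float(smooth[py, px] - med))
    xy_arr = np.asarray(xy, float).reshape(-1, 2)
    score_arr = np.asarray(scores, float)

    # Minimum-separation rule.
    keep = np.ones(xy_arr.shape[0], bool)
    if xy_arr.shape[0] > 1:
        tree = cKDTree(xy_arr)
        for i, j in tree.query_pairs(optics.min_separation):
            keep[i] = keep[j] = False
    return SpotSet(
        xy=xy_arr[keep],
        channel=channel,
        scores=score_arr[keep],
        multipeak_xy=xy_arr[~keep],
    )


def pair_channels(
    donor: SpotSet,
    acceptor: SpotSet,
    cmap: ChannelMap,
    radius_px: float = 2.0,
) -> list[PairedMolecule]:
    """Mutual-nearest-neighbor pairing of mapped donor spots with
    acceptor spots.

    Donor spots with no acceptor partner within ``radius_px`` are
    retained with the *mapped* coordinate as the acceptor ROI center:
    before any FRET the acceptor channel is dark, so an undetected
    acceptor spot is expected, not disqualifying.
    """
    if cmap.residual_rms >= radius_px:
        raise ParameterError("channel-map residual exceeds the pairing radius")
    if donor.n == 0:
        return []
    mapped = cmap.apply(donor.xy)
    pairs: list[PairedMolecule] = []
    if acceptor.n:
        tree = cKDTree(acceptor.xy)
        dist, j = tree.query(mapped, distance_upper_bound=radius_px)
        back = cKDTree(mapped)
        _, back_j = back.query(acceptor.xy)
        for i in range(donor.n):
            mutual = np.isfinite(dist[i]) and j[i] < acceptor.n and back_j[j[i]] == i
            axy = acceptor.xy[j[i]] if mutual else mapped[i]
            pairs.append(
                PairedMolecule(
                    index=i,
                    donor_xy=tuple(donor.xy[i]),
                    acceptor_xy=tuple(axy),
                    mutual=bool(mutual),
                )
            )
    else:
        for i in range(donor.n):
            pairs.append(
                PairedMolecule(
                    index=i,
                    donor_xy=tuple(donor.xy[i]),
                    acceptor_xy=tuple(mapped[i]),
                    mutual=False,
                )
            )
    return pairs


def extract_intensities(
    movie: np.ndarray,
    pairs: Sequence[PairedMolecule],
    excitation: np.ndarray,
    optics: OpticsConfig = OpticsConfig(),
    frame_period: float = 2.0,
    cycle: tuple[int, int] = (4, 1),
    roi_side: int = 5,
    ring_width: int = 2,
    replicate: int = 0,
    fov: int = 0,
) -> tuple[list[Trajectory], list[int]]:
    """Per-frame ROI intensities for every paired molecule.

    Channel intensity = ROI pixel sum - (median of the surrounding
    ring) x ROI area, which cancels any locally uniform background.
    Molecules whose ROI or ring would be clipped by an image edge are
    excluded and their indices returned.
    """
    if roi_side % 2 != 1:
        raise ParameterError("roi_side must be odd")
    movie = np.asarray(movie, float)
    n_frames, h, w = movie.shape
    half_w = optics.half_width
    r = roi_side // 2
    rr = r + ring_width
    times = np.arange(n_frames) * frame_period
    frames = np.arange(n_frames)
    exc = np.asarray(excitation)[:n_frames]

    trajectories: list[Trajectory] = []
    excluded: list[int] = []
    for pm in pairs:
        centers = {
            "donor": (pm.donor_xy, 0),
            "acceptor": (pm.acceptor_xy, half_w),
        }
        signals = {}
        clipped = False
        for name, ((x, y), x_off) in centers.items():
            cx, cy = int(round(x)) + x_off, int(round(y))
            if cx - rr < (x_off if name == "acceptor" else 0) or cy - rr < 0:
                clipped = True
                break
            x_hi = w if name == "acceptor" else half_w
            if cx + rr >= x_hi or cy + rr >= h:
                clipped = True
                break
            roi = movie[:, cy - r : cy + r + 1, cx - r : cx + r + 1]
            ring = movie[:, cy - rr : cy + rr + 1, cx - rr : cx + rr + 1].copy()
            ring[:, ring_width:-ring_width, ring_width:-ring_width] = np.nan
            ring_flat = ring.reshape(n_frames, -1)
            bg = np.nanmedian(ring_flat, axis=1)
            signals[name] = roi.sum(axis=(1, 2)) - bg * roi_side**2
        if clipped:
            excluded.append(pm.index)
            continue
        trajectories.append(
            Trajectory(
                replicate=replicate,
                fov=fov,
                molecule=pm.index,
                frame=frames.copy(),
                time_s=times.copy(),
                excitation=exc.copy(),
                donor=signals["donor"],
                acceptor=signals["acceptor"],
                frame_period=frame_period,
                cycle=cycle,
            )
        )
    return trajectories, excluded
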