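"""Rotamer-state, flexibility and statistical-error analysis of trajectories.

Dihedral time series wrap at the +-180 degree boundary, so a single torsional
well centered near 180 degrees appears split into two apparent populations.
Before any state counting or standard deviation is computed the series is
repaired by shifting the minority side of a straddling population by +-360
degrees, after which shifted angles live in [-360, +360] and each rotameric
state is contiguous.  State populations are read off a fixed histogram of 144
five-degree bins spanning [-360, +360].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

HIST_BINS = 144
HIST_RANGE = (-360.0, 360.0)


@dataclass
class DihedralTrajectory:
    """Named dihedral series (degrees, wrapped to [-180, 180)) per frame."""

    data: pd.DataFrame
    #: which series have had the +-360 shift applied
    shift_flags: dict = field(default_factory=dict)
    frame_spacing: float = 1.0   # arbitrary units between stored frames
    source: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list:
        return [c for c in self.data.columns if c != "frame"]

    def series(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def subsample(self, stride: int) -> "DihedralTrajectory":
        """Every k-th frame (mirrors saving one frame per fixed interval)."""
        return DihedralTrajectory(self.data.iloc[::stride].reset_index(drop=True),
                                  dict(self.shift_flags),
                                  self.frame_spacing * stride, self.source)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DihedralTrajectory":
        return cls(pd.read_csv(path), source=str(path))


# ---------------------------------------------------------------------------
# Wrap repair
# ---------------------------------------------------------------------------

def unwrap_series(series_deg, bin_width: float = 5.0, gap_bins: int = 4):
    """Repair a series whose population straddles the +-180 boundary.

    If an occupied run of circular histogram bins crosses the boundary while
    a clear gap (``gap_bins`` consecutive empty bins) exists elsewhere, the
    minority side of the straddling population is shifted by +-360 degrees
    so it becomes contiguous (ties shift the negative side up).  Sparse tail
    samples separated from the run by less than ``gap_bins`` empty bins are
    treated as part of it.  Returns ``(shifted series, flag)``; idempotent,
    and a no-op for series that do not straddle.
    """
    a = np.asarray(series_deg, dtype=float)
    if a.size == 0:
        return a.copy(), False
    nbins = int(round(360.0 / bin_width))
    counts, edges = np.histogram(a, bins=nbins, range=(-180.0, 180.0))
    occupied = counts > 0
    if not (occupied[0] and occupied[-1]) or occupied.all():
        return a.copy(), False

    def run_end(indices):
        """Last occupied bin of the gap-tolerant run along ``indices``."""
        last = indices[0]
        gap = 0
        for i in indices[1:]:
            if occupied[i]:
                last = i
                gap = 0
            else:
                gap += 1
                if gap >= gap_bins:
                    break
        return last

    low_end = run_end(list(range(nbins)))               # walk up from -180
    high_start = run_end(list(range(nbins - 1, -1, -1)))  # walk down from +180
    if low_end >= high_start:   # the tolerant runs meet: nothing to split
        return a.copy(), False
    low_side = a < edges[low_end + 1]      # near -180
    high_side = a >= edges[high_start]     # near +180
    out = a.copy()
    if int(np.sum(low_side)) <= int(np.sum(high_side)):
        out[low_side] += 360.0
    else:
        out[high_side] -= 360.0
    return out, True


def circular_stddev_deg(series_deg) -> float:
    """Independent circular-statistics route to the spread of a wrapped series.

    Deviations are taken about the circular mean and re-wrapped to
    (-180, 180]; for a contiguous population this equals the linear standard
    deviation of the shift-repaired series.
    """
    from scipy.stats import circmean
    a = np.asarray(series_deg, dtype=float)
    m = circmean(a, high=180.0, low=-180.0)
    dev = (a - m + 180.0) % 360.0 - 180.0
    return float(np.std(dev))


def angle_stddev(series_deg) -> float:
    """Ordinary standard deviation (degrees) of an unwrapped series."""
    return float(np.std(np.asarray(series_deg, dtype=float)))


# ---------------------------------------------------------------------------
# Rotamer states
# ---------------------------------------------------------------------------

@dataclass
class RotamerState:
    center_deg: float
    population: float     # fraction of frames
    width_bins: int


@dataclass
class RotamerProfile:
    """Histogram and occupied-state summary of one dihedral series."""

    name: str
    counts: np.ndarray          # 144 bins over [-360, 360]
    bin_centers: np.ndarray
    states: list                # of RotamerState
    stddev_deg: float           # post-shift
    shifted: bool
    n_frames: int

    @property
    def n_states(self) -> int:
        return len(self.states)

    def histogram_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center_deg": self.bin_centers, "count": self.counts})


def rotamer_states(traj: DihedralTrajectory, occupancy_threshold: float = 0.005,
                   gap_bins: int = 2, unwrap: bool = True) -> dict:
    """Count occupied rotameric states of every series in the trajectory.

    A state is a maximal run of histogram bins with occupancy at or above
    ``occupancy_threshold`` (fraction of frames), separated from the next run
    by at least ``gap_bins`` sub-threshold bins.  Returns
    ``{name: RotamerProfile}``.
    """
    import warnings

    out = {}
    if traj.n_frames and traj.n_frames < 100:
        warnings.warn(f"only {traj.n_frames} frames; rotamer populations will be noisy")
    for name in traj.names:
        raw = traj.series(name)
        if unwrap:
            shifted, flag = unwrap_series(raw)
        else:
            shifted, flag = raw, bool(traj.shift_flags.get(name, False))
        counts, edges = np.histogram(shifted, bins=HIST_BINS, range=HIST_RANGE)
        centers = 0.5 * (edges[:-1] + edges[1:])
        states = _states_from_histogram(counts, centers, len(shifted),
                                        occupancy_threshold, gap_bins)
        out[name] = RotamerProfile(
            name=name, counts=counts, bin_centers=centers, states=states,
            stddev_deg=angle_stddev(shifted) if len(shifted) else 0.0,
            shifted=flag, n_frames=len(shifted))
    return out


def _states_from_histogram(counts, centers, n_frames, occupancy_threshold, gap_bins):
    if n_frames == 0:
        return []
    thresh = occupancy_threshold * n_frames
    above = counts >= max(thresh, 1)
    states = []
    i = 0
    nb = len(counts)
    while i < nb:
        if not above[i]:
            i += 1
            continue
        j = i
        gap = 0
        last_occ = i
        while j + 1 < nb:
            if above[j + 1]:
                gap = 0
                last_occ = j + 1
            else:
                gap += 1
                if gap >= gap_bins:
                    break
            j += 1
        run = slice(i, last_occ + 1)
        c = counts[run]
        pop = float(np.sum(c)) / n_frames
        center = float(np.sum(c * centers[run]) / np.sum(c))
        states.append(RotamerState(center_deg=center, population=pop,
                                   width_bins=last_occ - i + 1))
        i = last_occ + 1 + gap_bins
    return states


# ---------------------------------------------------------------------------
# Cartesian flexibility measures
# ---------------------------------------------------------------------------

def superpose_frames(frames: np.ndarray, selection=None, reference: np.ndarray = None):
    """Least-squares fit every frame onto the reference over ``selection``."""
    frames = np.asarray(frames, dtype=float)
    sel = np.arange(frames.shape[1]) if selection is None else np.asarray(selection)
    ref = frames[0] if reference is None else np.asarray(reference, float)
    ref_sel = ref[sel] - ref[sel].mean(axis=0)
    out = np.empty_like(frames)
    for f, x in enumerate(frames):
        cen = x[sel].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_sel, x[sel] - cen)
        out[f] = rot.apply(x - cen) + ref[sel].mean(axis=0)
    return out


def rmsf(frames: np.ndarray, selection=None, superpose: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure (A).

    Frames are superposed onto the first frame over the analyzed selection
    before the fluctuation is measured.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("rmsf needs at least 2 frames of (N, 3) coordinates")
    sel = np.arange(frames.shape[1]) if selection is None else np.asarray(selection)
    if superpose:
        frames = superpose_frames(frames, sel)
    sub = frames[:, sel, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def block_average_error(series, n_blocks: int = 5) -> float:
    """Standard error of the mean from the spread of contiguous block means.

    The series is split into ``n_blocks`` contiguous blocks; the error is the
    standard deviation of the block means divided by sqrt(n_blocks).  A
    trending (non-stationary) series inflates the estimate; choose blocks
    longer than the correlation time.
    """
    a = np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    if len(a) < n_blocks:
        raise ValueError("series shorter than the number of blocks")
    blocks = np.array_split(a, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))
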