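"""Regions-of-interest (ROI) compression of centroided LC-MS scan series.

The ROI strategy reduces a full scan series to the mass traces that matter:
m/z values whose intensity exceeds a threshold (a fixed fraction of the
maximum signal in the run) for a minimum number of *consecutive* scans.
Each retained ROI is summarised by the arithmetic mean of the m/z values of
its member data points, and the traces are assembled into a retention-time
by ROI intensity matrix.

The extraction is single-pass over scans in retention-time order.  An open
ROI candidate carries a running (unweighted) mean m/z; a supra-threshold
data point joins the nearest open candidate whose mean is within the m/z
tolerance, otherwise it opens a new candidate.  A scan that contributes no
point to a candidate closes it: consecutiveness is counted in scan indices
and a single sub-threshold scan breaks the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Scan",
    "ScanSeries",
    "ROIParams",
    "ROIMatrix",
    "ROINotFoundError",
    "extract_rois",
    "roi_trace",
]


class ROINotFoundError(KeyError):
    """No ROI within tolerance of the queried m/z ("metabolite not found")."""


@dataclass
class Scan:
    """One centroided mass spectrum: retention time plus (m/z, intensity) pairs."""

    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class ScanSeries:
    """An ordered LC-MS scan series for one run and one ionization polarity."""

    scans: list[Scan]
    polarity: str = "positive"
    run_id: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @property
    def rt_axis(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def max_intensity(self) -> float:
        return max((float(s.intensity.max()) for s in self.scans if s.intensity.size), default=0.0)

    def total_ion_current(self) -> np.ndarray:
        """Summed intensity per scan."""
        return np.array([float(s.intensity.sum()) for s in self.scans])


@dataclass(frozen=True)
class ROIParams:
    """ROI extraction parameters.

    snr_fraction
        Intensity threshold as a fraction of the maximum signal in the run;
        default 0.001 (0.1% of the maximum MS signal intensity).
    mz_tolerance
        Half-width in Da for assigning a centroid to a ROI's running mean
        m/z; default 0.5 Da (unit-resolution triple-quadrupole accuracy).
    min_consecutive
        Minimum number of consecutive scans a trace must stay above the
        threshold to be retained as a chromatographic peak; default 25.
    """

    snr_fraction: float = 0.001
    mz_tolerance: float = 0.5
    min_consecutive: int = 25

    def __post_init__(self) -> None:
        if not 0 < self.snr_fraction <= 1:
            raise ValueError("snr_fraction must be in (0, 1]")
        if self.mz_tolerance <= 0:
            raise ValueError("mz_tolerance must be positive")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be a positive integer")


@dataclass
class ROIMatrix:
    """Retention-time x ROI intensity matrix with per-ROI mean m/z."""

    rt_axis: np.ndarray
    roi_mz: np.ndarray  # mean m/z per ROI, ascending
    intensities: np.ndarray  # |rt_axis| x |roi_mz|
    params: ROIParams = field(default_factory=ROIParams)
    run_id: str = ""
    polarity: str = "positive"

    @property
    def n_rois(self) -> int:
        return int(self.roi_mz.size)

    def trace(self, index: int) -> np.ndarray:
        return self.intensities[:, index]


@dataclass
class _Candidate:
    mz_sum: float
    n_points: int
    points: list[tuple[int, float, float]]  # (scan index, mz, intensity)

    @property
    def mean_mz(self) -> float:
        return self.mz_sum / self.n_points

    def add(self, scan_idx: int, mz: float, intensity: float) -> None:
        self.mz_sum += mz
        self.n_points += 1
        self.points.append((scan_idx, mz, intensity))

    def n_scans(self) -> int:
        return len({i for i, _, _ in self.points})


def extract_rois(series: ScanSeries, params: ROIParams | None = None) -> ROIMatrix:
    """Compress a centroided scan series into an ROI intensity matrix.

    The absolute threshold is ``params.snr_fraction`` times the maximum
    intensity over all scans.  Retained ROIs appear as columns sorted by
    ascending mean m/z; member intensities fill the column at their scan's
    retention time (summed if a ROI received two centroids in one scan) and
    all other entries are zero.
    """
    params = params or ROIParams()
    if not series.scans:
        raise ValueError("scan series is empty")

    top = series.max_intensity()
    rt_axis = series.rt_axis
    if top == 0.0:
        warnings.warn("all intensities are zero; returning empty ROI matrix")
        return ROIMatrix(rt_axis, np.empty(0), np.zeros((rt_axis.size, 0)),
                         params, series.run_id, series.polarity)
    threshold = params.snr_fraction * top

    open_cands: list[_Candidate] = []
    retained: list[_Candidate] = []

    def _close(cand: _Candidate) -> None:
        if cand.n_scans() >= params.min_consecutive:
            retained.append(cand)

    for i, scan in enumerate(series.scans):
        keep = scan.intensity > threshold
        # sorted processing makes the result independent of within-scan peak order
        order = np.argsort(scan.mz[keep], kind="stable")
        mzs = scan.mz[keep][order]
        intens = scan.intensity[keep][order]

        touched: set[int] = set()
        for mz, it in zip(mzs, intens):
            best = -1
            best_d = np.inf
            for j, cand in enumerate(open_cands):
                d = abs(mz - cand.mean_mz)
                if d > params.mz_tolerance:
                    continue
                # nearer mean wins; exact tie broken toward the lower mean m/z
                if d < best_d or (d == best_d and best >= 0
                                  and cand.mean_mz < open_cands[best].mean_mz):
                    best, best_d = j, d
            if best >= 0:
                open_cands[best].add(i, float(mz), float(it))
                touched.add(best)
            else:
                open_cands.append(_Candidate(float(mz), 1, [(i, float(mz), float(it))]))
                touched.add(len(open_cands) - 1)

        # a scan without a member point breaks the consecutive run: close
        still_open = []
        for j, cand in enumerate(open_cands):
            if j in touched:
                still_open.append(cand)
            else:
                _close(cand)
        open_cands = still_open

    for cand in open_cands:
        _close(cand)

    retained.sort(key=lambda c: c.mean_mz)
    roi_mz = np.array([c.mean_mz for c in retained])
    mat = np.zeros((rt_axis.size, len(retained)))
    for col, cand in enumerate(retained):
        for i, _, it in cand.points:
            mat[i, col] += it
    return ROIMatrix(rt_axis, roi_mz, mat, params, series.run_id, series.polarity)


def roi_trace(matrix: ROIMatrix, mz_query: float,
              tolerance: float) -> tuple[int, np.ndarray]:
    """Return (index, intensity-vs-rt trace) of the ROI nearest to ``mz_query``.

    The nearest mean m/z within ``tolerance`` wins; an exact distance tie is
    broken toward the lower m/z.  Raises :class:`ROINotFoundError` when no
    ROI lies within tolerance — distinguishable from a ROI with an empty
    trace, which would be returned normally.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if matrix.n_rois == 0:
        raise ROINotFoundError(f"no ROI within {tolerance} Da of m/z {mz_query}")
    d = np.abs(matrix.roi_mz - mz_query)
    # roi_mz ascending, so argmin lands on the lowest m/z among exact ties
    idx = int(np.argmin(d))
    if d[idx] > tolerance:
        raise ROINotFoundError(f"no ROI within {tolerance} Da of m/z {mz_query}")
    return idx, matrix.intensities[:, idx]
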