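"""Histogram-based separation of background, healthy brain and stroke tissue.

All voxel intensities of a volume are pooled into one histogram.  The large
low-intensity peak is the background, the broad higher peak the healthy
brain; the cut-off between them is the minimum of the dip between the two
peaks.  Acute stroke is hyperintense and skews the brain peak to the right,
so — assuming the healthy-brain values are symmetric about their mode — the
stroke cut-off is obtained by *reflecting* the left minimum across the
brain-peak mode:

    stroke_cutoff = 2 * brain_mode - left_minimum

The symmetry assumption can be probed with a one-sample Kolmogorov–Smirnov
test against a Gaussian; the check is advisory (a logged warning), never a
gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import SegmentationError
from .volume_io import DiffusionVolume

logger = logging.getLogger(__name__)


@dataclass
class IntensityHistogram:
    """Equal-width intensity histogram of a volume."""

    bin_edges: np.ndarray
    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise SegmentationError("counts length must be len(edges) - 1")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def smoothed(self, window: int = 5) -> np.ndarray:
        """Moving-average counts used for extremum detection."""
        # zero counts outside the histogram range (a replicating border would
        # inflate a clipped-intensity spike in the first bin)
        return uniform_filter1d(self.counts.astype(float), size=window, mode="constant", cval=0.0)


@dataclass
class SegmentationThresholds:
    """The two intensity cut-offs plus the healthy-brain mode (all a.u.)."""

    background_cutoff: float
    stroke_cutoff: float
    brain_mode: float

    def __post_init__(self) -> None:
        if not self.background_cutoff < self.brain_mode < self.stroke_cutoff:
            raise SegmentationError(
                "need background_cutoff < brain_mode < stroke_cutoff, got "
                f"{self.background_cutoff}, {self.brain_mode}, {self.stroke_cutoff}"
            )


def build_histogram(volume: DiffusionVolume, bin_width: float = 1.0) -> IntensityHistogram:
    """Histogram of every voxel in the volume at the given bin width.

    The default 1 a.u. width suits data in the 0-400 a.u. regime.  Total
    counts always equal the voxel count.
    """
    if bin_width <= 0:
        raise SegmentationError("bin_width must be > 0")
    data = volume.data.ravel()
    lo = np.floor(data.min() / bin_width) * bin_width
    hi = np.ceil(data.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(data, bins=edges)
    return IntensityHistogram(bin_edges=edges, counts=counts, bin_width=float(bin_width))


def _two_main_peaks(hist: IntensityHistogram, window: int) -> tuple[int, int, np.ndarray]:
    """Bin indices of the two most prominent smoothed local maxima (low, high).

    Prominence, not raw height, ranks the candidates: intensity clipping at 0
    piles mass into the first bins and can produce a tall but shallow bump
    there, which prominence ignores while height would not.
    """
    smooth = hist.smoothed(window)
    peaks, props = find_peaks(smooth, prominence=0.0)
    if len(peaks) < 2:
        raise SegmentationError("no background/brain separation: histogram is unimodal")
    order = np.argsort(props["prominences"])[::-1]
    top2 = np.sort(peaks[order[:2]])
    return int(top2[0]), int(top2[1]), smooth


def background_cutoff(hist: IntensityHistogram, window: int = 5) -> float:
    """Intensity at the minimum of the dip between the two main peaks.

    The smoothed counts are scanned strictly between the two tallest local
    maxima; ties take the lowest-intensity bin.  Raises on a unimodal
    histogram.
    """
    lo, hi, smooth = _two_main_peaks(hist, window)
    between = smooth[lo + 1 : hi]
    if between.size == 0:
        raise SegmentationError("peaks are adjacent; no dip to scan")
    dip = lo + 1 + int(np.argmin(between))  # argmin takes the first (lowest) tie
    return float(hist.centers[dip])


def brain_peak_mode(hist: IntensityHistogram, bg_cutoff: float, window: int = 5) -> float:
    """Location of the healthy-brain peak maximum above the background cut-off."""
    smooth = hist.smoothed(window)
    centers = hist.centers
    above = centers > bg_cutoff
    if not above.any():
        raise SegmentationError("no histogram mass above the background cut-off")
    sub = smooth[above]
    mode_idx = int(np.argmax(sub))  # lowest-intensity tie
    if mode_idx == len(sub) - 1:
        raise SegmentationError("brain peak sits at the histogram edge")
    return float(centers[above][mode_idx])


def stroke_cutoff(
    hist: IntensityHistogram, background_cutoff: float, window: int = 5
) -> float:
    """Healthy-brain / stroke cut-off by reflecting the left minimum.

    The left minimum — the intensity at the background/brain dip — is
    reflected across the brain-peak mode: ``2*mode - left_minimum``.  (The
    dip minimum and the background cut-off coincide by construction here;
    the caller passes the latter.)
    """
    mode = brain_peak_mode(hist, background_cutoff, window)
    return float(2.0 * mode - background_cutoff)


def segment_volume(
    volume: DiffusionVolume, bin_width: float = 1.0, window: int = 5
) -> SegmentationThresholds:
    """Full per-volume threshold determination from the intensity histogram."""
    hist = build_histogram(volume, bin_width)
    bg = background_cutoff(hist, window)
    mode = brain_peak_mode(hist, bg, window)
    return SegmentationThresholds(
        background_cutoff=bg,
        stroke_cutoff=float(2.0 * mode - bg),
        brain_mode=mode,
    )


def brain_mask(volume: DiffusionVolume, thresholds: SegmentationThresholds) -> np.ndarray:
    """Voxels classified as brain (healthy or stroke)."""
    return volume.data > thresholds.background_cutoff


def lesion_mask(volume: DiffusionVolume, thresholds: SegmentationThresholds) -> np.ndarray:
    """Voxels classified as stroke-affected tissue."""
    return volume.data > thresholds.stroke_cutoff


def gaussianity_check(
    brain_sample: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """One-sample KS test of a sample against a fitted Gaussian.

    The Gaussian uses the sample mean and SD, which makes the test
    conservative (true rejection rate below the nominal level).  A rejection
    at ``alpha`` is logged as a warning but never blocks the pipeline.
    Returns (KS statistic, p value).
    """
    sample = np.asarray(brain_sample, dtype=float).ravel()
    if sample.size < 20:
        raise SegmentationError("need at least 20 values for the KS check")
    sd = sample.std()
    if sd == 0:
        raise SegmentationError("zero-variance sample: KS check undefined")
    stat, p = stats.kstest(sample, "norm", args=(sample.mean(), sd))
    if p < alpha:
        logger.warning(
            "KS Gaussianity check rejected (stat=%.4f, p=%.4g): histogram-based "
            "thresholds assume near-Gaussian compartments", stat, p,
        )
    return float(stat), float(p)


def stroke_brain_ratio_3d(
    volume: DiffusionVolume, thresholds: SegmentationThresholds
) -> float:
    """Stroke-per-brain volume proportion from the 3D data.

    Counts voxels above the stroke cut-off over voxels above the background
    cut-off; invariant to voxel ordering.
    """
    data = volume.data
    n_brain = int(np.count_nonzero(data > thresholds.background_cutoff))
    if n_brain == 0:
        raise SegmentationError("no voxels above background cut-off: empty brain")
    n_stroke = int(np.count_nonzero(data > thresholds.stroke_cutoff))
    return n_stroke / n_brain


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
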