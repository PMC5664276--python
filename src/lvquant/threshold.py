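"""ROI intensity normalization, histogramming, Otsu thresholding, segmentation.

The area-based measurement normalizes myocardial intensities to [0, 1] by
min-max over the ROI, builds a 256-bin histogram, places Otsu's threshold
where the between-class variance sigma_b^2(t) = w0*w1*(mu0 - mu1)^2 is
maximal (equivalently, where the within-class variance is minimal), and
labels pixels beyond the threshold — above for hyperenhancing, below for
hypoenhancing modalities — as the lesion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from lvquant.io import ShortAxisImage
from lvquant.roi import MyocardialMask

DEFAULT_BINS = 256


@dataclass
class NormalizedROI:
    """Min-max-normalized intensities over the myocardial ROI.

    ``image`` holds normalized values inside the ROI and NaN elsewhere;
    ``values`` is the flat vector of ROI values (row-major ROI order).
    ``degenerate`` marks a constant ROI, whose values are all set to 0.5.
    """

    image: np.ndarray
    values: np.ndarray
    degenerate: bool = False


@dataclass
class IntensityHistogram:
    """Histogram of normalized intensities over [0, 1]."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("bin_edges must have len(counts) + 1 entries")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_values(cls, values: np.ndarray, n_bins: int = DEFAULT_BINS) -> "IntensityHistogram":
        counts, edges = np.histogram(np.asarray(values), bins=n_bins, range=(0.0, 1.0))
        return cls(counts=counts, bin_edges=edges)


@dataclass
class OtsuResult:
    """Otsu threshold plus the variance curves over all candidate cuts.

    ``thresholds[i]`` is the candidate threshold after bin ``i`` (the upper
    edge of the last below-class bin); ``sigma_b2``/``sigma_w2`` are the
    between-/within-class variances at each candidate.  ``threshold`` is the
    mean of the candidates maximizing sigma_b2 (the midpoint of a tied
    plateau); ``class_counts`` the (below, above) pixel counts at the tied
    cut closest to it.
    """

    threshold: float
    thresholds: np.ndarray
    sigma_b2: np.ndarray
    sigma_w2: np.ndarray
    class_counts: tuple[int, int]


@dataclass
class EnhancementPolarity:
    """Lesion polarity: 'hyper' (lesion above threshold) or 'hypo' (below)."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in ("hyper", "hypo"):
            raise ValueError(f"polarity must be 'hyper' or 'hypo', got {self.value!r}")


def _as_polarity(polarity: "EnhancementPolarity | str") -> str:
    return polarity.value if isinstance(polarity, EnhancementPolarity) else (
        EnhancementPolarity(polarity).value
    )


def normalize_intensity(
    image: ShortAxisImage | np.ndarray, mask: MyocardialMask | np.ndarray
) -> NormalizedROI:
    """Min-max normalize intensities over the myocardial pixels only.

    v' = (v - min) / (max - min), with min/max taken over ROI pixels.  A
    constant ROI yields the degenerate flag with all values at 0.5.
    """
    px = image.pixels if isinstance(image, ShortAxisImage) else np.asarray(image, dtype=float)
    m = mask.mask if isinstance(mask, MyocardialMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    roi = px[m].astype(float)
    lo, hi = roi.min(), roi.max()
    out = np.full(px.shape, np.nan)
    if hi == lo:
        out[m] = 0.5
        return NormalizedROI(image=out, values=out[m], degenerate=True)
    out[m] = (px[m] - lo) / (hi - lo)
    return NormalizedROI(image=out, values=out[m], degenerate=False)


def otsu_threshold(hist: IntensityHistogram) -> OtsuResult:
    """Otsu's threshold from a histogram.

    Scans every cut between consecutive bins, using bin centers as class
    values; each candidate threshold sits at the upper edge of the last
    below-class bin.  When several cuts tie for the maximal between-class
    variance (a plateau of empty bins between two modes), the threshold is
    the mean of the tied candidates, which places it midway between the
    modes rather than at the plateau edge.  Candidates leaving one class
    empty are excluded.
    """
    counts = hist.counts.astype(float)
    if hist.total == 0:
        raise ValueError("empty histogram")
    if int((counts > 0).sum()) < 2:
        raise ValueError("histogram has a single nonempty bin; no threshold exists")

    centers = hist.bin_centers
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]  # pixels in bins 0..k
    w1 = total - w0
    csum = np.cumsum(counts * centers)[:-1]
    mu_total = (counts * centers).sum() / total

    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = ((counts * centers).sum() - csum) / w1
        sigma_b2 = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    sigma_b2 = np.where(valid, sigma_b2, -np.inf)

    # within-class variances computed directly, not as total minus between
    sq = counts * centers**2
    csq = np.cumsum(sq)[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = csq / w0 - mu0**2
        var1 = (sq.sum() - csq) / w1 - mu1**2
        sigma_w2 = (w0 / total) * var0 + (w1 / total) * var1
    sigma_w2 = np.where(valid, sigma_w2, np.inf)

    m = sigma_b2.max()
    tol = 1e-10 * max(m, 1e-30)  # treat float-noise-level differences as ties
    tied = np.nonzero(sigma_b2 >= m - tol)[0]
    thresholds = hist.bin_edges[1:-1]
    threshold = float(thresholds[tied].mean())
    k = int(tied[np.argmin(np.abs(thresholds[tied] - threshold))])
    return OtsuResult(
        threshold=threshold,
        thresholds=thresholds,
        sigma_b2=np.where(np.isfinite(sigma_b2), sigma_b2, np.nan),
        sigma_w2=np.where(np.isfinite(sigma_w2), sigma_w2, np.nan),
        class_counts=(int(w0[k]), int(w1[k])),
    )


def segment_enhanced(
    normalized: NormalizedROI,
    otsu: OtsuResult,
    polarity: EnhancementPolarity | str,
) -> np.ndarray:
    """Binary lesion mask over the ROI under the modality's polarity.

    'hyper': lesion = values strictly above the threshold; 'hypo': strictly
    below.  Threshold-coincident pixels always go to the below class.  A
    degenerate (constant) ROI yields an empty lesion with a warning.
    """
    pol = _as_polarity(polarity)
    if normalized.degenerate:
        warnings.warn("degenerate ROI normalization; returning empty lesion", stacklevel=2)
        return np.zeros(normalized.image.shape, dtype=bool)
    img = normalized.image
    roi = ~np.isnan(img)
    if pol == "hyper":
        lesion = roi & (img > otsu.threshold)
    else:
        lesion = roi & (img < otsu.threshold)
    return lesion


def area_fraction(lesion_mask: np.ndarray, mask: MyocardialMask | np.ndarray) -> float:
    """Enhancement size in percent: 100 x lesion pixels / myocardium pixels."""
    m = mask.mask if isinstance(mask, MyocardialMask) else np.asarray(mask, dtype=bool)
    lesion = np.asarray(lesion_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty myocardium mask")
    if np.any(lesion & ~m):
        raise ValueError("lesion mask extends outside the myocardium")
    return 100.0 * lesion.sum() / m.sum()


def quantify_area(
    image: ShortAxisImage,
    mask: MyocardialMask,
    polarity: EnhancementPolarity | str,
    n_bins: int = DEFAULT_BINS,
) -> tuple[float, OtsuResult | None, np.ndarray]:
    """Full area-based measurement of one slice.

    Returns (enhancement percent, OtsuResult or None when degenerate,
    lesion mask).
    """
    norm = normalize_intensity(image, mask)
    if norm.degenerate:
        return 0.0, None, np.zeros(mask.mask.shape, dtype=bool)
    hist = IntensityHistogram.from_values(norm.values, n_bins=n_bins)
    otsu = otsu_threshold(hist)
    lesion = segment_enhanced(norm, otsu, polarity)
    return area_fraction(lesion, mask), otsu, lesion
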