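"""Sector-based quantification: 360 radial segments around the LV center.

Each myocardial pixel is assigned to the 1-degree sector containing its
pixel-center angle around the LV center (same angular convention as the
phantom generator: 0 degrees along +x, counterclockwise in (x, y), bins
half-open ``[k, k+1)``).  The sector value is the mean normalized
intensity of its member pixels; the per-sector values are then Otsu
thresholded and the enhancement size is the percentage of enhanced
sectors among valid (non-empty) sectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from lvquant.roi import MyocardialMask
from lvquant.threshold import (
    EnhancementPolarity,
    IntensityHistogram,
    NormalizedROI,
    OtsuResult,
    _as_polarity,
    otsu_threshold,
)

N_SECTORS = 360
SECTOR_BINS = 64  # histogram bins for Otsu on <=360 sector values


@dataclass
class SectorProfile:
    """Per-sector mean normalized intensity at 1-degree resolution.

    ``values`` is length 360 with NaN marking empty sectors;
    ``pixel_counts`` gives the myocardial pixel count per sector.
    """

    values: np.ndarray
    pixel_counts: np.ndarray
    center: tuple[float, float]
    angle_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.values) != N_SECTORS or len(self.pixel_counts) != N_SECTORS:
            raise ValueError("profile must have exactly 360 sectors")

    @property
    def valid(self) -> np.ndarray:
        return self.pixel_counts > 0


@dataclass
class SectorQuantification:
    """Otsu-thresholded sector measurement."""

    threshold: float
    enhanced: np.ndarray  # per-sector flag; False for empty sectors
    enhanced_sectors: int
    valid_sectors: int
    otsu: OtsuResult

    @property
    def fraction(self) -> float:
        return 100.0 * self.enhanced_sectors / self.valid_sectors


def sector_values(
    normalized: NormalizedROI,
    mask: MyocardialMask,
    center: tuple[float, float] | None = None,
    angle_offset: float = 0.0,
) -> SectorProfile:
    """Build the 360-sector radial profile of normalized ROI intensities.

    ``angle_offset`` (degrees) rotates the angular origin, e.g. for
    anatomical alignment.  Raises when more than 25% of sectors are empty,
    which usually means the center lies outside the cavity.
    """
    cx, cy = center if center is not None else mask.center
    rows, cols = np.nonzero(mask.mask)
    theta = (np.degrees(np.arctan2(rows - cy, cols - cx)) - angle_offset) % 360.0
    sector = np.floor(theta).astype(int) % N_SECTORS
    vals = normalized.image[rows, cols]

    counts = np.bincount(sector, minlength=N_SECTORS)
    sums = np.bincount(sector, weights=vals, minlength=N_SECTORS)
    values = np.full(N_SECTORS, np.nan)
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]

    n_empty = int((~nz).sum())
    if n_empty > 0.25 * N_SECTORS:
        raise ValueError(
            f"{n_empty}/360 sectors are empty; the center is likely outside the LV cavity"
        )
    return SectorProfile(
        values=values, pixel_counts=counts, center=(cx, cy), angle_offset=angle_offset
    )


def sector_quantify(
    profile: SectorProfile,
    polarity: EnhancementPolarity | str,
    n_bins: int = SECTOR_BINS,
) -> SectorQuantification:
    """Otsu-threshold the valid sector values and count enhanced sectors.

    Empty sectors are excluded from both numerator and denominator.
    Threshold-coincident sectors go to the below class, as in the
    area-based segmentation.
    """
    pol = _as_polarity(polarity)
    valid = profile.valid
    vals = profile.values[valid]
    if len(np.unique(vals)) < 2:
        raise ValueError("all sector values are equal; no threshold exists")
    hist = IntensityHistogram.from_values(vals, n_bins=n_bins)
    otsu = otsu_threshold(hist)
    enhanced = np.zeros(N_SECTORS, dtype=bool)
    if pol == "hyper":
        enhanced[valid] = profile.values[valid] > otsu.threshold
    else:
        enhanced[valid] = profile.values[valid] < otsu.threshold
    return SectorQuantification(
        threshold=otsu.threshold,
        enhanced=enhanced,
        enhanced_sectors=int(enhanced.sum()),
        valid_sectors=int(valid.sum()),
        otsu=otsu,
    )


def radial_profile_export(
    profile: SectorProfile,
    quant: SectorQuantification,
    path: str | Path,
    plot: bool = False,
) -> Path:
    """Write the radial profile as TSV (sector, value, pixel_count, enhanced);
    optionally also a PNG plot next to it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "sector": np.arange(N_SECTORS),
            "value": profile.values,
            "pixel_count": profile.pixel_counts,
            "enhanced": quant.enhanced.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    if plot:
        _plot_profile(profile, quant, path.with_suffix(".png"))
    return path


def read_radial_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _plot_profile(profile: SectorProfile, quant: SectorQuantification, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(N_SECTORS)
    ax.plot(x, profile.values, lw=0.8, color="k")
    ax.fill_between(x, 0, 1, where=quant.enhanced, alpha=0.3, color="green",
                    transform=ax.get_xaxis_transform())
    ax.axhline(quant.threshold, ls="--", color="gray")
    ax.set_xlabel("sector (degrees)")
    ax.set_ylabel("mean normalized intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
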