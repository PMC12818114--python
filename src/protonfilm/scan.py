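"""Scanned-film image handling: TIFF I/O, ROI statistics and net optical density.

A film piece is scanned in transmission mode before and after irradiation
(48-bit RGB, colour corrections off). The dose surrogate is the net optical
density per colour channel,

    netOD = log10(I0 / I),

where ``I0`` and ``I`` are the mean scanner signals of the unexposed and
exposed film over a central region of interest. The uncertainty follows from
first-order propagation of the relative signal errors; two published variants
of the formula are supported (see :func:`compute_netod`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from ._constants import CHANNELS, LN10
from .profiles import DoseProfile

__all__ = [
    "ScanFrame",
    "ROI",
    "ChannelStats",
    "NetODTriplet",
    "load_scan",
    "save_scan",
    "central_roi",
    "roi_stats",
    "compute_netod",
    "netod_triplet",
    "netod_map",
    "extract_profile",
]


@dataclass
class ScanFrame:
    """One scanner acquisition: co-registered RGB rasters plus metadata.

    Pixels are stored as float64 in 16-bit count units ([0, 65535]) so that
    synthetic noiseless frames are not quantised; :func:`save_scan` rounds to
    uint16 on write.
    """

    pixels: np.ndarray  # (H, W, 3)
    dpi: float = 300.0
    acquired_at_h: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ScanFrame requires an (H, W, 3) RGB raster")
        if self.pixels.min() < 0 or self.pixels.max() > 65535:
            raise ValueError("pixel values must lie in [0, 65535]")
        if not self.dpi > 0:
            raise ValueError("dpi must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[:, :, CHANNELS.index(name)]

    @property
    def pixel_pitch_mm(self) -> float:
        return 25.4 / self.dpi


@dataclass(frozen=True)
class ROI:
    """Axis-aligned rectangle, 0-based, half-open extent."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValueError("ROI must be at least 4x4 pixels")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")


@dataclass(frozen=True)
class ChannelStats:
    """Mean, sample standard deviation and pixel count of one channel ROI."""

    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class NetODTriplet:
    """Per-channel netOD and uncertainty for one film piece at one time point."""

    netod: np.ndarray  # length 3, channel order red/green/blue
    sigma: np.ndarray
    sigma_form: str = "standard"
    time_h: float | None = None

    def __getitem__(self, channel: str) -> tuple[float, float]:
        i = CHANNELS.index(channel)
        return float(self.netod[i]), float(self.sigma[i])


def save_scan(frame: ScanFrame, path: str | Path) -> None:
    """Write a frame as 48-bit RGB TIFF (16 bits/channel) with a DPI tag."""
    data = np.rint(frame.pixels).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="rgb",
        resolution=(frame.dpi, frame.dpi),
        resolutionunit="INCH",
    )


def load_scan(path: str | Path) -> ScanFrame:
    """Read a 16-bit RGB TIFF into a :class:`ScanFrame`.

    Raises
    ------
    ValueError
        If the file is not RGB with 16 bits per channel.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.dtype != np.uint16 or data.ndim != 3 or data.shape[2] != 3:
            raise ValueError(
                f"{path.name}: expected 48-bit RGB TIFF (16 bits/channel, 3 channels), "
                f"got dtype={data.dtype}, shape={data.shape}"
            )
        dpi = 300.0
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if den:
                dpi = num / den
    return ScanFrame(pixels=data.astype(np.float64), dpi=dpi)


def central_roi(frame: ScanFrame, fraction: float = 0.5) -> ROI:
    """Centered rectangle covering ``fraction`` of each frame dimension.

    The central region minimises cut-edge and lateral scanner effects; 50 %
    of each dimension is the package convention.
    """
    h, w = frame.shape
    rw = max(4, int(round(w * fraction)))
    rh = max(4, int(round(h * fraction)))
    return ROI(x0=(w - rw) // 2, y0=(h - rh) // 2, width=rw, height=rh)


def roi_stats(frame: ScanFrame, roi: ROI) -> dict[str, ChannelStats]:
    """Per-channel mean and sample SD over an ROI.

    The ROI must lie within the frame and contain at least 16 pixels.
    """
    h, w = frame.shape
    if roi.x0 + roi.width > w or roi.y0 + roi.height > h:
        raise ValueError(f"ROI {roi} exceeds frame bounds {w}x{h}")
    n = roi.width * roi.height
    if n < 16:
        raise ValueError(f"ROI has {n} pixels; at least 16 required")
    patch = frame.pixels[roi.y0 : roi.y0 + roi.height, roi.x0 : roi.x0 + roi.width, :]
    out = {}
    for i, ch in enumerate(CHANNELS):
        vals = patch[:, :, i]
        out[ch] = ChannelStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=n)
    return out


def _sigma_netod(
    netod: float,
    pre: ChannelStats,
    post: ChannelStats,
    sigma_form: str,
    sigma_mode: str,
) -> float:
    if sigma_mode == "sem":
        s0, s1 = pre.sd / np.sqrt(pre.n), post.sd / np.sqrt(post.n)
    elif sigma_mode == "pixel":
        s0, s1 = pre.sd, post.sd
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r} (use 'sem' or 'pixel')")
    rel = np.sqrt((s0 / pre.mean) ** 2 + (s1 / post.mean) ** 2) / LN10
    if sigma_form == "standard":
        return float(rel)
    if sigma_form == "paper":
        return float(abs(netod) * rel)
    raise ValueError(f"unknown sigma_form {sigma_form!r} (use 'standard' or 'paper')")


def compute_netod(
    pre: ChannelStats,
    post: ChannelStats,
    sigma_form: str = "standard",
    sigma_mode: str = "sem",
) -> tuple[float, float]:
    """netOD of one channel from pre/post ROI statistics, with uncertainty.

    ``netod = log10(pre.mean / post.mean)``. The uncertainty combines the
    relative errors of the two means:

    * ``sigma_form='standard'`` — sigma = (1/ln 10) * sqrt((s0/I0)^2 + (s1/I)^2),
      the usual first-order propagation of log10(I0/I);
    * ``sigma_form='paper'`` — the same quantity multiplied by netOD, a variant
      seen in the film literature (it vanishes at netOD=0).

    ``sigma_mode`` selects whether s0/s1 are standard errors of the ROI mean
    (``'sem'``, default — the mean is the estimator being propagated) or raw
    pixel SDs (``'pixel'``).

    Raises
    ------
    ValueError
        If either mean is non-positive, or the exposed film reads brighter
        than baseline by more than the 3-sigma noise floor.
    """
    if pre.mean <= 0 or post.mean <= 0:
        raise ValueError("channel means must be positive to form netOD")
    netod = float(np.log10(pre.mean / post.mean))
    sigma = _sigma_netod(netod, pre, post, sigma_form, sigma_mode)
    if netod < 0 and abs(netod) > 3 * max(sigma, np.finfo(float).tiny):
        raise ValueError(
            f"film lighter than baseline: netOD={netod:.4g} below -3*sigma ({sigma:.4g})"
        )
    return netod, sigma


def netod_triplet(
    pre: ScanFrame,
    post: ScanFrame,
    roi: ROI | None = None,
    sigma_form: str = "standard",
    sigma_mode: str = "sem",
) -> NetODTriplet:
    """netOD of all three channels over a common ROI (default: central 50 %)."""
    if roi is None:
        roi = central_roi(pre)
    s_pre = roi_stats(pre, roi)
    s_post = roi_stats(post, roi)
    netods, sigmas = np.empty(3), np.empty(3)
    for i, ch in enumerate(CHANNELS):
        netods[i], sigmas[i] = compute_netod(s_pre[ch], s_post[ch], sigma_form, sigma_mode)
    return NetODTriplet(
        netod=netods, sigma=sigmas, sigma_form=sigma_form, time_h=post.acquired_at_h
    )


def netod_map(pre: ScanFrame, post: ScanFrame) -> np.ma.MaskedArray:
    """Per-pixel netOD raster per channel.

    Returns an (H, W, 3) masked array; pixels where either frame is
    non-positive are masked invalid rather than raising.
    """
    if pre.shape != post.shape:
        raise ValueError(f"frame dimensions differ: {pre.shape} vs {post.shape}")
    invalid = (post.pixels <= 0) | (pre.pixels <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(invalid, 1.0, pre.pixels / np.where(invalid, 1.0, post.pixels))
        od = np.log10(ratio)
    return np.ma.MaskedArray(od, mask=invalid)


def extract_profile(
    raster: np.ndarray,
    axis: str,
    band_halfwidth: int,
    dpi: float,
    source: str = "film-R",
    origin: str = "start",
) -> DoseProfile:
    """Collapse a 2-D netOD raster to a 1-D profile along one axis.

    For ``axis='depth'`` the profile runs along columns (one value per
    column, averaged over the central horizontal band of
    ``2*band_halfwidth+1`` rows); for ``axis='lateral'`` it runs along rows.
    Positions are in mm (pixel pitch 25.4/dpi), measured from the first
    sample (``origin='start'``) or from the raster centre
    (``origin='center'``).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2:
        raise ValueError("raster must be 2-D (single channel)")
    if axis not in ("depth", "lateral"):
        raise ValueError("axis must be 'depth' or 'lateral'")
    h, w = raster.shape
    band = 2 * band_halfwidth + 1
    along_cols = axis == "depth"
    extent = h if along_cols else w
    if band > extent:
        raise ValueError(f"band of {band} rows/cols exceeds raster extent {extent}")
    c = extent // 2
    lo = max(0, c - band_halfwidth)
    strip = raster[lo : lo + band, :] if along_cols else raster[:, lo : lo + band]
    values = strip.mean(axis=0) if along_cols else strip.mean(axis=1)
    pitch = 25.4 / dpi
    npos = values.size
    idx = np.arange(npos, dtype=float)
    if origin == "center":
        idx -= (npos - 1) / 2.0
    elif origin != "start":
        raise ValueError("origin must be 'start' or 'center'")
    return DoseProfile(
        positions_mm=idx * pitch,
        values=values,
        geometry=axis,
        source=source,
        check_nonnegative=False,
    )
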