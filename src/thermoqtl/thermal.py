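"""Radiometric thermal image processing.

Converts 16-bit sensor counts to temperature with the camera's Planck-style
calibration curve

    T(raw) = PB / log(PR1 / (PR2 * (raw + PO)) + PF) - 273.15   [degC]

segments the plant canopy from its background by histogram thresholding of
the temperature image (default: the MEAN method, i.e. the threshold is the
arithmetic mean of all finite pixels), and reports the mean temperature over
the canopy region of interest.  Batch processing over image files mirrors
the macro-driven single-image workflow exactly.

The calibration log defaults to the natural logarithm (standard radiometric
practice); ``log_base="10"`` is available as a config switch.  All
conversions are exactly invertible up to 16-bit quantization, which the
scene simulator relies on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, DomainError, EmptyRoiError, InvalidParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CameraCalibration",
    "RadiometricImage",
    "SegmentationResult",
    "CanopyMeasurement",
    "raw_to_temperature",
    "temperature_to_raw",
    "emissivity_correct",
    "mean_threshold",
    "median_threshold",
    "otsu_threshold",
    "THRESHOLD_METHODS",
    "segment_canopy",
    "canopy_temperature",
    "process_batch",
    "read_radiometric",
    "write_radiometric",
]

RAW_MAX = 65535


@dataclass(frozen=True)
class CameraCalibration:
    """Sensor calibration constants for the raw <-> temperature curve.

    PB, PR1, PR2, PO, PF are camera-specific Planck calibration constants
    (normally extracted from image metadata and supplied here via config).
    ``log_base`` selects the logarithm in the conversion ("natural" or
    "10").  ``emissivity`` and ``reflected_temperature`` drive the optional
    reflected-component correction.
    """

    PB: float = 1428.0
    PR1: float = 21106.77
    PR2: float = 0.012545258
    PO: float = -7340.0
    PF: float = 1.0
    log_base: str = "natural"
    emissivity: float = 0.97
    reflected_temperature: float = 20.0

    def __post_init__(self):
        if self.PB <= 0 or self.PR1 <= 0 or self.PR2 <= 0:
            raise InvalidParameterError("PB, PR1 and PR2 must be > 0")
        if not (0.0 < self.emissivity <= 1.0):
            raise InvalidParameterError("emissivity must lie in (0, 1]")
        if self.log_base not in ("natural", "10"):
            raise InvalidParameterError("log_base must be 'natural' or '10'")

    def _log(self, x):
        return np.log(x) if self.log_base == "natural" else np.log10(x)

    def _exp(self, x):
        return np.exp(x) if self.log_base == "natural" else np.power(10.0, x)

    @classmethod
    def from_dict(cls, d: dict) -> "CameraCalibration":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "CameraCalibration":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class RadiometricImage:
    """16-bit single-channel sensor-count raster."""

    def __init__(self, counts):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise DataError("radiometric image must be 2-D")
        if np.any((counts < 0) | (counts > RAW_MAX)):
            raise DataError("counts outside the 16-bit range [0, 65535]")
        self.counts = counts.astype(np.uint16)

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class SegmentationResult:
    """Foreground mask at threshold ``tmin`` with the given polarity."""

    tmin: float
    mask: np.ndarray          # bool, True = foreground
    polarity: str             # "above" or "below"
    masked: np.ndarray        # temperature image with background set to NaN


@dataclass
class CanopyMeasurement:
    sample_id: str
    canopy_temperature: float  # degC, mean over the mask
    pixel_count: int
    threshold: float
    timepoint: float = float("nan")  # hours of deficit, optional


# ---------------------------------------------------------------------------
# raw <-> temperature
# ---------------------------------------------------------------------------
def raw_to_temperature(img: RadiometricImage, calib: CameraCalibration) -> np.ndarray:
    """Per-pixel temperature (degC) from sensor counts.

    Strictly increasing in raw over the valid domain.  Raises DomainError,
    naming a pixel, if the logarithm argument is <= 1 anywhere (the curve is
    only defined for positive log, i.e. positive absolute temperature).
    """
    raw = np.asarray(img.counts if isinstance(img, RadiometricImage) else img, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = calib.PR1 / (calib.PR2 * (raw + calib.PO)) + calib.PF
    bad = ~np.isfinite(arg) | (arg <= 1.0)
    if np.any(bad):
        r, c = np.argwhere(bad)[0]
        raise DomainError(
            f"raw value {raw[r, c]} at pixel ({r}, {c}) is outside the "
            "invertible domain of the calibration curve (log argument <= 1)"
        )
    return calib.PB / calib._log(arg) - 273.15


def temperature_to_raw(T, calib: CameraCalibration) -> RadiometricImage:
    """Exact algebraic inverse of :func:`raw_to_temperature`.

    raw = PR1 / (PR2 * (base^(PB / (T + 273.15)) - PF)) - PO, rounded to the
    nearest integer and clipped to [0, 65535] (clipping is logged).
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise DomainError("non-finite temperatures")
    denom = calib._exp(calib.PB / (T + 273.15)) - calib.PF
    if np.any(denom <= 0):
        raise DomainError(
            "temperature outside the invertible range of the calibration "
            "curve (base^(PB/(T+273.15)) - PF must be > 0)"
        )
    raw = calib.PR1 / (calib.PR2 * denom) - calib.PO
    raw = np.rint(raw)
    n_clip = int(np.sum((raw < 0) | (raw > RAW_MAX)))
    if n_clip:
        logger.warning("temperature_to_raw: clipping %d pixels to [0, %d]", n_clip, RAW_MAX)
    return RadiometricImage(np.clip(raw, 0, RAW_MAX))


def emissivity_correct(img: RadiometricImage, calib: CameraCalibration) -> RadiometricImage:
    """Remove the reflected ambient component from observed counts.

    The sensor sees  observed = eps * object + (1 - eps) * reflected  in
    count space; the object signal is recovered as
    (observed - (1 - eps) * raw_reflected) / eps.  Identity when eps = 1.
    """
    eps = calib.emissivity
    if eps == 1.0:
        return RadiometricImage(img.counts.copy())
    refl = float(
        temperature_to_raw(np.array([[calib.reflected_temperature]]), calib).counts[0, 0]
    )
    corrected = (img.counts.astype(float) - (1.0 - eps) * refl) / eps
    corrected = np.rint(corrected)
    n_clip = int(np.sum((corrected < 0) | (corrected > RAW_MAX)))
    if n_clip:
        logger.warning("emissivity_correct: clipping %d pixels", n_clip)
    return RadiometricImage(np.clip(corrected, 0, RAW_MAX))


# ---------------------------------------------------------------------------
# thresholding and segmentation
# ---------------------------------------------------------------------------
def _finite(T: np.ndarray) -> np.ndarray:
    vals = np.asarray(T, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRoiError("image has no finite pixels")
    return vals


def mean_threshold(T) -> float:
    """The MEAN method: threshold = arithmetic mean of all finite pixels."""
    return float(np.mean(_finite(T)))


def median_threshold(T) -> float:
    return float(np.median(_finite(T)))


def otsu_threshold(T, nbins: int = 256) -> float:
    """Otsu's between-class variance maximization on a histogram of the
    finite pixels; returned on the intensity scale of the image."""
    vals = _finite(T)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return lo
    hist, edges = np.histogram(vals, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    p = w / w.sum()
    omega = np.cumsum(p)
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # the criterion plateaus across empty gaps between modes; take the
    # middle of the maximizing plateau
    top = np.flatnonzero(sigma_b >= sigma_b.max() - 1e-12)
    return float(centers[top[len(top) // 2]])


THRESHOLD_METHODS = {
    "mean": mean_threshold,
    "median": median_threshold,
    "otsu": otsu_threshold,
}


def segment_canopy(T, tmin: float, polarity: str = "below") -> SegmentationResult:
    """Label foreground pixels against the threshold ``tmin``.

    ``polarity="above"`` labels a pixel foreground iff its intensity
    g(x) >= tmin; ``"below"`` labels iff g(x) < tmin (a transpiring canopy
    is typically cooler than the background board).  Background pixels are
    set to NaN in a copy of the temperature image.
    """
    if not math.isfinite(tmin):
        raise DomainError("tmin must be finite")
    if polarity not in ("above", "below"):
        raise InvalidParameterError("polarity must be 'above' or 'below'")
    T = np.asarray(T, dtype=float)
    finite = np.isfinite(T)
    if polarity == "above":
        mask = finite & (T >= tmin)
    else:
        mask = finite & (T < tmin)
    if mask.sum() == 0:
        raise EmptyRoiError(f"no pixels {polarity} threshold {tmin}")
    masked = np.where(mask, T, np.nan)
    return SegmentationResult(tmin=float(tmin), mask=mask, polarity=polarity, masked=masked)


def canopy_temperature(
    T, seg: SegmentationResult, sample_id: str = "", timepoint: float = float("nan")
) -> CanopyMeasurement:
    """Mean temperature over the segmented canopy."""
    T = np.asarray(T, dtype=float)
    vals = T[seg.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRoiError("empty foreground")
    return CanopyMeasurement(
        sample_id=sample_id,
        canopy_temperature=float(vals.mean()),
        pixel_count=int(vals.size),
        threshold=seg.tmin,
        timepoint=timepoint,
    )


# ---------------------------------------------------------------------------
# image I/O and batch processing
# ---------------------------------------------------------------------------
def read_radiometric(path) -> RadiometricImage:
    """Read a 16-bit grayscale PNG or a plain numeric CSV matrix."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return RadiometricImage(np.loadtxt(path, delimiter=",", ndmin=2))
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim != 2:
        raise DataError(f"{path}: expected a single-channel image")
    return RadiometricImage(arr)


def write_radiometric(img: RadiometricImage, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, img.counts, fmt="%d", delimiter=",")
        return
    import imageio.v3 as iio

    iio.imwrite(path, img.counts.astype(np.uint16))


def process_batch(
    image_paths,
    calib: CameraCalibration,
    polarity: str = "below",
    method: str = "mean",
    emissivity_correction: bool = False,
) -> pd.DataFrame:
    """Run the single-image workflow over many files.

    Returns one row per image, ordered by path; per-image failures are
    recorded in the ``error`` column without aborting the batch.
    """
    if method not in THRESHOLD_METHODS:
        raise InvalidParameterError(
            f"unknown threshold method {method!r}; choose from {sorted(THRESHOLD_METHODS)}"
        )
    rows = []
    for path in sorted(str(p) for p in image_paths):
        rec = {
            "sample_id": Path(path).stem,
            "path": path,
            "canopy_temp_C": np.nan,
            "pixel_count": 0,
            "threshold_C": np.nan,
            "error": "",
        }
        try:
            img = read_radiometric(path)
            if emissivity_correction:
                img = emissivity_correct(img, calib)
            T = raw_to_temperature(img, calib)
            tmin = THRESHOLD_METHODS[method](T)
            seg = segment_canopy(T, tmin, polarity)
            meas = canopy_temperature(T, seg, sample_id=rec["sample_id"])
            rec.update(
                canopy_temp_C=meas.canopy_temperature,
                pixel_count=meas.pixel_count,
                threshold_C=meas.threshold,
            )
        except Exception as exc:  # per-row error record, batch continues
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(
        rows, columns=["sample_id", "path", "canopy_temp_C", "pixel_count", "threshold_C", "error"]
    )
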