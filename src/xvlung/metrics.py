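"""Scalar ventilation metrics and phase-resolved ROI analysis.

The metrics summarize a 3D specific-ventilation (SV) map over a lung mask:

* **MSV** — mean specific ventilation: arithmetic mean of SV over the mask.
* **V_T** — tidal volume: Σ SV × voxel volume, reported in ml.
* **VDP / nVDP** — ventilation defect percentage: percent of lung voxels
  with SV strictly below ``threshold_fraction`` (default 0.6) times a
  reference MSV. The animal's own MSV gives VDP; a control-population MSV
  gives the normalized variant nVDP.
* **VH** — ventilation heterogeneity: interquartile range of SV divided by
  MSV (scale-free). **VH_SS / VH_LS** split VH into small-scale (intra-lobe)
  and large-scale (inter-lobe) components via a masked Gaussian low-pass
  filter: VH_LS is the VH of the low-pass field; VH_SS is the IQR of the
  high-pass residual divided by the *original* mean (the residual itself is
  ~zero-mean, so its own mean cannot normalize it).

All metrics are computed strictly over the mask: out-of-mask voxels never
contribute, including through the spatial filter (renormalized masked
convolution). Quantiles use linear interpolation between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volumes import CTVolume, LungMask, PhaseSeries, VentilationVolume

__all__ = [
    "XVMetrics",
    "ROICurve",
    "compute_msv",
    "compute_tidal_volume",
    "compute_vdp",
    "compute_vh",
    "decompose_scales",
    "compute_vh_scales",
    "extract_roi_curve",
    "mean_ct_gray",
    "compute_xv_metrics",
]

#: fraction of the reference MSV defining a ventilation defect
DEFAULT_THRESHOLD_FRACTION = 0.6
#: Gaussian standard deviation (mm) separating intra- from inter-lobe scales
DEFAULT_CUTOFF_MM = 2.0


@dataclass
class XVMetrics:
    """Per-animal scalar XV outputs."""

    msv: float
    vt_ml: float
    vdp_pct: float
    nvdp_pct: float
    vh: float
    vh_ss: float
    vh_ls: float
    mean_ct_gray: float
    threshold_fraction: float
    reference_msv: float
    cutoff_mm: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


@dataclass
class ROICurve:
    """Mean ± SD specific ventilation in a region across breath phases."""

    phase_means: np.ndarray
    phase_sds: np.ndarray
    roi_bounds_mm: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        self.phase_means = np.asarray(self.phase_means, dtype=float)
        self.phase_sds = np.asarray(self.phase_sds, dtype=float)
        if self.phase_means.shape != self.phase_sds.shape:
            raise ValueError("phase_means and phase_sds must have equal length")


def _final_volume(series_or_volume: PhaseSeries | VentilationVolume) -> VentilationVolume:
    if isinstance(series_or_volume, PhaseSeries):
        return series_or_volume.final
    return series_or_volume


def _masked(volume: VentilationVolume | CTVolume, mask: LungMask) -> np.ndarray:
    if volume.shape != mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match mask shape {mask.shape}"
        )
    if mask.n_voxels < 1:
        raise ValueError("empty lung mask")
    return volume.values[mask.values]


def compute_msv(series_or_volume: PhaseSeries | VentilationVolume, mask: LungMask) -> float:
    """Mean specific ventilation over the lung mask.

    Given a full :class:`PhaseSeries`, the final phase (peak exhalation to
    peak inspiration) is used, which is the full-breath SV the scalar
    metrics are defined on.
    """
    return float(np.mean(_masked(_final_volume(series_or_volume), mask)))


def compute_tidal_volume(
    series_or_volume: PhaseSeries | VentilationVolume, mask: LungMask
) -> float:
    """Tidal volume in ml: Σ SV × voxel volume (mm³ → ml)."""
    vol = _final_volume(series_or_volume)
    sv = _masked(vol, mask)
    return float(sv.sum() * vol.voxel_volume_mm3 * 1e-3)


def compute_vdp(
    series_or_volume: PhaseSeries | VentilationVolume,
    mask: LungMask,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    reference_msv: float | None = None,
) -> float:
    """Ventilation defect percentage.

    Percent of masked voxels with SV strictly below
    ``threshold_fraction × reference_msv``. ``reference_msv=None`` uses the
    volume's own MSV (VDP); passing a control-population MSV yields nVDP.
    """
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    sv = _masked(_final_volume(series_or_volume), mask)
    if reference_msv is None:
        reference_msv = float(np.mean(sv))
    if reference_msv <= 0:
        raise ValueError("non-positive reference MSV")
    n_defect = int(np.count_nonzero(sv < threshold_fraction * reference_msv))
    return 100.0 * n_defect / sv.size


def compute_vh(
    series_or_volume: PhaseSeries | VentilationVolume,
    mask: LungMask,
    quantile_method: str = "linear",
) -> float:
    """Ventilation heterogeneity: IQR of SV divided by its mean."""
    sv = _masked(_final_volume(series_or_volume), mask)
    mean = float(np.mean(sv))
    if mean == 0:
        raise ValueError("undefined VH for zero-mean field")
    q1, q3 = np.quantile(sv, [0.25, 0.75], method=quantile_method)
    return float((q3 - q1) / mean)


def decompose_scales(
    series_or_volume: PhaseSeries | VentilationVolume,
    mask: LungMask,
    cutoff_mm: float = DEFAULT_CUTOFF_MM,
) -> tuple[VentilationVolume, VentilationVolume]:
    """Split a field into large-scale (low-pass) and small-scale components.

    The low-pass field is a masked, renormalized Gaussian smoothing with
    standard deviation ``cutoff_mm`` (converted to voxels per axis); the
    high-pass field is the residual. Out-of-mask voxels carry zero weight so
    they never leak into in-mask averages; both outputs are zero outside the
    mask, and ``low + high == original`` on the mask by construction.
    """
    vol = _final_volume(series_or_volume)
    if vol.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if mask.n_voxels < 1:
        raise ValueError("empty lung mask")
    if cutoff_mm <= 0:
        raise ValueError("cutoff_mm must be > 0")
    if cutoff_mm < min(vol.spacing):
        raise ValueError("cutoff_mm smaller than one voxel")
    sigma_vox = [cutoff_mm / s for s in vol.spacing]
    m = mask.values.astype(float)
    num = ndimage.gaussian_filter(vol.values * m, sigma_vox, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(m, sigma_vox, mode="constant", cval=0.0)
    low = np.zeros_like(vol.values)
    inside = mask.values
    low[inside] = num[inside] / den[inside]
    high = np.zeros_like(vol.values)
    high[inside] = vol.values[inside] - low[inside]
    mk = dict(spacing=vol.spacing, origin=vol.origin, phase_index=vol.phase_index)
    return VentilationVolume(low, **mk), VentilationVolume(high, **mk)


def compute_vh_scales(
    series_or_volume: PhaseSeries | VentilationVolume,
    mask: LungMask,
    cutoff_mm: float = DEFAULT_CUTOFF_MM,
    quantile_method: str = "linear",
) -> tuple[float, float]:
    """Small- and large-scale ventilation heterogeneity ``(vh_ss, vh_ls)``.

    vh_ls is the VH of the low-pass field; vh_ss is the IQR of the high-pass
    residual normalized by the original field's in-mask mean.
    """
    vol = _final_volume(series_or_volume)
    low, high = decompose_scales(vol, mask, cutoff_mm)
    mean = float(np.mean(vol.values[mask.values]))
    if mean == 0:
        raise ValueError("undefined VH for zero-mean field")
    vh_ls = compute_vh(low, mask, quantile_method=quantile_method)
    q1, q3 = np.quantile(high.values[mask.values], [0.25, 0.75], method=quantile_method)
    vh_ss = float((q3 - q1) / mean)
    return vh_ss, vh_ls


def roi_index_mask(
    volume: VentilationVolume,
    roi_bounds_mm: tuple[tuple[float, float], ...],
) -> np.ndarray:
    """Boolean grid of voxels whose centers fall in the half-open mm box."""
    if len(roi_bounds_mm) != 3:
        raise ValueError("roi_bounds_mm must give (lo, hi) for three axes")
    sel = np.ones(volume.shape, dtype=bool)
    for axis, (lo, hi) in enumerate(roi_bounds_mm):
        centers = volume.origin[axis] + (np.arange(volume.shape[axis]) + 0.5) * volume.spacing[axis]
        axis_sel = (centers >= lo) & (centers < hi)
        sel &= np.expand_dims(
            axis_sel, axis=tuple(a for a in range(3) if a != axis)
        )
    return sel


def extract_roi_curve(
    series: PhaseSeries,
    roi_bounds_mm: tuple[tuple[float, float], ...],
    mask: LungMask | None = None,
    label: str = "",
) -> ROICurve:
    """Mean and SD specific ventilation over (mask ∩ ROI) at every phase.

    With the ROI set to the whole-lung bounding box this reproduces the
    whole-lung inflation curve the regional curves are compared against.
    """
    mask = mask if mask is not None else series.mask
    if mask is None:
        raise ValueError("a lung mask is required")
    roi = roi_index_mask(series.volumes[0], roi_bounds_mm) & mask.values
    if not roi.any():
        raise ValueError("ROI does not intersect the lung mask")
    means = np.array([float(np.mean(v.values[roi])) for v in series.volumes])
    sds = np.array([float(np.std(v.values[roi])) for v in series.volumes])
    return ROICurve(means, sds, tuple(tuple(map(float, b)) for b in roi_bounds_mm), label)


def mean_ct_gray(ct: CTVolume, mask: LungMask) -> float:
    """Average CT gray value over the lung mask (scanner units)."""
    return float(np.mean(_masked(ct, mask)))


def compute_xv_metrics(
    series: PhaseSeries,
    ct: CTVolume,
    mask: LungMask | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    cutoff_mm: float = DEFAULT_CUTOFF_MM,
    reference_msv: float | None = None,
) -> XVMetrics:
    """Compute the full scalar metric panel for one animal.

    ``reference_msv`` is the control-population MSV used for nVDP; if None,
    nVDP falls back to the animal's own MSV (i.e. equals VDP).
    """
    mask = mask if mask is not None else series.mask
    if mask is None:
        raise ValueError("a lung mask is required")
    vol = series.final
    msv = compute_msv(vol, mask)
    ref = msv if reference_msv is None else float(reference_msv)
    vh_ss, vh_ls = compute_vh_scales(vol, mask, cutoff_mm)
    return XVMetrics(
        msv=msv,
        vt_ml=compute_tidal_volume(vol, mask),
        vdp_pct=compute_vdp(vol, mask, threshold_fraction, reference_msv=None),
        nvdp_pct=compute_vdp(vol, mask, threshold_fraction, reference_msv=ref),
        vh=compute_vh(vol, mask),
        vh_ss=vh_ss,
        vh_ls=vh_ls,
        mean_ct_gray=mean_ct_gray(ct, mask),
        threshold_fraction=threshold_fraction,
        reference_msv=ref,
        cutoff_mm=cutoff_mm,
    )
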