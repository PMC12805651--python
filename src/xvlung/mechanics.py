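"""Forced-oscillation and maneuver-based lung mechanics estimation.

Implements the standard small-animal ventilator parameter battery:

* **Deep inflation** → inspiratory capacity (IC).
* **Single-compartment model** ``P = R·V̇ + V/C + P0`` fitted to a sinusoidal
  ventilation snapshot → respiratory-system resistance R_rs and compliance
  C_rs.
* **Constant-phase model** ``Z(f) = R_n + i·2πf·I + (G − iH)/(2πf)^α`` with
  ``α = (2/π)·arctan(H/G)`` fitted to an impedance spectrum → Newtonian
  resistance R_n, inertance I, tissue damping G, tissue elastance H.
* **Salazar–Knowles exponential** ``V(P) = A − B·e^(−K·P)`` fitted to the
  deflation limb of a stepwise pressure–volume maneuver → curvature K and
  static compliance C_st = B·K (the slope at P = 0); plus the PV loop area.
* **Negative-pressure forced expiration (NPFE)** → FEV0.05, FVC, FEF0.05.

Each regression reports a coefficient of determination (CoD); replicate
averaging excludes parameters whose governing fit has CoD < 0.9, mirroring
standard practice on commercial ventilator platforms.

Units: pressure cmH₂O, flow ml/s, volume ml, impedance cmH₂O·s/ml.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "VentilatorTrace",
    "ImpedanceSpectrum",
    "ConstantPhaseParams",
    "MechanicsRecord",
    "simulate_single_compartment",
    "fit_single_compartment",
    "constant_phase_impedance",
    "fit_constant_phase",
    "fit_pv_curve",
    "pv_loop_area",
    "npfe_metrics",
    "deep_inflation_ic",
    "aggregate_replicates",
    "COD_EXCLUSION_THRESHOLD",
]

#: fits with coefficient of determination below this are excluded
COD_EXCLUSION_THRESHOLD = 0.9

MANEUVERS = ("snapshot", "prime", "pv", "npfe", "deep_inflation")


@dataclass
class VentilatorTrace:
    """Time-aligned pressure/flow/volume channels from one maneuver."""

    time: np.ndarray          # s
    pressure: np.ndarray      # cmH2O
    flow: np.ndarray          # ml/s
    volume: np.ndarray        # ml, cumulative integral of flow
    maneuver: str = "snapshot"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.time.size
        if not (self.pressure.size == self.flow.size == self.volume.size == n):
            raise ValueError("trace channels must have equal length")
        if n >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.maneuver not in MANEUVERS:
            raise ValueError(f"unknown maneuver {self.maneuver!r}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "pressure_cmH2O": self.pressure,
                "flow_ml_s": self.flow,
                "volume_ml": self.volume,
                "maneuver": self.maneuver,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VentilatorTrace":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["pressure_cmH2O"].to_numpy(),
            df["flow_ml_s"].to_numpy(),
            df["volume_ml"].to_numpy(),
            maneuver=str(df["maneuver"].iloc[0]),
        )


@dataclass
class ImpedanceSpectrum:
    """Respiratory input impedance sampled at positive frequencies."""

    frequencies: np.ndarray   # Hz
    real_part: np.ndarray     # cmH2O.s/ml
    imag_part: np.ndarray     # cmH2O.s/ml

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.real_part = np.asarray(self.real_part, dtype=float)
        self.imag_part = np.asarray(self.imag_part, dtype=float)
        if not (self.frequencies.size == self.real_part.size == self.imag_part.size):
            raise ValueError("spectrum channels must have equal length")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be > 0")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"freq_hz": self.frequencies, "z_real": self.real_part, "z_imag": self.imag_part}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        return cls(df["freq_hz"].to_numpy(), df["z_real"].to_numpy(), df["z_imag"].to_numpy())


@dataclass
class ConstantPhaseParams:
    """Constant-phase tissue model parameters.

    The phase exponent is tied to the tissue parameters,
    ``alpha = (2/π)·arctan(h/g)``, so hysteresivity η = G/H alone sets the
    tissue phase angle.
    """

    rn: float       # Newtonian resistance, cmH2O.s/ml
    i_inert: float  # inertance, cmH2O.s^2/ml
    g: float        # tissue damping, cmH2O/ml
    h: float        # tissue elastance, cmH2O/ml

    def __post_init__(self) -> None:
        if self.g <= 0 or self.h <= 0:
            raise ValueError("tissue damping G and elastance H must be > 0")

    @property
    def alpha(self) -> float:
        return (2.0 / math.pi) * math.atan2(self.h, self.g)

    @property
    def hysteresivity(self) -> float:
        return self.g / self.h


@dataclass
class MechanicsRecord:
    """Per-animal (or per-replicate) mechanics outputs.

    Missing values are NaN. ``cod_per_fit`` maps a model name
    (``single_compartment``, ``constant_phase``, ``pv``) to the coefficient
    of determination of that fit; maneuvers without a regression (deep
    inflation, loop area, NPFE) carry no CoD and are never gated.
    """

    ic: float = math.nan
    rrs: float = math.nan
    crs: float = math.nan
    rn: float = math.nan
    i_inert: float = math.nan
    g: float = math.nan
    h: float = math.nan
    cst: float = math.nan
    k_curvature: float = math.nan
    pv_area: float = math.nan
    fev005: float = math.nan
    fvc: float = math.nan
    fef005: float = math.nan
    cod_per_fit: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        d = {k: v for k, v in self.__dict__.items() if k != "cod_per_fit"}
        for model, cod in self.cod_per_fit.items():
            d[f"cod_{model}"] = cod
        return d


#: which fitted model gates each parameter during replicate averaging
PARAM_GOVERNING_FIT: dict[str, str | None] = {
    "ic": None,
    "rrs": "single_compartment",
    "crs": "single_compartment",
    "rn": "constant_phase",
    "i_inert": "constant_phase",
    "g": "constant_phase",
    "h": "constant_phase",
    "cst": "pv",
    "k_curvature": "pv",
    "pv_area": None,
    "fev005": None,
    "fvc": None,
    "fef005": None,
}


def _cod(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination, clipped to [0, 1]."""
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - np.mean(observed)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Single-compartment model (SnapShot-style sinusoidal ventilation)
# ---------------------------------------------------------------------------


def simulate_single_compartment(
    r: float,
    c: float,
    rate_bpm: float = 150.0,
    tidal_volume_ml: float = 0.25,
    peep_cmh2o: float = 3.0,
    duration_s: float = 1.2,
    sample_rate_hz: float = 400.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> VentilatorTrace:
    """Forward-simulate ``P = R·V̇ + V/C + P0`` for a sinusoidal volume.

    The volume waveform is ``V(t) = V_T/2 · (1 − cos(2πf t))`` at the
    ventilation frequency, so it starts at 0 like an integrated flow
    channel. Gaussian noise of standard deviation ``noise_sd`` (cmH₂O) is
    added to the pressure channel only.
    """
    if c <= 0:
        raise ValueError("compliance must be > 0")
    if r < 0:
        raise ValueError("resistance must be >= 0")
    f = rate_bpm / 60.0
    t = np.arange(0.0, duration_s, 1.0 / sample_rate_hz)
    volume = 0.5 * tidal_volume_ml * (1.0 - np.cos(2 * np.pi * f * t))
    flow = 0.5 * tidal_volume_ml * 2 * np.pi * f * np.sin(2 * np.pi * f * t)
    pressure = r * flow + volume / c + peep_cmh2o
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        pressure = pressure + rng.normal(0.0, noise_sd, size=t.size)
    return VentilatorTrace(t, pressure, flow, volume, maneuver="snapshot")


def fit_single_compartment(trace: VentilatorTrace) -> tuple[float, float, float, float]:
    """Estimate (R_rs, C_rs, P0, CoD) by least squares on the equation of motion.

    Pressure is regressed on flow and volume; the elastance coefficient is
    inverted to compliance. Raises if the flow and volume channels are
    collinear (the regression is then unidentifiable).
    """
    if trace.time.size < 3:
        raise ValueError("trace too short to fit (need >= 3 samples)")
    X = np.column_stack([trace.flow, trace.volume, np.ones_like(trace.time)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("degenerate trace: flow and volume channels are collinear")
    coef, *_ = np.linalg.lstsq(X, trace.pressure, rcond=None)
    r, elastance, p0 = (float(v) for v in coef)
    if elastance <= 0:
        raise ValueError("fitted elastance is non-positive; trace inconsistent with model")
    cod = _cod(trace.pressure, X @ coef)
    return r, 1.0 / elastance, p0, cod


# ---------------------------------------------------------------------------
# Constant-phase model (Quick-Prime-style forced oscillation)
# ---------------------------------------------------------------------------


def default_prime_frequencies(n: int = 13, lo_hz: float = 1.0, hi_hz: float = 20.5) -> np.ndarray:
    """Log-spaced forced-oscillation frequencies (mouse range)."""
    return np.geomspace(lo_hz, hi_hz, n)


def constant_phase_impedance(
    params: ConstantPhaseParams, frequencies: np.ndarray
) -> ImpedanceSpectrum:
    """Evaluate ``Z(f) = R_n + i·2πf·I + (G − iH)/(2πf)^α`` exactly."""
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any(frequencies <= 0):
        raise ValueError("frequencies must be > 0")
    omega = 2 * np.pi * frequencies
    tissue = (params.g - 1j * params.h) / omega ** params.alpha
    z = params.rn + 1j * omega * params.i_inert + tissue
    return ImpedanceSpectrum(frequencies, z.real, z.imag)


def _cp_model(theta: np.ndarray, omega: np.ndarray) -> np.ndarray:
    rn, i_inert, g, h = theta
    alpha = (2.0 / math.pi) * math.atan2(h, g)
    tissue = (g - 1j * h) / omega ** alpha
    z = rn + 1j * omega * i_inert + tissue
    return np.concatenate([z.real, z.imag])


def fit_constant_phase(
    spectrum: ImpedanceSpectrum,
) -> tuple[ConstantPhaseParams, float]:
    """Nonlinear least squares for (R_n, I, G, H) with α tied to H/G.

    Residuals stack the real and imaginary parts; CoD is computed on the
    stacked vector. Initialization is from linearized estimates: R_n from
    the highest-frequency real part, H from the low-frequency reactance.
    """
    f = spectrum.frequencies
    if f.size < 4:
        raise ValueError("need >= 4 frequencies to fit the constant-phase model")
    if f[-1] / f[0] < 10 * (1 - 1e-9):
        raise ValueError("frequencies must span at least a decade")
    omega = 2 * np.pi * f
    observed = np.concatenate([spectrum.real_part, spectrum.imag_part])

    # linearized starting values (assume alpha ~ 0.8, small inertance)
    rn0 = max(float(spectrum.real_part[-1]), 1e-3)
    g0 = max(float((spectrum.real_part[0] - spectrum.real_part[-1]) * omega[0] ** 0.8), 1e-2)
    h0 = max(float(-spectrum.imag_part[0] * omega[0] ** 0.8), 1e-2)
    i0 = 1e-4
    x0 = np.array([rn0, i0, g0, h0])

    result = least_squares(
        lambda th: _cp_model(th, omega) - observed,
        x0,
        bounds=([0.0, 0.0, 1e-9, 1e-9], [np.inf] * 4),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=200 * 4,
    )
    if not result.success:
        raise RuntimeError(
            f"constant-phase fit failed to converge: {result.message}; "
            f"last iterate {result.x}, residual norm {np.linalg.norm(result.fun):.3g}"
        )
    params = ConstantPhaseParams(*(float(v) for v in result.x))
    cod = _cod(observed, _cp_model(result.x, omega))
    return params, cod


# ---------------------------------------------------------------------------
# Pressure-volume maneuver
# ---------------------------------------------------------------------------


def fit_pv_curve(
    pressures: np.ndarray, volumes: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Fit the exponential deflation limb ``V = A − B·e^(−K·P)``.

    Returns ``(a, b, k_curvature, cst, cod)`` with static compliance
    ``cst = B·K``, the slope of the fitted curve at P = 0. Expects ≥ 5
    deflation-limb points with pressures in decreasing order.

    Initialization is a log-linear regression of ``log(A₀ − V)`` on P.
    """
    p = np.asarray(pressures, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if p.size != v.size:
        raise ValueError("pressure and volume must have equal length")
    if p.size < 5:
        raise ValueError("need >= 5 deflation-limb points")
    if np.any(np.diff(p) >= 0):
        raise ValueError("deflation-limb pressures must be strictly decreasing")

    a0 = float(v.max()) + 0.05 * max(float(np.ptp(v)), 1e-6)
    with np.errstate(invalid="ignore"):
        y = np.log(np.maximum(a0 - v, 1e-12))
    slope, intercept = np.polyfit(p, y, 1)
    k0 = max(-float(slope), 1e-6)
    b0 = max(float(np.exp(intercept)), 1e-9)

    def residual(theta: np.ndarray) -> np.ndarray:
        a, b, k = theta
        return (a - b * np.exp(-k * p)) - v

    result = least_squares(
        residual,
        np.array([a0, b0, k0]),
        bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=3000,  # the K->0 limit is a flat valley in (A, B) and converges slowly
    )
    if not result.success:
        raise RuntimeError(
            f"PV fit failed to converge: {result.message}; last iterate {result.x}"
        )
    a, b, k = (float(x) for x in result.x)
    cod = _cod(v, a - b * np.exp(-k * p))
    return a, b, k, b * k, cod


def pv_loop_area(pressures: np.ndarray, volumes: np.ndarray) -> float:
    """Hysteresis area of a closed PV loop (shoelace polygon area, ml·cmH₂O).

    The loop is closed implicitly between the last and first point; the
    traversal direction does not affect the returned magnitude.
    """
    p = np.asarray(pressures, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if p.size != v.size:
        raise ValueError("pressure and volume must have equal length")
    if p.size < 3:
        raise ValueError("need >= 3 points to define a loop")
    return float(abs(np.sum(p * np.roll(v, -1) - np.roll(p, -1) * v)) / 2.0)


# ---------------------------------------------------------------------------
# NPFE and deep inflation
# ---------------------------------------------------------------------------


def npfe_metrics(trace: VentilatorTrace, window_s: float = 0.05) -> tuple[float, float, float]:
    """Spirometry-style quantities from a forced-expiration flow trace.

    Returns ``(fev005, fvc, fef005)``: volume expired in the first
    ``window_s`` seconds (trapezoidal, with linear interpolation exactly at
    the window boundary), total expired volume, and instantaneous flow at
    the boundary (linear interpolation). Flow is expiratory-positive and the
    trace must start at expiration onset (t = 0).
    """
    t = trace.time - trace.time[0]
    flow = trace.flow
    if t[-1] < window_s:
        raise ValueError(f"trace shorter than {window_s} s")
    fvc = float(np.trapezoid(flow, t))
    flow_at = float(np.interp(window_s, t, flow))
    sel = t <= window_s
    t_early = np.append(t[sel], window_s) if t[sel][-1] < window_s else t[sel]
    f_early = np.append(flow[sel], flow_at) if t[sel][-1] < window_s else flow[sel]
    fev = float(np.trapezoid(f_early, t_early))
    return fev, fvc, flow_at


def deep_inflation_ic(volume_trace: np.ndarray, peep_volume_ml: float = 0.0) -> float:
    """Inspiratory capacity: maximum volume attained minus the PEEP baseline."""
    v = np.asarray(volume_trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty volume trace")
    return float(v.max() - peep_volume_ml)


# ---------------------------------------------------------------------------
# Replicate aggregation with CoD gating
# ---------------------------------------------------------------------------


def aggregate_replicates(
    records: list[MechanicsRecord],
    cod_threshold: float = COD_EXCLUSION_THRESHOLD,
) -> MechanicsRecord:
    """Average replicate measurements, excluding poorly fitted replicates.

    For each parameter, only replicates whose governing fit reached
    ``cod_threshold`` contribute to the mean; if every replicate of a
    parameter is excluded the aggregate carries NaN (missing, not zero).
    The result is invariant to the order of the input records. Aggregated
    CoDs are the means over the replicates that actually reported one.
    """
    if not records:
        raise ValueError("need at least one replicate record")
    out = MechanicsRecord()
    for param, model in PARAM_GOVERNING_FIT.items():
        vals = []
        for rec in records:
            value = getattr(rec, param)
            if not np.isfinite(value):
                continue
            if model is not None:
                cod = rec.cod_per_fit.get(model, math.nan)
                if not (np.isfinite(cod) and cod >= cod_threshold):
                    continue
            vals.append(value)
        if vals:
            setattr(out, param, float(np.mean(vals)))
    models = sorted({m for rec in records for m in rec.cod_per_fit})
    for model in models:
        cods = [
            rec.cod_per_fit[model]
            for rec in records
            if np.isfinite(rec.cod_per_fit.get(model, math.nan))
        ]
        if cods:
            out.cod_per_fit[model] = float(np.mean(cods))
    return out
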