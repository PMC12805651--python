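"""Synthetic murine lung phantoms and cohort generation.

Builds complete virtual animals — lung mask, phase-resolved specific-
ventilation volumes with planted tumor foci, a paired CT volume, ventilator
maneuver traces, and exact ground truth — with the statistical structure the
analysis pipeline assumes:

* the lung is two ellipsoidal fields (left/right) on a 0.4 mm isotropic
  grid, ~6000 in-mask voxels at the default shape;
* healthy tissue inflates along a concave profile (rapid early expansion,
  late plateau); voxelwise lognormal noise makes the SV field heterogeneous;
* tumor foci are spheres that are denser on CT, have suppressed ventilation
  amplitude, and fill late — including an early dip in which regional SV
  decreases between the first two post-baseline phases;
* a scalar ``severity`` couples tumor burden to lung mechanics: compliance-
  like parameters shrink and resistance/elastance-like parameters grow with
  severity, and the overall ventilation amplitude is modestly suppressed
  (tumor-stiffened lungs expand less everywhere, not only inside foci).

All randomness flows from explicit integer seeds; per-animal seeds are
derived deterministically from the cohort seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import mechanics as mech
from .mechanics import ConstantPhaseParams, ImpedanceSpectrum, VentilatorTrace
from .volumes import (
    CTVolume,
    LungMask,
    PhaseSeries,
    VentilationVolume,
    save_mask,
    save_phase_series,
    save_volume,
)

__all__ = [
    "VirtualLung",
    "TumorFociSpec",
    "GroundTruth",
    "MechanicsGroundTruth",
    "CohortConfig",
    "generate_lung_mask",
    "inflation_profile",
    "tumor_inflation_profile",
    "generate_phase_series",
    "couple_mechanics_to_burden",
    "simulate_maneuver_battery",
    "analyze_maneuver_battery",
    "SimulatedAnimal",
    "iter_cohort",
    "generate_cohort",
]

DEFAULT_SHAPE = (32, 18, 40)
DEFAULT_SPACING = (0.4, 0.4, 0.4)


@dataclass
class MechanicsGroundTruth:
    """True mechanical parameters of a virtual lung (healthy baseline)."""

    r: float = 0.5            # cmH2O.s/ml, single-compartment resistance
    c: float = 0.05           # ml/cmH2O, single-compartment compliance
    rn: float = 0.3           # cmH2O.s/ml
    i_inert: float = 0.005    # cmH2O.s^2/ml
    g: float = 4.0            # cmH2O/ml
    h: float = 25.0           # cmH2O/ml
    pv_a: float = 1.0         # ml, Salazar-Knowles asymptote
    pv_b: float = 0.8         # ml
    pv_k: float = 0.1         # 1/cmH2O
    ic: float = 0.8           # ml
    fvc: float = 1.0          # ml
    npfe_tau: float = 0.04    # s, expiratory decay time constant

    @property
    def cst(self) -> float:
        return self.pv_b * self.pv_k

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d["cst"] = self.cst
        return d


@dataclass
class VirtualLung:
    """Geometry, ventilation and mechanics of one simulated healthy lung."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    baseline_sv: float = 0.15          # mean full-breath SV of healthy tissue
    sv_noise_sd: float = 0.25          # lognormal sigma of voxel noise
    n_phases: int = 10
    mech_params: MechanicsGroundTruth = field(default_factory=MechanicsGroundTruth)
    ct_lung_gray: float = 200.0
    ct_tumor_gray: float = 600.0
    ct_noise_sd: float = 10.0


@dataclass
class TumorFociSpec:
    """Planted tumor foci and their coupling to ventilation and mechanics."""

    n_foci: int = 0
    radius_mm: tuple[float, float] = (0.4, 1.0)   # uniform sampling bounds
    sv_suppression: float = 0.7        # multiplicative SV reduction in foci
    fill_delay: float = 1.0            # phase lag (in phase-point units)
    severity: float = 0.0              # couples burden to mechanics shifts
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sv_suppression <= 1:
            raise ValueError("sv_suppression must be in [0, 1]")
        if not 0 <= self.severity <= 1:
            raise ValueError("severity must be in [0, 1]")
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")


@dataclass
class GroundTruth:
    """Exact simulation truth recorded alongside each phantom."""

    tumor_count: int
    tumor_burden_pct: float
    foci_centers_mm: list[tuple[float, float, float]]
    severity: float
    mech_params: dict[str, float]

    def __post_init__(self) -> None:
        if not 0 <= self.tumor_burden_pct <= 100:
            raise ValueError("tumor_burden_pct must be in [0, 100]")
        if self.tumor_count != len(self.foci_centers_mm):
            raise ValueError("tumor_count must equal number of foci centers")


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def generate_lung_mask(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    seed: int = 0,
) -> LungMask:
    """Two ellipsoidal lung fields with a midline gap.

    Semi-axes are jittered a few percent per seed so cohorts are not
    clones; at the default 32×18×40 grid of 0.4 mm voxels the mask holds
    on the order of 6000 voxels.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    extent = np.array(shape) * np.array(spacing)
    # physical semi-axes (mm); the pair must fit inside the grid
    base_semi = np.array([0.28 * extent[0] / 2 * 2, 0.38 * extent[1], 0.42 * extent[2]])
    base_semi = np.array([0.21 * extent[0], 0.36 * extent[1], 0.40 * extent[2]])
    gap = 0.08 * extent[0]

    centers_x = (
        extent[0] / 2 - gap / 2 - base_semi[0],
        extent[0] / 2 + gap / 2 + base_semi[0],
    )
    if centers_x[0] - base_semi[0] < 0 or centers_x[1] + base_semi[0] > extent[0]:
        raise ValueError("shape too small to contain the two lung ellipsoids")
    if np.any(base_semi < np.asarray(spacing)):
        raise ValueError("shape too small to contain the two lung ellipsoids")

    coords = [
        (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    mask = np.zeros(shape, dtype=bool)
    for cx in centers_x:
        semi = base_semi * (1.0 + rng.uniform(-0.04, 0.04, size=3))
        center = np.array([cx, extent[1] / 2, extent[2] / 2])
        d2 = (
            ((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2
        )
        mask |= d2 <= 1.0
    lm = LungMask(mask)
    if lm.n_voxels < 1:
        raise ValueError("shape too small to contain the two lung ellipsoids")
    return lm


# ---------------------------------------------------------------------------
# Inflation dynamics
# ---------------------------------------------------------------------------


def inflation_profile(n_phases: int, rate: float = 3.0) -> np.ndarray:
    """Concave healthy inflation profile over ``n_phases`` phase points.

    ``f(k) = (1 − e^{−rate·k/(n−1)}) / (1 − e^{−rate})`` — starts at 0
    (peak exhalation), ends at 1 (peak inspiration), rises fastest early in
    the breath and plateaus near the end.
    """
    if n_phases < 2:
        raise ValueError("need at least two phase points")
    k = np.arange(n_phases) / (n_phases - 1)
    return (1.0 - np.exp(-rate * k)) / (1.0 - math.exp(-rate))


def tumor_inflation_profile(n_phases: int, fill_delay: float = 1.0, rate: float = 3.0) -> np.ndarray:
    """Slow-filling profile for tumor foci.

    The healthy profile is delayed by ``fill_delay`` phase points; when the
    delay is active, an early non-monotone dip is superimposed (regional SV
    rises slightly at the first post-baseline phase, then *decreases* at the
    next before recovering), as seen in obstructed/stiffened regions. The
    profile stays strictly below the healthy profile at every post-baseline
    phase and ends below 1.
    """
    if fill_delay < 0:
        raise ValueError("fill_delay must be >= 0")
    k = np.arange(n_phases, dtype=float)
    shifted = np.clip(k - fill_delay, 0.0, None) / (n_phases - 1)
    prof = (1.0 - np.exp(-rate * shifted)) / (1.0 - math.exp(-rate))
    if fill_delay > 0 and n_phases >= 4:
        first = prof[prof > 0]
        ref = first[0] if first.size else 0.1
        prof[1] = max(prof[1], 0.3 * ref + 0.02)
        prof[2] = min(prof[2], 0.5 * prof[1])
        prof[3] = max(prof[3], prof[2])
    return prof


# ---------------------------------------------------------------------------
# Phantom generation
# ---------------------------------------------------------------------------


def _place_foci(
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    spec: TumorFociSpec,
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> tuple[np.ndarray, list[tuple[float, float, float]]]:
    """Rejection-sample sphere centers on in-mask voxels.

    Overlapping foci are merged in the voxel label (burden counts unique
    voxels) but each planted sphere is counted as one focus.
    """
    focus = np.zeros_like(mask, dtype=bool)
    centers: list[tuple[float, float, float]] = []
    idx = np.argwhere(mask)
    coords = [
        (np.arange(mask.shape[a]) + 0.5) * spacing[a] for a in range(3)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    for _ in range(spec.n_foci):
        radius = rng.uniform(*spec.radius_mm)
        placed = False
        for _try in range(max_tries):
            vi = idx[rng.integers(len(idx))]
            center = (np.asarray(vi) + 0.5) * np.asarray(spacing)
            d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
            sphere = d2 <= radius ** 2
            in_mask = sphere & mask
            if in_mask.sum() >= 0.5 * sphere.sum() and in_mask.any():
                focus |= in_mask
                centers.append(tuple(float(c) for c in center))
                placed = True
                break
        if not placed:
            raise ValueError("could not place tumor focus inside the mask")
    return focus, centers


#: global ventilation-amplitude suppression per unit severity (stiff lungs
#: expand less everywhere, beyond the focal defects)
GLOBAL_SV_SUPPRESSION = 0.3


def generate_phase_series(
    lung: VirtualLung,
    foci: TumorFociSpec,
    mask: LungMask | None = None,
) -> tuple[PhaseSeries, CTVolume, GroundTruth]:
    """Simulate one animal's 4D SV series, CT volume and ground truth.

    Healthy voxel SV at phase k is
    ``baseline_sv × (1 − 0.3·severity) × profile(k) × noise(voxel)`` with
    fixed-per-voxel lognormal noise; focus voxels use the suppressed
    amplitude ``×(1 − sv_suppression)`` and the delayed tumor profile. CT
    gray is ``ct_lung_gray`` outside foci and ``ct_tumor_gray`` inside, plus
    Gaussian scanner noise.
    """
    rng = np.random.default_rng(foci.seed)
    if mask is None:
        mask = generate_lung_mask(lung.shape, lung.spacing, seed=foci.seed)
    m = mask.values
    focus, centers = _place_foci(m, lung.spacing, foci, rng)
    if focus.sum() > m.sum():
        raise ValueError("requested foci volume exceeds mask volume")

    noise = rng.lognormal(mean=-0.5 * lung.sv_noise_sd ** 2, sigma=lung.sv_noise_sd, size=m.shape)
    amplitude = lung.baseline_sv * (1.0 - GLOBAL_SV_SUPPRESSION * foci.severity)
    healthy_prof = inflation_profile(lung.n_phases)
    tumor_prof = tumor_inflation_profile(lung.n_phases, foci.fill_delay)

    volumes = []
    for k in range(lung.n_phases):
        sv = np.zeros(m.shape)
        sv[m] = amplitude * healthy_prof[k] * noise[m]
        if focus.any():
            sv[focus] = (
                amplitude * (1.0 - foci.sv_suppression) * tumor_prof[k] * noise[focus]
            )
        volumes.append(
            VentilationVolume(sv, spacing=lung.spacing, phase_index=k)
        )
    series = PhaseSeries(volumes, mask=mask)

    ct_vals = np.full(m.shape, 0.0)
    ct_vals[m] = lung.ct_lung_gray
    ct_vals[focus] = lung.ct_tumor_gray
    ct_vals = ct_vals + rng.normal(0.0, lung.ct_noise_sd, size=m.shape)
    ct = CTVolume(ct_vals, spacing=lung.spacing)

    burden = 100.0 * focus.sum() / m.sum()
    truth = GroundTruth(
        tumor_count=len(centers),
        tumor_burden_pct=float(burden),
        foci_centers_mm=centers,
        severity=foci.severity,
        mech_params=couple_mechanics_to_burden(lung.mech_params, foci.severity).as_dict(),
    )
    return series, ct, truth


# ---------------------------------------------------------------------------
# Mechanics coupling and maneuver simulation
# ---------------------------------------------------------------------------


def couple_mechanics_to_burden(
    base: MechanicsGroundTruth, severity: float, lam: float = 0.5
) -> MechanicsGroundTruth:
    """Shift mechanics with tumor severity.

    Compliance-like quantities (C, C_st via B, IC, FVC, PV asymptotes)
    scale by ``1 − λ·severity``; resistance and tissue elastance (R, R_n,
    G, H) scale by ``1 + λ·severity``. ``severity = 0`` is the identity.
    """
    if not 0 <= severity <= 1:
        raise ValueError("severity must be in [0, 1]")
    down = 1.0 - lam * severity
    up = 1.0 + lam * severity
    return MechanicsGroundTruth(
        r=base.r * up,
        c=base.c * down,
        rn=base.rn * up,
        i_inert=base.i_inert,
        g=base.g * up,
        h=base.h * up,
        pv_a=base.pv_a * down,
        pv_b=base.pv_b * down,
        pv_k=base.pv_k,
        ic=base.ic * down,
        fvc=base.fvc * down,
        npfe_tau=base.npfe_tau,
    )


def simulate_maneuver_battery(
    params: MechanicsGroundTruth,
    seed: int = 0,
    noise_scale: float = 0.01,
    n_replicates: int = 3,
) -> list[dict[str, object]]:
    """Simulate the five-maneuver script, ``n_replicates`` times.

    Each replicate is a dict with keys ``snapshot`` (VentilatorTrace),
    ``prime`` (ImpedanceSpectrum), ``pv`` (deflation-limb arrays plus the
    closed loop), ``npfe`` (VentilatorTrace) and ``deep_inflation``
    (volume-ramp VentilatorTrace). ``noise_scale`` is the relative
    measurement noise applied per channel.
    """
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(n_replicates):
        rep: dict[str, object] = {}
        rep["snapshot"] = mech.simulate_single_compartment(
            params.r,
            params.c,
            noise_sd=noise_scale * (params.ic / params.c / 10.0),
            seed=int(rng.integers(2**31 - 1)),
        )
        freqs = mech.default_prime_frequencies()
        spec = mech.constant_phase_impedance(
            ConstantPhaseParams(params.rn, params.i_inert, params.g, params.h), freqs
        )
        scale = np.abs(spec.real_part + 1j * spec.imag_part)
        rep["prime"] = ImpedanceSpectrum(
            freqs,
            spec.real_part + rng.normal(0, noise_scale * scale),
            spec.imag_part + rng.normal(0, noise_scale * scale),
        )
        p_defl = np.arange(30.0, -0.1, -3.0)
        v_defl = params.pv_a - params.pv_b * np.exp(-params.pv_k * p_defl)
        v_defl = v_defl + rng.normal(0, noise_scale * params.pv_b * 0.2, size=p_defl.size)
        p_infl = p_defl[::-1]
        # inflation limb lies below deflation (hysteresis) by a pressure offset
        v_infl = params.pv_a - params.pv_b * np.exp(-params.pv_k * np.maximum(p_infl - 5.0, 0.0))
        rep["pv"] = {
            "deflation_pressure": p_defl,
            "deflation_volume": v_defl,
            "loop_pressure": np.concatenate([p_infl, p_defl]),
            "loop_volume": np.concatenate([v_infl, v_defl]),
        }
        t = np.arange(0.0, 0.3, 1e-3)
        peak_flow = params.fvc / params.npfe_tau
        flow = peak_flow * np.exp(-t / params.npfe_tau)
        flow = flow + rng.normal(0, noise_scale * peak_flow * 0.1, size=t.size)
        vol = np.concatenate([[0.0], np.cumsum((flow[1:] + flow[:-1]) / 2 * np.diff(t))])
        rep["npfe"] = VentilatorTrace(t, np.zeros_like(t), flow, vol, maneuver="npfe")
        t_di = np.arange(0.0, 3.0, 0.01)
        peep_vol = 0.05
        ramp = peep_vol + params.ic * np.clip(t_di / 2.0, 0, 1)
        rep["deep_inflation"] = VentilatorTrace(
            t_di, np.zeros_like(t_di), np.zeros_like(t_di), ramp, maneuver="deep_inflation"
        )
        rep["peep_volume_ml"] = peep_vol
        replicates.append(rep)
    return replicates


def analyze_maneuver_battery(replicates: list[dict[str, object]]) -> mech.MechanicsRecord:
    """Fit every replicate and aggregate with CoD gating."""
    records = []
    for rep in replicates:
        rec = mech.MechanicsRecord()
        rrs, crs, _p0, cod_sc = mech.fit_single_compartment(rep["snapshot"])
        rec.rrs, rec.crs = rrs, crs
        rec.cod_per_fit["single_compartment"] = cod_sc
        cp, cod_cp = mech.fit_constant_phase(rep["prime"])
        rec.rn, rec.i_inert, rec.g, rec.h = cp.rn, cp.i_inert, cp.g, cp.h
        rec.cod_per_fit["constant_phase"] = cod_cp
        pv = rep["pv"]
        _a, _b, k, cst, cod_pv = mech.fit_pv_curve(
            pv["deflation_pressure"], pv["deflation_volume"]
        )
        rec.cst, rec.k_curvature = cst, k
        rec.cod_per_fit["pv"] = cod_pv
        rec.pv_area = mech.pv_loop_area(pv["loop_pressure"], pv["loop_volume"])
        rec.fev005, rec.fvc, rec.fef005 = mech.npfe_metrics(rep["npfe"])
        rec.ic = mech.deep_inflation_ic(
            rep["deep_inflation"].volume, rep["peep_volume_ml"]
        )
        records.append(rec)
    return mech.aggregate_replicates(records)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study layout: group sizes and per-group severity/foci distributions."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"control": 2, "week2": 3, "week3": 3}
    )
    severity_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "control": (0.0, 0.0),
            "week2": (0.1, 0.3),
            "week3": (0.5, 0.9),
        }
    )
    foci_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"control": (0, 0), "week2": (3, 8), "week3": (15, 25)}
    )
    lung: VirtualLung = field(default_factory=VirtualLung)
    simulate_leak: bool = False   # drop one week3 animal's mechanics
    weight_g: tuple[float, float] = (20.0, 2.0)   # mean, sd of body weight

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {g!r} must be >= 1")


def _animal_seed(cohort_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(cohort_seed), int(index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


@dataclass
class SimulatedAnimal:
    """One virtual animal with all of its simulated measurements."""

    animal_id: str
    group: str
    weight_g: float
    series: PhaseSeries
    ct: CTVolume
    truth: GroundTruth
    replicates: list[dict[str, object]] | None   # None emulates a system leak
    seed: int

    def truth_row(self) -> dict[str, object]:
        row = {
            "animal_id": self.animal_id,
            "group": self.group,
            "weight_g": self.weight_g,
            "severity": self.truth.severity,
            "tumor_count": self.truth.tumor_count,
            "tumor_burden_pct": self.truth.tumor_burden_pct,
            "has_mechanics": self.replicates is not None,
        }
        row.update({f"true_{k}": v for k, v in self.truth.mech_params.items()})
        return row


def iter_cohort(config: CohortConfig, seed: int = 0):
    """Yield :class:`SimulatedAnimal` objects for one cohort, in order.

    All per-animal randomness derives deterministically from ``seed``; the
    same (config, seed) pair always yields the same cohort.
    """
    rng = np.random.default_rng(seed)
    index = 0
    leak_id = None
    if config.simulate_leak and config.group_sizes.get("week3", 0) >= 1:
        leak_id = "week3_0"
    for group, n in config.group_sizes.items():
        lo, hi = config.severity_ranges[group]
        flo, fhi = config.foci_ranges[group]
        for i in range(n):
            animal_id = f"{group}_{i}"
            aseed = _animal_seed(seed, index)
            severity = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            n_foci = int(rng.integers(flo, fhi + 1)) if fhi > 0 else 0
            weight = float(rng.normal(*config.weight_g))
            foci = TumorFociSpec(
                n_foci=n_foci,
                sv_suppression=0.7,
                fill_delay=1.0,
                severity=severity,
                seed=aseed,
            )
            series, ct, truth = generate_phase_series(config.lung, foci)
            true_mech = couple_mechanics_to_burden(config.lung.mech_params, severity)
            has_mech = animal_id != leak_id
            replicates = (
                simulate_maneuver_battery(true_mech, seed=aseed) if has_mech else None
            )
            yield SimulatedAnimal(
                animal_id=animal_id,
                group=group,
                weight_g=weight,
                series=series,
                ct=ct,
                truth=truth,
                replicates=replicates,
                seed=aseed,
            )
            index += 1


def _write_animal(animal: SimulatedAnimal, adir: Path) -> None:
    adir.mkdir(parents=True, exist_ok=True)
    save_phase_series(animal.series, adir)
    save_volume(animal.ct, adir / "ct.nii.gz")
    tdir = adir / "traces"
    tdir.mkdir(exist_ok=True)
    if animal.replicates is not None:
        for r_i, rep in enumerate(animal.replicates):
            rep["snapshot"].to_csv(tdir / f"snapshot_{r_i}.csv")
            rep["prime"].to_csv(tdir / f"prime_{r_i}.csv")
            rep["npfe"].to_csv(tdir / f"npfe_{r_i}.csv")
            rep["deep_inflation"].to_csv(tdir / f"deep_inflation_{r_i}.csv")
            pv = rep["pv"]
            pd.DataFrame(
                {"pressure_cmH2O": pv["loop_pressure"], "volume_ml": pv["loop_volume"]}
            ).to_csv(tdir / f"pv_loop_{r_i}.csv", index=False)
            pd.DataFrame(
                {
                    "pressure_cmH2O": pv["deflation_pressure"],
                    "volume_ml": pv["deflation_volume"],
                }
            ).to_csv(tdir / f"pv_deflation_{r_i}.csv", index=False)
        (tdir / "peep_volume_ml.json").write_text(
            json.dumps({"peep_volume_ml": animal.replicates[0]["peep_volume_ml"]})
        )
    truth_dict = {
        "tumor_count": animal.truth.tumor_count,
        "tumor_burden_pct": animal.truth.tumor_burden_pct,
        "foci_centers_mm": animal.truth.foci_centers_mm,
        "severity": animal.truth.severity,
        "mech_params": animal.truth.mech_params,
        "seed": animal.seed,
    }
    (adir / "truth.json").write_text(json.dumps(truth_dict, indent=2))


def generate_cohort(
    config: CohortConfig,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate a full cohort; optionally write per-animal artifacts to disk.

    Returns the ground-truth study table (one row per animal: id, group,
    weight, severity, tumor count/burden, true mechanics). When ``out_dir``
    is given, each animal gets a directory with phase NIfTIs + manifest,
    mask, CT, maneuver trace CSVs and a ``truth.json``; the table is written
    as ``ground_truth.csv`` with a cohort-level ``manifest.json``.
    """
    rows = []
    animal_ids = []
    out_dir = Path(out_dir) if out_dir is not None else None
    for animal in iter_cohort(config, seed):
        rows.append(animal.truth_row())
        if out_dir is not None:
            _write_animal(animal, out_dir / animal.animal_id)
            animal_ids.append(animal.animal_id)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "ground_truth.csv", index=False)
        (out_dir / "manifest.json").write_text(
            json.dumps({"seed": int(seed), "animals": animal_ids}, indent=2)
        )
    return table
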