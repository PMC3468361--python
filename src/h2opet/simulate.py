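"""Synthetic dynamic-PET data with the statistical structure the analysis assumes.

Everything the pipeline consumes can be generated here: gamma-variate bolus
input functions, frame-sampled tissue curves from the one-tissue model, small
4-D water phantoms with an aorta and a tumour lesion plus the matched static
FDG volume and attenuation pair, and whole simulated cohorts for exercising
the group statistics.  All stochastic outputs are reproducible from
(spec, seed).

Noise model: zero-mean Gaussian per frame (or per voxel-frame) with standard
deviation sigma0 * sqrt(activity / frame_duration) — the usual count-limited
approximation in which longer frames and hotter regions are relatively less
noisy.  The default sigma0 = 2.2 kBq/mL * s^0.5 puts the peak-frame
signal-to-noise ratio of the default tumour curve at ~10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .kinetics import (
    DEFAULT_DT,
    FrameSchedule,
    InputFunction,
    OneTissueParams,
    TimeActivityCurve,
    forward_model,
)
from .voi import VolumeImage

#: Injected activity of the water bolus, MBq.
INJECTED_DOSE_MBQ = 370.0
#: Default frame-noise scale; peak-frame SNR ~ 10 for the default tumour curve.
DEFAULT_SIGMA0 = 2.2


def make_input_function(peak_time: float = 25.0, amplitude: float = 50.0,
                        shape: float = 3.0, t0: float = 5.0) -> InputFunction:
    """Canonical arterial bolus: gamma variate appearing at ``t0`` and peaking
    at ``peak_time`` (absolute, seconds) with maximum ``amplitude`` kBq/mL."""
    if peak_time <= t0:
        raise ParameterError("peak_time must exceed the appearance time t0")
    return InputFunction.gamma_variate(amplitude=amplitude, t0=t0,
                                       time_to_peak=peak_time - t0, shape=shape)


def frame_noise_sd(activity: np.ndarray, frame_duration: np.ndarray,
                   sigma0: float) -> np.ndarray:
    return sigma0 * np.sqrt(np.clip(activity, 0.0, None) / frame_duration)


def simulate_tac(params: OneTissueParams, input_fn: InputFunction,
                 schedule: FrameSchedule, sigma0: float = 0.0,
                 rng: np.random.Generator | None = None,
                 dt: float = DEFAULT_DT) -> TimeActivityCurve:
    """Forward-model TAC with optional seeded frame noise."""
    clean = forward_model(params, input_fn, schedule, dt)
    if sigma0 == 0.0:
        return clean
    rng = rng if rng is not None else np.random.default_rng(0)
    sd = frame_noise_sd(clean.activity, schedule.frame_duration, sigma0)
    return TimeActivityCurve(schedule, clean.activity + rng.normal(0.0, 1.0, clean.activity.size) * sd,
                             clean.decay_corrected)


# ---------------------------------------------------------------------------
# Image phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of a single simulated patient scan.

    The water-study volumes live in the "water" voxel space; the FDG study is
    the same anatomy rigidly translated by ``fdg_shift_voxels``, which the
    attenuation-based co-registration must recover (with opposite sign).
    """

    shape: tuple = (48, 48, 48)
    voxel_size_mm: float = 4.0
    tumour_centre: tuple = (30, 30, 24)
    tumour_radius_mm: float = 12.0
    tumour_params: OneTissueParams = field(
        default_factory=lambda: OneTissueParams(K1=0.8, k2=0.4, V0=0.05))
    aorta_centre_xy: tuple = (16, 16)
    aorta_radius_mm: float = 8.0
    background: float = 0.5
    fdg_tumour_suv: float = 8.0
    fdg_background_suv: float = 1.0
    fdg_shift_voxels: tuple = (2, -1, 0)
    sigma0: float = DEFAULT_SIGMA0
    seed: int = 0
    schedule: FrameSchedule = field(default_factory=FrameSchedule.water_default)
    input_fn: InputFunction = field(default_factory=make_input_function)

    def __post_init__(self):
        if any(n <= 0 for n in self.shape) or self.voxel_size_mm <= 0:
            raise ParameterError("phantom dimensions must be positive")
        tum = self._sphere_mask()
        aor = self._cylinder_mask()
        if not tum.any() or not aor.any():
            raise ParameterError("tumour/aorta geometry falls outside the image")
        if (tum & aor).any():
            raise ParameterError("tumour and aorta must be disjoint")
        idx = np.argwhere(tum)
        if idx.min() < 0 or (idx >= np.array(self.shape)).any():
            raise ParameterError("tumour extends outside the image")

    def _grid(self):
        return np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")

    def _sphere_mask(self) -> np.ndarray:
        x, y, z = self._grid()
        r_vox = self.tumour_radius_mm / self.voxel_size_mm
        cx, cy, cz = self.tumour_centre
        return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r_vox ** 2

    def _cylinder_mask(self) -> np.ndarray:
        x, y, _ = self._grid()
        r_vox = self.aorta_radius_mm / self.voxel_size_mm
        cx, cy = self.aorta_centre_xy
        return (x - cx) ** 2 + (y - cy) ** 2 <= r_vox ** 2


@dataclass(frozen=True)
class PatientSim:
    """Simulated single-patient study with ground truth attached."""

    water_dynamic: VolumeImage
    attenuation_water: VolumeImage
    attenuation_fdg: VolumeImage
    fdg: VolumeImage
    truth: dict


from .voi import _translate as _translate3  # shared integer-voxel shift


def simulate_patient(spec: PhantomSpec) -> PatientSim:
    """Build the full four-volume study for one phantom patient.

    Tumour voxels follow the one-tissue forward model of ``spec.tumour_params``;
    aorta voxels carry the frame-averaged input function; a uniform low
    background fills the rest; seeded Gaussian frame noise is added voxelwise.
    The FDG emission/attenuation pair is the water-space anatomy translated by
    ``spec.fdg_shift_voxels``.
    """
    rng = np.random.default_rng(spec.seed)
    sched = spec.schedule
    vox = (spec.voxel_size_mm,) * 3
    tumour = spec._sphere_mask()
    aorta = spec._cylinder_mask()

    tumour_tac = forward_model(spec.tumour_params, spec.input_fn, sched).activity
    grid = sched.fine_grid(DEFAULT_DT)
    aorta_tac = sched.frame_average(grid, spec.input_fn(grid))

    dyn = np.full(spec.shape + (sched.n_frames,), float(spec.background))
    dyn[tumour, :] = tumour_tac
    dyn[aorta, :] = aorta_tac
    if spec.sigma0 > 0:
        sd = spec.sigma0 * np.sqrt(np.clip(dyn, 0.0, None) / sched.frame_duration)
        dyn = dyn + rng.normal(0.0, 1.0, dyn.shape) * sd
    water = VolumeImage(dyn, vox, "water-dynamic", schedule=sched)

    # Attenuation: body ellipsoid with denser tumour/aorta texture so the
    # rigid registration has structure to lock onto.
    x, y, z = spec._grid()
    nx, ny, nz = spec.shape
    body = (((x - nx / 2) / (nx * 0.45)) ** 2 + ((y - ny / 2) / (ny * 0.4)) ** 2
            + ((z - nz / 2) / (nz * 0.48)) ** 2) <= 1.0
    mu = np.where(body, 0.096, 0.0)
    mu[tumour] = 0.104
    mu[aorta] = 0.100
    atten_noise = 0.002 * rng.standard_normal(spec.shape)
    atten_water = VolumeImage(mu + atten_noise, vox, "attenuation")

    fdg_data = np.where(body, spec.fdg_background_suv, 0.0)
    fdg_data[tumour] = spec.fdg_tumour_suv
    shift = tuple(int(s) for s in spec.fdg_shift_voxels)
    fdg = VolumeImage(_translate3(fdg_data, shift)
                      + 0.02 * rng.standard_normal(spec.shape) * (spec.fdg_background_suv),
                      vox, "FDG-SUV")
    atten_fdg = VolumeImage(_translate3(mu, shift) + 0.002 * rng.standard_normal(spec.shape),
                            vox, "attenuation")

    truth = {
        "K1": spec.tumour_params.K1,
        "k2": spec.tumour_params.k2,
        "V0": spec.tumour_params.V0,
        "delay": spec.tumour_params.delay,
        "fdg_shift_voxels": list(shift),
        "registration_shift_voxels": [-s for s in shift],
        "tumour_n_voxels": int(tumour.sum()),
        "aorta_n_voxels": int(aorta.sum()),
        "tumour_tac": tumour_tac.tolist(),
        "seed": spec.seed,
    }
    return PatientSim(water_dynamic=water, attenuation_water=atten_water,
                      attenuation_fdg=atten_fdg, fdg=fdg, truth=truth)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Generating distributions for a simulated pharmacodynamic cohort.

    Defaults mirror the observed study: baseline perfusion uniform on
    [0.74, 1.52] mL/g/min; week-2 percent perfusion change normal within each
    clinical-benefit group with the observed group means/SDs; SUV changes
    uniform on the observed [-67, -29] band.  Benefit labels are assigned by
    the generating group, so the cohort statistics can be tested against a
    known effect size.
    """

    n_benefit: int = 4
    n_non_benefit: int = 3
    baseline_perfusion_range: tuple = (0.74, 1.52)
    benefit_change_mean: float = -67.25
    benefit_change_sd: float = 20.9
    non_benefit_change_mean: float = -37.67
    non_benefit_change_sd: float = 19.9
    suv_change_range: tuple = (-67.0, -29.0)
    sigma0: float = DEFAULT_SIGMA0

    def __post_init__(self):
        if self.n_benefit + self.n_non_benefit < 1:
            raise ParameterError("cohort must contain at least one patient")
        for lo, hi in (self.baseline_perfusion_range, self.suv_change_range):
            if hi < lo:
                raise ParameterError("invalid range (high < low)")
        if self.benefit_change_sd < 0 or self.non_benefit_change_sd < 0:
            raise ParameterError("change SDs must be non-negative")


@dataclass
class SimulatedPatient:
    patient_id: int
    clinical_benefit: bool
    baseline_perfusion: float
    perfusion_change_pct: float
    suv_change_pct: float
    baseline_tac: TimeActivityCurve | None = None
    followup_tac: TimeActivityCurve | None = None


def simulate_cohort(params: CohortParams | None = None, seed: int = 0,
                    with_tacs: bool = False,
                    schedule: FrameSchedule | None = None) -> list:
    """Draw a cohort of simulated patients; optionally attach noisy TAC pairs.

    Week-2 perfusion is baseline * (1 + change/100), floored at 2 % of
    baseline so followup curves stay physical even in the far tail.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    sched = schedule or FrameSchedule.water_default()
    input_fn = make_input_function()
    patients = []
    labels = [True] * params.n_benefit + [False] * params.n_non_benefit
    for i, benefit in enumerate(labels):
        base = rng.uniform(*params.baseline_perfusion_range)
        if benefit:
            change = rng.normal(params.benefit_change_mean, params.benefit_change_sd)
        else:
            change = rng.normal(params.non_benefit_change_mean, params.non_benefit_change_sd)
        suv_change = rng.uniform(*params.suv_change_range)
        pat = SimulatedPatient(patient_id=i + 1, clinical_benefit=benefit,
                               baseline_perfusion=float(base),
                               perfusion_change_pct=float(change),
                               suv_change_pct=float(suv_change))
        if with_tacs:
            follow = max(base * (1.0 + change / 100.0), 0.02 * base)
            for attr, k1 in (("baseline_tac", base), ("followup_tac", follow)):
                p = OneTissueParams(K1=k1, k2=0.4, V0=0.05)
                setattr(pat, attr, simulate_tac(p, input_fn, sched,
                                                sigma0=params.sigma0, rng=rng))
        patients.append(pat)
    return patients
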