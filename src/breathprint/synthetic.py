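"""Synthetic temperature-cycled e-nose cohorts.

Emulates what one Aeonose-style measurement records: three metal-oxide
sensors driven through a 64-step heat/cool ramp for 36 cycles (~8 s per
cycle, roughly one breath), giving a 64 x 36 x 3 conductivity tensor per
participant.  A measurement is modeled as

    clean-air baseline  (temperature-response curve, near-constant in cycles)
  + VOC response        (amplitude a_i x unit-norm signature on the NOx sensor)
  + sensor drift        (Gaussian random walk across cycles, per sensor)
  + i.i.d. noise        + sporadic spikes + device offset

The VOC signature is a smooth bump over a band of temperature steps (with a
weaker echo on the cooling branch) modulated across cycles by a
breath-synchronous oscillation that builds up as exhaled VOCs accumulate.
Its amplitude is a_i = response_amplitude + effect_size * noise_sd * 1{case}
+ N(0, amp_jitter_sd): cases respond more strongly, which is the only way
the label enters the tensor.

Because the class difference is a pure mean shift along a known direction
in Gaussian noise, the Bayes-optimal detector is the matched filter and its
AUC has a closed form (see :func:`bayes_auc`); :func:`effect_size_for_auc`
inverts it.  The default effect size places the Bayes-optimal AUC at 0.85.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .io import (
    N_CYCLE,
    N_SENSOR,
    N_TEMP,
    CovariateProfile,
    SensorTensor,
)

DEVICE_SERIALS = ("257", "372")

#: Bayes-optimal AUC targeted by the default effect size.
DEFAULT_TARGET_AUC = 0.85


@dataclass
class GeneratorConfig:
    """Knobs of the cohort generator.

    ``effect_size`` is the class shift of the VOC response amplitude in
    units of the per-point noise SD; ``None`` resolves to the value that
    puts the Bayes-optimal AUC at :data:`DEFAULT_TARGET_AUC`.
    """

    n_cases: int = 49
    n_controls: int = 35
    effect_size: float | None = None
    spike_rate: float = 2e-5
    spike_magnitude: float = 0.6          # conductivity units
    drift_sd: float = 0.001               # conductivity units per cycle
    device_offsets: tuple[float, float] = (0.0, 0.02)
    baseline_amplitude: float = 1.0       # clean-air component
    noise_sd: float = 0.05
    response_amplitude: float = 1.0       # shared VOC response a_0
    amp_jitter_sd: float = 0.05           # person-to-person response spread
    nox_sensor_index: int = 0
    arrangement: str = "interleaved"      # or "blocked" (forces long runs)
    max_run: int = 5                      # run cap for interleaved order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must be a probability")
        if self.effect_size is not None and self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd <= 0 or self.drift_sd < 0:
            raise ValueError("noise_sd must be > 0 and drift_sd >= 0")
        if len(self.device_offsets) != len(DEVICE_SERIALS):
            raise ValueError("one device offset per device serial")
        if self.arrangement not in ("interleaved", "blocked"):
            raise ValueError("arrangement must be 'interleaved' or 'blocked'")

    def resolved_effect_size(self) -> float:
        if self.effect_size is not None:
            return self.effect_size
        return effect_size_for_auc(DEFAULT_TARGET_AUC, self)


# ---------------------------------------------------------------------------
# deterministic shapes


def temperature_profile() -> np.ndarray:
    """Heat/cool triangle over the 64 steps (32 up, 32 down), range [0, 1]."""
    up = np.linspace(0.0, 1.0, N_TEMP // 2)
    down = up[::-1]
    return np.concatenate([up, down])


def baseline_curve() -> np.ndarray:
    """Clean-air conductivity vs temperature step, peak height 1.

    Conductivity of a MOS sensor rises with surface temperature; the
    cooling branch is slightly depressed (thermal hysteresis).
    """
    ramp = temperature_profile()
    curve = 0.15 + 0.85 * ramp**1.5
    curve[N_TEMP // 2:] *= 0.95
    return curve


def signature_temperature_shape() -> np.ndarray:
    """VOC redox response vs temperature step: a bump on the heating branch
    with a weaker echo at the mirrored cooling step."""
    t = np.arange(N_TEMP)
    bump = np.exp(-0.5 * ((t - 22) / 4.0) ** 2)
    echo = 0.6 * np.exp(-0.5 * ((t - (N_TEMP - 1 - 22)) / 4.0) ** 2)
    return bump + echo


def signature_cycle_shape() -> np.ndarray:
    """Breath-synchronous modulation across cycles with a build-up envelope."""
    c = np.arange(N_CYCLE)
    envelope = 1.0 - np.exp(-(c + 1) / 6.0)
    return np.sin(2.0 * np.pi * c / N_CYCLE) * envelope


def unit_signature() -> np.ndarray:
    """Unit-Frobenius-norm class signature tensor (nonzero on one sensor)."""
    s = np.outer(signature_temperature_shape(), signature_cycle_shape())
    return s / np.linalg.norm(s)


def _signature_tensor(nox_sensor_index: int) -> np.ndarray:
    sig = np.zeros((N_TEMP, N_CYCLE, N_SENSOR))
    sig[:, :, nox_sensor_index] = unit_signature()
    return sig


# ---------------------------------------------------------------------------
# Bayes-optimal AUC of the generated tensors


def discriminant_noise_sd(config: GeneratorConfig) -> float:
    """SD of the matched-filter statistic under a fixed response amplitude.

    The matched filter m = <x, S> (S the unit signature) sees three noise
    sources: i.i.d. measurement noise (variance noise_sd^2 since ||S|| = 1),
    person-to-person response jitter (amp_jitter_sd^2), and the drift
    random walk projected onto S.  Spikes and the per-participant [0, 1]
    normalization are neglected here; the Monte-Carlo test in the suite
    checks the approximation.
    """
    s = unit_signature()
    w = s.sum(axis=0)  # drift adds equally to every temperature step
    c = np.arange(1, N_CYCLE + 1, dtype=float)
    cov = np.minimum.outer(c, c)  # random-walk covariance
    drift_var = config.drift_sd**2 * float(w @ cov @ w)
    return float(np.sqrt(config.noise_sd**2 + config.amp_jitter_sd**2 + drift_var))


def bayes_auc(config: GeneratorConfig, effect_size: float | None = None) -> float:
    """AUC of the Bayes-optimal detector on raw tensors."""
    e = config.resolved_effect_size() if effect_size is None else effect_size
    delta = e * config.noise_sd
    dprime = delta / discriminant_noise_sd(config)
    return float(stats.norm.cdf(dprime / np.sqrt(2.0)))


def effect_size_for_auc(target_auc: float, config: GeneratorConfig | None = None) -> float:
    """Effect size (units of noise SD) giving the requested Bayes AUC."""
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must be in [0.5, 1)")
    if config is None:
        config = GeneratorConfig(effect_size=0.0)
    dprime = np.sqrt(2.0) * stats.norm.ppf(target_auc)
    return float(dprime * discriminant_noise_sd(config) / config.noise_sd)


# ---------------------------------------------------------------------------
# measurement order


def _interleaved_labels(n_cases: int, n_controls: int, max_run: int, rng: np.random.Generator) -> list[int]:
    """Random label order with no same-class run longer than ``max_run``.

    Rejection sampling with a run-aware sampler; falls back to an
    evenly-spread (Bresenham) merge if the constraint cannot be satisfied
    by chance (e.g. very lopsided cohorts).
    """
    for _ in range(200):
        left = [n_cases, n_controls]
        seq: list[int] = []
        run_label, run_len = -1, 0
        ok = True
        while left[0] + left[1] > 0:
            choices = [k for k in (0, 1) if left[k] > 0]
            if run_len >= max_run and run_label in choices and len(choices) > 1:
                choices = [k for k in choices if k != run_label]
            if run_len >= max_run and choices == [run_label]:
                ok = False
                break
            probs = np.array([left[k] for k in choices], dtype=float)
            k = int(rng.choice(choices, p=probs / probs.sum()))
            seq.append(k)
            left[k] -= 1
            run_len = run_len + 1 if k == run_label else 1
            run_label = k
        if ok:
            return seq
    # even spread: case positions at fractional offsets
    n = n_cases + n_controls
    pos = set(np.floor((np.arange(n_cases) + 0.5) * n / max(n_cases, 1)).astype(int))
    return [0 if i in pos else 1 for i in range(n)]


def _blocked_labels(n_cases: int, n_controls: int, rng: np.random.Generator) -> list[int]:
    """Alternating same-class blocks, some longer than 5, to exercise the
    block-size exclusion rule (emulates clinic scheduling that clusters
    patients and controls)."""
    left = [n_cases, n_controls]
    seq: list[int] = []
    k = int(rng.integers(0, 2))
    while left[0] + left[1] > 0:
        if left[k] == 0:
            k = 1 - k
        run = int(min(left[k], rng.integers(3, 9)))
        seq.extend([k] * run)
        left[k] -= run
        k = 1 - k
    return seq


# ---------------------------------------------------------------------------
# covariates (directionally matched to the study cohort: controls younger,
# more toombak use and heavier smoking history than cases)

_AGE_MEAN = {("case", "male"): 55.6, ("case", "female"): 52.2,
             ("control", "male"): 48.4, ("control", "female"): 33.5}
_MALE_RATE = {"case": 0.49, "control": 0.829}
_TOOMBAK_RATE = {"case": 0.35, "control": 0.65}
_SMOKER_RATE = {"case": 0.40, "control": 0.60}
_PACKYEAR_MEAN = {"case": 8.0, "control": 15.0}


def _draw_covariates(group: str, rng: np.random.Generator) -> CovariateProfile:
    sex = "male" if rng.random() < _MALE_RATE[group] else "female"
    age = rng.normal(_AGE_MEAN[(group, sex)], 12.0)
    age = float(np.clip(age, 19.0, 95.0))
    toombak = bool(rng.random() < _TOOMBAK_RATE[group])
    if rng.random() < _SMOKER_RATE[group]:
        packyears = float(rng.gamma(2.0, _PACKYEAR_MEAN[group] / 2.0))
    else:
        packyears = 0.0
    return CovariateProfile(age=age, sex=sex, toombak_use=toombak,
                            smoking_packyears=packyears)


# ---------------------------------------------------------------------------
# main entry points


def generate_cohort(config: GeneratorConfig) -> list[SensorTensor]:
    """Generate ``n_cases + n_controls`` labelled measurements.

    Deterministic given ``config.seed``; the measurement order interleaves
    the classes (no run longer than ``max_run``) unless
    ``arrangement="blocked"``.
    """
    n = config.n_cases + config.n_controls
    if n == 0:
        return []
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    if config.arrangement == "interleaved":
        order = _interleaved_labels(config.n_cases, config.n_controls, config.max_run, rng)
    else:
        order = _blocked_labels(config.n_cases, config.n_controls, rng)

    effect = config.resolved_effect_size()
    base = config.baseline_amplitude * baseline_curve()          # (64,)
    sensor_scale = np.array([1.0, 0.9, 1.1])
    sig = _signature_tensor(config.nox_sensor_index)             # (64, 36, 3)
    cycle_trend = 1.0 + 0.02 * np.arange(N_CYCLE) / (N_CYCLE - 1)

    cohort: list[SensorTensor] = []
    case_no = control_no = 0
    for i, k in enumerate(order):
        is_case = k == 0  # slot 0 of the order sampler holds the cases
        if is_case:
            case_no += 1
            pid, group, label = f"P{case_no:03d}", "case", "positive"
        else:
            control_no += 1
            pid, group, label = f"C{control_no:03d}", "control", "negative"

        device = i % len(DEVICE_SERIALS)
        amp = (
            config.response_amplitude
            + (effect * config.noise_sd if is_case else 0.0)
            + rng.normal(0.0, config.amp_jitter_sd)
        )
        clean_air = base[:, None, None] * cycle_trend[None, :, None] * sensor_scale[None, None, :]
        drift_steps = rng.normal(0.0, config.drift_sd, size=(N_CYCLE, N_SENSOR))
        drift = np.cumsum(drift_steps, axis=0)                   # (36, 3)
        noise = rng.normal(0.0, config.noise_sd, size=(N_TEMP, N_CYCLE, N_SENSOR))
        values = (
            clean_air
            + amp * sig
            + drift[None, :, :]
            + noise
            + config.device_offsets[device]
        )
        # spike randomness is always drawn so cohorts that differ only in
        # spike_rate share every other random component (paired designs)
        mask = rng.random(values.shape) < config.spike_rate
        spikes = config.spike_magnitude * rng.uniform(0.75, 1.25, size=values.shape)
        values = values + mask * spikes

        cohort.append(
            SensorTensor(
                participant_id=pid,
                values=values,
                device_id=DEVICE_SERIALS[device],
                order_index=i,
                label=label,
                covariates=_draw_covariates(group, rng),
            )
        )
    return cohort


WORKED_FIXTURE_SEED = 2021


def generate_worked_fixture() -> list[SensorTensor]:
    """Deterministic 12-participant cohort with a large, clearly separable
    effect (Bayes AUC ~ 1), used as a known-ground-truth fixture."""
    config = GeneratorConfig(
        n_cases=6,
        n_controls=6,
        effect_size=12.0,
        amp_jitter_sd=0.01,
        spike_rate=2e-4,
        seed=WORKED_FIXTURE_SEED,
    )
    return generate_cohort(config)


def labels_array(cohort: Sequence[SensorTensor]) -> np.ndarray:
    """0/1 label vector (1 = positive) in cohort order."""
    return np.array([1 if t.label == "positive" else 0 for t in cohort])


def matched_filter_values(cohort: Sequence[SensorTensor], nox_sensor_index: int = 0) -> np.ndarray:
    """Oracle statistic <x, S> on raw tensors (for calibration checks)."""
    sig = _signature_tensor(nox_sensor_index)
    return np.array([float(np.sum(t.values * sig)) for t in cohort])
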