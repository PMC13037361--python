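"""Synthetic wrist-actigraphy cohorts with a controllable case effect.

The generator emulates the statistical structure the downstream analysis
assumes: a diurnal activity profile with a nocturnal plateau and a
mid-morning (10:00) peak, seasonal modulation (lower in winter, maximal in
July), BMI-linked daytime activity, demographics of a cohort around 65
years of age, and a small multiplicative daytime attenuation for
participants who carry, or will receive, a knee-osteoarthritis diagnosis.
Case diagnosis timing is split between "prediagnosed" (diagnosis before the
wear week) and "prodromal" (diagnosis up to ten years after).

All randomness flows from a single integer seed; the same config always
produces the same cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import yaml
from scipy.stats import norm

from .records import HOURS, ParticipantRecord, write_cohort

#: Hours whose activity is multiplicatively reduced for cases (inclusive).
ATTENUATED_HOURS = (9, 16)

#: Hours over which BMI above 25 linearly depresses activity (inclusive).
BMI_COUPLED_HOURS = (7, 21)

_NIGHT_END = 5   # last hour of the nocturnal plateau
_PEAK_HOUR = 10  # hour of maximal activity

_KOA_CODES = ("M17", "M17.0", "M17.1", "M17.9")
_DISTRACTOR_CODES = ("I10", "E11.9", "M54.5")

# Sex-specific height distributions (cm): 2018 Health Survey for England means.
_HEIGHT_MEAN = {"male": 175.6, "female": 162.1}
_HEIGHT_SD = {"male": 6.8, "female": 6.3}


class InfeasibleTargetError(ValueError):
    """The requested separability cannot be reached by any attenuation < 1."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters for one synthetic cohort.

    Acceleration levels and noise are on a milli-gravity-like positive
    scale; the absolute scale is arbitrary but internally consistent.
    """

    n_participants: int = 2000
    case_fraction: float = 0.12
    daytime_attenuation: float = 0.10
    seasonal_amplitude: float = 0.2
    noise_sd: float = 15.0
    night_level: float = 10.0
    peak_level: float = 40.0
    age_mean: float = 65.5
    age_sd: float = 7.5
    male_fraction: float = 0.47
    bmi_mean: float = 31.0
    bmi_sd: float = 3.0
    bmi_activity_slope: float = 0.6
    prodromal_lag_range: tuple[float, float] = (0.0, 10.0)
    prediagnosed_fraction: float = 0.57
    prodromal_fraction: float = 0.43
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if not 0.0 <= self.case_fraction <= 1.0:
            raise ValueError("case_fraction must lie in [0, 1]")
        if not 0.0 <= self.daytime_attenuation < 1.0:
            raise ValueError("daytime_attenuation must lie in [0, 1)")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must lie in [0, 1)")
        if min(self.noise_sd, self.night_level, self.peak_level) <= 0:
            raise ValueError("noise_sd, night_level and peak_level must be positive")
        if self.night_level >= self.peak_level:
            raise ValueError("night_level must be below peak_level")
        if abs(self.prediagnosed_fraction + self.prodromal_fraction - 1.0) > 1e-9:
            raise ValueError("prediagnosed_fraction + prodromal_fraction must equal 1")
        lo, hi = self.prodromal_lag_range
        if not 0.0 <= lo < hi:
            raise ValueError("prodromal_lag_range must be an interval with 0 <= lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["prodromal_lag_range"] = list(self.prodromal_lag_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "prodromal_lag_range" in d:
            d["prodromal_lag_range"] = tuple(d["prodromal_lag_range"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SyntheticConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def seasonal_factor(month, amplitude: float):
    """Multiplier 1 + a*cos(2*pi*(month-7)/12): maximal in July, minimal in January."""
    month = np.asarray(month)
    return 1.0 + amplitude * np.cos(2.0 * np.pi * (month - 7) / 12.0)


def _base_profile(config: SyntheticConfig) -> np.ndarray:
    """Seasonally neutral expected profile: plateau, rise to 10:00, decline."""
    hours = np.arange(HOURS)
    night, peak = config.night_level, config.peak_level
    span = peak - night
    rise = night + span * (hours - _NIGHT_END) / (_PEAK_HOUR - _NIGHT_END)
    decline = peak - span * (hours - _PEAK_HOUR) / (HOURS - _PEAK_HOUR)
    return np.where(
        hours <= _NIGHT_END, night, np.where(hours <= _PEAK_HOUR, rise, decline)
    )


def diurnal_template(hour, month, config: SyntheticConfig):
    """Noiseless expected acceleration at a given hour and month.

    Low plateau at ``night_level`` over hours 0-5, monotone rise to the
    maximum ``peak_level`` at hour 10, monotone decline through hour 23,
    all scaled by the seasonal factor. Accepts scalars or arrays.
    """
    hour_arr = np.asarray(hour)
    month_arr = np.asarray(month)
    if np.any((hour_arr < 0) | (hour_arr > 23)):
        raise ValueError("hour must lie in 0..23")
    if np.any((month_arr < 1) | (month_arr > 12)):
        raise ValueError("month must lie in 1..12")
    base = _base_profile(config)[hour_arr]
    value = base * seasonal_factor(month_arr, config.seasonal_amplitude)
    return float(value) if np.ndim(hour) == 0 and np.ndim(month) == 0 else value


def daytime_template_mean(config: SyntheticConfig) -> float:
    """Seasonal-neutral mean of the template over the attenuated hours 9-16."""
    lo, hi = ATTENUATED_HOURS
    return float(_base_profile(config)[lo : hi + 1].mean())


def daytime_mean_sd(config: SyntheticConfig) -> float:
    """SD of the hours-9-16 mean induced by the hour-level Gaussian noise."""
    lo, hi = ATTENUATED_HOURS
    return config.noise_sd / np.sqrt(hi - lo + 1)


def attenuation_for_auc(target_auc: float, mu_day: float, sigma_day: float) -> float:
    """Invert AUC = Phi(d/sqrt(2)), d = delta*mu_day/sigma_day, for delta.

    This is the theoretical AUC of a univariate discriminant on mean daytime
    activity when case and control daytime means differ by delta*mu_day and
    each carries independent Gaussian noise with sd sigma_day.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must lie in [0.5, 1)")
    d = np.sqrt(2.0) * norm.ppf(target_auc)
    delta = d * sigma_day / mu_day
    if delta >= 1.0:
        raise InfeasibleTargetError(
            f"target AUC {target_auc} requires attenuation {delta:.3f} >= 1 "
            f"given mu_day={mu_day:.3g}, sigma_day={sigma_day:.3g}"
        )
    return float(delta)


def auc_for_attenuation(delta: float, mu_day: float, sigma_day: float) -> float:
    """Forward map: theoretical daytime-mean AUC for a given attenuation."""
    return float(norm.cdf(delta * mu_day / (np.sqrt(2.0) * sigma_day)))


def calibrate_attenuation(target_auc: float, config: SyntheticConfig) -> float:
    """Attenuation delta at which the daytime-mean discriminant has the target AUC.

    The closed form is exact when ``seasonal_amplitude`` and
    ``bmi_activity_slope`` are zero; otherwise month and weight are observed
    covariates that a conditioning classifier can remove, so the calibrated
    delta still sets the separability available to the multi-modal model.
    """
    return attenuation_for_auc(
        target_auc, daytime_template_mean(config), daytime_mean_sd(config)
    )


def generate_population(config: SyntheticConfig) -> list[ParticipantRecord]:
    """Draw a full synthetic cohort from the configured distributions.

    Cases have hours 9-16 of the noiseless template multiplied by
    ``1 - daytime_attenuation`` before noise. Prediagnosed cases receive
    negative diagnosis offsets (uniform on (-10, 0)); prodromal cases
    receive offsets uniform on ``prodromal_lag_range``. Controls carry no
    qualifying diagnosis (a few carry unrelated distractor codes).
    """
    cfg = config
    n = cfg.n_participants
    rng = np.random.default_rng(cfg.seed)

    n_cases = int(round(n * cfg.case_fraction))
    is_case = np.zeros(n, dtype=bool)
    is_case[rng.permutation(n)[:n_cases]] = True

    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 40.0, 85.0)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 16.0, None)
    height_mean = np.where(sex == "male", _HEIGHT_MEAN["male"], _HEIGHT_MEAN["female"])
    height_sd = np.where(sex == "male", _HEIGHT_SD["male"], _HEIGHT_SD["female"])
    height_cm = rng.normal(height_mean, height_sd)
    weight = bmi * (height_cm / 100.0) ** 2
    month = rng.integers(1, 13, n)

    # Case diagnosis timing: fixed prediagnosed/prodromal split among cases.
    offsets = np.full(n, np.nan)
    case_idx = np.flatnonzero(is_case)
    n_pre = int(round(n_cases * cfg.prediagnosed_fraction))
    shuffled = rng.permutation(case_idx)
    pre_idx, pro_idx = shuffled[:n_pre], shuffled[n_pre:]
    offsets[pre_idx] = -rng.uniform(0.0, 10.0, pre_idx.size)
    lo, hi = cfg.prodromal_lag_range
    offsets[pro_idx] = rng.uniform(lo, hi, pro_idx.size)

    case_codes = rng.choice(_KOA_CODES, size=n)
    has_distractor = rng.random(n) < 0.05
    distractors = rng.choice(_DISTRACTOR_CODES, size=n)

    base = _base_profile(cfg)[None, :] * seasonal_factor(month, cfg.seasonal_amplitude)[:, None]
    b_lo, b_hi = BMI_COUPLED_HOURS
    base[:, b_lo : b_hi + 1] -= (
        cfg.bmi_activity_slope * np.maximum(bmi - 25.0, 0.0)[:, None]
    )
    a_lo, a_hi = ATTENUATED_HOURS
    base[is_case, a_lo : a_hi + 1] *= 1.0 - cfg.daytime_attenuation
    profiles = np.maximum(base + rng.normal(0.0, cfg.noise_sd, (n, HOURS)), 0.0)

    records = []
    for i in range(n):
        codes: set[str] = set()
        if is_case[i]:
            codes.add(str(case_codes[i]))
        if has_distractor[i]:
            codes.add(str(distractors[i]))
        records.append(
            ParticipantRecord(
                id=f"P{i:06d}",
                profile=tuple(profiles[i]),
                month=int(month[i]),
                sex=str(sex[i]),
                age=float(age[i]),
                weight=float(weight[i]),
                bmi=float(bmi[i]),
                icd10_codes=frozenset(codes),
                diagnosis_offset_years=float(offsets[i]) if is_case[i] else None,
            )
        )
    return records


def simulate_to_files(
    config: SyntheticConfig, out_path: str | Path, sidecar_path: str | Path | None = None
) -> list[ParticipantRecord]:
    """Generate a cohort, write the delimited table plus a config sidecar."""
    records = generate_population(config)
    out_path = Path(out_path)
    write_cohort(records, out_path)
    if sidecar_path is None:
        sidecar_path = out_path.with_suffix(".config.yaml")
    config.save(sidecar_path)
    return records
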