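"""Synthetic pressure-plate cohort generator.

Emulates the structure of a prospective overuse-injury study: a cohort
of young adults each completes five walking strides and five running
strides per foot (barefoot and shod running) over a 250 Hz pressure
plate, and is followed up for six months for lower-extremity overuse
injuries.  The generator reproduces the statistical structure the
downstream pipeline assumes —

* per-zone mean-pressure curves are smooth squared-sine bumps on a
  zone-specific sub-interval of stance, rolling heel -> midfoot ->
  metatarsals -> toes;
* mean force = mean pressure x zone area, exactly;
* whole-foot vertical force = sum of zone mean forces, exactly;
* peak pressure = mean pressure x a noisy peak factor, never below the
  mean pressure;
* trial lengths vary stochastically around gait-specific stance
  durations;

— plus a tunable injury effect ``effect_size`` (delta) that raises the
forefoot peak pressures of subjects who will go on to be injured.
Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .zones import (
    FEET,
    FOOTWEARS,
    FOREFOOT_ZONES,
    MEASUREMENTS,
    VERTICAL_FORCE,
    WHOLE_FOOT,
    ZONES,
    ZoneTemplate,
    default_zone_templates,
)

GRAVITY = 9.81  # m/s^2; converts body mass (kg) to weight (N)


class CohortError(ValueError):
    """Invalid cohort configuration or degenerate generated cohort."""


@dataclass(frozen=True)
class SubjectProfile:
    """Questionnaire record for one subject."""

    subject_id: str
    sex: str  # "male" | "female"
    height: float  # cm
    weight: float  # kg
    shoe_size: float  # EU
    injured: bool  # lower-extremity overuse injury within 6 months

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class Trial:
    """One measurement series of one footfall.

    ``vertical_force`` series carry ``zone="whole_foot"``; the zone
    measurements (peak/mean pressure, mean force) carry one of the ten
    anatomical zones.
    """

    subject_id: str
    footwear: str
    gait: str
    foot: str
    trial_index: int
    measurement: str
    zone: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measurement == VERTICAL_FORCE and self.zone != WHOLE_FOOT:
            raise ValueError("vertical_force requires zone='whole_foot'")
        if self.measurement != VERTICAL_FORCE and self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r}")
        if len(self.values) < 2:
            raise ValueError("trial needs at least 2 samples")
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("trial values must be nonnegative")


# Class-conditional anthropometrics of the emulated cohort
# (healthy / injured first-year students):
_ANTHROPOMETRICS = {
    # class: (height mean, height sd, weight mean, weight sd, male fraction)
    "healthy": (175.69, 8.23, 68.65, 9.00, 83 / 120),
    "injured": (177.70, 8.04, 69.75, 8.63, 26 / 35),
}


@dataclass
class CohortConfig:
    """Study-design and signal-model parameters of the synthetic cohort.

    ``effect_size`` (delta) is the relative increase of the injured
    subjects' forefoot load; by default it multiplies the forefoot peak
    factor, concentrating the effect on peak pressures
    (``effect_target="peak_pressure"``); with
    ``effect_target="mean_pressure"`` it scales the mean-pressure bump
    amplitude instead, propagating into mean force and vertical force.
    """

    n_subjects: int = 155
    injured_fraction: float = 35 / 155
    effect_size: float = 0.3
    effect_target: str = "peak_pressure"  # or "mean_pressure"
    timing_shift: float = 0.0  # stance fraction; injured forefoot shifted earlier
    stance_duration_run: tuple[float, float] = (0.22, 0.02)  # mean, sd in s
    stance_duration_walk: tuple[float, float] = (0.70, 0.05)
    sampling_rate: float = 250.0  # Hz
    n_trials_per_condition: int = 5
    seed: int = 0
    # signal-noise model (free parameters; see docs/methods.md)
    subject_amp_sd: float = 0.15  # lognormal sd of per-zone subject multipliers
    subject_pf_sd: float = 0.08  # lognormal sd of subject peak-factor multipliers
    subject_timing_sd: float = 0.02  # sd of subject-level onset/offset shift
    trial_amp_sd: float = 0.08  # lognormal sd of per-trial global amplitude
    zone_trial_amp_sd: float = 0.05  # lognormal sd of per-trial per-zone amplitude
    trial_timing_sd: float = 0.01  # sd of per-trial onset/offset jitter
    peak_noise_sd: float = 0.05  # lognormal sd of per-sample peak-factor noise
    shod_attenuation: float = 0.9  # shoe damping of mean-pressure amplitude
    vf_bodyweight_run: float = 2.5  # peak vertical force, multiples of body weight
    vf_bodyweight_walk: float = 1.1

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise CohortError("need at least 2 subjects")
        if not (0.0 < self.injured_fraction < 1.0):
            raise CohortError(
                "injured_fraction must be strictly between 0 and 1 "
                "(both outcome classes must be possible)"
            )
        if self.effect_size < 0:
            raise CohortError("effect_size must be >= 0")
        if self.sampling_rate <= 0:
            raise CohortError("sampling_rate must be positive")
        if self.effect_target not in ("peak_pressure", "mean_pressure"):
            raise CohortError(f"unknown effect_target {self.effect_target!r}")
        if self.n_trials_per_condition < 1:
            raise CohortError("n_trials_per_condition must be >= 1")


def sample_subject_profile(
    config: CohortConfig, stream: np.random.Generator, subject_id: str = "S0"
) -> SubjectProfile:
    """Draw one subject from the class-conditional anthropometric model."""
    injured = bool(stream.random() < config.injured_fraction)
    h_mu, h_sd, w_mu, w_sd, male_frac = _ANTHROPOMETRICS[
        "injured" if injured else "healthy"
    ]
    sex = "male" if stream.random() < male_frac else "female"
    height = float(stream.normal(h_mu, h_sd))
    weight = float(stream.normal(w_mu, w_sd))
    # truncate implausible tails (> ~4 sd) rather than resample, to keep
    # one-draw-per-field reproducibility
    height = float(np.clip(height, 140.0, 210.0))
    weight = float(np.clip(weight, 40.0, 120.0))
    shoe_size = float(np.round((42.0 + 0.25 * (height - 175.0)
                                + stream.normal(0.0, 1.0)) * 2) / 2)
    return SubjectProfile(subject_id, sex, height, weight, shoe_size, injured)


@dataclass
class _SubjectSignature:
    """Latent per-subject gait signature shared by all of a subject's trials."""

    amp_mult: dict[str, float]
    pf_mult: dict[str, float]
    timing_shift: float


def _draw_signature(config: CohortConfig, stream: np.random.Generator) -> _SubjectSignature:
    amp = {z: float(np.exp(stream.normal(0.0, config.subject_amp_sd))) for z in ZONES}
    pf = {z: float(np.exp(stream.normal(0.0, config.subject_pf_sd))) for z in ZONES}
    return _SubjectSignature(amp, pf, float(stream.normal(0.0, config.subject_timing_sd)))


def _nominal_peak_unit_force(templates: dict[str, ZoneTemplate]) -> float:
    """Peak of sum_z amplitude_z * area_z * bump_z(t) on a dense grid,
    for unit scaling; used to anchor vertical force to body weight."""
    t = np.linspace(0.0, 1.0, 2001)
    total = np.zeros_like(t)
    for tpl in templates.values():
        total += tpl.amplitude * tpl.area * _bump(t, tpl.onset_frac, tpl.offset_frac)
    return float(total.max())


def _bump(t_frac: np.ndarray, onset: float, offset: float) -> np.ndarray:
    """Squared-sine bump supported on [onset, offset] of stance."""
    out = np.zeros_like(t_frac)
    width = offset - onset
    mask = (t_frac >= onset) & (t_frac <= offset)
    out[mask] = np.sin(np.pi * (t_frac[mask] - onset) / width) ** 2
    return out


def simulate_trial(
    profile: SubjectProfile,
    footwear: str,
    gait: str,
    foot: str,
    trial_index: int,
    templates: dict[str, ZoneTemplate],
    config: CohortConfig,
    stream: np.random.Generator,
    signature: _SubjectSignature | None = None,
) -> list[Trial]:
    """Simulate one footfall; returns all 31 measurement series
    (3 zone measurements x 10 zones + whole-foot vertical force)."""
    missing = set(ZONES) - set(templates)
    if missing:
        raise CohortError(f"missing zone templates: {sorted(missing)}")
    if signature is None:
        signature = _draw_signature(config, stream)

    mu, sd = (config.stance_duration_run if gait == "run"
              else config.stance_duration_walk)
    stance_s = max(float(stream.normal(mu, sd)), 4.0 / config.sampling_rate)
    n = max(int(round(stance_s * config.sampling_rate)), 4)
    t_frac = (np.arange(n) + 0.5) / n

    vf_target = (config.vf_bodyweight_run if gait == "run"
                 else config.vf_bodyweight_walk)
    body_weight_n = profile.weight * GRAVITY
    force_scale = vf_target * body_weight_n / _nominal_peak_unit_force(templates)

    trial_amp = np.exp(stream.normal(0.0, config.trial_amp_sd))
    delta = config.effect_size if profile.injured else 0.0

    trials: list[Trial] = []
    vertical_force = np.zeros(n)
    meta = dict(subject_id=profile.subject_id, footwear=footwear, gait=gait,
                foot=foot, trial_index=trial_index)
    for zone in ZONES:
        tpl = templates[zone]
        shift = signature.timing_shift + stream.normal(0.0, config.trial_timing_sd)
        if profile.injured and zone in FOREFOOT_ZONES:
            shift -= config.timing_shift
        onset = float(np.clip(tpl.onset_frac + shift, 0.0, 0.95))
        offset = float(np.clip(tpl.offset_frac + shift, onset + 0.05, 1.0))

        amp = (tpl.amplitude * signature.amp_mult[zone] * trial_amp
               * np.exp(stream.normal(0.0, config.zone_trial_amp_sd)))
        if footwear == "shod":
            amp *= config.shod_attenuation
        if delta > 0 and zone in FOREFOOT_ZONES and config.effect_target == "mean_pressure":
            amp *= 1.0 + delta

        # pressure in N/cm^2 so that zone force (pressure x area) is in N;
        # force_scale anchors the whole-foot peak force to the body-weight target
        mean_pressure = amp * force_scale * _bump(t_frac, onset, offset)

        pf = tpl.peak_factor * signature.pf_mult[zone]
        if delta > 0 and zone in FOREFOOT_ZONES and config.effect_target == "peak_pressure":
            pf *= 1.0 + delta
        pf_samples = pf * np.exp(stream.normal(0.0, config.peak_noise_sd, size=n))
        peak_pressure = mean_pressure * np.maximum(pf_samples, 1.0)

        mean_force = mean_pressure * tpl.area  # exact, by construction
        vertical_force += mean_force

        trials.append(Trial(measurement="mean_pressure", zone=zone,
                            values=mean_pressure, **meta))
        trials.append(Trial(measurement="peak_pressure", zone=zone,
                            values=peak_pressure, **meta))
        trials.append(Trial(measurement="mean_force", zone=zone,
                            values=mean_force, **meta))

    trials.append(Trial(measurement=VERTICAL_FORCE, zone=WHOLE_FOOT,
                        values=vertical_force, **meta))
    return trials


class TrialStore:
    """In-memory collection of measurement series with long-format CSV I/O."""

    def __init__(self, trials: Iterable[Trial] = ()) -> None:
        self.trials: list[Trial] = list(trials)

    def __len__(self) -> int:
        return len(self.trials)

    def extend(self, trials: Iterable[Trial]) -> None:
        self.trials.extend(trials)

    def iter_trials(
        self,
        subject_id: str | None = None,
        footwear: str | None = None,
        gait: str | None = None,
        measurement: str | None = None,
        zone: str | None = None,
    ) -> Iterator[Trial]:
        for t in self.trials:
            if subject_id is not None and t.subject_id != subject_id:
                continue
            if footwear is not None and t.footwear != footwear:
                continue
            if gait is not None and t.gait != gait:
                continue
            if measurement is not None and t.measurement != measurement:
                continue
            if zone is not None and t.zone != zone:
                continue
            yield t

    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.subject_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(pd.DataFrame({
                "subject_id": t.subject_id,
                "footwear": t.footwear,
                "gait": t.gait,
                "foot": t.foot,
                "trial_index": t.trial_index,
                "measurement": t.measurement,
                "zone": t.zone,
                "sample_index": np.arange(len(t.values)),
                "value": t.values,
            }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialStore":
        keys = ["subject_id", "footwear", "gait", "foot",
                "trial_index", "measurement", "zone"]
        trials = []
        for key, grp in df.groupby(keys, sort=False):
            grp = grp.sort_values("sample_index")
            kw = dict(zip(keys, key))
            trials.append(Trial(values=grp["value"].to_numpy(float), **kw))
        return cls(trials)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialStore":
        return cls.from_frame(pd.read_csv(path))


def profiles_to_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    df = pd.DataFrame([{**asdict(p), "bmi": p.bmi} for p in profiles])
    return df[["subject_id", "sex", "height", "weight", "bmi",
               "shoe_size", "injured"]]


def generate_cohort(
    config: CohortConfig,
    templates: dict[str, ZoneTemplate] | None = None,
) -> tuple[TrialStore, list[SubjectProfile], pd.DataFrame]:
    """Generate the full synthetic study.

    Per subject: five running strides per foot, barefoot and shod, plus
    five barefoot walking strides per foot (the walking data only feeds
    the scale normalisation downstream).

    Returns the trial store, the subject profiles and an outcome roster
    (``subject_id``, ``outcome_class``) with classes ``healthy`` /
    ``lower_extremity_overuse``.
    """
    config.validate()
    if templates is None:
        templates = default_zone_templates()
    root = np.random.default_rng(config.seed)
    profile_stream, trial_seed_stream = root.spawn(2)

    profiles = [
        sample_subject_profile(config, profile_stream, subject_id=f"S{i:03d}")
        for i in range(config.n_subjects)
    ]
    labels = {p.injured for p in profiles}
    if len(labels) < 2:
        raise CohortError(
            "degenerate cohort: all subjects in one outcome class; "
            "increase n_subjects or adjust injured_fraction"
        )

    store = TrialStore()
    conditions = [("barefoot", "run"), ("shod", "run"), ("barefoot", "walk")]
    for profile in profiles:
        subj_stream = trial_seed_stream.spawn(1)[0]
        signature = _draw_signature(config, subj_stream)
        for footwear, gait in conditions:
            for foot in FEET:
                for idx in range(config.n_trials_per_condition):
                    store.extend(simulate_trial(
                        profile, footwear, gait, foot, idx,
                        templates, config, subj_stream, signature=signature,
                    ))

    roster = pd.DataFrame({
        "subject_id": [p.subject_id for p in profiles],
        "outcome_class": ["lower_extremity_overuse" if p.injured else "healthy"
                          for p in profiles],
    })
    return store, profiles, roster


def write_cohort(
    out_dir: str | Path,
    store: TrialStore,
    profiles: Sequence[SubjectProfile],
    roster: pd.DataFrame,
    config: CohortConfig,
) -> None:
    """Persist trial store, profiles, roster (CSV) and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    store.to_csv(out / "trials.csv")
    profiles_to_frame(profiles).to_csv(out / "profiles.csv", index=False)
    roster.to_csv(out / "roster.csv", index=False)
    meta = {
        "seed": config.seed,
        "sampling_rate": config.sampling_rate,
        "generator_version": 1,
        "n_subjects": config.n_subjects,
    }
    (out / "cohort_meta.json").write_text(json.dumps(meta, sort_keys=True, indent=2))
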