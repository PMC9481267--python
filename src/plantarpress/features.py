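"""Time-series feature bank and feature-table construction.

Each subject's 62 aligned signals (10 zones x {peak pressure, mean
pressure, mean force} x {barefoot, shod} + whole-foot vertical force x
{barefoot, shod}) are summarised by a configurable bank of scalar
features.  Two families matter most downstream and are implemented
exactly from their definitions:

* the phase (angle) of discrete Fourier coefficients
  ``A_k = sum_m X_m exp(-2*pi*i*m*k/n)``, and
* the coefficients ``phi_0..phi_k`` of an autoregressive AR(k) model
  ``X_t = phi_0 + sum_i phi_i X_{t-i} + eps_t`` fitted by conditional
  least squares (``phi_0`` is the intercept, so "coefficient 7 with
  maximum lag 10" is the lag-7 weight of the AR(10) fit).

The remaining bank members (maximum, absolute energy, linear trend,
autocorrelation, moments, ...) approximate the wide generic feature set
common in automated time-series feature extraction; the bank is
deliberately configurable rather than a frozen list.

Feature columns are named ``zone|measurement|footwear|feature_id`` —
a bijective encoding that the importance analysis parses back into
feature groups.  Person characteristics use the pseudo-signal
``person|characteristic|na|<field>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectProfile
from .preprocessing import SubjectSignalSet
from .zones import FOOTWEARS, MEASUREMENTS, VERTICAL_FORCE, WHOLE_FOOT, ZONES

SEP = "|"
PERSON_ZONE = "person"
PERSON_MEASUREMENT = "characteristic"
NO_FOOTWEAR = "na"
PERSON_FIELDS = ("sex", "height", "weight", "bmi", "shoe_size")

_VALID_ZONES = set(ZONES) | {WHOLE_FOOT, PERSON_ZONE}
_VALID_MEASUREMENTS = set(MEASUREMENTS) | {VERTICAL_FORCE, PERSON_MEASUREMENT}
_VALID_FOOTWEAR = set(FOOTWEARS) | {NO_FOOTWEAR}


class FeatureError(ValueError):
    pass


class DegenerateSeriesError(FeatureError):
    """Raised when a feature is undefined for a series (constant/too short)."""


# ---------------------------------------------------------------------------
# feature naming

def render_feature_name(zone: str, measurement: str, footwear: str,
                        feature_id: str) -> str:
    for tok, valid, what in ((zone, _VALID_ZONES, "zone"),
                             (measurement, _VALID_MEASUREMENTS, "measurement"),
                             (footwear, _VALID_FOOTWEAR, "footwear")):
        if tok not in valid:
            raise FeatureError(f"invalid {what} {tok!r}")
    if SEP in feature_id or not feature_id:
        raise FeatureError(f"invalid feature_id {feature_id!r}")
    return SEP.join((zone, measurement, footwear, feature_id))


def parse_feature_name(name: str) -> tuple[str, str, str, str]:
    parts = name.split(SEP)
    if len(parts) != 4:
        raise FeatureError(f"unparseable feature name {name!r}")
    zone, measurement, footwear, feature_id = parts
    # re-render validates tokens
    render_feature_name(zone, measurement, footwear, feature_id)
    return zone, measurement, footwear, feature_id


# ---------------------------------------------------------------------------
# the two exactly-specified families

def fft_coefficient(x: Sequence[float], k: int) -> complex:
    """k-th DFT coefficient A_k = sum_m x_m exp(-2*pi*i*m*k/n)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 <= k < n:
        raise FeatureError(f"FFT index k={k} out of range for length {n}")
    return complex(np.fft.fft(x)[k])


def fft_angle(coefficient: complex, zero_tol: float = 1e-12) -> float:
    """Phase of a DFT coefficient; exactly 0 for (numerically) zero
    coefficients to avoid platform-dependent atan2(0, 0)."""
    if abs(coefficient) < zero_tol:
        return 0.0
    return float(np.arctan2(coefficient.imag, coefficient.real))


def ar_coefficients(x: Sequence[float], max_lag: int = 10) -> np.ndarray:
    """Conditional-least-squares fit of an AR(max_lag) model with intercept.

    Returns ``[phi_0, phi_1, ..., phi_max_lag]`` where ``phi_0`` is the
    intercept and ``phi_i`` the lag-i weight.  Raises
    :class:`DegenerateSeriesError` for constant or too-short series.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= max_lag + 1:
        raise DegenerateSeriesError(
            f"series length {n} too short for AR({max_lag})")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series: AR design is singular")
    y = x[max_lag:]
    cols = [np.ones(n - max_lag)]
    cols += [x[max_lag - i: n - i] for i in range(1, max_lag + 1)]
    design = np.column_stack(cols)
    phi, *_ = np.linalg.lstsq(design, y, rcond=None)
    return phi


# ---------------------------------------------------------------------------
# the generic bank

@dataclass(frozen=True)
class BankConfig:
    """Which scalar features to extract from every signal.

    FFT features are emitted for ``k = 0 .. min(fft_max_k, n-1)`` (the
    DFT has only n coefficients), so the bank size depends on the
    signal length; :meth:`feature_ids` makes that explicit.
    """

    basic: bool = True          # max, min, mean, sd, abs energy, skew, kurtosis
    linear_trend: bool = True   # OLS slope and intercept vs sample index
    acf_lags: int = 10          # autocorrelation at lags 1..acf_lags
    fft_max_k: int = 99         # angle and magnitude of FFT coefficients
    ar_max_lag: int = 10        # AR coefficients phi_0..phi_ar_max_lag
    local_maxima: bool = True   # count of strict local maxima

    def feature_ids(self, n: int) -> list[str]:
        ids: list[str] = []
        if self.basic:
            ids += ["maximum", "minimum", "mean", "standard_deviation",
                    "abs_energy", "skewness", "kurtosis"]
        if self.linear_trend:
            ids += ["linear_trend_slope", "linear_trend_intercept"]
        ids += [f"autocorr_lag_{l}" for l in range(1, self.acf_lags + 1)]
        for k in range(min(self.fft_max_k, n - 1) + 1):
            ids += [f"fft_angle_{k}", f"fft_magnitude_{k}"]
        ids += [f"ar_coeff_{i}_maxlag_{self.ar_max_lag}"
                for i in range(self.ar_max_lag + 1)]
        if self.local_maxima:
            ids += ["count_local_maxima"]
        return ids


def _autocorrelation(x: np.ndarray, lag: int) -> float:
    n = x.size
    if lag >= n:
        return np.nan
    var = x.var()
    if var == 0:
        return np.nan
    mu = x.mean()
    return float(((x[:n - lag] - mu) * (x[lag:] - mu)).sum() / ((n - lag) * var))


def extract_feature_bank(x: Sequence[float],
                         config: BankConfig = BankConfig()) -> dict[str, float]:
    """Evaluate the bank on one signal; undefined features come out NaN
    (imputed fold-wise downstream)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise FeatureError("signal too short for feature extraction")
    out: dict[str, float] = {}
    constant = np.ptp(x) == 0

    if config.basic:
        out["maximum"] = float(x.max())
        out["minimum"] = float(x.min())
        out["mean"] = float(x.mean())
        out["standard_deviation"] = float(x.std())
        out["abs_energy"] = float((x ** 2).sum())
        out["skewness"] = np.nan if constant else float(stats.skew(x))
        out["kurtosis"] = np.nan if constant else float(stats.kurtosis(x))
    if config.linear_trend:
        t = np.arange(n, dtype=float)
        slope, intercept = np.polyfit(t, x, 1)
        out["linear_trend_slope"] = float(slope)
        out["linear_trend_intercept"] = float(intercept)
    for lag in range(1, config.acf_lags + 1):
        out[f"autocorr_lag_{lag}"] = _autocorrelation(x, lag)
    coeffs = np.fft.fft(x)
    for k in range(min(config.fft_max_k, n - 1) + 1):
        a = coeffs[k]
        out[f"fft_angle_{k}"] = fft_angle(complex(a))
        out[f"fft_magnitude_{k}"] = float(abs(a))
    try:
        phi = ar_coefficients(x, max_lag=config.ar_max_lag)
    except DegenerateSeriesError:
        phi = np.full(config.ar_max_lag + 1, np.nan)
    for i, p in enumerate(phi):
        out[f"ar_coeff_{i}_maxlag_{config.ar_max_lag}"] = float(p)
    if config.local_maxima:
        interior = (x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])
        out["count_local_maxima"] = float(interior.sum())
    return out


# ---------------------------------------------------------------------------
# feature table

LABEL_COLUMN = "injured"


def person_feature_row(profile: SubjectProfile) -> dict[str, float]:
    vals = {"sex": 1.0 if profile.sex == "male" else 0.0,
            "height": profile.height, "weight": profile.weight,
            "bmi": profile.bmi, "shoe_size": profile.shoe_size}
    return {
        render_feature_name(PERSON_ZONE, PERSON_MEASUREMENT, NO_FOOTWEAR, f): v
        for f, v in vals.items()
    }


def build_feature_table(
    signal_sets: Mapping[str, SubjectSignalSet],
    profiles: Sequence[SubjectProfile],
    bank: BankConfig = BankConfig(),
) -> pd.DataFrame:
    """Subjects x features table with the binary outcome label.

    Every subject must carry the same signal inventory (same
    (zone, measurement, footwear) keys with matching lengths); columns
    are emitted in a deterministic order: signal features (footwear,
    zone, measurement, bank order), then person characteristics, then
    the ``injured`` label.
    """
    profile_by_id = {p.subject_id: p for p in profiles}
    subject_ids = [p.subject_id for p in profiles if p.subject_id in signal_sets]
    missing = set(signal_sets) - set(profile_by_id)
    if missing:
        raise FeatureError(f"signal sets without profiles: {sorted(missing)}")
    if not subject_ids:
        raise FeatureError("no subjects")

    inventories = {
        sid: tuple(sorted((k, v.size) for k, v in signal_sets[sid].signals.items()))
        for sid in subject_ids
    }
    first = inventories[subject_ids[0]]
    for sid, inv in inventories.items():
        if inv != first:
            raise FeatureError(
                f"signal inventory of subject {sid} differs from "
                f"subject {subject_ids[0]}")

    signal_keys = _ordered_signal_keys(signal_sets[subject_ids[0]])
    rows = []
    for sid in subject_ids:
        sset = signal_sets[sid]
        row: dict[str, float] = {}
        for key in signal_keys:
            zone, measurement, footwear = key[0], key[1], key[2]
            fid_suffix = "" if len(key) == 3 else f"_{key[3]}"
            values = extract_feature_bank(sset.signals[key], bank)
            for fid, v in values.items():
                row[render_feature_name(zone, measurement, footwear,
                                        fid + fid_suffix)] = v
        row.update(person_feature_row(profile_by_id[sid]))
        row[LABEL_COLUMN] = int(profile_by_id[sid].injured)
        rows.append(row)

    df = pd.DataFrame(rows, index=pd.Index(subject_ids, name="subject_id"))
    return df


def _ordered_signal_keys(sset: SubjectSignalSet) -> list[tuple]:
    zone_order = {z: i for i, z in enumerate((*ZONES, WHOLE_FOOT))}
    meas_order = {m: i for i, m in enumerate((*MEASUREMENTS, VERTICAL_FORCE))}
    fw_order = {f: i for i, f in enumerate(FOOTWEARS)}
    return sorted(
        sset.signals.keys(),
        key=lambda k: (fw_order.get(k[2], 99), zone_order.get(k[0], 99),
                       meas_order.get(k[1], 99), k[3:] if len(k) > 3 else ()),
    )


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c != LABEL_COLUMN]
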