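"""Trial alignment, per-subject averaging and scale normalisation.

Running trials differ in length (stance duration varies between
footfalls), so before averaging, every trial is zero-padded to the
length of the longest running trial of its footwear condition
("the reference").  Among all ways of distributing the padding between
the beginning and the end of the series, the one maximising the
2D-histogram mutual information between the padded series and the
reference is kept — the alignment that best matches the stance phases
without stretching or compressing the signal.

Aligned trials of a subject are averaged pointwise per (zone,
measurement, footwear), and the pressure/force averages are divided by
the subject's maximum barefoot-walking vertical force to remove body
weight and speed differences while preserving the relative load
distribution across zones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import Trial, TrialStore
from .zones import MEASUREMENTS, VERTICAL_FORCE, WHOLE_FOOT, ZONES

DEFAULT_N_BINS = 256
#: MI values closer than this are treated as tied (smallest left pad wins)
MI_TIE_TOL = 1e-9


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# mutual information

def _bin_indices(x: np.ndarray, n_bins: int,
                 lo: float | None = None, hi: float | None = None):
    """Histogram bin index per sample on a uniform grid over [lo, hi]
    (defaults to the signal's own range).  Returns (indices, non_degenerate)."""
    if lo is None:
        lo = float(x.min())
    if hi is None:
        hi = float(x.max())
    if hi <= lo:
        return np.zeros(x.size, dtype=np.int64), False
    ix = ((x - lo) * (n_bins / (hi - lo))).astype(np.int64)
    np.clip(ix, 0, n_bins - 1, out=ix)
    return ix, True


def _entropy_nats(counts: np.ndarray, n: int) -> float:
    p = counts / n
    return float(-(p * np.log(p)).sum())


def _mi_from_indices(ix: np.ndarray, iy: np.ndarray, n_bins: int) -> float:
    """MI (nats) of the joint histogram given precomputed bin indices."""
    n = ix.size
    _, cx = np.unique(ix, return_counts=True)
    _, cy = np.unique(iy, return_counts=True)
    _, cxy = np.unique(ix.astype(np.int64) * n_bins + iy, return_counts=True)
    mi = _entropy_nats(cx, n) + _entropy_nats(cy, n) - _entropy_nats(cxy, n)
    return max(mi, 0.0)


def mutual_information_2d(x, y, n_bins: int = DEFAULT_N_BINS) -> float:
    """Histogram-based mutual information (in nats) between paired signals.

    The joint histogram lives on an ``n_bins`` x ``n_bins`` grid spanning
    each signal's own [min, max]; empty cells contribute nothing.
    Degenerate (constant) signals have MI 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 2:
        raise AlignmentError("need at least 2 samples")
    ix, okx = _bin_indices(x, n_bins)
    iy, oky = _bin_indices(y, n_bins)
    if not (okx and oky):
        return 0.0
    return _mi_from_indices(ix, iy, n_bins)


# ---------------------------------------------------------------------------
# reference selection and alignment

@dataclass(frozen=True)
class Reference:
    """Longest running trial for one footwear condition; shared across all
    subjects and measurement types."""

    footwear: str
    length: int
    subject_id: str
    foot: str
    trial_index: int
    #: measurement -> zone -> reference signal of that (measurement, zone)
    signals: Mapping[str, Mapping[str, np.ndarray]] = field(hash=False, default=None)


def select_reference(store: TrialStore, footwear: str) -> Reference:
    """Pick the longest running trial of ``footwear``; ties go to the
    lowest (subject_id, foot, trial_index)."""
    best_key = None
    best_len = -1
    for t in store.iter_trials(footwear=footwear, gait="run"):
        key = (t.subject_id, t.foot, t.trial_index)
        n = len(t.values)
        if n > best_len or (n == best_len and key < best_key):
            best_len, best_key = n, key
    if best_key is None:
        raise AlignmentError(f"no running trials for footwear {footwear!r}")

    subject_id, foot, trial_index = best_key
    signals: dict[str, dict[str, np.ndarray]] = {}
    for t in store.iter_trials(subject_id=subject_id, footwear=footwear, gait="run"):
        if t.foot == foot and t.trial_index == trial_index:
            signals.setdefault(t.measurement, {})[t.zone] = np.asarray(t.values, float)
    return Reference(footwear, best_len, subject_id, foot, trial_index, signals)


@dataclass(frozen=True)
class AlignedTrial:
    trial: Trial
    left_pad: int
    right_pad: int
    values: np.ndarray  # padded to reference length
    mi: float


def align_trial(trial: Trial, reference_values: np.ndarray,
                n_bins: int = DEFAULT_N_BINS) -> AlignedTrial:
    """Exhaustively try every (left, right) zero-padding that brings
    ``trial`` to the reference length and keep the one with maximal
    mutual information against ``reference_values``; ties break towards
    the smallest left pad."""
    x = np.asarray(trial.values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    n, m = x.size, ref.size
    if n > m:
        raise AlignmentError(f"trial length {n} exceeds reference length {m}")
    if n == m:
        return AlignedTrial(trial, 0, 0, x.copy(), mutual_information_2d(x, ref, n_bins))

    pad_total = m - n
    # Every padded variant holds the same multiset of values, so the
    # histogram range [min(0, min x), max(0, max x)] — and hence each
    # sample's bin and the marginal entropies — are shared across
    # variants; only the joint entropy depends on the padding.
    lo = min(0.0, float(x.min()))
    hi = max(0.0, float(x.max()))
    iy, oky = _bin_indices(ref, n_bins)
    if hi <= lo or not oky:
        # degenerate on either side: MI is 0 for every padding
        padded = np.zeros(m)
        padded[0:n] = x
        return AlignedTrial(trial, 0, pad_total, padded, 0.0)

    ix_vals, _ = _bin_indices(x, n_bins, lo, hi)
    ix_zero = int(np.clip((0.0 - lo) * (n_bins / (hi - lo)), 0, n_bins - 1))

    ix_full = np.full(m, ix_zero, dtype=np.int64)
    ix_full[:n] = ix_vals
    _, cx = np.unique(ix_full, return_counts=True)
    _, cy = np.unique(iy, return_counts=True)
    h_marginals = _entropy_nats(cx, m) + _entropy_nats(cy, m)

    # joint codes for all shifts at once: row s = padding (left=s)
    n_shifts = pad_total + 1
    codes = np.broadcast_to(np.int64(ix_zero) * n_bins + iy, (n_shifts, m)).copy()
    cols = np.arange(n) + np.arange(n_shifts)[:, None]
    codes[np.arange(n_shifts)[:, None], cols] = ix_vals * n_bins + iy[cols]
    codes.sort(axis=1)

    # run-length counts per row -> joint entropy per shift
    change = np.ones((n_shifts, m), dtype=bool)
    change[:, 1:] = codes[:, 1:] != codes[:, :-1]
    flat = np.flatnonzero(change.ravel())
    rows = flat // m
    starts = flat % m
    run_end = np.empty(flat.size, dtype=np.int64)
    run_end[:-1] = starts[1:]
    run_end[-1] = m
    last_in_row = np.empty(flat.size, dtype=bool)
    last_in_row[:-1] = rows[1:] != rows[:-1]
    last_in_row[-1] = True
    counts = np.where(last_in_row, m - starts, run_end - starts)
    p = counts / m
    h_joint = np.bincount(rows, weights=-p * np.log(p), minlength=n_shifts)

    mi_all = np.maximum(h_marginals - h_joint, 0.0)
    # smallest left pad among ties; the tolerance absorbs float-summation
    # noise between mathematically identical pairings
    best_left = int(np.flatnonzero(mi_all >= mi_all.max() - MI_TIE_TOL)[0])

    padded = np.zeros(m)
    padded[best_left:best_left + n] = x
    return AlignedTrial(trial, best_left, pad_total - best_left, padded,
                        float(mi_all[best_left]))


# ---------------------------------------------------------------------------
# aggregation and normalisation

def aggregate_subject(aligned: Iterable[AlignedTrial] | Iterable[np.ndarray]) -> np.ndarray:
    """Pointwise mean of a subject's aligned trials (equal lengths required)."""
    arrays = [a.values if isinstance(a, AlignedTrial) else np.asarray(a, float)
              for a in aligned]
    if not arrays:
        raise AlignmentError("no trials to aggregate")
    lengths = {a.size for a in arrays}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


@dataclass
class SubjectSignalSet:
    """All aligned, averaged (and optionally normalised) signals of a subject.

    ``signals`` maps (zone, measurement, footwear) -> array; vertical
    force uses zone ``whole_foot``.
    """

    subject_id: str
    signals: dict
    scale_factor: float = 1.0


def max_walking_vertical_force(store: TrialStore, subject_id: str) -> float:
    """Subject's maximum vertical force over all barefoot walking trials."""
    best = None
    for t in store.iter_trials(subject_id=subject_id, footwear="barefoot",
                               gait="walk", measurement=VERTICAL_FORCE):
        m = float(np.max(t.values))
        best = m if best is None else max(best, m)
    if best is None:
        raise AlignmentError(f"no barefoot walking vertical-force data "
                             f"for subject {subject_id}")
    if best <= 0:
        raise AlignmentError(f"all-zero walking vertical force for {subject_id}")
    return best


_NORMALIZED_MEASUREMENTS = set(MEASUREMENTS)  # peak/mean pressure, mean force


def normalize_scale(signal_set: SubjectSignalSet,
                    walking_max_vf: float) -> SubjectSignalSet:
    """Divide pressure/force signals by the subject's maximum
    barefoot-walking vertical force; relative zone ratios are unchanged."""
    if walking_max_vf <= 0:
        raise AlignmentError("walking maximum vertical force must be positive")
    out = {}
    for key, sig in signal_set.signals.items():
        _, measurement, _ = key
        if measurement in _NORMALIZED_MEASUREMENTS:
            out[key] = sig / walking_max_vf
        else:
            out[key] = sig.copy()
    return SubjectSignalSet(signal_set.subject_id, out, scale_factor=walking_max_vf)


# ---------------------------------------------------------------------------
# full preprocessing pass

def preprocess_cohort(
    store: TrialStore,
    subject_ids: Iterable[str] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    pool_feet: bool = True,
    normalize: bool = True,
) -> tuple[dict[str, SubjectSignalSet], dict]:
    """Align, average and normalise every subject's running signals.

    Returns ``(signal_sets, info)`` where ``info`` records the reference
    per footwear and per-trial alignment metadata.  With
    ``pool_feet=True`` (default) both feet contribute to one average per
    (zone, measurement, footwear); otherwise feet are averaged
    separately and the key gains a foot suffix.
    """
    if subject_ids is None:
        subject_ids = store.subject_ids()
    subject_ids = list(subject_ids)

    references = {fw: select_reference(store, fw) for fw in ("barefoot", "shod")}
    info: dict = {
        "references": {
            fw: {"length": r.length, "subject_id": r.subject_id,
                 "foot": r.foot, "trial_index": r.trial_index}
            for fw, r in references.items()
        },
        "alignments": [],
    }

    # group run trials: subject -> (zone, measurement, footwear[, foot]) -> list
    grouped: dict[str, dict[tuple, list[AlignedTrial]]] = {s: {} for s in subject_ids}
    wanted = set(subject_ids)
    for t in store.iter_trials(gait="run"):
        if t.subject_id not in wanted:
            continue
        ref = references[t.footwear]
        ref_sig = ref.signals[t.measurement][t.zone]
        at = align_trial(t, ref_sig, n_bins=n_bins)
        info["alignments"].append({
            "subject_id": t.subject_id, "footwear": t.footwear, "foot": t.foot,
            "trial_index": t.trial_index, "measurement": t.measurement,
            "zone": t.zone, "left_pad": at.left_pad, "right_pad": at.right_pad,
            "mi": at.mi,
        })
        key = ((t.zone, t.measurement, t.footwear) if pool_feet
               else (t.zone, t.measurement, t.footwear, t.foot))
        grouped[t.subject_id].setdefault(key, []).append(at)

    signal_sets: dict[str, SubjectSignalSet] = {}
    for sid in subject_ids:
        signals = {key: aggregate_subject(ats) for key, ats in grouped[sid].items()}
        sset = SubjectSignalSet(sid, signals)
        if normalize:
            sset = normalize_scale(sset, max_walking_vertical_force(store, sid))
        signal_sets[sid] = sset
    return signal_sets, info


def write_signal_cache(out_dir: str | Path,
                       signal_sets: Mapping[str, SubjectSignalSet],
                       info: dict) -> None:
    """Persist aligned signals as long CSV plus a JSON alignment sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, sset in signal_sets.items():
        for key, sig in sorted(sset.signals.items()):
            zone, measurement, footwear = key[0], key[1], key[2]
            rows.append(pd.DataFrame({
                "subject_id": sid, "zone": zone, "measurement": measurement,
                "footwear": footwear, "sample_index": np.arange(sig.size),
                "value": sig,
            }))
    pd.concat(rows, ignore_index=True).to_csv(out / "signals.csv", index=False)
    (out / "alignment.json").write_text(json.dumps(info, sort_keys=True))
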