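"""Inclusion/exclusion filter for the outcome roster.

Only subjects who either stayed healthy or developed a lower-extremity
overuse injury enter the analysis; subjects with an acute injury, an
unknown injury status, or missing/invalid records are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

OUTCOME_CLASSES = (
    "healthy",
    "lower_extremity_overuse",
    "acute",
    "unknown",
    "missing_invalid",
)
_INCLUDED_CLASSES = {"healthy": 0, "lower_extremity_overuse": 1}


class RosterError(ValueError):
    pass


@dataclass(frozen=True)
class InclusionResult:
    included_ids: tuple[str, ...]
    labels: dict  # subject_id -> 0 (healthy) / 1 (overuse)
    class_counts: dict  # outcome_class -> count over the full roster

    @property
    def n_included(self) -> int:
        return len(self.included_ids)


def apply_inclusion_criteria(roster: pd.DataFrame) -> InclusionResult:
    """Filter an outcome roster (columns ``subject_id``, ``outcome_class``).

    Healthy subjects get label 0, overuse-injured subjects label 1; all
    other classes are excluded.  Roster order is preserved.
    """
    if roster.duplicated("subject_id").any():
        dups = roster.loc[roster.duplicated("subject_id"), "subject_id"].tolist()
        raise RosterError(f"duplicate subject_id entries: {dups}")
    bad = set(roster["outcome_class"]) - set(OUTCOME_CLASSES)
    if bad:
        raise RosterError(f"unknown outcome classes: {sorted(bad)}")

    counts = {c: int((roster["outcome_class"] == c).sum()) for c in OUTCOME_CLASSES}
    mask = roster["outcome_class"].isin(_INCLUDED_CLASSES)
    included = roster.loc[mask]
    labels = {
        str(r.subject_id): _INCLUDED_CLASSES[r.outcome_class]
        for r in included.itertuples()
    }
    return InclusionResult(tuple(str(s) for s in included["subject_id"]),
                           labels, counts)


def filter_roster_files(
    roster_csv: str | Path, out_dir: str | Path
) -> InclusionResult:
    """CSV-in / CSV+JSON-out wrapper around :func:`apply_inclusion_criteria`."""
    roster = pd.read_csv(roster_csv)
    result = apply_inclusion_criteria(roster)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "subject_id": result.included_ids,
        "label": [result.labels[s] for s in result.included_ids],
    }).to_csv(out / "included_subjects.csv", index=False)
    (out / "inclusion_counts.json").write_text(
        json.dumps({"n_included": result.n_included,
                    "class_counts": result.class_counts},
                   sort_keys=True, indent=2))
    return result
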