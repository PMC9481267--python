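"""Group-exclusion importance analysis and fold-occurrence reporting.

Features form overlapping "groups" along three kinds: the foot area
they were measured on, the measurement type (peak pressure, mean
pressure, mean force, vertical force, or the general person
characteristics), and the footwear condition.  The impact of a group is
the change in LOOCV AUC/Brier when the whole group is removed from the
feature pool before fold-wise selection, relative to a baseline that
may select from everything.  Both runs pick a fixed budget of features
per fold — the 10% rule, round(0.1 * N) features for N subjects —
because re-running the full k grid for every group is needlessly
expensive.

Signs follow the convention "positive = the model improved when the
group was excluded": delta_auc = AUC_excluded - AUC_baseline and
delta_brier = Brier_baseline - Brier_excluded (Brier is
lower-is-better).  Rank 1 marks the most important group (most negative
delta_auc); exact ties share an average rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import LoocvResult, run_loocv
from .features import (
    LABEL_COLUMN,
    NO_FOOTWEAR,
    PERSON_ZONE,
    feature_columns,
    parse_feature_name,
)
from .model import ModelConfig
from .zones import FOOTWEARS, MEASUREMENTS, VERTICAL_FORCE, WHOLE_FOOT, ZONES

GROUP_KINDS = ("foot_area", "measurement", "footwear")
PERSON_GROUP = "general_person_characteristics"


class ImportanceError(ValueError):
    pass


def feature_budget(n_subjects: int) -> int:
    """10%-rule feature budget: floor(0.1 * N) (0.1 * 155 -> 15)."""
    return int(np.floor(0.1 * n_subjects))


def assign_feature_groups(names: list[str]) -> dict[str, dict[str, list[str]]]:
    """Map every feature into one group per kind.

    Foot-area groups are the ten anatomical zones (whole-foot vertical
    force and person characteristics belong to no foot-area group);
    measurement groups are the four signal types plus the person
    characteristics; footwear groups are barefoot/shod (person features
    belong to neither).
    """
    groups: dict[str, dict[str, list[str]]] = {
        "foot_area": {z: [] for z in ZONES},
        "measurement": {m: [] for m in (*MEASUREMENTS, VERTICAL_FORCE)},
        "footwear": {f: [] for f in FOOTWEARS},
    }
    groups["measurement"][PERSON_GROUP] = []
    for name in names:
        zone, measurement, footwear, _ = parse_feature_name(name)
        if zone == PERSON_ZONE:
            groups["measurement"][PERSON_GROUP].append(name)
            continue
        if zone != WHOLE_FOOT:
            groups["foot_area"][zone].append(name)
        groups["measurement"][measurement].append(name)
        if footwear != NO_FOOTWEAR:
            groups["footwear"][footwear].append(name)
    return groups


def group_exclusion_analysis(
    table: pd.DataFrame,
    config: ModelConfig = ModelConfig(),
    budget: int | None = None,
) -> tuple[pd.DataFrame, LoocvResult]:
    """LOOCV impact of excluding each feature group.

    Returns (impact table with columns kind/group/delta_auc/delta_brier/
    rank, baseline LoocvResult).  Runs are fully deterministic, so a
    group whose features are never selected produces deltas of exactly 0.
    """
    names = feature_columns(table)
    n = len(table)
    if budget is None:
        budget = feature_budget(n)
    groups = assign_feature_groups(names)

    baseline = run_loocv(table, config, fixed_k=budget)
    base_auc, base_brier = baseline.auc, baseline.brier

    rows = []
    for kind in GROUP_KINDS:
        for group_name, members in groups[kind].items():
            member_set = set(members)
            remaining = [c for c in names if c not in member_set]
            if len(remaining) < budget:
                raise ImportanceError(
                    f"excluding group {group_name!r} leaves "
                    f"{len(remaining)} < budget {budget} features")
            if members:
                res = run_loocv(table, config, fixed_k=budget, columns=remaining)
                d_auc = res.auc - base_auc
                d_brier = base_brier - res.brier
            else:  # empty group: identical run by construction
                d_auc = 0.0
                d_brier = 0.0
            rows.append({"kind": kind, "group": group_name,
                         "delta_auc": d_auc, "delta_brier": d_brier})

    impact = pd.DataFrame(rows)
    impact["rank"] = np.nan
    for kind in GROUP_KINDS:
        sub = impact[impact["kind"] == kind]
        impact.loc[sub.index, "rank"] = _lexicographic_ranks(
            sub["delta_auc"].to_numpy(), sub["delta_brier"].to_numpy())
    impact = impact.sort_values(["kind", "rank"]).reset_index(drop=True)
    return impact, baseline


def _lexicographic_ranks(primary: np.ndarray, secondary: np.ndarray) -> np.ndarray:
    """Ranks ascending in (primary, secondary); full ties share the
    average rank (e.g. two groups tied at the top rank 1.5 each)."""
    order = np.lexsort((secondary, primary))
    ranks = np.empty(len(primary))
    pos = 1.0
    i = 0
    while i < len(order):
        j = i
        while (j + 1 < len(order)
               and primary[order[j + 1]] == primary[order[i]]
               and secondary[order[j + 1]] == secondary[order[i]]):
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        pos += j - i + 1
        i = j + 1
    return ranks


def feature_occurrence(result: LoocvResult,
                       threshold: float = 0.10) -> pd.DataFrame:
    """Fraction of folds in which a feature survived both selection
    stages (top-k ranking AND a nonzero L1 weight); features at or above
    ``threshold`` are reported, sorted by foot area then occurrence."""
    n_folds = result.n
    counts: dict[str, int] = {}
    for rec in result.records:
        surviving = set(rec.selected) & set(rec.nonzero)
        for f in surviving:
            counts[f] = counts.get(f, 0) + 1

    zone_order = {z: i for i, z in enumerate((*ZONES, WHOLE_FOOT, PERSON_ZONE))}
    rows = []
    for name, c in counts.items():
        occ = c / n_folds
        if occ + 1e-12 >= threshold:
            zone, measurement, footwear, fid = parse_feature_name(name)
            rows.append({"foot_area": zone, "measurement": measurement,
                         "footwear": footwear, "feature": fid,
                         "occurrence_pct": 100.0 * occ})
    df = pd.DataFrame(rows, columns=["foot_area", "measurement", "footwear",
                                     "feature", "occurrence_pct"])
    if len(df):
        df["_z"] = df["foot_area"].map(zone_order)
        df = (df.sort_values(["_z", "occurrence_pct", "feature"],
                             ascending=[True, False, True])
                .drop(columns="_z").reset_index(drop=True))
    return df
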