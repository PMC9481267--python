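"""Anatomical foot zones and their default activation templates.

A pressure plate segments each footprint into ten anatomical zones:
hallux (toe 1), toes 2-5, the five metatarsal heads, midfoot, and the
medial and lateral heel.  During stance the load rolls from the heel
over the midfoot and metatarsal heads towards the toes, so each zone is
active only on a sub-interval of stance.  The templates below encode
that roll-off together with plausible zone areas (cm^2) and the ratio
between peak and mean pressure within a zone.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical zone order, medial-to-lateral within forefoot, then midfoot/heel.
ZONES: tuple[str, ...] = (
    "toe_1",
    "toes_2_5",
    "metatarsal_1",
    "metatarsal_2",
    "metatarsal_3",
    "metatarsal_4",
    "metatarsal_5",
    "midfoot",
    "medial_heel",
    "lateral_heel",
)

#: Zones under the forefoot: the metatarsal heads and the toes.
FOREFOOT_ZONES: frozenset[str] = frozenset(
    {"toe_1", "toes_2_5", "metatarsal_1", "metatarsal_2",
     "metatarsal_3", "metatarsal_4", "metatarsal_5"}
)

WHOLE_FOOT = "whole_foot"

MEASUREMENTS: tuple[str, ...] = ("peak_pressure", "mean_pressure", "mean_force")
VERTICAL_FORCE = "vertical_force"
FOOTWEARS: tuple[str, ...] = ("barefoot", "shod")
GAITS: tuple[str, ...] = ("walk", "run")
FEET: tuple[str, ...] = ("left", "right")


@dataclass(frozen=True)
class ZoneTemplate:
    """Activation window and load parameters for one anatomical zone.

    Parameters
    ----------
    zone : str
        One of :data:`ZONES`.
    onset_frac, offset_frac : float
        Start/end of the zone's active window as fractions of stance
        duration, ``0 <= onset < offset <= 1``.
    amplitude : float
        Relative mean-pressure amplitude of the zone (dimensionless; the
        absolute scale is set so the whole-foot vertical force reaches a
        gait-specific multiple of body weight).
    peak_factor : float
        Ratio of peak to mean pressure within the zone, ``>= 1``.
    area : float
        Zone contact area in cm^2.
    """

    zone: str
    onset_frac: float
    offset_frac: float
    amplitude: float
    peak_factor: float
    area: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.onset_frac < self.offset_frac <= 1.0):
            raise ValueError(
                f"zone {self.zone}: need 0 <= onset < offset <= 1, "
                f"got ({self.onset_frac}, {self.offset_frac})"
            )
        if self.area <= 0:
            raise ValueError(f"zone {self.zone}: area must be positive")
        if self.peak_factor < 1.0:
            raise ValueError(f"zone {self.zone}: peak_factor must be >= 1")


def default_zone_templates() -> dict[str, ZoneTemplate]:
    """Heel-to-toe roll-off templates: heels 0-40%, midfoot 20-60%,
    metatarsals 30-90%, toes 55-100% of stance."""
    params = {
        # zone: (onset, offset, amplitude, peak_factor, area)
        "medial_heel": (0.00, 0.40, 1.00, 1.6, 14.0),
        "lateral_heel": (0.00, 0.40, 0.90, 1.6, 11.0),
        "midfoot": (0.20, 0.60, 0.35, 1.8, 30.0),
        "metatarsal_1": (0.30, 0.90, 0.90, 1.7, 8.0),
        "metatarsal_2": (0.30, 0.90, 1.00, 1.7, 7.0),
        "metatarsal_3": (0.30, 0.90, 0.95, 1.7, 7.0),
        "metatarsal_4": (0.30, 0.90, 0.70, 1.7, 6.0),
        "metatarsal_5": (0.30, 0.90, 0.55, 1.8, 5.0),
        "toe_1": (0.55, 1.00, 0.80, 1.5, 9.0),
        "toes_2_5": (0.55, 1.00, 0.40, 1.9, 10.0),
    }
    return {
        z: ZoneTemplate(z, on, off, amp, pf, area)
        for z, (on, off, amp, pf, area) in params.items()
    }
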