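"""Behaviour catalogue for the captive-otariid ethogram.

26 behaviours grouped into five categories. The first four categories
(foraging, grooming, resting, travelling) are the modelling targets; the
'other' category collects husbandry and out-of-sight intervals that do not
occur in the wild and is excluded from analysis downstream.

The category printed as "Feeding" in some ethogram tables is the same class
as "foraging" in the running text; it is canonicalised to ``foraging`` here.
"""

from __future__ import annotations

#: canonical category order used everywhere (confusion matrices, transition
#: matrices, class probabilities).
MODEL_CATEGORIES: tuple[str, ...] = ("foraging", "grooming", "resting", "travelling")
CATEGORIES: tuple[str, ...] = MODEL_CATEGORIES + ("other",)

#: behaviour -> category. Travelling (5), foraging (5), resting (3),
#: grooming (7) follow the published bout catalogue; the six 'other'
#: behaviours cover trainer interaction and out-of-sight time.
BEHAVIOUR_TO_CATEGORY: dict[str, str] = {
    # travelling
    "Walking": "travelling",
    "Surface swimming": "travelling",
    "Swimming": "travelling",
    "Fast": "travelling",
    "Porpoising": "travelling",
    # foraging ("Feeding")
    "Chewing": "foraging",
    "Searching": "foraging",
    "Thrash": "foraging",
    "Manipulation": "foraging",
    "Hold and tear": "foraging",
    # resting
    "Lying": "resting",
    "Sitting": "resting",
    "Still": "resting",
    # grooming
    "Scratch": "grooming",
    "Rubbing": "grooming",
    "Sailing": "grooming",
    "Jugging": "grooming",
    "Face rub": "grooming",
    "Shake": "grooming",
    "Rolling": "grooming",
    # other (excluded from analysis)
    "Hand feeding": "other",
    "Out of sight": "other",
    "Pool transit": "other",
    "Station": "other",
    "Playing": "other",
    "Haul out": "other",
}

BEHAVIOURS: tuple[str, ...] = tuple(BEHAVIOUR_TO_CATEGORY)

#: tie-break precedence for epoch labelling: grooming and foraging take
#: precedence over travelling and resting (and foraging over grooming on a
#: direct tie); 'other' never wins a tie.
CATEGORY_PRECEDENCE: tuple[str, ...] = ("foraging", "grooming", "travelling", "resting", "other")


def category_of(behaviour: str) -> str:
    """Return the category of a behaviour name, raising on unknown names."""
    try:
        return BEHAVIOUR_TO_CATEGORY[behaviour]
    except KeyError:
        raise KeyError(f"unknown behaviour name: {behaviour!r}") from None
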