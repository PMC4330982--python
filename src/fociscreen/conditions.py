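"""Exposure conditions of the ex vivo irradiation assay.

Each blood sample is split three ways: an unirradiated control
(*preexisting* foci), a sample fixed 30 min after 0.5 Gy X-rays (*initial*
foci, near the peak of H2AX phosphorylation), and a sample fixed 24 h after
2 Gy (*remaining*, i.e. unrepaired, foci).  The low dose for the initial
time point keeps foci countable; the high dose for the 24 h time point
leaves enough residual damage to score.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ExposureCondition:
    """One arm of the ex vivo assay.

    Attributes
    ----------
    label:
        One of ``"preexisting"``, ``"initial"``, ``"remaining"``.
    dose_gy:
        X-ray dose in gray.
    incubation_min:
        Time between irradiation and fixation, in minutes.
    """

    label: str
    dose_gy: float
    incubation_min: float


PREEXISTING = ExposureCondition("preexisting", 0.0, 0)
INITIAL = ExposureCondition("initial", 0.5, 30)
REMAINING = ExposureCondition("remaining", 2.0, 1440)

#: The three assay arms, in assay order.  The label <-> (dose, incubation)
#: mapping is fixed and bijective.
CONDITIONS: dict[str, ExposureCondition] = {
    c.label: c for c in (PREEXISTING, INITIAL, REMAINING)
}

CONDITION_ORDER = ("preexisting", "initial", "remaining")

#: Study groups: healthy individuals and rectal cancer patients.
GROUPS = ("HI", "RC")


def condition(label: str) -> ExposureCondition:
    """Look up a condition by label; raise ``KeyError`` for unknown labels."""
    return CONDITIONS[label]
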