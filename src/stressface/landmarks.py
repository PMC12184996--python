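"""Facial landmark and composite-feature identifiers.

Seven landmarks are tracked on the face of a head-fixed mouse: the two
ears, the four eyelids (upper/lower for each eye) and the nose.  For
scoring purposes they collapse into five composite features: each ear,
each eye (owning its eyelid pair) and the nose.
"""

from __future__ import annotations

from enum import Enum


class Landmark(str, Enum):
    """The seven tracked facial landmarks, in canonical column order."""

    EAR_LEFT = "ear_left"
    EAR_RIGHT = "ear_right"
    EYELID_UPPER_LEFT = "eyelid_upper_left"
    EYELID_LOWER_LEFT = "eyelid_lower_left"
    EYELID_UPPER_RIGHT = "eyelid_upper_right"
    EYELID_LOWER_RIGHT = "eyelid_lower_right"
    NOSE = "nose"


#: Canonical ordering used for array axes and file columns.
LANDMARKS: tuple[Landmark, ...] = tuple(Landmark)

#: name -> array index in the canonical ordering
LANDMARK_INDEX: dict[str, int] = {lm.value: i for i, lm in enumerate(LANDMARKS)}

N_LANDMARKS = len(LANDMARKS)


class Feature(str, Enum):
    """The five composite scoring features."""

    EAR_LEFT = "EAR_LEFT"
    EAR_RIGHT = "EAR_RIGHT"
    EYE_LEFT = "EYE_LEFT"
    EYE_RIGHT = "EYE_RIGHT"
    NOSE = "NOSE"


FEATURES: tuple[Feature, ...] = tuple(Feature)

#: Which landmarks drive each composite feature.
FEATURE_LANDMARKS: dict[Feature, tuple[Landmark, ...]] = {
    Feature.EAR_LEFT: (Landmark.EAR_LEFT,),
    Feature.EAR_RIGHT: (Landmark.EAR_RIGHT,),
    Feature.EYE_LEFT: (Landmark.EYELID_UPPER_LEFT, Landmark.EYELID_LOWER_LEFT),
    Feature.EYE_RIGHT: (Landmark.EYELID_UPPER_RIGHT, Landmark.EYELID_LOWER_RIGHT),
    Feature.NOSE: (Landmark.NOSE,),
}

#: (upper, lower) eyelid pair per eye side.
EYELID_PAIRS: dict[str, tuple[Landmark, Landmark]] = {
    "left": (Landmark.EYELID_UPPER_LEFT, Landmark.EYELID_LOWER_LEFT),
    "right": (Landmark.EYELID_UPPER_RIGHT, Landmark.EYELID_LOWER_RIGHT),
}

EARS: dict[str, Landmark] = {"left": Landmark.EAR_LEFT, "right": Landmark.EAR_RIGHT}
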