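"""The four emotion categories and their canonical order.

Every matrix, kernel and report in the package indexes emotions in the fixed
order joy, neutral, sadness, anger; the single-letter aliases (J, N, S, A)
are the ones used in contrast labels such as ``"N<J"``.
"""
from __future__ import annotations

from enum import Enum


class EmotionLabel(str, Enum):
    """One of the four emotional states a listener can assign."""

    JOY = "joy"
    NEUTRAL = "neutral"
    SADNESS = "sadness"
    ANGER = "anger"

    @property
    def letter(self) -> str:
        return _LETTERS[self]

    @classmethod
    def from_string(cls, value: "str | EmotionLabel") -> "EmotionLabel":
        if isinstance(value, cls):
            return value
        v = str(value).strip().lower()
        if v in _ALIASES:
            return _ALIASES[v]
        raise ValueError(f"unknown emotion label: {value!r}")


#: Canonical ordering used for all matrices and reports.
EMOTIONS: tuple[EmotionLabel, ...] = (
    EmotionLabel.JOY,
    EmotionLabel.NEUTRAL,
    EmotionLabel.SADNESS,
    EmotionLabel.ANGER,
)

EMOTION_NAMES: tuple[str, ...] = tuple(e.value for e in EMOTIONS)

#: Canonical index of each emotion.
EMOTION_INDEX: dict[EmotionLabel, int] = {e: i for i, e in enumerate(EMOTIONS)}

_LETTERS = {
    EmotionLabel.JOY: "J",
    EmotionLabel.NEUTRAL: "N",
    EmotionLabel.SADNESS: "S",
    EmotionLabel.ANGER: "A",
}

_ALIASES: dict[str, EmotionLabel] = {}
for _e in EMOTIONS:
    _ALIASES[_e.value] = _e
    _ALIASES[_LETTERS[_e].lower()] = _e
_ALIASES["sad"] = EmotionLabel.SADNESS
_ALIASES["happy"] = EmotionLabel.JOY
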