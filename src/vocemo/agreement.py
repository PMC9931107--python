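"""Inter-rater agreement via Cohen's kappa.

kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
agreement p_e from the product of the two raters' marginal distributions.
Per-emotion agreement collapses labels to {emotion, other} before computing
kappa (one-vs-rest binarization).  Group-level agreement is the arithmetic
mean of pairwise kappas: over all unordered pairs within a group, or all
cross pairs between two groups; pairs whose kappa is undefined (chance
agreement 1, or the target emotion unused by both raters) are skipped and
counted, not imputed.

Strength-of-agreement bands (closed upper bounds): slight (<= 0.20), fair
(<= 0.40), moderate (<= 0.60), substantial (<= 0.80), almost perfect
(<= 1.00).  Negative kappa is retained, banded slight with a below-zero flag.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .emotions import EmotionLabel
from .errors import InvalidSpecError, UndefinedKappaError

BANDS = ("slight", "fair", "moderate", "substantial", "almost_perfect")
_BAND_UPPER = (0.20, 0.40, 0.60, 0.80, 1.00)


@dataclass
class KappaResult:
    kappa: float
    band: str
    scope: str                       # "pair", "within_group", "between_group"
    emotion: EmotionLabel | None     # None = all emotions
    n_pairs_averaged: int
    n_pairs_undefined: int = 0
    below_zero: bool = False


def band_strength(kappa: float) -> str:
    """Map a kappa value to its strength-of-agreement band."""
    if kappa > 1.0 + 1e-12:
        raise ValueError("kappa cannot exceed 1")
    if kappa < 0:
        return "slight"
    for band, upper in zip(BANDS, _BAND_UPPER):
        if kappa <= upper + 1e-12:
            return band
    return "almost_perfect"


def _normalize(labels) -> list[str]:
    return [EmotionLabel.from_string(l).value for l in labels]


def cohen_kappa(ratings_a, ratings_b) -> float:
    """Cohen's kappa between two raters over the same stimulus sequence."""
    a = list(ratings_a)
    b = list(ratings_b)
    if len(a) != len(b):
        raise InvalidSpecError("rating vectors must have equal length")
    n = len(a)
    if n < 2:
        raise InvalidSpecError("need at least 2 rated stimuli")
    cats = sorted(set(a) | set(b))
    idx = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedKappaError(
            "chance agreement is 1 (both raters constant); kappa undefined"
        )
    return (p_o - p_e) / (1.0 - p_e)


def per_emotion_kappa(ratings_a, ratings_b, emotion: EmotionLabel | str) -> float:
    """Kappa for one emotion after one-vs-rest binarization.

    Undefined when neither rater ever used the emotion (the degenerate case
    that blocks averaging in sparse panels).
    """
    target = EmotionLabel.from_string(emotion).value
    a = _normalize(ratings_a)
    b = _normalize(ratings_b)
    if target not in a and target not in b:
        raise UndefinedKappaError(
            f"emotion {target!r} absent from both raters; kappa undefined"
        )
    a_bin = [l if l == target else "other" for l in a]
    b_bin = [l if l == target else "other" for l in b]
    if len(a_bin) != len(b_bin):
        raise InvalidSpecError("rating vectors must have equal length")
    n = len(a_bin)
    table = np.zeros((2, 2))
    for x, y in zip(a_bin, b_bin):
        table[int(x == target), int(y == target)] += 1
    table /= n
    p_o = float(np.trace(table))
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedKappaError("chance agreement is 1; kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)


def _rating_vectors(table: pd.DataFrame, group: str) -> dict[str, list[str]]:
    sub = table[table["expert_group"] == group]
    if sub.empty:
        raise InvalidSpecError(f"no responses for group {group!r}")
    vectors = {}
    order = None
    for expert_id, rows in sub.groupby("expert_id"):
        rows = rows.sort_values("stimulus_id")
        if order is None:
            order = list(rows["stimulus_id"])
        elif list(rows["stimulus_id"]) != order:
            raise InvalidSpecError(
                f"expert {expert_id!r} rated a different stimulus set"
            )
        vectors[expert_id] = _normalize(rows["response"])
    return vectors


def group_kappa(
    table: pd.DataFrame,
    group_a: str,
    group_b: str | None = None,
    emotion: EmotionLabel | str | None = None,
) -> KappaResult:
    """Mean pairwise kappa within a group, or between two groups.

    Within-group uses all unordered expert pairs inside ``group_a``;
    between-group uses all cross pairs.  Undefined pairs are skipped and
    counted in the result.
    """
    vec_a = _rating_vectors(table, group_a)
    if group_b is None or group_b == group_a:
        if len(vec_a) < 2:
            raise InvalidSpecError(f"group {group_a!r} needs >= 2 experts")
        pairs = list(combinations(vec_a.values(), 2))
        scope = "within_group"
    else:
        vec_b = _rating_vectors(table, group_b)
        pairs = list(product(vec_a.values(), vec_b.values()))
        scope = "between_group"

    kappas = []
    undefined = 0
    for ra, rb in pairs:
        try:
            if emotion is None:
                kappas.append(cohen_kappa(ra, rb))
            else:
                kappas.append(per_emotion_kappa(ra, rb, emotion))
        except UndefinedKappaError:
            undefined += 1
    if not kappas:
        raise UndefinedKappaError("kappa undefined for every expert pair")
    k = float(np.mean(kappas))
    return KappaResult(
        kappa=k,
        band=band_strength(k),
        scope=scope,
        emotion=EmotionLabel.from_string(emotion) if emotion is not None else None,
        n_pairs_averaged=len(kappas),
        n_pairs_undefined=undefined,
        below_zero=k < 0,
    )


def agreement_report(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    speech_type: str = "",
    language: str = "",
) -> pd.DataFrame:
    """Agreement summary: per emotion and overall, within each group and
    between groups (columns mirror the standard report layout)."""
    rows = []
    from .emotions import EMOTIONS

    for emotion in list(EMOTIONS) + [None]:
        row = {
            "speech_type": speech_type,
            "language": language,
            "emotion": emotion.value if emotion else "all",
        }
        for label, kwargs in (
            (f"within_{group_a}", dict(group_a=group_a)),
            (f"within_{group_b}", dict(group_a=group_b)),
            ("between", dict(group_a=group_a, group_b=group_b)),
        ):
            try:
                row[label] = group_kappa(table, emotion=emotion, **kwargs).kappa
            except UndefinedKappaError:
                row[label] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
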