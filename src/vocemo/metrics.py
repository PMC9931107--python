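"""Confusion matrices and recognition metrics for listener panels.

Matrices are 4x4 row-percentage tables in the canonical emotion order
(rows = true emotion, columns = response).  Per-class metrics treat the row
percentages as counts, i.e. every true class carries equal weight; this is
the convention under which a row-percentage table determines precision.
Display values are rounded half-up to two decimals; unrounded values are
kept alongside.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .emotions import EMOTION_INDEX, EMOTION_NAMES, EMOTIONS, EmotionLabel
from .errors import InvalidSpecError

ROW_SUM_TOLERANCE = 0.5  # printed rows use half-percent granularity


def round_display(x: float, decimals: int = 2) -> float:
    """Half-up rounding for display, robust to float representation noise.

    Values are first quantized at 1e-9 so that e.g. a mean recall stored as
    0.53499999999…94 still rounds up at the .xx5 boundary.
    """
    if not np.isfinite(x):
        return float("nan")
    d = Decimal(repr(float(x))).quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(f"1e-{decimals}"), rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Row-percentage confusion matrix with per-row response counts."""

    values: np.ndarray                     # 4x4 row percentages
    n_responses_per_row: np.ndarray        # raw response counts per true class
    group_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (4, 4):
            raise InvalidSpecError("confusion matrix must be 4x4")
        if np.any(v < 0):
            raise InvalidSpecError("confusion matrix entries must be non-negative")
        n = np.asarray(self.n_responses_per_row, dtype=np.float64)
        rows_defined = ~(n == 0)  # NaN counts (e.g. transcribed tables) count as defined
        sums = v.sum(axis=1)
        bad = [
            EMOTION_NAMES[i]
            for i in range(4)
            if rows_defined[i] and abs(sums[i] - 100.0) > ROW_SUM_TOLERANCE
        ]
        if bad:
            raise InvalidSpecError(
                f"rows must sum to 100 +/- {ROW_SUM_TOLERANCE}: offending rows {bad}"
            )
        self.values = v
        self.n_responses_per_row = n

    @property
    def undefined_rows(self) -> list[EmotionLabel]:
        return [EMOTIONS[i] for i in range(4) if self.n_responses_per_row[i] == 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=EMOTION_NAMES, columns=EMOTION_NAMES)

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "true_emotion"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, group_label: str = "") -> "ConfusionMatrix":
        """Read the confusion-matrix CSV dialect: header of response labels,
        first column true labels, cells = row percentages."""
        df = pd.read_csv(path, index_col=0)
        df.index = [EmotionLabel.from_string(i).value for i in df.index]
        df.columns = [EmotionLabel.from_string(c).value for c in df.columns]
        df = df.loc[list(EMOTION_NAMES), list(EMOTION_NAMES)]
        return cls(
            values=df.to_numpy(dtype=float),
            n_responses_per_row=np.full(4, np.nan),
            group_label=group_label or Path(path).stem,
        )


@dataclass
class ClassMetrics:
    """Recognition metrics for one emotion class (unrounded)."""

    emotion: EmotionLabel
    recall: float
    precision: float
    f1: float

    def rounded(self) -> dict:
        return {
            "emotion": self.emotion.value,
            "recall": round_display(self.recall),
            "precision": round_display(self.precision),
            "f1": round_display(self.f1),
        }


def consensus_filter(annotations_a, annotations_b, samples) -> list:
    """Keep only samples where two annotators gave the same label."""
    a = list(annotations_a)
    b = list(annotations_b)
    s = list(samples)
    if not (len(a) == len(b) == len(s)):
        raise InvalidSpecError("annotation vectors and sample ids must align")
    return [
        sid
        for sid, la, lb in zip(s, a, b)
        if EmotionLabel.from_string(la) == EmotionLabel.from_string(lb)
    ]


def build_confusion(table: pd.DataFrame, group: str | None = None) -> ConfusionMatrix:
    """Count (true, response) pairs for one expert group and row-normalize
    to percentages.  A true class with zero stimuli yields an undefined row
    (excluded from UAR with a warning)."""
    df = table
    if group is not None:
        df = df[df["expert_group"] == group]
    if df.empty:
        raise InvalidSpecError(f"no responses for group {group!r}")
    counts = np.zeros((4, 4))
    ti = df["true_emotion"].map(lambda e: EMOTION_INDEX[EmotionLabel.from_string(e)])
    ri = df["response"].map(lambda e: EMOTION_INDEX[EmotionLabel.from_string(e)])
    np.add.at(counts, (ti.to_numpy(), ri.to_numpy()), 1)
    row_n = counts.sum(axis=1)
    values = np.zeros((4, 4))
    for i in range(4):
        if row_n[i] > 0:
            values[i] = 100.0 * counts[i] / row_n[i]
        else:
            warnings.warn(
                f"true class {EMOTION_NAMES[i]!r} has no stimuli; row undefined",
                stacklevel=2,
            )
    return ConfusionMatrix(values=values, n_responses_per_row=row_n,
                           group_label=group or "")


def class_metrics(cm: ConfusionMatrix) -> list[ClassMetrics]:
    """Per-class recall, precision and F1, treating row percentages as counts.

    Precision for an empty response column is undefined and reported as NaN
    with a warning, never silently zero.
    """
    v = cm.values
    col_sums = v.sum(axis=0)
    out = []
    for i, emotion in enumerate(EMOTIONS):
        row_sum = v[i].sum()
        recall = v[i, i] / row_sum if row_sum > 0 else np.nan
        if col_sums[i] > 0:
            precision = v[i, i] / col_sums[i]
        else:
            warnings.warn(
                f"no responses assigned to class {emotion.value!r}; "
                "precision undefined", stacklevel=2,
            )
            precision = np.nan
        if np.isfinite(recall) and np.isfinite(precision) and (recall + precision) > 0:
            f1 = 2 * recall * precision / (recall + precision)
        elif recall == 0 or precision == 0:
            f1 = 0.0
        else:
            f1 = np.nan
        out.append(ClassMetrics(emotion=emotion, recall=float(recall),
                                precision=float(precision), f1=float(f1)))
    return out


def uar(cm: ConfusionMatrix, skip_undefined: bool = False) -> float:
    """Unweighted average recall: arithmetic mean of the per-class recalls."""
    recalls = [m.recall for m in class_metrics(cm)]
    if any(not np.isfinite(r) for r in recalls):
        if not skip_undefined:
            raise InvalidSpecError(
                "confusion matrix has undefined rows; pass skip_undefined=True "
                "to average over the defined classes"
            )
        recalls = [r for r in recalls if np.isfinite(r)]
    return float(np.mean(recalls))


def metrics_report(cm: ConfusionMatrix) -> dict:
    """JSON-ready report: per-class rounded metrics plus UAR."""
    per_class = class_metrics(cm)
    return {
        "group": cm.group_label,
        "classes": [m.rounded() for m in per_class],
        "uar": round_display(uar(cm, skip_undefined=True)),
        "uar_unrounded": uar(cm, skip_undefined=True),
    }


def expert_accuracy(table: pd.DataFrame, per_emotion: bool = False) -> pd.DataFrame:
    """Per-expert proportion correct, overall or per true emotion."""
    df = table.copy()
    df["correct"] = df["true_emotion"] == df["response"]
    keys = ["expert_group", "expert_id"] + (["true_emotion"] if per_emotion else [])
    return df.groupby(keys)["correct"].mean().reset_index(name="accuracy")


def compare_groups(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    per_emotion: bool = False,
):
    """Compare two expert groups' accuracies with the Mann-Whitney test.

    Returns a single RankTestResult (overall) or a dict keyed by emotion.
    """
    from .stats import mann_whitney  # local import to keep modules acyclic

    acc = expert_accuracy(table, per_emotion=per_emotion)
    for g in (group_a, group_b):
        n = acc[acc["expert_group"] == g]["expert_id"].nunique()
        if n < 2:
            raise InvalidSpecError(f"group {g!r} has fewer than 2 experts")
    if not per_emotion:
        xa = acc[acc["expert_group"] == group_a]["accuracy"].to_numpy()
        xb = acc[acc["expert_group"] == group_b]["accuracy"].to_numpy()
        return mann_whitney(xa, xb)
    out = {}
    for emotion in EMOTIONS:
        sub = acc[acc["true_emotion"] == emotion.value]
        xa = sub[sub["expert_group"] == group_a]["accuracy"].to_numpy()
        xb = sub[sub["expert_group"] == group_b]["accuracy"].to_numpy()
        out[emotion.value] = mann_whitney(xa, xb)
    return out


# ---------------------------------------------------------------------------
# printed-table fixtures

PRINTED_TABLES = (
    "spontaneous_russian", "spontaneous_tamil",
    "acting_words_russian", "acting_words_tamil",
    "words_phrases_russian", "words_phrases_tamil",
    "meaningless_russian", "meaningless_tamil",
)
PRINTED_GROUPS = ("russian", "indian")


def load_printed_matrix(table: str, group: str) -> ConfusionMatrix:
    """Load a transcribed published confusion matrix.

    ``table`` names the speech material and speaker language (one of
    :data:`PRINTED_TABLES`); ``group`` is the expert panel ('russian' or
    'indian')."""
    name = f"{table}_{group}.csv"
    ref = resources.files("vocemo.data.printed") / name
    with resources.as_file(ref) as path:
        return ConfusionMatrix.from_csv(path, group_label=f"{table}_{group}")


def load_printed_metrics() -> pd.DataFrame:
    """The printed Recall/Precision/F1/UAR cells with their typo flags."""
    ref = resources.files("vocemo.data.printed") / "printed_metrics.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
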