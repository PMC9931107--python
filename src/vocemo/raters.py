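"""Simulated listener panels.

A panel's behaviour is abstracted by a confusion kernel: a row-stochastic
4x4 matrix giving the probability that a listener from the group responds
with each emotion, conditioned on the stimulus' true emotion.  Experts in a
group share the kernel by default (optionally perturbed per expert with a
Dirichlet draw around the group rows); votes are independent across experts
and stimuli.  The output long-format response table is also the ingest
format for real panel data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emotions import EMOTION_INDEX, EMOTION_NAMES, EMOTIONS, EmotionLabel
from .errors import InvalidSpecError

RESPONSE_COLUMNS = ["expert_id", "expert_group", "stimulus_id", "true_emotion", "response"]


@dataclass
class ConfusionKernel:
    """Row-stochastic response-probability matrix for one listener group."""

    matrix: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise InvalidSpecError("kernel must be 4x4")
        if np.any(m < 0):
            raise InvalidSpecError("kernel entries must be non-negative")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise InvalidSpecError("kernel rows must sum to 1")
        self.matrix = m

    @property
    def diagonal_mean(self) -> float:
        return float(np.mean(np.diag(self.matrix)))


def kernel_from_accuracy(
    diag: tuple[float, float, float, float] | np.ndarray,
    spread: str = "uniform",
    group_label: str = "",
) -> ConfusionKernel:
    """Build a kernel from per-class accuracies.

    The off-diagonal mass ``1 - diag[i]`` of each row is distributed either
    uniformly over the three wrong responses, or over the categories
    adjacent to the true one in canonical order (split equally; edge
    categories send everything to their single neighbour).
    """
    d = np.asarray(diag, dtype=np.float64)
    if d.shape != (4,) or np.any(d < 0) or np.any(d > 1):
        raise InvalidSpecError("diag must be four probabilities in [0, 1]")
    m = np.zeros((4, 4))
    for i in range(4):
        m[i, i] = d[i]
        rest = 1.0 - d[i]
        if spread == "uniform":
            for j in range(4):
                if j != i:
                    m[i, j] = rest / 3.0
        elif spread == "adjacent":
            neighbours = [j for j in (i - 1, i + 1) if 0 <= j < 4]
            for j in neighbours:
                m[i, j] = rest / len(neighbours)
        else:
            raise InvalidSpecError("spread must be 'uniform' or 'adjacent'")
    return ConfusionKernel(matrix=m, group_label=group_label)


def simulate_responses(
    stimuli: list[tuple[str, EmotionLabel | str]],
    kernel: ConfusionKernel,
    n_experts: int = 10,
    seed: int = 0,
    expert_group: str | None = None,
    expert_jitter_concentration: float | None = None,
) -> pd.DataFrame:
    """Simulate a rectangular panel: every expert votes on every stimulus.

    Each vote is an independent categorical draw from the kernel row of the
    stimulus' true emotion.  With ``expert_jitter_concentration`` set, each
    expert gets a private kernel drawn row-wise from a Dirichlet centred on
    the group kernel (larger concentration = closer to the group).
    Deterministic under ``seed``.
    """
    if n_experts < 2:
        raise InvalidSpecError("need at least 2 experts")
    if not stimuli:
        raise InvalidSpecError("stimulus list is empty")
    group = expert_group if expert_group is not None else (kernel.group_label or "group")
    rng = np.random.default_rng(seed)

    true_idx = np.array(
        [EMOTION_INDEX[EmotionLabel.from_string(e)] for _, e in stimuli]
    )
    stim_ids = [str(s) for s, _ in stimuli]

    records = []
    for x in range(n_experts):
        expert_id = f"{group}_e{x:02d}"
        m = kernel.matrix
        if expert_jitter_concentration is not None:
            m = np.vstack([
                rng.dirichlet(np.maximum(row, 1e-12) * expert_jitter_concentration)
                for row in kernel.matrix
            ])
        # inverse-CDF draw per stimulus from the row of its true emotion
        cdf = np.cumsum(m, axis=1)
        u = rng.random(len(stimuli))
        resp_idx = (u[:, None] > cdf[true_idx]).sum(axis=1)
        for s, (sid, ti) in enumerate(zip(stim_ids, true_idx)):
            records.append((
                expert_id, group, sid,
                EMOTION_NAMES[ti], EMOTION_NAMES[resp_idx[s]],
            ))
    return pd.DataFrame(records, columns=RESPONSE_COLUMNS)


def validate_response_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format response table's schema and rectangular design."""
    missing = [c for c in RESPONSE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidSpecError(f"response table missing columns: {missing}")
    for col in ("true_emotion", "response"):
        bad = set(table[col].unique()) - set(EMOTION_NAMES)
        if bad:
            raise InvalidSpecError(f"unknown labels in {col}: {sorted(bad)}")
    sets = table.groupby("expert_id")["stimulus_id"].apply(frozenset)
    per_group = table.groupby("expert_group")["expert_id"].unique()
    for group, experts in per_group.items():
        group_sets = {sets[e] for e in experts}
        if len(group_sets) > 1:
            raise InvalidSpecError(
                f"experts in group {group!r} did not rate the same stimulus set"
            )
    return table


def read_response_csv(path: str | Path) -> pd.DataFrame:
    return validate_response_table(pd.read_csv(path, dtype=str))


def write_response_csv(table: pd.DataFrame, path: str | Path) -> None:
    table[RESPONSE_COLUMNS].to_csv(path, index=False)
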