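"""End-to-end runs: synthesize -> extract -> panel -> metrics -> agreement -> contrasts.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
its master seed; every artifact it writes is re-derivable from that pair.
Per-stage randomness is split hierarchically from the master seed, so the
same config and seed always produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acoustics import TrackingParams, features_table
from .agreement import agreement_report
from .emotions import EMOTIONS, EmotionLabel
from .errors import InvalidSpecError
from .metrics import (ConfusionMatrix, build_confusion, metrics_report,
                      round_display, uar)
from .raters import ConfusionKernel, kernel_from_accuracy, simulate_responses, write_response_csv
from .stats import feature_emotion_contrasts
from .synth import CorpusSpec, EmotionPreset, default_presets, generate_corpus

logger = logging.getLogger("vocemo")


@dataclass
class PanelSpec:
    """One simulated expert panel: a group kernel and its size."""

    group_label: str
    diag: tuple[float, float, float, float]
    spread: str = "uniform"
    n_experts: int = 10

    def kernel(self) -> ConfusionKernel:
        return kernel_from_accuracy(self.diag, self.spread, self.group_label)


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    corpus: dict = field(default_factory=dict)       # CorpusSpec fields sans language/seed
    languages: list[str] = field(default_factory=lambda: ["lang_A", "lang_B"])
    presets: dict[str, dict] = field(default_factory=dict)
    panels: list[PanelSpec] = field(default_factory=list)
    tracking: dict = field(default_factory=dict)     # TrackingParams overrides
    seed: int = 0
    holm: bool = False

    def __post_init__(self) -> None:
        if not self.panels:
            self.panels = [
                PanelSpec("in_group", (0.85, 0.85, 0.85, 0.85)),
                PanelSpec("out_group", (0.55, 0.55, 0.55, 0.55)),
            ]
        self.panels = [
            p if isinstance(p, PanelSpec) else PanelSpec(**p) for p in self.panels
        ]
        labels = [p.group_label for p in self.panels]
        if len(set(labels)) != len(labels):
            raise InvalidSpecError("panel group labels must be unique")

    # -- presets ----------------------------------------------------------
    def preset_bank(self) -> dict[EmotionLabel, EmotionPreset]:
        bank = default_presets()
        for name, fields_ in self.presets.items():
            emotion = EmotionLabel.from_string(name)
            bank[emotion] = dataclasses.replace(bank[emotion], **fields_)
        missing = [e.value for e in EMOTIONS if e not in bank]
        if missing:
            raise InvalidSpecError(f"missing preset for emotions: {missing}")
        return bank

    def corpus_spec(self, language: str, seed: int) -> CorpusSpec:
        return CorpusSpec(language=language, seed=seed, **self.corpus)

    def tracking_params(self) -> TrackingParams:
        return TrackingParams(**self.tracking)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for p in d["panels"]:
            p["diag"] = list(p["diag"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        panels = [PanelSpec(**{**p, "diag": tuple(p["diag"])}) for p in d.pop("panels", [])]
        return cls(panels=panels, **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _stage_seed(master: int, *tags: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    ss = np.random.SeedSequence([master] + [zlib.crc32(t.encode()) for t in tags])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path, force: bool = False) -> dict:
    """Execute every stage and write the report artifacts.

    Writes, under ``out_dir``: the corpus WAVs + manifest per language, a
    features CSV per language, a response CSV per language, per-panel
    confusion CSV + metrics JSON, an agreement CSV, a contrast CSV, the
    persisted config, and ``run.json`` summarizing the run.  Returns the
    summary dict.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise InvalidSpecError(
            f"output directory {out} is not empty; pass force=True (--force) to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    presets = config.preset_bank()
    params = config.tracking_params()

    summary: dict = {"seed": config.seed, "version": __version__, "languages": {}}
    for language in config.languages:
        logger.info("stage synth: language %s", language)
        corpus_seed = _stage_seed(config.seed, "synth", language)
        spec = config.corpus_spec(language, corpus_seed)
        corpus_dir = out / "corpus" / language
        utterances = generate_corpus(spec, presets, out_dir=corpus_dir)

        logger.info("stage extract: language %s (%d utterances)", language, len(utterances))
        feats = features_table(utterances, params)
        feats.to_csv(out / f"features_{language}.csv", index=False)

        logger.info("stage panel: language %s", language)
        stimuli = [(u.id, u.emotion) for u in utterances]
        tables = []
        for panel in config.panels:
            panel_seed = _stage_seed(config.seed, "panel", language, panel.group_label)
            tables.append(simulate_responses(
                stimuli, panel.kernel(), panel.n_experts, panel_seed,
                expert_group=panel.group_label,
            ))
        responses = pd.concat(tables, ignore_index=True)
        write_response_csv(responses, out / f"responses_{language}.csv")

        logger.info("stage metrics: language %s", language)
        lang_summary: dict = {"panels": {}}
        for panel in config.panels:
            cm = build_confusion(responses, panel.group_label)
            cm.to_csv(out / f"confusion_{language}_{panel.group_label}.csv")
            report = metrics_report(cm)
            (out / f"metrics_{language}_{panel.group_label}.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
            lang_summary["panels"][panel.group_label] = {
                "uar": report["uar_unrounded"],
                "uar_display": report["uar"],
            }

        logger.info("stage agreement: language %s", language)
        groups = [p.group_label for p in config.panels]
        if len(groups) >= 2:
            agree = agreement_report(
                responses, groups[0], groups[1],
                speech_type=spec.speech_type, language=language,
            )
            agree.to_csv(out / f"agreement_{language}.csv", index=False)
            all_row = agree[agree["emotion"] == "all"].iloc[0]
            lang_summary["kappa"] = {
                f"within_{groups[0]}": float(all_row[f"within_{groups[0]}"]),
                f"within_{groups[1]}": float(all_row[f"within_{groups[1]}"]),
                "between": float(all_row["between"]),
            }

        logger.info("stage contrasts: language %s", language)
        contrasts = feature_emotion_contrasts(
            feats, speech_type=spec.speech_type, group=language, holm=config.holm,
        )
        contrasts.to_csv(out / f"contrasts_{language}.csv", index=False)
        summary["languages"][language] = lang_summary

    (out / "run.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def recompute_from_matrix(matrix_csv: str | Path) -> dict:
    """Recompute recall/precision/F1/UAR from a row-percentage confusion CSV."""
    cm = ConfusionMatrix.from_csv(matrix_csv)
    return metrics_report(cm)
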