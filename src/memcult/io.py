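"""Readers and writers for the pipeline's plain-text file dialects.

Trials travel as RFC-4180 CSV (UTF-8, header
``participant,group,phase,stimulus,status,response``); every matrix-like
table (dimension scores, embeddings, memorability) is TSV with a
``stimulus`` key column; categories are a two-column TSV; ground truth and
model artifacts are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .scoring import validate_trials
from .synthetic import StimulusDimensionTable, SyntheticDataset

MEMORABILITY_COLUMNS = [
    "stimulus", "group", "memorability", "prediction", "n_old", "n_new", "mean_old", "mean_new",
]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    trials.to_csv(path, index=False, lineterminator="\r\n")


def read_trials_csv(path) -> pd.DataFrame:
    return validate_trials(pd.read_csv(path))


def write_dimensions_tsv(dimensions, path) -> None:
    scores = dimensions.scores if isinstance(dimensions, StimulusDimensionTable) else dimensions
    scores.rename_axis("stimulus").to_csv(path, sep="\t")


def read_dimensions_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="stimulus")


def write_categories_tsv(categories: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"dimension": list(categories), "category": list(categories.values())}
    ).to_csv(path, sep="\t", index=False)


def read_categories_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["dimension"], df["category"]))


write_embeddings_tsv = write_dimensions_tsv
read_embeddings_tsv = read_dimensions_tsv


def write_memorability_tsv(table: pd.DataFrame, path) -> None:
    table[MEMORABILITY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_memorability_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def memorability_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Long memorability table -> stimulus x group score matrix."""
    return table.pivot(index="stimulus", columns="group", values="memorability")


def write_truth_json(dataset: SyntheticDataset, path) -> None:
    cfg = dataset.effect_config
    payload = {
        "seed": dataset.seed,
        "group_ids": list(dataset.group_ids),
        "true_memorability": {
            g: dataset.true_memorability[g].round(10).to_dict() for g in dataset.group_ids
        },
        "effect_config": {
            "shared_weights": None if cfg.shared_weights is None else list(map(float, cfg.shared_weights)),
            "group_specific_weights": {
                g: list(map(float, w)) for g, w in cfg.group_specific_weights.items()
            },
            "shared_sd": cfg.shared_sd,
            "group_sd": cfg.group_sd,
            "trial_sd": cfg.trial_sd,
            "old_offset": cfg.old_offset,
            "new_offset": cfg.new_offset,
            "prediction_attenuation": cfg.prediction_attenuation,
            "thresholds": list(cfg.thresholds),
        },
    }
    Path(path).write_text(json.dumps(payload))
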