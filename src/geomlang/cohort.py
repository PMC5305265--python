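"""Synthetic behavioral cohorts.

Simulates populations of model subjects through the experimental protocols
and produces long-format behavioral tables: one row per required response,
with subject, group, family, trial, phase, ordinal position, target,
response and correctness.  Because an error in the task is immediately
corrected (the sequence restarts and replays veridically), the model's
conditioning prefix at every position is the true preceding stream;
restarts therefore need no extra bookkeeping and each position is scored
once.

Randomness is organized as a tree: one cohort seed spawns independent
per-subject streams, so any subject's rows can be regenerated in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .atlas import ComplexityAtlas, default_atlas
from .language import LanguageError
from .predictor import (
    FULL_RESOURCES,
    PredictorParams,
    RunResources,
    draw_run_resources,
    predict_next,
)
from .stimuli import Trial, fitting_battery, make_battery

TABLE_COLUMNS = [
    "subject_id",
    "group",
    "sequence_family",
    "trial_index",
    "phase",
    "ordinal_position",
    "target",
    "response",
    "correct",
    "run_seed",
]


def simulate_trial(
    trial: Trial,
    params: PredictorParams,
    resources: RunResources = FULL_RESOURCES,
    rng: np.random.Generator | None = None,
    atlas: ComplexityAtlas | None = None,
    subject_id: int = 0,
    group: str = "",
    run_seed: int = 0,
) -> list[dict]:
    """One subject's first-attempt responses over one trial.

    Prefixes outside the no-revisit hypothesis space (they arise only in
    the short span-control stimuli) elicit chance responses.
    """
    rng = np.random.default_rng() if rng is None else rng
    atlas = default_atlas() if atlas is None else atlas
    rows = []
    for pos in trial.response_positions:
        prefix = trial.prefix(pos)
        target = trial.target(pos)
        response = predict_next(
            prefix, atlas, params, resources, rng, on_empty="chance"
        )
        rows.append(
            {
                "subject_id": subject_id,
                "group": group,
                "sequence_family": trial.stimulus.name,
                "trial_index": trial.index,
                "phase": trial.phase(pos),
                "ordinal_position": pos,
                "target": target,
                "response": response,
                "correct": bool(response == target),
                "run_seed": run_seed,
            }
        )
    return rows


def simulate_cohort(
    group: str,
    n_subjects: int,
    params: PredictorParams,
    seed: int = 0,
    atlas: ComplexityAtlas | None = None,
    battery: str = "experiment",
    n_previews: int = 0,
) -> pd.DataFrame:
    """Simulate a cohort through a protocol.

    ``battery="experiment"`` runs the full published battery for the group;
    ``battery="shared"`` runs one trial per shared family (the set model
    fits are computed on).  Each subject gets its own battery randomization
    and its own resource draw.
    """
    if n_subjects < 1:
        raise LanguageError(f"n_subjects must be >= 1, got {n_subjects}")
    atlas = default_atlas() if atlas is None else atlas
    root = np.random.SeedSequence(seed)
    all_rows: list[dict] = []
    for subject, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        run_seed = int(ss.generate_state(1)[0] % (2**31))
        battery_seed = int(rng.integers(2**31 - 1))
        if battery == "shared":
            trials = fitting_battery(group, seed=battery_seed, atlas=atlas)
        else:
            trials = make_battery(
                group, seed=battery_seed, n_previews=n_previews, atlas=atlas
            )
        resources = draw_run_resources(params, rng)
        for trial in trials:
            all_rows.extend(
                simulate_trial(
                    trial,
                    params,
                    resources,
                    rng,
                    atlas,
                    subject_id=subject,
                    group=group,
                    run_seed=run_seed,
                )
            )
    return pd.DataFrame(all_rows, columns=TABLE_COLUMNS)


def cohort_manifest(
    group: str, n_subjects: int, params: PredictorParams, seed: int, atlas=None, **extra
) -> dict:
    """Provenance sidecar: everything needed to regenerate a table."""
    atlas = default_atlas() if atlas is None else atlas
    return {
        "schema": "geomlang-cohort/1",
        "group": group,
        "n_subjects": n_subjects,
        "params": asdict(params),
        "seed": seed,
        "atlas": atlas.metadata,
        **extra,
    }


def save_table(table: pd.DataFrame, path, manifest: dict | None = None) -> None:
    table.to_csv(path, index=False)
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def load_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise LanguageError(f"behavioral table missing columns: {sorted(missing)}")
    table["correct"] = table["correct"].astype(bool)
    return table
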