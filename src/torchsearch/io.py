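"""Readers and writers for the pipeline's plain-text artifacts.

AOI sequences and trial records travel as CSV; layouts and reports as JSON.
Every data export is accompanied by a small data-dictionary JSON so the
files are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import TrialRecord
from .environment import SpatialLayout
from .markov import AOISequence, N_STATES

__all__ = [
    "write_sequences_csv",
    "read_sequences_csv",
    "write_trials_csv",
    "read_trials_csv",
    "write_layout_json",
    "read_layout_json",
    "write_data_dictionary",
]

SEQUENCE_COLUMNS = [
    "participant_id", "group", "condition", "block", "trial",
    "fixation_index", "aoi", "duration_s",
]

_SEQ_DICTIONARY = {
    "participant_id": "participant identifier (string)",
    "group": "younger-toddler | older-toddler | adult | model",
    "condition": "Skewed | Uniform",
    "block": "session block number",
    "trial": "test-trial number within the block",
    "fixation_index": "0-based position of the fixation within the trial",
    "aoi": "area of interest, location id 0-7",
    "duration_s": "fixation duration in seconds (empty for model sequences)",
}

_TRIAL_DICTIONARY = {
    "participant_id": "participant identifier (string)",
    "group": "younger-toddler | older-toddler | adult",
    "age_months": "toddler age in months; empty for adults",
    "condition": "Skewed | Uniform",
    "condition_order": "1 if this condition was presented first, else 2",
    "block": "session block number (1-4)",
    "trial": "test-trial number within the block (1-4)",
    "success": "1 if the dwell criterion was met within 10 s",
    "time_to_target": "seconds until the criterion was met; empty on failure",
    "scanning_count": "number of between-column eye movements",
    "anticipatory_look": "1 if the first fixation was in the correct column",
}


class SchemaError(ValueError):
    """A CSV row violates the expected schema."""


def write_sequences_csv(seqs: list[AOISequence], path: str | Path) -> None:
    rows = []
    for seq in seqs:
        durations = seq.durations or [np.nan] * len(seq.visits)
        for k, (aoi, dur) in enumerate(zip(seq.visits, durations)):
            rows.append(
                {
                    "participant_id": seq.participant_id,
                    "group": seq.group,
                    "condition": seq.condition,
                    "block": seq.block,
                    "trial": seq.trial,
                    "fixation_index": k,
                    "aoi": aoi,
                    "duration_s": dur,
                }
            )
    pd.DataFrame(rows, columns=SEQUENCE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )
    write_data_dictionary(_SEQ_DICTIONARY, Path(path).with_suffix(".dict.json"))


def read_sequences_csv(path: str | Path) -> list[AOISequence]:
    """Parse an AOI-sequence CSV back into sequences.

    Rows are grouped on (participant, condition, block, trial) in file
    order; a malformed AOI value raises :class:`SchemaError` naming the
    offending row.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in SEQUENCE_COLUMNS if c not in frame.columns and c != "duration_s"]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for idx, value in frame["aoi"].items():
        if not float(value).is_integer() or not 0 <= int(value) < N_STATES:
            raise SchemaError(f"row {idx}: aoi value {value!r} is not a location 0-7")

    keys = ["participant_id", "group", "condition", "block", "trial"]
    seqs: list[AOISequence] = []
    for key, chunk in frame.groupby(keys, dropna=False, sort=False):
        chunk = chunk.sort_values("fixation_index")
        pid, group, condition, block, trial = key
        durations = None
        if "duration_s" in chunk and chunk["duration_s"].notna().all():
            durations = tuple(float(d) for d in chunk["duration_s"])
        seqs.append(
            AOISequence(
                visits=tuple(int(a) for a in chunk["aoi"]),
                durations=durations,
                participant_id=None if pd.isna(pid) else str(pid),
                group=None if pd.isna(group) else str(group),
                condition=None if pd.isna(condition) else str(condition),
                block=None if pd.isna(block) else int(block),
                trial=None if pd.isna(trial) else int(trial),
            )
        )
    return seqs


def write_trials_csv(trials: list[TrialRecord], path: str | Path) -> None:
    frame = pd.DataFrame([asdict(t) for t in trials])
    frame["success"] = frame["success"].astype(int)
    frame["anticipatory_look"] = frame["anticipatory_look"].astype(int)
    frame.to_csv(path, index=False, float_format="%.17g")
    write_data_dictionary(_TRIAL_DICTIONARY, Path(path).with_suffix(".dict.json"))


def read_trials_csv(path: str | Path) -> list[TrialRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    records = []
    for idx, row in frame.iterrows():
        try:
            records.append(
                TrialRecord(
                    participant_id=str(row["participant_id"]),
                    group=str(row["group"]),
                    age_months=None if pd.isna(row["age_months"]) else float(row["age_months"]),
                    condition=str(row["condition"]),
                    condition_order=int(row["condition_order"]),
                    block=int(row["block"]),
                    trial=int(row["trial"]),
                    success=bool(row["success"]),
                    time_to_target=None
                    if pd.isna(row["time_to_target"])
                    else float(row["time_to_target"]),
                    scanning_count=int(row["scanning_count"]),
                    anticipatory_look=bool(row["anticipatory_look"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
    return records


def write_layout_json(layout: SpatialLayout, path: str | Path) -> None:
    Path(path).write_text(layout.to_json())


def read_layout_json(path: str | Path) -> SpatialLayout:
    return SpatialLayout.from_json(Path(path).read_text())


def write_data_dictionary(dictionary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dictionary, indent=2))
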