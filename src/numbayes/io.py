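"""Serialization: CSV trial tables, MAT ingestion, run configuration.

Trial tables are plain comma-separated files with a header row, one trial per
row and 1-based trial indices (so the "first 300 trials" burn-in is indices
1-300).  Estimation columns: trial, stimulus, feedback_given, feedback,
response.  Discrimination columns: s1, s2, anchor, offset, choice.

The deposited study data ships as MAT files whose internal layout is not
documented, so ingestion is best-effort behind a user-supplied mapping spec
naming the variables that hold each column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ESTIMATION_COLUMNS = ["trial", "stimulus", "feedback_given", "feedback", "response"]
DISCRIMINATION_COLUMNS = ["s1", "s2", "anchor", "offset", "choice"]

GROUP_LABELS = (
    "exp1-narrow",
    "exp1-medium",
    "exp1-wide",
    "exp2-narrow",
    "exp2-medium",
    "exp3-difficult",
    "exp3-easier",
    "exp3-rectangle",
)

__all__ = [
    "RunConfig",
    "Participant",
    "StudyDataset",
    "read_trial_table",
    "write_trial_table",
    "load_study_dataset",
    "GROUP_LABELS",
]


@dataclass
class RunConfig:
    """Materialized configuration of a pipeline run (serialized beside results)."""

    seed: int = 0
    mc_samples: int = 10_000
    burn_in: int = 300
    support_lo: int = 1
    support_hi: int = 100
    lapse: float = 0.001
    models: list = field(default_factory=list)
    output_dir: str = "results"

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_trial_table(table: pd.DataFrame, path):
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if set(ESTIMATION_COLUMNS) <= set(table.columns):
        table["feedback_given"] = table["feedback_given"].astype(bool)
        return table[ESTIMATION_COLUMNS].astype(
            {"trial": int, "stimulus": int, "feedback": int, "response": int}
        )
    if set(DISCRIMINATION_COLUMNS) <= set(table.columns):
        return table[DISCRIMINATION_COLUMNS].astype(int)
    raise ValueError(
        f"{path}: columns {list(table.columns)} match neither the estimation "
        f"layout {ESTIMATION_COLUMNS} nor the discrimination layout "
        f"{DISCRIMINATION_COLUMNS}"
    )


@dataclass
class Participant:
    id: str
    group: str
    estimation: pd.DataFrame | None = None
    discrimination: pd.DataFrame | None = None
    sigma: float | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class StudyDataset:
    participants: list

    def __iter__(self):
        return iter(self.participants)

    def __len__(self):
        return len(self.participants)


def _flatten(x) -> np.ndarray:
    return np.asarray(x).ravel()


def load_study_dataset(path, mapping_spec: dict) -> StudyDataset:
    """Load deposited participant data from a MAT (v5) file.

    ``mapping_spec`` maps participant ids to per-participant entries::

        {"p01": {"group": "exp1-narrow",
                 "estimation": {"stimulus": "stim_p01", "response": "resp_p01",
                                "feedback_given": "fb_p01"},        # optional
                 "discrimination": {"s1": ..., "s2": ..., "choice": ...}}}

    Each value names a variable in the MAT file holding one column (1-D,
    trial-ordered).  Unknown MAT variables are preserved in ``meta``.
    Missing required variables raise an error naming them; malformed rows are
    dropped with a warning count stored in ``meta``.
    """
    from scipy.io import loadmat

    raw = loadmat(path, squeeze_me=True)
    known = {k: v for k, v in raw.items() if not k.startswith("__")}
    participants = []
    for pid, entry in mapping_spec.items():
        group = entry.get("group", "unknown")
        if group not in GROUP_LABELS and group != "unknown":
            raise ValueError(f"{pid}: unknown group label {group!r}")
        meta: dict = {}
        est = disc = None
        if "estimation" in entry:
            cols = entry["estimation"]
            missing = [v for v in cols.values() if v not in known]
            if missing:
                raise KeyError(f"{pid}: MAT file is missing variables {missing}")
            stim = _flatten(known[cols["stimulus"]]).astype(int)
            resp = _flatten(known[cols["response"]])
            bad = ~np.isfinite(resp)
            if bad.any():
                meta["estimation_malformed_rows"] = int(bad.sum())
            if "feedback_given" in cols:
                fb = _flatten(known[cols["feedback_given"]]).astype(bool)
            else:
                fb = np.ones(len(stim), dtype=bool)
            est = pd.DataFrame(
                {
                    "trial": np.arange(1, len(stim) + 1),
                    "stimulus": stim,
                    "feedback_given": fb,
                    "feedback": np.where(fb, stim, -1),
                    "response": np.where(bad, -1, resp).astype(int),
                }
            )
        if "discrimination" in entry:
            cols = entry["discrimination"]
            missing = [v for v in cols.values() if v not in known]
            if missing:
                raise KeyError(f"{pid}: MAT file is missing variables {missing}")
            s1 = _flatten(known[cols["s1"]]).astype(int)
            s2 = _flatten(known[cols["s2"]]).astype(int)
            choice = _flatten(known[cols["choice"]]).astype(int)
            disc = pd.DataFrame(
                {
                    "s1": s1,
                    "s2": s2,
                    "anchor": np.minimum(s1, s2),
                    "offset": s2 - s1,
                    "choice": choice,
                }
            )
        participants.append(
            Participant(id=pid, group=group, estimation=est, discrimination=disc, meta=meta)
        )
    return StudyDataset(participants)


def write_fit_results(results, path):
    """FitResults as JSON records plus a flat one-row-per-model CSV."""
    records = [r.to_record() for r in results]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(records, fh, indent=2)
    pd.DataFrame(records).to_csv(path.with_suffix(".csv"), index=False)
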