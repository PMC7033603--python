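"""Cohort container with training/testing split semantics.

Training runs come from the two single-environment groups (treadmill-only,
sidewalk-only); testing runs come from the independent group that ran in both
environments.  Testing participants are disjoint from training participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from .errors import DatasetError
from .runs import RawRun

TRAINING = "training"
TESTING = "testing"


@dataclass
class Dataset:
    """A list of runs plus a participant manifest.

    ``manifest`` has one row per participant: participant, protocol, role and
    demographic columns (height_m, mass_kg, age_yr).  ``provenance`` records
    seeds and configuration needed to regenerate the cohort.
    """

    runs: list[RawRun]
    manifest: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seen = set()
        for run in self.runs:
            key = (run.participant, run.condition)
            if key in seen:
                raise DatasetError(f"duplicate (participant, condition): {key}")
            seen.add(key)
        roles = self.manifest.set_index("participant")["role"]
        train = {p for p, r in roles.items() if r == TRAINING}
        test = {p for p, r in roles.items() if r == TESTING}
        if train & test:
            raise DatasetError(f"participants in both splits: {train & test}")
        missing = {r.participant for r in self.runs} - set(roles.index)
        if missing:
            raise DatasetError(f"runs without manifest entry: {missing}")

    def role_of(self, participant: str) -> str:
        row = self.manifest.loc[self.manifest["participant"] == participant]
        if row.empty:
            raise DatasetError(f"unknown participant {participant!r}")
        return str(row["role"].iloc[0])

    @property
    def training_runs(self) -> list[RawRun]:
        return [r for r in self.runs if self.role_of(r.participant) == TRAINING]

    @property
    def testing_runs(self) -> list[RawRun]:
        return [r for r in self.runs if self.role_of(r.participant) == TESTING]

    def __len__(self) -> int:
        return len(self.runs)
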