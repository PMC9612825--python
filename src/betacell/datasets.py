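"""Fold-change observation tables and the train/validation split.

The training data emulate three published metabolomics experiments on
glucose-stimulated INS1 832/13 cells:

* ``spegel2013`` — 2.8 mM pre-incubation, then 16.7 mM for 3/6/10/15 min;
  fold change of 14 metabolites, 16.7 vs 2.8 mM.  3- and 10-min points
  train, 6- and 15-min points validate.
* ``malmgren`` — 60 min at 2.8 or 16.7 mM; 14 metabolites, all training.
* ``spegel2015`` — 16.7 mM from time zero, fold change vs the 0-min
  state at 6/15 min; 14 metabolites, all training.

That yields 70 training and 28 validation observations.  Observation
tables are tab-separated with columns ``metabolite, time_min,
comparison, fold_change, sd, source, role``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = ["metabolite", "time_min", "comparison", "fold_change", "sd", "source", "role"]
COMPARISONS = ("high_vs_low", "vs_t0")
ROLES = ("train", "validation")

#: metabolites measured by each emulated study (pooled names)
STUDY_METABOLITES = {
    "spegel2013": ["2PG", "3PG", "AKG", "ALA", "ASP", "CIT", "FUM", "G3P",
                   "LAC", "MAL", "PEP", "PYR", "R5P", "SUC"],
    "malmgren": ["AKG", "ALA", "ASP", "CIT", "FUM", "G3P", "G6P", "GLC",
                 "GLU", "ICIT", "LAC", "MAL", "PYR", "SUC"],
    "spegel2015": ["2PG", "3PG", "AKG", "ALA", "CIT", "F6P", "FUM", "G6P",
                   "ICIT", "LAC", "MAL", "PEP", "R5P", "SUC"],
}

STUDY_TIMEPOINTS = {
    "spegel2013": {"train": [3.0, 10.0], "validation": [6.0, 15.0]},
    "malmgren": {"train": [60.0], "validation": []},
    "spegel2015": {"train": [6.0, 15.0], "validation": []},
}

STUDY_COMPARISON = {
    "spegel2013": "high_vs_low",
    "malmgren": "high_vs_low",
    "spegel2015": "vs_t0",
}


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class Observation:
    metabolite: str
    time_min: float
    comparison: str
    fold_change: float
    sd: float
    source: str
    role: str

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise DatasetError(f"{self.metabolite}@{self.time_min}: fold change must be > 0")
        if self.sd < 0:
            raise DatasetError(f"{self.metabolite}@{self.time_min}: sd must be >= 0")
        if self.comparison not in COMPARISONS:
            raise DatasetError(f"unknown comparison {self.comparison!r}")
        if self.role not in ROLES:
            raise DatasetError(f"unknown role {self.role!r}")


def expected_role(source: str, time_min: float, comparison: str) -> str | None:
    """Role mandated by the split for a known source; None if free."""
    if source not in STUDY_TIMEPOINTS:
        return None
    if comparison != STUDY_COMPARISON[source]:
        raise DatasetError(
            f"source {source!r} uses comparison {STUDY_COMPARISON[source]!r}, got {comparison!r}"
        )
    for role, times in STUDY_TIMEPOINTS[source].items():
        if any(abs(time_min - t) < 1e-9 for t in times):
            return role
    raise DatasetError(f"source {source!r} has no {time_min}-minute time point")


class FoldChangeDataset:
    """Typed, validated collection of fold-change observations."""

    def __init__(self, frame: pd.DataFrame, enforce_split: bool = True):
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        frame = frame[COLUMNS].copy()
        frame["time_min"] = frame["time_min"].astype(float)
        frame["fold_change"] = frame["fold_change"].astype(float)
        frame["sd"] = frame["sd"].astype(float)
        self.observations: list[Observation] = []
        for i, row in frame.iterrows():
            obs = Observation(
                metabolite=str(row.metabolite), time_min=float(row.time_min),
                comparison=str(row.comparison), fold_change=float(row.fold_change),
                sd=float(row.sd), source=str(row.source), role=str(row.role),
            )
            if enforce_split:
                want = expected_role(obs.source, obs.time_min, obs.comparison)
                if want is not None and want != obs.role:
                    raise DatasetError(
                        f"row {i}: {obs.source} {obs.time_min}-min observations belong to "
                        f"the {want} split, got role {obs.role!r}"
                    )
            self.observations.append(obs)
        self.frame = frame

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def train(self) -> "FoldChangeDataset":
        return FoldChangeDataset(self.frame[self.frame.role == "train"].reset_index(drop=True),
                                 enforce_split=False)

    @property
    def validation(self) -> "FoldChangeDataset":
        return FoldChangeDataset(self.frame[self.frame.role == "validation"].reset_index(drop=True),
                                 enforce_split=False)

    def median_relative_sd(self) -> float:
        rel = self.frame.sd / self.frame.fold_change
        rel = rel[rel > 0]
        return float(rel.median()) if len(rel) else 0.0

    def keys(self) -> list[tuple[str, float, str]]:
        return [(o.metabolite, o.time_min, o.comparison) for o in self.observations]


def load_dataset(path: str | Path, valid_metabolites: list[str] | None = None,
                 enforce_split: bool = True) -> FoldChangeDataset:
    """Read a tab-separated observation table.

    Malformed rows raise with their (1-based, header-inclusive) line
    number; unknown metabolite names raise listing the valid names when
    ``valid_metabolites`` is given.  An empty file yields an empty
    dataset with a warning.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        import warnings

        warnings.warn(f"{path}: empty dataset")
        return FoldChangeDataset(pd.DataFrame(columns=COLUMNS), enforce_split=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: header missing columns {missing}")
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            fc = float(row.fold_change)
            sd = float(row.sd)
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"{path}:{line}: non-numeric fold_change/sd") from exc
        if fc <= 0:
            raise DatasetError(f"{path}:{line}: fold change must be > 0 (got {fc})")
        if sd < 0:
            raise DatasetError(f"{path}:{line}: sd must be >= 0 (got {sd})")
        if valid_metabolites is not None and row.metabolite not in valid_metabolites:
            raise DatasetError(
                f"{path}:{line}: unknown metabolite {row.metabolite!r}; "
                f"valid names: {sorted(valid_metabolites)}"
            )
    return FoldChangeDataset(frame, enforce_split=enforce_split)


def save_dataset(dataset: FoldChangeDataset | pd.DataFrame, path: str | Path) -> None:
    frame = dataset.frame if isinstance(dataset, FoldChangeDataset) else dataset
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
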