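"""In-memory containers for parcellated resting-state time series.

The pipeline's entry point is a set of per-subject region-by-time signal
matrices (one row per time point, one column per region), each carrying a
group label and demographic/cognitive covariates. All subjects in a set
share the same parcellation (region count and ordering).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Subject", "RoiTimeSeriesSet"]


@dataclass
class Subject:
    """One participant's conditioned ROI signals plus metadata.

    Parameters
    ----------
    subject_id
        Unique identifier (used in ``sub-<id>_ts.tsv`` file names).
    data
        Array of shape ``(n_timepoints, n_regions)``.
    group
        ``"patient"`` or ``"control"``.
    covariates
        Mapping of covariate name (age, sex, education, MMSE, AVLT
        subscores, ...) to value. Sex is encoded 0 = male, 1 = female.
    nuisance
        Optional ``(n_timepoints, k)`` matrix of nuisance regressors
        (global/WM/CSF proxies, motion parameters) supplied externally.
    """

    subject_id: str
    data: np.ndarray
    group: str
    covariates: dict = field(default_factory=dict)
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(
                f"subject {self.subject_id}: data must be 2-D "
                f"(time x region), got shape {self.data.shape}"
            )
        if np.isnan(self.data).any():
            raise ValueError(f"subject {self.subject_id}: data contains NaN")
        if self.group not in ("patient", "control"):
            raise ValueError(
                f"subject {self.subject_id}: group must be 'patient' or "
                f"'control', got {self.group!r}"
            )
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.data.shape[0]:
                raise ValueError(
                    f"subject {self.subject_id}: nuisance rows "
                    f"({self.nuisance.shape[0]}) != time points "
                    f"({self.data.shape[0]})"
                )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, nuisance: np.ndarray | None = None) -> "Subject":
        """Copy of this subject with a new signal matrix."""
        return replace(self, data=data, nuisance=nuisance)


@dataclass
class RoiTimeSeriesSet:
    """A dataset of subjects sharing one parcellation and sampling rate."""

    subjects: list
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset must contain at least one subject")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        n_regions = {s.n_regions for s in self.subjects}
        if len(n_regions) != 1:
            raise ValueError(f"subjects disagree on region count: {sorted(n_regions)}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in dataset")

    @property
    def n_regions(self) -> int:
        return self.subjects[0].n_regions

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds

    def group_ids(self, group: str) -> list:
        return [s.subject_id for s in self.subjects if s.group == group]

    def map_data(self, fn) -> "RoiTimeSeriesSet":
        """Apply ``fn(array) -> array`` to every subject's signal matrix."""
        return RoiTimeSeriesSet(
            subjects=[s.with_data(fn(s.data), nuisance=s.nuisance) for s in self.subjects],
            tr_seconds=self.tr_seconds,
        )

    def participants_frame(self) -> pd.DataFrame:
        """Participants table: one row per subject, id + group + covariates."""
        rows = []
        for s in self.subjects:
            row = {"subject_id": s.subject_id, "group": s.group}
            row.update(s.covariates)
            rows.append(row)
        return pd.DataFrame(rows)
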