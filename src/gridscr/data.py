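"""Encounter-history containers.

Field data arrive as one row per capture (individual, date, position, sex,
fork length) plus a per-cell-per-occasion fishing-effort table.  For the model
they are collapsed to a binary array ``y[i, j, k]`` — was individual i
encountered in cell j on occasion k — with repeat same-cell same-occasion
captures collapsing to a single encounter.  Cell-occasions that were never
fished constrain the encounter probability to zero, so an encounter recorded
there is a data error, not a model state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import StudyGrid

__all__ = ["EncounterData"]

SEX_CODES = {"F": 0, "M": 1}  # female = 0, male = 1


@dataclass
class EncounterData:
    """Binary encounter histories with effort and individual covariates.

    Attributes
    ----------
    y : (n, J, K) uint8
        Binary encounter array over individuals x cells x occasions.
    effort : (J, K) float
        Days fished per cell-occasion; 0 means not sampled.
    sex : (n,) int8
        0 female, 1 male, -1 unrecorded.
    size : (n,) float
        Fork length in cm; NaN where unrecorded.
    ids : sequence of str
        Individual identifiers, aligned with rows of ``y``.
    occasion_dates : sequence or None
        Ordered occasion start dates (ISO strings or datetimes).
    """

    y: np.ndarray
    effort: np.ndarray
    sex: np.ndarray
    size: np.ndarray
    ids: Sequence[str] | None = None
    occasion_dates: Sequence | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.uint8)
        self.effort = np.asarray(self.effort, dtype=float)
        self.sex = np.asarray(self.sex, dtype=np.int8)
        self.size = np.asarray(self.size, dtype=float)
        if self.y.ndim != 3:
            raise ValueError("y must have shape (n, J, K)")
        n, J, K = self.y.shape
        if self.effort.shape != (J, K):
            raise ValueError(f"effort shape {self.effort.shape} != (J, K) = {(J, K)}")
        if np.any(self.effort < 0):
            raise ValueError("effort must be non-negative")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")
        if self.sex.shape != (n,) or self.size.shape != (n,):
            raise ValueError("sex/size must have one entry per individual")
        if not np.isin(self.sex, (-1, 0, 1)).all():
            raise ValueError("sex codes must be in {-1, 0, 1}")
        if n > 0:
            bad = np.nonzero(self.y.sum(axis=(1, 2)) == 0)[0]
            if bad.size:
                raise ValueError(f"individuals with no encounters at rows {bad.tolist()}")
            viol = self.y[:, self.effort == 0]
            if np.any(viol != 0):
                raise ValueError(
                    "encounters recorded in zero-effort cell-occasions "
                    "(violates the zero-effort constraint)"
                )
        if self.ids is None:
            self.ids = [f"ind{i+1}" for i in range(n)]
        if len(self.ids) != n:
            raise ValueError("ids length must match number of individuals")
        if self.occasion_dates is not None:
            dates = list(np.asarray(self.occasion_dates, dtype="datetime64[D]"))
            if len(dates) != K:
                raise ValueError("occasion_dates length must equal K")
            if any(b <= a for a, b in zip(dates, dates[1:])):
                raise ValueError("occasion dates must be strictly increasing")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_cells(self) -> int:
        return self.y.shape[1]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[2]

    @property
    def sampled(self) -> np.ndarray:
        """Boolean (J, K): was any fishing effort expended there."""
        return self.effort > 0

    @property
    def n_encounters(self) -> int:
        return int(self.y.sum())

    def validate_against_grid(self, grid: StudyGrid) -> None:
        if grid.n_cells != self.n_cells:
            raise ValueError(
                f"grid has {grid.n_cells} active cells but data has {self.n_cells}"
            )

    def subset(self, cells=None, occasions=None) -> "EncounterData":
        """Restrict to a cell and/or occasion subset, dropping individuals
        left with no encounters (used e.g. for per-occasion trend fits)."""
        cells = np.arange(self.n_cells) if cells is None else np.asarray(cells)
        occs = np.arange(self.n_occasions) if occasions is None else np.asarray(occasions)
        y = self.y[:, cells][:, :, occs]
        keep = y.sum(axis=(1, 2)) > 0
        dates = None
        if self.occasion_dates is not None:
            dates = [self.occasion_dates[k] for k in occs]
        return EncounterData(
            y=y[keep],
            effort=self.effort[np.ix_(cells, occs)],
            sex=self.sex[keep],
            size=self.size[keep],
            ids=[self.ids[i] for i in np.nonzero(keep)[0]],
            occasion_dates=dates,
        )
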