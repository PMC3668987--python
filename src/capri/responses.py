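"""Respondent rating data: the respondent x scenario x rating table.

Ratings are 1-7 Likert integers (or raw latent values for continuous
simulation output used in exact-recovery checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .design import DesignPlan

__all__ = ["ResponseSet", "read_responses", "write_responses"]

COLUMNS = ("respondent_id", "run_id", "rating")


@dataclass
class ResponseSet:
    """Long-format ratings with one row per (respondent, scenario).

    ``continuous`` marks un-discretized latent values; otherwise ratings must
    be integers in [1, 7].
    """

    data: pd.DataFrame
    continuous: bool = False

    def __post_init__(self) -> None:
        missing = set(COLUMNS) - set(self.data.columns)
        if missing:
            raise ValidationError(f"response table missing column(s): {sorted(missing)}")
        df = self.data.loc[:, list(COLUMNS)].copy()
        df["respondent_id"] = df["respondent_id"].astype(str)
        df["run_id"] = df["run_id"].astype(str)
        df["rating"] = pd.to_numeric(df["rating"], errors="raise")
        dup = df.duplicated(subset=["respondent_id", "run_id"])
        if dup.any():
            rows = (df.index[dup] + 1).tolist()[:5]
            raise ValidationError(f"duplicate (respondent, run) pairs at row(s) {rows}")
        if not self.continuous:
            bad = ~df["rating"].between(1, 7) | (df["rating"] % 1 != 0)
            if bad.any():
                rows = (df.index[bad] + 1).tolist()[:5]
                raise ValidationError(
                    f"rating outside the 1..7 integer scale at row(s) {rows}"
                )
            df["rating"] = df["rating"].astype(int)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def respondents(self) -> list[str]:
        return sorted(self.data["respondent_id"].unique())

    def for_runs(self, run_ids: list[str]) -> "ResponseSet":
        sub = self.data[self.data["run_id"].isin(run_ids)]
        return ResponseSet(sub.reset_index(drop=True), continuous=self.continuous)

    def mean_by_run(self) -> pd.Series:
        return self.data.groupby("run_id")["rating"].mean()


def read_responses(path: str | Path, plan: "DesignPlan | None" = None) -> ResponseSet:
    """Read and validate a responses CSV (respondent_id, run_id, rating).

    With a ``plan``, ratings against unknown run ids are rejected.  Row
    numbers in error messages count from 1 excluding the header.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"responses file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValidationError(f"cannot parse responses file {path}: {exc}") from exc
    rs = ResponseSet(df)
    if plan is not None:
        known = set(plan.run_ids)
        bad = ~rs.data["run_id"].isin(known)
        if bad.any():
            rows = (rs.data.index[bad] + 1).tolist()[:5]
            raise ValidationError(f"unknown run_id at row(s) {rows}")
    return rs


def write_responses(rs: ResponseSet, path: str | Path) -> None:
    rs.data.to_csv(path, index=False)
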