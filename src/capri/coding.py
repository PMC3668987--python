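"""Effects (deviation) coding of profiles into a regression design matrix.

Effects coding is the contrast scheme under which each attribute's estimated
part-worths sum to zero: an attribute with L levels contributes L-1 columns,
where level j < L codes +1 in column j, the reference (last) level codes -1
in every column of the attribute, and other levels code 0.  The reference
level's part-worth is recovered as minus the sum of the estimated contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .attributes import AttributeSet, Profile
from .errors import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .design import DesignPlan

__all__ = ["CodingMatrix", "build_coding_matrix", "profiles_to_matrix"]


@dataclass(frozen=True)
class CodingMatrix:
    """Effects-coded model matrix for a list of profiles.

    ``column_map`` aligns columns to their meaning: ``None`` for the
    intercept, otherwise ``(attribute_name, level_index)`` of the non-reference
    level the column contrasts against the attribute's last level.
    """

    matrix: np.ndarray  # (n_profiles, 1 + sum(L_a - 1))
    column_map: tuple[tuple[str, int] | None, ...]
    run_ids: tuple[str, ...]

    @property
    def n_parameters(self) -> int:
        return self.matrix.shape[1]

    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


def profiles_to_matrix(
    profiles: Sequence[Profile],
    attrs: AttributeSet,
    run_ids: Sequence[str] | None = None,
) -> CodingMatrix:
    """Effects-code arbitrary profiles (intercept first, attribute order next)."""
    n = len(profiles)
    cols: list[np.ndarray] = [np.ones(n)]
    cmap: list[tuple[str, int] | None] = [None]
    for a in attrs:
        L = a.n_levels
        idx = np.array([p.level(a.name) for p in profiles])
        if idx.min() < 1 or idx.max() > L:
            raise ValidationError(f"profile level out of range for {a.name!r}")
        for j in range(1, L):
            col = np.where(idx == j, 1.0, 0.0) - np.where(idx == L, 1.0, 0.0)
            cols.append(col)
            cmap.append((a.name, j))
    ids = tuple(run_ids) if run_ids is not None else tuple(str(i) for i in range(n))
    if len(ids) != n:
        raise ValidationError("run_ids length must match profiles")
    return CodingMatrix(np.column_stack(cols), tuple(cmap), ids)


def build_coding_matrix(plan: "DesignPlan", attrs: AttributeSet | None = None) -> CodingMatrix:
    """Effects-code the *estimation* runs of a design plan."""
    attrs = attrs if attrs is not None else plan.attrs
    if attrs.names != plan.attrs.names:
        raise ValidationError("attribute set does not match the plan's attributes")
    runs, ids = plan.estimation_runs()
    return profiles_to_matrix(runs, attrs, ids)
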