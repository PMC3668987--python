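"""Synthetic stakeholder ratings under an additive part-worth utility model.

The generator stands in for survey respondents: each simulated respondent
carries individual part-worths (population means plus Gaussian heterogeneity,
re-centered to stay zero-sum within every attribute) and rates each scenario
as

    rating = clamp(round(midpoint + constant + sum of part-worths + noise), 1, 7)

with rounding half away from zero, i.e. the simplest latent-variable response
model consistent with treating Likert ratings as interval data.  The default
population is the published stakeholder utility table for postnatal-depression
innovations (:func:`population_from_table6`), with 139 respondents — the
realized sample of the original survey — heterogeneity SD 0.1 and rating
noise SD 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .attributes import AttributeSet, Profile, builtin_pnd_attributes, validate_profile
from .design import DesignPlan
from .errors import ValidationError
from .responses import ResponseSet

__all__ = [
    "PopulationSpec",
    "population_from_table6",
    "latent_utility",
    "simulate_ratings",
    "nonresponse_filter",
    "TABLE6_PARTWORTHS",
    "TABLE6_CONSTANT",
]

# Published pooled OLS part-worth estimates for the seven PND attributes
# (levels in attribute order; each attribute zero-sum), plus the constant.
TABLE6_PARTWORTHS: dict[str, tuple[float, ...]] = {
    "impact": (-0.228, 0.078, 0.150),        # significant, moderate, limited
    "cost": (0.252, -0.090, -0.162),         # low, moderate, high
    "needs": (-0.207, 0.207),                # low, high prevalence
    "standards": (-0.324, 0.324),            # not meeting, meeting
    "evidence": (-0.243, -0.135, -0.027, 0.405),  # none..strong
    "priority": (-0.108, -0.144, 0.252),     # national, local, both
    "expertise": (0.018, -0.018),            # none, present
}
TABLE6_CONSTANT = 0.048


@dataclass(frozen=True)
class PopulationSpec:
    """Latent preference population from which respondents are drawn."""

    attrs: AttributeSet
    mean_partworths: Mapping[str, tuple[float, ...]]
    constant: float
    heterogeneity_sd: float = 0.1
    noise_sd: float = 0.5
    n_respondents: int = 139
    scale_midpoint: float = 4.0
    continuous_output: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        pw = {k: tuple(float(x) for x in v) for k, v in self.mean_partworths.items()}
        object.__setattr__(self, "mean_partworths", pw)
        for a in self.attrs:
            if a.name not in pw:
                raise ValidationError(f"no part-worths for attribute {a.name!r}")
            vals = pw[a.name]
            if len(vals) != a.n_levels:
                raise ValidationError(
                    f"part-worth count mismatch for {a.name!r}: "
                    f"{len(vals)} values for {a.n_levels} levels"
                )
            if abs(sum(vals)) > 1e-9:
                raise ValidationError(
                    f"part-worths for {a.name!r} must sum to 0, got {sum(vals):g}"
                )
        if self.heterogeneity_sd < 0 or self.noise_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_respondents < 1:
            raise ValidationError("n_respondents must be >= 1")

    def replace(self, **kwargs) -> "PopulationSpec":
        return replace(self, **kwargs)


def population_from_table6(impact_reversed: bool = False, **overrides) -> PopulationSpec:
    """Population whose mean part-worths equal the published utility table.

    The published table assigns a *negative* utility to 'significant
    improvement' in impact on care, contradicting the accompanying claim that
    significant impact was preferred to limited impact — the printed rows may
    be reversed.  The table is reproduced as printed by default;
    ``impact_reversed=True`` selects the alternative reading with the impact
    utilities flipped.  Simulation defaults (heterogeneity, noise, N) can be
    overridden via keyword arguments.
    """
    pw = dict(TABLE6_PARTWORTHS)
    if impact_reversed:
        pw["impact"] = tuple(reversed(pw["impact"]))
    return PopulationSpec(
        attrs=builtin_pnd_attributes(),
        mean_partworths=pw,
        constant=TABLE6_CONSTANT,
        **overrides,
    )


def latent_utility(
    spec: PopulationSpec,
    respondent_partworths: Mapping[str, tuple[float, ...]] | None,
    p: Profile,
) -> float:
    """Constant plus the respondent's part-worths at the profile's levels.

    ``respondent_partworths=None`` uses the population means.
    """
    validate_profile(spec.attrs, p)
    pw = respondent_partworths if respondent_partworths is not None else spec.mean_partworths
    total = spec.constant
    for a in spec.attrs:
        total += pw[a.name][p.level(a.name) - 1]
    return float(total)


def _round_half_away_from_zero(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _draw_respondent_partworths(
    spec: PopulationSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Means plus Gaussian perturbation, re-centered to zero-sum per attribute."""
    pw = {}
    for a in spec.attrs:
        v = np.asarray(spec.mean_partworths[a.name]) + rng.normal(
            0.0, spec.heterogeneity_sd, size=a.n_levels
        )
        pw[a.name] = v - v.mean()
    return pw


def simulate_ratings(spec: PopulationSpec, plan: DesignPlan) -> ResponseSet:
    """Simulate every respondent rating every run of the plan (all roles).

    Deterministic in ``spec.seed``.
    """
    if spec.attrs.names != plan.attrs.names:
        raise ValidationError("plan attributes do not match population attributes")
    rng = np.random.default_rng(spec.seed)
    n_runs = len(plan.runs)
    # 0-based level index per attribute across all plan runs, computed once
    level_idx = {
        a.name: np.array([p.level(a.name) - 1 for p in plan.runs]) for a in spec.attrs
    }
    blocks = []
    for r in range(spec.n_respondents):
        pw = _draw_respondent_partworths(spec, rng)
        latent = np.full(n_runs, spec.scale_midpoint + spec.constant)
        for a in spec.attrs:
            latent += pw[a.name][level_idx[a.name]]
        latent += rng.normal(0.0, spec.noise_sd, size=n_runs)
        if spec.continuous_output:
            ratings = latent
        else:
            ratings = np.clip(_round_half_away_from_zero(latent), 1, 7)
        blocks.append(
            pd.DataFrame(
                {
                    "respondent_id": f"R{r + 1:04d}",
                    "run_id": list(plan.run_ids),
                    "rating": ratings,
                }
            )
        )
    df = pd.concat(blocks, ignore_index=True)
    return ResponseSet(df, continuous=spec.continuous_output)


def nonresponse_filter(rs: ResponseSet, response_rate: float, seed: int = 0) -> ResponseSet:
    """Retain an independent Bernoulli subset of respondents (all-or-none).

    Emulates survey nonresponse: each respondent returns the questionnaire
    with probability ``response_rate``.
    """
    if not 0 < response_rate <= 1:
        raise ValidationError(f"response_rate must be in (0, 1], got {response_rate}")
    if response_rate == 1.0:
        return rs
    rng = np.random.default_rng(seed)
    keep = {r for r in rs.respondents if rng.random() < response_rate}
    sub = rs.data[rs.data["respondent_id"].isin(keep)]
    return ResponseSet(sub.reset_index(drop=True), continuous=rs.continuous)
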