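"""Scoring and ranking real innovations with a fitted utility model.

Each candidate innovation is described on the shared attribute grid (a level
per attribute, assigned from evidence sources — input data, not computation);
its total utility is the model constant plus the part-worths at its levels,
and innovations are ranked by descending total utility.  What-if analysis
recomputes total and rank after swapping a single attribute level, making the
sensitivity of the ranking to the (subjective) scoring step explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .attributes import AttributeSet, Profile, builtin_pnd_attributes, profile_from_labels
from .errors import ValidationError
from .estimate import UtilityModel

__all__ = [
    "InnovationProfile",
    "InnovationGroup",
    "Ranking",
    "builtin_pnd_innovations",
    "load_innovations",
    "total_utility",
    "rank_innovations",
    "what_if",
    "combine_innovations",
    "group_utility",
]


@dataclass(frozen=True)
class InnovationProfile:
    """A named real innovation positioned on the attribute grid."""

    name: str
    profile: Profile
    notes: str = ""


@dataclass(frozen=True)
class InnovationGroup:
    """A named bundle of related innovations implemented as one."""

    name: str
    members: tuple[InnovationProfile, ...]


@dataclass
class Ranking:
    """Utility-ordered innovations: rank 1 = highest total utility.

    Ties are broken alphabetically by innovation name (recorded in
    ``tie_break``).
    """

    records: pd.DataFrame  # rank, name, total_utility
    provenance: str = ""
    tie_break: str = "alphabetical"

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def rank_of(self, name: str) -> int:
        row = self.records[self.records["name"] == name]
        if row.empty:
            raise ValidationError(f"innovation {name!r} not in ranking")
        return int(row["rank"].iloc[0])


def load_innovations(path: str | Path, attrs: AttributeSet) -> list[InnovationProfile]:
    """Read an innovations CSV: ``name`` plus one level-label column per attribute."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"innovations file not found: {path}")
    df = pd.read_csv(path, dtype=str).fillna("")
    if "name" not in df.columns:
        raise ValidationError("innovations file needs a 'name' column")
    out = []
    for _, row in df.iterrows():
        assignment = {a.name: row[a.name] for a in attrs}
        out.append(
            InnovationProfile(
                name=row["name"],
                profile=profile_from_labels(attrs, assignment),
                notes=row.get("notes", ""),
            )
        )
    if len({ip.name for ip in out}) != len(out):
        raise ValidationError("innovation names must be unique")
    return out


def builtin_pnd_innovations() -> list[InnovationProfile]:
    """The packaged postnatal-depression candidate list (11 innovations).

    The original project considered 12 innovations but only 11 appear in the
    published assessment grid; the fixture ships those 11.
    """
    attrs = builtin_pnd_attributes()
    with resources.as_file(
        resources.files("capri.data").joinpath("pnd_innovations.csv")
    ) as p:
        return load_innovations(p, attrs)


def total_utility(m: UtilityModel, ip: InnovationProfile) -> float:
    """Constant + sum of part-worths at the innovation's levels."""
    from .estimate import predict_rating

    return predict_rating(m, ip.profile, scale_midpoint=0.0)


def rank_innovations(m: UtilityModel, innovations: Sequence[InnovationProfile]) -> Ranking:
    """Rank by descending total utility; equal utilities rank alphabetically."""
    if not innovations:
        raise ValidationError("cannot rank an empty innovation list")
    rows = [
        {"name": ip.name, "total_utility": total_utility(m, ip)} for ip in innovations
    ]
    df = pd.DataFrame(rows).sort_values(
        ["total_utility", "name"], ascending=[False, True], kind="stable"
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return Ranking(
        df.reset_index(drop=True),
        provenance="total utility under fitted part-worth model",
    )


def what_if(
    m: UtilityModel,
    ip: InnovationProfile,
    attribute: str,
    new_level: int | str,
    context: Sequence[InnovationProfile],
) -> dict:
    """Recompute total and rank after moving one attribute to a new level.

    ``context`` is the full competitive set the innovation is ranked within
    (it should contain ``ip``).  Returns old/new totals and ranks.
    """
    a = m.attrs.get(attribute)
    idx = new_level if isinstance(new_level, int) else a.level_index(new_level)
    if not 1 <= idx <= a.n_levels:
        raise ValidationError(f"level {new_level!r} out of range for {a.name!r}")
    levels = dict(ip.profile.levels)
    levels[a.name] = idx
    modified = InnovationProfile(ip.name, Profile(levels), ip.notes)
    old_ranking = rank_innovations(m, context)
    new_context = [modified if c.name == ip.name else c for c in context]
    if all(c.name != ip.name for c in context):
        raise ValidationError(f"innovation {ip.name!r} not in the ranking context")
    new_ranking = rank_innovations(m, new_context)
    return {
        "old_total": total_utility(m, ip),
        "new_total": total_utility(m, modified),
        "old_rank": old_ranking.rank_of(ip.name),
        "new_rank": new_ranking.rank_of(ip.name),
    }


def combine_innovations(
    innovations: Sequence[InnovationProfile], name: str
) -> InnovationGroup:
    """Bundle >=2 related innovations under one name, preserving membership."""
    if len(innovations) < 2:
        raise ValidationError("a combined innovation needs >=2 members")
    return InnovationGroup(name=name, members=tuple(innovations))


def group_utility(m: UtilityModel, group: InnovationGroup) -> dict:
    """Max and mean of member total utilities (never a sum, which would
    double-count the constant)."""
    totals = [total_utility(m, ip) for ip in group.members]
    return {"max": max(totals), "mean": sum(totals) / len(totals)}
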