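"""Render a design plan as a rating questionnaire.

Each task presents one hypothetical innovation — all seven (in general, all)
attribute labels with that scenario's levels — to be rated on a seven-point
Likert scale anchored from 'Very likely to prioritize this guideline' to
'Very unlikely to prioritize this guideline'.  Consistency scenarios are
interleaved among the estimation scenarios by a seeded permutation recorded
in the questionnaire's provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .attributes import AttributeSet
from .design import DesignPlan
from .errors import ValidationError

__all__ = ["Questionnaire", "render_questionnaire", "SCALE_ANCHORS"]

SCALE_ANCHORS = (
    "Very likely to prioritize this guideline",
    "Very unlikely to prioritize this guideline",
)

PREAMBLE = (
    "Please rate how likely you would be to prioritize each of the following "
    "hypothetical innovations, on a scale of 1 to 7."
)


@dataclass
class Questionnaire:
    """Ordered rating tasks plus the 7-point response scale."""

    tasks: list[tuple[str, str]]  # (run_id, task text)
    scale_points: int
    scale_anchors: tuple[str, str]
    preamble: str
    provenance: str

    def to_text(self) -> str:
        lines = [self.preamble, "", f"1 = {self.scale_anchors[0]}",
                 f"{self.scale_points} = {self.scale_anchors[1]}", ""]
        for i, (rid, text) in enumerate(self.tasks, start=1):
            lines.append(f"Scenario {i} [{rid}]")
            lines.append(text)
            lines.append("")
        return "\n".join(lines)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def render_questionnaire(
    plan: DesignPlan, attrs: AttributeSet | None = None, seed: int = 0
) -> Questionnaire:
    """One task per plan run, consistency tasks interleaved by a seeded shuffle."""
    attrs = attrs if attrs is not None else plan.attrs
    if attrs.names != plan.attrs.names:
        raise ValidationError("attribute set does not match the plan")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(plan.runs)))
    tasks = []
    for i in order:
        p, rid = plan.runs[i], plan.run_ids[i]
        labels = p.labels(attrs)
        body = "\n".join(f"  {a.label}: {labels[a.name]}" for a in attrs)
        tasks.append((rid, body))
    prov = (
        f"task order: seeded permutation (seed {seed}) of run order "
        f"{[plan.run_ids[i] for i in order]}"
    )
    return Questionnaire(
        tasks=tasks,
        scale_points=7,
        scale_anchors=SCALE_ANCHORS,
        preamble=PREAMBLE,
        provenance=prov,
    )
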