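"""Attribute/level space describing competing innovations.

A conjoint study decomposes an innovation into a small set of categorical
attributes (impact on care, cost, strength of evidence, ...), each taking one
of a few discrete, ordered levels.  A :class:`Profile` fixes one level per
attribute and describes one (hypothetical or real) innovation.

Level indices are 1-based throughout, following the printed order of the
attribute definition file; files and reports always carry level *labels* so
that no off-by-one ambiguity can creep into serialized artifacts.

The packaged postnatal-depression (PND) fixture — seven attributes covering
impact, cost, local health needs, minimum standards, evidence strength,
priority status and local expertise — ships in ``capri/data`` and is returned
by :func:`builtin_pnd_attributes`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .errors import ValidationError

__all__ = [
    "Attribute",
    "AttributeSet",
    "Profile",
    "load_attribute_set",
    "write_attribute_set",
    "builtin_pnd_attributes",
    "full_factorial_size",
    "validate_profile",
    "profile_from_labels",
]


def _norm(s: str) -> str:
    """Normalization used for name/label matching: case- and final-dot-insensitive."""
    return s.strip().rstrip(".").casefold()


@dataclass(frozen=True)
class Attribute:
    """One categorical characteristic of an innovation.

    Parameters
    ----------
    name:
        Short machine identifier (e.g. ``"cost"``), unique within a set.
    label:
        Human-readable description as it appears on questionnaires.
    levels:
        Ordered level labels; order defines the 1-based level indices.
    """

    name: str
    label: str
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        if len(self.levels) < 2:
            raise ValidationError(
                f"attribute {self.name!r} needs >=2 levels, got {len(self.levels)}"
            )
        keys = [_norm(l) for l in self.levels]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"attribute {self.name!r} has duplicate level labels")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def level_index(self, label: str) -> int:
        """Resolve a level label to its 1-based index.

        Exact (normalized) matches win; otherwise a unique normalized prefix
        is accepted, so the shorthand ``"Moderate"`` resolves against
        ``"Moderate supporting evidence."``.
        """
        key = _norm(label)
        for i, lv in enumerate(self.levels, start=1):
            if _norm(lv) == key:
                return i
        prefix_hits = [
            i for i, lv in enumerate(self.levels, start=1) if _norm(lv).startswith(key)
        ]
        if len(prefix_hits) == 1:
            return prefix_hits[0]
        raise ValidationError(
            f"level {label!r} not found (or ambiguous) for attribute {self.name!r}"
        )


@dataclass(frozen=True)
class AttributeSet:
    """Ordered collection of attributes defining the preference space."""

    attributes: tuple[Attribute, ...]
    _by_key: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        if not self.attributes:
            raise ValidationError("AttributeSet must contain at least one attribute")
        by_key: dict[str, Attribute] = {}
        for a in self.attributes:
            k = _norm(a.name)
            if k in by_key:
                raise ValidationError(f"duplicate attribute name {a.name!r}")
            by_key[k] = a
        # labels may also be used as lookup keys when they do not clash
        for a in self.attributes:
            k = _norm(a.label)
            by_key.setdefault(k, a)
        object.__setattr__(self, "_by_key", by_key)

    def __iter__(self) -> Iterator[Attribute]:
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def __contains__(self, key: str) -> bool:
        return _norm(key) in self._by_key

    def get(self, key: str) -> Attribute:
        """Look up an attribute by name or label (case-insensitive)."""
        try:
            return self._by_key[_norm(key)]
        except KeyError:
            raise ValidationError(f"unknown attribute {key!r}") from None


@dataclass(frozen=True)
class Profile:
    """One level assignment per attribute: a single (hypothetical) innovation.

    ``levels`` maps attribute name to 1-based level index.
    """

    levels: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))

    def level(self, attr_name: str) -> int:
        return self.levels[attr_name]

    def key(self, attrs: AttributeSet) -> tuple[int, ...]:
        """Canonical tuple of level indices in attribute order (for comparisons)."""
        return tuple(self.levels[a.name] for a in attrs)

    def labels(self, attrs: AttributeSet) -> dict[str, str]:
        return {a.name: a.levels[self.levels[a.name] - 1] for a in attrs}


def _build_attribute_set(entries: list) -> AttributeSet:
    attrs = []
    for e in entries:
        if not isinstance(e, Mapping) or "name" not in e or "levels" not in e:
            raise ValidationError(
                "each attribute entry must be a mapping with 'name' and 'levels'"
            )
        attrs.append(
            Attribute(
                name=str(e["name"]),
                label=str(e.get("label", e["name"])),
                levels=tuple(str(l) for l in e["levels"]),
            )
        )
    return AttributeSet(tuple(attrs))


def load_attribute_set(config_path: str | Path) -> AttributeSet:
    """Load an :class:`AttributeSet` from a YAML (or JSON) document.

    The document is an ordered list of ``{name, label, levels: [...]}``
    mappings; file order defines attribute order and level indices.
    """
    path = Path(config_path)
    if not path.exists():
        raise ValidationError(f"attribute file not found: {path}")
    try:
        entries = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"cannot parse attribute file {path}: {exc}") from exc
    if not isinstance(entries, list):
        raise ValidationError("attribute file must contain a list of attributes")
    return _build_attribute_set(entries)


def write_attribute_set(attrs: AttributeSet, path: str | Path) -> None:
    """Serialize an attribute set so that :func:`load_attribute_set` round-trips."""
    docs = [
        {"name": a.name, "label": a.label, "levels": list(a.levels)} for a in attrs
    ]
    Path(path).write_text(json.dumps(docs, indent=2) + "\n")


def builtin_pnd_attributes() -> AttributeSet:
    """The packaged seven-attribute postnatal-depression fixture."""
    text = resources.files("capri.data").joinpath("pnd_attributes.yaml").read_text()
    return _build_attribute_set(yaml.safe_load(text))


def full_factorial_size(attrs: AttributeSet) -> int:
    """Number of distinct profiles in the full level-combination space."""
    return math.prod(a.n_levels for a in attrs)


def validate_profile(attrs: AttributeSet, p: Profile) -> Profile:
    """Check that ``p`` assigns exactly one in-range level to every attribute."""
    names = set(attrs.names)
    for a in attrs:
        if a.name not in p.levels:
            raise ValidationError(f"profile missing attribute {a.name!r}")
        idx = p.levels[a.name]
        if not isinstance(idx, int) or not 1 <= idx <= a.n_levels:
            raise ValidationError(
                f"level index {idx!r} out of range 1..{a.n_levels} "
                f"for attribute {a.name!r}"
            )
    unknown = set(p.levels) - names
    if unknown:
        raise ValidationError(f"profile has unknown attribute(s): {sorted(unknown)}")
    return p


def profile_from_labels(attrs: AttributeSet, assignment: Mapping[str, str]) -> Profile:
    """Build a validated profile from ``{attribute name/label: level label}``."""
    levels = {}
    for key, label in assignment.items():
        a = attrs.get(key)
        levels[a.name] = a.level_index(label)
    return validate_profile(attrs, Profile(levels))
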