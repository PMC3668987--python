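"""Orthogonal main-effects experimental plans for rating-based conjoint tasks.

The scenario set shown to respondents is a fractional factorial in the
Addelman orthogonal-main-effects tradition, built deterministically:

1. For a power-of-two run size ``n = 2**k``, the saturated two-level array has
   ``n - 1`` columns indexed by the nonzero vectors ``v`` of GF(2)^k; column
   ``v`` at run ``i`` is the parity of ``i & v``.  Any two distinct columns
   are orthogonal.
2. XOR-closed column triples ``{a, b, a XOR b}`` (lines of the projective
   geometry PG(k-1, 2)) are paired into 4-level pseudo-factors: the two
   leading columns of a line give 2 bits, hence codes 1..4, balanced ``n/4``
   each.  A greedy disjoint packing of lines (a spread, or partial spread)
   makes distinct pseudo-factors mutually orthogonal.
3. Attributes with 4 levels take a pseudo-factor as-is; 3-level attributes
   take a pseudo-factor collapsed by the fixed surjection 4 -> 1 (Addelman
   collapsing, proportional frequencies n/2 : n/4 : n/4); 2-level attributes
   take a single leftover column (or a pseudo-factor collapsed {1,2}/{3,4}).

Collapsed columns are no longer balanced but satisfy the Addelman
proportional-frequency condition count(i, j) = count(i) * count(j) / n
against every other attribute, which keeps all main effects estimable
(full-rank effects-coded model matrix).

Five extra "consistency" scenarios are appended for internal validity: each
duplicates an estimation scenario with one or more attributes moved to an
a-priori preferable level, so under any preference model that respects the
rational level orderings the new scenario must score at least as high as its
parent.  They double as holdout tasks and are never used for estimation.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import AttributeSet, Profile, validate_profile
from .coding import CodingMatrix, profiles_to_matrix
from .errors import ValidationError

__all__ = [
    "DesignPlan",
    "DesignDiagnostics",
    "minimum_hadamard_runs",
    "generate_plan",
    "collapse_column",
    "add_validation_scenarios",
    "design_diagnostics",
    "PND_RATIONAL_ORDERINGS",
]

# A-priori "worst -> best" level orderings for the packaged PND attribute set,
# used to construct dominance (consistency) scenarios.  Only cost, impact,
# evidence and prevalence have defensible rational orderings; minimum
# standards, priority status and local expertise are left unordered.
PND_RATIONAL_ORDERINGS: dict[str, tuple[int, ...]] = {
    "impact": (3, 2, 1),        # limited < moderate < significant
    "cost": (3, 2, 1),          # high < moderate < low
    "needs": (1, 2),            # low prevalence < high prevalence
    "evidence": (1, 2, 3, 4),   # none < limited < moderate < strong
}


@dataclass
class DesignPlan:
    """An ordered set of scenarios with estimation/consistency roles.

    ``parents`` maps a consistency run's id to the estimation run it
    dominates.  Regenerating with the same seed reproduces the plan exactly.
    """

    attrs: AttributeSet
    runs: list[Profile]
    roles: list[str]
    run_ids: list[str]
    seed: int
    provenance: str
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.runs) == len(self.roles) == len(self.run_ids)):
            raise ValidationError("runs, roles and run_ids must align 1:1")
        bad = set(self.roles) - {"estimation", "consistency"}
        if bad:
            raise ValidationError(f"unknown role(s): {sorted(bad)}")
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValidationError("run_ids must be unique")
        for p in self.runs:
            validate_profile(self.attrs, p)
        est = [p.key(self.attrs) for p, r in zip(self.runs, self.roles) if r == "estimation"]
        if len(set(est)) != len(est):
            raise ValidationError("estimation runs must be distinct profiles")

    def estimation_runs(self) -> tuple[list[Profile], list[str]]:
        pairs = [(p, i) for p, r, i in zip(self.runs, self.roles, self.run_ids) if r == "estimation"]
        return [p for p, _ in pairs], [i for _, i in pairs]

    def consistency_runs(self) -> tuple[list[Profile], list[str]]:
        pairs = [(p, i) for p, r, i in zip(self.runs, self.roles, self.run_ids) if r == "consistency"]
        return [p for p, _ in pairs], [i for _, i in pairs]

    def run(self, run_id: str) -> Profile:
        try:
            return self.runs[self.run_ids.index(run_id)]
        except ValueError:
            raise ValidationError(f"unknown run_id {run_id!r}") from None

    @property
    def n_estimation(self) -> int:
        return sum(r == "estimation" for r in self.roles)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, role, rid in zip(self.runs, self.roles, self.run_ids):
            row = {"run_id": rid, "role": role, "parent_id": self.parents.get(rid, "")}
            row.update(p.labels(self.attrs))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the plan as CSV (level labels) plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {"seed": self.seed, "provenance": self.provenance}
            path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, attrs: AttributeSet) -> "DesignPlan":
        path = Path(path)
        df = pd.read_csv(path, dtype=str).fillna("")
        runs, roles, ids, parents = [], [], [], {}
        for _, row in df.iterrows():
            levels = {a.name: attrs.get(a.name).level_index(row[a.name]) for a in attrs}
            runs.append(Profile(levels))
            roles.append(row["role"])
            ids.append(row["run_id"])
            if row.get("parent_id", ""):
                parents[row["run_id"]] = row["parent_id"]
        meta_path = path.with_suffix(".json")
        seed, prov = 0, f"loaded from {path.name}"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            seed, prov = meta.get("seed", 0), meta.get("provenance", prov)
        return cls(attrs, runs, roles, ids, seed, prov, parents)


@dataclass
class DesignDiagnostics:
    """Quality report for a plan's estimation runs."""

    level_frequencies: dict[str, list[int]]
    pairwise_frequency_tables: dict[tuple[str, str], np.ndarray]
    coding_matrix_rank: int
    n_parameters: int
    d_efficiency: float


def minimum_hadamard_runs(attrs: AttributeSet) -> int:
    """Smallest power-of-two run size covering intercept + all main effects.

    The main-effects model has ``1 + sum(L_a - 1)`` parameters; the run count
    is the smallest n in {4, 8, 16, 32, ...} with at least that many runs.
    """
    df = 1 + sum(a.n_levels - 1 for a in attrs)
    n = 4
    while n < df:
        n *= 2
    return n


def collapse_column(values: Sequence[int], target_levels: int) -> list[int]:
    """Addelman-collapse a 4-level column to 3 or 2 levels.

    Fixed surjections: to 3 levels, code 4 maps onto code 1 (frequencies
    become 2:1:1); to 2 levels, {1,2} -> 1 and {3,4} -> 2 (balance kept).
    """
    if target_levels == 3:
        mapping = {1: 1, 2: 2, 3: 3, 4: 1}
    elif target_levels == 2:
        mapping = {1: 1, 2: 1, 3: 2, 4: 2}
    else:
        raise ValidationError(f"target_levels must be 2 or 3, got {target_levels}")
    out = []
    for v in values:
        if v not in (1, 2, 3, 4):
            raise ValidationError(f"invalid 4-level code {v!r}")
        out.append(mapping[v])
    return out


def _hadamard_column(v: int, n: int) -> np.ndarray:
    """Two-level column (codes 0/1) indexed by nonzero GF(2)^k vector v."""
    i = np.arange(n)
    return np.array([bin(x & v).count("1") % 2 for x in i])


def _greedy_line_packing(n: int) -> tuple[list[tuple[int, int, int]], list[int]]:
    """Disjoint XOR-closed triples (lines) among columns 1..n-1, plus leftovers.

    For n = 16 this recovers a full spread of PG(3,2): five disjoint lines.
    """
    used: set[int] = set()
    lines: list[tuple[int, int, int]] = []
    for a in range(1, n):
        if a in used:
            continue
        for b in range(a + 1, n):
            c = a ^ b
            if b in used or c in used or c <= b:
                continue
            lines.append((a, b, c))
            used.update((a, b, c))
            break
    leftovers = [v for v in range(1, n) if v not in used]
    return lines, leftovers


def _pseudo_factor(line: tuple[int, int, int], n: int) -> np.ndarray:
    """4-level codes 1..4 from the two leading columns of a line."""
    a, b, _ = line
    return 2 * _hadamard_column(a, n) + _hadamard_column(b, n) + 1


def generate_plan(
    attrs: AttributeSet,
    n_runs: int | str = "auto",
    seed: int = 0,
) -> DesignPlan:
    """Generate an orthogonal main-effects plan of estimation scenarios.

    ``n_runs`` must be a power of two at least :func:`minimum_hadamard_runs`
    (or ``"auto"`` for exactly that minimum).  The seed permutes run order
    and which attributes receive which pseudo-factor/column among valid
    assignments; the construction itself is fixed.

    Raises :class:`ValidationError` if the run count is too small, an
    attribute has more than 4 levels, or no valid assignment exists.
    """
    min_runs = minimum_hadamard_runs(attrs)
    if n_runs == "auto":
        n = min_runs
    else:
        n = int(n_runs)
        if n & (n - 1) or n < min_runs:
            raise ValidationError(
                f"n_runs must be a power of two >= {min_runs}, got {n_runs}"
            )
    for a in attrs:
        if a.n_levels > 4:
            raise ValidationError(
                f"attribute {a.name!r} has {a.n_levels} levels; the largest "
                f"available pseudo-factor has 4"
            )

    lines, leftover_pts = _greedy_line_packing(n)
    multi = [a for a in attrs if a.n_levels >= 3]
    binary = [a for a in attrs if a.n_levels == 2]
    if len(multi) > len(lines):
        raise ValidationError(
            f"{len(multi)} attributes need 3/4-level pseudo-factors but only "
            f"{len(lines)} disjoint column triples exist in {n} runs"
        )

    rng = np.random.default_rng(seed)
    # Try seeded assignments until the collapsed design has distinct runs and
    # a full-rank coding matrix (the first try succeeds for all spaces the
    # minimum-run rule admits; the loop is a safety net).
    last_err = "no assignment attempted"
    for _ in range(64):
        line_order = list(rng.permutation(len(lines)))
        pf_lines = [lines[i] for i in line_order[: len(multi)]]
        spare_lines = [lines[i] for i in line_order[len(multi):]]
        single_pool = list(leftover_pts) + [v for ln in spare_lines for v in ln]
        single_pool = [single_pool[i] for i in rng.permutation(len(single_pool))]
        if len(binary) > len(single_pool):
            last_err = "not enough free columns for 2-level attributes"
            continue

        columns: dict[str, np.ndarray] = {}
        for a, line in zip(multi, pf_lines):
            codes = _pseudo_factor(line, n)
            if a.n_levels == 3:
                codes = np.array(collapse_column(list(codes), 3))
            columns[a.name] = codes
        for a, v in zip(binary, single_pool):
            columns[a.name] = _hadamard_column(v, n) + 1

        profiles = [
            Profile({a.name: int(columns[a.name][i]) for a in attrs}) for i in range(n)
        ]
        if len({p.key(attrs) for p in profiles}) != n:
            last_err = "collapsing produced duplicate estimation profiles"
            continue
        order = rng.permutation(n)
        profiles = [profiles[i] for i in order]
        cm = profiles_to_matrix(profiles, attrs)
        if cm.rank() != cm.n_parameters:
            last_err = "effects-coded matrix is rank deficient"
            continue
        freqs_ok = all(
            np.bincount(np.array([p.level(a.name) for p in profiles]), minlength=a.n_levels + 1)[1:].min() > 0
            for a in attrs
        )
        if not freqs_ok:  # cannot happen with these collapses; belt and braces
            last_err = "a level never appears in the plan"
            continue
        ids = [f"E{i + 1:02d}" for i in range(n)]
        prov = (
            f"Hadamard-derived {n}-run array; XOR-closed column triples as "
            f"4-level pseudo-factors; Addelman collapsing to 3/2 levels; "
            f"seed {seed} permutes assignment and run order"
        )
        return DesignPlan(attrs, profiles, ["estimation"] * n, ids, seed, prov)
    raise ValidationError(f"could not construct a valid plan: {last_err}")


def _dominating_variants(
    parent: Profile,
    attrs: AttributeSet,
    orderings: Mapping[str, Sequence[int]],
) -> list[Profile]:
    """All profiles obtained by moving >=1 orderable attribute to its best level."""
    improvable = []
    for name, order in orderings.items():
        best = order[-1]
        if parent.level(attrs.get(name).name) != best:
            improvable.append((attrs.get(name).name, best))
    variants = []
    for r in range(1, len(improvable) + 1):
        for combo in itertools.combinations(improvable, r):
            levels = dict(parent.levels)
            for name, best in combo:
                levels[name] = best
            variants.append(Profile(levels))
    return variants


def add_validation_scenarios(
    plan: DesignPlan,
    n: int = 5,
    seed: int = 0,
    orderings: Mapping[str, Sequence[int]] | None = None,
) -> DesignPlan:
    """Append ``n`` consistency scenarios that rationally dominate a parent run.

    Each added scenario copies an estimation run with one or more attributes
    moved to the a-priori preferable level, per ``orderings`` (worst -> best
    level indices; defaults to the PND rational orderings for whichever of
    those attributes the plan contains).  Added runs are tagged
    ``"consistency"`` and are excluded from estimation.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if orderings is None:
        orderings = {
            k: v for k, v in PND_RATIONAL_ORDERINGS.items() if k in plan.attrs
        }
    if not orderings:
        raise ValidationError("no rational level orderings available for this space")
    for name, order in orderings.items():
        a = plan.attrs.get(name)
        if sorted(order) != list(range(1, a.n_levels + 1)):
            raise ValidationError(f"ordering for {name!r} is not a permutation of levels")

    est_profiles, est_ids = plan.estimation_runs()
    candidates: list[tuple[str, Profile]] = []
    for pid, parent in zip(est_ids, est_profiles):
        for v in _dominating_variants(parent, plan.attrs, orderings):
            candidates.append((pid, v))
    # distinct (parent, variant) pairs, deterministic order
    seen: set = set()
    distinct = []
    for pid, v in candidates:
        key = (pid, v.key(plan.attrs))
        if key not in seen:
            seen.add(key)
            distinct.append((pid, v))
    if n > len(distinct):
        raise ValidationError(
            f"requested {n} consistency scenarios but only {len(distinct)} "
            f"distinct dominating variants exist"
        )
    rng = np.random.default_rng(seed)
    pick = rng.permutation(len(distinct))[:n]
    new_runs = list(plan.runs)
    new_roles = list(plan.roles)
    new_ids = list(plan.run_ids)
    parents = dict(plan.parents)
    for j, i in enumerate(sorted(pick), start=1):
        pid, v = distinct[i]
        cid = f"C{j:02d}"
        new_runs.append(v)
        new_roles.append("consistency")
        new_ids.append(cid)
        parents[cid] = pid
    prov = plan.provenance + f"; {n} dominance consistency scenarios (seed {seed})"
    return DesignPlan(plan.attrs, new_runs, new_roles, new_ids, plan.seed, prov, parents)


def _orthogonal_reference_det(attrs: AttributeSet, p: int) -> float:
    """det^(1/p) of X'X/n for the effects-coded balanced full factorial.

    Orthogonality across attributes makes the moment matrix block-diagonal;
    each attribute block is (I + J) / L with determinant L**(2 - L).
    """
    log_det = 0.0
    for a in attrs:
        L = a.n_levels
        log_det += (2 - L) * np.log(L)
    return float(np.exp(log_det / p))


def design_diagnostics(plan: DesignPlan) -> DesignDiagnostics:
    """Level/pairwise frequencies, model-matrix rank and D-efficiency.

    D-efficiency is det(X'X/n)^(1/p) for the effects-coded estimation runs,
    normalized by the same quantity for the orthogonal (full factorial)
    reference, so balanced orthogonal plans score exactly 1.
    """
    profiles, ids = plan.estimation_runs()
    attrs = plan.attrs
    n = len(profiles)
    freqs: dict[str, list[int]] = {}
    for a in attrs:
        counts = np.bincount(
            np.array([p.level(a.name) for p in profiles]), minlength=a.n_levels + 1
        )[1:]
        freqs[a.name] = counts.tolist()
    pairwise: dict[tuple[str, str], np.ndarray] = {}
    for a, b in itertools.combinations(attrs, 2):
        tab = np.zeros((a.n_levels, b.n_levels), dtype=int)
        for p in profiles:
            tab[p.level(a.name) - 1, p.level(b.name) - 1] += 1
        pairwise[(a.name, b.name)] = tab
    cm = profiles_to_matrix(profiles, attrs, ids)
    M = cm.matrix.T @ cm.matrix / n
    sign, log_det = np.linalg.slogdet(M)
    d_run = float(np.exp(log_det / cm.n_parameters)) if sign > 0 else 0.0
    d_eff = d_run / _orthogonal_reference_det(attrs, cm.n_parameters)
    return DesignDiagnostics(
        level_frequencies=freqs,
        pairwise_frequency_tables=pairwise,
        coding_matrix_rank=cm.rank(),
        n_parameters=cm.n_parameters,
        d_efficiency=d_eff,
    )
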