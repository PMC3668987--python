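"""End-to-end pipeline: design -> (simulated) responses -> fit -> validate -> rank.

``run_pipeline`` chains the stages and writes every artifact plus a JSON
manifest capturing seeds, configuration and artifact hashes; re-running with
the same configuration reproduces the manifest byte for byte.  Partial
outputs are removed if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .attributes import builtin_pnd_attributes, load_attribute_set
from .design import add_validation_scenarios, design_diagnostics, generate_plan
from .errors import ValidationError
from .estimate import attribute_importance, consistency_check, fit_pooled, holdout_validation
from .prioritize import builtin_pnd_innovations, load_innovations, rank_innovations
from .questionnaire import render_questionnaire
from .responses import read_responses, write_responses
from .simulate import PopulationSpec, population_from_table6, simulate_ratings

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "attributes": "pnd",          # "pnd" or a YAML/JSON path
    "design": {"runs": "auto", "holdouts": 5, "seed": 0},
    "population": "table6",       # "table6" or a population JSON path
    "simulate": {"n_respondents": 139, "noise_sd": 0.5, "heterogeneity_sd": 0.1, "seed": 0},
    "responses": None,            # path to a responses CSV (skips simulation)
    "innovations": "pnd",         # "pnd", a CSV path, or None to stop after validation
    "scale_midpoint": 4.0,
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _load_population(cfg: dict, attrs) -> PopulationSpec:
    sim = cfg["simulate"]
    overrides = {
        "n_respondents": int(sim["n_respondents"]),
        "noise_sd": float(sim["noise_sd"]),
        "heterogeneity_sd": float(sim["heterogeneity_sd"]),
        "seed": int(sim["seed"]),
        "scale_midpoint": float(cfg["scale_midpoint"]),
    }
    if cfg["population"] == "table6":
        return population_from_table6(**overrides)
    doc = json.loads(Path(cfg["population"]).read_text())
    return PopulationSpec(
        attrs=attrs,
        mean_partworths={k: tuple(v) for k, v in doc["mean_partworths"].items()},
        constant=float(doc["constant"]),
        **overrides,
    )


def run_pipeline(config: Mapping[str, Any] | str | Path, out_dir: str | Path) -> Path:
    """Run the full prioritization pipeline; returns the artifact directory.

    ``config`` is a mapping (or a YAML/JSON file path) overriding
    :data:`DEFAULT_CONFIG`.  Artifacts: design.csv(+json), questionnaire.txt,
    responses.csv (when simulated), model.json, importance.csv, holdout.json,
    consistency.csv, ranking.csv (when innovations given), manifest.json.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    try:
        attrs = (
            builtin_pnd_attributes()
            if cfg["attributes"] == "pnd"
            else load_attribute_set(cfg["attributes"])
        )
        dz = cfg["design"]
        plan = generate_plan(attrs, dz["runs"], int(dz["seed"]))
        plan = add_validation_scenarios(plan, int(dz["holdouts"]), int(dz["seed"]))
        logger.info("design: %d estimation + %d consistency runs",
                    plan.n_estimation, len(plan.runs) - plan.n_estimation)
        emit("design.csv", plan.to_csv)
        written.append(out / "design.json")  # sidecar written by to_csv
        diag = design_diagnostics(plan)
        emit("design_diagnostics.json", lambda p: p.write_text(json.dumps({
            "coding_matrix_rank": diag.coding_matrix_rank,
            "n_parameters": diag.n_parameters,
            "d_efficiency": diag.d_efficiency,
            "level_frequencies": diag.level_frequencies,
        }, indent=2) + "\n"))
        q = render_questionnaire(plan, attrs, seed=int(dz["seed"]))
        emit("questionnaire.txt", q.write)

        if cfg.get("responses"):
            rs = read_responses(cfg["responses"], plan)
            logger.info("responses: %d ratings from %d respondents (file)",
                        len(rs), len(rs.respondents))
        else:
            spec = _load_population(cfg, attrs)
            rs = simulate_ratings(spec, plan)
            logger.info("responses: simulated %d ratings from %d respondents",
                        len(rs), spec.n_respondents)
            emit("responses.csv", lambda p: write_responses(rs, p))

        model = fit_pooled(rs, plan, attrs)
        emit("model.json", model.to_json)
        imp = attribute_importance(model)
        emit("importance.csv", imp.to_csv)
        rep = holdout_validation(model, rs, plan, scale_midpoint=0.0)
        emit("holdout.json", lambda p: p.write_text(json.dumps({
            "pearson_r": rep.pearson_r,
            "r_squared": rep.r_squared,
            "scenarios": rep.table.to_dict(orient="records"),
        }, indent=2) + "\n"))
        cons = consistency_check(plan, rs=rs)
        emit("consistency.csv", lambda p: cons.to_csv(p, index=False))
        logger.info("validation: holdout r=%.3f, %d/%d dominance pairs passed",
                    rep.pearson_r, int(cons["passed"].sum()), len(cons))

        if cfg.get("innovations"):
            innovations = (
                builtin_pnd_innovations()
                if cfg["innovations"] == "pnd"
                else load_innovations(cfg["innovations"], attrs)
            )
            ranking = rank_innovations(model, innovations)
            emit("ranking.csv", ranking.to_csv)
            logger.info("ranking: %d innovations, top = %s",
                        len(ranking.records), ranking.records["name"].iloc[0])
        else:
            logger.info("no innovations file configured; stopping after validation")

        manifest = {
            "package_version": __version__,
            "config": cfg,
            "artifacts": {
                p.name: _sha256(p) for p in sorted(written) if p.exists()
            },
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return out
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
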