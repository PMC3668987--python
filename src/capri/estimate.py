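"""Part-worth utility estimation by ordinary least squares.

Ratings of the estimation scenarios are regressed on the effects-coded
attribute levels (intercept + L-1 contrasts per attribute), treating the 1-7
Likert responses as interval data.  Effects coding makes every attribute's
part-worths sum to zero and recovers a part-worth for every level, reference
level included (minus the sum of its siblings), matching the convention of
classic conjoint value analysis tools.

Ratings enter the regression as given; the constant therefore absorbs the
scale location.  Fits on simulated continuous data generated with midpoint 0
recover the generating constant directly.  Standard errors default to the
homoskedastic pooled-OLS formula; a respondent-clustered robust variant is
available via ``cluster_robust=True``.

Attribute importance uses the standard conjoint convention: the range
(max - min part-worth) of each attribute, normalized over attributes, with
ties broken by attribute order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .attributes import AttributeSet, Profile, validate_profile
from .coding import CodingMatrix, build_coding_matrix, profiles_to_matrix
from .design import DesignPlan
from .errors import EstimationError, ValidationError
from .responses import ResponseSet

__all__ = [
    "UtilityModel",
    "ImportanceTable",
    "HoldoutReport",
    "build_coding_matrix",
    "fit_pooled",
    "fit_individual",
    "attribute_importance",
    "predict_rating",
    "holdout_validation",
    "consistency_check",
]

logger = logging.getLogger(__name__)


@dataclass
class FitInfo:
    n_obs: int
    df_resid: int
    r_squared: float


@dataclass
class UtilityModel:
    """Constant plus zero-centered part-worths per attribute level."""

    attrs: AttributeSet
    constant: float
    partworths: dict[str, tuple[float, ...]]
    std_errors: dict[str, tuple[float, ...]] | None = None
    constant_se: float | None = None
    fit: FitInfo | None = None

    def __post_init__(self) -> None:
        for a in self.attrs:
            vals = self.partworths.get(a.name)
            if vals is None or len(vals) != a.n_levels:
                raise ValidationError(f"part-worths missing/misshaped for {a.name!r}")
            if abs(sum(vals)) > 1e-9:
                raise ValidationError(
                    f"part-worths for {a.name!r} must sum to zero, got {sum(vals):g}"
                )

    def partworth(self, attr: str, level: int | str) -> float:
        a = self.attrs.get(attr)
        idx = level if isinstance(level, int) else a.level_index(level)
        return self.partworths[a.name][idx - 1]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "constant": self.constant,
            "constant_se": self.constant_se,
            "attributes": [
                {
                    "name": a.name,
                    "label": a.label,
                    "levels": [
                        {
                            "label": a.levels[i],
                            "utility": self.partworths[a.name][i],
                            "se": None
                            if self.std_errors is None
                            else self.std_errors[a.name][i],
                        }
                        for i in range(a.n_levels)
                    ],
                }
                for a in self.attrs
            ],
            "fit": None
            if self.fit is None
            else {
                "n_obs": self.fit.n_obs,
                "df_resid": self.fit.df_resid,
                "r_squared": self.fit.r_squared,
            },
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "UtilityModel":
        from .attributes import Attribute

        doc = json.loads(Path(path).read_text())
        attrs = AttributeSet(
            tuple(
                Attribute(
                    e["name"], e.get("label", e["name"]), tuple(l["label"] for l in e["levels"])
                )
                for e in doc["attributes"]
            )
        )
        pw = {
            e["name"]: tuple(l["utility"] for l in e["levels"]) for e in doc["attributes"]
        }
        ses = None
        if all(l["se"] is not None for e in doc["attributes"] for l in e["levels"]):
            ses = {
                e["name"]: tuple(l["se"] for l in e["levels"]) for e in doc["attributes"]
            }
        fit = None
        if doc.get("fit"):
            fit = FitInfo(doc["fit"]["n_obs"], doc["fit"]["df_resid"], doc["fit"]["r_squared"])
        return cls(attrs, doc["constant"], pw, ses, doc.get("constant_se"), fit)


@dataclass
class ImportanceTable:
    """Range-based attribute importance (range / sum of ranges), ranked."""

    rows: pd.DataFrame  # columns: attribute, range, importance, rank

    def to_csv(self, path: str | Path) -> None:
        self.rows.to_csv(path, index=False)


@dataclass
class HoldoutReport:
    """Predicted vs observed mean ratings on the holdout scenarios."""

    pearson_r: float
    r_squared: float
    table: pd.DataFrame  # run_id, predicted, observed


def _safe_rsquared(res) -> float:
    """R-squared, defined as 1.0 when the response has no variance at all."""
    tss = float(res.centered_tss)
    if tss <= 0:
        return 1.0 if float(res.ssr) <= 1e-300 else 0.0
    return float(1.0 - res.ssr / tss)


def _decode(cm: CodingMatrix, attrs: AttributeSet, beta: np.ndarray,
            cov: np.ndarray | None) -> tuple[float, dict, dict | None, float | None]:
    """Recover constant + per-level part-worths (and SEs) from contrast estimates."""
    constant = float(beta[0])
    constant_se = float(np.sqrt(cov[0, 0])) if cov is not None else None
    partworths: dict[str, tuple[float, ...]] = {}
    std_errors: dict[str, tuple[float, ...]] | None = {} if cov is not None else None
    for a in attrs:
        cols = [i for i, m in enumerate(cm.column_map) if m is not None and m[0] == a.name]
        b = beta[cols]
        vals = list(b) + [-float(b.sum())]
        partworths[a.name] = tuple(float(x) for x in vals)
        if cov is not None:
            ses = [float(np.sqrt(cov[i, i])) for i in cols]
            ones = np.ones(len(cols))
            ref_var = float(ones @ cov[np.ix_(cols, cols)] @ ones)
            ses.append(float(np.sqrt(max(ref_var, 0.0))))
            std_errors[a.name] = tuple(ses)  # type: ignore[index]
    return constant, partworths, std_errors, constant_se


def _stack_observations(
    rs: ResponseSet, plan: DesignPlan, attrs: AttributeSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray, CodingMatrix]:
    """Design rows, ratings and respondent group labels for estimation runs."""
    cm = build_coding_matrix(plan, attrs)
    row_of = {rid: i for i, rid in enumerate(cm.run_ids)}
    est_ids = set(cm.run_ids)
    unknown = set(rs.data["run_id"]) - set(plan.run_ids)
    if unknown:
        raise ValidationError(f"responses reference unknown run_id(s): {sorted(unknown)[:5]}")
    sub = rs.data[rs.data["run_id"].isin(est_ids)]
    if sub.empty:
        raise EstimationError("no ratings on estimation runs")
    rated = set(sub["run_id"])
    if rated != est_ids:
        raise EstimationError(
            f"estimation runs without any rating: {sorted(est_ids - rated)[:5]}"
        )
    X = cm.matrix[[row_of[r] for r in sub["run_id"]], :]
    y = sub["rating"].to_numpy(dtype=float)
    groups = sub["respondent_id"].to_numpy()
    return X, y, groups, cm


def fit_pooled(
    rs: ResponseSet,
    plan: DesignPlan,
    attrs: AttributeSet | None = None,
    cluster_robust: bool = False,
) -> UtilityModel:
    """Pooled OLS over all respondents' ratings of the estimation runs.

    ``cluster_robust=True`` swaps the homoskedastic standard errors for
    respondent-clustered robust ones (point estimates unchanged).
    """
    attrs = attrs if attrs is not None else plan.attrs
    X, y, groups, cm = _stack_observations(rs, plan, attrs)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise EstimationError("rank-deficient model matrix; cannot estimate all main effects")
    ols = sm.OLS(y, X)
    if cluster_robust:
        res = ols.fit(cov_type="cluster", cov_kwds={"groups": pd.Series(groups)})
    else:
        res = ols.fit()
    cov = np.asarray(res.cov_params())
    constant, pw, ses, c_se = _decode(cm, attrs, np.asarray(res.params), cov)
    fit = FitInfo(int(res.nobs), int(res.df_resid), _safe_rsquared(res))
    return UtilityModel(attrs, constant, pw, ses, c_se, fit)


def fit_individual(
    rs: ResponseSet,
    plan: DesignPlan,
    attrs: AttributeSet | None = None,
) -> tuple[list[tuple[str, UtilityModel]], UtilityModel]:
    """Per-respondent OLS fits plus their arithmetic-mean model.

    Respondents who did not rate every estimation run are excluded with a
    logged warning.  Saturated fits (zero residual df) carry no standard
    errors.  On complete balanced data the averaged model's point estimates
    coincide with the pooled fit.
    """
    attrs = attrs if attrs is not None else plan.attrs
    cm = build_coding_matrix(plan, attrs)
    est_ids = set(cm.run_ids)
    row_of = {rid: i for i, rid in enumerate(cm.run_ids)}
    models: list[tuple[str, UtilityModel]] = []
    for rid, grp in rs.data.groupby("respondent_id", sort=True):
        grp_est = grp[grp["run_id"].isin(est_ids)]
        if set(grp_est["run_id"]) != est_ids:
            logger.warning(
                "respondent %s rated %d/%d estimation runs; excluded from "
                "individual-level estimation", rid, grp_est["run_id"].nunique(), len(est_ids),
            )
            continue
        X = cm.matrix[[row_of[r] for r in grp_est["run_id"]], :]
        y = grp_est["rating"].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        saturated = res.df_resid <= 0
        cov = None if saturated else np.asarray(res.cov_params())
        constant, pw, ses, c_se = _decode(cm, attrs, np.asarray(res.params), cov)
        fit = FitInfo(int(res.nobs), int(res.df_resid), _safe_rsquared(res))
        models.append((str(rid), UtilityModel(attrs, constant, pw, ses, c_se, fit)))
    if not models:
        raise EstimationError("no respondent with complete estimation-run coverage")
    mean_constant = float(np.mean([m.constant for _, m in models]))
    mean_pw = {
        a.name: tuple(
            float(np.mean([m.partworths[a.name][i] for _, m in models]))
            for i in range(a.n_levels)
        )
        for a in attrs
    }
    averaged = UtilityModel(attrs, mean_constant, mean_pw)
    return models, averaged


def attribute_importance(m: UtilityModel) -> ImportanceTable:
    """Range-based relative importance; rank 1 = widest part-worth range."""
    rows = []
    for a in m.attrs:
        vals = m.partworths[a.name]
        rows.append({"attribute": a.name, "range": max(vals) - min(vals)})
    df = pd.DataFrame(rows)
    total = df["range"].sum()
    if total <= 0:
        df["importance"] = 1.0 / len(df)
    else:
        df["importance"] = df["range"] / total
    # stable ascending sort on the negated range keeps attribute order on ties
    order = (-df["range"]).sort_values(kind="stable").index
    ranks = pd.Series(range(1, len(df) + 1), index=order)
    df["rank"] = ranks
    return ImportanceTable(df)


def predict_rating(m: UtilityModel, p: Profile, scale_midpoint: float = 0.0) -> float:
    """Midpoint + constant + sum of part-worths at the profile's levels (unclamped)."""
    validate_profile(m.attrs, p)
    total = scale_midpoint + m.constant
    for a in m.attrs:
        total += m.partworths[a.name][p.level(a.name) - 1]
    return float(total)


def holdout_validation(
    m: UtilityModel,
    rs: ResponseSet,
    plan: DesignPlan,
    scale_midpoint: float = 0.0,
) -> HoldoutReport:
    """Correlate predicted with observed mean ratings on the holdout scenarios.

    r-squared is the squared Pearson correlation: the proportion of variation
    in observed holdout preferences explained by the model's predictions.
    """
    profiles, ids = plan.consistency_runs()
    observed_means = rs.mean_by_run()
    rows = []
    for p, rid in zip(profiles, ids):
        if rid not in observed_means.index:
            continue
        rows.append(
            {
                "run_id": rid,
                "predicted": predict_rating(m, p, scale_midpoint),
                "observed": float(observed_means[rid]),
            }
        )
    if len(rows) < 2:
        raise ValidationError("holdout validation needs >=2 rated holdout scenarios")
    table = pd.DataFrame(rows)
    pred, obs = table["predicted"].to_numpy(), table["observed"].to_numpy()
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise EstimationError("zero variance in predicted or observed holdout means")
    if np.allclose(pred - pred.mean(), obs - obs.mean(), atol=1e-12):
        r = 1.0  # exact agreement; pearsonr would still return 1 but noisily
    else:
        r = float(stats.pearsonr(pred, obs)[0])
    return HoldoutReport(pearson_r=r, r_squared=r * r, table=table)


def consistency_check(
    plan: DesignPlan,
    rs: ResponseSet | None = None,
    model: UtilityModel | None = None,
    scale_midpoint: float = 0.0,
) -> pd.DataFrame:
    """Flag whether each dominance pair scores the dominating scenario >= parent.

    Uses observed mean ratings when ``rs`` is given, otherwise model
    predictions.  Returns one row per consistency run: parent_id, run_id,
    parent value, dominating value, passed.
    """
    if (rs is None) == (model is None):
        raise ValidationError("provide exactly one of rs or model")
    profiles, ids = plan.consistency_runs()
    if not ids:
        raise ValidationError("plan has no consistency runs")
    missing = [i for i in ids if i not in plan.parents]
    if missing:
        raise ValidationError(f"consistency runs without parent metadata: {missing}")

    def value(run_id: str) -> float:
        if rs is not None:
            means = rs.mean_by_run()
            if run_id not in means.index:
                raise ValidationError(f"no observed ratings for run {run_id!r}")
            return float(means[run_id])
        return predict_rating(model, plan.run(run_id), scale_midpoint)  # type: ignore[arg-type]

    rows = []
    for rid in ids:
        pid = plan.parents[rid]
        pv, dv = value(pid), value(rid)
        rows.append(
            {
                "parent_id": pid,
                "run_id": rid,
                "parent_value": pv,
                "dominating_value": dv,
                "passed": bool(dv >= pv),
            }
        )
    return pd.DataFrame(rows)
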