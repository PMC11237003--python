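"""Trial-level regression models for the search DVs.

Success (yes/no) and anticipatory looks are analyzed with logistic models,
time-to-target with linear models, and scanning counts with Poisson models.
Models are fixed-effects GLMs with optional participant-clustered (sandwich)
standard errors standing in for the original random-effect structure; model
selection uses an AIC ladder against the intercept-only null, and the
condition x age interaction is probed with the Johnson-Neyman procedure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "Coefficient",
    "GLMResult",
    "ModelComparisonTable",
    "JNResult",
    "fit_glm",
    "compare_models_aic",
    "condition_contrast",
    "johnson_neyman",
    "DEFAULT_LADDER",
]

_FAMILIES = {
    "poisson": sm.families.Poisson,
    "binomial": sm.families.Binomial,
    "gaussian": sm.families.Gaussian,
}

#: The four model specifications compared for each toddler DV.
DEFAULT_LADDER: dict[str, str] = {
    "null": "1",
    "condition": "condition",
    "condition+age": "condition + age_months",
    "condition*age": "condition * age_months",
}


class Coefficient(NamedTuple):
    estimate: float
    se: float
    statistic: float
    pvalue: float


@dataclass
class GLMResult:
    """A fitted GLM: per-term estimates plus fit statistics.

    ``aic`` always satisfies ``2k - 2 * log_likelihood``.  The underlying
    statsmodels results object is retained for contrasts and covariances.
    """

    family: str
    coefficients: dict[str, Coefficient]
    log_likelihood: float
    aic: float
    n_obs: int
    cluster_variable: str | None = None
    null_aic: float | None = None
    sm_results: object = field(default=None, repr=False)

    @classmethod
    def from_statsmodels(
        cls,
        results,
        family: str,
        cluster_variable: str | None = None,
        null_aic: float | None = None,
    ) -> "GLMResult":
        stats_values = results.tvalues
        coefficients = {
            name: Coefficient(
                estimate=float(results.params[name]),
                se=float(results.bse[name]),
                statistic=float(stats_values[name]),
                pvalue=float(results.pvalues[name]),
            )
            for name in results.params.index
        }
        k = len(results.params)
        return cls(
            family=family,
            coefficients=coefficients,
            log_likelihood=float(results.llf),
            aic=float(2 * k - 2 * results.llf),
            n_obs=int(results.nobs),
            cluster_variable=cluster_variable,
            null_aic=null_aic,
            sm_results=results,
        )

    def summary(self) -> str:
        return str(self.sm_results.summary())

    def tidy(self) -> pd.DataFrame:
        """One row per term: estimate, SE, statistic, p."""
        return pd.DataFrame(
            [
                {"term": term, "estimate": c.estimate, "se": c.se,
                 "statistic": c.statistic, "p": c.pvalue}
                for term, c in self.coefficients.items()
            ]
        )


@dataclass(frozen=True)
class ModelComparisonTable:
    """AIC ladder: each row's delta is taken against the null model."""

    table: pd.DataFrame  # columns: model, aic, delta_aic
    best_model: str

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.1f}")


@dataclass(frozen=True)
class JNResult:
    """Johnson-Neyman probe of a condition x age interaction.

    ``boundary`` is reported only when the significant region is contiguous
    and one-sided on the grid; otherwise every region edge is listed in
    ``crossings``.  ``side`` is ``"above"`` when the effect is significant
    from the boundary age onward, ``"below"`` when only younger ages are
    significant.
    """

    age_grid: np.ndarray
    effects: np.ndarray
    ses: np.ndarray
    significant: np.ndarray
    alpha: float
    critical_value: float
    boundary: float | None
    side: str | None
    crossings: tuple[float, ...]


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials.copy()
    from dataclasses import asdict, is_dataclass

    if len(trials) and is_dataclass(trials[0]):
        return pd.DataFrame([asdict(t) for t in trials])
    return pd.DataFrame(trials)


def _check_dv(values: pd.Series, family: str, dv: str) -> None:
    v = values.to_numpy()
    if family == "poisson":
        if not np.allclose(v, np.round(v)) or (v < 0).any():
            raise ValueError(f"{dv}: Poisson family requires nonnegative counts")
        if (v == 0).all():
            raise ValueError(f"{dv}: all counts are zero; nothing to model")
    elif family == "binomial":
        if not set(np.unique(v)).issubset({0, 1, 0.0, 1.0}):
            raise ValueError(f"{dv}: binomial family requires 0/1 outcomes")
    elif family == "gaussian":
        if not np.isfinite(v).all():
            raise ValueError(f"{dv}: gaussian family requires finite values")
    else:
        raise ValueError(f"unknown family: {family!r}")


def fit_glm(
    trials,
    dv: str,
    family: str,
    formula_terms: str,
    cluster_by: str | None = None,
) -> GLMResult:
    """Fit ``dv ~ formula_terms`` with the named family via IRLS.

    ``cluster_by`` switches to cluster-robust (sandwich) standard errors
    grouped by that column, the stand-in for participant random effects.
    Rows with missing values in the DV or predictors are dropped.
    """
    frame = _as_frame(trials)
    used = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", formula_terms)) & set(frame.columns)
    frame = frame.dropna(subset=[dv, *used])
    if len(frame) < 10:
        raise ValueError(f"need at least 10 observations, got {len(frame)}")
    _check_dv(frame[dv], family, dv)

    model = smf.glm(
        f"{dv} ~ {formula_terms}", data=frame, family=_FAMILIES[family]()
    )
    fit_kwargs: dict = {}
    if cluster_by is not None:
        fit_kwargs = {
            "cov_type": "cluster",
            "cov_kwds": {"groups": frame[cluster_by]},
        }
    try:
        results = model.fit(**fit_kwargs)
    except Exception as exc:  # non-convergence, separation
        raise ValueError(f"GLM fit failed for {dv}: {exc}") from exc
    if not np.isfinite(results.params).all():
        raise ValueError(f"GLM for {dv} did not converge to finite estimates "
                         "(possible perfect separation)")
    return GLMResult.from_statsmodels(results, family=family, cluster_variable=cluster_by)


def compare_models_aic(
    trials,
    dv: str,
    family: str,
    ladder: Mapping[str, str] | None = None,
    cluster_by: str | None = None,
) -> ModelComparisonTable:
    """Fit every ladder member on the same observations and rank by AIC."""
    ladder = dict(ladder) if ladder is not None else dict(DEFAULT_LADDER)
    if "null" not in ladder:
        ladder = {"null": "1", **ladder}
    frame = _as_frame(trials)
    # One shared dropna pass so every model sees identical observations.
    used: set[str] = {dv}
    for terms in ladder.values():
        used |= set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", terms)) & set(frame.columns)
    frame = frame.dropna(subset=sorted(used))

    rows = []
    for name, terms in ladder.items():
        result = fit_glm(frame, dv, family, terms, cluster_by=cluster_by)
        rows.append({"model": name, "aic": result.aic})
    table = pd.DataFrame(rows)
    null_aic = float(table.loc[table["model"] == "null", "aic"].iloc[0])
    table["delta_aic"] = table["aic"] - null_aic
    best = str(table.loc[table["aic"].idxmin(), "model"])
    return ModelComparisonTable(table=table, best_model=best)


def _term_names(result: GLMResult) -> pd.Index:
    return result.sm_results.params.index


def condition_contrast(
    result: GLMResult, at_group: str
) -> tuple[float, float, float, float]:
    """Wald test of the condition effect within one group.

    The model must contain a two-level ``condition`` term and a ``group``
    term (with interaction for non-reference groups).  Returns
    ``(estimate, SE, statistic, p)``, two-tailed.
    """
    names = _term_names(result)
    cond_main = [n for n in names if n.startswith("condition[") and ":" not in n]
    if len(cond_main) != 1:
        raise ValueError("model must contain a single condition main-effect term")
    if not any("group[" in n for n in names):
        raise ValueError("model must contain a group term")
    vec = pd.Series(0.0, index=names)
    vec[cond_main[0]] = 1.0
    inter = [
        n for n in names
        if ":" in n and "condition[" in n and f"group[T.{at_group}]" in n
    ]
    if inter:
        vec[inter[0]] = 1.0
    test = result.sm_results.t_test(vec.to_numpy())
    return (
        float(np.squeeze(test.effect)),
        float(np.squeeze(test.sd)),
        float(np.squeeze(test.statistic)),
        float(np.squeeze(test.pvalue)),
    )


def johnson_neyman(
    result: GLMResult,
    age_grid: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> JNResult:
    """Simple condition effect across the age moderator, with its region
    of significance.

    At each grid age the conditional effect is ``b_cond + age * b_inter``
    with a delta-method standard error from the fitted covariance (robust if
    the model used clustered errors); the boundary is the edge of the
    contiguous significant region.
    """
    names = _term_names(result)
    cond_main = [n for n in names if n.startswith("condition[") and ":" not in n]
    inter = [n for n in names if ":" in n and "condition[" in n and "age" in n]
    if len(cond_main) != 1 or len(inter) != 1:
        raise ValueError("model must contain condition, age and their interaction")
    b = result.sm_results.params
    V = result.sm_results.cov_params()
    if age_grid is None:
        age_grid = np.linspace(18.0, 36.0, 181)
    ages = np.asarray(age_grid, dtype=float)

    bc, bi = float(b[cond_main[0]]), float(b[inter[0]])
    vcc = float(V.loc[cond_main[0], cond_main[0]])
    vii = float(V.loc[inter[0], inter[0]])
    vci = float(V.loc[cond_main[0], inter[0]])
    effects = bc + ages * bi
    ses = np.sqrt(vcc + ages**2 * vii + 2 * ages * vci)
    if getattr(result.sm_results, "use_t", False):
        crit = float(sps.t.ppf(1 - alpha / 2, result.sm_results.df_resid))
    else:
        crit = float(sps.norm.ppf(1 - alpha / 2))
    significant = np.abs(effects / ses) > crit

    boundary: float | None = None
    side: str | None = None
    crossings: list[float] = []
    runs = _contiguous_runs(significant)
    if len(runs) == 1:
        start, stop = runs[0]
        if start == 0 and stop == len(ages):
            boundary, side = float(ages[0]), "above"
        elif stop == len(ages):
            boundary, side = float(ages[start]), "above"
        elif start == 0:
            boundary, side = float(ages[stop - 1]), "below"
        else:
            crossings = [float(ages[start]), float(ages[stop - 1])]
    elif len(runs) > 1:
        for start, stop in runs:
            crossings.extend([float(ages[start]), float(ages[stop - 1])])
    return JNResult(
        age_grid=ages,
        effects=effects,
        ses=ses,
        significant=significant,
        alpha=alpha,
        critical_value=crit,
        boundary=boundary,
        side=side,
        crossings=tuple(crossings),
    )


def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges where ``mask`` is True."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs
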