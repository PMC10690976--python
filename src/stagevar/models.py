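"""Stage-specific logistic regressions with region dummies.

Each patient-journey stage (treatment, initial visit, treatment given a
visit) is modelled by a logit regression at one of three adjustment levels:

* level 1 — *crude*: region dummies only;
* level 2 — *needs-adjusted*: adds age category, obesity, childbirth;
* level 3 — *needs- and preference-adjusted*: adds sex, SES, income and
  urbanization.

The conditional stage additionally carries a binary visit indicator
distinguishing observed from assumed (censored) initial visits; within the
conditional sample everyone has a visit, so the indicator is the only
visit-related regressor that is not constant.

All covariates are categorical, so fitting collapses the table onto
covariate cells and maximizes the grouped binomial likelihood — identical
estimates to the row-level Bernoulli fit, at a fraction of the cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import claims
from ._newton import NewtonResult, fit_grouped_logit

__all__ = [
    "StageModelSpec",
    "FittedStageModel",
    "StageLogit",
    "build_design",
    "fit_logit",
    "marginal_effects",
    "covariates_for_level",
]


class StateError(RuntimeError):
    """The input table violates a stage-sample precondition."""


def covariates_for_level(model_level: int) -> tuple[str, ...]:
    """Covariates entering the linear predictor at a given adjustment level."""
    if model_level == 1:
        return ()
    if model_level == 2:
        return claims.NEEDS_COVARIATES
    if model_level == 3:
        return claims.NEEDS_COVARIATES + claims.PREFERENCE_COVARIATES
    raise ValueError(f"model_level must be 1, 2 or 3, got {model_level!r}")


@dataclass(frozen=True)
class StageModelSpec:
    """Which outcome to model and at what adjustment level."""

    stage: str
    model_level: int
    reference_region: str | None = None
    include_visit_indicator: bool = True

    def __post_init__(self):
        object.__setattr__(self, "stage", claims.normalize_stage(self.stage))
        covariates_for_level(self.model_level)  # validates

    @property
    def has_visit_indicator(self) -> bool:
        return self.stage == "T_given_I" and self.include_visit_indicator

    @property
    def outcome_column(self) -> str:
        return "initial_visit" if self.stage == "I" else "treated"


@dataclass
class _Column:
    name: str
    kind: str  # "intercept" | "region" | "covariate" | "visit"
    covariate: str | None = None
    level: object | None = None


@dataclass
class FittedStageModel:
    """Coefficient container for one fitted stage regression."""

    spec: StageModelSpec
    beta0: float
    beta_region: dict  # region -> coefficient; reference fixed at 0
    theta: dict = field(default_factory=dict)  # needs effects by design column
    gamma: dict = field(default_factory=dict)  # preference effects by design column
    pi: float | None = None  # visit-indicator effect
    n_obs: int = 0
    converged: bool = False
    loglik: float = float("nan")
    aic: float = float("nan")


def _check_stage_sample(table: pd.DataFrame, spec: StageModelSpec) -> None:
    if spec.stage == "I":
        if claims.n_censored(table) > 0:
            raise StateError(
                "stage-I sample contains treated records with censored visits; "
                "apply select_sample(table, 'I') first"
            )
    elif spec.stage == "T_given_I":
        if (table["initial_visit"] == 0).any():
            raise StateError(
                "conditional-stage sample contains records without an initial "
                "visit; apply select_sample(table, 'T_given_I') first"
            )


def _region_levels(table: pd.DataFrame) -> list[str]:
    col = table["region"]
    if isinstance(col.dtype, pd.CategoricalDtype):
        declared = [str(c) for c in col.cat.categories]
        present = set(col.astype(str).unique())
        unused = [r for r in declared if r not in present]
        if unused:
            warnings.warn(
                f"region dummies dropped for empty region(s): {unused}",
                stacklevel=3,
            )
        return sorted(present)
    return sorted(col.astype(str).unique())


class _SpecDesign:
    """Cell structure of one stage sample for one model specification.

    Collapses rows onto cells of (region x model covariates [x visit
    indicator]) and holds the per-cell design matrix.  ``counts(rows)``
    recomputes per-cell (events, trials) for any multiset of row indices,
    which is all a bootstrap replicate needs.
    """

    def __init__(self, table: pd.DataFrame, spec: StageModelSpec):
        _check_stage_sample(table, spec)
        self.spec = spec
        self.n_rows = len(table)
        self.regions = _region_levels(table)
        if len(self.regions) < 1:
            raise ValueError("table has no regions")
        self.reference_region = (
            str(spec.reference_region) if spec.reference_region is not None else self.regions[0]
        )
        if self.reference_region not in self.regions:
            raise ValueError(
                f"reference region {self.reference_region!r} not present in table"
            )

        covs = covariates_for_level(spec.model_level)
        dropped: list[str] = []
        use_visit = False
        if spec.has_visit_indicator:
            if table["visit_observed"].nunique() > 1:
                use_visit = True
            else:
                dropped.append("visit_observed")
                warnings.warn(
                    "visit indicator is constant in the conditional sample "
                    "(no censored visits); term dropped",
                    stacklevel=3,
                )
        self.dropped_columns = dropped

        # integer codes per dimension of the cell grid
        region_code = pd.Categorical(
            table["region"].astype(str), categories=self.regions
        ).codes.astype(np.int64)
        dims = [len(self.regions)]
        code_arrays = [region_code]
        self._grid_covs: list[str] = []
        for cov in covs:
            levels = claims.CATEGORICAL_LEVELS[cov]
            vals = table[cov]
            if isinstance(vals.dtype, pd.CategoricalDtype):
                codes = pd.Categorical(vals, categories=levels).codes.astype(np.int64)
            else:
                codes = pd.Categorical(
                    vals.astype(type(levels[0])), categories=levels
                ).codes.astype(np.int64)
            if (codes < 0).any():
                raise claims.ValidationError(f"column {cov!r} has out-of-set values")
            code_arrays.append(codes)
            dims.append(len(levels))
            self._grid_covs.append(cov)
        if use_visit:
            code_arrays.append(table["visit_observed"].to_numpy(dtype=np.int64))
            dims.append(2)
            self._grid_covs.append("visit_observed")

        raveled = np.ravel_multi_index(code_arrays, dims)
        uniq, inverse = np.unique(raveled, return_inverse=True)
        self.cell_of_row = inverse.astype(np.int64)
        self.n_cells = len(uniq)
        cell_codes = np.vstack(np.unravel_index(uniq, dims))  # (dims, cells)
        self.cell_codes = cell_codes
        self.cell_region = cell_codes[0]

        # design columns: intercept, region dummies (reference omitted),
        # covariate dummies (first level is the reference), visit indicator
        self.columns: list[_Column] = [_Column("Intercept", "intercept")]
        X = [np.ones(self.n_cells)]
        for j, r in enumerate(self.regions):
            if r == self.reference_region:
                continue
            self.columns.append(_Column(f"region[{r}]", "region", "region", r))
            X.append((cell_codes[0] == j).astype(float))
        for d, cov in enumerate(self._grid_covs, start=1):
            if cov == "visit_observed":
                self.columns.append(_Column("visit_observed", "visit", "visit_observed", 1))
                X.append(cell_codes[d].astype(float))
                continue
            for lev_idx, lev in enumerate(claims.CATEGORICAL_LEVELS[cov]):
                if lev_idx == 0:
                    continue  # reference level
                self.columns.append(_Column(f"{cov}[{lev}]", "covariate", cov, lev))
                X.append((cell_codes[d] == lev_idx).astype(float))
        self.X_cells = np.column_stack(X)
        self.column_names = [c.name for c in self.columns]

        y = table[spec.outcome_column].to_numpy(dtype=np.float64)
        self._y = y

    def counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell (events, trials) for a multiset of row indices."""
        if rows is None:
            cells, y = self.cell_of_row, self._y
        else:
            cells, y = self.cell_of_row[rows], self._y[rows]
        trials = np.bincount(cells, minlength=self.n_cells).astype(np.float64)
        events = np.bincount(cells, weights=y, minlength=self.n_cells)
        return events, trials

    def region_prediction_rows(self, reference_covariates: Mapping | None = None) -> np.ndarray:
        """One design row per region with covariates fixed at reference values."""
        ref = dict(reference_covariates or {})
        rows = np.zeros((len(self.regions), len(self.columns)))
        for k, col in enumerate(self.columns):
            if col.kind == "intercept":
                rows[:, k] = 1.0
            elif col.kind == "region":
                rows[self.regions.index(col.level), k] = 1.0
            elif col.kind == "visit":
                rows[:, k] = float(ref.get("visit_observed", 1))
            else:
                chosen = ref.get(col.covariate, claims.CATEGORICAL_LEVELS[col.covariate][0])
                if str(chosen) == str(col.level):
                    rows[:, k] = 1.0
        return rows


def build_design(
    table: pd.DataFrame, spec: StageModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Row-level design matrix, outcome vector and column names for a spec.

    The table must already be the analysis sample for ``spec.stage``
    (see :func:`stagevar.claims.select_sample`); a violation raises
    :class:`StateError`.
    """
    d = _SpecDesign(table, spec)
    X = d.X_cells[d.cell_of_row]
    return X, d._y.copy(), d.column_names


def _result_to_fitted(
    spec: StageModelSpec, d: _SpecDesign, res: NewtonResult, n_obs: int
) -> FittedStageModel:
    params = res.params
    beta_region = {d.reference_region: 0.0}
    theta: dict = {}
    gamma: dict = {}
    pi = None
    for k, col in enumerate(d.columns):
        if col.kind == "region":
            beta_region[col.level] = float(params[k])
        elif col.kind == "visit":
            pi = float(params[k])
        elif col.kind == "covariate":
            dest = theta if col.covariate in claims.NEEDS_COVARIATES else gamma
            dest[col.name] = float(params[k])
    return FittedStageModel(
        spec=spec,
        beta0=float(params[0]),
        beta_region=beta_region,
        theta=theta,
        gamma=gamma,
        pi=pi,
        n_obs=n_obs,
        converged=bool(res.converged),
        loglik=res.loglik,
        aic=2.0 * len(params) - 2.0 * res.loglik,
    )


class StageLogit(BaseEstimator):
    """Logistic regression for one patient-journey stage and adjustment level.

    Parameters
    ----------
    stage : {"T", "I", "T_given_I"}
        Outcome: treatment in the full population, initial visit, or
        treatment among those with an initial visit.
    model_level : {1, 2, 3}
        1 = region dummies only; 2 = + needs covariates; 3 = + preferences.
    reference_region : str, optional
        Region absorbed into the intercept; defaults to the first region in
        sorted order.
    include_visit_indicator : bool
        For the conditional stage, include the observed-vs-assumed visit
        indicator (dropped automatically when constant).
    tol, max_iter : Newton convergence controls (gradient max-norm scaled by
        sample size; iteration cap).

    Attributes (after ``fit``)
    --------------------------
    beta0_, beta_region_, theta_, gamma_, pi_ : estimated coefficients.
    regions_ : region levels in the fitted sample.
    n_obs_, converged_, separated_, loglik_, aic_ : fit diagnostics.
    cov_params_ : covariance of the coefficient vector (inverse observed
        information), ordered as ``columns_``.
    """

    def __init__(
        self,
        stage: str = "T",
        model_level: int = 3,
        reference_region: str | None = None,
        include_visit_indicator: bool = True,
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.stage = stage
        self.model_level = model_level
        self.reference_region = reference_region
        self.include_visit_indicator = include_visit_indicator
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self) -> StageModelSpec:
        return StageModelSpec(
            stage=self.stage,
            model_level=self.model_level,
            reference_region=self.reference_region,
            include_visit_indicator=self.include_visit_indicator,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "StageLogit":
        """Fit on a stage analysis sample (a validated policy-holder table)."""
        spec = self._spec()
        d = _SpecDesign(X, spec)
        events, trials = d.counts()
        # quasi-separation: a dummy whose support carries zero events (or
        # only events) has an MLE at infinity; retained and flagged, since
        # dropping e.g. a zero-event region would change the region set
        sup_trials = d.X_cells[:, 1:].T @ trials
        sup_events = d.X_cells[:, 1:].T @ events
        sep_mask = (sup_trials > 0) & ((sup_events == 0) | (sup_events == sup_trials))
        self.separated_columns_ = [
            name for name, bad in zip(d.column_names[1:], sep_mask) if bad
        ]
        if self.separated_columns_:
            warnings.warn(
                "quasi-separation: no outcome variation on the support of "
                f"{self.separated_columns_}; coefficient(s) diverge and are "
                "flagged, estimates returned",
                stacklevel=2,
            )
        res = fit_grouped_logit(
            d.X_cells, events, trials, tol=self.tol, max_iter=self.max_iter
        )
        if not (res.converged or res.separated or self.separated_columns_):
            warnings.warn(
                f"logit for stage={spec.stage} model={spec.model_level} did not "
                f"converge in {self.max_iter} iterations; estimates returned",
                stacklevel=2,
            )
        self.design_ = d
        self.result_ = res
        self.columns_ = list(d.column_names)
        self.params_ = res.params.copy()
        self.cov_params_ = res.cov_params.copy()
        self.regions_ = list(d.regions)
        self.reference_region_ = d.reference_region
        self.n_obs_ = len(X)
        self.converged_ = bool(res.converged)
        self.separated_ = bool(res.separated or self.separated_columns_)
        self.loglik_ = float(res.loglik)
        self.aic_ = 2.0 * len(res.params) - 2.0 * float(res.loglik)
        f = _result_to_fitted(spec, d, res, len(X))
        self.beta0_ = f.beta0
        self.beta_region_ = f.beta_region
        self.theta_ = f.theta
        self.gamma_ = f.gamma
        self.pi_ = f.pi
        self.fitted_ = f
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("StageLogit instance is not fitted yet")

    def _design_rows(self, records: pd.DataFrame) -> np.ndarray:
        """Design rows for arbitrary records, using the fitted column layout."""
        self._check_fitted()
        d: _SpecDesign = self.design_
        n = len(records)
        X = np.zeros((n, len(d.columns)))
        region = records["region"].astype(str)
        unknown = sorted(set(region) - set(d.regions))
        if unknown:
            raise ValueError(f"unknown region(s) not in fitted model: {unknown}")
        for k, col in enumerate(d.columns):
            if col.kind == "intercept":
                X[:, k] = 1.0
            elif col.kind == "region":
                X[:, k] = (region == col.level).to_numpy(dtype=float)
            elif col.kind == "visit":
                if "visit_observed" not in records.columns:
                    raise ValueError(
                        "model uses the visit indicator but records lack "
                        "'visit_observed'"
                    )
                X[:, k] = records["visit_observed"].to_numpy(dtype=float)
            else:
                if col.covariate not in records.columns:
                    raise ValueError(f"records lack model covariate {col.covariate!r}")
                vals = records[col.covariate].astype(str)
                X[:, k] = (vals == str(col.level)).to_numpy(dtype=float)
        return X

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted event probability for each record."""
        rows = self._design_rows(X)
        return expit(rows @ self.params_)

    def marginal_effects(self, X: pd.DataFrame | None = None) -> pd.DataFrame:
        """Average marginal effects of the needs/preference covariates.

        For each non-reference level of each covariate in the model, the AME
        is the sample mean of the discrete change in predicted probability
        when the covariate is switched from its reference level to that
        level, holding everything else at observed values.  Standard errors
        are delta-method.  Region dummies and the visit indicator are not
        tabulated.  Returns an empty frame for the crude (level-1) model.
        """
        self._check_fitted()
        if X is None:
            d: _SpecDesign = self.design_
            Xc = d.X_cells
            _, weights = d.counts()
            cols = d.columns
        else:
            d = self.design_
            Xc = self._design_rows(X)
            weights = np.ones(len(Xc))
            cols = d.columns
        total = weights.sum()
        params, cov = self.params_, self.cov_params_

        by_cov: dict[str, list[int]] = {}
        for k, c in enumerate(cols):
            if c.kind == "covariate":
                by_cov.setdefault(c.covariate, []).append(k)

        rows = []
        for cov_name, idxs in by_cov.items():
            X0 = Xc.copy()
            X0[:, idxs] = 0.0  # reference level: all dummies of this covariate off
            p0 = expit(X0 @ params)
            g0 = (weights * p0 * (1 - p0)) @ X0 / total
            for k in idxs:
                X1 = X0.copy()
                X1[:, k] = 1.0
                p1 = expit(X1 @ params)
                ame = float(weights @ (p1 - p0) / total)
                g1 = (weights * p1 * (1 - p1)) @ X1 / total
                grad = g1 - g0
                var = float(grad @ cov @ grad)
                # a quasi-separated coefficient yields an indefinite
                # information matrix; its delta-method SE is meaningless
                se = float(np.sqrt(var)) if var >= 0 else float("nan")
                rows.append(
                    {
                        "covariate": cov_name,
                        "level": cols[k].level,
                        "term": cols[k].name,
                        "ame": ame,
                        "se": se,
                    }
                )
        return pd.DataFrame(rows, columns=["covariate", "level", "term", "ame", "se"])


def fit_logit(
    design: np.ndarray,
    outcome: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NewtonResult:
    """Maximum-likelihood logit fit on a row-level design matrix.

    Thin functional wrapper over the Newton engine for callers that built a
    design by hand; :class:`StageLogit` is the structured interface.
    """
    outcome = np.asarray(outcome, dtype=np.float64)
    return fit_grouped_logit(
        np.asarray(design, dtype=np.float64),
        events=outcome,
        trials=np.ones_like(outcome),
        tol=tol,
        max_iter=max_iter,
    )


def marginal_effects(model: StageLogit, X: pd.DataFrame | None = None) -> pd.DataFrame:
    """Functional alias for :meth:`StageLogit.marginal_effects`."""
    return model.marginal_effects(X)
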