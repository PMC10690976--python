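"""Synthetic gatekept two-stage claims populations with known regional effects.

The generator emulates the structure of an insurer claims extract in a
gatekept system: an individual first obtains (or not) an initial specialist
visit — the referral stage — and, only conditional on a visit, is treated
(or not).  Both stages are Bernoulli on the logit scale with per-region
intercepts and needs/preference covariate effects, which matches the
analysis models so that parameter recovery is well-posed.  A configurable
fraction of treated individuals has the visit record censored (the claim
fell outside the observation window), mirroring real treated patients with
no in-window visit claim.

Because the regional intercepts are known, the *true* standardized regional
probabilities — and hence the true per-stage CVUs — are available in closed
form (:func:`true_stage_cvus`), which is what makes every downstream stage
of the pipeline testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from . import claims
from .models import StateError

__all__ = [
    "DgpParams",
    "TrueCvus",
    "table2_margins",
    "generate_population",
    "simulate_journey",
    "simulate_claims",
    "true_stage_cvus",
    "regional_alphas_from_probs",
    "referral_dominated_params",
    "equal_stage_dispersion_params",
]

_PROB_TOL = 1e-12

#: Share of treated individuals whose initial-visit claim is out-of-window,
#: as observed in the motivating claims extract (5,345 of 20,453 treated).
DEFAULT_CENSOR_RATE = 5345.0 / 20453.0


def table2_margins() -> dict:
    """Default marginal covariate distribution.

    Age, sex, childbirth and urbanization follow the descriptive margins of
    the motivating claims population (49.0/27.5/11.1/12.4% across age bands,
    half female, 2% recent childbirth, uniform urbanization quartiles).
    The obesity flag there rounds to 0.00 at two decimals; 0.002 keeps it
    small but estimable.  SES and income margins are not reported and
    default to uniform thirds.
    """
    return {
        "age_cat": {"0-40": 0.490, "41-60": 0.275, "61-70": 0.111, "70+": 0.124},
        "obesity": 0.002,
        "childbirth": 0.02,
        "sex_female": 0.50,
        "ses_cat": {"high": 1 / 3, "low": 1 / 3, "middle": 1 / 3},
        "income_cat": {"high": 1 / 3, "low": 1 / 3, "middle": 1 / 3},
        "urban_cat": {"1": 0.25, "2": 0.25, "3": 0.25, "4": 0.25},
    }


def _norm_dist(cov: str, dist) -> dict:
    """Normalize a covariate distribution to {level: prob} over all levels."""
    levels = claims.CATEGORICAL_LEVELS[cov]
    if isinstance(dist, Mapping):
        out = {lev: float(dist.get(lev, dist.get(str(lev), 0.0))) for lev in levels}
    else:  # scalar = probability of the "1" level of a binary covariate
        p = float(dist)
        if set(levels) != {0, 1}:
            raise ValueError(f"scalar distribution only valid for binary covariate, got {cov!r}")
        out = {0: 1.0 - p, 1: p}
    total = sum(out.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ValueError(f"covariate_dist[{cov!r}] sums to {total!r}, not 1")
    if any(p < 0 for p in out.values()):
        raise ValueError(f"covariate_dist[{cov!r}] has negative probabilities")
    return out


@dataclass
class DgpParams:
    """Parameters of the two-stage gatekept data-generating process.

    ``alpha_visit`` / ``alpha_treat`` are per-region intercepts on the logit
    scale for the initial-visit and treatment-given-visit stages.  Effect
    dicts map a covariate either to a scalar (binary covariates) or to a
    ``{level: coefficient}`` dict (multi-level covariates; the reference
    level is implicitly 0).
    """

    n_individuals: int
    regions: Sequence[str]
    alpha_visit: Mapping[str, float]
    alpha_treat: Mapping[str, float]
    region_weights: Sequence[float] | None = None
    theta_visit: Mapping = field(default_factory=dict)  # needs effects, visit stage
    gamma_visit: Mapping = field(default_factory=dict)  # preference effects, visit stage
    theta_treat: Mapping = field(default_factory=dict)
    gamma_treat: Mapping = field(default_factory=dict)
    covariate_dist: Mapping = field(default_factory=table2_margins)
    p_censor_visit: float = DEFAULT_CENSOR_RATE
    seed: int = 0

    def __post_init__(self):
        if int(self.n_individuals) <= 0:
            raise ValueError("n_individuals must be positive")
        self.n_individuals = int(self.n_individuals)
        self.regions = [str(r) for r in self.regions]
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate region codes")
        for name, alpha in (("alpha_visit", self.alpha_visit), ("alpha_treat", self.alpha_treat)):
            missing = [r for r in self.regions if r not in alpha]
            if missing:
                raise ValueError(f"{name} lacks region(s): {missing}")
        if self.region_weights is not None:
            w = np.asarray(self.region_weights, dtype=float)
            if len(w) != len(self.regions) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("region_weights must be non-negative, one per region")
        if not 0.0 <= self.p_censor_visit <= 1.0:
            raise ValueError("p_censor_visit must be in [0, 1]")
        self._dist = {cov: _norm_dist(cov, d) for cov, d in dict(self.covariate_dist).items()}
        for cov in claims.COVARIATES:
            if cov not in self._dist:
                self._dist[cov] = _norm_dist(cov, table2_margins()[cov])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_individuals": self.n_individuals,
            "regions": list(self.regions),
            "region_weights": None if self.region_weights is None else list(map(float, self.region_weights)),
            "alpha_visit": {k: float(v) for k, v in self.alpha_visit.items()},
            "alpha_treat": {k: float(v) for k, v in self.alpha_treat.items()},
            "theta_visit": _plain(self.theta_visit),
            "gamma_visit": _plain(self.gamma_visit),
            "theta_treat": _plain(self.theta_treat),
            "gamma_treat": _plain(self.gamma_treat),
            "covariate_dist": _plain(dict(self.covariate_dist)),
            "p_censor_visit": float(self.p_censor_visit),
            "seed": int(self.seed),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DgpParams":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _plain(obj):
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _rng_for(params: DgpParams, stream: int) -> np.random.Generator:
    # streams: 0 = population, 1 = journey outcomes, 2 = censoring
    return np.random.default_rng(np.random.SeedSequence(params.seed).spawn(3)[stream])


def generate_population(params: DgpParams) -> pd.DataFrame:
    """Draw regions and covariates for ``n_individuals`` (outcomes unset).

    Covariates are drawn independently of region from the marginal
    ``covariate_dist``; reproducible given ``params.seed``.
    """
    rng = _rng_for(params, 0)
    n = params.n_individuals
    if params.region_weights is None:
        w = np.full(len(params.regions), 1.0 / len(params.regions))
    else:
        w = np.asarray(params.region_weights, dtype=float)
        w = w / w.sum()
    region_idx = rng.choice(len(params.regions), size=n, p=w)
    data = {
        "person_id": [f"p{i:08d}" for i in range(n)],
        "region": np.asarray(params.regions, dtype=object)[region_idx],
    }
    for cov in claims.COVARIATES:
        dist = params._dist[cov]
        levels = list(dist)
        probs = np.asarray(list(dist.values()), dtype=float)
        idx = rng.choice(len(levels), size=n, p=probs)
        data[cov] = np.asarray(levels, dtype=object)[idx]
    df = pd.DataFrame(data)
    return claims.validate_claims(df, has_outcomes=False)


def _effect_vector(df: pd.DataFrame, effects: Mapping) -> np.ndarray:
    out = np.zeros(len(df))
    for cov, eff in effects.items():
        if cov not in claims.COVARIATES:
            raise ValueError(f"unknown covariate in effects: {cov!r}")
        col = df[cov]
        if isinstance(eff, Mapping):
            coef = col.astype(str).map({str(k): float(v) for k, v in eff.items()})
            out += coef.fillna(0.0).to_numpy(dtype=float)
        else:
            out += float(eff) * col.to_numpy(dtype=float)
    return out


def simulate_journey(population: pd.DataFrame, params: DgpParams) -> pd.DataFrame:
    """Simulate the gatekept two-stage pathway on a generated population.

    ``initial_visit`` is Bernoulli on the visit-stage linear predictor;
    ``treated`` is Bernoulli on the treatment-stage predictor *only among
    those with a visit* (gatekeeping: no treatment without an initial
    visit).  Treated individuals lose their visit record with probability
    ``p_censor_visit``; untreated visit records are never censored.
    """
    for cov in ("region",) + claims.COVARIATES:
        if cov not in population.columns:
            raise StateError(f"population lacks covariate column {cov!r}")
        if population[cov].isna().any():
            raise StateError(f"population has unset values in {cov!r}")
    rng = _rng_for(params, 1)
    rng_censor = _rng_for(params, 2)
    df = population.copy().reset_index(drop=True)
    n = len(df)

    alpha_v = df["region"].astype(str).map({k: float(v) for k, v in params.alpha_visit.items()})
    alpha_t = df["region"].astype(str).map({k: float(v) for k, v in params.alpha_treat.items()})
    if alpha_v.isna().any() or alpha_t.isna().any():
        raise StateError("population contains regions without DGP intercepts")

    w_visit = alpha_v.to_numpy(dtype=float) + _effect_vector(df, dict(params.theta_visit)) \
        + _effect_vector(df, dict(params.gamma_visit))
    w_treat = alpha_t.to_numpy(dtype=float) + _effect_vector(df, dict(params.theta_treat)) \
        + _effect_vector(df, dict(params.gamma_treat))

    visit = (rng.random(n) < expit(w_visit)).astype(np.int8)
    treat_draw = (rng.random(n) < expit(w_treat)).astype(np.int8)
    treated = np.where(visit == 1, treat_draw, 0).astype(np.int8)

    visit_observed = visit.copy()
    censored = (treated == 1) & (rng_censor.random(n) < params.p_censor_visit)
    visit_observed[censored] = 0

    df["initial_visit"] = visit
    df["treated"] = treated
    df["visit_observed"] = visit_observed
    return claims.validate_claims(df)


def simulate_claims(params: DgpParams) -> pd.DataFrame:
    """Generate a population and simulate its journey in one call."""
    return simulate_journey(generate_population(params), params)


class TrueCvus(tuple):
    """Triple of true per-stage CVUs: (treatment, visit, treatment-given-visit)."""

    def __new__(cls, cvu_T, cvu_I, cvu_TI):
        return super().__new__(cls, (float(cvu_T), float(cvu_I), float(cvu_TI)))

    cvu_T = property(lambda self: self[0])
    cvu_I = property(lambda self: self[1])
    cvu_TI = property(lambda self: self[2])

    def as_dict(self) -> dict:
        return {"T": self[0], "I": self[1], "T_given_I": self[2]}


def _effect_at_reference(effects: Mapping, reference: Mapping) -> float:
    total = 0.0
    for cov, eff in effects.items():
        ref_level = reference.get(cov, claims.CATEGORICAL_LEVELS[cov][0])
        if isinstance(eff, Mapping):
            total += float({str(k): v for k, v in eff.items()}.get(str(ref_level), 0.0))
        else:
            total += float(eff) * float(ref_level)
    return total


def true_stage_cvus(
    params: DgpParams,
    reference_covariates: Mapping | None = None,
    ddof: int = 1,
) -> TrueCvus:
    """Closed-form per-stage CVUs implied by the DGP.

    Per region: the standardized visit probability is
    ``invlogit(alpha_visit + effects at the reference assignment)``, the
    conditional treatment probability likewise, and the unconditional
    treatment probability is their product (gatekeeping).  The CVU is the
    SD/mean of each across regions.
    """
    if len(params.regions) < 2:
        raise ValueError("CVU is undefined for fewer than 2 regions")
    ref = dict(reference_covariates or {})
    off_v = _effect_at_reference({**dict(params.theta_visit), **dict(params.gamma_visit)}, ref)
    off_t = _effect_at_reference({**dict(params.theta_treat), **dict(params.gamma_treat)}, ref)
    p_visit = np.array([expit(params.alpha_visit[r] + off_v) for r in params.regions])
    p_treat = np.array([expit(params.alpha_treat[r] + off_t) for r in params.regions])
    p_uncond = p_visit * p_treat

    def _cvu(p):
        return float(p.std(ddof=ddof) / p.mean())

    return TrueCvus(_cvu(p_uncond), _cvu(p_visit), _cvu(p_treat))


# -- scenario factories ---------------------------------------------------

def regional_alphas_from_probs(regions: Sequence[str], probs: Sequence[float]) -> dict:
    """Logit-scale intercepts reproducing given per-region probabilities."""
    if len(regions) != len(probs):
        raise ValueError("one probability per region required")
    return {str(r): float(logit(p)) for r, p in zip(regions, probs)}


def _standard_pattern(n: int) -> np.ndarray:
    """Deterministic mean-0, sample-SD-1 pattern across regions."""
    z = np.linspace(-1.0, 1.0, n)
    return (z - z.mean()) / z.std(ddof=1)


def referral_dominated_params(
    n_individuals: int,
    n_regions: int = 30,
    mean_visit: float = 0.05,
    sigma_visit: float = 0.8,
    mean_treat: float = 0.6,
    cv_treat: float = 0.15,
    seed: int = 0,
    **overrides,
) -> DgpParams:
    """A DGP in the qualitative regime of the motivating study.

    Visit-stage dispersion is large (log-scale spread ``sigma_visit`` over a
    low mean visit rate), conditional-stage dispersion is small, and the two
    patterns are anti-correlated (regions with many referrals treat a
    smaller fraction), so that CVU(I) > CVU(T) > CVU(T|I).  Modest covariate
    effects on both stages exercise the adjusted models: women and older
    individuals seek visits more, while conditional treatment is more likely
    for the young and the obese.
    """
    regions = [f"R{i + 1:02d}" for i in range(n_regions)]
    z = _standard_pattern(n_regions)
    p_visit = mean_visit * np.exp(sigma_visit * z)
    p_visit = p_visit / p_visit.mean() * mean_visit
    p_treat = mean_treat * (1.0 - cv_treat * z)  # anti-correlated with visits
    defaults = dict(
        n_individuals=n_individuals,
        regions=regions,
        alpha_visit=regional_alphas_from_probs(regions, p_visit),
        alpha_treat=regional_alphas_from_probs(regions, p_treat),
        theta_visit={"age_cat": {"41-60": 0.6, "61-70": 0.4, "70+": 0.3}},
        gamma_visit={"sex_female": 0.8, "ses_cat": {"low": -0.2, "middle": -0.1}},
        theta_treat={
            "age_cat": {"41-60": -0.4, "61-70": -0.6, "70+": -0.7},
            "obesity": 0.8,
        },
        gamma_treat={"sex_female": -0.3},
        seed=seed,
    )
    defaults.update(overrides)
    return DgpParams(**defaults)


def equal_stage_dispersion_params(
    n_individuals: int,
    n_regions: int = 10,
    cv: float = 0.2,
    mean_visit: float = 0.5,
    mean_treat: float = 0.5,
    seed: int = 0,
    **overrides,
) -> DgpParams:
    """A DGP in which the visit and conditional stages share the same CVU.

    Both stages use the identical multiplicative regional pattern, so the
    true CVU(I) and CVU(T|I) are exactly equal (to ``cv``) — the null of
    the conditional-vs-visit hypothesis holds by construction.  Stage
    probabilities default to 0.5 (maximum binomial information, so the
    sampling-noise inflation of the regional SD is small and symmetric
    across the two stages) and visit censoring defaults to off, keeping the
    stage-I estimand exactly the visit probability under the null.
    """
    regions = [f"R{i + 1:02d}" for i in range(n_regions)]
    z = _standard_pattern(n_regions)
    if cv * np.abs(z).max() >= 1.0:
        raise ValueError("cv too large for a strictly positive linear pattern")
    p_visit = mean_visit * (1.0 + cv * z)
    p_treat = mean_treat * (1.0 + cv * z)
    defaults = dict(
        n_individuals=n_individuals,
        regions=regions,
        alpha_visit=regional_alphas_from_probs(regions, p_visit),
        alpha_treat=regional_alphas_from_probs(regions, p_treat),
        p_censor_visit=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return DgpParams(**defaults)
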