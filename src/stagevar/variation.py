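"""CVU computation, joint bootstrap, and hypothesis tests on CVU differences.

The CVU — the coefficient of variation of the standardized regional
probabilities (SD across regions divided by their mean) — quantifies
regional dispersion at each stage of the patient journey.  Its sampling
distribution is obtained by resampling individuals with replacement,
re-applying the stage sample selections, refitting every model, and
recomputing the standardized probabilities and the CVU per replicate.  All
stages and model levels are computed on the *same* resample, so paired
differences between stage CVUs are valid and the three hypotheses

* H1: CVU(Pr(T))   = CVU(Pr(I))
* H2: CVU(Pr(T|I)) = CVU(Pr(I))
* H3: CVU(Pr(T))   = CVU(Pr(T|I))

are tested with percentile intervals of the per-replicate difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import claims
from .models import StageModelSpec, _SpecDesign
from ._newton import fit_grouped_logit
from .standardize import RegionalProbabilities, default_reference_covariates

__all__ = [
    "HYPOTHESIS_PAIRS",
    "CvuEstimate",
    "HypothesisResult",
    "BootstrapCvus",
    "cvu",
    "bootstrap_cvus",
    "test_cvu_difference",
]

#: Contrast (first, second) per hypothesis; delta = CVU(first) - CVU(second).
HYPOTHESIS_PAIRS = {
    "H1": ("T", "I"),
    "H2": ("T_given_I", "I"),
    "H3": ("T", "T_given_I"),
}


def cvu(regional, ddof: int = 1) -> float:
    """Coefficient of variation across regions: SD / mean.

    Accepts a :class:`RegionalProbabilities`, a region->probability mapping,
    or a plain sequence of regional probabilities.  Requires at least two
    regions and a strictly positive mean.
    """
    if isinstance(regional, RegionalProbabilities):
        values = regional.values
    elif isinstance(regional, Mapping):
        values = np.asarray(list(regional.values()), dtype=float)
    else:
        values = np.asarray(list(regional), dtype=float)
    if values.size < 2:
        raise ValueError("CVU is undefined for fewer than 2 regions")
    mean = values.mean()
    if mean <= 0:
        raise ZeroDivisionError("CVU undefined: mean regional probability is 0")
    return float(values.std(ddof=ddof) / mean)


@dataclass
class CvuEstimate:
    """Point CVU with bootstrap spread for one (stage, model level)."""

    stage: str
    model_level: int
    cvu: float
    boot_sd: float
    ci_low: float
    ci_high: float
    n_boot: int


@dataclass
class HypothesisResult:
    """Bootstrap test of equality of two stage CVUs."""

    hypothesis_id: str
    pair: tuple
    model_level: int
    delta: float
    delta_ci: tuple
    p_value: float
    reject: bool
    level: float
    n_boot: int


_STAGE_MASKS = {
    "T": lambda t: np.ones(len(t), dtype=bool),
    "I": lambda t: ~((t["treated"].to_numpy() == 1) & (t["visit_observed"].to_numpy() == 0)),
    "T_given_I": lambda t: t["initial_visit"].to_numpy() == 1,
}


class BootstrapCvus:
    """Joint bootstrap CVU samples for a set of (stage, model) specifications.

    Attributes
    ----------
    samples : DataFrame, one row per retained replicate, one column per
        ``(stage, model_level)`` pair (MultiIndex).
    point : dict mapping ``(stage, model_level)`` to the full-sample CVU.
    n_boot, n_excluded, seed, stratified : bookkeeping.
    """

    def __init__(self, samples: pd.DataFrame, point: dict, n_boot: int,
                 n_excluded: int, seed, stratified: bool, ddof: int = 1):
        self.samples = samples
        self.point = point
        self.n_boot = n_boot
        self.n_excluded = n_excluded
        self.seed = seed
        self.stratified = stratified
        self.ddof = ddof

    def keys(self):
        return list(self.samples.columns)

    def cvu_estimate(self, stage: str, model_level: int, level: float = 0.05) -> CvuEstimate:
        stage = claims.normalize_stage(stage)
        s = self.samples[(stage, model_level)].to_numpy()
        lo, hi = np.quantile(s, [level / 2.0, 1.0 - level / 2.0])
        return CvuEstimate(
            stage=stage,
            model_level=model_level,
            cvu=self.point[(stage, model_level)],
            boot_sd=float(s.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            n_boot=len(s),
        )


def bootstrap_cvus(
    table: pd.DataFrame,
    specs: Sequence[StageModelSpec],
    reference_covariates: Mapping | None = None,
    n_boot: int = 10_000,
    seed: int | None = None,
    stratify_by_region: bool = True,
    ddof: int = 1,
    max_excluded_frac: float = 0.05,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> BootstrapCvus:
    """Jointly bootstrap the CVU for every given (stage, model) specification.

    Each replicate resamples individuals with replacement — by default
    *within* region, preserving regional sample sizes so every region dummy
    stays estimable — then re-applies the stage sample selections, refits
    every model from scratch on the resample, recomputes the standardized
    regional probabilities at the reference covariate assignment, and
    records each CVU.  Replicates in which any model loses all events (or
    becomes inestimable) are excluded with a count; more than
    ``max_excluded_frac`` exclusions is an error.

    Per-replicate random streams are spawned from ``seed`` by counter, so
    results are independent of execution order.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ref = default_reference_covariates()
    if reference_covariates:
        ref.update(reference_covariates)

    specs = list(specs)
    stages = sorted({s.stage for s in specs})
    stage_tables = {}
    stage_rows = {}
    for st in stages:
        mask = _STAGE_MASKS[st](table)
        rows = np.flatnonzero(mask)
        stage_tables[st] = table.iloc[rows].reset_index(drop=True)
        # map full-table row -> local stage row (-1 outside the stage sample)
        inv = np.full(len(table), -1, dtype=np.int64)
        inv[rows] = np.arange(len(rows))
        stage_rows[st] = inv

    designs = []
    for spec in specs:
        d = _SpecDesign(stage_tables[spec.stage], spec)
        pred_rows = d.region_prediction_rows(ref)
        visit_dim = None
        if "visit_observed" in d._grid_covs:
            visit_dim = d._grid_covs.index("visit_observed") + 1
        designs.append((spec, d, pred_rows, visit_dim))

    def one_cvu(d: _SpecDesign, pred_rows, visit_dim, local_rows) -> float | None:
        events, trials = d.counts(local_rows)
        ev, tr = events.sum(), trials.sum()
        if ev <= 0 or ev >= tr:
            return None
        # a region (or the visit indicator) with no exposure in the resample
        # makes the model inestimable for this replicate
        region_trials = np.bincount(d.cell_region, weights=trials, minlength=len(d.regions))
        if (region_trials <= 0).any():
            return None
        if visit_dim is not None:
            v = d.cell_codes[visit_dim]
            if trials[v == 0].sum() <= 0 or trials[v == 1].sum() <= 0:
                return None
        res = fit_grouped_logit(d.X_cells, events, trials, tol=tol, max_iter=max_iter)
        probs = expit(pred_rows @ res.params)
        return float(probs.std(ddof=ddof) / probs.mean())

    # point estimates on the full sample
    point = {}
    for spec, d, pred_rows, visit_dim in designs:
        value = one_cvu(d, pred_rows, visit_dim, None)
        if value is None:
            raise ValueError(
                f"model for stage={spec.stage} level={spec.model_level} is "
                "inestimable on the full sample"
            )
        point[(spec.stage, spec.model_level)] = value

    n = len(table)
    region_codes = pd.Categorical(table["region"].astype(str)).codes
    region_groups = [np.flatnonzero(region_codes == g) for g in range(region_codes.max() + 1)]

    children = np.random.SeedSequence(seed).spawn(n_boot)
    kept_rows = []
    n_excluded = 0
    for b in range(n_boot):
        rng = np.random.default_rng(children[b])
        if stratify_by_region:
            parts = [grp[rng.integers(0, len(grp), len(grp))] for grp in region_groups]
            idx = np.concatenate(parts)
        else:
            idx = rng.integers(0, n, n)
        row = {}
        ok = True
        for spec, d, pred_rows, visit_dim in designs:
            local = stage_rows[spec.stage][idx]
            local = local[local >= 0]
            value = one_cvu(d, pred_rows, visit_dim, local)
            if value is None:
                ok = False
                break
            row[(spec.stage, spec.model_level)] = value
        if ok:
            kept_rows.append(row)
        else:
            n_excluded += 1

    if n_excluded > max_excluded_frac * n_boot:
        raise RuntimeError(
            f"{n_excluded}/{n_boot} bootstrap replicates excluded "
            f"(> {max_excluded_frac:.0%}); the sample is too sparse for a "
            "reliable bootstrap at these settings"
        )

    samples = pd.DataFrame(kept_rows)
    samples.columns = pd.MultiIndex.from_tuples(samples.columns, names=["stage", "model_level"])
    return BootstrapCvus(
        samples=samples,
        point=point,
        n_boot=n_boot,
        n_excluded=n_excluded,
        seed=seed,
        stratified=stratify_by_region,
        ddof=ddof,
    )


def test_cvu_difference(
    boot: BootstrapCvus,
    hypothesis_id: str,
    model_level: int | None = None,
    level: float = 0.05,
) -> HypothesisResult:
    """Percentile bootstrap test of equality of two stage CVUs.

    ``delta`` is CVU(first) - CVU(second) per replicate for the hypothesis'
    stage pair; the two-sided p-value is ``2 * min(frac <= 0, frac >= 0)``
    and the null is rejected when 0 falls outside the ``1 - level``
    percentile interval of delta.
    """
    if hypothesis_id not in HYPOTHESIS_PAIRS:
        raise ValueError(f"unknown hypothesis {hypothesis_id!r}; expected H1/H2/H3")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    first, second = HYPOTHESIS_PAIRS[hypothesis_id]
    if model_level is None:
        levels = sorted({lvl for _, lvl in boot.keys()})
        if len(levels) != 1:
            raise ValueError("model_level required when several levels were bootstrapped")
        model_level = levels[0]
    for st in (first, second):
        if (st, model_level) not in boot.samples.columns:
            raise ValueError(f"bootstrap lacks stage {st!r} at model level {model_level}")
    a = boot.samples[(first, model_level)].to_numpy()
    b = boot.samples[(second, model_level)].to_numpy()
    if len(a) != len(b):
        raise RuntimeError("mismatched replicate counts; bootstrap must be joint")
    delta = a - b
    lo, hi = np.quantile(delta, [level / 2.0, 1.0 - level / 2.0])
    p = 2.0 * min(float(np.mean(delta <= 0.0)), float(np.mean(delta >= 0.0)))
    p = float(min(max(p, 0.0), 1.0))
    point_delta = boot.point[(first, model_level)] - boot.point[(second, model_level)]
    return HypothesisResult(
        hypothesis_id=hypothesis_id,
        pair=((first, model_level), (second, model_level)),
        model_level=model_level,
        delta=float(point_delta),
        delta_ci=(float(lo), float(hi)),
        p_value=p,
        reject=not (lo <= 0.0 <= hi),
        level=level,
        n_boot=len(delta),
    )
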