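"""Configured end-to-end runs: simulate/load -> fit -> attribute -> bootstrap -> report.

A run is a pure function of its configuration: every random draw traces to
the master seed, outputs are written in deterministic formats, and the run
manifest lists each artifact with a SHA-256 checksum so that reruns can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import pandas as pd
import yaml

from . import __version__, claims
from .attribution import PracticeVariationAttribution
from .simulate import DgpParams, simulate_claims, true_stage_cvus

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]

log = logging.getLogger("stagevar")

_PNG_META = {"Software": "stagevar"}  # fixed metadata keeps PNGs reproducible


@dataclass
class PipelineConfig:
    """Everything a full run needs; exactly one of input_csv / dgp."""

    input_csv: str | None = None
    dgp: DgpParams | dict | None = None
    model_levels: tuple = (1, 2, 3)
    reference_region: str | None = None
    reference_covariates: dict | None = None
    include_visit_indicator: bool = True
    n_boot: int = 1000
    level: float = 0.05
    stratify_by_region: bool = True
    seed: int = 0
    outdir: str = "stagevar_run"
    log_level: str = "INFO"
    save_bootstrap_draws: bool = True
    make_figures: bool = True

    def __post_init__(self):
        if (self.input_csv is None) == (self.dgp is None):
            raise ValueError("exactly one of input_csv / dgp must be given")
        if isinstance(self.dgp, dict):
            self.dgp = DgpParams(**self.dgp)
        self.model_levels = tuple(int(x) for x in self.model_levels)

    def to_dict(self) -> dict:
        d = {
            "input_csv": self.input_csv,
            "dgp": self.dgp.to_dict() if self.dgp is not None else None,
            "model_levels": list(self.model_levels),
            "reference_region": self.reference_region,
            "reference_covariates": self.reference_covariates,
            "include_visit_indicator": self.include_visit_indicator,
            "n_boot": self.n_boot,
            "level": self.level,
            "stratify_by_region": self.stratify_by_region,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "log_level": self.log_level,
            "save_bootstrap_draws": self.save_bootstrap_draws,
            "make_figures": self.make_figures,
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full attribution pipeline; returns the run manifest.

    On failure the exception propagates, the failing stage is named in a
    ``FAILED`` marker file, and partial outputs are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    stage_name = "configure"
    artifacts: list[Path] = []
    try:
        cfg_echo = config.to_dict()
        cfg_echo.pop("outdir")  # implicit in the file's location; keeps the
        # checksummed echo identical across runs of the same analysis config
        with open(outdir / "config.yaml", "w", encoding="utf-8") as f:
            yaml.safe_dump(cfg_echo, f, sort_keys=True)
        artifacts.append(outdir / "config.yaml")

        stage_name = "load-input"
        t0 = time.time()
        if config.input_csv is not None:
            if not Path(config.input_csv).exists():
                raise FileNotFoundError(f"input file not found: {config.input_csv}")
            table = claims.read_claims(config.input_csv)
            log.info("loaded %d policy-holders from %s", len(table), config.input_csv)
        else:
            stage_name = "simulate"
            table = simulate_claims(config.dgp)
            claims.write_claims(table, outdir / "claims.csv")
            artifacts.append(outdir / "claims.csv")
            truth = {
                "params": config.dgp.to_dict(),
                "true_cvus": true_stage_cvus(
                    config.dgp, config.reference_covariates
                ).as_dict(),
            }
            with open(outdir / "truth.yaml", "w", encoding="utf-8") as f:
                yaml.safe_dump(truth, f, sort_keys=True)
            artifacts.append(outdir / "truth.yaml")
            log.info("simulated %d policy-holders (%d regions) in %.1fs",
                     len(table), table["region"].nunique(), time.time() - t0)

        stage_name = "fit-attribute-bootstrap"
        t0 = time.time()
        est = PracticeVariationAttribution(
            model_levels=config.model_levels,
            reference_region=config.reference_region,
            reference_covariates=config.reference_covariates,
            include_visit_indicator=config.include_visit_indicator,
            n_boot=config.n_boot,
            level=config.level,
            stratify_by_region=config.stratify_by_region,
            random_state=config.seed,
        ).fit(table)
        log.info("fit + bootstrap (%d replicates, %d excluded) in %.1fs",
                 config.n_boot, est.boot_.n_excluded, time.time() - t0)

        stage_name = "write-outputs"
        coef_rows, stat_rows, ame_rows, prob_frames = [], [], [], []
        for (st, lvl), model in est.models_.items():
            for name, value in zip(model.columns_, model.params_):
                coef_rows.append(
                    {"stage": st, "model_level": lvl, "term": name, "estimate": value}
                )
            stat_rows.append(
                {
                    "stage": st, "model_level": lvl, "n_obs": model.n_obs_,
                    "loglik": model.loglik_, "aic": model.aic_,
                    "converged": model.converged_,
                }
            )
            ame = model.marginal_effects()
            ame.insert(0, "model_level", lvl)
            ame.insert(0, "stage", st)
            ame_rows.append(ame)
            prob_frames.append(est.regional_probs_[(st, lvl)].to_frame())
        _write_csv(outdir / "coefficients.csv", pd.DataFrame(coef_rows))
        _write_csv(outdir / "model_stats.csv", pd.DataFrame(stat_rows))
        nonempty_ame = [a for a in ame_rows if len(a)]
        _write_csv(
            outdir / "marginal_effects.csv",
            pd.concat(nonempty_ame, ignore_index=True) if nonempty_ame else ame_rows[0],
        )
        _write_csv(outdir / "regional_probs.csv",
                   pd.concat(prob_frames, ignore_index=True))
        _write_csv(outdir / "cvu_estimates.csv", est.cvu_estimates_)
        _write_csv(outdir / "hypothesis_tests.csv", est.hypothesis_results_)
        artifacts += [
            outdir / n
            for n in (
                "coefficients.csv", "model_stats.csv", "marginal_effects.csv",
                "regional_probs.csv", "cvu_estimates.csv", "hypothesis_tests.csv",
            )
        ]
        summary = {
            "stagevar_version": __version__,
            "seed": config.seed,
            "n_boot": config.n_boot,
            "n_excluded_replicates": est.boot_.n_excluded,
            "cvu": {
                f"{st}_model{lvl}": est.cvus_[(st, lvl)]
                for (st, lvl) in est.cvus_
            },
        }
        _write_json(outdir / "summary.json", summary)
        artifacts.append(outdir / "summary.json")
        if config.save_bootstrap_draws:
            draws = est.boot_.samples.copy()
            draws.columns = [f"{st}_model{lvl}" for st, lvl in draws.columns]
            draws.insert(0, "replicate", range(len(draws)))
            _write_csv(outdir / "bootstrap_draws.csv", draws)
            artifacts.append(outdir / "bootstrap_draws.csv")

        manifest = {
            "stagevar_version": __version__,
            "seed": config.seed,
            "status": "ok",
            "config": config.to_dict(),
            "outputs": {},
        }
        _write_json(outdir / "manifest.json", manifest)

        if config.make_figures:
            stage_name = "report"
            artifacts += render_report(outdir)

        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(set(artifacts))
        }
        _write_json(outdir / "manifest.json", manifest)
        log.info("run complete: %d artifacts in %s", len(manifest["outputs"]), outdir)
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(
            f"stage: {stage_name}\nerror: {exc}\n", encoding="utf-8"
        )
        log.error("pipeline failed at stage %r: %s", stage_name, exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def render_report(outdir) -> list[Path]:
    """Figures and summary tables from a completed run directory.

    Produces a boxplot of the bootstrap CVU distributions per stage and
    model level, a boxplot of the three pairwise CVU-difference
    distributions, and a regression summary table.  The numbers behind each
    figure are emitted as CSV alongside the image so downstream checks can
    assert on data rather than pixels.
    """
    outdir = Path(outdir)
    if not (outdir / "cvu_estimates.csv").exists():
        raise FileNotFoundError(f"no completed run found in {outdir}")
    estimates = pd.read_csv(outdir / "cvu_estimates.csv")
    made: list[Path] = []

    draws_path = outdir / "bootstrap_draws.csv"
    if draws_path.exists():
        draws = pd.read_csv(draws_path).drop(columns=["replicate"])
    else:
        warnings.warn(
            "bootstrap draws not found; report degrades to point estimates",
            stacklevel=2,
        )
        draws = pd.DataFrame(
            {
                f"{r.stage}_model{r.model_level}": [r.cvu]
                for r in estimates.itertuples()
            }
        )

    stage_order = [c for c in draws.columns]
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.boxplot([draws[c] for c in stage_order], tick_labels=stage_order, whis=(2.5, 97.5))
    ax.set_ylabel("CVU (SD/mean of standardized regional probabilities)")
    ax.set_title("Bootstrap CVU distributions by stage and model")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(outdir / "fig_cvu_distributions.png", dpi=120, metadata=_PNG_META)
    plt.close(fig)
    _write_csv(outdir / "fig_cvu_distributions.csv", draws)
    made += [outdir / "fig_cvu_distributions.png", outdir / "fig_cvu_distributions.csv"]

    # pairwise differences per hypothesis and model level
    pairs = {"H1": ("T", "I"), "H2": ("T_given_I", "I"), "H3": ("T", "T_given_I")}
    diff_cols = {}
    for hid, (a, b) in pairs.items():
        for lvl in sorted(estimates["model_level"].unique()):
            ca, cb = f"{a}_model{lvl}", f"{b}_model{lvl}"
            if ca in draws.columns and cb in draws.columns:
                diff_cols[f"{hid}_model{lvl}"] = draws[ca] - draws[cb]
    diffs = pd.DataFrame(diff_cols)
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.boxplot([diffs[c] for c in diffs.columns], tick_labels=list(diffs.columns),
               whis=(2.5, 97.5))
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("CVU difference")
    ax.set_title("Bootstrap CVU-difference distributions (H1/H2/H3)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(outdir / "fig_cvu_differences.png", dpi=120, metadata=_PNG_META)
    plt.close(fig)
    _write_csv(outdir / "fig_cvu_differences.csv", diffs)
    made += [outdir / "fig_cvu_differences.png", outdir / "fig_cvu_differences.csv"]

    # regression summary table (marginal effects + fit statistics)
    ame = pd.read_csv(outdir / "marginal_effects.csv")
    stats = pd.read_csv(outdir / "model_stats.csv")
    if len(ame):
        wide = ame.pivot_table(
            index="term", columns=["stage", "model_level"], values="ame"
        )
        wide.columns = [f"{s}_model{l}" for s, l in wide.columns]
        wide = wide.reset_index()
    else:
        wide = pd.DataFrame({"term": []})
    _write_csv(outdir / "summary_table.csv", wide)
    _write_csv(outdir / "summary_model_stats.csv", stats)
    made += [outdir / "summary_table.csv", outdir / "summary_model_stats.csv"]
    return made
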