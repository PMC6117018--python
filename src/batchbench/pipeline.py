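"""End-to-end orchestration: generate, calibrate, simulate, fit, evaluate.

``run_study`` is the single entry point used by the analysis drivers, the
test suite and the acceptance script: it generates (or accepts) a base
cohort, calibrates it, then for every scenario runs the replicate loop —
inject effects, optionally re-estimate and apply QC calibration, fit the
requested per-gene methods, BH-adjust, score against the known effect-gene
set — and averages over replicates.  All randomness descends from a single
master seed through per-(scenario, replicate) seed sequences, so a rerun
with the same configuration reproduces outputs bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, evaluate, methods, simulate
from .cohort import CohortConfig, ExpressionMatrix, generate_base_cohort

__all__ = ["RunConfig", "run_study", "run_replicate", "METHODS"]

METHODS = ("lmm", "lm", "lm_batch", "eb_lm")


@dataclass
class RunConfig:
    """A full simulation-study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    scenarios: list[simulate.SimulationScenario] = field(default_factory=list)
    methods: tuple[str, ...] = METHODS
    alpha: float = 0.05
    output_dir: str | Path | None = None
    master_seed: int = 0

    def validate(self) -> None:
        self.cohort.validate()
        if not self.scenarios:
            raise ValueError("at least one scenario is required")
        if not self.methods:
            raise ValueError("at least one method is required")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; choose from {METHODS}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        cohort = CohortConfig(**raw.get("cohort", {}))
        scenarios = []
        for s in raw.get("scenarios", []):
            design = simulate.Design(**s.pop("design", {}))
            scenarios.append(simulate.SimulationScenario(design=design, **s))
        return cls(cohort=cohort, scenarios=scenarios,
                   methods=tuple(raw.get("methods", METHODS)),
                   alpha=raw.get("alpha", 0.05),
                   output_dir=raw.get("output_dir"),
                   master_seed=raw.get("master_seed", 0))


def _fit_pvalues(Y: np.ndarray, covariate: np.ndarray, batch: np.ndarray,
                 method: str) -> np.ndarray:
    if method == "lm":
        return methods.fit_lm(Y, covariate).p_value
    if method == "lm_batch":
        return methods.fit_lm_batch(Y, covariate, batch).p_value
    if method == "lmm":
        return methods.fit_lmm(Y, covariate, batch).p_value
    if method == "eb_lm":
        adjusted, _ = methods.eb_batch_adjust(Y, batch)
        return methods.fit_lm(adjusted, covariate).p_value
    raise ValueError(f"unknown method {method!r}")


def run_replicate(base: ExpressionMatrix, stats: calibration.CalibrationStats,
                  scenario: simulate.SimulationScenario,
                  method_names: tuple[str, ...],
                  rng: np.random.Generator, alpha: float = 0.05,
                  replicate: int = 0) -> list[evaluate.ReplicateResult]:
    """Simulate one dataset and evaluate every requested method on it."""
    sim = simulate.inject_effects(base, scenario, stats, rng)
    matrix = sim.matrix
    if scenario.with_qc_term:
        # the QC arm applies the calibration coefficients estimated from the
        # base cohort's QC measurements (raw-scale ratio factors), the way a
        # study would: the coefficients predate the perturbation, so a
        # simulated batch effect is invisible to them, and the correction
        # differs from the injected log-scale QC term only by the
        # arithmetic-vs-geometric mean gap
        matrix = calibration.apply_qc_calibration(matrix, stats, scale="raw")
    study = matrix.study()
    Y = study.values.to_numpy()
    covariate = sim.treatment.to_numpy()
    batch = sim.study_batch.to_numpy()
    effect_mask = np.zeros(base.n_genes, dtype=bool)
    effect_mask[: scenario.n_effect_genes] = True

    out = []
    for name in method_names:
        p = _fit_pvalues(Y, covariate, batch, name)
        adjusted = evaluate.bh_adjust(p)
        score = evaluate.score_detection(adjusted, effect_mask, alpha)
        auc = evaluate.roc_auc(p, effect_mask)
        out.append(evaluate.ReplicateResult(
            scenario=scenario.label or _default_label(scenario),
            method=name, replicate=replicate,
            tp=score.tp, fp=score.fp,
            mean_fdrval_tp=score.mean_fdrval_tp,
            mean_fdrval_fp=score.mean_fdrval_fp,
            auc=auc, n_effect_genes=scenario.n_effect_genes,
            n_genes=base.n_genes,
        ))
    return out


def _default_label(s: simulate.SimulationScenario) -> str:
    bits = [f"SD{s.effect_sd:g}", f"g{s.gamma:g}", s.design.kind]
    if s.with_error:
        bits.append("err")
    bits.append("qc" if s.with_qc_term else "noqc")
    return "_".join(bits)


def prepare_design_cohort(config: CohortConfig,
                          scenario: simulate.SimulationScenario,
                          seed: int) -> tuple[ExpressionMatrix,
                                              calibration.CalibrationStats]:
    """Generate and calibrate the base cohort a scenario operates on."""
    import dataclasses

    base = generate_base_cohort(dataclasses.replace(config, seed=seed))
    if scenario.design.kind in ("reduced", "batch_size_grid"):
        base = simulate.subset_cohort(base, scenario.design, config)
    stats = calibration.calibrate(base)
    return base, stats


def run_study(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every scenario of a study; returns (summary, per-replicate) tables.

    If ``config.output_dir`` is set, writes ``summary.tsv``, the long-format
    per-replicate table and a JSON manifest there.
    """
    config.validate()
    all_results: list[evaluate.ReplicateResult] = []
    base_cache: dict[str, tuple] = {}
    for s_idx, scenario in enumerate(config.scenarios):
        cohort_seed = int(
            np.random.SeedSequence([config.master_seed, 7919]).generate_state(1)[0]
            % (2 ** 31))
        cache_key = f"{scenario.design.kind}:{scenario.design.first_k_batches}:" \
                    f"{scenario.design.per_batch_size}" \
            if scenario.design.kind in ("reduced", "batch_size_grid") else "base"
        if cache_key not in base_cache:
            base_cache[cache_key] = prepare_design_cohort(
                config.cohort, scenario, cohort_seed)
        base, stats = base_cache[cache_key]
        for rep in range(scenario.n_replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.master_seed, s_idx, rep]))
            all_results.extend(run_replicate(
                base, stats, scenario, config.methods, rng,
                alpha=config.alpha, replicate=rep))

    per_replicate = pd.DataFrame([vars(r) for r in all_results])
    summary = evaluate.summarize_replicates(all_results)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        per_replicate.to_csv(out / "per_replicate.tsv", sep="\t", index=False,
                             float_format="%.6g")
        manifest = {
            "master_seed": config.master_seed,
            "alpha": config.alpha,
            "methods": list(config.methods),
            "n_genes": config.cohort.n_genes,
            "scenarios": [vars(s) | {"design": vars(s.design)}
                          for s in config.scenarios],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    return summary, per_replicate
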