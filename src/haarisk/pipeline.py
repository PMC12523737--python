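"""End-to-end orchestration, configuration and report rendering.

A single YAML config drives the whole analysis. The stages are:

1. **data** — read a long-form concentration CSV, or synthesize one with
   the seeded generator;
2. **validate** — per-compound calibration figures of merit (slope, r²,
   LOD/LOQ, lack of fit), matrix effect from solvent vs matrix-spiked
   slopes, spike recovery and precision;
3. **doe** (optional) — factorial effect screening and surrogate +
   desirability optimization of the extraction conditions;
4. **risk** — the exposure grid: per-(base, treatment) mean profiles ×
   age groups × servings, cumulative ILCR, band and EC intake flag;
5. **stats** — commercial vs homemade Welch comparison, profile PCA and
   hierarchical clustering.

Reports are emitted as JSON (machine) and Markdown (human); both embed a
run manifest (config snapshot, input digests, seed, package version).
Identical manifests produce identical reports apart from the timestamp.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .data import (
    CensoringPolicy,
    ConcentrationSet,
    read_concentrations,
    totals_by_sample,
    iter_profiles,
    write_concentrations,
)
from .doe import (
    Factor,
    Goal,
    ResponseGoal,
    build_full_factorial,
    estimate_effects,
    optimize_conditions,
)
from .errors import ComputationError, ConfigError, DataValidationError
from .registry import RiskParameters, compound_names, get_compound
from .risk import scenario_grid
from .simulate import (
    DEFAULT_LODS,
    GeneratorConfig,
    generate_calibration,
    generate_concentrations,
    generate_doe_responses,
    generate_recovery_training,
)
from .stats import compare_commercial_homemade, hcluster, pca, scale_matrix
from .validation import (
    SN_LOD,
    fit_calibration,
    matrix_effect,
    precision_rsd,
    recovery,
)

__all__ = ["load_config", "run_full", "render_markdown", "RunManifest"]

REQUIRED_CONFIG_KEYS = ("seed", "risk")


@dataclasses.dataclass(frozen=True)
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    seed: int
    version: str
    timestamp: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    """Load and structurally validate a YAML pipeline config."""
    import yaml

    try:
        raw = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    config = yaml.safe_load(raw)
    if not isinstance(config, dict):
        raise ConfigError(f"config {path} is not a mapping")
    return validate_config(config)


def validate_config(config: dict) -> dict:
    for key in REQUIRED_CONFIG_KEYS:
        if key not in config:
            raise ConfigError(f"missing config key: {key}")
    if not isinstance(config["seed"], int):
        raise ConfigError("config key 'seed' must be an integer")
    risk_cfg = config["risk"]
    if not isinstance(risk_cfg, dict):
        raise ConfigError("config key 'risk' must be a mapping")
    if not config.get("synthesize", True) and not config.get("input_path"):
        raise ConfigError(
            "missing config key: input_path (required when synthesize is false)"
        )
    policy = config.get("censoring_policy", "zero")
    try:
        CensoringPolicy(policy)
    except ValueError:
        raise ConfigError(f"invalid censoring_policy {policy!r}") from None
    return config


def _risk_parameters(risk_cfg: dict) -> RiskParameters:
    kwargs: dict[str, Any] = {}
    if "serving_volume" in risk_cfg:
        kwargs["serving_volume"] = float(risk_cfg["serving_volume"])
    if "adaf" in risk_cfg:
        kwargs["adaf_by_age"] = {int(k): float(v) for k, v in risk_cfg["adaf"].items()}
    if "body_weight" in risk_cfg:
        kwargs["body_weight_by_age"] = {
            int(k): float(v) for k, v in risk_cfg["body_weight"].items()
        }
    return RiskParameters(**kwargs)


# ---------------------------------------------------------------------------
# stages


def _stage_data(config: dict, logger) -> ConcentrationSet:
    if config.get("synthesize", True):
        gen_cfg = GeneratorConfig(
            seed=int(config["seed"]), **config.get("generator", {})
        )
        logger("data: synthesizing concentrations (seed=%d)" % gen_cfg.seed)
        return generate_concentrations(gen_cfg)
    path = config["input_path"]
    logger(f"data: reading {path}")
    return read_concentrations(path)


def _stage_validation(seed: int) -> list[dict]:
    """Table of per-compound figures of merit from seeded calibrations."""
    rows = []
    rng = np.random.default_rng(seed)
    for compound in compound_names():
        target_lod = DEFAULT_LODS[compound]
        noise_sd = 5.0
        slope = SN_LOD * noise_sd / target_lod
        matrix_factor = float(rng.uniform(0.947, 1.053))
        true_recovery = float(rng.uniform(84.0, 100.0))
        solvent, spiked = generate_calibration(
            compound=compound,
            slope=slope,
            noise_sd=noise_sd,
            matrix_factor=matrix_factor,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fit_solvent = fit_calibration(solvent)
        fit_spiked = fit_calibration(spiked)
        c_real, c_added = 1.0, 1.0
        c_found = c_real + true_recovery / 100.0 * c_added
        replicate_rsd = precision_rsd(
            100.0 + rng.normal(0.0, 3.0, size=5)
        )
        rows.append(
            {
                "compound": compound,
                "slope": fit_solvent.slope,
                "intercept": fit_solvent.intercept,
                "r_squared": fit_solvent.r_squared,
                "lod_ug_per_L": fit_solvent.lod,
                "loq_ug_per_L": fit_solvent.loq,
                "linear_range": list(fit_solvent.linear_range),
                "lof_p_value": fit_solvent.lof_p_value,
                "recovery_pct": recovery(c_found, c_real, c_added),
                "matrix_effect_pct": matrix_effect(
                    fit_spiked.slope, fit_solvent.slope
                ),
                "precision_rsd_pct": replicate_rsd,
            }
        )
    return rows


def _stage_doe(seed: int) -> dict:
    """Factorial screening + surrogate optimization on synthetic truth."""
    factors = [
        Factor("A", 5.0, 15.0, "mg"),
        Factor("B", 10.0, 40.0, "mL"),
        Factor("C", 0.5, 2.0, "mL/min"),
    ]
    design = build_full_factorial(factors, n_center=3)
    truth = {"intercept": 80.0, "A": 6.0, "B": 1.5, "C": 0.5, "A:B": 2.0}
    design.responses["recovery"] = generate_doe_responses(
        truth, design, noise_sd=1.0, seed=seed
    )
    table = estimate_effects(design, "recovery")

    X, recoveries, opt_factors = generate_recovery_training(seed=seed)
    spec = {
        name: ResponseGoal(Goal.TARGET, 70.0, 130.0, target=100.0)
        for name in recoveries.columns
    }
    x_opt, predicted, overall = optimize_conditions(
        X, recoveries, spec, surrogate="quadratic", seed=seed, resolution=21
    )
    return {
        "screening": {
            "factors": [dataclasses.asdict(f) for f in design.factors],
            "effects": table.to_frame().to_dict(orient="records"),
            "pse": table.pse,
            "margin_of_error": table.margin_of_error,
            "method": table.method,
        },
        "optimization": {
            "factors": [dataclasses.asdict(f) for f in opt_factors],
            "optimum_coded": [float(v) for v in x_opt],
            "optimum_natural": {
                f.name: f.decode(float(v)) for f, v in zip(opt_factors, x_opt)
            },
            "predicted_recoveries": predicted,
            "overall_desirability": overall,
        },
    }


def _stage_risk(cset: ConcentrationSet, config: dict) -> dict:
    risk_cfg = config["risk"]
    params = _risk_parameters(risk_cfg)
    policy = CensoringPolicy(config.get("censoring_policy", "zero"))
    grid = scenario_grid(
        cset,
        params,
        policy=policy,
        aggregation=risk_cfg.get("aggregation", "mean"),
    )
    return {
        "parameters": {
            "serving_volume_L": params.serving_volume,
            "adaf_by_age": params.adaf_by_age,
            "body_weight_by_age": params.body_weight_by_age,
            "censoring_policy": policy.value,
            "aggregation": risk_cfg.get("aggregation", "mean"),
        },
        "grid": grid.to_dict(orient="records"),
        "n_cells": len(grid),
        "n_unacceptable": int((grid["band"] == "unacceptable").sum()),
        "n_further_evaluation": int((grid["band"] == "further_evaluation").sum()),
        "n_negligible": int((grid["band"] == "negligible").sum()),
    }


def _stage_stats(cset: ConcentrationSet, config: dict) -> dict:
    stats_cfg = config.get("stats", {})
    policy = CensoringPolicy(config.get("censoring_policy", "zero"))
    comparison = compare_commercial_homemade(cset, policy)
    profiles = iter_profiles(cset, policy)
    pca_result = pca(profiles, scaling=stats_cfg.get("scaling", "autoscale"))
    k = int(stats_cfg.get("clusters", 3))
    clusters = hcluster(
        scale_matrix(profiles, stats_cfg.get("scaling", "autoscale")),
        linkage=stats_cfg.get("linkage", "ward"),
        k=k,
    )
    return {
        "group_comparison": {
            "groups": [comparison.group_a, comparison.group_b],
            "mean_difference_ug_per_L": comparison.mean_difference,
            "ci95": list(comparison.ci95),
            "t_stat": comparison.t_stat,
            "p_value": comparison.p_value,
            "df": comparison.df,
        },
        "pca": {
            "explained_variance_pct": [
                float(v) for v in pca_result.explained_variance_pct
            ],
            "top2_pct": float(pca_result.explained_variance_pct[:2].sum()),
        },
        "clustering": {
            "k": k,
            "labels": {
                str(sid): int(lbl) for sid, lbl in clusters.labels.items()
            },
            "tree": clusters.to_tree_dict(),
        },
        "totals_by_sample": {
            str(k_): float(v) for k_, v in totals_by_sample(cset, policy).items()
        },
    }


def run_full(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    logger=None,
) -> dict:
    """Execute the full pipeline and return the JSON-able report.

    When *out_dir* is given, writes ``report.json``, ``report.md``, the
    concentration table and the risk grid there.
    """
    logger = logger or (lambda msg: None)
    input_digests: dict[str, str] = {}
    if isinstance(config, (str, Path)):
        input_digests["config"] = _sha256(config)
        config = load_config(config)
    else:
        config = validate_config(dict(config))
    if config.get("input_path"):
        input_digests["input"] = _sha256(config["input_path"])

    seed = int(config["seed"])
    logger(
        "decisions of record: censoring_policy=%s, adaf=%s, aggregation=%s"
        % (
            config.get("censoring_policy", "zero"),
            config["risk"].get("adaf", {5: 3, 13: 3, 84: 1}),
            config["risk"].get("aggregation", "mean"),
        )
    )
    cset = _stage_data(config, logger)
    report: dict[str, Any] = {
        "manifest": RunManifest(
            config=config,
            input_digests=input_digests,
            seed=seed,
            version=__version__,
            timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        ).to_dict(),
        "n_samples": len(cset.sample_ids()),
        "validation": _stage_validation(seed),
    }
    if config.get("doe", {}).get("enabled", True):
        logger("doe: screening + optimization")
        report["doe"] = _stage_doe(seed)
    logger("risk: scenario grid")
    report["risk"] = _stage_risk(cset, config)
    logger("stats: comparison, PCA, clustering")
    report["stats"] = _stage_stats(cset, config)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, ensure_ascii=False, sort_keys=True),
            encoding="utf-8",
        )
        (out / "report.md").write_text(render_markdown(report), encoding="utf-8")
        write_concentrations(cset, out / "concentrations.csv")
        import pandas as pd

        pd.DataFrame(report["risk"]["grid"]).to_csv(
            out / "risk_grid.csv", index=False
        )
    return report


# ---------------------------------------------------------------------------
# markdown rendering


def _md_table(rows: list[dict], columns: list[str], fmt: str = "{:.4g}") -> str:
    def cell(value):
        if isinstance(value, float):
            return fmt.format(value)
        return str(value)

    lines = [
        "| " + " | ".join(columns) + " |",
        "| " + " | ".join("---" for _ in columns) + " |",
    ]
    for row in rows:
        lines.append("| " + " | ".join(cell(row.get(c, "")) for c in columns) + " |")
    return "\n".join(lines)


def render_markdown(report: dict) -> str:
    """Deterministic human-readable report."""
    parts = ["# HAA exposure and risk report", ""]
    manifest = report["manifest"]
    parts += [
        f"Package version {manifest['version']}, seed {manifest['seed']}.",
        "",
        "## Method validation (figures of merit)",
        "",
        _md_table(
            report["validation"],
            [
                "compound",
                "slope",
                "r_squared",
                "lod_ug_per_L",
                "loq_ug_per_L",
                "recovery_pct",
                "matrix_effect_pct",
                "precision_rsd_pct",
            ],
        ),
        "",
    ]
    if "doe" in report:
        opt = report["doe"]["optimization"]
        parts += [
            "## Extraction screening and optimization",
            "",
            _md_table(
                report["doe"]["screening"]["effects"],
                ["term", "effect", "standardized_effect", "margin", "significant"],
            ),
            "",
            "Optimum (coded): "
            + ", ".join(f"{v:+.2f}" for v in opt["optimum_coded"])
            + f"; overall desirability {opt['overall_desirability']:.3f}.",
            "",
        ]
    risk = report["risk"]
    grid_rows = risk["grid"]
    parts += [
        "## Risk grid",
        "",
        f"{risk['n_cells']} scenario cells: "
        f"{risk['n_negligible']} negligible, "
        f"{risk['n_further_evaluation']} further evaluation, "
        f"{risk['n_unacceptable']} unacceptable.",
        "",
    ]
    if grid_rows:
        parts += [
            _md_table(
                grid_rows,
                [
                    "base",
                    "treatment",
                    "age_group",
                    "servings",
                    "ilcr_total",
                    "band",
                    "ec_limit_exceeded",
                ],
                fmt="{:.3e}",
            ),
            "",
        ]
    else:
        parts += ["No samples: the risk grid is empty.", ""]
    stats_section = report.get("stats")
    if stats_section:
        gc = stats_section["group_comparison"]
        parts += [
            "## Profile statistics",
            "",
            (
                f"Commercial − homemade mean total HAA difference "
                f"{gc['mean_difference_ug_per_L']:.2f} µg/L "
                f"(95% CI {gc['ci95'][0]:.2f} to {gc['ci95'][1]:.2f}, "
                f"p = {gc['p_value']:.3g})."
            ),
            "",
            (
                "PCA: first two components explain "
                f"{stats_section['pca']['top2_pct']:.1f}% of total variance."
            ),
            "",
        ]
    return "\n".join(parts)
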