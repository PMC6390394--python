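"""End-to-end analysis pipeline: preprocess, correlations, model ladder,
model comparison, and derived statistics for the best-fitting model.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .biometric import FitOptions, ModelSpec, FitResult, compare, fit, profile_ci
from .correlations import (
    cross_twin_cross_trait,
    ml_twin_correlation,
    phenotypic_correlations,
)
from .data_model import TwinDataset, Zygosity, group_counts
from .derived import derive_stats, implied_phenotypic_correlation
from .preprocessing import preprocess_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "correlation_table"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    The default model roster mirrors the standard multivariate ladder:
    full ACE; full ADE; ADE without A covariances; ADE without D
    covariances; ADE without E covariances; DE. Entries are
    ``(name, parent_name_or_None, spec_builder_kwargs)``.
    """

    out_dir: Path
    seed: int = 0
    transform_threshold: float = 0.5
    per_trait_transform: dict[str, str] | None = None
    ci_level: float | None = None  # None = skip CIs (they are slow)
    n_restarts: int = 4
    compute_correlations: bool = True
    model_roster: list[tuple[str, str | None, dict]] = field(default_factory=list)

    def default_roster(self) -> list[tuple[str, str | None, dict]]:
        return [
            ("ACE_full", None, {"components": {"A", "C", "E"}}),
            ("ADE_full", None, {"components": {"A", "D", "E"}}),
            ("ADE_noAcov", "ADE_full", {"components": {"A", "D", "E"},
                                        "drop_cov": "A"}),
            ("ADE_noDcov", "ADE_full", {"components": {"A", "D", "E"},
                                        "drop_cov": "D"}),
            ("ADE_noEcov", "ADE_full", {"components": {"A", "D", "E"},
                                        "drop_cov": "E"}),
            ("DE", "ADE_full", {"components": {"D", "E"}}),
        ]


def _build_spec(traits: tuple[str, ...], kwargs: dict) -> ModelSpec:
    spec = ModelSpec(traits=traits, components=frozenset(kwargs["components"]))
    if "drop_cov" in kwargs:
        spec = spec.drop_covariances(kwargs["drop_cov"])
    return spec


def correlation_table(data: TwinDataset, level: float = 0.95) -> pd.DataFrame:
    """Tidy table of twin, cross-twin cross-trait, and phenotypic correlations."""
    rows = []
    for group in Zygosity:
        fams = data.group_families(group)
        if len(fams) < 3:
            continue
        for j, name in enumerate(data.trait_names):
            pairs = np.array([f.traits[:, j] for f in fams])
            try:
                est = ml_twin_correlation(
                    pairs, constrain_order=group != Zygosity.DOS, level=level
                )
            except ValueError:
                continue
            rows.append(
                dict(group=group.value, trait_i=name, trait_j=name,
                     kind="within-trait", r=est.r, ci_low=est.ci_low,
                     ci_high=est.ci_high, n_pairs=est.n_pairs)
            )
    for zclass in ("MZ", "DZ"):
        for a in range(len(data.trait_names)):
            for b in range(a + 1, len(data.trait_names)):
                ti, tj = data.trait_names[a], data.trait_names[b]
                est = cross_twin_cross_trait(data, ti, tj, zclass, level=level)
                rows.append(
                    dict(group=zclass, trait_i=ti, trait_j=tj,
                         kind="cross-trait", r=est.r, ci_low=est.ci_low,
                         ci_high=est.ci_high, n_pairs=est.n_pairs)
                )
    pheno = phenotypic_correlations(data)
    for a in range(len(data.trait_names)):
        for b in range(a + 1, len(data.trait_names)):
            ti, tj = data.trait_names[a], data.trait_names[b]
            rows.append(
                dict(group="all", trait_i=ti, trait_j=tj, kind="phenotypic",
                     r=float(pheno.loc[ti, tj]), ci_low=np.nan, ci_high=np.nan,
                     n_pairs=len(data.families))
            )
    return pd.DataFrame(rows)


def _fit_roster(data, traits, roster, options):
    fits: dict[str, FitResult] = {}
    comparisons = []
    for name, parent, kwargs in roster:
        spec = _build_spec(traits, kwargs)
        fits[name] = fit(data, spec, options=options)
        row = {
            "model": name,
            "parent": parent or "",
            "minus2LL": fits[name].minus2ll,
            "n_params": fits[name].n_params,
            "aic": fits[name].aic,
            "converged": fits[name].converged,
        }
        if parent is not None:
            row.update(compare(fits[parent], fits[name]))
        comparisons.append(row)
    return fits, pd.DataFrame(comparisons)


def _select_best(table: pd.DataFrame) -> str:
    """Best model: lowest AIC among models not rejected against their parent."""
    ok = table[
        (table["parent"] == "")
        | (table.get("p_value", pd.Series(dtype=float)).fillna(1.0) >= 0.05)
    ]
    return str(ok.sort_values("aic").iloc[0]["model"])


def run_pipeline(
    data: TwinDataset, config: PipelineConfig
) -> dict:
    """Run the full analysis and write a report bundle to ``config.out_dir``.

    Stages: preprocess -> correlations -> multivariate model ladder ->
    comparison table -> derived statistics for the best-fitting model.
    Every artifact is written as CSV/JSON; the log records seeds and stage
    timings. Raises :class:`PipelineError` tagged with the failing stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    t_start = time.time()

    def log(stage: str, **kw):
        entry = {"stage": stage, "elapsed_s": round(time.time() - t_start, 3), **kw}
        with open(log_path, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    log("start", seed=config.seed,
        group_counts={g.value: n for g, n in group_counts(data).items()})

    try:
        prepped, report = preprocess_dataset(
            data,
            threshold=config.transform_threshold,
            per_trait=config.per_trait_transform,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("preprocess", str(exc)) from exc
    (out / "preprocess_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True)
    )
    log("preprocess", transforms=report.transform)

    if config.compute_correlations:
        try:
            corr = correlation_table(prepped)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("correlations", str(exc)) from exc
        corr.to_csv(out / "correlations.csv", index=False, float_format="%.6f")
        log("correlations", n_rows=len(corr))

    roster = config.model_roster or config.default_roster()
    options = FitOptions(n_restarts=config.n_restarts, seed=config.seed)
    try:
        fits, table = _fit_roster(prepped, prepped.trait_names, roster, options)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("fit", str(exc)) from exc
    table.to_csv(out / "model_comparison.csv", index=False, float_format="%.6f")
    log("fit", models=list(fits))

    best_name = _select_best(table)
    best = fits[best_name]
    stats_ = derive_stats(best.estimates)
    report_best = {
        "best_model": best_name,
        "fit": best.to_dict(),
        "derived": stats_.to_dict(),
        "implied_phenotypic": implied_phenotypic_correlation(stats_).tolist(),
    }

    if config.ci_level is not None:
        cis = {}
        spec = best.estimates.spec
        for t_idx, trait in enumerate(spec.traits):
            def prop_genetic(p, t=t_idx):
                total = p.total_sigma()[t, t]
                gen = sum(p.sigma(c)[t, t] for c in ("A", "D") if c in spec.components)
                return gen / total
            lo, hi, flags = profile_ci(
                prepped, spec, best, prop_genetic, level=config.ci_level,
                target_limits=(0.0, 1.0),
            )
            cis[f"total_genetic[{trait}]"] = {"low": lo, "high": hi, **flags}
        report_best["profile_cis"] = cis
        log("profile_ci", n=len(cis))

    (out / "best_model.json").write_text(
        json.dumps(report_best, indent=2, sort_keys=True)
    )

    md = ["# Model comparison", "", "```", table.to_string(index=False), "```",
          "", f"Best model: **{best_name}**", ""]
    (out / "report.md").write_text("\n".join(md))
    log("done", best_model=best_name)
    return {"best_model": best_name, "fits": fits, "comparison": table,
            "derived": stats_, "out_dir": out}
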