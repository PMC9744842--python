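"""End-to-end orchestration: data -> fits -> scenarios -> effect sizes -> meta.

:func:`run_pipeline` executes every analysis stage under a single
:class:`PipelineConfig` — either on a real long-format table or on a
synthetic study with known truth — and returns a :class:`ResultBundle` of
tidy tables.  Traits that fail cleaning, preconditions or convergence are
skipped and listed with reasons; they never abort the run.  Given the same
config and seed the bundle is bit-for-bit reproducible, and the manifest
records everything needed to rerun it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dataset import EmptyTraitError, SingleSexError, TraitDataset
from .effects import (
    EffectSize,
    cohens_d,
    effect_sizes_from_fit,
    effects_to_table,
    fold,
    log_transform_folded,
)
from .ingest import TraitGroupMap, partition_by_trait, read_table
from .lmm import AllometryFit, FitConfig, fit_allometry, fits_to_table
from .meta import (
    CorrelationResult,
    MetaResult,
    fit_effect_size_correlations,
    fit_meta_regression,
    fit_multilevel_meta,
    meta_to_dict,
)
from .sexdiff import (
    ScenarioCall,
    build_unit_calls,
    calls_to_table,
    scenario_counts,
    tally_sex_bias,
)
from .simulate import StudySpec, generate_study

logger = logging.getLogger(__name__)

META_KINDS = ("intercept_diff", "slope_diff", "sd_diff", "fit_zr")


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run.

    Exactly one of ``data_path`` (real long-format table) or ``study``
    (synthetic study spec) must be provided.
    """

    data_path: str | Path | None = None
    study: StudySpec | None = None
    group_map: TraitGroupMap | None = None
    alpha: float = 0.05
    merge: bool = True
    fit_config: FitConfig = field(default_factory=FitConfig)
    run_correlations: bool = True
    n_boot_correlations: int = 100
    master_seed: int = 0
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.data_path is None) == (self.study is None):
            raise ValueError("provide exactly one of data_path or study")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ResultBundle:
    """All tidy outputs of one pipeline run."""

    fits: list[AllometryFit]
    fit_table: pd.DataFrame
    calls_unmerged: list[ScenarioCall]
    calls_merged: list[ScenarioCall] | None
    bias_summary: pd.DataFrame
    effect_table: pd.DataFrame          # raw + folded + log_folded states
    meta_results: dict[str, MetaResult]
    meta_regressions: dict[str, MetaResult]
    correlations: CorrelationResult | None
    smd_table: pd.DataFrame
    skipped: list[dict]
    truth: pd.DataFrame | None
    manifest: dict


def trait_seed(master_seed: int, trait_name: str) -> int:
    """Per-trait seed from the master seed and the trait name (stable under
    reordering and parallelism)."""
    return (master_seed * 1_000_003 + zlib.crc32(trait_name.encode())) % (2**31 - 1)


def _load_datasets(cfg: PipelineConfig) -> tuple[list[TraitDataset], pd.DataFrame | None]:
    if cfg.study is not None:
        study = replace(cfg.study, master_seed=cfg.master_seed or cfg.study.master_seed)
        datasets, truth = generate_study(study)
        return datasets, truth
    records, problems = read_table(cfg.data_path)
    if problems:
        logger.info("%d rows rejected at ingest", len(problems))
    return partition_by_trait(records), None


def run_pipeline(cfg: PipelineConfig) -> ResultBundle:
    """Execute all stages and assemble a :class:`ResultBundle`.

    Stages: ingest or simulate; per-trait heteroscedastic REML fits;
    scenario classification (unmerged, and merged when a group map is
    available); sex-bias tallies; the four effect sizes with folded and
    log-folded transforms; Cohen's d; multilevel meta-analysis and
    functional-group meta-regression per folded kind; and (optionally) the
    quad-variate correlation model when enough complete units exist.
    """
    datasets, truth = _load_datasets(cfg)
    group_map = cfg.group_map or (cfg.study.group_map if cfg.study else None)

    fits: list[AllometryFit] = []
    skipped: list[dict] = []
    smd_rows = []
    for ds in datasets:
        try:
            fit = fit_allometry(ds, cfg.fit_config)
        except (SingleSexError, ValueError, EmptyTraitError) as exc:
            skipped.append({"trait_name": ds.trait_name, "stage": "fit", "reason": str(exc)})
            continue
        if not fit.converged:
            skipped.append(
                {"trait_name": ds.trait_name, "stage": "fit", "reason": fit.message or "non-convergence"}
            )
            continue
        fits.append(fit)
        try:
            es_d, category = cohens_d(ds)
            smd_rows.append(
                {
                    "trait_name": ds.trait_name,
                    "functional_group": ds.functional_group,
                    "d": es_d.es,
                    "se": es_d.se,
                    "category": category,
                }
            )
        except ValueError as exc:
            skipped.append({"trait_name": ds.trait_name, "stage": "smd", "reason": str(exc)})

    calls_unmerged = build_unit_calls(fits, merge=False, alpha=cfg.alpha)
    calls_merged = None
    if cfg.merge and group_map is not None:
        covered = [f for f in fits if f.trait_name in group_map.groups]
        dropped = sorted(set(f.trait_name for f in fits) - set(f.trait_name for f in covered))
        for name in dropped:
            skipped.append(
                {"trait_name": name, "stage": "merge", "reason": "not in group map"}
            )
        if covered:
            calls_merged = build_unit_calls(
                covered, group_map=group_map, merge=True, alpha=cfg.alpha
            )
    bias = tally_sex_bias(calls_unmerged)

    # effect sizes: raw -> folded -> log-folded
    all_effects: list[EffectSize] = []
    for fit in fits:
        raw = effect_sizes_from_fit(fit)
        for e in raw:
            if group_map is not None and e.unit_id in group_map.groups:
                e.trait_group = group_map.group_of(e.unit_id)
        folded = [fold(e) if e.kind != "fit_zr" else e for e in raw]
        logf = []
        for e in folded:
            try:
                logf.append(log_transform_folded(e))
            except ValueError:
                pass
        all_effects.extend(raw + [e for e in folded if e.state == "folded"] + logf)
    effect_table = effects_to_table(all_effects)

    meta_results: dict[str, MetaResult] = {}
    meta_regressions: dict[str, MetaResult] = {}
    for kind in META_KINDS:
        state = "raw" if kind == "fit_zr" else "folded"
        subset = [e for e in all_effects if e.kind == kind and e.state == state]
        if len(subset) >= 3:
            meta_results[kind] = fit_multilevel_meta(subset, seed=cfg.master_seed)
            groups = {e.functional_group for e in subset}
            if len(groups) > 1:
                meta_regressions[kind] = fit_meta_regression(subset, seed=cfg.master_seed)

    correlations = None
    if cfg.run_correlations:
        log_table = effect_table[effect_table["state"] == "log_folded"]
        try:
            correlations = fit_effect_size_correlations(
                log_table, n_boot=cfg.n_boot_correlations, seed=cfg.master_seed
            )
        except ValueError as exc:
            logger.info("correlation model skipped: %s", exc)

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "alpha": cfg.alpha,
        "merge": cfg.merge,
        "n_traits_in": len(datasets),
        "n_fits": len(fits),
        "n_skipped": len(skipped),
        "skipped": skipped,
        "config_hash": _config_hash(cfg),
    }

    bundle = ResultBundle(
        fits=fits,
        fit_table=fits_to_table(fits),
        calls_unmerged=calls_unmerged,
        calls_merged=calls_merged,
        bias_summary=bias,
        effect_table=effect_table,
        meta_results=meta_results,
        meta_regressions=meta_regressions,
        correlations=correlations,
        smd_table=pd.DataFrame(smd_rows),
        skipped=skipped,
        truth=truth,
        manifest=manifest,
    )
    if cfg.out_dir is not None:
        write_bundle(bundle, cfg.out_dir)
    return bundle


def _config_hash(cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    parts = [
        str(cfg.data_path),
        str(cfg.alpha),
        str(cfg.merge),
        str(cfg.master_seed),
        str(cfg.fit_config),
    ]
    if cfg.study is not None:
        parts.append(str([t.__dict__ for t in cfg.study.traits]))
    h.update("|".join(parts).encode())
    return h.hexdigest()[:16]


def summarize(bundle: ResultBundle) -> tuple[str, dict]:
    """Human-readable and JSON summaries of a finished run.

    Reports scenario counts and percentages (merged and unmerged), sex-bias
    tallies, and headline pooled estimates with CI and PI per effect-size
    kind.  Empty scenario classes are reported as zero, never omitted.
    """
    def count_block(calls):
        counts = scenario_counts(calls)
        total = max(sum(counts.values()), 1)
        return {
            s: {"count": counts[s], "percent": 100.0 * counts[s] / total}
            for s in ("A", "B", "C", "NS")
        }

    js: dict = {
        "n_traits_fitted": len(bundle.fits),
        "n_skipped": len(bundle.skipped),
        "scenarios_unmerged": count_block(bundle.calls_unmerged),
    }
    if bundle.calls_merged is not None:
        js["scenarios_merged"] = count_block(bundle.calls_merged)
    js["bias"] = (
        bundle.bias_summary.reset_index().to_dict(orient="records")
        if len(bundle.bias_summary)
        else []
    )
    js["meta"] = {kind: meta_to_dict(r) for kind, r in bundle.meta_results.items()}
    if bundle.correlations is not None:
        js["correlations"] = {
            "kinds": bundle.correlations.kinds,
            "matrix": bundle.correlations.corr.tolist(),
        }

    lines = [
        f"traits fitted: {js['n_traits_fitted']} (skipped {js['n_skipped']})",
        "scenario counts (unmerged): "
        + ", ".join(
            f"{s}={b['count']} ({b['percent']:.0f}%)"
            for s, b in js["scenarios_unmerged"].items()
        ),
    ]
    if "scenarios_merged" in js:
        lines.append(
            "scenario counts (merged):   "
            + ", ".join(
                f"{s}={b['count']} ({b['percent']:.0f}%)"
                for s, b in js["scenarios_merged"].items()
            )
        )
    for kind, r in bundle.meta_results.items():
        lines.append(
            f"meta[{kind}]: mu={r.mu:.4f} CI=[{r.ci95[0]:.4f}, {r.ci95[1]:.4f}] "
            f"PI=[{r.pi95[0]:.4f}, {r.pi95[1]:.4f}]"
            + (" *" if r.significant else "")
        )
    return "\n".join(lines), js


def write_bundle(bundle: ResultBundle, out_dir: str | Path) -> None:
    """Write every table of a bundle as TSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.fit_table.to_csv(out / "fits.tsv", sep="\t", index=False)
    calls_to_table(bundle.calls_unmerged).to_csv(
        out / "scenario_calls_unmerged.tsv", sep="\t", index=False
    )
    if bundle.calls_merged is not None:
        calls_to_table(bundle.calls_merged).to_csv(
            out / "scenario_calls_merged.tsv", sep="\t", index=False
        )
    if len(bundle.bias_summary):
        bundle.bias_summary.reset_index().to_csv(
            out / "bias_summary.tsv", sep="\t", index=False
        )
    bundle.effect_table.to_csv(out / "effect_sizes.tsv", sep="\t", index=False)
    if len(bundle.smd_table):
        bundle.smd_table.to_csv(out / "smd.tsv", sep="\t", index=False)
    meta = {k: meta_to_dict(r) for k, r in bundle.meta_results.items()}
    metareg = {k: meta_to_dict(r) for k, r in bundle.meta_regressions.items()}
    with open(out / "meta.json", "w") as fh:
        json.dump({"meta": meta, "meta_regression": metareg}, fh, indent=2, default=float)
    if bundle.truth is not None:
        bundle.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, default=str)
    text, js = summarize(bundle)
    with open(out / "summary.json", "w") as fh:
        json.dump(js, fh, indent=2, default=float)
    (out / "summary.txt").write_text(text + "\n")
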