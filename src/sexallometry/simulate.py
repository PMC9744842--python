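"""Synthetic mouse-phenotyping data with known sex-specific allometry.

The generator inverts the analysis model: each trait follows a power law of
body weight on the log-log scale, with sex-specific intercept, slope, and
residual SD, crossed grouping factors (same-day batch with random intercepts;
metadata group and sub-strain with correlated random intercepts and random
weight slopes), and lognormal body weights (males heavier by a configurable
factor, default 1.2x).  Because every parameter is known, downstream fitting,
scenario classification, and meta-analysis can be scored against ground truth.

Reproducibility: all randomness flows through ``numpy.random.Generator``
(PCG64) seeded via ``SeedSequence``.  Per-trait streams are spawned from the
master seed with fixed keys, so adding a trait to a study never perturbs the
data of another, and generation is byte-stable across platforms for a given
seed and numpy version.

Scenario vocabulary (used throughout the package):

- ``A``: sexes differ in allometric slope only (same intercept at the
  grand-mean weight);
- ``B``: sexes differ in intercept only (same slope) — the "scaled female"
  hypothesis;
- ``C``: both differ;
- ``NS``: neither differs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .dataset import FUNCTIONAL_GROUPS, TraitDataset
from .ingest import TraitGroupMap

SCENARIOS = ("A", "B", "C", "NS")


@dataclass
class SyntheticTraitSpec:
    """Generating parameters for one synthetic trait.

    Intercepts are log trait values at the grand-mean log weight; slopes are
    allometric exponents (dimensionless); residual SDs are on the log scale.
    ``cov_mg`` and ``cov_strain`` are 2x2 covariance matrices of per-level
    (intercept, slope) deviations; ``var_batch_intercept`` is the batch
    random-intercept variance.
    """

    trait_name: str
    intercept_f: float = 1.0
    intercept_m: float = 1.0
    slope_f: float = 0.3
    slope_m: float = 0.3
    sd_f: float = 0.12
    sd_m: float = 0.12
    n_f: int = 1000
    n_m: int = 1000
    weight_logmean_f: float = float(np.log(22.0))
    weight_logmean_m: float = float(np.log(22.0) + np.log(1.2))
    weight_logsd: float = 0.15
    n_batches: int = 20
    n_metadata_groups: int = 1
    n_substrains: int = 1
    var_batch_intercept: float = 0.0
    cov_mg: np.ndarray | None = None
    cov_strain: np.ndarray | None = None
    functional_group: str = "morphology"
    scenario_truth: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_f <= 0 or self.n_m <= 0:
            raise ValueError("sample sizes must be positive")
        if self.sd_f < 0 or self.sd_m < 0:
            raise ValueError("residual SDs must be nonnegative")
        if self.var_batch_intercept < 0:
            raise ValueError("batch variance must be nonnegative")
        for name in ("cov_mg", "cov_strain"):
            cov = getattr(self, name)
            if cov is not None:
                cov = np.asarray(cov, dtype=float)
                if cov.shape != (2, 2):
                    raise ValueError(f"{name} must be 2x2")
                if not np.allclose(cov, cov.T):
                    raise ValueError(f"{name} must be symmetric")
                if np.linalg.eigvalsh(cov).min() < -1e-12:
                    raise ValueError(f"{name} must be positive semi-definite")
                object.__setattr__(self, name, cov)
        if self.scenario_truth is not None:
            if self.scenario_truth not in SCENARIOS:
                raise ValueError(f"unknown scenario {self.scenario_truth!r}")
            implied = implied_scenario(self)
            if implied != self.scenario_truth:
                raise ValueError(
                    f"scenario_truth={self.scenario_truth!r} inconsistent with "
                    f"parameter differences (implied {implied!r})"
                )

    @property
    def delta_intercept(self) -> float:
        return self.intercept_m - self.intercept_f

    @property
    def delta_slope(self) -> float:
        return self.slope_m - self.slope_f


def implied_scenario(spec: SyntheticTraitSpec) -> str:
    slope_diff = spec.slope_m != spec.slope_f
    int_diff = spec.intercept_m != spec.intercept_f
    if slope_diff and int_diff:
        return "C"
    if slope_diff:
        return "A"
    if int_diff:
        return "B"
    return "NS"


def spec_from_scenario(
    scenario: str,
    delta_intercept: float = 0.0,
    delta_slope: float = 0.0,
    base: SyntheticTraitSpec | None = None,
    **overrides,
) -> SyntheticTraitSpec:
    """Build a spec realizing a requested sex-difference scenario.

    Deltas are male minus female and must be nonnegative; the scenario must
    be consistent with the deltas (e.g. scenario ``A`` requires
    ``delta_slope > 0`` and ``delta_intercept == 0``).
    """
    if delta_intercept < 0 or delta_slope < 0:
        raise ValueError("deltas must be nonnegative (male - female convention)")
    need = {
        "A": (delta_slope > 0, delta_intercept == 0),
        "B": (delta_slope == 0, delta_intercept > 0),
        "C": (delta_slope > 0, delta_intercept > 0),
        "NS": (delta_slope == 0, delta_intercept == 0),
    }
    if scenario not in need:
        raise ValueError(f"unknown scenario {scenario!r}")
    if not all(need[scenario]):
        raise ValueError(
            f"scenario {scenario!r} inconsistent with deltas "
            f"(delta_intercept={delta_intercept}, delta_slope={delta_slope})"
        )
    base = base or SyntheticTraitSpec(trait_name=f"synthetic_{scenario}")
    return replace(
        base,
        intercept_m=base.intercept_f + delta_intercept,
        slope_m=base.slope_f + delta_slope,
        scenario_truth=scenario,
        **overrides,
    )


def _trait_rng(spec: SyntheticTraitSpec) -> np.random.Generator:
    key = zlib.crc32(spec.trait_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(key,)))


def generate_trait(
    spec: SyntheticTraitSpec,
    rng: np.random.Generator | None = None,
    weights: np.ndarray | None = None,
    animal_ids: Sequence[str] | None = None,
) -> TraitDataset:
    """Draw one synthetic trait dataset from its generating spec.

    Per animal: body weight lognormal by sex; batch / metadata group /
    sub-strain assigned uniformly; log trait value = sex intercept + sex
    slope x centred log weight + batch deviation + group (intercept +
    slope x centred log weight) deviations + Normal(0, sd_sex) noise; the
    exported value is on the natural scale (exponentiated).  Centring is at
    the grand mean of the sampled log weights, matching the fitted model, so
    in the noise-free limit values follow the exact power law
    ``value = exp(intercept) * (weight / GM)^slope`` with GM the geometric
    mean weight.

    ``weights``/``animal_ids`` allow correlated traits to share the same
    latent animals (used by :func:`generate_study` for trait groups).
    """
    rng = rng or _trait_rng(spec)
    n = spec.n_f + spec.n_m
    sex = np.array(["female"] * spec.n_f + ["male"] * spec.n_m)
    male = sex == "male"

    if weights is None:
        logw = np.where(male, spec.weight_logmean_m, spec.weight_logmean_f)
        logw = logw + rng.normal(0.0, spec.weight_logsd, size=n)
        weights = np.exp(logw)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (n,):
            raise ValueError("shared weights length must equal n_f + n_m")
        logw = np.log(weights)

    x = logw - logw.mean()  # grand-mean-centred log weight

    batch = rng.integers(0, spec.n_batches, size=n)
    mg = rng.integers(0, spec.n_metadata_groups, size=n)
    strain = rng.integers(0, spec.n_substrains, size=n)

    y = np.where(male, spec.intercept_m, spec.intercept_f) + np.where(
        male, spec.slope_m, spec.slope_f
    ) * x

    if spec.var_batch_intercept > 0:
        b_dev = rng.normal(0.0, np.sqrt(spec.var_batch_intercept), size=spec.n_batches)
        y = y + b_dev[batch]
    if spec.cov_mg is not None and np.any(spec.cov_mg):
        dev = rng.multivariate_normal(
            np.zeros(2), spec.cov_mg, size=spec.n_metadata_groups, method="cholesky"
        )
        y = y + dev[mg, 0] + dev[mg, 1] * x
    if spec.cov_strain is not None and np.any(spec.cov_strain):
        dev = rng.multivariate_normal(
            np.zeros(2), spec.cov_strain, size=spec.n_substrains, method="cholesky"
        )
        y = y + dev[strain, 0] + dev[strain, 1] * x

    sd = np.where(male, spec.sd_m, spec.sd_f)
    y = y + sd * rng.standard_normal(n)

    if animal_ids is None:
        animal_ids = [f"{spec.trait_name}:a{i:06d}" for i in range(n)]

    data = pd.DataFrame(
        {
            "animal_id": list(animal_ids),
            "sex": sex,
            "weight": weights,
            "weight_age_days": 70,
            "trait_name": spec.trait_name,
            "trait_value": np.exp(y),
            "batch": [f"batch{b:03d}" for b in batch],
            "metadata_group": [f"mg{g:02d}" for g in mg],
            "substrain": [f"C57BL/6sub{s}" for s in strain],
            "centre": "synthetic_centre",
            "procedure_name": "synthetic_procedure",
            "functional_group": spec.functional_group,
        }
    )
    provenance = {
        "generator": "sexallometry.simulate",
        "seed": spec.seed,
        "truth": truth_row(spec),
    }
    return TraitDataset(spec.trait_name, spec.functional_group, data, provenance)


def truth_row(spec: SyntheticTraitSpec) -> dict:
    """Tidy ground-truth record for one trait (for recovery scoring)."""
    return {
        "trait_name": spec.trait_name,
        "functional_group": spec.functional_group,
        "scenario_truth": spec.scenario_truth or implied_scenario(spec),
        "intercept_f": spec.intercept_f,
        "intercept_m": spec.intercept_m,
        "slope_f": spec.slope_f,
        "slope_m": spec.slope_m,
        "sd_f": spec.sd_f,
        "sd_m": spec.sd_m,
        "delta_intercept": spec.delta_intercept,
        "delta_slope": spec.delta_slope,
        "n_f": spec.n_f,
        "n_m": spec.n_m,
    }


@dataclass
class StudySpec:
    """A collection of trait specs plus the correlated-trait grouping."""

    traits: list[SyntheticTraitSpec]
    group_map: TraitGroupMap | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        names = [t.trait_name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in study")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudySpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = [SyntheticTraitSpec(**t) for t in raw.get("traits", [])]
        gm = raw.get("group_map")
        group_map = TraitGroupMap(gm["groups"], gm.get("r", 0.8)) if gm else None
        return cls(traits=traits, group_map=group_map, master_seed=raw.get("master_seed", 0))

    def to_yaml(self, path: str | Path) -> None:
        def trait_dict(t: SyntheticTraitSpec) -> dict:
            d = {}
            for k, v in t.__dict__.items():
                if isinstance(v, np.ndarray):
                    v = v.tolist()
                elif isinstance(v, (np.floating, np.integer)):
                    v = v.item()
                d[k] = v
            return d

        raw = {
            "master_seed": self.master_seed,
            "traits": [trait_dict(t) for t in self.traits],
        }
        if self.group_map is not None:
            raw["group_map"] = {"groups": self.group_map.groups, "r": self.group_map.r}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def generate_study(study: StudySpec) -> tuple[list[TraitDataset], pd.DataFrame]:
    """Generate every trait in a study plus its tidy ground-truth table.

    Traits mapped to the same correlated-trait group share the same latent
    animals (identical body weights and animal IDs), so that merged-p
    machinery downstream sees genuinely correlated traits.  Each trait's
    stream is derived from the master seed and the trait name, so traits are
    otherwise independent and stable under study edits.
    """
    datasets: list[TraitDataset] = []
    shared: dict[str, tuple[np.ndarray, list[str]]] = {}
    for spec in study.traits:
        spec = replace(spec, seed=study.master_seed) if spec.seed == 0 else spec
        rng = _trait_rng(spec)
        weights = None
        ids = None
        if study.group_map is not None and spec.trait_name in study.group_map.groups:
            gid = study.group_map.group_of(spec.trait_name)
            if gid in shared:
                weights, ids = shared[gid]
                if len(ids) != spec.n_f + spec.n_m:
                    raise ValueError(
                        f"traits in group {gid!r} must share sample sizes to share animals"
                    )
            else:
                ds = generate_trait(spec, rng=rng)
                shared[gid] = (
                    ds.data["weight"].to_numpy(),
                    list(ds.data["animal_id"]),
                )
                datasets.append(ds)
                continue
        datasets.append(generate_trait(spec, rng=rng, weights=weights, animal_ids=ids))
    truth = pd.DataFrame([truth_row(t) for t in study.traits])
    return datasets, truth


def write_study(datasets: Sequence[TraitDataset], path: str | Path) -> None:
    """Write all generated traits as one long-format CSV that
    :func:`sexallometry.ingest.read_table` round-trips."""
    pd.concat([ds.data for ds in datasets], ignore_index=True).to_csv(path, index=False)
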