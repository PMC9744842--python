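"""Per-trait effect sizes of sex difference and magnitude transforms.

Four effect sizes are extracted per converged fit, all male minus female:

- ``intercept_diff``: the sex contrast on the intercept at grand-mean weight
  (a log response ratio, lnRR) with its model SE;
- ``slope_diff``: the sex contrast on the allometric slope with its model SE;
- ``sd_diff``: the bias-corrected log variability ratio (lnVR) of the
  residual SDs with its analytic SE;
- ``fit_zr``: model fit, Fisher's Zr of the square root of marginal
  R-squared, variance 1/(n - 3).

When only the magnitude of a difference matters, a signed effect X with
sampling SE is mapped to the mean and variance of |X| under the folded
normal distribution:

    ES_folded  = SE sqrt(2/pi) exp(-ES^2 / (2 SE^2)) + ES [1 - 2 Phi(-ES/SE)]
    SE_folded^2 = ES^2 + SE^2 - ES_folded^2

Folded effects (and Zr) can be further log-transformed with the first-order
delta method (es' = ln es, se' = se / es) for the correlation model.

Cohen's d (standardised mean difference on the log-trait scale) is also
provided with the conventional small/medium/large benchmarks 0.2 / 0.5 / 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import NotConvergedError, TraitDataset
from .lmm import AllometryFit
from .sexdiff import lnvr_test

EFFECT_KINDS = ("intercept_diff", "slope_diff", "sd_diff", "fit_zr", "smd")

#: marginal R^2 at which Zr is clipped to stay finite
ZR_CLIP_R2 = 0.999999


@dataclass
class EffectSize:
    """One effect size with its sampling SE and transform state."""

    unit_id: str
    kind: str
    es: float
    se: float
    state: str = "raw"  # raw | folded | log_folded
    functional_group: str | None = None
    trait_group: str | None = None
    n_total: int | None = None
    clipped: bool = False

    def __post_init__(self) -> None:
        if self.kind not in EFFECT_KINDS:
            raise ValueError(f"unknown effect-size kind {self.kind!r}")
        if self.se < 0:
            raise ValueError("SE must be nonnegative")

    @property
    def variance(self) -> float:
        return self.se**2


def effect_sizes_from_fit(fit: AllometryFit) -> list[EffectSize]:
    """The four effect sizes (raw state) from one converged fit."""
    if not fit.converged:
        raise NotConvergedError(f"trait {fit.trait_name!r} did not converge")
    d_int, se_int, _ = fit.contrast_intercept
    d_slo, se_slo, _ = fit.contrast_slope
    vt = lnvr_test(fit.sd_resid_m, fit.n_m, fit.sd_resid_f, fit.n_f)

    r2 = fit.r2_marginal
    clipped = False
    if r2 >= ZR_CLIP_R2:
        r2 = ZR_CLIP_R2
        clipped = True
    zr = math.atanh(math.sqrt(max(r2, 0.0)))
    se_zr = math.sqrt(1.0 / (fit.n_total - 3))

    common = dict(
        unit_id=fit.trait_name,
        functional_group=fit.functional_group,
        n_total=fit.n_total,
    )
    return [
        EffectSize(kind="intercept_diff", es=d_int, se=se_int, **common),
        EffectSize(kind="slope_diff", es=d_slo, se=se_slo, **common),
        EffectSize(kind="sd_diff", es=vt.lnvr, se=vt.se_lnvr, **common),
        EffectSize(kind="fit_zr", es=zr, se=se_zr, clipped=clipped, **common),
    ]


def folded_normal_mean_var(es: float, se: float) -> tuple[float, float]:
    """Mean and variance of |X| for X ~ Normal(es, se^2)."""
    if se == 0.0:
        return abs(es), 0.0
    mean = se * math.sqrt(2.0 / math.pi) * math.exp(-(es**2) / (2.0 * se**2)) + es * (
        1.0 - 2.0 * norm.cdf(-es / se)
    )
    var = es**2 + se**2 - mean**2
    return mean, max(var, 0.0)


def fold(es: EffectSize) -> EffectSize:
    """Map a signed effect size to its folded-normal magnitude.

    The se = 0 limit returns (|ES|, 0) and is flagged via ``clipped``.
    """
    if es.state != "raw":
        raise ValueError(f"fold expects a raw effect size, got state={es.state!r}")
    mean, var = folded_normal_mean_var(es.es, es.se)
    return replace(
        es, es=mean, se=math.sqrt(var), state="folded", clipped=es.clipped or es.se == 0.0
    )


def log_transform_folded(es: EffectSize) -> EffectSize:
    """First-order delta-method log transform: (ln es, se / es).

    Applies to folded effects and to raw Zr (which is already a magnitude).
    """
    ok = es.state == "folded" or (es.kind == "fit_zr" and es.state == "raw")
    if not ok:
        raise ValueError(f"cannot log-transform kind={es.kind!r} in state={es.state!r}")
    if es.es <= 0:
        raise ValueError("log transform requires a positive effect size")
    return replace(es, es=math.log(es.es), se=es.se / es.es, state="log_folded")


_SMD_BENCHMARKS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def smd_category(d: float) -> str:
    for threshold, label in _SMD_BENCHMARKS:
        if abs(d) >= threshold:
            return label
    return "below-small"


def cohens_d(ds: TraitDataset) -> tuple[EffectSize, str]:
    """Cohen's d of male vs female log trait value, with its benchmark
    category (small 0.2 / medium 0.5 / large 0.8 by |d|).

    Computed on the log scale for consistency with the allometric model;
    sampling variance uses the standard normal-theory formula
    ``(n_f + n_m) / (n_f n_m) + d^2 / (2 (n_f + n_m))``.
    """
    logv = np.log(ds.data["trait_value"].to_numpy(dtype=float))
    male = ds.sex_mask("male")
    ym, yf = logv[male], logv[~male]
    n_m, n_f = len(ym), len(yf)
    if n_m < 2 or n_f < 2:
        raise ValueError("Cohen's d requires at least 2 observations per sex")
    pooled = math.sqrt(
        ((n_m - 1) * ym.var(ddof=1) + (n_f - 1) * yf.var(ddof=1)) / (n_m + n_f - 2)
    )
    if pooled == 0.0:
        raise ValueError("zero pooled SD")
    d = (ym.mean() - yf.mean()) / pooled
    var = (n_f + n_m) / (n_f * n_m) + d**2 / (2.0 * (n_f + n_m))
    es = EffectSize(
        unit_id=ds.trait_name,
        kind="smd",
        es=float(d),
        se=math.sqrt(var),
        functional_group=ds.functional_group,
        n_total=n_m + n_f,
    )
    return es, smd_category(d)


def effects_to_table(effects: Sequence[EffectSize]) -> pd.DataFrame:
    """Tidy effect-size table (the direct input of the meta-models)."""
    rows = []
    for e in effects:
        rows.append(
            {
                "unit_id": e.unit_id,
                "kind": e.kind,
                "state": e.state,
                "es": e.es,
                "se": e.se,
                "variance": e.variance,
                "functional_group": e.functional_group,
                "trait_group": e.trait_group,
                "n_total": e.n_total,
                "clipped": e.clipped,
            }
        )
    return pd.DataFrame(rows)
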