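"""Sex-difference inference on fitted allometric models.

Three per-trait tests feed the scenario classification: Wald p-values for the
sex contrasts on slope and intercept (from the mixed model), and a log
variability ratio (lnVR) test for the difference in residual SDs.  Traits
known to be correlated (e.g. left/right eye measurements) can have their
p-values merged within trait groups using Fisher's method rescaled by the
Li-Ji effective number of tests under an assumed equicorrelation (default
r = 0.8).  Significant calls are tallied into per-functional-group sex-bias
summaries; under scenario C a unit whose slope and intercept biases point to
opposite sexes is counted as "mixed".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .ingest import TraitGroupMap
from .lmm import AllometryFit

logger = logging.getLogger(__name__)

SCENARIO_LABELS = ("A", "B", "C", "NS")


@dataclass
class VarianceTestResult:
    """Bias-corrected log ratio of male to female residual SD with its
    analytic sampling SE and a two-sided normal p-value."""

    lnvr: float
    se_lnvr: float
    z: float
    p_value: float


@dataclass
class ScenarioCall:
    """Scenario classification for one unit (trait or merged trait group)."""

    unit_id: str
    p_slope: float
    p_intercept: float
    p_sd: float
    scenario: str
    bias_slope: str = "none"       # male / female / none
    bias_intercept: str = "none"
    bias_sd: str = "none"
    merged: bool = False
    functional_group: str | None = None
    n_traits: int = 1


def lnvr_test(sd_m: float, n_m: int, sd_f: float, n_f: int) -> VarianceTestResult:
    """Compare two group SDs via the bias-corrected log variability ratio.

    lnVR = ln(sd_m / sd_f) + 1/(2(n_m - 1)) - 1/(2(n_f - 1)), with sampling
    variance 1/(2(n_m - 1)) + 1/(2(n_f - 1)); the p-value is two-sided
    normal.  Positive lnVR means males are more variable.
    """
    if n_m <= 2 or n_f <= 2:
        raise ValueError("lnVR requires at least 3 observations per group")
    if sd_m <= 0 or sd_f <= 0:
        raise ValueError("SDs must be positive")
    lnvr = math.log(sd_m / sd_f) + 1.0 / (2.0 * (n_m - 1)) - 1.0 / (2.0 * (n_f - 1))
    se = math.sqrt(1.0 / (2.0 * (n_m - 1)) + 1.0 / (2.0 * (n_f - 1)))
    z = lnvr / se
    p = float(np.clip(2.0 * norm.sf(abs(z)), 1e-300, 1.0))
    return VarianceTestResult(lnvr=lnvr, se_lnvr=se, z=z, p_value=p)


def li_ji_m_eff(k: int, r: float) -> float:
    """Effective number of tests among k equicorrelated tests.

    Eigenvalues of the k x k equicorrelation matrix are 1 + (k-1)r (once)
    and 1 - r (k-1 times); each contributes I(lambda >= 1) plus its
    fractional part.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (0.0 <= r < 1.0):
        raise ValueError("r must be in [0, 1)")
    eigvals = np.concatenate([[1.0 + (k - 1) * r], np.full(k - 1, 1.0 - r)])
    return float(np.sum((eigvals >= 1.0).astype(float) + (eigvals - np.floor(eigvals))))


def merge_pvalues(p_list: Sequence[float], r: float = 0.8) -> float:
    """Combine correlated p-values: Fisher's statistic rescaled by the Li-Ji
    effective number of tests under equicorrelation r.

    The Fisher statistic X = -2 sum(ln p) is scaled by m_eff / k and referred
    to a chi-square with fractional df 2 * m_eff.  A single p-value is
    returned unchanged; r = 0 reduces to plain Fisher.
    """
    p = np.asarray(list(p_list), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    k = p.size
    if k == 1:
        return float(p[0])
    m_eff = li_ji_m_eff(k, r)
    fisher = -2.0 * float(np.sum(np.log(p)))
    scaled = fisher * m_eff / k
    return float(np.clip(chi2.sf(scaled, df=2.0 * m_eff), 1e-300, 1.0))


def classify_scenario(p_slope: float, p_intercept: float, alpha: float = 0.05) -> str:
    """Scenario label from the two contrast p-values (strict inequality;
    ties at alpha are non-significant)."""
    slope_sig = p_slope < alpha
    int_sig = p_intercept < alpha
    if slope_sig and int_sig:
        return "C"
    if slope_sig:
        return "A"
    if int_sig:
        return "B"
    return "NS"


def _bias(sign: float, significant: bool) -> str:
    if not significant:
        return "none"
    return "male" if sign > 0 else "female"


def build_unit_calls(
    fits: Sequence[AllometryFit],
    group_map: TraitGroupMap | None = None,
    merge: bool = False,
    alpha: float = 0.05,
) -> list[ScenarioCall]:
    """Scenario calls per trait, or per merged trait group.

    Unmerged: one call per converged trait from its raw p-values, with
    male/female bias directions from the contrast signs (male - female
    convention; for SD, the sign of lnVR).  Merged: slope, intercept and SD
    p-values are each combined within trait groups via :func:`merge_pvalues`
    with the map's correlation, then classified; bias directions are not
    reported for merged units because directionality is meaningless across
    merged traits.
    """
    fits = [f for f in fits if f.converged]
    rows = []
    for f in fits:
        d_int, _, p_int = f.contrast_intercept
        d_slo, _, p_slo = f.contrast_slope
        vt = lnvr_test(f.sd_resid_m, f.n_m, f.sd_resid_f, f.n_f)
        rows.append((f, p_slo, p_int, vt.p_value, d_slo, d_int, vt.lnvr))

    if not merge:
        calls = []
        for f, p_slo, p_int, p_sd, d_slo, d_int, lnvr in rows:
            scen = classify_scenario(p_slo, p_int, alpha)
            calls.append(
                ScenarioCall(
                    unit_id=f.trait_name,
                    p_slope=p_slo,
                    p_intercept=p_int,
                    p_sd=p_sd,
                    scenario=scen,
                    bias_slope=_bias(d_slo, p_slo < alpha),
                    bias_intercept=_bias(d_int, p_int < alpha),
                    bias_sd=_bias(lnvr, p_sd < alpha),
                    functional_group=f.functional_group,
                )
            )
        return calls

    if group_map is None:
        raise ValueError("merge=True requires a trait group map")
    missing = [f.trait_name for f, *_ in rows if f.trait_name not in group_map.groups]
    if missing:
        raise ValueError(f"traits missing from group map: {missing}")

    by_group: dict[str, list] = {}
    for row in rows:
        by_group.setdefault(group_map.group_of(row[0].trait_name), []).append(row)

    calls = []
    for gid in sorted(by_group):
        members = by_group[gid]
        r = group_map.r
        p_slo = merge_pvalues([m[1] for m in members], r)
        p_int = merge_pvalues([m[2] for m in members], r)
        p_sd = merge_pvalues([m[3] for m in members], r)
        fgs = {m[0].functional_group for m in members}
        calls.append(
            ScenarioCall(
                unit_id=gid,
                p_slope=p_slo,
                p_intercept=p_int,
                p_sd=p_sd,
                scenario=classify_scenario(p_slo, p_int, alpha),
                merged=True,
                functional_group=fgs.pop() if len(fgs) == 1 else "mixed",
                n_traits=len(members),
            )
        )
    return calls


def tally_sex_bias(calls: Sequence[ScenarioCall]) -> pd.DataFrame:
    """Per-functional-group tallies of which sex shows the greater parameter.

    Four panels, mirroring how significant sex differences are reported:

    - ``slope``: scenario A units, bias of the slope contrast;
    - ``intercept``: scenario B units, bias of the intercept contrast;
    - ``slope_and_intercept``: scenario C units; "mixed" counts units whose
      slope and intercept biases point to opposite sexes;
    - ``sd``: all units with a significant SD difference, bias by lnVR sign.

    Counts within a panel and group sum to the number of significant units.
    Merged calls carry no directionality and are excluded.
    """
    recs = []
    for c in calls:
        if c.merged:
            continue
        g = c.functional_group or "unknown"
        if c.scenario == "A":
            recs.append((g, "slope", c.bias_slope))
        elif c.scenario == "B":
            recs.append((g, "intercept", c.bias_intercept))
        elif c.scenario == "C":
            if c.bias_slope == c.bias_intercept:
                recs.append((g, "slope_and_intercept", c.bias_slope))
            else:
                recs.append((g, "slope_and_intercept", "mixed"))
        if c.bias_sd != "none":
            recs.append((g, "sd", c.bias_sd))

    index = pd.MultiIndex.from_tuples([], names=["functional_group", "panel"])
    out = pd.DataFrame(
        0, index=index, columns=["male", "female", "mixed"], dtype=int
    )
    for g, panel, bias in recs:
        if (g, panel) not in out.index:
            out.loc[(g, panel), :] = 0
        out.loc[(g, panel), bias] += 1
    return out.sort_index().astype(int)


def calls_to_table(calls: Sequence[ScenarioCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def scenario_counts(calls: Sequence[ScenarioCall]) -> dict[str, int]:
    counts = {s: 0 for s in SCENARIO_LABELS}
    for c in calls:
        counts[c.scenario] += 1
    return counts
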