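"""Nonparametric cohort statistics and contrast tables.

Rank-based tests as used for the cohort contrasts: Wilcoxon signed-rank for
paired comparisons (corrected vs uncorrected metrics, day vs night activity),
Mann-Whitney U for group contrasts (UWS vs MCS/EMCS, TBI vs NTBI) and
Kendall's tau-b for correlations with CRS-R behavioural scores. All tests are
two-sided. Z values come from the tie-corrected normal approximation without
continuity correction; an exact enumeration mode exists for small samples.
Effect sizes follow r = |Z| / sqrt(N) with the conventional small/medium/
large cuts at 0.1 / 0.3 / 0.5.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import CircadianSummary
from .types import CohortTable, ValidationError

__all__ = [
    "TestResult",
    "ContrastTables",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kendall_tau",
    "effect_size_r",
    "effect_size_label",
    "round_half_away",
    "build_contrast_tables",
]

logger = logging.getLogger(__name__)

#: Metrics reported per patient in the cohort tables.
METRIC_NAMES = ["IS", "IV", "deviation_from_24h", "normalized_power", "mean_day", "mean_night"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sided rank test.

    ``n`` holds the sample sizes: ``{"n": N}`` for paired tests (pairs
    entering the contrast, before zero differences are dropped — the N used
    in r = |Z|/sqrt(N)) or ``{"n1": ..., "n2": ...}`` for two-sample tests.
    ``defined`` is False when the test is undefined (e.g. all paired
    differences zero), in which case the numeric fields are ``nan``.
    """

    test_name: str
    statistic: float
    z_value: float
    p_value: float
    effect_size_r: float
    n: Mapping[str, int]
    two_sided: bool = True
    defined: bool = True


def _undefined(test_name: str, n: Mapping[str, int]) -> TestResult:
    return TestResult(test_name, math.nan, math.nan, math.nan, math.nan, n, defined=False)


def effect_size_r(z: float, n_total: int) -> float:
    """Effect size r = |Z| / sqrt(N) for a rank test."""
    if n_total <= 0:
        raise ValidationError("n_total must be positive")
    return abs(z) / math.sqrt(n_total)


def effect_size_label(r: float) -> str:
    """Conventional interpretation: small at 0.1, medium at 0.3, large at 0.5."""
    if math.isnan(r):
        return "undefined"
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    if r >= 0.1:
        return "small"
    return "negligible"


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report convention), e.g. 0.545 -> 0.55."""
    if math.isnan(x):
        return x
    q = 10**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def wilcoxon_signed_rank(
    a: Sequence[float], b: Sequence[float], exact: Optional[bool] = None
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (standard convention); ranks of tied
    absolute differences are averaged. The statistic is W+, the sum of ranks
    of positive differences. Default inference uses the tie-corrected normal
    approximation without continuity correction; ``exact=True`` (automatic
    for n <= 10 nonzero pairs when unspecified) enumerates all sign
    assignments. The effect size uses the pre-drop number of pairs.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired samples must have equal length")
    n_pre = int(a.size)
    d = a - b
    d = d[d != 0]
    n = int(d.size)
    if n == 0:
        return _undefined("wilcoxon_signed_rank", {"n": n_pre})
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # variance with tie correction on the ranks of |d|
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return _undefined("wilcoxon_signed_rank", {"n": n_pre})
    z = (w_plus - mu) / math.sqrt(sigma2)
    if exact is None:
        exact = n <= 10
    if exact:
        # null distribution of W+ over all 2^n sign assignments of the ranks
        dev = abs(w_plus - mu)
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            w = float(np.dot(signs, ranks))
            if abs(w - mu) >= dev - 1e-12:
                count += 1
        p = count / 2.0**n
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TestResult(
        "wilcoxon_signed_rank",
        statistic=w_plus,
        z_value=z,
        p_value=p,
        effect_size_r=effect_size_r(z, n_pre),
        n={"n": n_pre},
    )


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], exact: Optional[bool] = None
) -> TestResult:
    """Two-sided Mann-Whitney U test for two independent groups.

    The statistic is U of the first group. Z uses the tie-corrected normal
    approximation without continuity correction; ``exact=True`` (automatic
    for n1 + n2 <= 10 when unspecified) enumerates all group assignments of
    the pooled ranks. The effect size uses N = n1 + n2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = int(x.size), int(y.size)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return _undefined("mann_whitney_u", {"n1": n1, "n2": n2})
    z = (u1 - mu) / math.sqrt(sigma2)
    if exact is None:
        exact = n <= 10
    if exact:
        dev = abs(u1 - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            u = float(ranks[list(combo)].sum()) - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        p = count / total
    else:
        p = 2.0 * sps.norm.sf(abs(z))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TestResult(
        "mann_whitney_u",
        statistic=u1,
        z_value=z,
        p_value=p,
        effect_size_r=effect_size_r(z, n),
        n={"n1": n1, "n2": n2},
    )


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall's tau-b rank correlation (tie-corrected), two-sided.

    The z value is recovered from the two-sided p with the sign of tau, so
    the uniform r = |Z|/sqrt(N) effect size is available for reporting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("samples must have equal length")
    n = int(x.size)
    if n < 4:
        raise ValidationError("kendall_tau requires at least 4 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return _undefined("kendall_tau", {"n": n})
    res = sps.kendalltau(x, y, variant="b")
    tau = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(tau):
        return _undefined("kendall_tau", {"n": n})
    p = min(max(p, np.finfo(float).tiny), 1.0)
    z = math.copysign(sps.norm.isf(p / 2.0), tau if tau != 0 else 1.0)
    return TestResult(
        "kendall_tau",
        statistic=tau,
        z_value=z,
        p_value=p,
        effect_size_r=effect_size_r(z, n),
        n={"n": n},
    )


# ---------------------------------------------------------------------------
# Contrast tables


def _summary_frame(summaries: Mapping[str, CircadianSummary]) -> pd.DataFrame:
    rows = []
    for pid, s in summaries.items():
        rows.append(
            {
                "patient_id": pid,
                "IS": s.IS,
                "IV": s.IV,
                "deviation_from_24h": s.deviation_from_24h,
                "normalized_power": s.normalized_power,
                "mean_day": s.day_night.mean_day,
                "mean_night": s.day_night.mean_night,
                "is_circadian": s.peak.is_circadian,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def _row(metric: str, labels: dict, res: TestResult, extra: dict) -> dict:
    row = {"metric": metric, **labels}
    row.update(
        {
            "test": res.test_name,
            "statistic": res.statistic,
            "z": res.z_value,
            "p": res.p_value,
            "r": res.effect_size_r,
            "effect": effect_size_label(res.effect_size_r)
            if res.defined
            else "undefined",
            "trend": bool(res.defined and 0.05 < res.p_value <= 0.1),
            "defined": res.defined,
            **{f"n_{k}": v for k, v in res.n.items()},
        }
    )
    row.update(extra)
    return row


def _not_computed(metric: str, labels: dict, reason: str) -> dict:
    return {
        "metric": metric,
        **labels,
        "test": None,
        "statistic": math.nan,
        "z": math.nan,
        "p": math.nan,
        "r": math.nan,
        "effect": "not_computed",
        "trend": False,
        "defined": False,
        "reason": reason,
    }


@dataclass
class ContrastTables:
    """The cohort-level result tables.

    * ``paired_datasets`` — corrected vs uncorrected, per metric (paired).
    * ``diagnosis`` — UWS vs pooled MCS/EMCS, per metric, per dataset.
    * ``day_night`` — day vs night activity (paired), per group and dataset.
    * ``etiology`` — TBI vs NTBI, per metric, per dataset.
    * ``crs_r`` — Kendall correlations of CRS-R scores with each metric.
    * ``circadian_counts`` — patients classified circadian per dataset.
    """

    paired_datasets: pd.DataFrame
    diagnosis: pd.DataFrame
    day_night: pd.DataFrame
    etiology: pd.DataFrame
    crs_r: pd.DataFrame
    circadian_counts: pd.DataFrame


def build_contrast_tables(
    corrected: Mapping[str, CircadianSummary],
    uncorrected: Mapping[str, CircadianSummary],
    cohort: CohortTable,
    min_pairs: int = 5,
) -> ContrastTables:
    """All cohort contrast tables from per-patient summaries of both datasets.

    Patients flagged excluded in the cohort table are left out. Patients
    with an undefined value for a metric are excluded listwise per metric
    (and logged); a paired contrast with fewer than ``min_pairs`` usable
    pairs is marked not computed.
    """
    analyzed = cohort.analyzed()
    ids = [r.patient_id for r in analyzed if r.patient_id in corrected and r.patient_id in uncorrected]
    dropped = [r.patient_id for r in analyzed if r.patient_id not in ids]
    if dropped:
        logger.info("patients without summaries in both datasets: %s", dropped)
    corr = _summary_frame({i: corrected[i] for i in ids})
    unco = _summary_frame({i: uncorrected[i] for i in ids})
    frames = {"corrected": corr, "uncorrected": unco}
    groups = {g: [i for i in ids if cohort.get(i).diagnosis_group == g] for g in ("UWS", "MCS_EMCS")}
    etio = {g: [i for i in ids if cohort.get(i).etiology == g] for g in ("TBI", "NTBI")}

    paired_rows = []
    for metric in METRIC_NAMES:
        pair = pd.concat([corr[metric], unco[metric]], axis=1, keys=["c", "u"]).dropna()
        if len(pair) < len(ids):
            logger.info(
                "metric %s: %d patients dropped (undefined values)",
                metric,
                len(ids) - len(pair),
            )
        labels = {"contrast": "corrected_vs_uncorrected"}
        if len(pair) < min_pairs:
            paired_rows.append(_not_computed(metric, labels, f"fewer than {min_pairs} usable pairs"))
            continue
        res = wilcoxon_signed_rank(pair["c"], pair["u"], exact=False)
        paired_rows.append(
            _row(
                metric,
                labels,
                res,
                {
                    "median_corrected": float(pair["c"].median()),
                    "median_uncorrected": float(pair["u"].median()),
                },
            )
        )

    diag_rows = []
    for dataset, frame in frames.items():
        for metric in METRIC_NAMES:
            labels = {"contrast": "UWS_vs_MCS_EMCS", "dataset": dataset}
            g1 = frame.loc[frame.index.isin(groups["MCS_EMCS"]), metric].dropna()
            g2 = frame.loc[frame.index.isin(groups["UWS"]), metric].dropna()
            if len(g1) < 3 or len(g2) < 3:
                diag_rows.append(_not_computed(metric, labels, "group too small"))
                continue
            res = mann_whitney_u(g1, g2, exact=False)
            diag_rows.append(
                _row(
                    metric,
                    labels,
                    res,
                    {
                        "median_MCS_EMCS": float(g1.median()),
                        "median_UWS": float(g2.median()),
                    },
                )
            )

    dn_rows = []
    for dataset, frame in frames.items():
        for group_name, members in (("all", ids), ("UWS", groups["UWS"]), ("MCS_EMCS", groups["MCS_EMCS"])):
            sub = frame.loc[frame.index.isin(members), ["mean_day", "mean_night"]].dropna()
            labels = {"contrast": "day_vs_night", "dataset": dataset, "group": group_name}
            if len(sub) < min_pairs:
                dn_rows.append(_not_computed("mean_activity", labels, f"fewer than {min_pairs} usable pairs"))
                continue
            res = wilcoxon_signed_rank(sub["mean_day"], sub["mean_night"], exact=False)
            dn_rows.append(
                _row(
                    "mean_activity",
                    labels,
                    res,
                    {
                        "median_day": float(sub["mean_day"].median()),
                        "median_night": float(sub["mean_night"].median()),
                    },
                )
            )

    etio_rows = []
    for dataset, frame in frames.items():
        for metric in METRIC_NAMES:
            labels = {"contrast": "TBI_vs_NTBI", "dataset": dataset}
            g1 = frame.loc[frame.index.isin(etio["TBI"]), metric].dropna()
            g2 = frame.loc[frame.index.isin(etio["NTBI"]), metric].dropna()
            if len(g1) < 3 or len(g2) < 3:
                etio_rows.append(_not_computed(metric, labels, "group too small"))
                continue
            res = mann_whitney_u(g1, g2, exact=False)
            etio_rows.append(
                _row(
                    metric,
                    labels,
                    res,
                    {"median_TBI": float(g1.median()), "median_NTBI": float(g2.median())},
                )
            )

    crs_rows = []
    subscale_names = sorted(
        {
            name
            for pid in ids
            for name in (cohort.get(pid).crs_r_subscales or {})
        }
    )
    scores: dict[str, dict[str, float]] = {
        "crs_r_sum": {pid: cohort.get(pid).crs_r_sum for pid in ids}
    }
    for name in subscale_names:
        scores[f"crs_r_{name}"] = {
            pid: (cohort.get(pid).crs_r_subscales or {}).get(name, math.nan)
            for pid in ids
        }
    for score_name, per_pid in scores.items():
        for metric in METRIC_NAMES:
            labels = {"contrast": "crs_r_correlation", "dataset": "corrected", "score": score_name}
            joined = pd.DataFrame(
                {"score": pd.Series(per_pid), "metric": corr[metric]}
            ).dropna()
            if len(joined) < 4 or joined["score"].nunique() < 2:
                crs_rows.append(_not_computed(metric, labels, "too few observations"))
                continue
            res = kendall_tau(joined["score"], joined["metric"])
            crs_rows.append(_row(metric, labels, res, {"tau": res.statistic}))

    count_rows = []
    for dataset, frame in frames.items():
        count_rows.append(
            {
                "dataset": dataset,
                "n_circadian": int(frame["is_circadian"].sum()),
                "n_total": int(len(frame)),
                "pct_circadian": 100.0 * frame["is_circadian"].mean() if len(frame) else math.nan,
            }
        )

    return ContrastTables(
        paired_datasets=pd.DataFrame(paired_rows),
        diagnosis=pd.DataFrame(diag_rows),
        day_night=pd.DataFrame(dn_rows),
        etiology=pd.DataFrame(etio_rows),
        crs_r=pd.DataFrame(crs_rows),
        circadian_counts=pd.DataFrame(count_rows),
    )
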