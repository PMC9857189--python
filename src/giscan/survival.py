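"""Kaplan-Meier / log-rank machinery, per-gene univariate screens with
small-arm exclusion rules, and the median-CA125 four-subgroup analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .panel import ClinicalRecord

logger = logging.getLogger(__name__)

DFS = "DFS"
OS = "OS"


@dataclass
class SurvivalOutcome:
    patient_id: str
    time: float  # months
    event: int   # 1 = event observed, 0 = censored
    endpoint: str

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: time must be positive")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0/1")
        if self.endpoint not in (DFS, OS):
            raise ValueError(f"bad endpoint {self.endpoint!r}")


@dataclass
class KmCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    endpoint: str

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float
    group_sizes: dict = field(default_factory=dict)


@dataclass
class Ca125Subgroup:
    label: int          # 1..4
    has_cnv: int
    ca125_high: int
    median_ca125: float


def classify_recurrence(months_to_recurrence: float) -> str:
    """Recurrence within six months of surgery (inclusive) is progression;
    later recurrence is relapse."""
    if months_to_recurrence <= 0:
        raise ValueError("months_to_recurrence must be positive")
    return "progression" if months_to_recurrence <= 6 else "relapse"


def outcomes_from_records(
    records: Sequence[ClinicalRecord], endpoint: str
) -> list[SurvivalOutcome]:
    """Build endpoint outcomes from clinical records.

    Patients lost to OS follow-up (os_months NaN) are dropped from OS
    analyses, not censored at zero.
    """
    out = []
    for r in records:
        if endpoint == DFS:
            if np.isnan(r.dfs_months):
                continue
            out.append(SurvivalOutcome(r.patient_id, r.dfs_months, r.dfs_event, DFS))
        elif endpoint == OS:
            if np.isnan(r.os_months):
                continue
            out.append(SurvivalOutcome(r.patient_id, r.os_months, r.os_event, OS))
        else:
            raise ValueError(f"bad endpoint {endpoint!r}")
    return out


def km_estimate(outcomes: Sequence[SurvivalOutcome]) -> KmCurve:
    """Product-limit estimator; events precede censoring at tied times."""
    if not outcomes:
        raise ValueError("cannot estimate survival from an empty list")
    endpoints = {o.endpoint for o in outcomes}
    if len(endpoints) > 1:
        raise ValueError(f"mixed endpoints {endpoints}")
    times = np.array([o.time for o in outcomes])
    events = np.array([o.event for o in outcomes])
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return KmCurve(
        times=surv.index.values.astype(float),
        survival=surv.values.astype(float),
        at_risk=tab["at_risk"].values.astype(float),
        endpoint=endpoints.pop(),
    )


def logrank_test(
    outcomes: Sequence[SurvivalOutcome],
    groups: Sequence,
) -> LogRankResult:
    """k-sample log-rank test (observed-minus-expected chi-square, df = k-1)."""
    if len(outcomes) != len(groups):
        raise ValueError("outcomes and groups must align")
    labels = pd.Series(list(groups))
    sizes = labels.value_counts().to_dict()
    if len(sizes) < 2:
        raise ValueError("need >= 2 non-empty groups")
    if min(sizes.values()) == 0:
        raise ValueError("a group has zero subjects")
    times = np.array([o.time for o in outcomes])
    events = np.array([o.event for o in outcomes])
    res = multivariate_logrank_test(times, labels.values, events)
    chi = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi):  # no events at all -> no information
        chi, p = 0.0, 1.0
    return LogRankResult(chi_square=chi, df=len(sizes) - 1, p=min(p, 1.0),
                         group_sizes=sizes)


def univariate_gene_screen(
    groups: Mapping[str, int],
    outcomes: Sequence[SurvivalOutcome],
    endpoint: str,
) -> tuple[LogRankResult | None, bool]:
    """Log-rank between carriers (group 1) and non-carriers for one gene.

    Eligibility mirrors the small-arm exclusions: the carrier arm must have
    >= 2 patients for a DFS screen, and >= 1 death for an OS screen.
    Returns (result, eligible); result is None when the test cannot run.
    """
    mismatched = [o for o in outcomes if o.endpoint != endpoint]
    if mismatched:
        raise ValueError(f"outcomes endpoint does not match {endpoint}")
    paired = [(o, groups[o.patient_id]) for o in outcomes if o.patient_id in groups]
    if not paired:
        raise ValueError("no outcomes with matching group labels")
    outs = [o for o, _ in paired]
    labs = [g for _, g in paired]
    n_carriers = sum(labs)
    carrier_events = sum(o.event for o, g in paired if g == 1)
    if endpoint == DFS:
        eligible = n_carriers >= 2
    else:
        eligible = n_carriers >= 1 and carrier_events >= 1
    if n_carriers == 0 or n_carriers == len(labs):
        return None, False
    result = logrank_test(outs, labs)
    return result, eligible


def screen_panel(
    call_table: pd.DataFrame,
    records: Sequence[ClinicalRecord],
    endpoint: str,
) -> pd.DataFrame:
    """Per-gene univariate screen over the whole panel.

    Returns one row per gene: n_carriers, n_carrier_events, chi_square, p,
    eligible, plus an informational Benjamini-Hochberg column (the screen
    itself is uncorrected).
    """
    outcomes = outcomes_from_records(records, endpoint)
    ids = {o.patient_id for o in outcomes}
    rows = []
    for gene, sub in call_table.groupby("gene", sort=False):
        groups = dict(zip(sub["sample_id"].astype(str), sub["group"].astype(int)))
        analyzed = {k: v for k, v in groups.items() if k in ids}
        n_car = sum(analyzed.values())
        ev = {o.patient_id: o.event for o in outcomes}
        n_ev = sum(ev[k] for k, v in analyzed.items() if v == 1)
        try:
            res, eligible = univariate_gene_screen(analyzed, outcomes, endpoint)
        except ValueError:
            res, eligible = None, False
        rows.append({
            "gene": gene,
            "endpoint": endpoint,
            "n_carriers": n_car,
            "n_carrier_events": n_ev,
            "chi_square": res.chi_square if res else np.nan,
            "p": res.p if res else np.nan,
            "eligible": eligible,
        })
    df = pd.DataFrame(rows)
    df["p_bh"] = _benjamini_hochberg(df["p"].values)
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (informational only; NaNs pass through)."""
    p = np.asarray(p, float)
    adj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return adj
    order = np.argsort(p[ok])
    ranked = p[ok][order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(ranked, 1.0)
    adj[ok] = vals
    return adj


def ca125_subgroups(
    groups: Mapping[str, int],
    records: Sequence[ClinicalRecord],
    endpoint: str = DFS,
    median_ca125: float | None = None,
) -> tuple[dict[str, Ca125Subgroup], LogRankResult, dict[tuple[int, int], LogRankResult]]:
    """Median-CA125 x CNV four-subgroup stratification for one gene.

    Labels: 1 = CNV & CA125 > median, 2 = CNV & CA125 <= median,
    3 = no CNV & CA125 > median, 4 = no CNV & CA125 <= median (boundary
    CA125 == median goes to the low arm). Returns per-patient labels, the
    global df = (#arms - 1) log-rank, and uncorrected pairwise tests.
    """
    analyzed = [r for r in records if r.patient_id in groups]
    with_ca = [r for r in analyzed if not np.isnan(r.ca125)]
    dropped = len(analyzed) - len(with_ca)
    if dropped:
        logger.warning("excluding %d patients without CA125", dropped)
    if not with_ca:
        raise ValueError("no patients with CA125 values")
    if median_ca125 is None:
        median_ca125 = float(np.median([r.ca125 for r in with_ca]))

    labels: dict[str, Ca125Subgroup] = {}
    for r in with_ca:
        has_cnv = int(groups[r.patient_id])
        high = int(r.ca125 > median_ca125)
        label = {(1, 1): 1, (1, 0): 2, (0, 1): 3, (0, 0): 4}[(has_cnv, high)]
        labels[r.patient_id] = Ca125Subgroup(label, has_cnv, high, median_ca125)

    outcomes = [o for o in outcomes_from_records(with_ca, endpoint)
                if o.patient_id in labels]
    labs = [labels[o.patient_id].label for o in outcomes]
    present = sorted(set(labs))
    if len(present) < 2:
        raise ValueError("fewer than 2 non-empty subgroup arms")
    overall = logrank_test(outcomes, labs)

    pairwise: dict[tuple[int, int], LogRankResult] = {}
    for a, b in combinations(present, 2):
        sel = [(o, l) for o, l in zip(outcomes, labs) if l in (a, b)]
        if len({l for _, l in sel}) < 2:
            continue
        pairwise[(a, b)] = logrank_test([o for o, _ in sel], [l for _, l in sel])
    return labels, overall, pairwise
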