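"""Kaplan-Meier estimation and log-rank comparison of genotype groups.

Hand-authored implementations of the two standard right-censoring tools a
small clinical follow-up study needs: the product-limit survival curve
with Greenwood standard errors, and the unweighted (Mantel-Cox) log-rank
test for two or more groups.  Deaths tied with censorings at the same
time are processed as events first, the usual convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .panel import CASE, MISSING, GenotypePanel


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int  # 1 = death, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 (censored) or 1 (death)")


@dataclass
class KmCurve:
    """Product-limit curve: S(t) evaluated at the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_se: np.ndarray
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function value of S at time t (1 before the first event)."""
        s = 1.0
        for ti, si in zip(self.times, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p: float


def km_estimate(records: Sequence[SurvivalRecord]) -> KmCurve:
    """Kaplan-Meier estimate S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    The risk set at an event time includes individuals censored at that
    same time (deaths first); Greenwood's formula supplies pointwise
    standard errors.
    """
    if not records:
        raise ValueError("at least one record required")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    n = len(records)

    event_times = np.unique(times[events == 1])
    surv = []
    at_risk = []
    d_list = []
    se_terms = 0.0
    se = []
    s = 1.0
    for t in event_times:
        ni = int(np.sum(times >= t))
        di = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - di / ni
        if ni > di:
            se_terms += di / (ni * (ni - di))
        surv.append(s)
        at_risk.append(ni)
        d_list.append(di)
        se.append(s * math.sqrt(se_terms))
    return KmCurve(
        times=event_times,
        survival=np.array(surv),
        at_risk=np.array(at_risk),
        n_events=np.array(d_list),
        greenwood_se=np.array(se),
        n=n,
    )


def log_rank(groups: Sequence[Sequence[SurvivalRecord]]) -> LogRankResult:
    """Unweighted (Mantel-Cox) log-rank test for >= 2 groups.

    At each distinct event time the observed group event counts are
    compared with their hypergeometric expectations given the risk sets;
    the statistic is the quadratic form of the first g-1 (observed -
    expected) sums in the inverse of their covariance, chi-square with
    g - 1 df under the null.
    """
    groups = [list(g) for g in groups if len(g) > 0]
    g = len(groups)
    if g < 2:
        raise ValueError("log-rank needs at least two non-empty groups")
    times = np.concatenate([[r.time for r in grp] for grp in groups])
    events = np.concatenate([[r.event for r in grp] for grp in groups])
    labels = np.concatenate([[i] * len(grp) for i, grp in enumerate(groups)])
    if events.sum() == 0:
        raise ValueError("log-rank needs at least one event")

    event_times = np.unique(times[events == 1])
    o_minus_e = np.zeros(g)
    cov = np.zeros((g, g))
    for t in event_times:
        at_risk = times >= t
        n_t = int(at_risk.sum())
        d_t = int(((times == t) & (events == 1)).sum())
        if n_t == 0:
            continue
        n_g = np.array([(at_risk & (labels == i)).sum() for i in range(g)], dtype=float)
        d_g = np.array(
            [((times == t) & (events == 1) & (labels == i)).sum() for i in range(g)],
            dtype=float,
        )
        e_g = d_t * n_g / n_t
        o_minus_e += d_g - e_g
        if n_t > 1:
            frac = d_t * (n_t - d_t) / (n_t - 1)
            for i in range(g):
                for j in range(g):
                    delta = 1.0 if i == j else 0.0
                    cov[i, j] += frac * (n_g[i] / n_t) * (delta - n_g[j] / n_t)

    v = o_minus_e[:-1]
    c = cov[:-1, :-1]
    try:
        chi2 = float(v @ np.linalg.solve(c, v))
    except np.linalg.LinAlgError:
        chi2 = float(v @ np.linalg.pinv(c) @ v)
    df = g - 1
    return LogRankResult(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)))


@dataclass
class GenotypeSurvival:
    """KM curves per genotype group at one SNP, plus the log-rank test."""

    snp_id: str
    curves: dict[str, KmCurve]
    records: dict[str, list[SurvivalRecord]]
    test: LogRankResult | None
    notes: list[str] = field(default_factory=list)


def survival_by_genotype(
    panel: GenotypePanel, snp_id: str, censor_cap: float = 60.0
) -> GenotypeSurvival:
    """Case-only KM curves by genotype at one SNP with a log-rank test.

    Administrative censoring at ``censor_cap`` months is applied on top of
    whatever censoring the data carry.  Genotype groups of size zero are
    excluded with a note; when fewer than two groups remain (e.g. a
    monomorphic SNP), curves are reported without a test.
    """
    if panel.survival_time is None:
        raise ValueError("panel has no survival data")
    j = panel.snp_index(snp_id)
    meta = panel.snps[j]
    names = {
        0: meta.allele_major * 2,
        1: meta.allele_major + meta.allele_minor,
        2: meta.allele_minor * 2,
    }
    notes: list[str] = []
    records: dict[str, list[SurvivalRecord]] = {}
    for i in np.flatnonzero(panel.case_mask):
        g = panel.genotypes[i, j]
        if g == MISSING:
            continue
        t = float(panel.survival_time[i])
        if math.isnan(t):
            continue
        e = int(panel.event[i])
        if t > censor_cap:
            t, e = censor_cap, 0
        records.setdefault(names[int(g)], []).append(
            SurvivalRecord(sample_id=panel.samples[i], time=t, event=e, group=names[int(g)])
        )
    for g, label in names.items():
        if label not in records:
            notes.append(f"genotype group {label} empty; excluded")
    curves = {label: km_estimate(recs) for label, recs in records.items()}
    test = None
    if len(records) >= 2 and sum(r.event for recs in records.values() for r in recs) > 0:
        test = log_rank(list(records.values()))
    elif len(records) < 2:
        notes.append("fewer than two genotype groups; log-rank not performed")
    return GenotypeSurvival(
        snp_id=snp_id, curves=curves, records=records, test=test, notes=notes
    )
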