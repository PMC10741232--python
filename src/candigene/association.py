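"""Single-SNP case-control statistics.

Hardy-Weinberg goodness of fit, pooled minor-allele frequency, allelic and
genotypic 2x2 odds ratios with Woolf (log-method) confidence intervals,
Pearson chi-square and Fisher exact tests with the usual expected-count
switch rule, and the normal-approximation power of a two-sample proportion
comparison used when planning a candidate-gene study.

All tests here are the unadjusted 2x2 contingency-table versions used by
small candidate-gene studies; no covariate adjustment and, by default, no
multiple-testing correction (helpers for Bonferroni / Benjamini-Hochberg
are provided for callers who want one).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .panel import MISSING, GenotypePanel

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype class counts for one SNP in one group (dosage order)."""

    n_hom_major: int
    n_het: int
    n_hom_minor: int
    group: str = "pooled"

    def __post_init__(self) -> None:
        if min(self.n_hom_major, self.n_het, self.n_hom_minor) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_hom_major + self.n_het + self.n_hom_minor

    def allele_counts(self) -> "AlleleCounts":
        return AlleleCounts(
            n_major=2 * self.n_hom_major + self.n_het,
            n_minor=2 * self.n_hom_minor + self.n_het,
            group=self.group,
        )


@dataclass(frozen=True)
class AlleleCounts:
    """Major/minor allele counts for one SNP in one group."""

    n_major: int
    n_minor: int
    group: str = "pooled"

    @property
    def n(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg 1-df chi-square goodness-of-fit result."""

    chi2: float
    df: int
    p: float
    maf: float

    @property
    def in_hwe(self) -> bool:
        """True when the test does not reject at alpha = 0.05."""
        return self.p >= 0.05


@dataclass(frozen=True)
class OrEstimate:
    """Odds ratio with a 95% Woolf (log-method) confidence interval."""

    oddsratio: float
    ci_low: float
    ci_high: float
    orientation: str = ""
    continuity_corrected: bool = False


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p: float
    method: Literal["pearson_chi2", "fisher_exact"]


def genotype_counts_from_panel(panel: GenotypePanel, snp_id: str) -> tuple[GenotypeCounts, GenotypeCounts]:
    """(case, control) genotype counts for one SNP, missing excluded."""
    col = panel.column(snp_id)
    out = []
    for mask, name in ((panel.case_mask, "case"), (~panel.case_mask, "control")):
        sub = col[mask]
        sub = sub[sub != MISSING]
        out.append(
            GenotypeCounts(
                n_hom_major=int((sub == 0).sum()),
                n_het=int((sub == 1).sum()),
                n_hom_minor=int((sub == 2).sum()),
                group=name,
            )
        )
    return out[0], out[1]


# --------------------------------------------------------------------------
# Hardy-Weinberg
# --------------------------------------------------------------------------

def hwe_chi_square(counts: GenotypeCounts) -> HweResult:
    """1-df chi-square goodness-of-fit test against HWE proportions.

    Expected counts are n*(p^2, 2pq, q^2) with p the major-allele
    frequency estimated from the counts themselves (hence 1 df for the
    three classes).  A monomorphic SNP fits HWE trivially (chi2 = 0,
    p = 1).
    """
    n = counts.n
    if n <= 0:
        raise ValueError("HWE test requires at least one genotype")
    q = (2 * counts.n_hom_minor + counts.n_het) / (2 * n)
    p = 1.0 - q
    if q == 0.0 or p == 0.0:
        return HweResult(chi2=0.0, df=1, p=1.0, maf=0.0)
    expected = np.array([n * p * p, n * 2 * p * q, n * q * q])
    observed = np.array([counts.n_hom_major, counts.n_het, counts.n_hom_minor], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(
        chi2=chi2,
        df=1,
        p=float(stats.chi2.sf(chi2, 1)),
        maf=min(q, p),
    )


def hwe_exact(counts: GenotypeCounts) -> HweResult:
    """Exact HWE test (conditional on allele counts) for low-count SNPs.

    Sums the probabilities of all heterozygote counts with probability
    <= that of the observed one, conditional on the observed allele
    counts (the standard exact formulation).  Reported alongside the
    chi-square statistic for comparability.
    """
    n = counts.n
    if n <= 0:
        raise ValueError("HWE test requires at least one genotype")
    n_minor = 2 * counts.n_hom_minor + counts.n_het
    chi = hwe_chi_square(counts)
    if n_minor == 0 or n_minor == 2 * n:
        return HweResult(chi2=chi.chi2, df=1, p=1.0, maf=chi.maf)

    def log_prob(n_het: int) -> float:
        n_aa = (n_minor - n_het) // 2
        n_AA = n - n_aa - n_het
        return (
            n_het * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(n_AA + 1)
            - math.lgamma(n_het + 1)
            - math.lgamma(n_aa + 1)
            + math.lgamma(n_minor + 1)
            + math.lgamma(2 * n - n_minor + 1)
            - math.lgamma(2 * n + 1)
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logs = {h: log_prob(h) for h in hets}
    obs = logs[counts.n_het]
    p = sum(math.exp(v) for v in logs.values() if v <= obs + 1e-12)
    return HweResult(chi2=chi.chi2, df=1, p=min(1.0, p), maf=chi.maf)


def pooled_maf(cases: AlleleCounts, controls: AlleleCounts) -> float:
    """Pooled minor-allele frequency over both groups' alleles."""
    total = cases.n + controls.n
    if total == 0:
        raise ValueError("no alleles observed")
    return (cases.n_minor + controls.n_minor) / total


# --------------------------------------------------------------------------
# 2x2 tables
# --------------------------------------------------------------------------

def odds_ratio_woolf(
    table: Sequence[Sequence[float]], orientation: str = ""
) -> OrEstimate:
    """Odds ratio with Woolf's log-interval for a 2x2 table [[a, b], [c, d]].

    OR = (a*d)/(b*c); 95% CI = exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).
    With a zero cell, the Haldane-Anscombe correction (+0.5 to every cell)
    is applied and flagged; with a zero margin the estimate is undefined
    (NaN).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return OrEstimate(math.nan, math.nan, math.nan, orientation)
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OrEstimate(
        oddsratio=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        orientation=orientation,
        continuity_corrected=corrected,
    )


def pearson_chi2_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square (1 df, no continuity correction) for a 2x2 table."""
    (a, b), (c, d) = table
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if 0 in (r1, r2, c1, c2):
        warnings.warn("2x2 table has a zero margin; chi-square undefined, p=1")
        return TestResult(statistic=0.0, p=1.0, method="pearson_chi2")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(
        statistic=float(chi2), p=float(stats.chi2.sf(chi2, 1)), method="pearson_chi2"
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table [[a, b], [c, d]].

    The two-sided p sums, over all tables with the observed margins, the
    hypergeometric probabilities not exceeding that of the observed table
    (with the usual 1+1e-7 relative tolerance against ties lost to
    rounding).
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("Fisher test requires non-negative integer cells")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return TestResult(statistic=None, p=1.0, method="fisher_exact")
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return TestResult(statistic=None, p=min(1.0, p), method="fisher_exact")


def expected_counts_2x2(table: Sequence[Sequence[float]]) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(1), t.sum(0)) / t.sum()


def auto_test_2x2(
    table: Sequence[Sequence[int]], fisher_threshold: float = 5.0
) -> TestResult:
    """Pearson chi-square, switching to Fisher when any expected cell is small.

    The default threshold of 5 is the textbook expected-count rule; it is
    configurable because published candidate-gene reports describe their
    small-sample switch rules loosely.
    """
    if (expected_counts_2x2(table) < fisher_threshold).any():
        return fisher_exact_2x2(table)
    return pearson_chi2_2x2(table)


# --------------------------------------------------------------------------
# per-SNP association
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationRow:
    """One 2x2 contrast: counts, OR with CI, and the selected test."""

    snp_id: str
    model: str
    contrast: str
    case_counts: tuple[int, int]
    control_counts: tuple[int, int]
    or_estimate: OrEstimate
    test: TestResult | None


def allelic_association(
    cases: AlleleCounts, controls: AlleleCounts, snp_id: str = "",
    fisher_threshold: float = 5.0,
) -> AssociationRow:
    """Major-vs-minor allele 2x2 test, case odds in the numerator."""
    table = [
        [cases.n_major, cases.n_minor],
        [controls.n_major, controls.n_minor],
    ]
    return AssociationRow(
        snp_id=snp_id,
        model="allelic",
        contrast="major vs minor allele, cases vs controls",
        case_counts=(cases.n_major, cases.n_minor),
        control_counts=(controls.n_major, controls.n_minor),
        or_estimate=odds_ratio_woolf(table, "odds of major allele, cases/controls"),
        test=auto_test_2x2(table, fisher_threshold) if min(map(sum, table)) > 0 else None,
    )


def genotypic_association(
    cases: GenotypeCounts,
    controls: GenotypeCounts,
    model: Literal["genotype-pairwise", "dominant", "recessive"] = "genotype-pairwise",
    snp_id: str = "",
    fisher_threshold: float = 5.0,
) -> list[AssociationRow]:
    """Genotype-level 2x2 contrasts for one SNP.

    ``genotype-pairwise`` compares the homozygous-major class against the
    heterozygote and against the homozygous-minor class (case odds of the
    first-listed genotype in the numerator); ``dominant`` compares
    minor-allele carriers against homozygous-major; ``recessive`` compares
    homozygous-minor against the rest.  Contrasts whose 2x2 has an empty
    margin (e.g. at a monomorphic SNP) are reported with NA statistics
    rather than dropped.
    """
    ca, co = cases, controls
    contrasts: list[tuple[str, tuple[int, int], tuple[int, int]]] = []
    if model == "genotype-pairwise":
        contrasts = [
            ("hom_major vs het", (ca.n_hom_major, ca.n_het), (co.n_hom_major, co.n_het)),
            ("hom_major vs hom_minor", (ca.n_hom_major, ca.n_hom_minor), (co.n_hom_major, co.n_hom_minor)),
        ]
    elif model == "dominant":
        contrasts = [
            (
                "carrier vs hom_major",
                (ca.n_het + ca.n_hom_minor, ca.n_hom_major),
                (co.n_het + co.n_hom_minor, co.n_hom_major),
            )
        ]
    elif model == "recessive":
        contrasts = [
            (
                "hom_minor vs carrier+hom_major",
                (ca.n_hom_minor, ca.n_hom_major + ca.n_het),
                (co.n_hom_minor, co.n_hom_major + co.n_het),
            )
        ]
    else:
        raise ValueError(f"unknown model {model!r}")

    rows = []
    for label, case_pair, ctrl_pair in contrasts:
        table = [list(case_pair), list(ctrl_pair)]
        est = odds_ratio_woolf(table, f"odds of {label.split(' vs ')[0]}, cases/controls")
        degenerate = any(sum(col) == 0 for col in zip(*table)) or any(
            sum(r) == 0 for r in table
        )
        rows.append(
            AssociationRow(
                snp_id=snp_id,
                model=model,
                contrast=label,
                case_counts=case_pair,
                control_counts=ctrl_pair,
                or_estimate=est,
                test=None if degenerate else auto_test_2x2(table, fisher_threshold),
            )
        )
    return rows


# --------------------------------------------------------------------------
# design power
# --------------------------------------------------------------------------

def power_two_proportions(
    p_control: float, delta: float, n1: int, n2: int, alpha: float = 0.05
) -> float:
    """Normal-approximation power of a two-sided two-sample proportion test.

    ``p_control`` is the allele frequency in group 1 (size ``n1``),
    ``p_control + delta`` the frequency in group 2 (size ``n2``).  Uses the
    pooled-variance null SE (matching the usual chi-square test) and the
    unpooled alternative SE.
    """
    p2 = p_control + delta
    if not (0 < p_control < 1) or not (0 < p2 < 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    p_bar = (n1 * p_control + n2 * p2) / (n1 + n2)
    se0 = math.sqrt(p_bar * (1 - p_bar) * (1 / n1 + 1 / n2))
    se1 = math.sqrt(p_control * (1 - p_control) / n1 + p2 * (1 - p2) / n2)
    z = stats.norm.ppf(1 - alpha / 2)
    upper = stats.norm.cdf((delta - z * se0) / se1)
    lower = stats.norm.cdf((-delta - z * se0) / se1)
    return float(upper + lower)


def adjust_pvalues(pvalues: Iterable[float], method: Literal["bonferroni", "bh"] = "bh") -> list[float]:
    """Optional multiple-testing adjustment (off by default everywhere)."""
    p = np.asarray(list(pvalues), dtype=float)
    m = len(p)
    if m == 0:
        return []
    if method == "bonferroni":
        return list(np.minimum(1.0, p * m))
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(1.0, ranked)
    return list(out)
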