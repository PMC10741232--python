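"""EM haplotype-frequency estimation and pairwise linkage disequilibrium.

Population haplotype frequencies are estimated from unphased genotypes by
plain expectation-maximization over the latent phase: the E-step
distributes each individual over their compatible haplotype pairs with
probability proportional to f(h1)*f(h2) (doubled for heterozygous pairs),
summing over all completions of missing genotypes; the M-step resets the
frequencies to the expected haplotype counts over 2N chromosomes.  At
candidate-gene scale (blocks of 2-4 SNPs, at most 16 haplotypes) no
partition-ligation staging or restarts are needed; the likelihood surface
is small and the EM monotonicity guarantee is asserted in tests.

Pairwise LD statistics (D, D', r^2) are derived from the two-locus
haplotype frequencies the same EM produces.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .association import pearson_chi2_2x2
from .panel import CASE, MISSING, GenotypePanel

GroupFilter = Literal["pooled", "case", "control"]


@dataclass
class EmResult:
    """Estimated haplotype frequencies for one block.

    ``haplotypes`` are allele strings in block-SNP order; ``loglik_trace``
    records the observed-data log-likelihood after every iteration (it is
    non-decreasing, an EM invariant).
    """

    block: tuple[str, ...]
    haplotypes: tuple[str, ...]
    frequencies: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_individuals: int
    loglik_trace: list[float] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {h: float(f) for h, f in zip(self.haplotypes, self.frequencies)}


@dataclass(frozen=True)
class HaplotypeAssoc:
    haplotype: str
    freq_pooled: float
    freq_case: float
    freq_control: float
    chi2: float
    p: float


@dataclass(frozen=True)
class LdResult:
    """Pairwise LD between two SNPs; ``defined`` is False at monomorphic pairs."""

    snp_a: str
    snp_b: str
    d: float
    d_prime: float
    r2: float
    defined: bool = True


class EstimationError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# EM core
# --------------------------------------------------------------------------

def _select_group(panel: GenotypePanel, group: GroupFilter) -> np.ndarray:
    if group == "pooled":
        return np.ones(panel.n_samples, dtype=bool)
    if group == "case":
        return panel.case_mask
    if group == "control":
        return ~panel.case_mask
    raise ValueError(f"unknown group filter {group!r}")


def _compatible_pairs(
    pattern: tuple[int, ...], m: int
) -> list[tuple[int, int]]:
    """Unordered haplotype-index pairs compatible with a genotype pattern.

    Haplotype index bit j is the allele (0 = major, 1 = minor) at block
    SNP j.  Missing entries (MISSING) are compatible with anything.
    """
    pairs = []
    for h1 in range(2**m):
        for h2 in range(h1, 2**m):
            ok = True
            for j in range(m):
                g = pattern[j]
                if g == MISSING:
                    continue
                if ((h1 >> j) & 1) + ((h2 >> j) & 1) != g:
                    ok = False
                    break
            if ok:
                pairs.append((h1, h2))
    return pairs


def em_haplotype_freqs(
    panel: GenotypePanel,
    block: Sequence[str],
    group: GroupFilter = "pooled",
    tol: float = 1e-10,
    max_iter: int = 1000,
    max_missing: int = 2,
) -> EmResult:
    """EM estimate of haplotype frequencies for a block of 2-4 SNPs.

    Individuals with more than ``max_missing`` missing genotypes in the
    block are excluded; the rest contribute through all compatible
    completions.  Frequencies are initialised at allele-frequency products
    (the linkage-equilibrium point) and iterated until the largest
    frequency change drops below ``tol`` or ``max_iter`` is reached.
    """
    block = tuple(block)
    if not 2 <= len(block) <= 4:
        raise ValueError("block size must be 2-4 SNPs")
    m = len(block)
    idx = [panel.snp_index(s) for s in block]
    sel = _select_group(panel, group)
    geno = panel.genotypes[np.ix_(np.flatnonzero(sel), np.array(idx))]
    n_missing = (geno == MISSING).sum(axis=1)
    geno = geno[n_missing <= max_missing]
    # drop individuals with nothing observed at all
    geno = geno[(geno != MISSING).any(axis=1)]
    n = geno.shape[0]
    if n == 0:
        raise EstimationError(f"no usable individuals for block {block} in group {group!r}")

    patterns, counts = np.unique(geno, axis=0, return_counts=True)
    pair_sets = [_compatible_pairs(tuple(p), m) for p in patterns]

    # init: product of observed allele frequencies
    freq_minor = np.empty(m)
    for j in range(m):
        col = geno[:, j]
        ok = col != MISSING
        freq_minor[j] = col[ok].sum() / (2 * ok.sum()) if ok.any() else 0.0
    nh = 2**m
    f = np.empty(nh)
    for h in range(nh):
        prob = 1.0
        for j in range(m):
            prob *= freq_minor[j] if (h >> j) & 1 else 1 - freq_minor[j]
        f[h] = prob
    f = np.maximum(f, 1e-12)
    f /= f.sum()

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        expected = np.zeros(nh)
        loglik = 0.0
        for pat_i, pairs in enumerate(pair_sets):
            w = np.array([(2.0 if h1 != h2 else 1.0) * f[h1] * f[h2] for h1, h2 in pairs])
            total = w.sum()
            if total <= 0:
                continue
            loglik += counts[pat_i] * np.log(total)
            w *= counts[pat_i] / total
            for (h1, h2), wi in zip(pairs, w):
                expected[h1] += wi
                expected[h2] += wi
        new_f = expected / (2.0 * n)
        trace.append(float(loglik))
        delta = np.abs(new_f - f).max()
        f = new_f
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"haplotype EM did not converge in {max_iter} iterations")

    # allele strings in block order
    labels = []
    metas = [panel.snps[i] for i in idx]
    for h in range(nh):
        labels.append(
            "".join(
                metas[j].allele_minor if (h >> j) & 1 else metas[j].allele_major
                for j in range(m)
            )
        )
    return EmResult(
        block=block,
        haplotypes=tuple(labels),
        frequencies=f,
        loglik=trace[-1] if trace else float("nan"),
        n_iter=it,
        converged=converged,
        n_individuals=n,
        loglik_trace=trace,
    )


def haplotype_association(
    panel: GenotypePanel,
    block: Sequence[str],
    min_freq: float = 0.001,
    **em_kwargs,
) -> list[HaplotypeAssoc]:
    """Per-haplotype case/control chi-square using group-wise EM estimates.

    For each haplotype above ``min_freq`` pooled frequency, a 2x2 Pearson
    chi-square compares expected haplotype counts (group frequency times
    2n chromosomes) of this haplotype against all others between cases
    and controls.  Rows are sorted by descending pooled frequency, the
    layout haplotype tables are conventionally printed in.
    """
    pooled = em_haplotype_freqs(panel, block, group="pooled", **em_kwargs)
    case = em_haplotype_freqs(panel, block, group="case", **em_kwargs)
    control = em_haplotype_freqs(panel, block, group="control", **em_kwargs)
    n_case_chrom = 2 * case.n_individuals
    n_ctrl_chrom = 2 * control.n_individuals
    fc, fo = case.as_dict(), control.as_dict()
    rows = []
    for h, f_pool in pooled.as_dict().items():
        if f_pool < min_freq:
            continue
        f_case, f_ctrl = fc.get(h, 0.0), fo.get(h, 0.0)
        table = [
            [f_case * n_case_chrom, (1 - f_case) * n_case_chrom],
            [f_ctrl * n_ctrl_chrom, (1 - f_ctrl) * n_ctrl_chrom],
        ]
        test = pearson_chi2_2x2(table)
        rows.append(
            HaplotypeAssoc(
                haplotype=h,
                freq_pooled=f_pool,
                freq_case=f_case,
                freq_control=f_ctrl,
                chi2=test.statistic,
                p=test.p,
            )
        )
    rows.sort(key=lambda r: -r.freq_pooled)
    return rows


# --------------------------------------------------------------------------
# pairwise LD
# --------------------------------------------------------------------------

def ld_from_haplotype_freqs(
    p_ab: float, p_a: float, p_b: float
) -> tuple[float, float, float]:
    """(D, D', r^2) from the major-major haplotype and allele frequencies.

    D = p_AB - p_A p_B.  D' = |D| / D_max with
    D_max = min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B) for
    D < 0 (q = 1 - p); r^2 = D^2 / (p_A q_A p_B q_B).
    """
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    d = p_ab - p_a * p_b
    denom = p_a * q_a * p_b * q_b
    if denom <= 0:
        raise ValueError("LD undefined for a monomorphic locus")
    r2 = d * d / denom
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, q_a * q_b)
    else:
        return 0.0, 0.0, 0.0
    return d, abs(d) / d_max, r2


def pairwise_ld(
    panel: GenotypePanel,
    snp_a: str,
    snp_b: str,
    group: GroupFilter = "pooled",
    **em_kwargs,
) -> LdResult:
    """Pairwise D / D' / r^2 via EM two-locus haplotype frequencies."""
    em = em_haplotype_freqs(panel, (snp_a, snp_b), group=group, **em_kwargs)
    f = em.frequencies  # index bit 0 -> snp_a allele, bit 1 -> snp_b allele
    p_ab = f[0]                      # major at both
    p_a = f[0] + f[2]                # major at snp_a
    p_b = f[0] + f[1]                # major at snp_b
    try:
        d, d_prime, r2 = ld_from_haplotype_freqs(float(p_ab), float(p_a), float(p_b))
    except ValueError as exc:
        raise EstimationError(f"{snp_a}/{snp_b}: {exc}") from exc
    return LdResult(snp_a=snp_a, snp_b=snp_b, d=d, d_prime=d_prime, r2=r2)


def ld_matrix(
    panel: GenotypePanel, snps: Sequence[str] | None = None, group: GroupFilter = "pooled"
) -> list[LdResult]:
    """All pairwise LD results (upper triangle); undefined pairs flagged."""
    snps = list(snps) if snps is not None else panel.snp_ids
    if len(snps) < 2:
        raise ValueError("LD matrix needs at least two SNPs")
    out = []
    for a, b in itertools.combinations(snps, 2):
        try:
            out.append(pairwise_ld(panel, a, b, group=group))
        except EstimationError:
            out.append(
                LdResult(snp_a=a, snp_b=b, d=float("nan"), d_prime=float("nan"),
                         r2=float("nan"), defined=False)
            )
    return out
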