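"""Genotype panel data model.

A :class:`GenotypePanel` is the in-memory container every analysis stage
consumes: a samples x SNPs matrix of minor-allele dosage codes (0, 1, 2,
or :data:`MISSING`), a case/control label per sample, SNP metadata, and
optional right-censored survival fields for the cases.

Coding convention
-----------------
Genotypes are stored as the count of minor alleles, with the minor allele
decided on the pooled (cases + controls) sample and ties broken
lexicographically (the lexicographically smaller allele is taken as major).
Missing genotypes keep a distinct sentinel and are never imputed here; each
downstream statistic defines its own handling, because per-SNP call rates
legitimately differ in candidate-gene panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

#: Sentinel for an uncalled genotype.
MISSING: int = -1

#: Phenotype codes used throughout the package.
CONTROL, CASE = 0, 1


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP.

    Parameters
    ----------
    snp_id : str
        Marker identifier (e.g. an rs number); unique within a panel.
    chromosome : str
        Chromosome label as given (no normalisation).
    position : int
        1-based base-pair coordinate.
    allele_major : str
        Single-character major allele (pooled-sample orientation).
    allele_minor : str
        Single-character minor allele; ``"."`` when the site is
        monomorphic and the second allele is unknown.
    """

    snp_id: str
    chromosome: str = "0"
    position: int = 1
    allele_major: str = "A"
    allele_minor: str = "B"

    def __post_init__(self) -> None:
        if self.allele_major == self.allele_minor:
            raise ValueError(
                f"{self.snp_id}: major and minor allele must differ "
                f"(both {self.allele_major!r})"
            )
        if self.position <= 0:
            raise ValueError(f"{self.snp_id}: position must be positive")


@dataclass
class GenotypePanel:
    """Samples x SNPs panel of dosage-coded biallelic genotypes.

    ``genotypes[i, j]`` is the minor-allele dosage of sample ``i`` at SNP
    ``j`` (0/1/2) or :data:`MISSING`.  ``phenotype`` holds
    :data:`CASE`/:data:`CONTROL` codes.  ``survival_time`` (months) and
    ``event`` (1 = death, 0 = censored) are either both absent or both
    arrays over all samples (entries for controls may be NaN / 0).
    """

    snps: list[SnpMeta]
    samples: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    survival_time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"genotype matrix is {n}x{m} but panel has "
                f"{len(self.samples)} samples and {len(self.snps)} SNPs"
            )
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype must be defined for every sample")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.genotypes[i, j]} for sample "
                f"{self.samples[i]!r} at SNP {self.snps[j].snp_id!r}"
            )
        if not np.isin(self.phenotype, (CASE, CONTROL)).all():
            raise ValueError("phenotype codes must be 0 (control) or 1 (case)")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in panel")
        if (self.survival_time is None) != (self.event is None):
            raise ValueError("survival_time and event must be given together")
        if self.survival_time is not None:
            self.survival_time = np.asarray(self.survival_time, dtype=float)
            self.event = np.asarray(self.event, dtype=np.int8)
            if self.survival_time.shape != (n,) or self.event.shape != (n,):
                raise ValueError("survival fields must cover every sample")
            if np.nanmin(self.survival_time) < 0:
                raise ValueError("survival times must be non-negative")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def n_cases(self) -> int:
        return int(self.case_mask.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.case_mask).sum())

    def snp_index(self, snp_id: str) -> int:
        for j, s in enumerate(self.snps):
            if s.snp_id == snp_id:
                return j
        raise KeyError(f"SNP {snp_id!r} not in panel")

    def column(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP (copy)."""
        return self.genotypes[:, self.snp_index(snp_id)].copy()

    def subset_samples(self, index: np.ndarray) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            snps=list(self.snps),
            samples=[self.samples[i] for i in np.atleast_1d(index)],
            genotypes=self.genotypes[index],
            phenotype=self.phenotype[index],
            survival_time=None if self.survival_time is None else self.survival_time[index],
            event=None if self.event is None else self.event[index],
        )

    def cases(self) -> "GenotypePanel":
        return self.subset_samples(np.flatnonzero(self.case_mask))

    def controls(self) -> "GenotypePanel":
        return self.subset_samples(np.flatnonzero(~self.case_mask))

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(
            snps=list(self.snps),
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            phenotype=self.phenotype.copy(),
            survival_time=None if self.survival_time is None else self.survival_time.copy(),
            event=None if self.event is None else self.event.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        surv_eq = (self.survival_time is None) == (other.survival_time is None)
        if surv_eq and self.survival_time is not None:
            surv_eq = np.allclose(
                self.survival_time, other.survival_time, equal_nan=True
            ) and np.array_equal(self.event, other.event)
        return (
            self.snps == other.snps
            and self.samples == other.samples
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and surv_eq
        )


@dataclass(frozen=True)
class CohortSummary:
    """Per-panel summary: group sizes plus per-SNP call rate and pooled MAF."""

    n_cases: int
    n_controls: int
    call_rate: dict[str, float]
    maf: dict[str, float]


def summarize_panel(panel: GenotypePanel) -> CohortSummary:
    """Summarise a panel: group sizes, per-SNP call rate and pooled MAF.

    The MAF is computed over the pooled non-missing alleles of both groups.
    If the stored "minor" allele in fact exceeds 0.5 in this sample the
    frequency is folded so that 0 <= maf <= 0.5.  An entirely missing SNP
    has call rate 0 and MAF 0 (a monomorphic SNP also gives MAF 0; neither
    is an error).
    """
    if panel.n_samples == 0 or panel.n_snps == 0:
        raise ValueError("cannot summarise an empty panel")
    call_rate: dict[str, float] = {}
    maf: dict[str, float] = {}
    for j, snp in enumerate(panel.snps):
        col = panel.genotypes[:, j]
        ok = col != MISSING
        call_rate[snp.snp_id] = float(ok.mean())
        n_alleles = 2 * int(ok.sum())
        if n_alleles == 0:
            maf[snp.snp_id] = 0.0
            continue
        q = float(col[ok].sum()) / n_alleles
        maf[snp.snp_id] = min(q, 1.0 - q)
    return CohortSummary(
        n_cases=panel.n_cases,
        n_controls=panel.n_controls,
        call_rate=call_rate,
        maf=maf,
    )


#: Genotype-count keys accepted by :func:`panel_from_marginal_counts`, in
#: dosage order: homozygous major, heterozygote, homozygous minor.
GENOTYPE_ORDER = ("hom_major", "het", "hom_minor")


def panel_from_marginal_counts(
    counts: Mapping[str, Mapping[str, Sequence[int]]],
    n_cases: int,
    n_controls: int,
    snps: Sequence[SnpMeta] | None = None,
    seed: int = 0,
) -> GenotypePanel:
    """Reconstruct an individual-level panel from per-SNP genotype counts.

    Published case-control tables report, per SNP and group, the counts of
    the three genotype classes — but not the joint genotypes across SNPs.
    This builder returns a panel whose per-SNP, per-group genotype counts
    equal the input *exactly*; the joint assignment across SNPs is an
    arbitrary but seed-deterministic shuffle.  Samples beyond a SNP's
    per-group total are set :data:`MISSING` there, which reproduces the
    varying per-SNP denominators of real genotyping tables.

    Parameters
    ----------
    counts
        ``{snp_id: {"case": (n0, n1, n2), "control": (n0, n1, n2)}}`` with
        genotype counts in dosage order (hom-major, het, hom-minor).
    n_cases, n_controls
        Group sizes; each SNP/group total must not exceed its group size.
    snps
        Optional metadata per SNP id; defaults to placeholder alleles.
    seed
        Seed for the per-SNP shuffles.
    """
    rng = np.random.default_rng(seed)
    snp_meta: list[SnpMeta] = []
    meta_by_id = {s.snp_id: s for s in snps} if snps else {}
    for snp_id in counts:
        snp_meta.append(meta_by_id.get(snp_id, SnpMeta(snp_id=snp_id)))

    samples = [f"ctrl{i + 1:04d}" for i in range(n_controls)] + [
        f"case{i + 1:04d}" for i in range(n_cases)
    ]
    phenotype = np.r_[
        np.full(n_controls, CONTROL, dtype=np.int8),
        np.full(n_cases, CASE, dtype=np.int8),
    ]
    geno = np.full((n_controls + n_cases, len(snp_meta)), MISSING, dtype=np.int8)

    group_slices = {"control": slice(0, n_controls), "case": slice(n_controls, None)}
    group_sizes = {"control": n_controls, "case": n_cases}
    for j, snp in enumerate(snp_meta):
        for group, triple in counts[snp.snp_id].items():
            if group not in group_slices:
                raise ValueError(f"unknown group {group!r} (use 'case'/'control')")
            triple = tuple(int(x) for x in triple)
            if any(x < 0 for x in triple):
                raise ValueError(f"{snp.snp_id}/{group}: negative genotype count")
            total = sum(triple)
            if total > group_sizes[group]:
                raise ValueError(
                    f"{snp.snp_id}/{group}: counts sum to {total} but the "
                    f"group has only {group_sizes[group]} samples"
                )
            codes = np.full(group_sizes[group], MISSING, dtype=np.int8)
            codes[:total] = np.repeat([0, 1, 2], triple)
            rng.shuffle(codes)
            geno[group_slices[group], j] = codes

    return GenotypePanel(
        snps=snp_meta, samples=samples, genotypes=geno, phenotype=phenotype
    )
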