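"""Bundled summary counts from a published ghrelin-system prostate-cancer study.

A published case-control study of six SNPs in the ghrelin gene (*GHRL*)
and its receptor (*GHSR*) — 120 prostate-cancer patients, 95 controls —
reports per-SNP genotype counts but no individual-level data.  Those
printed genotype counts are embedded here as inputs: the fixture builder
reconstructs an individual-level panel whose per-SNP, per-group counts
match them exactly, and :func:`reproduce_published_tables` re-derives the
study's association tables (HWE chi-square, pooled MAF, allelic and
genotypic odds ratios with Woolf CIs, chi-square / Fisher p-values)
through this package's own pipeline.  Statistics that require joint
genotypes across SNPs (haplotype frequencies, LD, MDR accuracies) cannot
be recomputed from marginals and are deliberately absent.

Two garbled rows in the published genotype table (rs572169, rs2948694)
were reconstructed from the study's allele-count table, which they
reproduce exactly; see ``GENOTYPE_COUNTS`` comments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import (
    allelic_association,
    fisher_exact_2x2,
    genotype_counts_from_panel,
    genotypic_association,
    hwe_chi_square,
    pooled_maf,
)
from .panel import GenotypePanel, SnpMeta, panel_from_marginal_counts, summarize_panel

N_CASES = 120
N_CONTROLS = 95

#: SNP metadata: chromosome arm, position, and the major/minor alleles as
#: observed in the study population.
SNP_META = [
    SnpMeta("rs4684677", "3", 10286769, "A", "G"),
    SnpMeta("rs696217", "3", 10289773, "G", "T"),
    SnpMeta("rs34911341", "3", 10289835, "C", "T"),
    SnpMeta("rs2948694", "3", 172447373, "A", "G"),
    SnpMeta("rs572169", "3", 172447937, "C", "T"),
    SnpMeta("rs2922126", "3", 172449471, "A", "T"),
]

#: Genes of the panel, in marker order used by haplotype tables.
GENE_BLOCKS = {
    "GHRL": ("rs34911341", "rs696217", "rs4684677"),
    "GHSR": ("rs2922126", "rs572169", "rs2948694"),
}

#: Published per-SNP genotype counts (hom-major, het, hom-minor) per group.
#: rs572169 and rs2948694 rows are reconstructed from the allele table
#: (C/T 118/42 and 147/57; A/G 167/3 and 229/9), which they match exactly.
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "rs34911341": {"control": (85, 0, 0), "case": (100, 0, 0)},
    "rs696217": {"control": (54, 30, 0), "case": (61, 46, 0)},
    "rs4684677": {"control": (85, 1, 0), "case": (103, 1, 0)},
    "rs2922126": {"control": (31, 56, 0), "case": (36, 78, 6)},
    "rs572169": {"control": (38, 42, 0), "case": (45, 57, 0)},
    "rs2948694": {"control": (82, 3, 0), "case": (110, 9, 0)},
}


def build_study_panel(seed: int = 0) -> GenotypePanel:
    """Individual-level panel matching every published marginal count.

    The joint assignment across SNPs is an arbitrary seed-deterministic
    shuffle (the study deposited no raw data), so single-SNP statistics
    are exact while cross-SNP statistics are not meaningful on this panel.
    """
    return panel_from_marginal_counts(
        {s.snp_id: GENOTYPE_COUNTS[s.snp_id] for s in SNP_META},
        n_cases=N_CASES,
        n_controls=N_CONTROLS,
        snps=SNP_META,
        seed=seed,
    )


def reproduce_published_tables(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Re-derive the study's single-SNP tables from the embedded counts.

    Returns DataFrames ``hwe`` (per-group chi-square, p, MAF and the
    pooled MAF), ``allelic`` (major-vs-minor OR, Woolf CI, test p) and
    ``genotypic`` (per-genotype contrasts: het and hom-minor vs hom-major,
    dominant carrier, recessive).  Monomorphic contrasts are emitted with
    NA statistics rather than dropped.
    """
    panel = build_study_panel(seed)
    summary = summarize_panel(panel)

    hwe_rows = []
    allelic_rows = []
    genotypic_rows = []
    for meta in SNP_META:
        snp = meta.snp_id
        case_g, ctrl_g = genotype_counts_from_panel(panel, snp)
        for grp, counts in (("control", ctrl_g), ("case", case_g)):
            if counts.n == 0:
                continue
            res = hwe_chi_square(counts)
            hwe_rows.append(
                {
                    "snp": snp,
                    "group": grp,
                    "n": counts.n,
                    "chi2": res.chi2 if res.maf > 0 else float("nan"),
                    "p": res.p if res.maf > 0 else float("nan"),
                    "maf": res.maf,
                    "in_hwe": "yes" if res.in_hwe else "no",
                }
            )
        maf = pooled_maf(case_g.allele_counts(), ctrl_g.allele_counts())
        row = allelic_association(
            case_g.allele_counts(), ctrl_g.allele_counts(), snp_id=snp
        )
        allelic_rows.append(
            {
                "snp": snp,
                "case_major": row.case_counts[0],
                "case_minor": row.case_counts[1],
                "control_major": row.control_counts[0],
                "control_minor": row.control_counts[1],
                "pooled_maf": maf,
                "OR": row.or_estimate.oddsratio,
                "CI_low": row.or_estimate.ci_low,
                "CI_high": row.or_estimate.ci_high,
                "method": row.test.method if row.test else "NA",
                "p": row.test.p if row.test else float("nan"),
            }
        )
        for model in ("genotype-pairwise", "dominant", "recessive"):
            for contrast in genotypic_association(case_g, ctrl_g, model=model, snp_id=snp):
                genotypic_rows.append(
                    {
                        "snp": snp,
                        "model": model,
                        "contrast": contrast.contrast,
                        "case_counts": "/".join(map(str, contrast.case_counts)),
                        "control_counts": "/".join(map(str, contrast.control_counts)),
                        "OR": contrast.or_estimate.oddsratio,
                        "CI_low": contrast.or_estimate.ci_low,
                        "CI_high": contrast.or_estimate.ci_high,
                        "method": contrast.test.method if contrast.test else "NA",
                        "p": contrast.test.p if contrast.test else float("nan"),
                    }
                )

    return {
        "hwe": pd.DataFrame(hwe_rows),
        "allelic": pd.DataFrame(allelic_rows),
        "genotypic": pd.DataFrame(genotypic_rows),
    }


def tt_genotype_fisher_p() -> float:
    """Fisher exact p for the homozygous-minor excess at the promoter SNP.

    The study's one nominally significant genotype finding: 6/120 patients
    vs 0/87 typed controls carry the T/T genotype at rs2922126.  (The
    recessive contrast of :func:`reproduce_published_tables` computes the
    same table; this helper exposes it directly.)
    """
    case = GENOTYPE_COUNTS["rs2922126"]["case"]
    ctrl = GENOTYPE_COUNTS["rs2922126"]["control"]
    table = [
        [case[2], case[0] + case[1]],
        [ctrl[2], ctrl[0] + ctrl[1]],
    ]
    return fisher_exact_2x2(table).p
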