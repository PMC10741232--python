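"""Readers and writers for genotype panels and analysis reports.

Two text formats are supported:

* PLINK-style PED/MAP (whitespace-separated, ``0`` = missing allele,
  phenotype column 1 = control / 2 = case);
* a simple CSV genotype matrix with header
  ``sample_id,phenotype[,time,event],<snp>,...`` where genotype cells are
  two-letter strings (``"GT"``) or ``NA``.

Both readers recode raw alleles to minor-allele dosage with the minor
allele decided on the pooled sample (ties broken lexicographically:
the smaller allele becomes major), so the coding is stable under any
relabelling of the input allele columns.
"""

from __future__ import annotations

import csv
import json
import math
import os
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import CASE, CONTROL, MISSING, GenotypePanel, SnpMeta


class ParseError(ValueError):
    """Raised for malformed genotype input files."""


# --------------------------------------------------------------------------
# allele recoding
# --------------------------------------------------------------------------

def _orient_alleles(pairs: Sequence[tuple[str, str] | None], snp_id: str) -> tuple[str, str]:
    """Decide (major, minor) from observed allele pairs of one SNP.

    Ties in pooled frequency are broken lexicographically (smaller allele
    taken as major).  Monomorphic sites get minor ``"."``.
    """
    tally: Counter[str] = Counter()
    for pair in pairs:
        if pair is not None:
            tally.update(pair)
    alleles = sorted(tally)
    if len(alleles) > 2:
        raise ParseError(f"SNP {snp_id!r} has >2 distinct alleles: {alleles}")
    if not alleles:
        return "A", "."
    if len(alleles) == 1:
        return alleles[0], "."
    a, b = alleles  # a < b lexicographically
    if tally[a] == tally[b]:
        return a, b
    return (a, b) if tally[a] > tally[b] else (b, a)


def _dosage(pair: tuple[str, str] | None, minor: str) -> int:
    if pair is None:
        return MISSING
    return (pair[0] == minor) + (pair[1] == minor)


def _recode_columns(
    raw: list[list[tuple[str, str] | None]],
    snp_ids: Sequence[str],
    chrom: Sequence[str] | None = None,
    pos: Sequence[int] | None = None,
) -> tuple[list[SnpMeta], np.ndarray]:
    """Recode per-SNP allele-pair columns into SnpMeta + dosage matrix."""
    n = len(raw[0]) if raw else 0
    geno = np.full((n, len(snp_ids)), MISSING, dtype=np.int8)
    metas: list[SnpMeta] = []
    for j, snp_id in enumerate(snp_ids):
        major, minor = _orient_alleles(raw[j], snp_id)
        metas.append(
            SnpMeta(
                snp_id=snp_id,
                chromosome=chrom[j] if chrom else "0",
                position=pos[j] if pos else j + 1,
                allele_major=major,
                allele_minor=minor,
            )
        )
        geno[:, j] = [_dosage(p, minor) for p in raw[j]]
    return metas, geno


def _parse_phenotype(code: str, where: str) -> int:
    if code == "1":
        return CONTROL
    if code == "2":
        return CASE
    raise ParseError(
        f"{where}: unknown phenotype code {code!r} (expected 1=control, 2=case)"
    )


# --------------------------------------------------------------------------
# PED / MAP
# --------------------------------------------------------------------------

def read_ped_map(ped_path: str, map_path: str) -> GenotypePanel:
    """Read a PLINK-style PED/MAP pair into a :class:`GenotypePanel`.

    MAP lines: ``chrom snp_id cM position``.  PED lines: six leading
    fields (family, individual, father, mother, sex, phenotype) then two
    allele columns per SNP; ``0`` denotes a missing allele and a
    half-missing genotype is treated as missing.
    """
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected >=4 fields")
            chrom.append(fields[0])
            snp_ids.append(fields[1])
            pos.append(int(fields[3]))

    m = len(snp_ids)
    samples: list[str] = []
    phen: list[int] = []
    raw: list[list[tuple[str, str] | None]] = [[] for _ in range(m)]
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields for "
                    f"{m} SNPs, got {len(fields)}"
                )
            samples.append(fields[1])
            phen.append(_parse_phenotype(fields[5], f"{ped_path}:{lineno}"))
            for j in range(m):
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                raw[j].append(None if "0" in (a, b) else (a, b))

    metas, geno = _recode_columns(raw, snp_ids, chrom, pos)
    return GenotypePanel(
        snps=metas,
        samples=samples,
        genotypes=geno,
        phenotype=np.array(phen, dtype=np.int8),
    )


def write_ped_map(panel: GenotypePanel, ped_path: str, map_path: str) -> None:
    """Write a panel as a PED/MAP pair (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for s in panel.snps:
            fh.write(f"{s.chromosome}\t{s.snp_id}\t0\t{s.position}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(panel.samples):
            phen = "2" if panel.phenotype[i] == CASE else "1"
            fields = [sid, sid, "0", "0", "0", phen]
            for j, s in enumerate(panel.snps):
                g = panel.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [s.allele_major, s.allele_major]
                elif g == 1:
                    fields += [s.allele_major, s.allele_minor]
                else:
                    fields += [s.allele_minor, s.allele_minor]
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# CSV genotype matrix
# --------------------------------------------------------------------------

def read_genotype_table(csv_path: str) -> GenotypePanel:
    """Read the CSV genotype-matrix dialect.

    Header: ``sample_id,phenotype[,time,event],<snp1>,<snp2>,...``; the
    phenotype column holds ``1`` (control) / ``2`` (case); genotype cells
    are two-letter allele strings or ``NA``; an optional ``time``/``event``
    pair carries survival months and death flag (1 = death, 0 = censored).
    Column order is preserved as panel SNP order.
    """
    with open(csv_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["sample_id", "phenotype"]:
            raise ParseError(
                f"{csv_path}: header must start with sample_id,phenotype"
            )
        has_surv = header[2:4] == ["time", "event"]
        snp_ids = header[4:] if has_surv else header[2:]
        samples: list[str] = []
        phen: list[int] = []
        times: list[float] = []
        events: list[int] = []
        raw: list[list[tuple[str, str] | None]] = [[] for _ in snp_ids]
        for lineno, row in enumerate(reader, 2):
            if not row:
                continue
            if len(row) != len(header):
                raise ParseError(f"{csv_path}:{lineno}: ragged row")
            samples.append(row[0])
            phen.append(_parse_phenotype(row[1], f"{csv_path}:{lineno}"))
            if has_surv:
                times.append(float("nan") if row[2] in ("", "NA") else float(row[2]))
                events.append(0 if row[3] in ("", "NA") else int(row[3]))
            cells = row[4:] if has_surv else row[2:]
            for j, cell in enumerate(cells):
                if cell in ("NA", ""):
                    raw[j].append(None)
                elif len(cell) == 2:
                    raw[j].append((cell[0], cell[1]))
                else:
                    raise ParseError(
                        f"{csv_path}:{lineno}: bad genotype {cell!r} in "
                        f"column {snp_ids[j]!r}"
                    )

    # per-SNP allele sanity: at most two distinct letters (checked in recode)
    metas, geno = _recode_columns(raw, snp_ids)
    return GenotypePanel(
        snps=metas,
        samples=samples,
        genotypes=geno,
        phenotype=np.array(phen, dtype=np.int8),
        survival_time=np.array(times) if has_surv else None,
        event=np.array(events, dtype=np.int8) if has_surv else None,
    )


def write_genotype_table(panel: GenotypePanel, csv_path: str) -> None:
    """Write a panel in the CSV genotype-matrix dialect."""
    has_surv = panel.survival_time is not None
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        head = ["sample_id", "phenotype"]
        if has_surv:
            head += ["time", "event"]
        writer.writerow(head + panel.snp_ids)
        for i, sid in enumerate(panel.samples):
            row = [sid, "2" if panel.phenotype[i] == CASE else "1"]
            if has_surv:
                t = panel.survival_time[i]
                row += ["NA" if math.isnan(t) else f"{t:g}", str(int(panel.event[i]))]
            for j, s in enumerate(panel.snps):
                g = panel.genotypes[i, j]
                if g == MISSING:
                    cell = "NA"
                elif g == 0:
                    cell = s.allele_major * 2
                elif g == 1:
                    cell = s.allele_major + s.allele_minor
                else:
                    cell = s.allele_minor * 2
                row.append(cell)
            writer.writerow(row)


# --------------------------------------------------------------------------
# report bundle
# --------------------------------------------------------------------------

def _fmt(x: object) -> object:
    if isinstance(x, (float, np.floating)):
        if math.isnan(x):
            return "NA"
        return f"{x:.3f}"
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def write_report(tables: Mapping[str, pd.DataFrame], out_dir: str) -> None:
    """Write one TSV per analysis stage plus a JSON bundle.

    Floats are formatted to 3 decimals (``NA`` for missing), matching the
    precision of typical published association tables; re-running on
    identical inputs yields byte-identical files.
    """
    os.makedirs(out_dir, exist_ok=True)
    bundle: dict[str, list[dict]] = {}
    for name, df in tables.items():
        formatted = df.map(_fmt) if len(df) else df
        formatted.to_csv(os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False)
        bundle[name] = json.loads(formatted.to_json(orient="records"))
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
        fh.write("\n")
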