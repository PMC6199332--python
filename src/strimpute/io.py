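"""Reading and writing the standard file formats.

VCF carries the genotypes: SNP records with single-base REF/ALT followed
by one symbolic multi-allelic STR record per region with INFO keys MOTIF,
PERIOD, REFLEN and per-ALT length offsets in OFFSETS.  Phased panels use
``|``-separated GT; unphased cohort tables use ``/``.  Pedigrees travel
as PED, segmental-duplication masks as 0-based half-open BED, founder
haplotypes as two-column TSV, and simulation configurations as YAML.

Writing goes through :mod:`pysam`; reading through :mod:`cyvcf2`.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
import yaml

from .containers import MISSING, GenotypeTable, HaplotypePanel, QuadFamily, StrLocus
from .founder import FounderHaplotype
from .simulate import SimulationConfig

SNP_REF, SNP_ALT = "A", "C"


def _symbolic_alt(offset: int) -> str:
    return f"<STR{offset}>"


def _vcf_header(chrom: str, length: int, samples: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=MOTIF,Number=1,Type=String,Description="STR motif">')
    header.add_line('##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="STR motif length in bp">')
    header.add_line('##INFO=<ID=REFLEN,Number=1,Type=Integer,Description="Reference STR length in bp">')
    header.add_line(
        '##INFO=<ID=OFFSETS,Number=A,Type=Integer,Description="ALT allele length offsets from the reference in bp">'
    )
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End of the STR interval">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def _write_records(
    out: pysam.VariantFile,
    chrom: str,
    positions: np.ndarray,
    is_str: np.ndarray,
    locus: StrLocus,
    genotype_at,
    samples: Sequence[str],
    phased: bool,
) -> None:
    str_row = int(np.flatnonzero(is_str)[0])
    # STR ALT alleles: offsets observed anywhere at the locus, reference last out
    observed = sorted(
        {
            a
            for j in range(len(samples))
            for a in genotype_at(str_row, j)
            if a is not None and a != 0
        }
    )
    alt_index = {off: k + 1 for k, off in enumerate(observed)}
    for row, pos in enumerate(positions):
        stop = locus.end if row == str_row else int(pos)
        rec = out.new_record(contig=chrom, start=int(pos) - 1, stop=stop, id=None, qual=None)
        if row == str_row:
            rec.id = f"STR_{pos}"
            ref_seq = (locus.motif * math.ceil(locus.reference_length / locus.period))[
                : locus.reference_length
            ]
            rec.alleles = tuple([ref_seq] + [_symbolic_alt(o) for o in observed])
            rec.info["MOTIF"] = locus.motif
            rec.info["PERIOD"] = locus.period
            rec.info["REFLEN"] = locus.reference_length
            if observed:
                rec.info["OFFSETS"] = tuple(observed)
        else:
            rec.id = f"snp_{pos}"
            rec.alleles = (SNP_REF, SNP_ALT)
        for j, sample in enumerate(samples):
            a, b = genotype_at(row, j)
            if a is None:
                rec.samples[sample]["GT"] = (None, None)
            elif row == str_row:
                rec.samples[sample]["GT"] = (alt_index.get(a, 0), alt_index.get(b, 0))
            else:
                rec.samples[sample]["GT"] = (int(a), int(b))
            rec.samples[sample].phased = phased
        out.write(rec)


def write_panel_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a phased SNP+STR panel as VCF (GT with ``|``)."""
    if panel.samples is None:
        samples = [f"hap_pair{i}" for i in range(panel.n_haplotypes // 2)]
    else:
        samples = panel.samples
    if 2 * len(samples) != panel.n_haplotypes:
        raise ValueError("panel must have an even number of haplotypes to export")
    header = _vcf_header(panel.chrom, int(panel.positions[-1]) + panel.str_locus.reference_length, samples)

    def genotype_at(row: int, j: int):
        a = int(panel.alleles[row, 2 * j])
        b = int(panel.alleles[row, 2 * j + 1])
        if a == MISSING or b == MISSING:
            return None, None
        return a, b

    with pysam.VariantFile(str(path), "w", header=header) as out:
        _write_records(
            out, panel.chrom, panel.positions, panel.is_str, panel.str_locus, genotype_at, samples, True
        )


def write_genotypes_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write an unphased cohort genotype table as VCF (GT with ``/``)."""
    header = _vcf_header(table.chrom, int(table.positions[-1]) + table.str_locus.reference_length, table.samples)

    def genotype_at(row: int, j: int):
        if table.missing[row, j]:
            return None, None
        return int(table.allele_a[row, j]), int(table.allele_b[row, j])

    with pysam.VariantFile(str(path), "w", header=header) as out:
        _write_records(
            out, table.chrom, table.positions, table.is_str, table.str_locus, genotype_at, table.samples, False
        )


def _parse_vcf(path: str | Path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    is_str: list[bool] = []
    rows_a: list[np.ndarray] = []
    rows_b: list[np.ndarray] = []
    rows_missing: list[np.ndarray] = []
    locus: StrLocus | None = None
    phased = True
    chrom = None
    for v in vcf:
        chrom = v.CHROM
        motif = v.INFO.get("MOTIF")
        gts = np.array([[g[0], g[1]] for g in v.genotypes], dtype=np.int64)
        phased = phased and all(bool(g[2]) for g in v.genotypes)
        miss = (gts[:, 0] < 0) | (gts[:, 1] < 0)
        if motif is not None:
            reflen = int(v.INFO.get("REFLEN"))
            locus = StrLocus(v.CHROM, v.POS, v.POS + reflen - 1, str(motif), reflen)
            raw = v.INFO.get("OFFSETS")
            if raw is None:
                offsets: list[int] = []
            elif isinstance(raw, (tuple, list)):
                offsets = [int(o) for o in raw]
            else:
                offsets = [int(o) for o in str(raw).split(",")]
            mapping = np.array([0] + offsets, dtype=np.int64)
            a = np.where(miss, MISSING, mapping[np.clip(gts[:, 0], 0, None)])
            b = np.where(miss, MISSING, mapping[np.clip(gts[:, 1], 0, None)])
            is_str.append(True)
        else:
            a = np.where(miss, MISSING, gts[:, 0])
            b = np.where(miss, MISSING, gts[:, 1])
            is_str.append(False)
        positions.append(v.POS)
        rows_a.append(a)
        rows_b.append(b)
        rows_missing.append(miss)
    if locus is None:
        raise ValueError(f"no STR record (MOTIF INFO key) found in {path}")
    return (
        chrom,
        np.array(positions),
        np.array(is_str),
        np.vstack(rows_a),
        np.vstack(rows_b),
        np.vstack(rows_missing),
        locus,
        samples,
        phased,
    )


def read_panel_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased SNP+STR panel VCF back into a haplotype matrix."""
    chrom, positions, is_str, a, b, miss, locus, samples, phased = _parse_vcf(path)
    if not phased:
        raise ValueError(f"{path} contains unphased genotypes; not a panel")
    if miss.any():
        raise ValueError(f"{path} contains missing alleles; not a valid panel")
    n_sites = positions.shape[0]
    H = np.empty((n_sites, 2 * len(samples)), dtype=np.int32)
    H[:, 0::2] = a
    H[:, 1::2] = b
    return HaplotypePanel(chrom, positions, is_str, H, locus, samples)


def read_genotypes_vcf(path: str | Path) -> GenotypeTable:
    """Read a cohort VCF (phased or not) as an unphased genotype table."""
    chrom, positions, is_str, a, b, miss, locus, samples, _ = _parse_vcf(path)
    a = np.where(miss, 0, a)
    b = np.where(miss, 0, b)
    return GenotypeTable(chrom, positions, is_str, a, b, miss, locus, samples)


def write_ped(families: Sequence[QuadFamily], path: str | Path) -> None:
    """Write quad families as a 6-column PED file."""
    with open(path, "w") as fh:
        for i, q in enumerate(families):
            fam = f"fam{i:04d}"
            fh.write(f"{fam}\t{q.father}\t0\t0\t1\t0\n")
            fh.write(f"{fam}\t{q.mother}\t0\t0\t2\t0\n")
            for child in q.children:
                fh.write(f"{fam}\t{child}\t{q.father}\t{q.mother}\t0\t0\n")


def read_ped(path: str | Path) -> list[QuadFamily]:
    """Read a PED file of quad families (two parents, two children each)."""
    fams: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: PED line needs 6 columns")
            fam, sample, father, mother = parts[0], parts[1], parts[2], parts[3]
            d = fams.setdefault(fam, {"children": []})
            if father == "0" and mother == "0":
                key = "father" if parts[4] == "1" else "mother"
                d[key] = sample
            else:
                d["children"].append(sample)
    quads = []
    for fam, d in fams.items():
        if "father" not in d or "mother" not in d or len(d["children"]) != 2:
            raise ValueError(f"family {fam!r} is not a quad (two parents, two children)")
        c1, c2 = sorted(d["children"])
        quads.append(QuadFamily(d["father"], d["mother"], c1, c2))
    return quads


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED file as 0-based half-open (chrom, start, end) intervals."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs at least 3 columns: {line.strip()!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates: {line.strip()!r}") from e
            if end < start:
                raise ValueError(f"{path}:{lineno}: BED end < start: {line.strip()!r}")
            intervals.append((parts[0], start, end))
    return intervals


def read_founder_tsv(path: str | Path) -> FounderHaplotype:
    """Read a founder haplotype from a two-column (marker, allele) TSV."""
    markers: list[str] = []
    alleles: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'marker<TAB>allele'")
            markers.append(parts[0])
            alleles.append(parts[1])
    return FounderHaplotype(tuple(markers), tuple(alleles))


def save_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
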