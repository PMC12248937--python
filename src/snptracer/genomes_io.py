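"""Data model and readers/writers for genomes, variants, trees and reports.

Coordinate convention: VCF positions are 1-based as on disk; everything held
in memory uses 0-based half-open intervals.  Conversion happens here, at the
I/O boundary, and nowhere else.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Genotype",
    "ReferenceGenome",
    "VariantRecord",
    "GenotypeMatrix",
    "BandPattern",
    "read_fasta",
    "read_vcf",
    "write_newick",
]

_VALID_BASES = frozenset("ACGTN")
_NEWICK_LABEL = re.compile(r"^[A-Za-z0-9_.\-]+$")


class Genotype(enum.IntEnum):
    """Diploid genotype class of one strain at one biallelic locus."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


@dataclass
class ReferenceGenome:
    """Named chromosome sequences, uppercase ACGTN.

    ``masked`` optionally carries one boolean array per chromosome marking
    positions that were soft-masked (lowercase) in the source FASTA.
    """

    chromosomes: dict[str, str]
    masked: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    def __contains__(self, name: str) -> bool:
        return name in self.chromosomes

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)

    def is_masked(self, chrom: str, start: int, end: int) -> bool:
        """True if any base of [start, end) was soft-masked in the input."""
        mask = self.masked.get(chrom)
        if mask is None:
            return False
        return bool(mask[start:end].any())

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with per-strain genotype class and depth."""

    chromosome: str
    position: int  # 1-based, as printed in the VCF
    ref_allele: str
    alt_allele: str
    genotypes: Mapping[str, Genotype]
    depths: Mapping[str, int]

    @property
    def pos0(self) -> int:
        """0-based coordinate of the first reference base."""
        return self.position - 1

    def is_snp(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1


@dataclass
class GenotypeMatrix:
    """Strains x biallelic loci."""

    strain_names: list[str]
    records: list[VariantRecord]

    def __post_init__(self) -> None:
        if len(self.strain_names) < 2:
            raise ValueError("a genotype matrix needs at least two strains")
        if len(set(self.strain_names)) != len(self.strain_names):
            raise ValueError("duplicate strain names")
        for rec in self.records:
            missing = set(self.strain_names) - set(rec.genotypes)
            if missing:
                raise ValueError(
                    f"record {rec.chromosome}:{rec.position} lacks genotypes "
                    f"for {sorted(missing)}"
                )

    @property
    def n_strains(self) -> int:
        return len(self.strain_names)

    def genotype_array(self) -> np.ndarray:
        """(n_strains, n_loci) int8 array of Genotype values."""
        arr = np.empty((len(self.strain_names), len(self.records)), dtype=np.int8)
        for j, rec in enumerate(self.records):
            for i, name in enumerate(self.strain_names):
                arr[i, j] = int(rec.genotypes[name])
        return arr

    def depth_array(self) -> np.ndarray:
        arr = np.zeros((len(self.strain_names), len(self.records)), dtype=np.int64)
        for j, rec in enumerate(self.records):
            for i, name in enumerate(self.strain_names):
                arr[i, j] = rec.depths[name]
        return arr


@dataclass(frozen=True)
class BandPattern:
    """Multiset of amplicon sizes in one gel lane, sorted ascending."""

    sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")
        if list(self.sizes) != sorted(self.sizes):
            object.__setattr__(self, "sizes", tuple(sorted(self.sizes)))

    def __len__(self) -> int:
        return len(self.sizes)

    def __iter__(self):
        return iter(self.sizes)

    def is_empty(self) -> bool:
        return not self.sizes

    def matches(self, other: "BandPattern", tolerance: float) -> bool:
        """Band-by-band equality: same band count, each size within tolerance."""
        if len(self.sizes) != len(other.sizes):
            return False
        return all(abs(a - b) <= tolerance for a, b in zip(self.sizes, other.sizes))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a FASTA file into a :class:`ReferenceGenome`.

    Lowercase (soft-masked) bases are uppercased; which positions were masked
    is retained in ``masked`` so marker selection can avoid them.
    """
    chromosomes: dict[str, str] = {}
    masked: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise ValueError(f"duplicate sequence name {record.id!r}")
        raw = str(record.seq)
        if not raw:
            raise ValueError(f"sequence {record.id!r} is empty")
        mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        is_lower = (mask >= ord("a")) & (mask <= ord("z"))
        chromosomes[record.id] = raw.upper()
        if is_lower.any():
            masked[record.id] = is_lower
    if not chromosomes:
        raise ValueError(f"no FASTA records found in {path}")
    return ReferenceGenome(chromosomes=chromosomes, masked=masked)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SYMBOLIC = re.compile(r"[<>\[\]]|^\*$")


def read_vcf(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    keep_filtered: bool = False,
) -> GenotypeMatrix:
    """Load a multi-sample VCF into a :class:`GenotypeMatrix`.

    Multiallelic records are split into one biallelic record per ALT allele;
    symbolic alleles are dropped.  By default only records whose FILTER is
    PASS or "." are loaded (``keep_filtered`` overrides).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    all_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in all_samples]
        if absent:
            raise ValueError(f"samples not present in VCF header: {absent}")
        vcf.close()
        vcf = VCF(str(path), samples=list(sample_subset))
    samples = list(vcf.samples)

    records: list[VariantRecord] = []
    for var in vcf:
        if not keep_filtered and var.FILTER is not None:
            continue
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        depths = {}
        for i, name in enumerate(samples):
            if dp is None:
                depths[name] = 0
            else:
                v = int(dp[i][0]) if dp[i][0] is not None else 0
                depths[name] = max(v, 0) if v != -2147483648 else 0
        gts = var.genotypes  # [allele_a, allele_b, phased] per sample
        for alt_idx, alt in enumerate(var.ALT):
            if _SYMBOLIC.search(alt):
                continue
            k = alt_idx + 1
            genotypes: dict[str, Genotype] = {}
            for i, name in enumerate(samples):
                g = gts[i]
                if len(g) < 3:
                    raise ValueError(
                        f"malformed genotype for sample {name} at "
                        f"{var.CHROM}:{var.POS}"
                    )
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    genotypes[name] = Genotype.MISSING
                else:
                    n_alt = int(a == k) + int(b == k)
                    genotypes[name] = Genotype(n_alt)
            records.append(
                VariantRecord(
                    chromosome=var.CHROM,
                    position=var.POS,
                    ref_allele=var.REF,
                    alt_allele=alt,
                    genotypes=genotypes,
                    depths=depths,
                )
            )
    vcf.close()
    return GenotypeMatrix(strain_names=samples, records=records)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Re-emit a genotype matrix as a minimal plain-text VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.strain_names)
            + "\n"
        )
        gt_text = {
            Genotype.HOM_REF: "0/0",
            Genotype.HET: "0/1",
            Genotype.HOM_ALT: "1/1",
            Genotype.MISSING: "./.",
        }
        for rec in sorted(matrix.records, key=lambda r: (r.chromosome, r.position)):
            cells = [
                f"{gt_text[rec.genotypes[s]]}:{rec.depths[s]}"
                for s in matrix.strain_names
            ]
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t.\t{rec.ref_allele}\t"
                f"{rec.alt_allele}\t.\tPASS\t.\tGT:DP\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | Path) -> None:
    """Serialize a phylogenetic tree to a Newick file.

    Labels are restricted to ``[A-Za-z0-9_.-]``; anything else is rejected so
    that the written file round-trips deterministically in every dialect.
    """
    labels = tree.leaf_labels()
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels")
    for label in labels:
        if not _NEWICK_LABEL.match(label):
            raise ValueError(f"label {label!r} not representable in Newick output")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
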