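"""Strain-private SNP discovery and marker-selection criteria.

A SNP is *private* to a strain when its alternate allele is observed in that
strain and in no other strain of the collection.  Private SNPs that survive
the depth / completeness filters become candidate traceability markers and
are then screened for locus quality (flank polymorphism, repeats, GC,
primer-footprint uniqueness) and ranked to spread markers across
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from ._seq import count_occurrences, gc_fraction, revcomp
from .genomes_io import GenotypeMatrix, Genotype, ReferenceGenome

__all__ = [
    "PrivateSNP",
    "MarkerCandidate",
    "MarkerConfig",
    "call_private_snps",
    "apply_marker_criteria",
    "write_candidate_report",
]

# criterion-failure codes carried by MarkerCandidate.flags
POLYMORPHIC_FLANK = "polymorphic_flank"
REPETITIVE = "repetitive"
GC_EXTREME = "gc_extreme"
MASKED = "masked"
NON_UNIQUE_3PRIME = "non_unique_3prime"


@dataclass(frozen=True)
class PrivateSNP:
    """A single-nucleotide variant whose alt allele occurs in one strain only."""

    owner_strain: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    zygosity: Genotype  # HET or HOM_ALT in the owner
    min_depth_across_strains: int

    @property
    def pos0(self) -> int:
        return self.position - 1


@dataclass
class MarkerCandidate:
    snp: PrivateSNP
    flank: str
    flags: frozenset[str]
    rank_score: float = 0.0

    @property
    def passes(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class MarkerConfig:
    """Thresholds for the marker-selection criteria (all configurable)."""

    min_depth: int = 50
    max_primer_len: int = 28
    #: half-width of the primer footprint window used for the
    #: flank-polymorphism, repeat and mask checks
    footprint_extra: int = 5
    max_homopolymer: int = 6
    max_dinuc_units: int = 4
    gc_window: int = 100
    gc_min: float = 0.30
    gc_max: float = 0.65
    three_prime_k: int = 15

    @property
    def footprint_half_width(self) -> int:
        return self.max_primer_len + self.footprint_extra


def call_private_snps(
    matrix: GenotypeMatrix, min_depth: int = 50
) -> list[PrivateSNP]:
    """Return the SNPs whose alt allele is carried by exactly one strain.

    A locus qualifies only if every strain has a called genotype (a missing
    call cannot certify allele absence), every strain's depth is at least
    ``min_depth``, and both alleles are single nucleotides (InDels excluded).
    """
    if matrix.n_strains < 2:
        raise ValueError("private-SNP calling needs at least two strains")
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")

    out: list[PrivateSNP] = []
    for rec in matrix.records:
        if not rec.is_snp():
            continue
        carriers = [
            s for s in matrix.strain_names if rec.genotypes[s].carries_alt()
        ]
        if len(carriers) != 1:
            continue
        if any(rec.genotypes[s] is Genotype.MISSING for s in matrix.strain_names):
            continue
        depths = [rec.depths[s] for s in matrix.strain_names]
        if min(depths) < min_depth:
            continue
        out.append(
            PrivateSNP(
                owner_strain=carriers[0],
                chromosome=rec.chromosome,
                position=rec.position,
                ref_allele=rec.ref_allele,
                alt_allele=rec.alt_allele,
                zygosity=rec.genotypes[carriers[0]],
                min_depth_across_strains=min(depths),
            )
        )
    return out


def _max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = ""
    for base in seq:
        run = run + 1 if base == prev else 1
        prev = base
        best = max(best, run)
    return best


def _max_dinucleotide_units(seq: str) -> int:
    """Longest tandem repeat of a 2-mer with two distinct bases, in units."""
    best = 0
    n = len(seq)
    for i in range(n - 1):
        a, b = seq[i], seq[i + 1]
        if a == b:
            continue
        units = 1
        j = i + 2
        while j + 1 < n and seq[j : j + 2] == a + b:
            units += 1
            j += 2
        best = max(best, units)
    return best


def _kmer_occurrences(reference: ReferenceGenome, kmer: str, limit: int) -> int:
    n = 0
    rc = revcomp(kmer)
    for seq in reference.chromosomes.values():
        n += count_occurrences(seq, kmer, limit=limit - n)
        if n >= limit:
            return n
        n += count_occurrences(seq, rc, limit=limit - n)
        if n >= limit:
            return n
    return n


def _evaluate_flags(
    snp: PrivateSNP,
    reference: ReferenceGenome,
    matrix: GenotypeMatrix,
    config: MarkerConfig,
) -> tuple[frozenset[str], str]:
    chrom_seq = reference[snp.chromosome]
    p = snp.pos0
    w = config.footprint_half_width
    if p < w or p + w >= len(chrom_seq):
        raise ValueError(
            f"SNP {snp.chromosome}:{snp.position} lies within "
            f"{w} bp of a chromosome end"
        )
    if chrom_seq[p] != snp.ref_allele:
        raise ValueError(
            f"SNP {snp.chromosome}:{snp.position} ref allele "
            f"{snp.ref_allele!r} does not match reference base {chrom_seq[p]!r}"
        )

    flags: set[str] = set()
    footprint = chrom_seq[p - w : p + w + 1]

    # (a1) another variant of the collection inside the primer footprint
    for rec in matrix.records:
        if rec.chromosome != snp.chromosome:
            continue
        d = abs(rec.position - snp.position)
        if 0 < d <= w:
            flags.add(POLYMORPHIC_FLANK)
            break

    # (a2) repeats and soft-masked bases
    if (
        _max_homopolymer_run(footprint) > config.max_homopolymer
        or _max_dinucleotide_units(footprint) > config.max_dinuc_units
    ):
        flags.add(REPETITIVE)
    if reference.is_masked(snp.chromosome, p - w, p + w + 1):
        flags.add(MASKED)

    # (a3) flank GC content
    lo = max(0, p - config.gc_window)
    hi = min(len(chrom_seq), p + config.gc_window + 1)
    gc = gc_fraction(chrom_seq[lo:hi])
    if not (config.gc_min <= gc <= config.gc_max):
        flags.add(GC_EXTREME)

    # uniqueness of the 3'-terminal k-mer of the would-be AS primer footprint
    k = config.three_prime_k
    kmer = chrom_seq[p - k + 1 : p + 1]
    if _kmer_occurrences(reference, kmer, limit=2) > 1:
        flags.add(NON_UNIQUE_3PRIME)

    return frozenset(flags), footprint


def apply_marker_criteria(
    snps: Iterable[PrivateSNP],
    reference: ReferenceGenome,
    matrix: GenotypeMatrix,
    config: MarkerConfig | None = None,
) -> list[MarkerCandidate]:
    """Screen private SNPs against the marker criteria and rank the survivors.

    Passing candidates (empty flag set) come first, ordered per strain by a
    greedy chromosome-dispersion rule: each next pick prefers a chromosome
    not yet used for that strain, ties broken by (chromosome, position).
    Failing candidates follow with rank_score 0.
    """
    config = config or MarkerConfig()
    evaluated: list[MarkerCandidate] = []
    for snp in snps:
        if snp.chromosome not in reference:
            raise ValueError(f"SNP chromosome {snp.chromosome!r} not in reference")
        flags, footprint = _evaluate_flags(snp, reference, matrix, config)
        evaluated.append(MarkerCandidate(snp=snp, flank=footprint, flags=flags))

    passing = [c for c in evaluated if c.passes]
    failing = [c for c in evaluated if not c.passes]

    ranked: list[MarkerCandidate] = []
    for owner in sorted({c.snp.owner_strain for c in passing}):
        pool = sorted(
            (c for c in passing if c.snp.owner_strain == owner),
            key=lambda c: (c.snp.chromosome, c.snp.position),
        )
        used_chroms: set[str] = set()
        order: list[MarkerCandidate] = []
        while pool:
            fresh = [c for c in pool if c.snp.chromosome not in used_chroms]
            pick = fresh[0] if fresh else pool[0]
            pool.remove(pick)
            used_chroms.add(pick.snp.chromosome)
            order.append(pick)
        for i, cand in enumerate(order):
            cand.rank_score = 1.0 / (1 + i)
        ranked.extend(order)

    failing.sort(key=lambda c: (c.snp.owner_strain, c.snp.chromosome, c.snp.position))
    return ranked + failing


def write_candidate_report(
    candidates: Iterable[MarkerCandidate], path: str | Path
) -> None:
    """TSV report: strain, chrom, pos, ref, alt, zygosity, flags, rank."""
    import pandas as pd

    rows = [
        {
            "strain": c.snp.owner_strain,
            "chrom": c.snp.chromosome,
            "pos": c.snp.position,
            "ref": c.snp.ref_allele,
            "alt": c.snp.alt_allele,
            "zygosity": c.snp.zygosity.name.lower(),
            "flags": ",".join(sorted(c.flags)) or ".",
            "rank_score": c.rank_score,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
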