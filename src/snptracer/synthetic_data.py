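"""Seeded generator of toy references and strain collections.

The generator emulates a multi-strain collection with cluster structure:
members of a cluster share a SNP backbone and a planted delta-element layout
(so inter-delta fingerprints are identical within a cluster), while every
strain additionally carries its own private SNPs, placed with enough clean
flank that allele-specific assays are designable.  Everything is
deterministic per seed, and a truth bundle (genomes, VCF, labels) can be
written as plain text.

Layout convention: the first chromosome is reserved for delta elements, the
remaining chromosomes carry all variants.  Delta layouts are deterministic
functions of their integer id, with convergent primer-site pairs spaced so
no cross-pair amplicon fits under the amplicon cutoff.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp
from .assay_design import DesignConfig, allele_primer_designable
from .genomes_io import (
    GenotypeMatrix,
    Genotype,
    ReferenceGenome,
    VariantRecord,
    write_vcf,
)
from .insilico_pcr import DELTA12, DELTA21, _binding_sites
from ._seq import encode
from .variant_selection import PrivateSNP

__all__ = [
    "ClusterSpec",
    "CollectionSpec",
    "TruthSet",
    "generate_reference",
    "derive_strains",
    "sample_colonies",
    "default_collection_spec",
    "assay_design_spec",
]

_BASES = np.array(list("ACGT"))

# geometry of planted delta layouts
_DELTA_ZONE_START = 500
_PAIR_PITCH = 3600  # > max_amplicon so neighbouring pairs never cross-amplify
_SPAN_BASE = 400
_SPAN_PER_LAYOUT = 60
_SPAN_PER_PAIR = 150


@dataclass(frozen=True)
class ClusterSpec:
    name: str
    members: int
    shared_snps: int
    delta_layout: int

    def __post_init__(self) -> None:
        if self.members < 1:
            raise ValueError("cluster needs at least one member")
        if self.shared_snps < 0 or self.delta_layout < 0:
            raise ValueError("counts must be non-negative")

    def strain_names(self) -> list[str]:
        if self.members == 1:
            return [self.name]
        return [f"{self.name}.{chr(ord('A') + i)}" for i in range(self.members)]


@dataclass(frozen=True)
class CollectionSpec:
    seed: int
    chromosome_count: int = 4
    chrom_length: int | tuple[int, ...] = 50_000
    gc: float = 0.40
    clusters: tuple[ClusterSpec, ...] = ()
    private_snp_range: tuple[int, int] = (2, 3)
    depth_model: tuple = ("constant", 60)
    locus_spacing: int = 1_000
    #: when True, private SNPs are planted only at loci where an engineered
    #: allele-specific primer can reach the Tm window, spaced >=
    #: ``private_pitch`` apart so multiplex assays cannot cross-amplify
    assay_ready: bool = False
    private_pitch: int = 4_000

    def __post_init__(self) -> None:
        if self.chromosome_count < 2:
            raise ValueError("need >= 2 chromosomes (chr1 is the delta zone)")
        for length in self.chrom_lengths():
            if length < 10_000:
                raise ValueError("chromosomes must be at least 10 kb")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must lie in [0, 1]")
        if self.private_snp_range[0] > self.private_snp_range[1]:
            raise ValueError("bad private_snp_range")

    def chrom_lengths(self) -> tuple[int, ...]:
        if isinstance(self.chrom_length, int):
            return (self.chrom_length,) * self.chromosome_count
        if len(self.chrom_length) != self.chromosome_count:
            raise ValueError("chrom_length tuple does not match chromosome_count")
        return tuple(self.chrom_length)

    def strain_names(self) -> list[str]:
        names: list[str] = []
        for cluster in self.clusters:
            names.extend(cluster.strain_names())
        return names


@dataclass
class TruthSet:
    reference: ReferenceGenome
    strain_genomes: dict[str, ReferenceGenome]
    records: list[VariantRecord]
    private_snps: dict[str, list[PrivateSNP]]
    delta_layouts: dict[str, int]
    cluster_of: dict[str, str]
    delta_writes: dict[int, list[tuple[str, int, str]]]

    def matrix(self) -> GenotypeMatrix:
        return GenotypeMatrix(
            strain_names=list(self.strain_genomes), records=list(self.records)
        )

    def reconstruct(self, strain: str) -> ReferenceGenome:
        """Reference + delta layout + carried alt alleles -> strain genome."""
        chroms = {name: list(seq) for name, seq in self.reference.chromosomes.items()}
        for chrom, pos, motif in self.delta_writes[self.delta_layouts[strain]]:
            chroms[chrom][pos : pos + len(motif)] = list(motif)
        for rec in self.records:
            if rec.genotypes[strain].carries_alt():
                chroms[rec.chromosome][rec.pos0] = rec.alt_allele
        return ReferenceGenome(
            chromosomes={name: "".join(seq) for name, seq in chroms.items()}
        )

    def write_bundle(self, outdir: str | Path) -> None:
        """Plain-text fixture bundle: FASTAs, truth VCF, labels, spec echo."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write_fasta(outdir / "reference.fa")
        for name, genome in self.strain_genomes.items():
            genome.write_fasta(outdir / f"strain_{name.replace('.', '_')}.fa")
        write_vcf(self.matrix(), outdir / "truth.vcf")
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("strain\tcluster\tdelta_layout\tn_private_snps\n")
            for name in self.strain_genomes:
                fh.write(
                    f"{name}\t{self.cluster_of[name]}\t"
                    f"{self.delta_layouts[name]}\t{len(self.private_snps[name])}\n"
                )

    def write_spec(self, spec: "CollectionSpec", outdir: str | Path) -> None:
        with open(Path(outdir) / "spec.json", "w") as fh:
            json.dump(asdict(spec), fh, indent=2)


def _scrub_delta_sites(chromosomes: dict[str, str]) -> dict[str, str]:
    """Mutate away any spurious delta-primer binding site (<=2 internal
    mismatches) so that only deliberately planted sites fingerprint."""
    for _ in range(6):
        dirty = False
        for name, seq in chromosomes.items():
            arr = encode(seq)
            chars = list(seq)
            for primer in (DELTA12, DELTA21):
                fwd, rev = _binding_sites(arr, primer, 2)
                for s in fwd:
                    i = int(s) + len(primer) - 1  # break the 3'-terminal match
                    chars[i] = "A" if chars[i] != "A" else "C"
                    dirty = True
                for s in rev:
                    chars[int(s)] = "A" if chars[int(s)] != "A" else "C"
                    dirty = True
            if dirty:
                chromosomes[name] = "".join(chars)
        if not dirty:
            return chromosomes
    raise RuntimeError("could not scrub spurious delta sites")


def generate_reference(spec: CollectionSpec) -> ReferenceGenome:
    """Seeded i.i.d. reference at the target GC, free of delta-primer sites.

    Spurious binding sites for the delta primers are mutated away so that
    planted layouts alone determine inter-delta fingerprints; at most a few
    dozen bases per genome are touched, leaving observed GC within the
    binomial envelope of the target.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    chromosomes = {
        f"chr{i + 1}": "".join(rng.choice(_BASES, size=length, p=p))
        for i, length in enumerate(spec.chrom_lengths())
    }
    if 0.0 < spec.gc < 1.0:
        chromosomes = _scrub_delta_sites(chromosomes)
    return ReferenceGenome(chromosomes=chromosomes)


def _layout_writes(layout: int, chrom: str, chrom_length: int) -> list[tuple[str, int, str]]:
    """Deterministic delta-site plan for one layout id.

    Each pair is a forward delta12 site and a reverse delta21 site ``span``
    bp apart (one amplicon of exactly ``span`` bp); pairs sit ``_PAIR_PITCH``
    apart so no cross-pair product fits under a 3 kb amplicon cutoff.
    """
    n_pairs = 2 + layout % 3
    writes: list[tuple[str, int, str]] = []
    for j in range(n_pairs):
        span = _SPAN_BASE + _SPAN_PER_LAYOUT * layout + _SPAN_PER_PAIR * j
        start = _DELTA_ZONE_START + j * _PAIR_PITCH
        end = start + span
        if end + 100 > chrom_length:
            raise ValueError(
                f"delta layout {layout} does not fit a {chrom_length} bp chromosome"
            )
        writes.append((chrom, start, DELTA12))
        writes.append((chrom, end - len(DELTA21), revcomp(DELTA21)))
    return writes


def _depth(rng: np.random.Generator, model: tuple) -> int:
    if model[0] == "constant":
        return int(model[1])
    if model[0] == "range":
        return int(rng.integers(model[1], model[2] + 1))
    raise ValueError(f"unknown depth model {model[0]!r}")


def derive_strains(reference: ReferenceGenome, spec: CollectionSpec) -> TruthSet:
    """Plant cluster backbones, private SNPs and delta layouts; emit truth.

    Cluster members share their cluster's SNP backbone (hom-alt in every
    member) and delta layout; each strain receives a per-strain number of
    private SNPs drawn from ``private_snp_range``, alternating hom-alt and
    het.  All variant loci are at least ``locus_spacing`` apart and clear of
    the delta chromosome.
    """
    rng = np.random.default_rng(spec.seed + 1)
    strains = spec.strain_names()
    if len(strains) < 2:
        raise ValueError("collection needs at least two strains")
    if len(set(strains)) != len(strains):
        raise ValueError("duplicate strain names across clusters")

    chrom_names = reference.names()
    delta_chrom = chrom_names[0]

    # candidate variant slots on chromosomes 2..n, shuffled once
    slots: list[tuple[str, int]] = []
    for chrom in chrom_names[1:]:
        length = len(reference[chrom])
        pos = spec.locus_spacing
        while pos < length - spec.locus_spacing:
            slots.append((chrom, pos))
            pos += spec.locus_spacing
    shuffled = [slots[i] for i in rng.permutation(len(slots))]
    used: set[tuple[str, int]] = set()
    private_loci: list[tuple[str, int]] = []

    design_cfg = DesignConfig() if spec.assay_ready else None

    def pick_alt(chrom: str, pos0: int) -> str:
        ref_base = reference[chrom][pos0]
        return str(rng.choice([b for b in "ACGT" if b != ref_base]))

    def alloc(private: bool) -> tuple[str, int, str]:
        for chrom, pos0 in shuffled:
            if (chrom, pos0) in used:
                continue
            if private and spec.assay_ready:
                if any(
                    c == chrom and abs(p - pos0) < spec.private_pitch
                    for c, p in private_loci
                ):
                    continue
                alt = pick_alt(chrom, pos0)
                if not allele_primer_designable(
                    reference[chrom], pos0, alt, design_cfg
                ):
                    continue
            else:
                alt = pick_alt(chrom, pos0)
            used.add((chrom, pos0))
            if private:
                private_loci.append((chrom, pos0))
            return chrom, pos0, alt
        raise ValueError("spec demands more variant loci than the genome can place")

    n_private = {
        s: int(rng.integers(spec.private_snp_range[0], spec.private_snp_range[1] + 1))
        for s in strains
    }

    records: list[VariantRecord] = []
    private_snps: dict[str, list[PrivateSNP]] = {s: [] for s in strains}
    cluster_of: dict[str, str] = {}
    delta_layouts: dict[str, int] = {}

    def make_record(
        chrom: str, pos0: int, alt_base: str, carriers: Mapping[str, Genotype]
    ) -> VariantRecord:
        genotypes = {s: carriers.get(s, Genotype.HOM_REF) for s in strains}
        depths = {s: _depth(rng, spec.depth_model) for s in strains}
        return VariantRecord(
            chromosome=chrom,
            position=pos0 + 1,
            ref_allele=reference[chrom][pos0],
            alt_allele=alt_base,
            genotypes=genotypes,
            depths=depths,
        )

    for cluster in spec.clusters:
        members = cluster.strain_names()
        for member in members:
            cluster_of[member] = cluster.name
            delta_layouts[member] = cluster.delta_layout
        for _ in range(cluster.shared_snps):
            chrom, pos0, alt = alloc(private=False)
            records.append(
                make_record(chrom, pos0, alt, {m: Genotype.HOM_ALT for m in members})
            )
        for member in members:
            for k in range(n_private[member]):
                chrom, pos0, alt = alloc(private=True)
                zyg = Genotype.HOM_ALT if k % 2 == 0 else Genotype.HET
                rec = make_record(chrom, pos0, alt, {member: zyg})
                records.append(rec)
                private_snps[member].append(
                    PrivateSNP(
                        owner_strain=member,
                        chromosome=chrom,
                        position=rec.position,
                        ref_allele=rec.ref_allele,
                        alt_allele=rec.alt_allele,
                        zygosity=zyg,
                        min_depth_across_strains=min(rec.depths.values()),
                    )
                )

    records.sort(key=lambda r: (r.chromosome, r.position))

    delta_writes = {
        layout: _layout_writes(layout, delta_chrom, len(reference[delta_chrom]))
        for layout in sorted({c.delta_layout for c in spec.clusters})
    }

    strain_genomes: dict[str, ReferenceGenome] = {}
    for strain in strains:
        chroms = {name: list(seq) for name, seq in reference.chromosomes.items()}
        for chrom, pos, motif in delta_writes[delta_layouts[strain]]:
            chroms[chrom][pos : pos + len(motif)] = list(motif)
        for rec in records:
            if rec.genotypes[strain].carries_alt():
                chroms[rec.chromosome][rec.pos0] = rec.alt_allele
        strain_genomes[strain] = ReferenceGenome(
            chromosomes={name: "".join(seq) for name, seq in chroms.items()}
        )

    return TruthSet(
        reference=reference,
        strain_genomes=strain_genomes,
        records=records,
        private_snps=private_snps,
        delta_layouts=delta_layouts,
        cluster_of=cluster_of,
        delta_writes=delta_writes,
    )


def sample_colonies(
    strain_genomes: Mapping[str, ReferenceGenome],
    proportions: Mapping[str, float],
    n: int,
    seed: int,
) -> list[tuple[str, ReferenceGenome, str]]:
    """Multinomial colony draw; every colony is one pure strain.

    Colonies arise from single plated cells, so mixtures exist only at the
    population level.  Returns (colony id, genome, truth label) triples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not proportions:
        raise ValueError("empty proportions")
    names = sorted(proportions)
    probs = np.array([proportions[s] for s in names], dtype=float)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    missing = [s for s in names if s not in strain_genomes]
    if missing:
        raise ValueError(f"no genome for strains {missing}")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(names), size=n, p=probs)
    return [
        (f"colony_{i + 1}", strain_genomes[names[k]], names[k])
        for i, k in enumerate(draws)
    ]


def default_collection_spec(seed: int) -> CollectionSpec:
    """A 28-strain collection: one 6-member cluster, four 2-member clusters,
    fourteen singletons -- 19 distinct delta layouts in total."""
    clusters = [ClusterSpec("C1", 6, 10, 0)]
    clusters += [ClusterSpec(f"C{i}", 2, 6, i - 1) for i in range(2, 6)]
    clusters += [ClusterSpec(f"U{i}", 1, 0, 4 + i) for i in range(1, 15)]
    return CollectionSpec(
        seed=seed,
        chromosome_count=4,
        chrom_length=50_000,
        clusters=tuple(clusters),
        private_snp_range=(2, 3),
    )


def assay_design_spec(seed: int, strains: int = 4, private_per_strain: int = 3) -> CollectionSpec:
    """A compact ~100 kb spec for assay-design exercises: one cluster whose
    members share a delta layout, each strain with private SNPs planted at
    assay-compatible, well-separated loci."""
    return CollectionSpec(
        seed=seed,
        chromosome_count=3,
        chrom_length=(10_000, 45_000, 45_000),
        gc=0.45,
        clusters=(ClusterSpec("C1", strains, 4, 0),),
        private_snp_range=(private_per_strain, private_per_strain),
        assay_ready=True,
    )
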