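"""Allele-specific PCR assay design.

For each validated marker SNP two primer pairs are designed: one whose
allele-specific member terminates on the reference base (the "wild-type"
pair) and one terminating on the variant base.  Both allele-specific primers
additionally carry an engineered destabilizing mismatch at offset -2 from
the 3' end, so that a primer matching the wrong allele suffers two terminal
mismatches and fails to extend, while the right allele tolerates the single
internal one.  The two pairs are forced to produce amplicons differing by at
least ``min_size_gap`` (default 200 bp) so wild-type and variant products
separate cleanly on a gel.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameter set (SantaLucia 1998) with monovalent-salt entropy correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from ._seq import complement, count_occurrences, revcomp
from .genomes_io import BandPattern, GenotypeMatrix, ReferenceGenome
from .variant_selection import PrivateSNP

__all__ = [
    "DesignConfig",
    "Primer",
    "ASAssay",
    "MultiplexPanel",
    "ThermalProtocol",
    "AssayDesignError",
    "melting_temperature",
    "design_as_primer",
    "design_assay",
    "design_assays",
    "build_multiplex_panel",
    "touchdown_protocol",
    "write_panel_report",
]


class AssayDesignError(ValueError):
    """Raised when no primer/amplicon placement satisfies the constraints."""


# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol K); keys are 5'->3' dinucleotides of one strand.
_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_INIT_DH = {"A": 2.3, "T": 2.3, "G": 0.1, "C": 0.1}
_INIT_DS = {"A": 4.1, "T": 4.1, "G": -2.8, "C": -2.8}
_R_GAS = 1.987  # cal/(mol K)


@dataclass(frozen=True)
class DesignConfig:
    min_len: int = 18
    max_len: int = 28
    tm_target: float = 62.0
    tm_tol: float = 2.0
    tm_spread_max: float = 3.0
    min_size_gap: int = 200
    product_min: int = 150
    product_max: int = 800
    gel_resolution: int = 25
    dimer_max: int = 8  # a 3'-anchored cross-complement run this long flags a dimer
    monovalent_mM: float = 50.0
    primer_uM: float = 0.5
    #: engineered -2 base = this table applied to the base on the strand the
    #: primer anneals to; identity produces a homo (non-Watson-Crick) pair
    mismatch_table: tuple[tuple[str, str], ...] = (
        ("A", "A"), ("C", "C"), ("G", "G"), ("T", "T"),
    )

    @property
    def tm_window(self) -> tuple[float, float]:
        return (self.tm_target - self.tm_tol, self.tm_target + self.tm_tol)


@dataclass(frozen=True)
class Primer:
    sequence: str  # 5'->3'
    chromosome: str
    start: int  # 0-based half-open interval on the template top strand
    end: int
    strand: Literal["+", "-"]
    is_allele_specific: bool = False
    #: offsets from the 3' end: -1 = allele-discriminating base,
    #: -2 = engineered destabilizer
    mismatch_positions: frozenset[int] = frozenset()
    tm_celsius: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("primer interval does not match sequence length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ASAssay:
    snp: PrivateSNP
    wt_pair: tuple[Primer, Primer]
    as_pair: tuple[Primer, Primer]
    wt_product_size: int
    as_product_size: int
    assay_id: str = ""

    def __post_init__(self) -> None:
        for fwd, rev in (self.wt_pair, self.as_pair):
            if fwd.strand == rev.strand:
                raise ValueError("pair members must converge (opposite strands)")


@dataclass(frozen=True)
class ThermalProtocol:
    activation: tuple[float, int]
    touchdown_cycles: tuple[tuple[tuple[float, int], tuple[float, int], tuple[float, int]], ...]
    standard_cycle_count: int
    standard_cycle: tuple[tuple[float, int], tuple[float, int], tuple[float, int]]
    final_extension: tuple[float, int]

    @property
    def total_cycles(self) -> int:
        return len(self.touchdown_cycles) + self.standard_cycle_count

    def anneal_temperatures(self) -> list[float]:
        return [cycle[1][0] for cycle in self.touchdown_cycles]

    def describe(self) -> str:
        lines = [
            f"activation: {self.activation[0]:g} C for {self.activation[1]} s",
            f"touch-down phase ({len(self.touchdown_cycles)} cycles):",
        ]
        for den, ann, ext in self.touchdown_cycles:
            lines.append(
                f"  denature {den[0]:g} C {den[1]} s | anneal {ann[0]:g} C "
                f"{ann[1]} s | extend {ext[0]:g} C {ext[1]} s"
            )
        den, ann, ext = self.standard_cycle
        lines.append(
            f"standard phase: {self.standard_cycle_count} cycles of "
            f"denature {den[0]:g} C {den[1]} s | anneal {ann[0]:g} C {ann[1]} s "
            f"| extend {ext[0]:g} C {ext[1]} s"
        )
        lines.append(
            f"final extension: {self.final_extension[0]:g} C "
            f"for {self.final_extension[1]} s"
        )
        lines.append(f"total cycles: {self.total_cycles}")
        return "\n".join(lines)


@dataclass
class MultiplexPanel:
    assays: list[ASAssay]
    protocol: ThermalProtocol
    strain_signatures: dict[str, BandPattern]
    gel_resolution: int

    @property
    def primer_count(self) -> int:
        return 2 * len(self.assays)

    def primers(self) -> list[Primer]:
        out: list[Primer] = []
        for assay in self.assays:
            out.extend(assay.as_pair)
        return out


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


def melting_temperature(sequence: str, config: DesignConfig | None = None) -> float:
    """Nearest-neighbor melting temperature in Celsius.

    Unified NN table, two-state model, with the 0.368 * (N-1) * ln[Na+]
    entropic salt correction; total strand concentration taken as twice the
    per-primer concentration (non-self-complementary duplex, CT/4 term).
    """
    config = config or DesignConfig()
    seq = sequence.upper()
    if len(seq) < 8:
        raise ValueError("sequence shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError("melting temperature requires an ACGT-only sequence")

    dh = _INIT_DH[seq[0]] + _INIT_DH[seq[-1]]
    ds = _INIT_DS[seq[0]] + _INIT_DS[seq[-1]]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]

    na = config.monovalent_mM / 1000.0
    ds += 0.368 * (len(seq) - 1) * math.log(na)
    # CT/4 with CT = 2 * primer concentration (mol/L)
    ct4 = (2.0 * config.primer_uM * 1e-6) / 4.0
    return dh * 1000.0 / (ds + _R_GAS * math.log(ct4)) - 273.15


# ---------------------------------------------------------------------------
# Primer construction
# ---------------------------------------------------------------------------


def _mismatch_sub(config: DesignConfig, annealed_base: str) -> str:
    table = dict(config.mismatch_table)
    return table[annealed_base]


def _engineer_forward(
    chrom_seq: str, p: int, allele: str, length: int, config: DesignConfig
) -> str:
    """Forward AS primer of given length with 3' end on top-strand position p."""
    start = p - length + 1
    body = chrom_seq[start : p + 1]
    # -2 base anneals to the bottom strand: homo-pair with complement(top)
    engineered = _mismatch_sub(config, complement(body[-2]))
    return body[:-2] + engineered + allele


def _engineer_reverse(
    chrom_seq: str, p: int, allele: str, length: int, config: DesignConfig
) -> str:
    """Reverse AS primer of given length with 3' end on top-strand position p."""
    segment = chrom_seq[p : p + length]
    primer = revcomp(segment)
    # -2 position anneals to the top strand base at p+1: homo-pair with it
    engineered = _mismatch_sub(config, segment[1])
    return primer[:-2] + engineered + complement(allele)


def allele_primer_designable(
    chrom_seq: str, pos0: int, alt: str, config: DesignConfig | None = None
) -> bool:
    """True if an engineered allele-specific primer anchored at ``pos0`` can
    reach the Tm window on either strand.  Used by the synthetic-data
    generator to plant SNPs at assay-compatible loci."""
    config = config or DesignConfig()
    lo, hi = config.tm_window
    for n in range(config.min_len, config.max_len + 1):
        if pos0 - n + 1 >= 0:
            seq = _engineer_forward(chrom_seq, pos0, alt, n, config)
            if lo <= melting_temperature(seq, config) <= hi:
                return True
        if pos0 + n <= len(chrom_seq):
            seq = _engineer_reverse(chrom_seq, pos0, alt, n, config)
            if lo <= melting_temperature(seq, config) <= hi:
                return True
    return False


def design_as_primer(
    reference: ReferenceGenome,
    snp: PrivateSNP,
    allele: Literal["ref", "alt"],
    direction: Literal["+", "-"],
    config: DesignConfig | None = None,
    length: int | None = None,
) -> Primer:
    """Design one allele-specific primer ending on the SNP.

    The 3'-terminal base equals the chosen allele; the base at offset -2 is
    substituted so that it mismatches the template of *every* strain (the
    locus is private, so all strains share the reference context around it).
    Length is tuned within bounds to bring Tm into the target window; pass
    ``length`` to pin it (used to give the WT primer the same footprint).
    """
    config = config or DesignConfig()
    chrom_seq = reference[snp.chromosome]
    p = snp.pos0
    base = snp.ref_allele if allele == "ref" else snp.alt_allele

    def build(n: int) -> str:
        if direction == "+":
            if p - n + 1 < 0:
                raise AssayDesignError("flank too short for forward AS primer")
            return _engineer_forward(chrom_seq, p, base, n, config)
        if p + n > len(chrom_seq):
            raise AssayDesignError("flank too short for reverse AS primer")
        return _engineer_reverse(chrom_seq, p, base, n, config)

    lengths: Iterable[int]
    if length is not None:
        lengths = [length]
    else:
        lengths = range(config.min_len, config.max_len + 1)

    lo, hi = config.tm_window
    best: tuple[float, int, str, float] | None = None
    for n in lengths:
        seq = build(n)
        tm = melting_temperature(seq, config)
        if length is None and not (lo <= tm <= hi):
            continue
        score = abs(tm - config.tm_target)
        if best is None or score < best[0]:
            best = (score, n, seq, tm)
    if best is None:
        raise AssayDesignError(
            f"no primer length in [{config.min_len}, {config.max_len}] reaches "
            f"Tm {config.tm_target:g} +/- {config.tm_tol:g} C at "
            f"{snp.chromosome}:{snp.position} ({direction} strand)"
        )
    _, n, seq, tm = best
    if direction == "+":
        start, end = p - n + 1, p + 1
    else:
        start, end = p, p + n
    return Primer(
        sequence=seq,
        chromosome=snp.chromosome,
        start=start,
        end=end,
        strand=direction,
        is_allele_specific=True,
        mismatch_positions=frozenset({-1, -2}),
        tm_celsius=tm,
        name=f"{snp.owner_strain}_{snp.chromosome}_{snp.position}_{allele}_{direction}AS",
    )


def _footprint_unique(reference: ReferenceGenome, chrom: str, start: int, end: int) -> bool:
    """True if the reference sequence under the primer occurs exactly once
    genome-wide (both strands)."""
    word = reference[chrom][start:end]
    n = 0
    rc = revcomp(word)
    for seq in reference.chromosomes.values():
        n += count_occurrences(seq, word, limit=2 - n)
        if n > 1:
            return False
        n += count_occurrences(seq, rc, limit=2 - n)
        if n > 1:
            return False
    return n == 1


def _footprint_clean(
    matrix: GenotypeMatrix | None, snp: PrivateSNP, chrom: str, start: int, end: int
) -> bool:
    """No known collection variant under the footprint, except the target SNP."""
    if matrix is None:
        return True
    for rec in matrix.records:
        if rec.chromosome != chrom:
            continue
        if rec.position == snp.position and rec.chromosome == snp.chromosome:
            continue
        if start < rec.position <= end:  # rec.position is 1-based
            return False
    return True


def _design_conventional(
    reference: ReferenceGenome,
    chrom: str,
    outer: int,
    strand: Literal["+", "-"],
    config: DesignConfig,
    matrix: GenotypeMatrix | None,
    snp: PrivateSNP,
) -> Primer | None:
    """Conventional (perfect-match) mate primer anchored at a product edge.

    ``outer`` is the 0-based top-strand coordinate of the primer's 5' end:
    for a forward (+) mate the product *starts* at ``outer`` (interval
    [outer, outer + n)); for a reverse (-) mate the product *ends* at
    ``outer`` (interval [outer - n, outer)).  Anchoring the 5' end keeps the
    product size independent of the length chosen for the Tm fit.  Returns
    None if no length hits the Tm window with a unique, variant-free
    footprint.
    """
    chrom_seq = reference[chrom]
    lo, hi = config.tm_window

    def interval(n: int) -> tuple[int, int]:
        return (outer, outer + n) if strand == "+" else (outer - n, outer)

    best: tuple[float, int, str, float] | None = None
    for n in range(config.min_len, config.max_len + 1):
        start, end = interval(n)
        if start < 0 or end > len(chrom_seq):
            continue
        word = chrom_seq[start:end]
        if "N" in word:
            continue
        seq = word if strand == "+" else revcomp(word)
        tm = melting_temperature(seq, config)
        if not (lo <= tm <= hi):
            continue
        score = abs(tm - config.tm_target)
        if best is None or score < best[0]:
            best = (score, n, seq, tm)
    if best is None:
        return None
    _, n, seq, tm = best
    start, end = interval(n)
    if not _footprint_unique(reference, chrom, start, end):
        return None
    if not _footprint_clean(matrix, snp, chrom, start, end):
        return None
    return Primer(
        sequence=seq,
        chromosome=chrom,
        start=start,
        end=end,
        strand=strand,
        tm_celsius=tm,
        name=f"{snp.owner_strain}_{chrom}_{outer}_{strand}mate",
    )


def design_assay(
    reference: ReferenceGenome,
    snp: PrivateSNP,
    config: DesignConfig | None = None,
    matrix: GenotypeMatrix | None = None,
    product_size_start: int | None = None,
    assay_id: str = "",
) -> ASAssay:
    """Design the WT and variant primer pairs for one marker SNP.

    The allele-specific member is tried as the forward (+) primer first,
    falling back to the reverse (-) orientation.  The conventional mates are
    placed so the two products differ by at least ``min_size_gap`` and both
    lie within [product_min, product_max]; every mate footprint must be
    unique in the reference and free of known collection variants.
    ``product_size_start`` shifts where the product-size scan begins, which
    lets a panel stagger its band sizes.
    """
    config = config or DesignConfig()
    scan_from = product_size_start or config.product_min
    if not (config.product_min <= scan_from <= config.product_max):
        raise ValueError("product_size_start outside [product_min, product_max]")
    reasons: list[str] = []
    for direction in ("+", "-"):
        try:
            return _attempt_assay(
                reference, snp, direction, config, matrix, scan_from, assay_id
            )
        except AssayDesignError as exc:
            reasons.append(f"{direction}: {exc}")
    raise AssayDesignError(
        f"assay design failed for {snp.chromosome}:{snp.position} -- "
        + "; ".join(reasons)
    )


def _attempt_assay(
    reference: ReferenceGenome,
    snp: PrivateSNP,
    direction: Literal["+", "-"],
    config: DesignConfig,
    matrix: GenotypeMatrix | None,
    scan_from: int,
    assay_id: str,
) -> ASAssay:
    chrom_seq = reference[snp.chromosome]
    p = snp.pos0

    as_primer = design_as_primer(reference, snp, "alt", direction, config)
    wt_primer = design_as_primer(
        reference, snp, "ref", direction, config, length=len(as_primer)
    )
    if not _footprint_unique(
        reference, snp.chromosome, as_primer.start, as_primer.end
    ):
        raise AssayDesignError("AS primer footprint not unique in reference")

    mate_strand: Literal["+", "-"] = "-" if direction == "+" else "+"

    def mate_for_size(size: int) -> Primer | None:
        if direction == "+":
            # product spans [as_primer.start, as_primer.start + size)
            outer = as_primer.start + size
            if outer > len(chrom_seq):
                return None
        else:
            # product spans [as_primer.end - size, as_primer.end)
            outer = as_primer.end - size
            if outer < 0:
                return None
        mate = _design_conventional(
            reference, snp.chromosome, outer, mate_strand, config, matrix, snp
        )
        if mate is None:
            return None
        # product must contain the SNP position
        if direction == "+":
            if not (as_primer.start <= p < as_primer.start + size):
                return None
        else:
            if not (as_primer.end - size <= p < as_primer.end):
                return None
        return mate

    def scan(sizes: Iterable[int]) -> tuple[int, Primer] | None:
        for size in sizes:
            mate = mate_for_size(size)
            if mate is not None:
                return size, mate
        return None

    found = scan(range(scan_from, config.product_max + 1))
    if found is None and scan_from > config.product_min:
        found = scan(range(scan_from - 1, config.product_min - 1, -1))
    if found is None:
        raise AssayDesignError("no valid conventional mate for the AS product")
    as_size, as_mate = found

    wt_candidates: list[range] = []
    if as_size + config.min_size_gap <= config.product_max:
        wt_candidates.append(
            range(as_size + config.min_size_gap, config.product_max + 1)
        )
    if as_size - config.min_size_gap >= config.product_min:
        wt_candidates.append(
            range(as_size - config.min_size_gap, config.product_min - 1, -1)
        )
    wt_found = None
    for sizes in wt_candidates:
        wt_found = scan(sizes)
        if wt_found is not None:
            break
    if wt_found is None:
        raise AssayDesignError(
            f"no WT product size at least {config.min_size_gap} bp away from "
            f"the AS product ({as_size} bp) fits in "
            f"[{config.product_min}, {config.product_max}]"
        )
    wt_size, wt_mate = wt_found

    if direction == "+":
        as_pair, wt_pair = (as_primer, as_mate), (wt_primer, wt_mate)
    else:
        as_pair, wt_pair = (as_mate, as_primer), (wt_mate, wt_primer)
    return ASAssay(
        snp=snp,
        wt_pair=wt_pair,
        as_pair=as_pair,
        wt_product_size=wt_size,
        as_product_size=as_size,
        assay_id=assay_id or f"{snp.owner_strain}:{snp.chromosome}:{snp.position}",
    )


def design_assays(
    reference: ReferenceGenome,
    snps: Sequence[PrivateSNP],
    config: DesignConfig | None = None,
    matrix: GenotypeMatrix | None = None,
    size_stagger: int = 53,
    max_amplicon: int = 3000,
) -> tuple[list[ASAssay], list[tuple[PrivateSNP, str]]]:
    """Design assays for a marker set with panel-friendly staggered sizes.

    Successive assays start their product-size scan ``size_stagger`` bp apart
    so panel bands spread across the gel.  Markers closer than
    ``max_amplicon`` to an already-accepted marker on the same chromosome are
    skipped (their primers could cross-amplify in a multiplex reaction).
    Returns (assays, failures) where each failure carries its reason.
    """
    config = config or DesignConfig()
    assays: list[ASAssay] = []
    failures: list[tuple[PrivateSNP, str]] = []
    taken: list[tuple[str, int]] = []
    span = config.product_max - config.min_size_gap - config.product_min
    for snp in snps:
        if any(
            chrom == snp.chromosome and abs(pos - snp.position) <= max_amplicon
            for chrom, pos in taken
        ):
            failures.append((snp, "within max_amplicon of an accepted marker"))
            continue
        offset = (len(assays) * size_stagger) % max(span, 1)
        try:
            assay = design_assay(
                reference,
                snp,
                config,
                matrix,
                product_size_start=config.product_min + offset,
                assay_id=f"A{len(assays) + 1}",
            )
        except AssayDesignError as exc:
            failures.append((snp, str(exc)))
            continue
        assays.append(assay)
        taken.append((snp.chromosome, snp.position))
    return assays, failures


def interleave_by_owner(snps: Sequence[PrivateSNP]) -> list[PrivateSNP]:
    """Round-robin the markers across owner strains, preserving the per-owner
    order.  Feeding this ordering to :func:`design_assays` spreads design
    attempts evenly so every strain gets assays before any strain gets many."""
    by_owner: dict[str, list[PrivateSNP]] = {}
    for snp in snps:
        by_owner.setdefault(snp.owner_strain, []).append(snp)
    out: list[PrivateSNP] = []
    depth = 0
    while True:
        layer = [
            pool[depth] for _, pool in sorted(by_owner.items()) if depth < len(pool)
        ]
        if not layer:
            return out
        out.extend(layer)
        depth += 1


def select_compatible_assays(
    assays: Sequence[ASAssay],
    config: DesignConfig | None = None,
    per_strain: Mapping[str, int] | int = 3,
) -> list[ASAssay]:
    """Greedily pick a mutually compatible assay subset for one panel.

    Candidates are tried owners-round-robin (per-owner order preserved); a
    candidate is kept only if the growing set still passes every panel
    compatibility check.  ``per_strain`` caps assays per owner, either
    globally or per strain.
    """
    config = config or DesignConfig()
    caps = per_strain if isinstance(per_strain, Mapping) else None
    flat_cap = per_strain if isinstance(per_strain, int) else None

    by_owner: dict[str, list[ASAssay]] = {}
    for assay in assays:
        by_owner.setdefault(assay.snp.owner_strain, []).append(assay)

    chosen: list[ASAssay] = []
    counts: dict[str, int] = {}
    depth = 0
    while len(chosen) < 6:
        layer = [
            pool[depth] for _, pool in sorted(by_owner.items()) if depth < len(pool)
        ]
        if not layer:
            break
        for cand in layer:
            owner = cand.snp.owner_strain
            cap = caps.get(owner, 0) if caps is not None else flat_cap
            if counts.get(owner, 0) >= cap or len(chosen) >= 6:
                continue
            try:
                build_multiplex_panel(chosen + [cand], config)
            except ValueError:
                continue
            chosen.append(cand)
            counts[owner] = counts.get(owner, 0) + 1
        depth += 1
    return chosen


# ---------------------------------------------------------------------------
# Multiplex panel
# ---------------------------------------------------------------------------


def _three_prime_dimer_run(a: str, b: str) -> int:
    """Longest run of perfect complementarity anchored at the 3' end of ``a``
    against any window of ``b`` (either orientation of b's sense)."""
    tail = revcomp(a)  # complement of a, 3' end first... see below
    # complement of the 3' tail of a, 5'->3', is a prefix of revcomp(a)
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        if tail[:k] in b:
            best = k
        else:
            break
    return best


def build_multiplex_panel(
    assays: Sequence[ASAssay],
    config: DesignConfig | None = None,
    protocol: ThermalProtocol | None = None,
) -> MultiplexPanel:
    """Validate assay compatibility and assemble a multiplex panel.

    Only the allele-specific pairs enter the reaction.  Checks: 2-12 total
    primers, pairwise Tm spread, within-strain band separation at gel
    resolution, and absence of long 3'-anchored cross-complementarity
    between any two primers.  Violations raise with the offending pair.
    """
    config = config or DesignConfig()
    if not (1 <= len(assays) <= 6):
        raise ValueError("a panel holds between 1 and 6 assays (2-12 primers)")

    primers: list[Primer] = []
    for assay in assays:
        primers.extend(assay.as_pair)

    tms = [p.tm_celsius for p in primers]
    spread = max(tms) - min(tms)
    if spread > config.tm_spread_max:
        hot = max(primers, key=lambda p: p.tm_celsius)
        cold = min(primers, key=lambda p: p.tm_celsius)
        raise ValueError(
            f"Tm spread {spread:.2f} C exceeds {config.tm_spread_max:g} C "
            f"({hot.name} vs {cold.name})"
        )

    for i in range(len(primers)):
        for j in range(len(primers)):
            if i == j:
                continue
            run = _three_prime_dimer_run(primers[i].sequence, primers[j].sequence)
            if run >= config.dimer_max:
                raise ValueError(
                    f"3' cross-complementarity of {run} nt between "
                    f"{primers[i].name} and {primers[j].name}"
                )

    signatures: dict[str, BandPattern] = {}
    for assay in assays:
        owner = assay.snp.owner_strain
        sizes = list(signatures.get(owner, BandPattern(())).sizes)
        sizes.append(float(assay.as_product_size))
        signatures[owner] = BandPattern(tuple(sorted(sizes)))

    for strain, pattern in signatures.items():
        sizes = pattern.sizes
        for a, b in zip(sizes, sizes[1:]):
            if b - a < config.gel_resolution:
                raise ValueError(
                    f"bands {a:g} and {b:g} bp for strain {strain} are closer "
                    f"than the gel resolution ({config.gel_resolution} bp)"
                )

    names = sorted(signatures)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if signatures[a].matches(signatures[b], config.gel_resolution):
                raise ValueError(
                    f"strains {a} and {b} would have indistinguishable "
                    f"signatures at {config.gel_resolution} bp resolution"
                )

    return MultiplexPanel(
        assays=list(assays),
        protocol=protocol or touchdown_protocol(),
        strain_signatures=signatures,
        gel_resolution=config.gel_resolution,
    )


# ---------------------------------------------------------------------------
# Thermal protocol
# ---------------------------------------------------------------------------


def touchdown_protocol(
    start_temp: float = 69.5,
    end_temp: float = 61.5,
    step: float = 1.0,
    standard_cycles: int = 25,
    activation: tuple[float, int] = (98.0, 120),
    denature: tuple[float, int] = (95.0, 30),
    anneal_seconds: int = 30,
    extend: tuple[float, int] = (72.0, 60),
    final_extension: tuple[float, int] = (72.0, 300),
) -> ThermalProtocol:
    """Touch-down cycling program.

    The annealing temperature starts at ``start_temp`` and decreases by
    ``step`` per cycle; the touch-down phase stops at the last temperature
    still >= ``end_temp`` (no overshoot), then ``standard_cycles`` cycles run
    at ``end_temp``.  Defaults reproduce a 69.5 -> 61.5 C ramp at 1 C/cycle
    (9 touch-down cycles) plus 25 standard cycles: 34 total.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if end_temp > start_temp:
        raise ValueError("end_temp must not exceed start_temp")
    if standard_cycles < 0:
        raise ValueError("standard_cycles must be non-negative")

    n_touchdown = int(math.floor((start_temp - end_temp) / step + 1e-9)) + 1
    touchdown = tuple(
        (denature, (start_temp - i * step, anneal_seconds), extend)
        for i in range(n_touchdown)
    )
    return ThermalProtocol(
        activation=activation,
        touchdown_cycles=touchdown,
        standard_cycle_count=standard_cycles,
        standard_cycle=(denature, (end_temp, anneal_seconds), extend),
        final_extension=final_extension,
    )


def write_panel_report(panel: MultiplexPanel, path: str | Path) -> None:
    """TSV: assay id, strain, locus, primer sequences, Tm, product sizes."""
    import pandas as pd

    rows = []
    for assay in panel.assays:
        fwd, rev = assay.as_pair
        rows.append(
            {
                "assay_id": assay.assay_id,
                "strain": assay.snp.owner_strain,
                "chrom": assay.snp.chromosome,
                "pos": assay.snp.position,
                "ref": assay.snp.ref_allele,
                "alt": assay.snp.alt_allele,
                "as_forward": fwd.sequence,
                "as_reverse": rev.sequence,
                "tm_forward": round(fwd.tm_celsius, 2),
                "tm_reverse": round(rev.tm_celsius, 2),
                "as_product_bp": assay.as_product_size,
                "wt_product_bp": assay.wt_product_size,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
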