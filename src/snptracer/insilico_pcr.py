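"""In-silico PCR: amplicon prediction, gel rendering, fingerprint clustering,
colony assignment, and frequency tallies.

Binding model: a primer anneals at a site iff its 3'-terminal base matches
the template exactly and the number of internal mismatches does not exceed a
configurable bound (default 1, which tolerates the engineered destabilizer
of allele-specific primers on their intended template; inter-delta primers
use a looser bound because delta elements diverge).  Every convergent
forward/reverse site pair on one chromosome within ``max_amplicon`` yields
an amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import encode, revcomp
from .genomes_io import BandPattern, ReferenceGenome
from .assay_design import MultiplexPanel, Primer

__all__ = [
    "PCRConfig",
    "Amplicon",
    "ColonyAssignment",
    "DELTA12",
    "DELTA21",
    "predict_amplicons",
    "gel_pattern",
    "interdelta_fingerprint",
    "cluster_fingerprints",
    "assign_colony",
    "tally_frequencies",
    "write_assignment_report",
]

# delta-element primers of the standard interdelta typing method
DELTA12 = "TCAACAATGGAATCCCAAC"
DELTA21 = "CATCTTAACACCGTATATGA"

_MIN_PRIMER_LEN = 8


@dataclass(frozen=True)
class PCRConfig:
    internal_mismatch_max: int = 1
    max_amplicon: int = 3000
    gel_resolution: int = 25


@dataclass(frozen=True)
class Amplicon:
    chromosome: str
    start: int  # 0-based half-open on the template
    end: int
    forward_primer: str  # primer id
    reverse_primer: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ColonyAssignment:
    colony_id: str
    observed: BandPattern
    call: str  # strain name, "unassigned", or "ambiguous"
    matched_signature: BandPattern | None = None


def _as_id_seq(primer) -> tuple[str, str]:
    if isinstance(primer, Primer):
        return (primer.name or primer.sequence, primer.sequence)
    if isinstance(primer, tuple):
        return primer
    return (str(primer), str(primer))


def _binding_sites(
    template: np.ndarray, primer: str, max_internal: int
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions where the primer binds as a forward / reverse primer.

    Returns (forward_starts, reverse_starts); a start is the leftmost
    template coordinate of the primer footprint.
    """
    L = len(primer)
    n = len(template)
    if n < L:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty

    w = n - L + 1

    def scan(pattern: np.ndarray, terminal_index: int) -> np.ndarray:
        mism = np.zeros(w, dtype=np.int32)
        for j in range(L):
            mism += template[j : j + w] != pattern[j]
        term_bad = template[terminal_index : terminal_index + w] != pattern[terminal_index]
        internal = mism - term_bad.astype(np.int32)
        return np.flatnonzero(~term_bad & (internal <= max_internal))

    fwd = scan(encode(primer), L - 1)  # primer == top strand, 3' at right
    rev = scan(encode(revcomp(primer)), 0)  # 3' at left
    return fwd, rev


def predict_amplicons(
    template: ReferenceGenome | Mapping[str, str],
    primers: Iterable,
    config: PCRConfig | None = None,
) -> list[Amplicon]:
    """Enumerate all amplicons the primer set produces on the template.

    ``primers`` may hold :class:`Primer` objects, (id, sequence) tuples, or
    bare sequences.  Every primer is scanned in both orientations; each
    convergent forward/reverse site combination within ``max_amplicon`` on
    the same chromosome is emitted.
    """
    config = config or PCRConfig()
    chromosomes = (
        template.chromosomes if isinstance(template, ReferenceGenome) else template
    )
    prims = [_as_id_seq(p) for p in primers]
    for pid, seq in prims:
        if len(seq) < _MIN_PRIMER_LEN:
            raise ValueError(f"primer {pid!r} shorter than {_MIN_PRIMER_LEN} nt")

    amplicons: list[Amplicon] = []
    for chrom, seq in chromosomes.items():
        arr = encode(seq)
        fwd_sites: list[tuple[int, int, str]] = []  # (start, length, id)
        rev_sites: list[tuple[int, int, str]] = []
        for pid, pseq in prims:
            f, r = _binding_sites(arr, pseq, config.internal_mismatch_max)
            fwd_sites.extend((int(s), len(pseq), pid) for s in f)
            rev_sites.extend((int(s), len(pseq), pid) for s in r)
        fwd_sites.sort()
        rev_sites.sort()
        for f_start, f_len, f_id in fwd_sites:
            for r_start, r_len, r_id in rev_sites:
                if r_start < f_start:
                    continue
                if r_start - f_start > config.max_amplicon:
                    break  # rev_sites sorted: everything further is longer
                end = r_start + r_len
                length = end - f_start
                if length > config.max_amplicon or length < max(f_len, r_len):
                    continue
                amplicons.append(
                    Amplicon(
                        chromosome=chrom,
                        start=f_start,
                        end=end,
                        forward_primer=f_id,
                        reverse_primer=r_id,
                    )
                )
    return amplicons


def gel_pattern(
    amplicons: Iterable[Amplicon] | Iterable[float], gel_resolution: int = 25
) -> BandPattern:
    """Render amplicon sizes as gel bands.

    Sizes closer than ``gel_resolution`` chain into one band reported at
    their mean -- a gel resolves bands, not molecules.  Idempotent: merged
    group means are always at least one resolution apart.
    """
    sizes = sorted(
        a.length if isinstance(a, Amplicon) else float(a) for a in amplicons
    )
    if not sizes:
        return BandPattern(())
    bands: list[float] = []
    group = [sizes[0]]
    for s in sizes[1:]:
        if s - group[-1] < gel_resolution:
            group.append(s)
        else:
            bands.append(sum(group) / len(group))
            group = [s]
    bands.append(sum(group) / len(group))
    return BandPattern(tuple(bands))


def interdelta_fingerprint(
    genome: ReferenceGenome | Mapping[str, str],
    delta12_seq: str = DELTA12,
    delta21_seq: str = DELTA21,
    config: PCRConfig | None = None,
) -> BandPattern:
    """Inter-delta fingerprint: all amplicons between delta-primer sites.

    Delta elements diverge, so the default binding rule tolerates two
    internal mismatches.
    """
    config = config or PCRConfig(internal_mismatch_max=2)
    amplicons = predict_amplicons(genome, [("delta12", delta12_seq), ("delta21", delta21_seq)], config)
    return gel_pattern(amplicons, config.gel_resolution)


def cluster_fingerprints(
    patterns: Mapping[str, BandPattern], gel_resolution: int = 25
) -> list[list[str]]:
    """Partition strains by fingerprint equality.

    Two strains share a class iff their patterns match band-by-band within
    the gel resolution.  Classes are returned sorted by size descending,
    then by the name of their first member; members are sorted by name.
    """
    classes: list[tuple[BandPattern, list[str]]] = []
    for strain in sorted(patterns):
        pattern = patterns[strain]
        for rep, members in classes:
            if pattern.matches(rep, gel_resolution):
                members.append(strain)
                break
        else:
            classes.append((pattern, [strain]))
    out = [sorted(members) for _, members in classes]
    out.sort(key=lambda members: (-len(members), members[0]))
    return out


def assign_colony(
    observed: BandPattern, panel: MultiplexPanel
) -> ColonyAssignment:
    """Call a colony from its observed band pattern.

    Exact signature match (within the panel's gel resolution) wins; an empty
    pattern or one matching no signature is "unassigned"; a pattern equal to
    the merged union of two or more signatures is "ambiguous" (mixed
    template) rather than a guessed single parent.
    """
    return _assign(observed, panel, colony_id="")


def _assign(
    observed: BandPattern, panel: MultiplexPanel, colony_id: str
) -> ColonyAssignment:
    tol = panel.gel_resolution
    if observed.is_empty():
        return ColonyAssignment(colony_id, observed, "unassigned")
    hits = [
        (strain, sig)
        for strain, sig in sorted(panel.strain_signatures.items())
        if observed.matches(sig, tol)
    ]
    if len(hits) == 1:
        strain, sig = hits[0]
        return ColonyAssignment(colony_id, observed, strain, sig)
    if len(hits) > 1:
        return ColonyAssignment(colony_id, observed, "ambiguous")
    strains = sorted(s for s, sig in panel.strain_signatures.items() if not sig.is_empty())
    for k in range(2, len(strains) + 1):
        for combo in combinations(strains, k):
            union = gel_pattern(
                [s for name in combo for s in panel.strain_signatures[name].sizes],
                tol,
            )
            if observed.matches(union, tol):
                return ColonyAssignment(colony_id, observed, "ambiguous")
    return ColonyAssignment(colony_id, observed, "unassigned")


def assign_colonies(
    observations: Mapping[str, BandPattern], panel: MultiplexPanel
) -> list[ColonyAssignment]:
    return [_assign(pattern, panel, cid) for cid, pattern in observations.items()]


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def tally_frequencies(
    assignments: Sequence[ColonyAssignment],
    grouping: Mapping[str, str] | None = None,
) -> dict[str, dict[str, int]]:
    """Per-strain (and optionally per-cluster) percentages, nearest integer.

    Percentages are taken over the full colony count, assigned or not;
    rounding is half-away-from-zero (14 of 26 -> 54).
    """
    if not assignments:
        raise ValueError("no assignments to tally")
    total = len(assignments)
    strain_counts: dict[str, int] = {}
    for a in assignments:
        strain_counts[a.call] = strain_counts.get(a.call, 0) + 1
    result: dict[str, dict[str, int]] = {
        "strain": {
            name: _round_half_away(100.0 * count / total)
            for name, count in sorted(strain_counts.items())
        }
    }
    if grouping is not None:
        cluster_counts: dict[str, int] = {}
        for a in assignments:
            cluster = grouping.get(a.call, a.call)
            cluster_counts[cluster] = cluster_counts.get(cluster, 0) + 1
        result["cluster"] = {
            name: _round_half_away(100.0 * count / total)
            for name, count in sorted(cluster_counts.items())
        }
    return result


def write_assignment_report(
    assignments: Sequence[ColonyAssignment], path: str | Path
) -> None:
    """TSV: colony, observed band sizes, call."""
    import pandas as pd

    rows = [
        {
            "colony": a.colony_id,
            "observed_bp": ",".join(f"{s:g}" for s in a.observed.sizes) or ".",
            "call": a.call,
        }
        for a in assignments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
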