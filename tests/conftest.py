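"""Shared fixtures: toy matrices, a 28-strain synthetic collection, and a
fully designed 4-strain assay panel (session-scoped, built once)."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from snptracer.assay_design import (
    DesignConfig,
    build_multiplex_panel,
    design_assays,
    interleave_by_owner,
    select_compatible_assays,
)
from snptracer.genomes_io import GenotypeMatrix, Genotype, VariantRecord
from snptracer.synthetic_data import (
    assay_design_spec,
    default_collection_spec,
    derive_strains,
    generate_reference,
)
from snptracer.variant_selection import apply_marker_criteria, call_private_snps

SESSION_SEED = 20250904


def make_matrix(strains, loci):
    """Build a GenotypeMatrix from compact tuples.

    Each locus is (chrom, pos, ref, alt, {strain: Genotype}, depth) with
    unlisted strains hom-ref and a single depth applied to all strains, or
    optionally a per-strain depth dict.
    """
    records = []
    for chrom, pos, ref, alt, carriers, depth in loci:
        genotypes = {s: carriers.get(s, Genotype.HOM_REF) for s in strains}
        depths = depth if isinstance(depth, dict) else {s: depth for s in strains}
        records.append(
            VariantRecord(
                chromosome=chrom,
                position=pos,
                ref_allele=ref,
                alt_allele=alt,
                genotypes=genotypes,
                depths=depths,
            )
        )
    return GenotypeMatrix(strain_names=list(strains), records=records)


@pytest.fixture(scope="session")
def collection28():
    """The 28-strain collection: 1 six-member + 4 two-member clusters + 14
    singletons, with planted delta layouts and private SNPs."""
    spec = default_collection_spec(SESSION_SEED)
    reference = generate_reference(spec)
    truth = derive_strains(reference, spec)
    return SimpleNamespace(spec=spec, reference=reference, truth=truth)


@pytest.fixture(scope="session")
def assay_world():
    """A 4-strain cluster with designed assays and a 6-assay multiplex panel
    (2 assays each for strains A and B, 1 each for C and D)."""
    spec = assay_design_spec(SESSION_SEED)
    reference = generate_reference(spec)
    truth = derive_strains(reference, spec)
    matrix = truth.matrix()
    snps = call_private_snps(matrix)
    candidates = apply_marker_criteria(snps, reference, matrix)
    passing = interleave_by_owner([c.snp for c in candidates if c.passes])
    config = DesignConfig()
    assays, failures = design_assays(reference, passing, config, matrix)
    chosen = select_compatible_assays(
        assays, config, per_strain={"C1.A": 2, "C1.B": 2, "C1.C": 1, "C1.D": 1}
    )
    panel = build_multiplex_panel(chosen, config)
    return SimpleNamespace(
        spec=spec,
        reference=reference,
        truth=truth,
        matrix=matrix,
        snps=snps,
        candidates=candidates,
        config=config,
        assays=assays,
        failures=failures,
        panel=panel,
    )
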