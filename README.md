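# snptracer

SNP-based strain traceability, end-to-end in silico:

1. **Discover strain-private SNP markers** from a multi-sample VCF:
   biallelic SNPs whose alternate allele occurs in exactly one strain, with
   every strain covered at ≥ 50× and no missing call (InDels excluded), then
   screened against marker-quality criteria (polymorphic flanks, repeats,
   soft-masked or GC-extreme regions, non-unique primer footprints) and
   ranked to spread markers across chromosomes.
2. **Design allele-specific (AS) PCR assays**: for each marker, a wild-type
   pair and a variant pair whose allele-specific primer ends on the SNP and
   carries an engineered destabilizing mismatch at position −2 from the
   3′ end; the two products are forced to differ by ≥ 200 bp. Melting
   temperatures come from unified nearest-neighbor thermodynamics with salt
   correction.
3. **Assemble multiplex panels** (2–12 primers, AS pairs only) with Tm
   spread, primer-dimer, and gel band-separation compatibility checks, plus
   the touch-down thermal protocol (69.5 → 61.5 °C at −1 °C/cycle, 9
   touch-down + 25 standard = 34 cycles).
4. **Verify in silico**: simulate AS-PCR and inter-delta amplification on
   strain genomes, render gel band patterns, cluster fingerprints, assign
   colonies to strains by signature matching, and tally strain/cluster
   frequencies.
5. **Phylogeny**: pairwise unshared-variant distances and a from-scratch
   neighbor-joining tree, written as Newick.
6. **Synthetic data**: a seeded generator of toy references and strain
   collections with cluster structure (shared SNP backbones, private SNPs,
   planted delta-element layouts), so everything is testable offline.

## CLI

```sh
snptracer protocol                          # print the touch-down program
snptracer simulate-collection --seed 1 --outdir bundle/
snptracer call-private bundle/truth.vcf --out private.tsv
snptracer call-private bundle/truth.vcf --reference bundle/reference.fa --out candidates.tsv
snptracer design-panel bundle/reference.fa bundle/truth.vcf --out panel.tsv
snptracer fingerprint bundle/strain_*.fa --out fingerprints.tsv
snptracer nj-tree bundle/truth.vcf --newick-out tree.nwk --distances-out d.tsv
```

## Library layout

| module | contents |
| --- | --- |
| `snptracer.genomes_io` | `ReferenceGenome`, `GenotypeMatrix`, `BandPattern`; FASTA/VCF readers, Newick writer |
| `snptracer.variant_selection` | private-SNP calling, marker criteria and ranking |
| `snptracer.phylo` | unshared-variant distances, neighbor joining |
| `snptracer.assay_design` | Tm, AS primer/assay design, multiplex panels, touch-down protocol |
| `snptracer.insilico_pcr` | amplicon prediction, gel rendering, inter-delta fingerprints, colony assignment, tallies |
| `snptracer.synthetic_data` | seeded collection generator, truth bundles, colony sampling |
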