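import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snptracer._seq import revcomp
from snptracer.genomes_io import BandPattern, ReferenceGenome
from snptracer.insilico_pcr import (
    DELTA12,
    DELTA21,
    Amplicon,
    PCRConfig,
    assign_colony,
    cluster_fingerprints,
    gel_pattern,
    interdelta_fingerprint,
    predict_amplicons,
    tally_frequencies,
    write_assignment_report,
)
from snptracer.insilico_pcr import ColonyAssignment


def _planted_template(fwd_primer, rev_primer, gap, seed=0, pad=2000):
    """Random sequence with one convergent primer pair yielding a product of
    length len(fwd) + gap + len(rev)."""
    rng = np.random.default_rng(seed)
    left = "".join(rng.choice(list("ACGT"), size=pad))
    mid = "".join(rng.choice(list("ACGT"), size=gap))
    right = "".join(rng.choice(list("ACGT"), size=pad))
    seq = left + fwd_primer + mid + revcomp(rev_primer) + right
    return ReferenceGenome({"chr1": seq}), pad


class TestPredictAmplicons:
    FWD = "ACGTGCATCGATCGTAGCAT"
    REV = "TGCATGCATCGATCAGGTCA"

    def test_exact_pair_amplifies_planned_size(self):
        genome, pad = _planted_template(self.FWD, self.REV, gap=160, seed=1)
        amps = predict_amplicons(genome, [("f", self.FWD), ("r", self.REV)])
        assert len(amps) == 1
        assert amps[0].length == len(self.FWD) + 160 + len(self.REV)
        assert amps[0].start == pad

    def test_three_prime_terminal_mismatch_blocks(self):
        genome, _ = _planted_template(self.FWD, self.REV, gap=160, seed=2)
        bad_fwd = self.FWD[:-1] + ("A" if self.FWD[-1] != "A" else "C")
        amps = predict_amplicons(genome, [("f", bad_fwd), ("r", self.REV)])
        assert amps == []

    def test_one_internal_mismatch_tolerated(self):
        genome, _ = _planted_template(self.FWD, self.REV, gap=160, seed=3)
        mut = list(self.FWD)
        mut[5] = "A" if mut[5] != "A" else "C"
        amps = predict_amplicons(genome, [("f", "".join(mut)), ("r", self.REV)])
        assert len(amps) == 1

    def test_two_internal_mismatches_blocked_at_default(self):
        genome, _ = _planted_template(self.FWD, self.REV, gap=160, seed=4)
        mut = list(self.FWD)
        for i in (5, 9):
            mut[i] = "A" if mut[i] != "A" else "C"
        assert predict_amplicons(genome, [("f", "".join(mut)), ("r", self.REV)]) == []
        relaxed = PCRConfig(internal_mismatch_max=2)
        assert (
            len(predict_amplicons(genome, [("f", "".join(mut)), ("r", self.REV)], relaxed))
            == 1
        )

    def test_max_amplicon_cutoff(self):
        genome, _ = _planted_template(self.FWD, self.REV, gap=5000, seed=5, pad=500)
        assert predict_amplicons(genome, [("f", self.FWD), ("r", self.REV)]) == []
        roomy = PCRConfig(max_amplicon=10_000)
        assert len(predict_amplicons(genome, [("f", self.FWD), ("r", self.REV)], roomy)) == 1

    def test_short_primer_rejected(self):
        genome, _ = _planted_template(self.FWD, self.REV, gap=100)
        with pytest.raises(ValueError, match="shorter"):
            predict_amplicons(genome, ["ACGT"])

    def test_as_assay_owner_vs_reference(self, assay_world):
        """AS pairs amplify the planned size on the owner genome and nothing
        on the reference haplotype (3'-terminal discrimination)."""
        truth = assay_world.truth
        for assay in assay_world.panel.assays:
            owner = assay.snp.owner_strain
            amps = predict_amplicons(truth.strain_genomes[owner], assay.as_pair)
            assert assay.as_product_size in [a.length for a in amps]
            assert predict_amplicons(truth.reference, assay.as_pair) == []

    def test_wt_pair_amplifies_reference(self, assay_world):
        for assay in assay_world.panel.assays:
            amps = predict_amplicons(assay_world.truth.reference, assay.wt_pair)
            assert [a.length for a in amps] == [assay.wt_product_size]


class TestGelPattern:
    def test_empty(self):
        assert gel_pattern([]).is_empty()

    def test_close_sizes_merge_to_mean(self):
        assert gel_pattern([300.0, 310.0], 25).sizes == (305.0,)

    def test_distant_sizes_stay_separate(self):
        assert gel_pattern([203.0, 430.0], 25).sizes == (203.0, 430.0)

    def test_single_linkage_chain_merges(self):
        # oracle: single-linkage chaining 100-120-140 under resolution 25
        assert gel_pattern([100.0, 120.0, 140.0], 25).sizes == (120.0,)

    def test_accepts_amplicons(self):
        amp = Amplicon("chr1", 0, 300, "f", "r")
        assert gel_pattern([amp]).sizes == (300.0,)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(min_value=50, max_value=3000), max_size=20),
        st.integers(1, 100),
    )
    def test_idempotent(self, sizes, resolution):
        once = gel_pattern(sizes, resolution)
        twice = gel_pattern(once.sizes, resolution)
        assert once == twice
        # merged bands are separated by at least the resolution
        for a, b in zip(once.sizes, once.sizes[1:]):
            assert b - a >= resolution


class TestInterdelta:
    def test_planted_convergent_sites_one_band(self):
        rng = np.random.default_rng(9)
        from snptracer.synthetic_data import CollectionSpec, generate_reference

        spec = CollectionSpec(seed=9, chromosome_count=2, chrom_length=12_000, clusters=())
        clean = generate_reference(spec)  # scrubbed of spurious delta sites
        seq = list(clean["chr1"])
        span = 400
        seq[3000 : 3000 + len(DELTA12)] = list(DELTA12)
        rc21 = revcomp(DELTA21)
        seq[3000 + span - len(DELTA21) : 3000 + span] = list(rc21)
        genome = ReferenceGenome({"chr1": "".join(seq)})
        pattern = interdelta_fingerprint(genome)
        assert pattern.sizes == (float(span),)

    def test_no_sites_empty_pattern(self):
        from snptracer.synthetic_data import CollectionSpec, generate_reference

        spec = CollectionSpec(seed=10, chromosome_count=2, chrom_length=12_000, clusters=())
        assert interdelta_fingerprint(generate_reference(spec)).is_empty()

    def test_same_layout_identical_patterns(self, collection28):
        truth = collection28.truth
        by_layout = {}
        for strain, layout in truth.delta_layouts.items():
            by_layout.setdefault(layout, []).append(strain)
        for layout, members in by_layout.items():
            patterns = [
                interdelta_fingerprint(truth.strain_genomes[s]) for s in members
            ]
            assert all(p == patterns[0] for p in patterns)

    def test_different_layouts_differ(self, collection28):
        truth = collection28.truth
        seen = {}
        for strain, layout in truth.delta_layouts.items():
            pattern = interdelta_fingerprint(truth.strain_genomes[strain])
            if layout in seen:
                assert pattern == seen[layout]
            else:
                for other_layout, other in seen.items():
                    assert not pattern.matches(other, 25), (layout, other_layout)
                seen[layout] = pattern


class TestClusterFingerprints:
    def test_all_identical_one_class(self):
        p = BandPattern((100.0, 200.0))
        assert cluster_fingerprints({"A": p, "B": p, "C": p}) == [["A", "B", "C"]]

    def test_partition_is_well_defined(self):
        patterns = {
            "A": BandPattern((100.0,)),
            "B": BandPattern((100.0,)),
            "C": BandPattern((400.0,)),
        }
        classes = cluster_fingerprints(patterns, 25)
        assert classes == [["A", "B"], ["C"]]

    def test_order_by_size_then_name(self):
        patterns = {
            "Z": BandPattern((100.0,)),
            "A": BandPattern((400.0,)),
            "B": BandPattern((400.0,)),
            "M": BandPattern((700.0,)),
        }
        classes = cluster_fingerprints(patterns, 25)
        assert classes == [["A", "B"], ["M"], ["Z"]]


class TestAssignColony:
    def test_exact_match(self, assay_world):
        panel = assay_world.panel
        strain, sig = next(iter(sorted(panel.strain_signatures.items())))
        result = assign_colony(sig, panel)
        assert result.call == strain
        assert result.matched_signature == sig

    def test_empty_unassigned(self, assay_world):
        assert assign_colony(BandPattern(()), assay_world.panel).call == "unassigned"

    def test_unknown_pattern_unassigned(self, assay_world):
        weird = BandPattern((123.0, 1234.0, 2345.0))
        assert assign_colony(weird, assay_world.panel).call == "unassigned"

    def test_union_of_two_signatures_ambiguous(self, assay_world):
        panel = assay_world.panel
        names = sorted(panel.strain_signatures)
        a, b = names[0], names[1]
        union = gel_pattern(
            list(panel.strain_signatures[a].sizes)
            + list(panel.strain_signatures[b].sizes),
            panel.gel_resolution,
        )
        assert assign_colony(union, panel).call == "ambiguous"


class TestTallyFrequencies:
    def _assignments(self, calls):
        return [
            ColonyAssignment(f"c{i}", BandPattern(()), call)
            for i, call in enumerate(calls)
        ]

    def test_14_of_26_rounds_to_54(self):
        calls = ["C1.B"] * 14 + ["U4"] * 12
        grouping = {"C1.B": "C1", "U4": "U4"}
        out = tally_frequencies(self._assignments(calls), grouping)
        assert out["cluster"]["C1"] == 54

    def test_all_one_strain(self):
        out = tally_frequencies(self._assignments(["X"] * 7))
        assert out["strain"]["X"] == 100

    def test_pooled_replicates_total(self):
        calls = ["A"] * 13 + ["B"] * 13
        out = tally_frequencies(self._assignments(calls))
        assert out["strain"] == {"A": 50, "B": 50}

    def test_unassigned_in_denominator(self):
        calls = ["A"] * 3 + ["unassigned"] * 1
        out = tally_frequencies(self._assignments(calls))
        assert out["strain"]["A"] == 75
        assert out["strain"]["unassigned"] == 25

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tally_frequencies([])

    def test_report_written(self, tmp_path):
        write_assignment_report(
            self._assignments(["A", "unassigned"]), tmp_path / "a.tsv"
        )
        text = (tmp_path / "a.tsv").read_text()
        assert "unassigned" in text


class TestPanelContracts:
    def test_specificity_no_offtarget_strain_amplifies(self, assay_world):
        """Strains lacking the target allele give no product for any assay."""
        truth = assay_world.truth
        for assay in assay_world.panel.assays:
            owner = assay.snp.owner_strain
            for strain, genome in truth.strain_genomes.items():
                if strain == owner:
                    continue
                assert predict_amplicons(genome, assay.as_pair) == [], (
                    assay.assay_id,
                    strain,
                )

    def test_adding_unrelated_primers_preserves_products(self, assay_world):
        """Scaling the reaction from 2 to 12 primers never changes the
        product set attributable to one assay's own primers."""
        truth = assay_world.truth
        panel = assay_world.panel
        all_primers = panel.primers()
        for assay in panel.assays:
            owner = assay.snp.owner_strain
            genome = truth.strain_genomes[owner]
            alone = {
                (a.chromosome, a.start, a.end)
                for a in predict_amplicons(genome, assay.as_pair)
            }
            own_ids = {p.name for p in assay.as_pair}
            with_all = {
                (a.chromosome, a.start, a.end)
                for a in predict_amplicons(genome, all_primers)
                if a.forward_primer in own_ids and a.reverse_primer in own_ids
            }
            assert alone == with_all
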