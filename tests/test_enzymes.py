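"""Cleavage geometry: offsets, fragment lengths, constrained sites,
theoretical digests and fragment/read classification."""

import numpy as np
import pytest

from mfremotif.enzymes import (
    FSPEI,
    GENERIC_MFRE,
    MSPJI,
    CleavageDistances,
    FragmentCategory,
    IncompatibleMotifError,
    Methylome,
    MotifModel,
    bin_distance,
    ccmd_length,
    classify_read_cutting,
    cleavage_distances,
    constrained_site,
    digest,
    expected_cuts,
    fragments_from_cuts,
    offset_x,
)
from mfremotif.sequence import ReferenceGenome, expand_degenerate, iupac_match

from conftest import random_genome


class TestOffsetGeometry:
    @pytest.mark.parametrize("motif,top,expected_x", [
        ("AGCT", 2, 1),
        ("CCWGG", 1, -2),
        ("CG", 0, -1),   # both C's methylated in the 2-mer palindrome
    ])
    def test_offset_examples(self, motif, top, expected_x):
        assert MotifModel.palindromic(motif, top).x == expected_x

    def test_x_zero_impossible(self):
        # GC with top m5C opposite the bottom m5C would mean the two
        # methylated bases are paired; the model must refuse it.
        with pytest.raises(ValueError):
            MotifModel("GC", 1, 1)
        with pytest.raises(ValueError):
            ccmd_length(0)

    @pytest.mark.parametrize("x,length", [(-2, 31), (1, 34), (-7, 26), (7, 40)])
    def test_ccmd_length(self, x, length):
        assert ccmd_length(x) == length

    def test_eight_base_motif_length_range(self):
        # All valid m5C placements in an 8-base motif give lengths 26-40,
        # never 33.
        lengths = set()
        for top in range(8):
            for bottom in range(8):
                if top == bottom:
                    continue
                lengths.add(ccmd_length(top - bottom))
        assert min(lengths) == 26
        assert max(lengths) == 40
        assert 33 not in lengths


class TestConstrainedSite:
    @pytest.mark.parametrize("motif,top,enzyme,expected", [
        ("GATC", 3, MSPJI, "YNNGATCNNR"),
        ("TCGA", 1, MSPJI, "YTCGAR"),
        ("CGATCG", 0, FSPEI, "CCGATCGG"),
        ("CCWGG", 1, MSPJI, "CCWGG"),  # already satisfies the context
    ])
    def test_printed_cases(self, motif, top, enzyme, expected):
        model = MotifModel.palindromic(motif, top)
        assert constrained_site(model, enzyme) == expected

    def test_incompatible_motif(self):
        # FspEI needs CC: a motif with A 5' of the m5C cannot be cut.
        model = MotifModel("ACGT", 1, 2)
        with pytest.raises(IncompatibleMotifError):
            constrained_site(model, FSPEI)

    def test_constrained_instances_subset_of_padded_motif(self):
        model = MotifModel.palindromic("GATC", 3)
        constrained = constrained_site(model, MSPJI)
        padded = "NNNGATCNNN"
        assert all(iupac_match(inst, padded)
                   for inst in expand_degenerate(constrained))

    def test_constrained_sites_doubly_cleavable(self, rng):
        # Every genome position matching the constrained site must receive
        # cuts on both sides under a full digest.
        genome = random_genome(rng, 10_000)
        model = MotifModel.palindromic("GATC", 3)
        pattern = constrained_site(model, MSPJI)
        seq = genome["chr"]
        methylome = Methylome()
        starts = []
        for s in range(30, len(seq) - 30):
            if seq[s:s + 4] == "GATC":
                methylome.add_full_site("chr", s, model)
                starts.append(s)
        assert len(starts) > 5
        cuts = expected_cuts(genome, methylome, [MSPJI])
        cut_pos = {(c.position, c.side) for c in cuts}
        for s in starts:
            window = seq[s - 3:s + 7]
            both = ((s - 16, "left") in cut_pos and (s + 3 + 17, "right") in cut_pos)
            assert both == iupac_match(window, pattern)


def genome_with_site(rng, motif_instance, pos=100, length=200):
    genome = random_genome(rng, length)
    seq = list(genome["chr"])
    seq[pos:pos + len(motif_instance)] = motif_instance
    return ReferenceGenome([("chr", "".join(seq))])


class TestDigest:
    def test_fully_methylated_site_excised(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100)
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        frags = digest(genome, methylome, [GENERIC_MFRE])
        excised = [f for f in frags if f.category == FragmentCategory.MOTIF_CLEAVED]
        assert len(excised) == 1
        frag = excised[0]
        assert frag.length == 31 == ccwgg.ccmd_len
        # 15th base (1-based) of the excised top strand is the methylated C
        assert genome["chr"][frag.start + 14] == "C"
        assert frag.start + 14 == 100 + ccwgg.top_m5c_index

    def test_unmethylated_site_uncut(self, rng):
        genome = genome_with_site(rng, "CCAGG", pos=100)
        frags = digest(genome, Methylome(), [GENERIC_MFRE])
        assert len(frags) == 1
        assert frags[0].length == genome.total_length()

    def test_hemi_methylated_single_cut(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100)
        methylome = Methylome()
        methylome.add_hemi_site("chr", 100, ccwgg)
        frags = digest(genome, methylome, [GENERIC_MFRE])
        assert len(frags) == 2  # one cut, no short excised fragment
        assert not any(f.category == FragmentCategory.MOTIF_CLEAVED for f in frags)

    def test_enzyme_context_gates_cleavage(self, rng, ccwgg):
        # CCAGG's bottom strand context CTGG starts C-T: MspJI needs CNNR
        # around each m5C; both strands of CCWGG match (CAGG->? top strand
        # m5C context CAGG fits CNNR), so MspJI cuts; FspEI needs CC 5' of
        # m5C and also cuts CCWGG. An enzyme context that cannot match must
        # produce no cuts.
        from mfremotif.enzymes import EnzymeModel
        never = EnzymeModel("never", "CCCCCC", 0)
        genome = genome_with_site(rng, "CCAGG", pos=100)
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        assert expected_cuts(genome, methylome, [never]) == []

    def test_sites_far_apart_interstitial(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100, length=400)
        seq = list(genome["chr"])
        seq[200:205] = "CCTGG"
        genome = ReferenceGenome([("chr", "".join(seq))])
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        methylome.add_full_site("chr", 200, ccwgg)
        frags = digest(genome, methylome, [GENERIC_MFRE])
        cats = [f.category for f in frags]
        assert cats.count(FragmentCategory.MOTIF_CLEAVED) == 2
        assert cats.count(FragmentCategory.INTERSTITIAL) == 3

    def test_sites_close_together_overlap(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100, length=400)
        seq = list(genome["chr"])
        seq[120:125] = "CCTGG"
        genome = ReferenceGenome([("chr", "".join(seq))])
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        methylome.add_full_site("chr", 120, ccwgg)
        frags = digest(genome, methylome, [GENERIC_MFRE])
        cats = {f.category for f in frags}
        assert FragmentCategory.OVERLAP_SHORT in cats
        assert FragmentCategory.MOTIF_CLEAVED not in cats

    def test_overlap_long_when_inner_cuts_missed(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100, length=400)
        seq = list(genome["chr"])
        seq[120:125] = "CCTGG"
        genome = ReferenceGenome([("chr", "".join(seq))])
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        methylome.add_full_site("chr", 120, ccwgg)
        cuts = expected_cuts(genome, methylome, [GENERIC_MFRE])
        outer = [min(cuts, key=lambda c: c.position),
                 max(cuts, key=lambda c: c.position)]
        inner = [c for c in cuts if c not in outer]
        from mfremotif.enzymes import classify_fragments
        frags = fragments_from_cuts(genome, outer, inner)
        classify_fragments(frags, methylome)
        assert any(f.category == FragmentCategory.OVERLAP_LONG for f in frags)

    def test_spanning_missed_cut_is_concatenated(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100)
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        cuts = expected_cuts(genome, methylome, [GENERIC_MFRE])
        right_only = [c for c in cuts if c.side == "right"]
        missed = [c for c in cuts if c.side == "left"]
        from mfremotif.enzymes import classify_fragments
        frags = fragments_from_cuts(genome, right_only, missed)
        classify_fragments(frags, methylome)
        assert any(f.category == FragmentCategory.CONCATENATED for f in frags)

    def test_fragments_tile_genome(self, rng, ccwgg):
        # Conservation on 100 random small fixtures: fragment lengths sum
        # to the record length, no gaps or overlaps.
        for trial in range(100):
            trial_rng = np.random.default_rng(5000 + trial)
            genome = random_genome(trial_rng, 2_000)
            seq = list(genome["chr"])
            methylome = Methylome()
            n_sites = int(trial_rng.integers(0, 6))
            pos = 50
            for _ in range(n_sites):
                pos += int(trial_rng.integers(40, 300))
                if pos + 5 > len(seq) - 20:
                    break
                seq[pos:pos + 5] = "CCAGG"
                methylome.add_full_site("chr", pos, ccwgg)
            genome = ReferenceGenome([("chr", "".join(seq))])
            frags = digest(genome, methylome, [GENERIC_MFRE])
            assert sum(f.length for f in frags) == 2_000
            ends = sorted((f.start, f.end) for f in frags)
            for (s1, e1), (s2, _) in zip(ends, ends[1:]):
                assert e1 == s2


class TestReadCutting:
    @pytest.mark.parametrize("dev,expected", [
        ((0, 0), "exact"),
        ((1, 3), "approximate"),
        ((2, 9), "one-cut"),
        ((9, 9), "neither"),
        ((0, 4), "approximate"),
        ((0, 5), "one-cut"),
    ])
    def test_rule_table(self, dev, expected):
        from mfremotif.enzymes import FragmentAnnotation
        frag = FragmentAnnotation("chr", 100, 131)
        start, end = 100 + dev[0], 131 + dev[1]
        assert classify_read_cutting(start, end, frag) == expected

    def test_exact_digest_reads_are_exact(self, rng, ccwgg):
        genome = genome_with_site(rng, "CCAGG", pos=100)
        methylome = Methylome()
        methylome.add_full_site("chr", 100, ccwgg)
        frags = digest(genome, methylome, [GENERIC_MFRE])
        for frag in frags:
            if frag.category == FragmentCategory.MOTIF_CLEAVED:
                assert classify_read_cutting(frag.start, frag.end, frag) == "exact"


class TestCleavageDistances:
    def test_correctly_cut_read(self, rng, ccwgg):
        from mfremotif.simulate import gen_ccmd_reads
        read = gen_ccmd_reads(ccwgg, 1, 0.5, rng)[0]
        d = cleavage_distances(read, ccwgg)
        assert d.pair == (16, 16)
        assert d.is_ccmd()

    def test_one_extra_base(self, rng, ccwgg):
        from mfremotif.simulate import gen_ccmd_reads
        read = gen_ccmd_reads(ccwgg, 1, 0.5, rng)[0] + "A"  # 3' slip by 1
        d = cleavage_distances(read, ccwgg)
        assert d.pair == (16, 17)

    def test_motif_absent(self, ccwgg):
        assert cleavage_distances("A" * 31, ccwgg) is None

    def test_reverse_orientation_symmetric(self, rng):
        # A non-palindromic motif model: distances computed on a
        # bottom-strand rendering must mirror the top-strand ones.
        from mfremotif.sequence import reverse_complement
        model = MotifModel("CCCGC", 1, 3)
        read = "A" * 13 + "CCCGC" + "G" * 13  # 31 nt, motif at s0=13
        d_fwd = cleavage_distances(read, model)
        d_rev = cleavage_distances(reverse_complement(read), model)
        assert d_fwd.pair == d_rev.pair == (16, 16)

    @pytest.mark.parametrize("d,expected", [
        (12, "-13"), (13, "-13"), (14, "14"), (16, "16"),
        (18, "18"), (19, "19+"), (21, "19+"),
    ])
    def test_binning(self, d, expected):
        assert bin_distance(d) == expected

    def test_pair_sorted(self):
        assert CleavageDistances(17, 16).pair == (16, 17)
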