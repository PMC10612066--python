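import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phagemosaic import genome_io as gio
from phagemosaic import synthetic_data as synth
from phagemosaic import variant_immunity as vi
from phagemosaic.genome_io import Feature, GenomeRecord


def random_genome(seed, n=3000, cds=((600, 1500),)):
    rng = np.random.default_rng(seed)
    feats = []
    seq = list("".join(rng.choice(list("ACGT"), size=n)))
    for i, (s, e) in enumerate(cds):
        dna = synth.back_translate(rng, synth._random_protein(rng, (e - s) // 3 - 1))
        seq[s : s + len(dna)] = dna
        feats.append(Feature("CDS", s, s + len(dna), 1,
                             {"locus_tag": f"c{i}", "product": f"protein {i}"}))
    return GenomeRecord("g", "".join(seq), "linear", feats)


class TestDiffGenomes:
    def test_identical_empty(self):
        g = random_genome(0)
        rep = vi.diff_genomes(g, g)
        assert rep.variants == []

    def test_planted_six_outside_eight_inside_mask(self):
        g = random_genome(1, n=6000, cds=((600, 1500), (3000, 4200)))
        rng = np.random.default_rng(10)
        seq = list(g.sequence)
        mask = ("antireceptor", 3000, 4200)
        inside = rng.choice(np.arange(3050, 4150), size=8, replace=False)
        outside = np.array([100, 700, 1600, 2200, 2600, 5500])
        for pos in [*inside, *outside]:
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        rep = vi.diff_genomes(g, b, masks=[mask])
        assert len(rep.variants) == 14
        assert rep.n_outside_mask == 6

    def test_deletion_in_cds_is_frameshift(self):
        g = random_genome(2)
        seq = list(g.sequence)
        del seq[1000]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        rep = vi.diff_genomes(g, b)
        assert len(rep.variants) == 1
        v = rep.variants[0]
        assert v.type == "deletion"
        assert v.effect == "frameshift"

    def test_substitution_effects(self):
        g = random_genome(3)
        cds = g.cds()[0]
        # nonsense: turn a codon into TAA
        seq = list(g.sequence)
        codon_start = cds.start + 33
        old = seq[codon_start : codon_start + 3]
        seq[codon_start : codon_start + 3] = "TAA"
        changed = [i for i in range(3) if seq[codon_start + i] != old[i]]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        rep = vi.diff_genomes(g, b)
        assert any(v.effect == "nonsense" for v in rep.variants)

    def test_diverged_genomes_rejected(self):
        a = random_genome(4)
        rng = np.random.default_rng(5)
        b_seq = "".join(rng.choice(list("ACGT"), size=len(a.sequence)))
        b = GenomeRecord("b", b_seq, "linear", [])
        with pytest.raises(ValueError):
            vi.diff_genomes(a, b)

    def test_symmetry_of_variant_count(self):
        g = random_genome(6)
        seq = list(g.sequence)
        for pos in (200, 900, 2500):
            seq[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[pos]]
        del seq[1800]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        assert len(vi.diff_genomes(g, b).variants) == len(vi.diff_genomes(b, g).variants)

    def test_positions_strictly_increasing(self):
        g = random_genome(7)
        seq = list(g.sequence)
        for pos in (100, 200, 300, 400):
            seq[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[pos]]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        positions = [v.position for v in vi.diff_genomes(g, b).variants]
        assert positions == sorted(set(positions))

    def test_antireceptor_mask_from_annotation(self):
        rec, truth = synth.gen_dgr(synth.DGRSimConfig(seed=3))
        name, s, e = vi.antireceptor_mask(rec, truth["vr_interval"])
        assert name == "antireceptor"
        assert s <= truth["antireceptor"][0]
        assert e >= truth["vr_interval"][1]

    def test_vcf_emission(self, tmp_path):
        g = random_genome(8)
        seq = list(g.sequence)
        seq[700] = {"A": "G", "C": "T", "G": "A", "T": "C"}[seq[700]]
        b = GenomeRecord("b", "".join(seq), "linear", [])
        rep = vi.diff_genomes(g, b, masks=[("m", 600, 1500)])
        out = tmp_path / "diff.vcf"
        vi.write_vcf(rep, out)
        lines = out.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        row = lines[-1].split("\t")
        assert row[1] == "701"  # 1-based
        assert "MASK=m" in row[7]


class TestAlleleFractions:
    def test_eight_of_hundred(self):
        df = pd.DataFrame([{"pos": 5, "A": 92, "C": 0, "G": 8, "T": 0, "N": 0}])
        out = vi.allele_fractions(df, [(5, "G")])
        assert out.sites[0]["minor_fraction"] == pytest.approx(0.08)

    def test_all_reference_zero(self):
        df = pd.DataFrame([{"pos": 1, "A": 50, "C": 0, "G": 0, "T": 0, "N": 0}])
        out = vi.allele_fractions(df, [(1, "G")])
        assert out.sites[0]["minor_fraction"] == 0.0

    def test_zero_coverage_flagged_excluded(self):
        df = pd.DataFrame([
            {"pos": 1, "A": 0, "C": 0, "G": 0, "T": 0, "N": 0},
            {"pos": 2, "A": 90, "C": 0, "G": 10, "T": 0, "N": 0},
        ])
        out = vi.allele_fractions(df, [(1, "G"), (2, "G")])
        assert out.sites[0]["excluded"]
        assert out.min_minor_fraction == out.max_minor_fraction == pytest.approx(0.1)

    def test_unbiased_estimator(self):
        # mean recovered fraction over 1000 replicates within 3 SE of truth
        mixture, depth, n = 0.08, 200, 1000
        fracs = []
        for seed in range(n):
            df = synth.gen_pileup([0], depth, mixture, seed)
            out = vi.allele_fractions(df, [(0, "G")])
            fracs.append(out.sites[0]["minor_fraction"])
        se = np.sqrt(mixture * (1 - mixture) / depth / n)
        assert abs(np.mean(fracs) - mixture) <= 3 * se

    def test_pileup_tsv_roundtrip(self, tmp_path):
        df = synth.gen_pileup([3, 7], 100, 0.1, seed=1)
        p = tmp_path / "pileup.tsv"
        synth.write_pileup_tsv(df, p)
        back = vi.read_pileup_tsv(p)
        pd.testing.assert_frame_equal(df, back)
        (tmp_path / "bad.tsv").write_text("pos\tA\n1\t2\n")
        with pytest.raises(ValueError):
            vi.read_pileup_tsv(tmp_path / "bad.tsv")


class TestPromoterScan:
    def test_exact_consensus(self):
        region = "G" * 20 + "TTGACA" + "C" * 17 + "TATAAT" + "G" * 20
        hits = vi.promoter_scan(region, max_mismatches=0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand, h.mismatch_count, h.spacer_len) == (20, 1, 0, 17)
        assert h.minus35_sequence == "TTGACA"
        assert h.minus10_sequence == "TATAAT"

    def test_one_mismatch_counted(self):
        region = "G" * 20 + "TTGACA" + "C" * 17 + "TATAAC" + "G" * 20
        hits = vi.promoter_scan(region, max_mismatches=1)
        assert hits and hits[0].mismatch_count == 1

    def test_spacer_range_enforced(self):
        region = "G" * 20 + "TTGACA" + "C" * 10 + "TATAAT" + "G" * 20
        assert vi.promoter_scan(region, max_mismatches=0, spacer_range=(15, 19)) == []

    def test_offset_applied(self):
        region = "TTGACA" + "C" * 17 + "TATAAT" + "G" * 10
        hits = vi.promoter_scan(region, offset=1000, max_mismatches=0)
        assert hits[0].start == 1000

    def test_opposing_promoters_flagged(self):
        fwd = "TTGACA" + "C" * 17 + "TATAAT"
        region = "G" * 10 + fwd + gio.revcomp(fwd)[6:] + "G" * 10
        hits = vi.promoter_scan(region, max_mismatches=2)
        strands = {h.strand for h in hits}
        if strands == {1, -1}:
            assert any(h.opposing for h in hits)

    @settings(max_examples=15, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=40, max_size=120))
    def test_invariant_under_revcomp(self, region):
        fwd = vi.promoter_scan(region, max_mismatches=2)
        rev = vi.promoter_scan(gio.revcomp(region), max_mismatches=2)
        n = len(region)
        fwd_set = {(h.start, h.end, h.strand, h.mismatch_count) for h in fwd}
        rev_set = {(n - h.end, n - h.start, -h.strand, h.mismatch_count) for h in rev}
        assert fwd_set == rev_set

    def test_stronger_minus10_scores_fewer_mismatches(self):
        # the qualitative promoter-variant comparison: a TATAAT box beats a
        # TATAAC box on mismatch count at the same -35
        strong = "TTGACA" + "C" * 17 + "TATAAT"
        weak = "TTGACA" + "C" * 17 + "TATAAC"
        h_strong = vi.promoter_scan("G" * 5 + strong + "G" * 5, max_mismatches=3)[0]
        h_weak = vi.promoter_scan("G" * 5 + weak + "G" * 5, max_mismatches=3)[0]
        assert h_strong.mismatch_count < h_weak.mismatch_count
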