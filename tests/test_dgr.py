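import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import binom_tail

from phagemosaic import dgr_retroelement as dgr
from phagemosaic import genome_io as gio
from phagemosaic import synthetic_data as synth


class TestClassifyVariants:
    def test_all_conforming(self):
        c = dgr.classify_variants("AAGCTA", "TCGCTG")
        positions = [m[0] for m in c.mismatches]
        assert positions == [0, 1, 5]
        assert c.n_conforming == 3
        assert c.n_nonconforming == 0

    def test_identity_zero_mismatches(self):
        c = dgr.classify_variants("TGGA", "TGGA")
        assert c.n_conforming == c.n_nonconforming == 0
        assert c.p_value_adenine_bias == 1.0

    def test_nonconforming_g_to_c(self):
        c = dgr.classify_variants("TGGA", "TCGA")
        assert c.mismatches == [(1, "G", "C", "nonconforming")]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            dgr.classify_variants("", "ACGT")

    def test_gap_columns_excluded(self):
        c = dgr.classify_variants("ACGTACGTACGT", "ACGTCGTACGT")  # 1 deletion
        assert c.n_gap_columns == 1
        assert c.n_conforming + c.n_nonconforming == len(c.mismatches)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_self_comparison_clean(self, tr):
        c = dgr.classify_variants(tr, tr)
        assert c.mismatches == []
        assert c.p_value_adenine_bias == 1.0


class TestAdenineBiasTest:
    def test_closed_form_three_hits(self):
        # TR adenine fraction 0.4, 3 mismatches all at A -> p = 0.4^3
        tr = "AAAAGGCCTT"  # 4 A of 10
        vr = "CCCAGGCCTT"  # A->C at 0,1,2
        c = dgr.classify_variants(tr, vr)
        assert c.n_conforming == 3
        assert c.p_value_adenine_bias == pytest.approx(0.4**3)

    def test_single_nonconforming_gives_one(self):
        tr = "AAAAGGCCTT"
        vr = "AAAACGCCTT"
        c = dgr.classify_variants(tr, vr)
        assert c.n_conforming == 0
        assert c.p_value_adenine_bias == pytest.approx(1.0)  # P(X >= 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        tr = "".join(rng.choice(list("ACGT"), size=n))
        vr = list(tr)
        m = int(rng.integers(1, 6))  # enumerable m <= 5
        for i in rng.choice(n, size=m, replace=False):
            vr[i] = rng.choice([b for b in "ACGT" if b != tr[i]])
        c = dgr.classify_variants(tr, "".join(vr))
        f = tr.count("A") / len(tr)
        want = binom_tail(c.n_conforming, m, f)
        assert c.p_value_adenine_bias == pytest.approx(want, rel=1e-9)

    def test_permutation_agrees_with_closed_form(self):
        record, truth = synth.gen_dgr(
            synth.DGRSimConfig(seed=5, theta=0.15, epsilon=0.01)
        )
        c = dgr.classify_variants(truth["tr"], truth["vr"])
        p_exact = c.p_value_adenine_bias
        n_draws = 10_000
        p_perm = dgr.adenine_bias_permutation(c, n_draws=n_draws, seed=0)
        se = max(np.sqrt(p_exact * (1 - p_exact) / n_draws), 1.0 / n_draws)
        assert abs(p_perm - p_exact) <= 3 * se + 1.0 / n_draws

    def test_power_monotone_in_theta(self):
        # more A->N events -> smaller p, at fixed repeat length
        rng_cfg = dict(repeat_len=150, adenine_fraction=0.45, epsilon=0.0)
        mean_p = []
        for theta in (0.05, 0.2, 0.5):
            ps = []
            for seed in range(40):
                _, truth = synth.gen_dgr(
                    synth.DGRSimConfig(seed=seed, theta=theta, **rng_cfg)
                )
                c = dgr.classify_variants(truth["tr"], truth["vr"])
                ps.append(c.p_value_adenine_bias)
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]


class TestFindTrVr:
    CFG = dict(repeat_len=501, adenine_fraction=0.35, theta=0.1, epsilon=0.01)
    RANGE = (50, 700)

    def test_exact_recovery_single_seed(self):
        rec, truth = synth.gen_dgr(synth.DGRSimConfig(seed=0, **self.CFG))
        cassettes = dgr.find_tr_vr(rec, repeat_len_range=self.RANGE)
        assert len(cassettes) == 1
        c = cassettes[0]
        assert c.tr_interval == truth["tr_interval"]
        assert c.vr_interval == truth["vr_interval"]
        assert c.antireceptor_gene is not None
        assert "antireceptor" in c.antireceptor_gene.qualifiers["product"]
        assert c.avd_gene is not None
        assert c.tr_is_rt_extension

    def test_identical_repeats_rejected(self):
        rec, truth = synth.gen_dgr(
            synth.DGRSimConfig(seed=3, theta=0.0, epsilon=0.0)
        )
        assert truth["tr"] == truth["vr"]
        assert dgr.find_tr_vr(rec) == []

    def test_no_rt_annotation_raises(self):
        rec, _ = synth.gen_dgr(synth.DGRSimConfig(seed=1))
        stripped = gio.GenomeRecord(
            rec.id, rec.sequence, "linear",
            [gio.Feature(f.kind, f.start, f.end, f.strand,
                         {k: v for k, v in f.qualifiers.items() if k != "product"})
             for f in rec.features],
        )
        with pytest.raises(ValueError, match="reverse transcriptase"):
            dgr.find_tr_vr(stripped)

    def test_explicit_rt_gene_accepted(self):
        rec, truth = synth.gen_dgr(synth.DGRSimConfig(seed=0, **self.CFG))
        rt = [f for f in rec.cds() if "reverse" in f.qualifiers["product"]][0]
        stripped = gio.GenomeRecord(
            rec.id, rec.sequence, "linear",
            [gio.Feature(f.kind, f.start, f.end, f.strand, {})
             for f in rec.features],
        )
        cassettes = dgr.find_tr_vr(stripped, repeat_len_range=self.RANGE, rt_gene=rt)
        assert cassettes and cassettes[0].tr_interval == truth["tr_interval"]

    def test_prophage_rt_frameshift_flagged(self):
        rec, _ = synth.gen_dgr(
            synth.DGRSimConfig(seed=2, rt_frameshift=True, **self.CFG)
        )
        prots = gio.extract_proteome(rec)
        rt_prot = [p for p in prots if "reverse" in p.product][0]
        assert rt_prot.possible_frameshift
        cassettes = dgr.find_tr_vr(rec, repeat_len_range=self.RANGE)
        assert cassettes[0].rt_pseudogene

    def test_orientation_recovery_theta_only(self):
        # the copy designated TR is the simulated template (theta=0.1, eps=0)
        ok = 0
        for seed in range(100):
            rec, truth = synth.gen_dgr(
                synth.DGRSimConfig(seed=seed, theta=0.1, epsilon=0.0,
                                   repeat_len=501, adenine_fraction=0.35)
            )
            cassettes = dgr.find_tr_vr(rec, repeat_len_range=self.RANGE)
            if cassettes and cassettes[0].tr_interval == truth["tr_interval"]:
                ok += 1
        assert ok >= 99


class TestCompareVrProteins:
    def _proteins(self, seed, theta):
        rec, truth = synth.gen_dgr(
            synth.DGRSimConfig(seed=seed, theta=theta, epsilon=0.0)
        )
        prots = gio.extract_proteome(rec)
        anti = [p for p in prots if "antireceptor" in p.product][0]
        return rec, truth, anti

    def test_identical_proteins_empty_table(self):
        _, _, anti = self._proteins(4, 0.0)
        rows = dgr.compare_vr_proteins([("g1", anti), ("g2", anti)])
        assert rows == []

    def test_known_residue_changes_recovered(self):
        # the unmutated antireceptor is the same gene with the TR swapped in
        # place of the VR; expected residue changes follow from the truth
        from Bio.Seq import Seq
        import dataclasses

        rec, truth, anti = self._proteins(6, 0.12)
        a0, a1 = truth["antireceptor"]
        v0, v1 = truth["vr_interval"]
        dna_ref = rec.sequence[a0:v0] + truth["tr"] + rec.sequence[v1:a1]
        aa_ref = str(Seq(dna_ref).translate(table=11)).rstrip("*")
        assert len(aa_ref) == len(anti.aa_sequence)  # no internal stop drawn
        expected = {
            i + 1
            for i, (x, y) in enumerate(zip(aa_ref, anti.aa_sequence))
            if x != y
        }
        assert expected  # the simulation did change residues
        ref_prot = dataclasses.replace(anti, aa_sequence=aa_ref)
        rows = dgr.compare_vr_proteins([("ref", ref_prot), ("mut", anti)])
        assert {r["residue"] for r in rows} == expected

    def test_internal_stop_flagged_as_terminator(self):
        _, _, anti = self._proteins(8, 0.0)
        mutated = list(anti.aa_sequence)
        mutated[50] = "*"
        import dataclasses
        m = dataclasses.replace(anti, aa_sequence="".join(mutated))
        # align against the unmutated reference; the '*' is in the variant
        rows = dgr.compare_vr_proteins([("ref", anti), ("mut", m)])
        hit = [r for r in rows if r["residue"] == 51]
        assert hit and hit[0]["terminator"]

    def test_region_outside_protein_raises(self):
        _, _, anti = self._proteins(9, 0.0)
        with pytest.raises(ValueError):
            dgr.compare_vr_proteins([("a", anti), ("b", anti)],
                                    region=(1, len(anti.aa_sequence) + 10))

    def test_fewer_than_two_raises(self):
        _, _, anti = self._proteins(9, 0.0)
        with pytest.raises(ValueError):
            dgr.compare_vr_proteins([("a", anti)])


def test_reports_emission(tmp_path):
    rec, _ = synth.gen_dgr(synth.DGRSimConfig(
        seed=0, repeat_len=501, adenine_fraction=0.35, theta=0.1, epsilon=0.01))
    cassettes = dgr.find_tr_vr(rec, repeat_len_range=(50, 700))
    report = tmp_path / "cassettes.tsv"
    gff = tmp_path / "cassettes.gff3"
    dgr.write_cassette_report(cassettes, report)
    dgr.write_cassette_gff3(cassettes, gff)
    assert len(report.read_text().splitlines()) == 2
    gff_text = gff.read_text()
    assert gff_text.startswith("##gff-version 3")
    assert "template_repeat" in gff_text and "variable_region" in gff_text
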