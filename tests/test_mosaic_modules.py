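import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import table_from_matrix
from oracles import enumerate_threshold_separable, exhaustive_segmentation

from phagemosaic import mosaic_modules as mm


class TestSummarizeModule:
    def test_median_with_unmeasured(self):
        # brute-force median of {95, 90, 43} = 90; one NONE cell excluded
        t = table_from_matrix([[95.0], [90.0], [43.0], [None]], ["r"])
        s = mm.summarize_module(t, mm.ModuleDefinition("m", 0, 3), "r")
        assert s.median_identity == 90.0
        assert (s.n_measured, s.n_unmeasured) == (3, 1)

    def test_single_gene_module(self):
        t = table_from_matrix([[77.0]], ["r"])
        s = mm.summarize_module(t, mm.ModuleDefinition("m", 0, 0), "r")
        assert s.median_identity == 77.0

    def test_even_median_is_midpoint(self):
        t = table_from_matrix([[10.0], [20.0], [70.0], [80.0]], ["r"])
        s = mm.summarize_module(t, mm.ModuleDefinition("m", 0, 3), "r")
        assert s.median_identity == 45.0

    def test_all_none_gives_none(self):
        t = table_from_matrix([[None], [None]], ["r"])
        s = mm.summarize_module(t, mm.ModuleDefinition("m", 0, 1), "r")
        assert s.median_identity is None
        assert s.n_measured == 0

    def test_empty_range_raises(self):
        t = table_from_matrix([[50.0]], ["r"])
        with pytest.raises(ValueError):
            mm.summarize_module(t, mm.ModuleDefinition("m", 5, 9), "r")

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=9),
           st.data())
    def test_permutation_invariant_and_monotone(self, vals, data):
        t1 = table_from_matrix([[v] for v in vals], ["r"])
        perm = data.draw(st.permutations(vals))
        t2 = table_from_matrix([[v] for v in perm], ["r"])
        m = mm.ModuleDefinition("m", 0, len(vals) - 1)
        s1 = mm.summarize_module(t1, m, "r")
        s2 = mm.summarize_module(t2, m, "r")
        assert s1.median_identity == pytest.approx(s2.median_identity)
        # monotone: raising one value cannot lower the median
        idx = data.draw(st.integers(0, len(vals) - 1))
        raised = list(vals)
        raised[idx] = min(100.0, raised[idx] + data.draw(st.floats(0, 50)))
        t3 = table_from_matrix([[v] for v in raised], ["r"])
        s3 = mm.summarize_module(t3, m, "r")
        assert s3.median_identity >= s1.median_identity - 1e-9

    def test_median_more_robust_than_mean_to_outliers(self):
        # one interjected gene (identity 0 or 100) moves the median less
        # than the mean on >=5-gene modules: quantified over 1000 seeds
        rng = np.random.default_rng(123)
        d_median, d_mean = [], []
        for _ in range(1000):
            base = rng.uniform(30, 95, size=rng.integers(5, 12))
            outlier = rng.choice([0.0, 100.0])
            with_outlier = np.append(base, outlier)
            d_median.append(abs(np.median(with_outlier) - np.median(base)))
            d_mean.append(abs(np.mean(with_outlier) - np.mean(base)))
        assert np.mean(d_median) < np.mean(d_mean)
        # and the median is the less-moved summary in a clear majority of draws
        assert np.mean(np.array(d_median) <= np.array(d_mean)) > 0.7


class TestSegmentModules:
    def test_perfect_contrast(self):
        vals = [[90.0, 10.0]] * 3 + [[30.0, 80.0]] * 3
        t = table_from_matrix(vals, ["r1", "r2"])
        mods = mm.segment_modules(t, min_len=2, n_modules=2)
        assert [(m.first_gene, m.last_gene) for m in mods] == [(0, 2), (3, 5)]

    def test_constant_profile_earliest_boundary(self):
        vals = [[50.0, 50.0]] * 6
        t = table_from_matrix(vals, ["r1", "r2"])
        mods = mm.segment_modules(t, min_len=2, n_modules=2)
        # all boundaries cost-tied: earliest valid boundary wins
        assert mods[0].first_gene == 0
        assert mods[0].last_gene == 1

    def test_requires_two_references(self):
        t = table_from_matrix([[50.0]] * 6, ["r"])
        with pytest.raises(ValueError):
            mm.segment_modules(t, min_len=2, n_modules=2)

    def test_min_len_infeasible_raises(self):
        t = table_from_matrix([[50.0, 1.0]] * 5, ["r1", "r2"])
        with pytest.raises(ValueError):
            mm.segment_modules(t, min_len=3, n_modules=2)

    def test_none_imputed_as_absent_level(self):
        # absence itself is the signal separating the two blocks
        vals = [[None, 60.0]] * 3 + [[80.0, 60.0]] * 3
        t = table_from_matrix(vals, ["r1", "r2"])
        mods = mm.segment_modules(t, min_len=2, n_modules=2)
        assert mods[0].last_gene == 2

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        vals = []
        for _ in range(n):
            row = [
                None if rng.random() < 0.15 else float(rng.integers(0, 101))
                for _ in range(2)
            ]
            vals.append(row)
        t = table_from_matrix(vals, ["r1", "r2"])
        k = int(rng.integers(2, 4))
        min_len = 2
        if min_len * k > n:
            k = 2
        mods = mm.segment_modules(t, min_len=min_len, n_modules=k)
        got_bounds = [m.first_gene for m in mods[1:]]
        x = mm._profile_matrix(t)
        want_bounds, _ = exhaustive_segmentation(x, k, min_len)
        assert got_bounds == want_bounds


class TestBipartition:
    def test_exemplars_themselves(self):
        panel = {"A_self": (100.0, 20.0), "B_self": (20.0, 100.0)}
        b = mm.bipartition_by_gene(panel, "sheath")
        assert b.per_phage_assignment == {"A_self": "A", "B_self": "B"}
        assert b.is_separable

    def test_threshold_at_widest_gap_midpoint(self):
        panel = {"p1": (80.0, 20.0), "p2": (75.0, 25.0), "p3": (15.0, 85.0)}
        b = mm.bipartition_by_gene(panel, "tube")
        assert b.per_phage_assignment == {"p1": "A", "p2": "A", "p3": "B"}
        assert b.is_separable
        # margins +60, +50, -70: midpoint between +50 and -70
        assert b.separating_threshold == pytest.approx(-10.0)
        assert enumerate_threshold_separable([60.0, 50.0], [-70.0])

    def test_interleaved_margins_not_separable(self):
        panel = {"p1": (60.0, 50.0), "p2": (45.0, 50.0), "p3": (53.0, 50.0)}
        expected = {"p1": "A", "p2": "A", "p3": "B"}
        b = mm.bipartition_by_gene(panel, "gpU", expected_groups=expected)
        assert not b.is_separable
        assert not enumerate_threshold_separable([10.0, -5.0], [3.0])

    def test_both_none_unresolved(self):
        panel = {"p1": (None, None), "p2": (50.0, 10.0)}
        b = mm.bipartition_by_gene(panel, "g")
        assert b.per_phage_assignment["p1"] == "unresolved"

    def test_small_panel_raises(self):
        with pytest.raises(ValueError):
            mm.bipartition_by_gene({"p1": (1.0, 2.0)}, "g")


class TestConsensusGroups:
    def _bp(self, assignment, gene="g"):
        return mm.Bipartition(gene, "A", "B", assignment)

    def test_unanimous(self):
        bps = [self._bp({"p": "A"}, f"g{i}") for i in range(3)]
        assert mm.consensus_groups(bps)["p"] == ("A", 1.0)

    def test_majority_two_thirds(self):
        bps = [self._bp({"p": v}, f"g{i}") for i, v in enumerate("AAB")]
        group, agreement = mm.consensus_groups(bps)["p"]
        assert group == "A"
        assert agreement == pytest.approx(2 / 3)

    def test_tie_unresolved(self):
        bps = [self._bp({"p": v}, f"g{i}") for i, v in enumerate("AB")]
        assert mm.consensus_groups(bps)["p"][0] == "unresolved"

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mm.consensus_groups([])

    def test_two_lineage_panel_full_recovery(self):
        from phagemosaic import synthetic_data as synth

        panels, truth_groups = synth.gen_two_lineage_panel(
            seed=2024, n_genes=5, n_phages_per_group=6, intra_identity=35.0
        )
        bps = [mm.bipartition_by_gene(panel, gene) for gene, panel in panels.items()]
        groups = mm.consensus_groups(bps)
        for phage, want in truth_groups.items():
            got, agreement = groups[phage]
            assert got == want
            assert agreement == 1.0


def test_module_definition_file_roundtrip(tmp_path):
    p = tmp_path / "modules.tsv"
    p.write_text("# name first last\nnonstructural\t0\t21\ntail\t30\t40\n")
    mods = mm.read_module_definitions(p)
    assert [(m.name, m.first_gene, m.last_gene) for m in mods] == [
        ("nonstructural", 0, 21), ("tail", 30, 40)
    ]
    p.write_text("a\t0\t10\nb\t5\t12\n")
    with pytest.raises(ValueError, match="overlap"):
        mm.read_module_definitions(p)


def test_summary_and_track_emission(tmp_path):
    t = table_from_matrix([[90.0, None], [80.0, 20.0]], ["r1", "r2"])
    mods = [mm.ModuleDefinition("m", 0, 1)]
    summaries = [mm.summarize_module(t, mods[0], r) for r in ("r1", "r2")]
    out = tmp_path / "summ.tsv"
    mm.write_module_summaries(summaries, out)
    lines = out.read_text().splitlines()
    assert lines[1].startswith("m\t0\t1\tr1\t85.0\t2\t0")
    track = tmp_path / "track.csv"
    mm.write_gene_track(t, mods, track)
    assert track.read_text().splitlines()[1].endswith("m,90.0,")
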