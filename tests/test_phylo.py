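"""Variant filtering, attribution, founder/progression and clonal architecture."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant_table
from uvclone.phylo import (
    FilterParams,
    attribute_variants,
    build_sample_phylogeny,
    compute_vaf_dispersion,
    filter_somatic_variants,
    infer_clonal_architecture,
    partition_founder_progression,
)

SAMPLES2 = [("s1", "marrow", "cryopreserved"), ("s2", "skin", "cryopreserved")]


class TestFiltering:
    def test_below_min_vaf_everywhere_removed(self):
        table = make_variant_table({"v1": [0.05, 0.08]}, SAMPLES2)
        g = pd.Series(0.0, index=["v1"])
        filtered, report = filter_somatic_variants(table, g)
        assert not report.loc["v1", "retained"]

    def test_whitelisted_low_vaf_kept(self):
        table = make_variant_table({"v1": [0.05, 0.08]}, SAMPLES2)
        g = pd.Series(0.0, index=["v1"])
        _, report = filter_somatic_variants(
            table, g, FilterParams(whitelist={"v1"})
        )
        assert report.loc["v1", "retained"]

    def test_germline_one_fifth_rule(self):
        table = make_variant_table({"v1": [0.40, 0.10]}, SAMPLES2)
        g = pd.Series(0.20, index=["v1"])  # 0.20 > 0.40 / 5
        _, report = filter_somatic_variants(table, g)
        assert not report.loc["v1", "pass_germline"]
        g_ok = pd.Series(0.05, index=["v1"])
        _, report = filter_somatic_variants(table, g_ok)
        assert report.loc["v1", "pass_germline"]

    def test_cross_patient_recurrent_dropped_unless_hotspot(self):
        table = make_variant_table({"v1": [0.3, 0.3], "v2": [0.3, 0.3]}, SAMPLES2)
        g = pd.Series(0.0, index=["v1", "v2"])
        _, report = filter_somatic_variants(
            table, g, FilterParams(hotspot_whitelist={"v2"}), recurrent_ids={"v1", "v2"}
        )
        assert not report.loc["v1", "retained"]
        assert report.loc["v2", "retained"]

    def test_coverage_floor_by_sample_type(self):
        samples = [("s1", "marrow", "cryopreserved"), ("s2", "skin", "FFPE")]
        t_pass = make_variant_table({"v1": [0.3, 0.3]}, samples, depth=21)
        g = pd.Series(0.0, index=["v1"])
        _, rep = filter_somatic_variants(t_pass, g)
        assert rep.loc["v1", "pass_coverage"]  # 21 > 20 and 21 > 10
        t_fail = make_variant_table({"v1": [0.3, 0.3]}, samples, depth=15)
        _, rep = filter_somatic_variants(t_fail, g)
        assert not rep.loc["v1", "pass_coverage"]  # 15 <= 20 in the cryo sample

    def test_missing_germline_rejected(self):
        table = make_variant_table({"v1": [0.3, 0.3]}, SAMPLES2)
        with pytest.raises(ValueError, match="germline"):
            filter_somatic_variants(table, None)

    def test_planted_failures_fixture(self):
        """100 variants, 12 planted rule violations -> exactly 88 retained,
        cross-checked by brute-force re-application of each rule."""
        rng = np.random.default_rng(42)
        rows = {}
        germ = {}
        recurrent = set()
        for i in range(100):
            vid = f"v{i:03d}"
            rows[vid] = [float(rng.uniform(0.15, 0.45)), float(rng.uniform(0.15, 0.45))]
            germ[vid] = 0.0
        # 4 fail the VAF rule, 4 the germline rule, 4 recurrence
        for i in range(4):
            rows[f"v{i:03d}"] = [0.05, 0.02]
        for i in range(4, 8):
            germ[f"v{i:03d}"] = 0.4
        for i in range(8, 12):
            recurrent.add(f"v{i:03d}")
        table = make_variant_table(rows, SAMPLES2)
        g = pd.Series(germ)
        filtered, report = filter_somatic_variants(table, g, recurrent_ids=recurrent)
        assert report["retained"].sum() == 88
        # brute force oracle
        for vid in rows:
            expect = (
                max(rows[vid]) >= 0.1
                and germ[vid] <= max(rows[vid]) / 5
                and vid not in recurrent
            )
            assert report.loc[vid, "retained"] == expect, vid

    def test_filtering_idempotent(self, demo_table):
        g = pd.Series(0.0, index=demo_table.variants.index)
        once, _ = filter_somatic_variants(demo_table, g)
        twice, _ = filter_somatic_variants(once, g.reindex(once.variants.index))
        assert list(once.variants.index) == list(twice.variants.index)


class TestAttribution:
    def test_first_sample_above_threshold(self):
        samples = [(f"s{i}", "marrow", "cryopreserved") for i in (1, 2, 3)]
        table = make_variant_table({"v1": [0.02, 0.15, 0.30]}, samples)
        attr = attribute_variants(table)
        assert attr.loc["v1", "first_sample"] == "s2"
        assert not attr.loc["v1", "present:s1"]
        assert attr.loc["v1", "present:s3"]

    def test_gap_in_detection_still_marks_later_samples(self):
        samples = [(f"s{i}", "marrow", "cryopreserved") for i in (1, 2, 3)]
        table = make_variant_table({"v1": [0.2, 0.0, 0.3]}, samples)
        attr = attribute_variants(table)
        assert attr.loc["v1", "first_sample"] == "s1"
        assert attr.loc["v1", "present:s3"]

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(0)
        samples = [(f"s{i}", "marrow", "cryopreserved") for i in range(4)]
        rows = {f"v{i}": list(rng.uniform(0, 0.4, size=4)) for i in range(500)}
        table = make_variant_table(rows, samples)
        attr = attribute_variants(table)
        for vid, vafs in rows.items():
            expect = next((f"s{j}" for j, v in enumerate(vafs) if v > 0.1), None)
            got = attr.loc[vid, "first_sample"]
            assert (got == expect) or (expect is None and pd.isna(got))


class TestFounderProgression:
    def test_trivial_rules(self):
        table = make_variant_table(
            {"v1": [0.3, 0.25], "v2": [0.0, 0.4]}, SAMPLES2
        )
        founder, progression = partition_founder_progression(table)
        assert founder == {"v1"}
        assert progression == {"v2"}

    def test_noise_free_partition_matches_planted_truth(self, demo_table):
        """With true VAFs as observations the partition is exact."""
        noise_free = demo_table.subset(demo_table.variants.index)
        truth_vafs = demo_table.variants[
            [f"true_vaf:{s}" for s in demo_table.sample_order]
        ]
        calls = noise_free.calls
        for s in demo_table.sample_order:
            m = calls["sample_id"] == s
            calls.loc[m, "vaf"] = truth_vafs.loc[
                calls.loc[m, "variant_id"], f"true_vaf:{s}"
            ].to_numpy()
        founder, progression = partition_founder_progression(noise_free)
        founder_clones = {"f1", "f2", "f3", "f4"}
        truth = demo_table.variants["clone"]
        assert all(truth[v] in founder_clones for v in founder)
        assert all(truth[v] not in founder_clones for v in progression)

    def test_noisy_partition_misassignment_rate_low(self, demo_table):
        """Binomial sampling noise misassigns under 5% of variants."""
        founder, progression = partition_founder_progression(demo_table)
        founder_clones = {"f1", "f2", "f3", "f4"}
        truth = demo_table.variants["clone"]
        wrong = sum(truth[v] not in founder_clones for v in founder)
        wrong += sum(truth[v] in founder_clones for v in progression)
        assert wrong / len(demo_table.variants) < 0.05


class TestPhylogeny:
    def test_nested_sets_give_shared_skin_node(self):
        samples = [("marrow", "marrow", "cryopreserved"),
                   ("skin1", "skin", "cryopreserved"),
                   ("skin2", "skin", "cryopreserved")]
        rows = {
            "trunk1": [0.3, 0.3, 0.3],
            "trunk2": [0.3, 0.3, 0.3],
            "shared_skin": [0.0, 0.3, 0.3],
            "only1": [0.0, 0.3, 0.0],
            "only2": [0.0, 0.0, 0.3],
        }
        table = make_variant_table(rows, samples)
        result = build_sample_phylogeny(table)
        clades = {k: set(v) for k, v in result.clades.items()}
        assert clades[frozenset({"marrow", "skin1", "skin2"})] == {"trunk1", "trunk2"}
        assert clades[frozenset({"skin1", "skin2"})] == {"shared_skin"}
        assert result.tree[frozenset({"skin1"})] == frozenset({"skin1", "skin2"})
        assert not result.conflicts

    def test_single_sample_tree(self):
        table = make_variant_table({"v1": [0.3]}, [("s1", "marrow", "cryopreserved")])
        result = build_sample_phylogeny(table)
        assert set(result.clades) == {frozenset({"s1"})}

    def test_conflicting_patterns_reported_not_dropped(self):
        samples = [(s, "marrow", "cryopreserved") for s in ("a", "b", "c")]
        rows = {f"ab{i}": [0.3, 0.3, 0.0] for i in range(5)}
        rows["bc"] = [0.0, 0.3, 0.3]  # crosses the ab clade
        table = make_variant_table(rows, samples)
        result = build_sample_phylogeny(table)
        assert result.conflicts == ["bc"]

    def test_simulated_tree_topology_recovered(self, demo_table):
        result = build_sample_phylogeny(demo_table)
        assert frozenset({"skin1", "skin2"}) in result.clades
        assert frozenset({"marrow", "skin1", "skin2"}) in result.clades
        # trunk variants are the founder clones detected everywhere
        assert len(result.conflicts) == 0


class TestClonalArchitecture:
    def test_two_well_separated_modes(self):
        vafs = pd.Series([0.40] * 5 + [0.20] * 5, index=[f"v{i}" for i in range(10)])
        model = infer_clonal_architecture(vafs)
        assert len(model.clones) == 2
        assert model.clones[0].cancer_cell_fraction == pytest.approx(0.8)
        assert model.clones[1].cancer_cell_fraction == pytest.approx(0.4)
        assert model.clones[1].parent == "clone0"
        assert model.nesting_ok

    def test_uniform_vafs_single_clone(self):
        vafs = pd.Series([0.3] * 8, index=[f"v{i}" for i in range(8)])
        model = infer_clonal_architecture(vafs)
        assert len(model.clones) == 1

    def test_empty_after_masking(self):
        vafs = pd.Series([0.3, 0.4], index=["a", "b"])
        model = infer_clonal_architecture(vafs, cna_mask=pd.Index(["a", "b"]))
        assert model.clones == []
        assert model.masked_variants == ["a", "b"]

    def test_recovers_simulated_subclone_fractions(self, catalogue):
        from uvclone.sim.bulk import SamplePlan, simulate_bulk_vafs
        from uvclone.sim.tree import ClonalTreeSpec, simulate_clonal_tree

        mix = np.zeros(30)
        mix[0] = 1.0
        spec = ClonalTreeSpec(
            nodes=["p", "q"], parent_of={"q": "p"},
            n_new_mutations={"p": 15, "q": 15},
            signature_mix={"p": mix, "q": mix},
        )
        cat = simulate_clonal_tree(spec, 21, catalogue)
        plan = SamplePlan("s", "marrow", {"p": 0.45, "q": 0.35}, mean_depth=300)
        table = simulate_bulk_vafs(spec, cat, [plan], 22)
        model = infer_clonal_architecture(table.vaf_matrix()["s"])
        assert len(model.clones) == 2
        # lineage fractions: p=0.8, q=0.35
        assert model.clones[0].cancer_cell_fraction == pytest.approx(0.8, abs=0.05)
        assert model.clones[1].cancer_cell_fraction == pytest.approx(0.35, abs=0.05)


class TestDispersion:
    def test_constant_vafs(self):
        assert compute_vaf_dispersion([0.1, 0.1, 0.1]) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_population_sd(self):
        assert compute_vaf_dispersion([0.1, 0.3]) == pytest.approx(0.5)

    def test_sample_sd_flag(self):
        assert compute_vaf_dispersion([0.1, 0.3], ddof=1) == pytest.approx(
            np.std([0.1, 0.3], ddof=1) / 0.2
        )

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariant(self, values, c):
        assert compute_vaf_dispersion(values) == pytest.approx(
            compute_vaf_dispersion([c * v for v in values]), rel=1e-9
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_vaf_dispersion([0.2])
        with pytest.raises(ValueError):
            compute_vaf_dispersion([0.0, 0.0])
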