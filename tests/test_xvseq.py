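"""UMI-consensus genotyping: read matching, consensus rule, cell calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uvclone.sim import SingleCellPlan
from uvclone.sim.singlecell import simulate_sc_data
from uvclone.xvseq import (
    LocusSpec,
    SpliceProductSpec,
    collapse_umi,
    detect_deletion_junction,
    genotype_cell,
    genotype_cells,
    match_read,
    quantify_pre_enrichment,
    replicate_concordance,
)

SPEC = LocusSpec("L1", wt_sequence="ACGTACGTAC", mut_sequence="ACGTTCGTAC")


class TestMatchRead:
    def test_exact_templates(self):
        assert match_read("ACGTTCGTAC", SPEC) == "MUT"
        assert match_read("ACGTACGTAC", SPEC) == "WT"

    def test_far_from_both_is_ambiguous(self):
        assert match_read("GGGGGGGGGG", SPEC) == "AMB"

    def test_equidistant_within_tolerance_is_ambiguous(self):
        # differs from WT and MUT by exactly one base each
        assert match_read("ACGTGCGTAC", SPEC) == "AMB"

    def test_matches_brute_force_hamming_oracle(self):
        rng = np.random.default_rng(4)
        bases = np.array(list("ACGT"))
        for _ in range(2000):
            read = "".join(rng.choice(bases, size=10))
            d_wt = sum(a != b for a, b in zip(read, SPEC.wt_sequence))
            d_mut = sum(a != b for a, b in zip(read, SPEC.mut_sequence))
            tol = SPEC.mismatch_tolerance * 10
            if d_wt <= tol and (d_mut > tol or d_wt < d_mut):
                expect = "WT"
            elif d_mut <= tol and (d_wt > tol or d_mut < d_wt):
                expect = "MUT"
            else:
                expect = "AMB"
            assert match_read(read, SPEC) == expect, read


class TestCollapseUMI:
    @pytest.mark.parametrize(
        "reads,expected",
        [
            (["WT"] * 3, "WT"),
            (["MUT"] * 4 + ["WT"] * 2, "discard"),   # 4 < 3x2
            (["MUT"] * 7 + ["WT"] * 2, "MUT"),       # 7 >= 6
            (["WT", "WT"], "discard"),               # below min reads
            (["AMB"] * 5 + ["MUT"] * 2, "discard"),  # AMB reads uninformative
            (["MUT"] * 3, "MUT"),
        ],
    )
    def test_consensus_rule(self, reads, expected):
        assert collapse_umi(reads, SPEC) == expected

    def test_read_threshold_one(self):
        relaxed = LocusSpec("L", "AA", "AT", min_reads=1)
        assert collapse_umi(["MUT"], relaxed) == "MUT"

    def test_order_invariance(self):
        reads = ["MUT"] * 7 + ["WT"] * 2 + ["AMB"]
        for perm in itertools.islice(itertools.permutations(reads), 50):
            assert collapse_umi(list(perm), SPEC) == "MUT"

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(1, 6), st.integers(1, 5))
    def test_raising_thresholds_never_creates_calls(self, wt, mut, min_reads, fold):
        reads = ["WT"] * wt + ["MUT"] * mut
        base = LocusSpec("L", "AA", "AT", min_reads=min_reads, majority_fold=fold)
        stricter_reads = LocusSpec("L", "AA", "AT", min_reads=min_reads + 1, majority_fold=fold)
        stricter_fold = LocusSpec("L", "AA", "AT", min_reads=min_reads, majority_fold=fold + 1)
        if collapse_umi(reads, base) == "discard":
            assert collapse_umi(reads, stricter_reads) == "discard"
            assert collapse_umi(reads, stricter_fold) == "discard"

    def test_brute_force_equivalence_random_read_sets(self):
        """Consensus matches direct application of the rule on 10,000 random
        UMI read sets."""
        rng = np.random.default_rng(11)
        for _ in range(10_000):
            wt = int(rng.integers(0, 8))
            mut = int(rng.integers(0, 8))
            amb = int(rng.integers(0, 4))
            reads = ["WT"] * wt + ["MUT"] * mut + ["AMB"] * amb
            rng.shuffle(reads)
            if wt + mut < 3:
                expect = "discard"
            elif wt >= 3 * mut and wt > mut:
                expect = "WT"
            elif mut >= 3 * wt and mut > wt:
                expect = "MUT"
            else:
                expect = "discard"
            assert collapse_umi(reads, SPEC) == expect


class TestGenotypeCell:
    def test_mutant_dominance(self):
        g = genotype_cell(["WT", "MUT"], "c1", SPEC)
        assert g.call == "MUT" and g.definitive

    def test_wt_at_hemizygous_locus_is_definitive(self):
        hemi = LocusSpec("L", "AA", "AT", zygosity="hemizygous")
        g = genotype_cell(["WT"], "c1", hemi)
        assert g.call == "WT" and g.definitive

    def test_wt_at_heterozygous_locus_not_definitive(self):
        g = genotype_cell(["WT"], "c1", SPEC)
        assert g.call == "WT" and not g.definitive

    def test_no_umis_is_none(self):
        g = genotype_cell([], "c1", SPEC)
        assert g.call == "NONE"

    def test_adding_mut_umi_never_leaves_mut(self):
        for umis in (["WT"], [], ["WT", "WT"], ["MUT"]):
            assert genotype_cell(umis + ["MUT"], "c", SPEC).call == "MUT"

    def test_false_mut_rate_under_noise(self):
        """With per-read error 0.005, dropout 0.5 and 5 reads/UMI, fewer than
        1% of truly wild-type cells are miscalled mutant."""
        plan = SingleCellPlan(
            cells_per_type={"t": 500}, per_read_error=0.005, allelic_dropout=0.5,
            capture_rate=3.0, mean_reads_per_umi=5.0, n_genes=50,
            mean_umis_per_cell=100,
        )
        cells = {f"CELL{i:05d}": "wtclone" for i in range(500)}
        _, reads = simulate_sc_data(plan, 5, ["m1"], cells, {"m1": {"other"}})
        geno = genotype_cells(reads, LocusSpec("m1", "AA", "AT"))
        false_mut = (geno["call"] == "MUT").mean()
        assert false_mut < 0.01

    def test_noise_free_genotypes_exact(self):
        plan = SingleCellPlan(
            cells_per_type={"t": 100}, per_read_error=0.0, allelic_dropout=0.0,
            capture_rate=3.0, mean_reads_per_umi=5.0, n_genes=50,
            mean_umis_per_cell=100,
        )
        cells = {f"CELL{i:05d}": ("mut" if i % 2 else "wt") for i in range(100)}
        _, reads = simulate_sc_data(plan, 6, ["m1"], cells, {"m1": {"mut"}})
        geno = genotype_cells(reads, LocusSpec("m1", "AA", "AT"))
        for cb, row in geno.iterrows():
            if row["call"] == "NONE":
                continue  # no captured transcript
            assert row["call"] == ("MUT" if cells[cb] == "mut" else "WT")


class TestJunctionDetection:
    def _reads(self, rows):
        return pd.DataFrame(rows, columns=["locus", "cell_barcode", "umi", "read_index", "allele"])

    def test_junction_match_positive(self):
        spec = SpliceProductSpec(
            "MTAP", junction_sequences=["AATTCCGG"], reference_sequence="AATTAATT"
        )
        rows = [("MTAP", "c1", "u1", i, "AATTCCGG") for i in range(3)]
        out = detect_deletion_junction(self._reads(rows), spec)
        assert bool(out.loc["c1", "event_positive"])

    def test_no_junction_reads_negative(self):
        spec = SpliceProductSpec(
            "MTAP", junction_sequences=["AATTCCGG"], reference_sequence="AATTAATT"
        )
        rows = [("MTAP", "c1", "u1", i, "AATTAATT") for i in range(3)]
        out = detect_deletion_junction(self._reads(rows), spec)
        assert not bool(out.loc["c1", "event_positive"])

    def test_any_of_several_products_suffices(self):
        spec = SpliceProductSpec(
            "MTAP",
            junction_sequences=["AATTCCGG", "AATTGGGG", "AATTTTGG"],
            reference_sequence="AATTAATT",
        )
        rows = [("MTAP", "c1", "u1", i, "AATTGGGG") for i in range(3)]
        out = detect_deletion_junction(self._reads(rows), spec)
        assert bool(out.loc["c1", "event_positive"])


class TestPreEnrichment:
    def test_empty_pileup_all_zero(self):
        pile = pd.DataFrame(columns=["mutation_id", "cell_barcode", "umi", "base_matches_alt"])
        out = quantify_pre_enrichment(pile, ["m1", "m2"])
        assert (out[["n_cells", "n_umis"]] == 0).all().all()

    def test_distinct_cell_count(self):
        pile = pd.DataFrame(
            {
                "mutation_id": ["m1"] * 4,
                "cell_barcode": ["c1", "c1", "c2", "c3"],
                "umi": ["u1", "u1", "u2", "u3"],
                "base_matches_alt": [True] * 4,
            }
        )
        out = quantify_pre_enrichment(pile, ["m1"])
        assert out.loc["m1", "n_cells"] == 3
        assert out.loc["m1", "n_umis"] == 3  # c1's duplicate UMI collapses

    def test_detection_tracks_expression_rank(self):
        """Capture scales with expression, so detection counts and expression
        rank correlate strongly across 50 loci."""
        rng = np.random.default_rng(7)
        expr = np.exp(rng.normal(0, 1, size=50))
        rows = []
        for i, e in enumerate(expr):
            n = rng.poisson(e * 20)
            for j in range(n):
                rows.append({"mutation_id": f"m{i}", "cell_barcode": f"c{j % 100}",
                             "umi": f"u{j}", "base_matches_alt": True})
        pile = pd.DataFrame(rows)
        out = quantify_pre_enrichment(pile, [f"m{i}" for i in range(50)])
        from scipy.stats import spearmanr

        rho = spearmanr(out["n_umis"].reindex([f"m{i}" for i in range(50)]).fillna(0), expr).statistic
        assert rho > 0.8


class TestConcordance:
    def _calls(self, mapping):
        return pd.DataFrame(
            {"call": list(mapping.values())}, index=list(mapping.keys())
        )

    def test_identical_calls_jaccard_one(self):
        a = self._calls({"c1": "MUT", "c2": "WT"})
        res = replicate_concordance(a, a.copy())
        assert res.jaccard_mut == 1.0 and res.jaccard_wt == 1.0

    def test_disjoint_calls_jaccard_zero(self):
        a = self._calls({"c1": "MUT"})
        b = self._calls({"c2": "MUT"})
        assert replicate_concordance(a, b).jaccard_mut == 0.0

    def test_independent_capture_expectation(self):
        """Two replicates each capturing mutant transcripts with probability p
        overlap with expected Jaccard p / (2 - p)."""
        rng = np.random.default_rng(9)
        p = 0.3
        n = 4000
        caught_a = rng.random(n) < p
        caught_b = rng.random(n) < p
        a = self._calls({f"c{i}": "MUT" for i in np.flatnonzero(caught_a)})
        b = self._calls({f"c{i}": "MUT" for i in np.flatnonzero(caught_b)})
        res = replicate_concordance(a, b)
        expect = p**2 / (2 * p - p**2)
        assert res.jaccard_mut == pytest.approx(expect, abs=0.03)

    def test_disagreements_listed(self):
        a = self._calls({"c1": "MUT", "c2": "WT"})
        b = self._calls({"c1": "WT", "c2": "WT"})
        assert replicate_concordance(a, b).disagreements == ["c1"]
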