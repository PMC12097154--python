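import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import comb
from sklearn.metrics import adjusted_rand_score

from pupitome.design import generate_design
from pupitome.interactome import (TierThresholds, assign_tiers,
                                  benchmark_ratio, cluster_modules,
                                  coexpression_communities,
                                  filter_promiscuous,
                                  filter_reference_evidence,
                                  interaction_robustness,
                                  overlap_significance, tally_replication,
                                  tier_from_counts, tier_sets)
from pupitome.simulate import ReferenceSets


def call_row(protein, run, bait_a, bc_a, treat_a, bait_b, bc_b, treat_b,
             factor, log2fc, q):
    return {"protein": protein, "run_id": run, "varying_factor": factor,
            "bait_a": bait_a, "bait_construct_a": bc_a,
            "treatment_a": treat_a, "bait_b": bait_b,
            "bait_construct_b": bc_b, "treatment_b": treat_b,
            "log2fc": log2fc, "q": q,
            "enriched": q < 0.05 and log2fc > 0}


def vs_gfp(protein, run, bc, log2fc=3.0, q=0.001, treat="sucrose"):
    bait = bc.split("/")[0]
    return call_row(protein, run, bait, bc, treat, "GFP", "GFP", treat,
                    "bait", log2fc, q)


@pytest.fixture
def two_run_design():
    return generate_design(2, ["LST8", "RAPTOR", "GFP"],
                           ["sucrose", "mannitol"], [4])


class TestTallyReplication:
    def test_worked_replication_example(self, two_run_design):
        """Enriched in run 1 with both baits and in run 2 with one bait
        counts as thrice replicated."""
        calls = pd.DataFrame([
            vs_gfp("P1", "run1", "LST8/constitutive"),
            vs_gfp("P1", "run1", "RAPTOR/constitutive"),
            vs_gfp("P1", "run2", "LST8/constitutive"),
        ])
        tally = tally_replication(calls, two_run_design)
        assert tally.set_index("protein").at["P1", "replication_count"] == 3

    def test_never_enriched_absent(self, two_run_design):
        calls = pd.DataFrame([vs_gfp("P1", "run1", "LST8/constitutive",
                                     log2fc=0.5, q=0.9)])
        tally = tally_replication(calls, two_run_design)
        assert len(tally) == 0

    def test_gfp_flag_from_negative_side(self, two_run_design):
        """Enrichment on the control-bait side of a bait contrast (large
        negative fold change) marks the protein GFP-enriched."""
        calls = pd.DataFrame([
            vs_gfp("P1", "run1", "LST8/constitutive", log2fc=-4.0, q=0.001),
            vs_gfp("P1", "run2", "RAPTOR/constitutive"),
        ])
        t = tally_replication(calls, two_run_design).set_index("protein")
        assert t.at["P1", "ever_gfp_enriched"]
        assert t.at["P1", "replication_count"] == 1

    def test_control_treatment_flag(self, two_run_design):
        calls = pd.DataFrame([
            vs_gfp("P1", "run1", "LST8/constitutive", treat="mannitol"),
        ])
        t = tally_replication(calls, two_run_design).set_index("protein")
        assert t.at["P1", "ever_control_enriched"]
        assert t.at["P1", "replication_count"] == 1

    def test_random_fixtures_match_brute_force(self, two_run_design):
        """Oracle equivalence: counts equal an explicit set enumeration
        over (run, bait construct) on 50 random call fixtures."""
        rng = np.random.default_rng(0)
        bcs = ["LST8/constitutive", "RAPTOR/constitutive"]
        for _ in range(50):
            rows = []
            for pid in [f"P{i}" for i in range(8)]:
                for run in ("run1", "run2"):
                    for bc in bcs:
                        if rng.random() < 0.4:
                            rows.append(vs_gfp(pid, run, bc,
                                               log2fc=rng.uniform(1, 5)))
            if not rows:
                continue
            calls = pd.DataFrame(rows)
            tally = tally_replication(calls, two_run_design)
            expected = calls[calls["enriched"]].groupby("protein").apply(
                lambda g: len({(r, b) for r, b in
                               zip(g["run_id"], g["bait_construct_a"])}),
                include_groups=False)
            got = tally.set_index("protein")["replication_count"]
            assert got.sort_index().equals(
                expected.sort_index().astype("int64"))


class TestTiers:
    @pytest.mark.parametrize("count,gfp,control,substrate,expected", [
        (5, False, False, False, "core"),
        (2, True, False, False, "widest"),
        (4, False, False, False, "wider"),
        (1, False, False, True, "core"),
        (3, False, False, False, "wider"),
        (2, False, False, False, "widest"),
        (1, False, False, False, "none"),
        (5, True, False, False, "widest"),
        (5, False, True, False, "widest"),
    ])
    def test_rule_table(self, count, gfp, control, substrate, expected):
        assert tier_from_counts(count, gfp, control, substrate) == expected

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 8), st.booleans(), st.booleans())
    def test_nesting_without_substrate_clause(self, count, gfp, control):
        """core-eligible implies wider-eligible implies widest-eligible."""
        thr = TierThresholds()
        core = tier_from_counts(count, gfp, control, False,
                                substrate_clause=False) == "core"
        wider_ok = tier_from_counts(min(count, thr.wider), gfp, control,
                                    False, substrate_clause=False) \
            in ("wider", "core")
        widest_ok = tier_from_counts(min(count, thr.widest), gfp, control,
                                     False, substrate_clause=False) != "none" \
            if count >= thr.widest else True
        if core:
            assert wider_ok and widest_ok

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 8), st.booleans(), st.booleans(), st.booleans())
    def test_raising_thresholds_never_grows_a_tier(self, count, gfp, control,
                                                   substrate):
        loose = TierThresholds(2, 3, 5)
        strict = TierThresholds(3, 4, 6)
        rank = {"none": 0, "widest": 1, "wider": 2, "core": 3}
        t_loose = tier_from_counts(count, gfp, control, substrate, loose)
        t_strict = tier_from_counts(count, gfp, control, substrate, strict)
        assert rank[t_strict] <= rank[t_loose]

    def test_substrate_rescues_only_substrates(self):
        tally = pd.DataFrame({
            "protein": ["A", "B"], "replication_count": [1, 1],
            "bait_constructs_hit": [frozenset(), frozenset()],
            "ever_gfp_enriched": [False, False],
            "ever_control_enriched": [False, False],
        })
        out = assign_tiers(tally, substrates={"A"})
        tiers = dict(zip(out["protein"], out["tier"]))
        assert tiers == {"A": "core", "B": "none"}


class TestBenchmarks:
    def refs(self, known=(), vanleene=(), thylakoid=(), promiscuous=()):
        return ReferenceSets(known={k: 1.0 for k in known},
                             vanleene=set(vanleene), thylakoid=set(thylakoid),
                             promiscuous=set(promiscuous))

    def test_ratio_arithmetic(self):
        tier = {f"P{i}" for i in range(20)}
        refs = self.refs(known=[f"P{i}" for i in range(10)],
                         thylakoid=[f"P{i}" for i in range(10, 14)])
        high, low, ratio = benchmark_ratio(tier, refs)
        assert (high, low, ratio) == (10, 4, 2.5)

    def test_disjoint_sets_flagged(self):
        high, low, ratio = benchmark_ratio({"X"}, self.refs())
        assert (high, low) == (0, 0)
        assert math.isnan(ratio)

    def test_zero_low_is_infinite_not_error(self):
        high, low, ratio = benchmark_ratio({"A"}, self.refs(known=["A"]))
        assert (high, low) == (1, 0)
        assert math.isinf(ratio)

    def test_hypergeometric_degenerate(self):
        u = {f"P{i}" for i in range(30)}
        assert overlap_significance(u, u, 30) == pytest.approx(1.0)

    def test_hypergeometric_zero_overlap(self):
        a = {f"A{i}" for i in range(10)}
        b = {f"B{i}" for i in range(10)}
        assert overlap_significance(a, b, 100) == pytest.approx(1.0)

    def test_hypergeometric_closed_form_full_overlap(self):
        s = {f"P{i}" for i in range(5)}
        p = overlap_significance(s, s, 50)
        assert p == pytest.approx(1.0 / comb(50, 5), rel=1e-9)

    def test_evidence_threshold_is_strict(self):
        known = {"A": 0.25, "B": 0.26, "C": 0.24}
        assert filter_reference_evidence(known) == {"B"}
        assert filter_reference_evidence({}) == set()

    def test_promiscuous_partition(self):
        tier = {"A", "B", "C"}
        assert filter_promiscuous(tier, set()) == (tier, set())
        assert filter_promiscuous(tier, tier | {"D"}) == (set(), tier)
        spec, prom = filter_promiscuous(tier, {"B"})
        assert spec == {"A", "C"} and prom == {"B"}


class TestClustering:
    def test_two_blocks_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, (20, 6))
        b = rng.normal(5, 0.2, (20, 6))
        m = pd.DataFrame(np.vstack([a, b]),
                         index=[f"P{i}" for i in range(40)])
        rows, _ = cluster_modules(m, k=2)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, rows) == 1.0

    def test_duplicate_rows_same_module(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, (10, 4))
        m = pd.DataFrame(np.vstack([base, base[:1]]),
                         index=[f"P{i}" for i in range(11)])
        rows, _ = cluster_modules(m, k=3)
        assert rows.iloc[0] == rows.iloc[10]

    def test_missing_cells_treated_as_unchanged(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(0, 1, (12, 4)))
        m2 = m.copy()
        m2.iloc[3, 2] = np.nan
        m.iloc[3, 2] = 0.0
        r1, _ = cluster_modules(m, k=3)
        r2, _ = cluster_modules(m2, k=3)
        assert r1.equals(r2)

    def test_k_larger_than_rows_rejected(self):
        m = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cluster_modules(m, k=6)


class TestRobustness:
    def test_sums_enriched_fold_changes(self):
        calls = pd.DataFrame({
            "protein": ["A", "A", "A", "B"],
            "log2fc": [2.0, 3.0, 1.5, 2.5],
            "enriched": [True, True, True, True],
        })
        s = interaction_robustness(calls)
        assert s["A"] == pytest.approx(6.5)
        assert s["B"] == pytest.approx(2.5)

    def test_unenriched_ignored(self):
        calls = pd.DataFrame({"protein": ["A"], "log2fc": [9.0],
                              "enriched": [False]})
        assert "A" not in interaction_robustness(calls).index


class TestCoexpression:
    def cliques(self):
        edges = []
        for base in ("x", "y"):
            nodes = [f"{base}{i}" for i in range(10)]
            for i in range(10):
                for j in range(i + 1, 10):
                    edges.append((nodes[i], nodes[j], 10.0))
        edges.append(("x0", "y0", 0.1))
        # weak background so the percentile cut removes noise edges
        rng = np.random.default_rng(0)
        for i in range(6000):
            edges.append((f"b{i}", f"b{i + 1}", rng.uniform(0.01, 0.2)))
        return edges

    def test_planted_cliques_recovered(self):
        labels = coexpression_communities(self.cliques(), percentile=98)
        xs = {labels[f"x{i}"] for i in range(10)}
        ys = {labels[f"y{i}"] for i in range(10)}
        assert len(xs) == 1 and len(ys) == 1 and xs != ys

    def test_percentile_retains_top_fraction(self):
        rng = np.random.default_rng(1)
        edges = [(f"a{i}", f"b{i}", float(v))
                 for i, v in enumerate(rng.uniform(0, 1, 1000))]
        sd = np.std([e[2] for e in edges], ddof=1)
        cut = np.percentile([e[2] / sd for e in edges], 99)
        kept = sum(e[2] / sd >= cut for e in edges)
        assert abs(kept - 10) <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            coexpression_communities([("a", "b", 1.0), ("b", "c", 1.0)])


def test_tier_sets_nested(two_run_design):
    tally = pd.DataFrame({
        "protein": list("ABCDE"),
        "replication_count": [5, 3, 2, 1, 4],
        "bait_constructs_hit": [frozenset()] * 5,
        "ever_gfp_enriched": [False] * 5,
        "ever_control_enriched": [False] * 5,
    })
    tiers = assign_tiers(tally)
    sets = tier_sets(tiers)
    assert sets["core"] <= sets["wider"] <= sets["widest"]
    assert sets["core"] == {"A"}
    assert sets["wider"] == {"A", "B", "E"}
    assert sets["widest"] == {"A", "B", "C", "E"}
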