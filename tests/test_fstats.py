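import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleocline.fstats import (
    BlockSpec, UndefinedStatisticError, admixture_weights, continuity_scan,
    f2, f3_outgroup, f4, f4_ratio, jackknife, make_blocks,
)
from paleocline.genotype_store import GroupFreqs, group_frequencies
from paleocline.synthetic_data import (
    SamplePlan, admixture_recovery_graph, make_panel,
    sample_individuals, simulate_graph_freqs, simulate_turnover,
)


def freqs_from(matrix_like: dict[str, np.ndarray]) -> GroupFreqs:
    """GroupFreqs straight from frequency vectors (totals set large)."""
    groups = list(matrix_like)
    f = np.vstack([matrix_like[g] for g in groups])
    totals = np.where(np.isnan(f), 0.0, 100.0)
    counts = np.where(np.isnan(f), 0.0, f * 100.0)
    return GroupFreqs(groups, counts, totals)


def one_block(n: int) -> BlockSpec:
    return BlockSpec(np.zeros(n, dtype=int), 1)


def uniform_blocks(n: int, g: int) -> BlockSpec:
    return BlockSpec(np.arange(n) * g // n, g)


class TestMakeBlocks:
    def test_single_block_under_size(self):
        panel = make_panel(50, morgans=0.049)
        assert make_blocks(panel).n_blocks == 1

    def test_boundary_split(self):
        panel = make_panel(2, morgans=0.12)  # sites at 0.00 and 0.06 M
        spec = make_blocks(panel)
        assert spec.n_blocks == 2

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        chroms, gpos = [], []
        for c in ("1", "2"):
            n = 200
            g = np.sort(rng.uniform(0, 0.4, n))
            chroms += [c] * n
            gpos += list(g)
        panel_df = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(len(gpos))],
            "chrom": chroms, "pos": list(range(1, 201)) * 2,
            "genetic_pos": gpos, "allele1": "A", "allele2": "C",
            "ancestral": "A"})
        from paleocline.genotype_store import SnpPanel
        panel = SnpPanel(panel_df)
        spec = make_blocks(panel, 0.05)
        # independent scan
        expected = []
        block = -1
        prev_c, start = None, 0.0
        for c, g in zip(chroms, gpos):
            if c != prev_c or g - start > 0.05:
                block += 1
                start = g
                prev_c = c
            expected.append(block)
        assert list(spec.block_index) == expected

    def test_physical_fallback_when_genetic_missing(self):
        panel = make_panel(3).sites.copy()
        panel["genetic_pos"] = np.nan
        panel["pos"] = [1, 4_000_000, 12_000_000]
        from paleocline.genotype_store import SnpPanel
        spec = make_blocks(SnpPanel(panel), fallback_bp=5_000_000)
        assert list(spec.block_index) == [0, 0, 1]


class TestEstimators:
    def test_f4_zero_for_identical_arms(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 100)
        gf = freqs_from({"A": p, "B": p.copy(), "C": rng.uniform(0, 1, 100),
                         "D": rng.uniform(0, 1, 100)})
        st_ = f4(gf, "A", "B", "C", "D", one_block(100))
        assert st_.estimate == 0.0

    def test_f4_hand_example(self):
        gf = freqs_from({"A": np.array([1.0, 1.0]), "B": np.array([0.0, 0.0]),
                         "C": np.array([1.0, 0.0]), "D": np.array([0.0, 1.0])})
        st_ = f4(gf, "A", "B", "C", "D", one_block(2))
        assert st_.estimate == pytest.approx(0.0)

    def test_f2_fixed_vectors(self):
        gf = freqs_from({"A": np.array([1.0, 0.0]), "B": np.array([0.0, 1.0])})
        assert f2(gf, "A", "B", one_block(2)).estimate == pytest.approx(1.0)

    def test_f3_self_comparison_nonnegative(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0, 1, 200)
        gf = freqs_from({"O": rng.uniform(0, 1, 200), "A": p, "B": p.copy()})
        assert f3_outgroup(gf, "O", "A", "B", one_block(200)).estimate >= 0

    @pytest.mark.parametrize("kind", ["f2", "f3", "f4"])
    def test_matches_brute_force_loop(self, kind):
        rng = np.random.default_rng(2)
        names = ["A", "B", "C", "D"]
        vec = {n: rng.uniform(0, 1, 1000) for n in names}
        for n in names:  # sprinkle missingness
            vec[n][rng.random(1000) < 0.05] = np.nan
        gf = freqs_from(vec)
        blocks = uniform_blocks(1000, 10)
        if kind == "f2":
            st_ = f2(gf, "A", "B", blocks)
            prod = (vec["A"] - vec["B"]) ** 2
            mask = ~(np.isnan(vec["A"]) | np.isnan(vec["B"]))
        elif kind == "f3":
            st_ = f3_outgroup(gf, "A", "B", "C", blocks)
            prod = (vec["A"] - vec["B"]) * (vec["A"] - vec["C"])
            mask = ~np.isnan(vec["A"] + vec["B"] + vec["C"])
        else:
            st_ = f4(gf, "A", "B", "C", "D", blocks)
            prod = (vec["A"] - vec["B"]) * (vec["C"] - vec["D"])
            mask = ~np.isnan(vec["A"] + vec["B"] + vec["C"] + vec["D"])
        brute = float(np.mean(prod[mask]))
        assert st_.estimate == pytest.approx(brute, abs=1e-12)
        assert st_.n_snps == int(mask.sum())

    def test_f4_antisymmetry_and_additivity_exact(self):
        rng = np.random.default_rng(3)
        vec = {n: rng.uniform(0, 1, 500) for n in "ABCDE"}
        gf = freqs_from(vec)
        b = uniform_blocks(500, 5)
        ab_cd = f4(gf, "A", "B", "C", "D", b).estimate
        assert f4(gf, "B", "A", "C", "D", b).estimate == pytest.approx(
            -ab_cd, abs=1e-15)
        assert f4(gf, "A", "B", "D", "C", b).estimate == pytest.approx(
            -ab_cd, abs=1e-15)
        ab_ce = f4(gf, "A", "B", "C", "E", b).estimate
        ab_ed = f4(gf, "A", "B", "E", "D", b).estimate
        assert ab_ce + ab_ed == pytest.approx(ab_cd, abs=1e-12)

    def test_no_shared_sites_is_an_error(self):
        a = np.array([0.5, np.nan])
        b = np.array([np.nan, 0.5])
        gf = freqs_from({"A": a, "B": b})
        with pytest.raises(UndefinedStatisticError):
            f2(gf, "A", "B", one_block(2))


class TestJackknife:
    def test_identical_blocks_zero_se(self):
        sums = np.full(10, 3.0)
        counts = np.full(10, 100)
        se, z = jackknife(sums, counts)
        assert se == pytest.approx(0.0, abs=1e-15)

    def test_equal_blocks_reduce_to_classic_formula(self):
        rng = np.random.default_rng(5)
        g, m = 20, 50
        x = rng.normal(0, 1, (g, m))
        sums = x.sum(axis=1)
        counts = np.full(g, m)
        est = sums.sum() / counts.sum()
        loo = np.array([(sums.sum() - sums[j]) / (counts.sum() - m)
                        for j in range(g)])
        classic = np.sqrt((g - 1) / g * ((loo - loo.mean()) ** 2).sum())
        se, _ = jackknife(sums, counts)
        assert se == pytest.approx(classic, rel=1e-10)

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ValueError):
            jackknife(np.array([1.0]), np.array([10]))

    def test_ci_coverage_near_nominal(self):
        # mean-zero clade f4: nominal 95% CI should cover 0 ~95% of runs
        rng = np.random.default_rng(6)
        n, g, cover = 20_000, 50, 0
        reps = 120
        for _ in range(reps):
            a = rng.uniform(0.05, 0.95, n)
            noise = 0.05
            pa = np.clip(a + rng.normal(0, noise, n), 0, 1)
            pb = np.clip(a + rng.normal(0, noise, n), 0, 1)
            pc = rng.uniform(0.05, 0.95, n)
            pd_ = rng.uniform(0.05, 0.95, n)
            gf = freqs_from({"A": pa, "B": pb, "C": pc, "D": pd_})
            st_ = f4(gf, "A", "B", "C", "D", uniform_blocks(n, g))
            lo, hi = st_.ci95
            cover += lo <= 0.0 <= hi
        assert 0.89 <= cover / reps <= 1.0


@pytest.fixture(scope="module")
def graph_freqs():
    graph = admixture_recovery_graph(0.3)
    fr = simulate_graph_freqs(graph, 20_000, 7)
    plans = [SamplePlan(n, 10, ploidy=1)
             for n in ["O", "S1", "S2", "X", "R0", "R1", "R2", "R3"]]
    panel, matrix, meta = sample_individuals(fr, plans, 8)
    gf = group_frequencies(matrix, meta)
    blocks = make_blocks(panel)
    return gf, blocks


@pytest.fixture(scope="module")
def system():
    graph = admixture_recovery_graph(0.7)
    fr = simulate_graph_freqs(graph, 20_000, 11)
    plans = [SamplePlan(n, 10, ploidy=1)
             for n in ["O", "S1", "S2", "X", "R0", "R1", "R2", "R3"]]
    panel, matrix, meta = sample_individuals(fr, plans, 12)
    return group_frequencies(matrix, meta), make_blocks(panel)


class TestF4Ratio:
    def test_endpoints(self, graph_freqs):
        gf, blocks = graph_freqs
        # X = B endpoint: alpha = 1 exactly; X = C endpoint: alpha = 0
        assert f4_ratio(gf, "S1", "R1", "S1", "S2", "O",
                        blocks).alpha == pytest.approx(1.0)
        assert f4_ratio(gf, "S2", "R1", "S1", "S2", "O",
                        blocks).alpha == pytest.approx(0.0)

    def test_recovers_mixture_weight(self, graph_freqs):
        gf, blocks = graph_freqs
        est = f4_ratio(gf, "X", "R1", "S1", "S2", "O", blocks)
        assert est.ci_low[0] <= 0.3 <= est.ci_high[0]
        assert not est.warnings

    def test_weak_denominator_flagged(self):
        rng = np.random.default_rng(9)
        n = 500
        vec = {k: rng.uniform(0.4, 0.6, n) for k in "XABCO"}
        gf = freqs_from(vec)
        est = f4_ratio(gf, "X", "A", "B", "C", "O", uniform_blocks(n, 10))
        assert est.warnings


class TestAdmixtureWeights:
    def test_single_source_weight_is_one(self, system):
        gf, blocks = system
        est = admixture_weights(gf, "X", ["S1"], ["R0", "R1", "R2", "R3"],
                                "O", blocks)
        assert est.weights[0] == pytest.approx(1.0)
        assert est.df == 3
        # X is admixed, so the single-source (cladality) fit should fail
        assert est.tail_prob < 0.05

    def test_two_source_recovery_and_sum(self, system):
        gf, blocks = system
        est = admixture_weights(gf, "X", ["S1", "S2"],
                                ["R0", "R1", "R2", "R3"], "O", blocks)
        assert est.weights.sum() == pytest.approx(1.0)
        assert est.ci_low[0] <= 0.7 <= est.ci_high[0]

    def test_rights_order_invariance(self, system):
        gf, blocks = system
        w1 = admixture_weights(gf, "X", ["S1", "S2"],
                               ["R0", "R1", "R2", "R3"], "O", blocks).weights
        w2 = admixture_weights(gf, "X", ["S1", "S2"],
                               ["R0", "R3", "R2", "R1"], "O", blocks).weights
        np.testing.assert_allclose(w1, w2, atol=1e-10)

    def test_collinear_sources_rejected(self, system):
        gf, blocks = system
        with pytest.raises(ValueError, match="disjoint|collinear"):
            admixture_weights(gf, "X", ["S1", "S1"],
                              ["R0", "R1", "R2", "R3"], "O", blocks)

    def test_agrees_with_f4_ratio_on_two_sources(self, system):
        gf, blocks = system
        w = admixture_weights(gf, "X", ["S1", "S2"],
                              ["R0", "R1", "R2", "R3"], "O", blocks)
        r = f4_ratio(gf, "X", "R1", "S1", "S2", "O", blocks)
        se = np.hypot(w.se[0], r.se[0])
        assert abs(w.weights[0] - r.alpha) < 2 * se


class TestContinuityScan:
    def test_turnover_scenario_flags_exactly_post(self):
        panel, matrix, meta, truth = simulate_turnover(4, 4, 30_000, 21)
        grouping = {i: (i if i.startswith(("pre", "post")) else "Outgroup")
                    for i in matrix.individuals}
        gf = group_frequencies(matrix, meta, grouping)
        blocks = make_blocks(panel)
        ages = dict(zip(meta["id"], meta["cal_bp_mid"]))
        scan = continuity_scan(
            gf, truth.params["pre_ids"] + truth.params["post_ids"],
            truth.params["pre_ids"][0], "Outgroup", blocks, ages)
        flagged = set(scan.loc[scan["discontinuous"], "id"])
        assert flagged == set(truth.params["post_ids"])

    def test_low_coverage_individual_excluded_not_flagged(self):
        panel, matrix, meta, truth = simulate_turnover(3, 2, 2_000, 22)
        # knock one pre individual down to almost no data
        sparse = truth.params["pre_ids"][-1]
        i = matrix.index_of(sparse)
        calls = matrix.calls.copy()
        keep = np.zeros(matrix.n_sites, bool)
        keep[:400] = True
        calls[i, ~keep] = 9
        from paleocline.genotype_store import GenotypeMatrix
        matrix = GenotypeMatrix(matrix.individuals, matrix.ploidy, calls)
        grouping = {i: (i if i.startswith(("pre", "post")) else "Outgroup")
                    for i in matrix.individuals}
        gf = group_frequencies(matrix, meta, grouping)
        scan = continuity_scan(
            gf, truth.params["pre_ids"] + truth.params["post_ids"],
            truth.params["pre_ids"][0], "Outgroup", make_blocks(panel),
            dict(zip(meta["id"], meta["cal_bp_mid"])), min_sites=500)
        row = scan.set_index("id").loc[sparse]
        assert row["excluded"] and not row["discontinuous"]

    def test_missing_anchor_rejected(self):
        gf = freqs_from({"A": np.array([0.5]), "O": np.array([0.5])})
        with pytest.raises(KeyError):
            continuity_scan(gf, ["A"], "nope", "O", one_block(1), {"A": 1.0})


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_f4_antisymmetry_property(seed):
    rng = np.random.default_rng(seed)
    vec = {n: rng.uniform(0, 1, 64) for n in "ABCD"}
    gf = freqs_from(vec)
    b = uniform_blocks(64, 4)
    assert f4(gf, "A", "B", "C", "D", b).estimate == pytest.approx(
        -f4(gf, "B", "A", "C", "D", b).estimate, abs=1e-15)
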