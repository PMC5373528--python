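"""Count-level pipeline: normalization, thresholding, DE, set algebra, qPCR."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import null_count_matrix
from zfscreen.simulate import simulate_counts
from zfscreen.transcriptomics import (
    CountMatrix,
    QpcrRecord,
    active_genes,
    background_subtract,
    bh_adjust,
    call_degs,
    category_enrichment,
    de_test,
    estimate_size_factors,
    flag_replicate_outliers,
    normalize,
    qpcr_relative_expression,
    venn_partition,
)


def brute_force_bh(p):
    """Textbook step-up rule, implemented independently for cross-checking."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p)
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self, rng):
        col = rng.poisson(60, size=800)
        counts = pd.DataFrame({"a": col, "b": col})
        assert estimate_size_factors(counts).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_normalizes_away(self, rng):
        col = rng.poisson(60, size=800) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        lengths = pd.Series(1.0, index=counts.index)
        expr = normalize(counts, lengths)
        assert expr["a"].to_numpy() == pytest.approx(expr["b"].to_numpy(), rel=1e-9)

    def test_robust_to_composition_bias(self, rng):
        """A 10% minority of 4-fold-up genes barely moves the depth estimate."""
        base = rng.poisson(100, size=2000).astype(float)
        a = rng.poisson(base).astype(float)
        b = rng.poisson(base).astype(float)
        up = rng.choice(2000, 200, replace=False)
        b[up] = rng.poisson(base[up] * 4)
        counts = pd.DataFrame({"a": a, "b": b})
        factors = estimate_size_factors(counts)
        eff = (counts.sum(axis=0) * factors).to_numpy()
        assert abs(eff[1] / eff[0] - 1.0) < 0.05

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            estimate_size_factors(counts)


class TestNormalize:
    def test_length_scaling(self):
        counts = pd.DataFrame({"s1": [100, 100], "s2": [100, 100]}, index=["g1", "g2"])
        lengths = pd.Series([1.0, 2.0], index=["g1", "g2"])
        expr = normalize(counts, lengths)
        assert expr.loc["g1"].to_numpy() == pytest.approx(2 * expr.loc["g2"].to_numpy())

    def test_zero_counts_stay_zero(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 9]}, index=["g1", "g2"])
        lengths = pd.Series([1.0, 1.0], index=["g1", "g2"])
        assert (normalize(counts, lengths).loc["g1"] == 0).all()

    def test_missing_length_names_genes(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="g2"):
            normalize(counts, pd.Series([1.0], index=["g1"]))

    def test_round_trip_recovers_relative_expression(self):
        """Simulated counts, once normalized, rank like the true means."""
        cm, lengths, _ = simulate_counts(
            n_genes=1000, lines=["l1"], line_specific_deg_fraction=0.0,
            background_deg_fraction=0.0, seed=5,
        )
        expr = normalize(cm.counts, lengths)
        # control replicates should correlate strongly after normalization
        cols = cm.samples_of("Col-0")
        r = np.corrcoef(np.log1p(expr[cols[0]]), np.log1p(expr[cols[1]]))[0, 1]
        assert r > 0.95


class TestActiveGenes:
    @staticmethod
    def _mixture(rng, n_active=1400, n_inactive=600, n_samples=3):
        cols = {}
        for i in range(n_samples):
            act = 2.0 ** rng.normal(5, 1, n_active)
            inact = 2.0 ** rng.normal(-2, 1, n_inactive)
            cols[f"s{i}"] = np.concatenate([act, inact])
        expr = pd.DataFrame(cols, index=[f"g{i}" for i in range(n_active + n_inactive)])
        truth = np.array([True] * n_active + [False] * n_inactive)
        return expr, truth

    def test_mixture_modes_separated(self, rng):
        expr, truth = self._mixture(rng)
        groups = pd.Series(["A"] * 3, index=expr.columns)
        active = active_genes(expr, groups).to_numpy()
        sensitivity = (active & truth).sum() / truth.sum()
        false_rate = (active & ~truth).sum() / (~truth).sum()
        assert sensitivity >= 0.95
        assert false_rate <= 0.05

    def test_lowering_z_min_only_adds_genes(self, rng):
        expr, _ = self._mixture(rng)
        groups = pd.Series(["A"] * 3, index=expr.columns)
        strict = active_genes(expr, groups, z_min=-1.0)
        loose = active_genes(expr, groups, z_min=-4.0)
        assert (strict & ~loose).sum() == 0

    def test_degenerate_distribution_errors(self):
        expr = pd.DataFrame({"s1": np.full(200, 8.0)})
        with pytest.raises(ValueError, match="degenerate"):
            active_genes(expr, min_positive=100)

    def test_too_few_positive_genes_errors(self):
        expr = pd.DataFrame({"s1": np.concatenate([np.zeros(150), np.ones(50)])})
        with pytest.raises(ValueError, match="positive"):
            active_genes(expr, min_positive=100)


class TestDeTest:
    def test_identical_counts_give_null_result(self, rng):
        col = rng.poisson(100, size=300)
        counts = pd.DataFrame(
            {f"s{i}": col for i in range(6)}, index=[f"g{i}" for i in range(300)]
        )
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=counts.columns)
        table = de_test(CountMatrix(counts=counts, groups=groups), "A", "B")
        assert table["log2fc"].to_numpy() == pytest.approx(0.0, abs=1e-12)
        assert (table["pvalue"] == 1.0).all()

    def test_type_i_error_calibrated(self):
        """Null NB simulations reject at close to the nominal 5% rate."""
        rates = []
        for seed in range(25):
            cm = null_count_matrix(seed)
            table = de_test(cm, "A", "B")
            rates.append((table["pvalue"] < 0.05).mean())
        assert 0.025 <= np.mean(rates) <= 0.075

    def test_planted_fold_changes_detected(self, rng):
        """4-fold changes at mean 100, phi=0.05, n=3 are almost all found
        at BH-adjusted p < 1e-4."""
        n_genes, n_deg = 2000, 40
        phi = 0.05
        size = 1.0 / phi
        mu = np.full(n_genes, 100.0)
        mu_b = mu.copy()
        planted_idx = rng.choice(n_genes, n_deg, replace=False)
        mu_b[planted_idx] *= np.where(rng.random(n_deg) < 0.5, 4.0, 0.25)
        counts = pd.DataFrame(
            np.column_stack(
                [rng.negative_binomial(size, size / (size + mu), (3, n_genes)).T,
                 rng.negative_binomial(size, size / (size + mu_b), (3, n_genes)).T]
            ),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["ctrl"] * 3 + ["line"] * 3, index=counts.columns)
        table = de_test(CountMatrix(counts=counts, groups=groups), "line", "ctrl")
        up, down = call_degs(table, alpha=1e-4)
        planted = {f"g{i}" for i in planted_idx}
        assert len(planted & (up | down)) / n_deg >= 0.8

    def test_direction_convention(self, rng):
        """Positive log2fc means higher expression in group_a; only a
        subset of genes is shifted so depth normalization cannot absorb it."""
        mu = np.full(300, 200.0)
        mu_hi = mu.copy()
        mu_hi[:30] *= 4  # genes g0..g29 up in the 'hi' group
        counts = pd.DataFrame(
            np.column_stack(
                [rng.poisson(mu_hi, (3, 300)).T, rng.poisson(mu, (3, 300)).T]
            ),
            index=[f"g{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series(["hi"] * 3 + ["lo"] * 3, index=counts.columns)
        table = de_test(CountMatrix(counts=counts, groups=groups), "hi", "lo")
        assert (table["log2fc"].iloc[:30] > 0).all()
        assert table["log2fc"].iloc[30:].abs().mean() < 0.2

    def test_undersized_group_rejected(self):
        counts = pd.DataFrame({"a": [1], "b": [2], "c": [3]}, index=["g"])
        groups = pd.Series(["A", "A", "B"], index=counts.columns)
        cm = CountMatrix(counts=counts, groups=groups)
        with pytest.raises(ValueError):
            de_test(cm, "A", "B")


class TestBhAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 60)))
            assert bh_adjust(p) == pytest.approx(brute_force_bh(p))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_order_preserving_and_bounded(self, p):
        adj = bh_adjust(p)
        assert ((adj >= np.asarray(p) - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDegs:
    def test_empty_table(self):
        up, down = call_degs(pd.DataFrame())
        assert up == set() and down == set()

    def test_threshold_filtering_matches_list_comprehension(self, rng):
        table = pd.DataFrame(
            {
                "padj": rng.uniform(0, 0.01, 500),
                "log2fc": rng.normal(0, 2, 500),
            },
            index=[f"g{i}" for i in range(500)],
        )
        for alpha, min_fold in [(1e-4, None), (1e-3, 2.0), (0.05, 1.5)]:
            up, down = call_degs(table, alpha, min_fold)
            expect_up = {
                g
                for g, r in table.iterrows()
                if r["padj"] < alpha
                and r["log2fc"] > 0
                and (min_fold is None or abs(r["log2fc"]) >= np.log2(min_fold))
            }
            assert up == expect_up

    def test_fold_criterion_never_enlarges(self, rng):
        table = pd.DataFrame(
            {"padj": rng.uniform(0, 0.001, 300), "log2fc": rng.normal(0, 1, 300)},
            index=[f"g{i}" for i in range(300)],
        )
        up0, down0 = call_degs(table, 1e-2)
        up2, down2 = call_degs(table, 1e-2, min_fold=2.0)
        assert up2 <= up0 and down2 <= down0


def shared_deg_fixture():
    """Three lines sharing 157 DEGs: 116 in both background pools, 31 in
    exactly one, 10 in neither — the structure background subtraction is
    built to resolve."""
    shared = [f"s{i}" for i in range(157)]
    in_both = set(shared[:116])
    in_one = set(shared[116:147])  # 31 genes
    specific = set(shared[147:])  # 10 genes
    lines = {f"L{k}": set(shared) | {f"L{k}_own{i}" for i in range(20)} for k in range(3)}
    backgrounds = {
        "bg1": in_both | set(list(in_one)[:16]) | {"bg1_own"},
        "bg2": in_both | set(list(in_one)[16:]) | {"bg2_own"},
    }
    return lines, backgrounds, specific


class TestSetAlgebra:
    def test_disjoint_sets(self):
        regions = venn_partition({"a": {1, 2, 3}, "b": {4, 5, 6, 7, 8}})
        assert regions[frozenset({"a"})] == 3
        assert regions[frozenset({"b"})] == 5
        assert frozenset({"a", "b"}) not in regions

    def test_identical_sets(self):
        regions = venn_partition({"a": {1, 2}, "b": {1, 2}})
        assert regions == {frozenset({"a", "b"}): 2}

    def test_regions_sum_to_union(self, rng):
        sets = {
            name: set(rng.choice(100, size=rng.integers(5, 40), replace=False))
            for name in "abcd"
        }
        regions = venn_partition(sets)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_three_line_two_background_partition(self):
        lines, backgrounds, specific = shared_deg_fixture()
        regions = venn_partition({**lines, **backgrounds})
        line_names = frozenset(lines)
        assert regions[line_names] == 10
        assert regions[frozenset(set(lines) | set(backgrounds))] == 116
        in_exactly_one_bg = sum(
            regions.get(frozenset(set(lines) | {bg}), 0) for bg in backgrounds
        )
        assert in_exactly_one_bg == 31

    def test_background_subtract_fixture(self):
        lines, backgrounds, specific = shared_deg_fixture()
        assert background_subtract(lines, backgrounds) == specific

    def test_background_subtract_degenerate_cases(self):
        lines = {"a": {1, 2, 3}, "b": {2, 3, 4}}
        assert background_subtract(lines, None) == {2, 3}
        assert background_subtract(lines, {"bg": {2, 3}}) == set()


class TestCategoryEnrichment:
    def test_chloroplast_fraction_of_shared_degs(self):
        """33 labeled among 157 drawn from a 12546-gene universe with 2039
        labeled reproduces the 21% chloroplast fraction, mildly enriched
        over the 16.5% background."""
        genes = [f"At{i}" for i in range(12546)]
        labels = pd.Series(False, index=genes)
        labels.iloc[:2039] = True
        deg = genes[:33] + genes[2039 : 2039 + 124]
        frac, p = category_enrichment(deg, labels)
        assert round(100 * frac) == 21
        assert 100 * labels.mean() == pytest.approx(16.25, abs=0.5)
        assert p < 0.15  # modest excess over background

    def test_full_universe_label(self):
        labels = pd.Series(True, index=[f"g{i}" for i in range(10)])
        frac, p = category_enrichment(["g1", "g2"], labels)
        assert frac == 1.0
        assert p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Hypergeometric tail equals brute-force enumeration over C(10,3)."""
        genes = [f"g{i}" for i in range(10)]
        labels = pd.Series([True] * 4 + [False] * 6, index=genes)
        deg = ["g0", "g1", "g5"]  # k = 2 labeled
        _, p = category_enrichment(deg, labels)
        count = sum(
            sum(labels[g] for g in combo) >= 2
            for combo in itertools.combinations(genes, 3)
        )
        assert p == pytest.approx(count / 120)

    def test_empty_set_rejected(self):
        labels = pd.Series([True], index=["g"])
        with pytest.raises(ValueError):
            category_enrichment([], labels)


class TestQc:
    def test_outlier_replicate_flagged(self, rng):
        base = rng.lognormal(3, 1, 500)
        expr = pd.DataFrame(
            {f"s{i}": base * rng.lognormal(0, 0.05, 500) for i in range(6)}
        )
        expr["s5"] = rng.permutation(base) * 30  # scrambled, distant replicate
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=expr.columns)
        flags = flag_replicate_outliers(expr, groups)
        assert flags["s5"]
        assert flags.drop("s5").sum() == 0


class TestQpcr:
    def test_equal_cq_gives_unity(self):
        rec = QpcrRecord("s", cq_target=20.0, cq_ref1=20.0, cq_ref2=20.0)
        assert qpcr_relative_expression(rec) == pytest.approx(1.0)

    @pytest.mark.parametrize("eff,expected", [(2.0, 2.0), (1.9, 1.9)])
    def test_one_cycle_advantage(self, eff, expected):
        rec = QpcrRecord("s", 19.0, 20.0, 20.0, efficiency=eff)
        assert qpcr_relative_expression(rec) == pytest.approx(expected)

    def test_reference_averaging_is_geometric(self):
        rec = QpcrRecord("s", 20.0, 19.0, 21.0, efficiency=2.0)
        # mean Cq of refs is 20 -> geometric mean of their E^-Cq values
        assert qpcr_relative_expression(rec) == pytest.approx(1.0)

    def test_invalid_efficiency(self):
        with pytest.raises(ValueError):
            qpcr_relative_expression(QpcrRecord("s", 20, 20, 20, efficiency=1.0))
        with pytest.raises(ValueError):
            qpcr_relative_expression(QpcrRecord("s", 20, 20, 20, efficiency=2.5))

    def test_invalid_cq(self):
        with pytest.raises(ValueError):
            qpcr_relative_expression(QpcrRecord("s", -1.0, 20, 20))
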