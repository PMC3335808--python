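"""TMM normalisation, exact conditional test, FDR, DEG calling and summaries."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, rankdata

import dgetag as d
from dgetag.mapping import GeneCountMatrix

getcontext().prec = 60


def ac_two_sided_oracle(x, y, n1, n2):
    """Naive big-float direct summation of the conditional tag law."""
    r = Decimal(str(n2)) / Decimal(str(n1))
    one = Decimal(1)
    term = one / (one + r) ** (x + 1)  # p(0 | x)
    lower_incl = Decimal(0)
    lower_excl = Decimal(0)
    for k in range(0, y + 1):
        if k < y:
            lower_excl += term
        lower_incl += term
        term = term * r / (one + r) * Decimal(x + k + 1) / Decimal(k + 1)
    upper_incl = one - lower_excl
    p = 2 * min(lower_incl, upper_incl)
    return float(min(one, p))


def tmm_oracle(counts, sizes, ref, trim_m=0.30, trim_a=0.05):
    """From-definition trimmed weighted mean of M values, plain loops."""
    logf = {}
    xr = counts[ref]
    nr = sizes[ref]
    for lib in counts.columns:
        if lib == ref:
            logf[lib] = 0.0
            continue
        rows = [
            (math.log2((counts[lib][g] / sizes[lib]) / (xr[g] / nr)),
             0.5 * math.log2((counts[lib][g] / sizes[lib]) * (xr[g] / nr)),
             (sizes[lib] - counts[lib][g]) / (sizes[lib] * counts[lib][g])
             + (nr - xr[g]) / (nr * xr[g]))
            for g in counts.index
            if counts[lib][g] > 0 and xr[g] > 0
        ]
        m = np.array([r[0] for r in rows])
        a = np.array([r[1] for r in rows])
        w = np.array([r[2] for r in rows])
        k = len(m)
        keep = np.ones(k, bool)
        for vals, trim in ((m, trim_m), (a, trim_a)):
            lo = math.floor(k * trim) + 1
            hi = k - math.floor(k * trim)
            rk = rankdata(vals)
            keep &= (rk >= lo) & (rk <= hi)
        logf[lib] = float(np.sum(m[keep] / w[keep]) / np.sum(1 / w[keep]))
    f = pd.Series({lib: 2.0 ** v for lib, v in logf.items()})
    return f / np.exp(np.log(f).mean())


@pytest.fixture(scope="module")
def null_matrix(gene_stubs):
    truth = d.simulate_expression_profiles(gene_stubs, de_fraction=0.0, seed=61)
    return GeneCountMatrix.from_counts(d.simulate_count_matrix(truth, 60_000, seed=62))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(100, 200) + 1
        m = GeneCountMatrix.from_counts(pd.DataFrame({"0h": a, "24h": a}))
        assert d.tmm_factors(m).factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        # doubling every gene changes the library size, not the composition
        rng = np.random.default_rng(2)
        a = rng.poisson(80, 300) + 1
        m = GeneCountMatrix.from_counts(pd.DataFrame({"0h": a, "24h": 2 * a}))
        nr = d.tmm_factors(m)
        assert nr.factors.to_numpy() == pytest.approx([1.0, 1.0])
        assert nr.effective_sizes["24h"] == pytest.approx(2 * nr.effective_sizes["0h"])

    def test_spiked_matrix_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(60, 150) + 1
        counts = pd.DataFrame({
            "0h": base,
            "24h": np.concatenate([base[:-1], [base[-1] * 40]]),
            "48h": rng.poisson(60, 150) + 1,
        })
        m = GeneCountMatrix.from_counts(counts)
        got = d.tmm_factors(m, ref_label="0h").factors
        want = tmm_oracle(m.counts, m.library_sizes.astype(float), "0h")
        assert got.to_numpy() == pytest.approx(want.loc[got.index].to_numpy(), abs=1e-6)

    def test_factor_product_is_one(self, null_matrix):
        f = d.tmm_factors(null_matrix).factors
        assert np.prod(f) == pytest.approx(1.0)

    def test_no_coexpressed_genes_is_an_error(self):
        counts = pd.DataFrame({"0h": [5, 0], "24h": [0, 5]}, index=["a", "b"])
        with pytest.raises(ValueError, match="co-expressed"):
            d.tmm_factors(GeneCountMatrix.from_counts(counts))


class TestExactTest:
    def test_equal_observation_equal_sizes_is_not_significant(self):
        assert d.exact_test_p(7, 7, 1e6, 1e6) == pytest.approx(1.0)

    def test_matches_direct_summation_oracle(self):
        cases = [(5, 50, 1e6, 1e6), (0, 0, 1, 2), (3, 7, 1000, 2000),
                 (100, 80, 5e5, 7e5), (0, 10, 1e4, 2e4), (20, 20, 3e5, 3e5)]
        for x, y, n1, n2 in cases:
            assert d.exact_test_p(x, y, n1, n2) == pytest.approx(
                ac_two_sided_oracle(x, y, n1, n2), abs=1e-10)

    def test_swap_symmetry_up_to_discreteness(self):
        # swapping (x, N1) and (y, N2) changes the doubled-tail p by no
        # more than the point masses at the observation
        rng = np.random.default_rng(7)
        for _ in range(100):
            x, y = (int(v) for v in rng.integers(0, 300, 2))
            n1, n2 = rng.uniform(1e4, 1e6, 2)
            fwd = d.exact_test_p(x, y, n1, n2)
            rev = d.exact_test_p(y, x, n2, n1)
            pr = n1 / (n1 + n2)
            slack = 2 * (nbinom.pmf(y, x + 1, pr) + nbinom.pmf(x, y + 1, 1 - pr))
            assert abs(fwd - rev) <= slack + 1e-12

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            d.exact_test_p(1.5, 2, 100, 100)

    def test_more_extreme_count_is_more_significant(self):
        ps = [d.exact_test_p(10, y, 1e5, 1e5) for y in (20, 40, 80)]
        assert ps[0] > ps[1] > ps[2]


class TestLogFoldChange:
    def test_worked_example_with_and_without_pseudo(self):
        assert d.log_fold_change(10, 160, 1e6, 1e6, pseudo=1) == pytest.approx(
            np.log2(161 / 11))
        assert d.log_fold_change(10, 160, 1e6, 1e6, pseudo=0) == pytest.approx(4.0)

    def test_identity_and_antisymmetry(self):
        assert d.log_fold_change(9, 9, 1e5, 1e5) == 0.0
        a = d.log_fold_change(3, 50, 2e5, 3e5)
        b = d.log_fold_change(50, 3, 3e5, 2e5)
        assert a == pytest.approx(-b)


class TestBHFDR:
    def test_edge_cases(self):
        assert list(d.bh_fdr([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]
        assert list(d.bh_fdr([0.03])) == [0.03]

    def test_matches_from_definition_step_up(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 10)
        got = d.bh_fdr(p)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * n / (rank_idx + 1))
            adj[i] = running
        assert got == pytest.approx(adj)


class TestCallDegs:
    def test_gene_absent_everywhere_is_ns(self, null_matrix):
        counts = null_matrix.counts.copy()
        counts.iloc[0] = 0
        m = GeneCountMatrix.from_counts(counts)
        cmp0 = d.call_degs(m, [("0h", "24h")])[0]
        assert cmp0.table.iloc[0]["call"] == "NS"

    def test_loosening_any_threshold_never_loses_degs(self, gene_stubs):
        truth = d.simulate_expression_profiles(gene_stubs[:500], 0.3, 4.0, seed=71)
        m = GeneCountMatrix.from_counts(d.simulate_count_matrix(truth, 200_000, seed=72))
        base = dict(p_max=0.01, fdr_max=0.01, lfc_min=2.0)
        n_base = sum(len(c.deg_genes) for c in d.call_degs(m, **base))
        for loose in (dict(base, p_max=0.05), dict(base, fdr_max=0.05),
                      dict(base, lfc_min=1.0)):
            n_loose = sum(len(c.deg_genes) for c in d.call_degs(m, **loose))
            assert n_loose >= n_base

    def test_cofpositive_logfc_uses_raw_counts(self, null_matrix):
        cmp0 = d.call_degs(null_matrix, [("0h", "24h")])[0]
        t = cmp0.table
        g = t[(t.x > 0) & (t.y > 0)].iloc[0]
        assert g["log2fc"] == pytest.approx(
            d.log_fold_change(g.x, g.y, cmp0.n1, cmp0.n2, pseudo=0))


class TestVenn:
    def test_disjoint_sets_add_up(self):
        comps = []
        for i, (a, b) in enumerate([("0h", "24h"), ("24h", "48h"), ("48h", "72h")]):
            table = pd.DataFrame(
                {"call": ["up"] * (i + 1) + ["NS"]},
                index=[f"g{i}_{j}" for j in range(i + 2)],
            )
            comps.append(d.DEComparison(pair=(a, b), n1=1.0, n2=1.0, table=table))
        out = d.venn_summary(comps)
        assert out["distinct_total"] == 1 + 2 + 3
        assert out["exactly_one"] == 6 and out["exactly_two"] == 0

    def test_constructed_overlaps_match_set_algebra(self):
        rng = np.random.default_rng(13)
        pools = [set(rng.choice(200, 40, replace=False)) for _ in range(3)]
        comps = []
        for (a, b), pool in zip([("0h", "24h"), ("24h", "48h"), ("48h", "72h")], pools):
            table = pd.DataFrame({"call": ["down"] * len(pool)},
                                 index=[f"g{int(i)}" for i in sorted(pool)])
            comps.append(d.DEComparison(pair=(a, b), n1=1.0, n2=1.0, table=table))
        out = d.venn_summary(comps)
        sets = [{f"g{int(i)}" for i in p} for p in pools]
        union = set().union(*sets)
        assert out["distinct_total"] == len(union)
        mult = {g: sum(g in s for s in sets) for g in union}
        assert out["exactly_two"] == sum(1 for v in mult.values() if v == 2)
        assert out["all_three"] == sum(1 for v in mult.values() if v == 3)

    def test_distinct_total_arithmetic(self):
        assert d.distinct_deg_total((10, 20, 30), 5, 2) == 51


class TestCommonReference:
    def test_reference_column_is_zero(self, null_matrix):
        ratios = d.to_common_reference(null_matrix, ref_label="0h")
        assert (ratios["0h"] == 0).all()

    def test_consecutive_logfcs_telescope_without_pseudo(self, null_matrix):
        norm = d.tmm_factors(null_matrix, ref_label="0h")
        ratios = d.to_common_reference(null_matrix, norm, "0h", pseudo=0)
        c = null_matrix.counts
        pairwise = d.log_fold_change(
            c["24h"].to_numpy(), c["48h"].to_numpy(),
            norm.effective_sizes["24h"], norm.effective_sizes["48h"], pseudo=0)
        both = (c["24h"] > 0) & (c["48h"] > 0) & (c["0h"] > 0)
        diff = (ratios["48h"] - ratios["24h"]).to_numpy()[both]
        assert diff == pytest.approx(pairwise[both.to_numpy()])

    def test_entries_match_direct_recomputation(self, null_matrix):
        norm = d.tmm_factors(null_matrix, ref_label="0h")
        ratios = d.to_common_reference(null_matrix, norm, "0h")
        c = null_matrix.counts
        for lib in ("24h", "72h"):
            want = np.log2(
                ((c[lib] + 1) / norm.effective_sizes[lib])
                / ((c["0h"] + 1) / norm.effective_sizes["0h"]))
            assert ratios[lib].to_numpy() == pytest.approx(want.to_numpy())
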