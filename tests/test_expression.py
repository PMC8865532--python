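"""Expression quantification, Fisher/FDR statistics and FRG classification."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from mycomine import expression as ex
from mycomine import synthetic_data as sd


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    p_obs = prob(a)
    return float(
        sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
            if prob(x) <= p_obs)
    )


def bh_oracle(pvals):
    """Direct step-up formula: adjusted[i] = min over j>=rank(i) of p_(j)*m/j."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_matrix(counts: dict, lengths: dict, groups: dict) -> ex.CountMatrix:
    df = pd.DataFrame(counts)
    return ex.CountMatrix(df, pd.Series(lengths), groups)


class TestQuantification:
    @pytest.mark.parametrize(
        "count,length,expected", [(100, 1000, 100.0), (0, 500, 0.0), (250, 2500, 100.0)]
    )
    def test_rpk(self, count, length, expected):
        assert ex.rpk(count, length) == expected

    def test_single_gene_tpm_is_one_million(self):
        m = make_matrix({"s1": [7]}, {0: 900}, {"s1": "A"})
        m.counts.index = ["g1"]; m.lengths.index = ["g1"]
        assert ex.tpm(m).iloc[0, 0] == pytest.approx(1e6)

    def test_equal_rpk_splits_evenly(self):
        # equal counts and equal lengths -> equal RPK -> 1e6/n each
        m = make_matrix({"s1": [5, 5, 5, 5]}, dict(enumerate([800] * 4)), {"s1": "A"})
        np.testing.assert_allclose(ex.tpm(m)["s1"], 2.5e5)

    def test_matches_spreadsheet_recomputation(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, (5, 3))
        lengths = rng.integers(200, 3000, 5)
        m = make_matrix(
            {f"s{j}": counts[:, j] for j in range(3)},
            dict(enumerate(lengths)),
            {f"s{j}": "A" for j in range(3)},
        )
        got = ex.tpm(m).to_numpy()
        # independent recomputation, cell by cell
        for j in range(3):
            rpks = [counts[i, j] / (lengths[i] / 1000) for i in range(5)]
            for i in range(5):
                want = rpks[i] / sum(rpks) * 1e6
                assert got[i, j] == pytest.approx(want, rel=1e-9)

    def test_all_zero_sample_stays_zero(self):
        m = make_matrix({"s1": [0, 0]}, {0: 100, 1: 100}, {"s1": "A"})
        assert (ex.tpm(m)["s1"] == 0).all()

    def test_tpm_columns_sum_to_one_million(self, expr_sim):
        sums = ex.tpm(expr_sim.matrix).sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-6)

    @pytest.mark.parametrize(
        "count,length,lib,expected",
        [(10, 1000, 10**7, 1.0), (0, 1000, 10**7, 0.0), (37, 1850, 2 * 10**6, 10.0)],
    )
    def test_fpkm(self, count, length, lib, expected):
        assert ex.fpkm(count, length, lib) == pytest.approx(expected)


class TestFisherExact:
    def test_symmetric_table_p_one(self):
        assert ex.fisher_exact_de(5, 95, 5, 95) == pytest.approx(1.0)

    def test_extreme_table_matches_enumeration(self):
        assert ex.fisher_exact_de(0, 10, 10, 0) == pytest.approx(
            fisher_oracle(0, 10, 10, 0), abs=1e-12
        )

    def test_random_tables_match_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 31, 4))
            if a + b == 0 or c + d == 0:
                continue
            assert ex.fisher_exact_de(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-12
            )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ex.fisher_exact_de(-1, 5, 5, 5)
        with pytest.raises(ValueError):
            ex.fisher_exact_de(0, 0, 5, 5)


class TestBhFdr:
    def test_single_p_identity(self):
        assert ex.bh_fdr([0.03]) == pytest.approx([0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(ex.bh_fdr([0.2] * 5), 0.2)

    def test_matches_direct_formula(self):
        p = [0.01, 0.02, 0.04, 0.9]
        np.testing.assert_allclose(ex.bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_random_vectors_match_formula_and_never_decrease(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(0, 1, int(rng.integers(1, 60)))
            adj = ex.bh_fdr(p)
            np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
            assert (adj >= p - 1e-15).all() and (adj <= 1).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0, 1, 30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(ex.bh_fdr(p)[perm], ex.bh_fdr(p[perm]))


class TestCallDeg:
    def _strong_matrix(self):
        """One 10-fold induced gene over deep flat background."""
        rng = np.random.default_rng(4)
        n = 200
        base = rng.integers(500, 1500, n)
        counts = {}
        groups = {}
        for g, k in (("A", 3), ("B", 3)):
            for r in range(k):
                sid = f"{g}{r}"
                col = rng.poisson(base)
                if g == "A":
                    col[0] = rng.poisson(base[0] * 10)
                counts[sid] = col
                groups[sid] = g
        return make_matrix(counts, dict(enumerate([1000] * n)), groups)

    def test_planted_tenfold_gene_called_up(self):
        res = ex.call_deg(self._strong_matrix(), "A", "B")
        assert res.iloc[0]["call"] == "up"
        assert res.iloc[0]["fold_change"] > 3

    def test_tpm_floor_blocks_low_expression(self):
        rng = np.random.default_rng(5)
        n = 50
        counts, groups = {}, {}
        base = rng.integers(5000, 8000, n)
        for g in ("A", "B"):
            for r in range(2):
                sid = f"{g}{r}"
                col = rng.poisson(base)
                col[0] = 20 if g == "A" else 0   # strong ratio, tiny TPM
                counts[sid] = col
                groups[sid] = g
        lengths = dict(enumerate([1000] * n))
        lengths[0] = 200_000  # drives gene 0 TPM below the floor
        m = make_matrix(counts, lengths, groups)
        res = ex.call_deg(m, "A", "B")
        assert max(res.iloc[0]["mean_tpm_a"], res.iloc[0]["mean_tpm_b"]) <= 0.5
        assert res.iloc[0]["call"] == "ns"

    def test_up_down_symmetry(self, expr_sim):
        ab = ex.call_deg(expr_sim.matrix, "FB", "mono_mycelium")
        ba = ex.call_deg(expr_sim.matrix, "mono_mycelium", "FB")
        assert set(ab.index[ab["call"] == "up"]) == set(ba.index[ba["call"] == "down"])
        assert set(ab.index[ab["call"] == "down"]) == set(ba.index[ba["call"] == "up"])

    def test_planted_recovery_sensitivity_and_false_calls(self, expr_sim):
        res = ex.call_deg(expr_sim.matrix, "FB", "mono_mycelium")
        up = set(res.index[res["call"] == "up"])
        sensitivity = len(up & expr_sim.up_genes) / len(expr_sim.up_genes)
        false_rate = len(up - expr_sim.up_genes) / (
            expr_sim.spec.n_genes - len(expr_sim.up_genes)
        )
        assert sensitivity >= 0.80
        assert false_rate <= 0.05

    def test_zero_denominator_maps_to_infinite_fold(self):
        counts = {"a1": [100, 50], "b1": [0, 50]}
        m = make_matrix(counts, {0: 1000, 1: 1000}, {"a1": "A", "b1": "B"})
        res = ex.call_deg(m, "A", "B")
        assert np.isinf(res.iloc[0]["fold_change"])


class TestFrgClassification:
    def _contrast(self, genes, up):
        return pd.DataFrame(
            {"call": ["up" if g in up else "ns" for g in genes]}, index=genes
        )

    def test_conjunction_rule(self):
        genes = [f"g{i}" for i in range(6)]
        mono = self._contrast(genes, {"g0", "g1", "g2"})
        di = self._contrast(genes, {"g1", "g2", "g3"})
        assert ex.classify_frg(mono, di) == {"g1", "g2"}
        assert ex.classify_frg(mono, di, require_both=False) == {"g0", "g1", "g2", "g3"}

    def test_thirty_planted_both_contrast_genes(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(500)]
        both = set(rng.choice(genes, 30, replace=False))
        only_mono = set(rng.choice(sorted(set(genes) - both), 40, replace=False))
        mono = self._contrast(genes, both | only_mono)
        di = self._contrast(genes, both)
        assert ex.classify_frg(mono, di) == both

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ex.classify_frg(
                self._contrast(["a"], set()), self._contrast(["b"], set())
            )


class TestVennClasses:
    def test_precedence_and_exhaustive_partition(self):
        hits = pd.DataFrame(
            {
                "query": ["g1", "g1", "g2", "g3"],
                "subject": ["fbig1", "fbdg1", "fbdg2", "ccx1"],
                "evalue": [1e-10, 1e-10, 1e-8, 1e-9],
            }
        )
        frg = {"g1", "g2", "g3", "g4"}
        out = ex.venn_classes(frg, hits, {"fbig1"}, {"fbdg1", "fbdg2"})
        assert out["fbig_ortholog"] == {"g1"}     # FBIG wins over FBDG
        assert out["fbdg_ortholog"] == {"g2"}
        assert out["other_ortholog"] == {"g3"}
        assert out["species_specific"] == {"g4"}
        got = set().union(*out.values())
        assert got == frg and sum(len(v) for v in out.values()) == len(frg)

    def test_weak_hits_above_cutoff_ignored(self):
        hits = pd.DataFrame(
            {"query": ["g1"], "subject": ["fbig1"], "evalue": [1e-3]}
        )
        out = ex.venn_classes({"g1"}, hits, {"fbig1"}, set())
        assert out["species_specific"] == {"g1"}

    def test_planted_partition_recovered(self):
        rng = np.random.default_rng(7)
        labels = ["fbig_ortholog", "fbdg_ortholog", "other_ortholog",
                  "species_specific"]
        genes = [f"g{i:04d}" for i in range(1000)]
        planted = {g: labels[int(rng.integers(0, 4))] for g in genes}
        fbig = {f"FBIG{i}" for i in range(50)}
        fbdg = {f"FBDG{i}" for i in range(300)}
        rows = []
        for g, lab in planted.items():
            if lab == "fbig_ortholog":
                rows.append((g, f"FBIG{rng.integers(0, 50)}", 1e-20))
            elif lab == "fbdg_ortholog":
                rows.append((g, f"FBDG{rng.integers(0, 300)}", 1e-20))
            elif lab == "other_ortholog":
                rows.append((g, f"CC{rng.integers(0, 999)}", 1e-20))
        hits = pd.DataFrame(rows, columns=["query", "subject", "evalue"])
        out = ex.venn_classes(set(genes), hits, fbig, fbdg)
        for lab in labels:
            assert out[lab] == {g for g, l in planted.items() if l == lab}


class TestFbigCoverage:
    def test_reference_set_arithmetic(self):
        fbig = {f"cc{i}" for i in range(666)}
        hits = pd.DataFrame(
            {
                "query": [f"q{i}" for i in range(254)],
                "subject": [f"cc{i}" for i in range(254)],
                "evalue": [1e-20] * 254,
            }
        )
        assert ex.fbig_coverage(hits, fbig) == (254, 38.1)

    def test_zero_hits(self):
        hits = pd.DataFrame({"query": [], "subject": [], "evalue": []})
        assert ex.fbig_coverage(hits, {"a", "b"}) == (0, 0.0)

    def test_planted_fraction(self):
        fbig = {f"cc{i}" for i in range(500)}
        hits = pd.DataFrame(
            {
                "query": ["q"] * 123,
                "subject": [f"cc{i}" for i in range(123)],
                "evalue": [1e-9] * 123,
            }
        )
        assert ex.fbig_coverage(hits, fbig) == (123, 24.6)
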