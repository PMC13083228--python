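"""Matreotype derivation, composition tests, and enrichment statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ecmclock as ec
from ecmclock.matreotype import percentile_count_threshold


def _assoc_from_counts(counts_by_chapter, n_phenotypes=12):
    """Build an association table realizing given per-chapter counts."""
    rows = []
    for chapter, counts in counts_by_chapter.items():
        for j in range(n_phenotypes):  # ensure chapter retention
            rows.append({"protein_id": "__filler__", "phenotype_id": f"{chapter}_f{j}",
                         "chapter": chapter, "p_value": 0.5})
        for protein, k in counts.items():
            for j in range(k):
                rows.append({"protein_id": protein, "phenotype_id": f"{chapter}_f{j}",
                             "chapter": chapter, "p_value": 1e-8})
    return ec.validate_phenotype_associations(pd.DataFrame(rows))


@pytest.fixture
def abcd_annotation():
    return ec.make_annotation(
        ["A", "B", "C", "D", "N1", "N2", "__filler__"],
        ["collagens", "proteoglycans", "secreted_factors", "ecm_regulators",
         "none", "none", "none"],
    )


class TestDiseaseMatreotype:
    def test_worked_two_chapter_example(self, abcd_annotation):
        assoc = _assoc_from_counts({
            "CH01": {"A": 5, "B": 3, "C": 1},
            "CH02": {"A": 4, "B": 4, "D": 2},
        })
        mt = ec.derive_disease_matreotype(assoc, abcd_annotation, min_phenotypes=10)
        assert mt.parameters["thresholds"] == {"CH01": 3, "CH02": 4}
        assert set(mt.proteins) == {"A", "B"}
        assert mt.provenance == "disease"

    def test_all_counts_equal_all_retained(self, abcd_annotation):
        assoc = _assoc_from_counts({"CH01": {"A": 3, "B": 3, "C": 3}})
        mt = ec.derive_disease_matreotype(assoc, abcd_annotation, min_phenotypes=10)
        assert set(mt.proteins) == {"A", "B", "C"}

    def test_boundary_ties_retain_over_half(self, abcd_annotation):
        """Ties at the percentile rank push retention above 50%."""
        assoc = _assoc_from_counts({"CH01": {"A": 5, "B": 2, "C": 2, "D": 2}})
        mt = ec.derive_disease_matreotype(assoc, abcd_annotation, min_phenotypes=10)
        assert len(mt.proteins) / 4 > 0.5

    def test_chapter_retention_rule(self, abcd_annotation):
        assoc = _assoc_from_counts({"CH01": {"A": 5, "B": 3}},
                                   n_phenotypes=5)  # below min_phenotypes
        with pytest.raises(ValueError, match="no chapters retained"):
            ec.derive_disease_matreotype(assoc, abcd_annotation, min_phenotypes=10)

    def test_monotone_in_added_associations(self, abcd_annotation):
        base = {"CH01": {"A": 5, "B": 3, "C": 1}}
        mt0 = ec.derive_disease_matreotype(_assoc_from_counts(base), abcd_annotation)
        assert "C" not in mt0.proteins
        grown = {"CH01": {"A": 5, "B": 3, "C": 6}}
        mt1 = ec.derive_disease_matreotype(_assoc_from_counts(grown), abcd_annotation)
        assert "C" in mt1.proteins  # adding associations for C never removes C

    def test_percentile_rank_definition(self):
        counts = pd.Series({"A": 5, "B": 3, "C": 1})
        assert percentile_count_threshold(counts, 0.5) == 3
        assert percentile_count_threshold(pd.Series({"A": 7}), 0.5) == 7


class TestChapterEnrichment:
    def test_ratio_arithmetic(self, abcd_annotation):
        # ECM 2/4 associated vs non-ECM 1/3 associated in one chapter
        rows = [
            {"protein_id": p, "phenotype_id": "CH01_x", "chapter": "CH01",
             "p_value": 1e-8} for p in ["A", "B", "N1"]
        ]
        assoc = ec.validate_phenotype_associations(pd.DataFrame(rows))
        out = ec.chapter_ecm_enrichment(assoc, abcd_annotation)
        assert out.loc["CH01", "log2_enrichment"] == pytest.approx(
            math.log2((2 / 4) / (1 / 3)))

    def test_equal_fractions_zero(self):
        ann = ec.make_annotation(["E1", "E2", "N1", "N2"],
                                 ["collagens", "collagens", "none", "none"])
        rows = [{"protein_id": p, "phenotype_id": "CH01_x", "chapter": "CH01",
                 "p_value": 1e-8} for p in ["E1", "N1"]]
        assoc = ec.validate_phenotype_associations(pd.DataFrame(rows))
        out = ec.chapter_ecm_enrichment(assoc, ann)
        assert out.loc["CH01", "log2_enrichment"] == pytest.approx(0.0)

    def test_fisher_matches_enumeration_oracle(self):
        """Two-sided Fisher p equals the hypergeometric tail enumeration."""
        def fisher_oracle(a, b, c, d):
            row1, col1, n = a + b, a + c, a + b + c + d
            p_obs = stats.hypergeom.pmf(a, n, row1, col1)
            total = 0.0
            for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
                px = stats.hypergeom.pmf(x, n, row1, col1)
                if px <= p_obs * (1 + 1e-9):
                    total += px
            return total

        for a, b, c, d in itertools.product(range(4), repeat=4):
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            expected = fisher_oracle(a, b, c, d)
            got = stats.fisher_exact([[a, b], [c, d]])[1]
            assert got == pytest.approx(expected, abs=1e-9), (a, b, c, d)


class TestCompositionTest:
    @staticmethod
    def _background(n_core=50, n_assoc=50):
        ids = [f"C{i}" for i in range(n_core)] + [f"A{i}" for i in range(n_assoc)]
        cats = ["collagens"] * n_core + ["secreted_factors"] * n_assoc
        return ec.make_annotation(ids, cats)

    def test_worked_residual_example(self):
        """O=[10,30] at p=[.5,.5]: chi2=10, residuals ∓10/sqrt(10)."""
        ann = self._background()
        signature = ec.Matreotype("sig", {f"C{i}" for i in range(10)}
                                  | {f"A{i}" for i in range(30)}, "custom")
        res = ec.composition_test(signature, ann, grouping="division", seed=1)
        assert res.statistic == pytest.approx(10.0)
        assert res.table.loc["core", "std_residual"] == pytest.approx(-3.1623, abs=1e-4)
        assert res.table.loc["associated", "std_residual"] == pytest.approx(3.1623, abs=1e-4)
        assert np.allclose(res.table["expected"], [20, 20])
        assert not res.monte_carlo  # n=40, all E=20

    def test_matching_proportions_null(self):
        ann = self._background()
        signature = ec.Matreotype("sig", {f"C{i}" for i in range(20)}
                                  | {f"A{i}" for i in range(20)}, "custom")
        res = ec.composition_test(signature, ann, grouping="division", seed=1)
        assert np.allclose(res.table["std_residual"], 0.0)
        assert res.p_value > 0.95

    def test_monte_carlo_matches_exact_enumeration(self):
        """2-category toy with n=20: MC p within the 99% binomial envelope
        of the exact multinomial tail."""
        ann = self._background()
        signature = ec.Matreotype("sig", {f"C{i}" for i in range(15)}
                                  | {f"A{i}" for i in range(5)}, "custom")
        res = ec.composition_test(signature, ann, grouping="division", seed=7,
                                  n_monte_carlo=2000)
        assert res.monte_carlo
        # exact tail: sum over k of Binom(20, 0.5) where chi2(k) >= chi2(15)
        n, p = 20, 0.5
        obs_stat = res.statistic
        exact = sum(
            stats.binom.pmf(k, n, p)
            for k in range(n + 1)
            if (k - 10) ** 2 / 10 + ((n - k) - 10) ** 2 / 10 >= obs_stat - 1e-12
        )
        half_width = 2.576 * math.sqrt(exact * (1 - exact) / 2000)
        assert abs(res.p_value - exact) <= half_width + 1 / 2001

    def test_residual_sum_identity(self):
        ann = self._background(30, 70)
        rng = np.random.default_rng(3)
        chosen = set(rng.choice(ann.index, 45, replace=False))
        res = ec.composition_test(ec.Matreotype("s", chosen, "custom"), ann, seed=0)
        p = res.table["proportion"].to_numpy()
        weighted = (res.table["std_residual"] * np.sqrt(res.table["expected"] * (1 - p))).sum()
        assert weighted == pytest.approx(0.0, abs=1e-9)
        assert res.table["observed"].sum() == pytest.approx(res.table["expected"].sum())

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ec.composition_test(ec.Matreotype("s", set(), "custom"), self._background())

    def test_non_matrisome_signature_rejected(self):
        ann = ec.make_annotation(["E", "N"], ["collagens", "none"])
        with pytest.raises(ValueError, match="outside matrisome"):
            ec.composition_test(ec.Matreotype("s", {"N"}, "custom"), ann)


class TestCategoryEnrichment:
    def test_whole_background_p_one(self):
        ann = ec.make_annotation(["A", "B", "C"],
                                 ["collagens", "collagens", "secreted_factors"])
        out = ec.category_enrichment(ec.Matreotype("s", {"A", "B", "C"}, "custom"), ann)
        assert (out["p_value"] == 1.0).all()

    def test_bh_matches_hand_computation(self):
        ann = ec.make_annotation(
            [f"P{i}" for i in range(12)],
            ["collagens", "ecm_glycoproteins", "proteoglycans",
             "secreted_factors", "ecm_regulators", "ecm_affiliated"] * 2)
        out = ec.category_enrichment(
            ec.Matreotype("s", {"P0", "P6", "P1"}, "custom"), ann)
        p = out["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        hand = np.empty(m)
        running = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            running = min(running, p[idx] * m / rank)
            hand[idx] = running
        assert np.allclose(out["q_value"].to_numpy(), hand)


class TestDiseaseBurden:
    def test_exact_small_sample(self):
        """counts ECM=[3,4] vs non=[1,2]: exact rank-sum p = 1/3."""
        ann = ec.make_annotation(["E1", "E2", "N1", "N2"],
                                 ["collagens", "proteoglycans", "none", "none"])
        rows = []
        for protein, k in [("E1", 3), ("E2", 4), ("N1", 1), ("N2", 2)]:
            for j in range(k):
                rows.append({"protein_id": protein, "phenotype_id": f"ph{j}",
                             "chapter": "CH01", "p_value": 1e-8})
        assoc = ec.validate_phenotype_associations(pd.DataFrame(rows))
        out = ec.disease_burden_comparison(assoc, ann)
        assert out["overall"]["p_value"] == pytest.approx(1 / 3)
        assert out["overall"]["mean_ecm"] == pytest.approx(3.5)

    def test_planted_enrichment_detected(self):
        cfg = ec.SimulationConfig(seed=4, n_proteins=400, matrisome_fraction=0.5,
                                  n_linear_aging=0, n_ushape=0)
        ann = ec.generate_annotation(cfg)
        assoc = ec.generate_phenotype_associations(ann, ecm_enrichment=2.0, seed=11)
        out = ec.disease_burden_comparison(assoc, ann)
        assert out["overall"]["mean_ecm"] > out["overall"]["mean_non_ecm"]
        assert out["overall"]["p_value"] < 0.05


class TestPrioritizeTargets:
    @staticmethod
    def _mr(rows):
        return pd.DataFrame(rows, columns=["protein_id", "phenotype", "domain",
                                           "method", "p_value"])

    def test_domain_rule(self):
        rows = [("P1", f"ph{i}", f"d{i % 2}", "ivw", 0.01) for i in range(5)]
        out = ec.prioritize_targets(self._mr(rows))
        assert out.empty  # 5 phenotypes but only 2 domains

    def test_phenotype_rule(self):
        rows = [("P1", f"ph{i}", f"d{i}", "ivw", 0.01) for i in range(4)]
        out = ec.prioritize_targets(self._mr(rows))
        assert out.empty  # 4 domains but only 4 phenotypes

    def test_hand_ranking(self):
        rows = []
        spec = {"A": (6, 4), "B": (5, 3), "C": (8, 3), "D": (10, 2), "E": (3, 3)}
        for protein, (n_ph, n_dom) in spec.items():
            for i in range(n_ph):
                rows.append((protein, f"ph{i}", f"d{i % n_dom}", "wald_ratio", 0.01))
        rows.append(("F", "phX", "dX", "ivw", 0.2))       # not significant
        rows.append(("G", "phX", "dX", "egger", 0.001))   # wrong method
        out = ec.prioritize_targets(self._mr(rows))
        assert list(out.index) == ["A", "C", "B"]
        assert out.loc["A", "n_domains"] == 4
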