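"""Contingency tables, Cohen's kappa, banding, Venn summaries, disagreements."""

from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from cypmatch import datafiles
from cypmatch.agreement import (
    ContingencyTable2x2,
    band,
    build_contingency,
    cohens_kappa,
    disagreement_table,
    jointly_assessed,
    reconstruct_contingency,
    venn_summary,
)
from cypmatch.classification import ClassificationMatrix
from cypmatch.substrate_resources import TriState
from cypmatch.synthetic import plant_matrix


def exact_kappa(a: int, b: int, c: int, d: int) -> Fraction | None:
    """Independent oracle: Cohen's kappa in exact rational arithmetic."""
    n = a + b + c + d
    p_o = Fraction(a + d, n)
    p_e = Fraction((a + b) * (a + c) + (c + d) * (b + d), n * n)
    if p_e == 1:
        return None
    return (p_o - p_e) / (1 - p_e)


class TestCohensKappa:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((9, 0, 3, 88), 0.84),
            ((5, 0, 0, 5), 1.0),
            ((1, 1, 1, 1), 0.0),
        ],
    )
    def test_worked_examples(self, cells, expected):
        result = cohens_kappa(ContingencyTable2x2(*cells))
        assert result.kappa_rounded == expected

    def test_undefined_when_expected_agreement_is_one(self):
        result = cohens_kappa(ContingencyTable2x2(0, 0, 0, 12))
        assert result.kappa is None
        assert not result.defined
        assert result.p_expected == 1.0

    def test_all_both_substrate_also_undefined(self):
        assert cohens_kappa(ContingencyTable2x2(7, 0, 0, 0)).kappa is None

    def test_exhaustive_oracle_equivalence_small_n(self):
        """Matches the exact-rational oracle for every 2x2 table with n <= 30."""
        checked = 0
        for n in range(1, 31):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        expected = exact_kappa(a, b, c, d)
                        got = cohens_kappa(ContingencyTable2x2(a, b, c, d)).kappa
                        if expected is None:
                            assert got is None
                        else:
                            assert got == pytest.approx(float(expected), abs=1e-12)
                        checked += 1
        assert checked == sum((n + 3) * (n + 2) * (n + 1) // 6 for n in range(1, 31))

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    def test_symmetries_and_bounds(self, cells):
        a, b, c, d = cells
        base = cohens_kappa(ContingencyTable2x2(a, b, c, d))
        swapped_methods = cohens_kappa(ContingencyTable2x2(a, c, b, d))
        swapped_labels = cohens_kappa(ContingencyTable2x2(d, c, b, a))
        if base.kappa is None:
            assert swapped_methods.kappa is None and swapped_labels.kappa is None
            return
        assert swapped_methods.kappa == pytest.approx(base.kappa)
        assert swapped_labels.kappa == pytest.approx(base.kappa)
        assert base.kappa <= base.p_observed + 1e-12
        assert (base.kappa == 1.0) == (b == 0 and c == 0)


class TestBand:
    @pytest.mark.parametrize(
        "kappa, label",
        [
            (-0.5, "poor"),
            (0.0, "slight"),
            (0.19, "slight"),
            (0.20, "fair"),
            (0.40, "fair"),
            (0.41, "moderate"),
            (0.43, "moderate"),
            (0.48, "moderate"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.71, "substantial"),
            (0.80, "substantial"),
            (0.81, "almost perfect"),
            (0.84, "almost perfect"),
            (0.90, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_boundaries(self, kappa, label):
        assert band(kappa) == label

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            band(1.5)


class TestJointSetAndContingency:
    def _mixed_matrix(self) -> ClassificationMatrix:
        matrix = ClassificationMatrix(drugs=["a", "b", "c", "d"])
        states_m = {
            "a": TriState.SUBSTRATE,
            "b": TriState.NON_SUBSTRATE,
            "c": TriState.SUBSTRATE,
            "d": TriState.NOT_ASSESSED,
        }
        states_r = {
            "a": TriState.SUBSTRATE,
            "b": TriState.SUBSTRATE,
            "c": TriState.NOT_ASSESSED,
            "d": TriState.SUBSTRATE,
        }
        matrix.add_method("M", {(k, "CYP2D6"): v for k, v in states_m.items()})
        matrix.add_method("R", {(k, "CYP2D6"): v for k, v in states_r.items()})
        return matrix

    def test_joint_set_excludes_not_assessed(self):
        assert jointly_assessed(self._mixed_matrix(), "M", "R") == {"a", "b"}

    def test_method_with_itself_gives_own_assessed_set(self):
        matrix = self._mixed_matrix()
        assert jointly_assessed(matrix, "M", "M") == matrix.assessed_drugs("M")

    def test_unknown_method_is_error(self):
        with pytest.raises(KeyError):
            jointly_assessed(self._mixed_matrix(), "M", "NOPE")

    def test_contingency_counts_joint_set_only(self):
        table = build_contingency(self._mixed_matrix(), "M", "R", "CYP2D6")
        assert (table.a, table.b, table.c, table.d) == (1, 0, 1, 0)

    def test_identical_vectors_have_no_off_diagonal(self):
        matrix = plant_matrix(4, 0, 0, 6, seed=3)
        table = build_contingency(matrix, "METHOD_A", "METHOD_B", "CYP2D6")
        assert (table.b, table.c) == (0, 0)

    def test_empty_joint_set_is_error(self):
        matrix = ClassificationMatrix(drugs=["a", "b"])
        matrix.add_method("M", {("a", "CYP2D6"): TriState.SUBSTRATE})
        matrix.add_method("R", {("b", "CYP2D6"): TriState.SUBSTRATE})
        with pytest.raises(ValueError, match="jointly"):
            build_contingency(matrix, "M", "R", "CYP2D6")

    @settings(max_examples=50, derandomize=True)
    @given(
        st.tuples(*[st.integers(0, 20)] * 4).filter(lambda t: sum(t) > 0),
        st.integers(0, 2**31 - 1),
    )
    def test_planted_matrix_recovers_cells_exactly(self, cells, seed):
        matrix = plant_matrix(*cells, seed=seed)
        table = build_contingency(matrix, "METHOD_A", "METHOD_B", "CYP2D6")
        assert (table.a, table.b, table.c, table.d) == cells

    def test_marginal_identities(self):
        matrix = plant_matrix(5, 2, 3, 7, seed=1)
        table = build_contingency(matrix, "METHOD_A", "METHOD_B", "CYP2D6")
        assert table.a + table.b == 7  # method A substrates within joint set
        assert table.a + table.c == 8  # method B substrates within joint set


class TestReconstruction:
    def test_marginals_plus_one_cell_determine_table(self):
        table = reconstruct_contingency(100, marginal_a=9, marginal_b=12, a_only=0)
        assert (table.a, table.b, table.c, table.d) == (9, 0, 3, 88)

    def test_published_tables_reproduce_published_kappas(self):
        expected = {
            ("drugbank", "CYP2D6"): (0.84, "almost perfect"),
            ("drugbank", "CYP2C19"): (0.71, "substantial"),
            ("drugbank", "CYP2C9"): (0.48, "moderate"),
            ("fda", "CYP2D6"): (0.43, "moderate"),
            ("fda", "CYP2C19"): (0.43, "moderate"),
            ("flockhart", "CYP2C9"): (0.20, "fair"),
        }
        tables = datafiles.reconstructed_tables()
        for key, (kappa, label) in expected.items():
            result = cohens_kappa(tables[key])
            assert result.kappa_rounded == kappa, key
            assert result.band == label, key
        # FDA/CYP2C9: neither method found any substrate -> kappa undefined
        assert cohens_kappa(tables[("fda", "CYP2C9")]).kappa is None


class TestVenn:
    def test_region_counts_match_brute_force(self):
        matrix = ClassificationMatrix(drugs=[f"d{i}" for i in range(20)])
        sets = {
            "M1": {f"d{i}" for i in range(0, 12)},
            "M2": {f"d{i}" for i in range(6, 18)},
            "M3": {f"d{i}" for i in range(4, 8)},
        }
        for method, assessed in sets.items():
            matrix.add_method(
                method,
                {
                    (d, "CYP2D6"): (
                        TriState.NON_SUBSTRATE if d in assessed else TriState.NOT_ASSESSED
                    )
                    for d in matrix.drugs
                },
            )
        summary = venn_summary(matrix)
        assert summary.intersection_size("M1", "M2") == len(sets["M1"] & sets["M2"])
        assert summary.intersection_size("M1", "M2", "M3") == len(
            sets["M1"] & sets["M2"] & sets["M3"]
        )
        regions = summary.region_counts()
        assert sum(regions.values()) == len(sets["M1"] | sets["M2"] | sets["M3"])

    def test_planted_assessment_counts_reproduced(self):
        """Assessed-set sizes like the published study layout reproduce exactly."""
        n_total = 895
        drugs = [f"d{i}" for i in range(n_total)]
        manual = set(drugs[:109])
        drugbank = set(drugs[:100]) | set(drugs[109 : 109 + 696])
        fda = set(drugs[:12]) | set(drugs[150 : 150 + 97])
        flockhart = set(drugs[:26]) | set(drugs[300 : 300 + 141])
        matrix = ClassificationMatrix(drugs=list(drugs))
        for method, assessed in {
            "MANUAL": manual,
            "DRUGBANK": drugbank,
            "FDA": fda,
            "FLOCKHART": flockhart,
        }.items():
            matrix.add_method(
                method,
                {
                    (d, "CYP2D6"): TriState.NON_SUBSTRATE
                    for d in drugs
                    if d in assessed
                },
            )
        summary = venn_summary(matrix)
        assert {m: len(s) for m, s in summary.assessed.items()} == {
            "MANUAL": 109,
            "DRUGBANK": 796,
            "FDA": 109,
            "FLOCKHART": 167,
        }
        assert summary.intersection_size("MANUAL", "DRUGBANK") == 100
        assert summary.intersection_size("MANUAL", "FDA") == 12
        assert summary.intersection_size("MANUAL", "FLOCKHART") == 26

    def test_single_method(self):
        matrix = ClassificationMatrix(drugs=["a"])
        matrix.add_method("M", {("a", "CYP2D6"): TriState.SUBSTRATE})
        summary = venn_summary(matrix)
        assert summary.region_counts() == {"M": 1}


class TestDisagreementTable:
    def test_rows_sorted_by_entry_count_with_percent(self):
        matrix = plant_matrix(1, 2, 1, 3, seed=5, enzyme="CYP2C9")
        table = build_contingency(matrix, "METHOD_A", "METHOD_B", "CYP2C9")
        counts = {drug: (i + 1) * 10 for i, drug in enumerate(matrix.drugs)}
        rows = disagreement_table(
            matrix, "METHOD_A", "METHOD_B", "CYP2C9", counts, total_entries=1000
        )
        assert len(rows) == table.b + table.c
        assert [r.entry_count for r in rows] == sorted(
            (r.entry_count for r in rows), reverse=True
        )
        top = rows[0]
        assert top.entry_percent == round(100 * top.entry_count / 1000, 1)

    def test_identical_classifications_empty(self):
        matrix = plant_matrix(3, 0, 0, 4, seed=2)
        rows = disagreement_table(
            matrix, "METHOD_A", "METHOD_B", "CYP2D6",
            {d: 1 for d in matrix.drugs}, total_entries=7,
        )
        assert rows == []

    def test_missing_entry_count_is_error(self):
        matrix = plant_matrix(0, 1, 0, 1, seed=2)
        with pytest.raises(ValueError, match="entry count"):
            disagreement_table(
                matrix, "METHOD_A", "METHOD_B", "CYP2D6", {}, total_entries=10
            )

    def test_transcribed_top_disagreement_is_high_frequency_analgesic(self):
        """The most frequent CYP2C9 disagreement covers 4.0% of all entries."""
        disagreements = datafiles.load_disagreements()
        sub = disagreements[
            (disagreements["enzyme"] == "CYP2C9")
            & (disagreements["manual"] != disagreements["drugbank"])
            & (disagreements["drugbank"] != "NA")
            & (disagreements["manual"] != "NA")
        ].sort_values("entries", ascending=False)
        top = sub.iloc[0]
        assert top["drug"] == "acetylsalicylic acid"
        assert top["entries"] == 952
        assert round(100 * top["entries"] / 23878, 1) == 4.0
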