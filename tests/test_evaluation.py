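"""Fold-error metric, within-k percentages, class summaries, exports."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xenodose.evaluation import (
    EvaluationRow,
    bootstrap_ci,
    evaluate,
    export_scatter,
    fold_error,
    format_pct,
    pct_within,
    summarize,
)
from xenodose.records import DrugRecord, ModalityClass
from xenodose.scaling import (
    HUMAN,
    MOUSE,
    DoseDomainError,
    DoseSpec,
    Method,
    UnitBasis,
)

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def make_row(fe, method=Method.BSA, modality=ModalityClass.SM_PO, name="d"):
    return EvaluationRow(
        drug_name=name,
        method=method,
        predicted_dose=fe,
        clinical_dose=1.0,
        fold_error=fe,
        within_2x=fe <= 2,
        within_3x=fe <= 3,
        modality_class=modality,
    )


def make_record(name, modality, mouse_mgkg, clinical_mgkg, mw=None):
    return DrugRecord(
        drug_name=name,
        modality_class=modality,
        molecular_weight_kda=mw,
        nonclinical_dose=DoseSpec(mouse_mgkg, UnitBasis.MG_PER_KG, MOUSE),
        clinical_dose_low=DoseSpec(clinical_mgkg, UnitBasis.MG_PER_KG, HUMAN),
    )


class TestFoldError:
    @pytest.mark.parametrize(
        "pred, clin, expected", [(9, 3, 3), (3, 9, 3), (5, 5, 1)]
    )
    def test_examples(self, pred, clin, expected):
        assert fold_error(pred, clin) == pytest.approx(expected)

    @given(positive, positive)
    def test_symmetry_and_floor(self, a, b):
        fe = fold_error(a, b)
        assert fe == pytest.approx(fold_error(b, a))
        assert fe >= 1.0

    @given(positive, positive, st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance(self, a, b, c):
        assert fold_error(c * a, c * b) == pytest.approx(fold_error(a, b), rel=1e-9)

    @pytest.mark.parametrize("pred, clin", [(0, 1), (1, 0), (-2, 1), (1, -2)])
    def test_nonpositive_rejected(self, pred, clin):
        with pytest.raises(DoseDomainError):
            fold_error(pred, clin)


class TestPctWithin:
    def test_published_fraction_pairings(self):
        rows = [make_row(2.0)] * 5 + [make_row(10.0)] * 25
        assert format_pct(pct_within(rows, 3)) == "16.7"

    def test_boundary_is_inclusive(self):
        assert pct_within([make_row(3.0)], 3) == 100.0

    def test_all_and_none(self):
        assert pct_within([make_row(1.5)] * 4, 2) == 100.0
        assert pct_within([make_row(9.0)] * 4, 2) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pct_within([], 3)

    @given(
        st.lists(st.floats(min_value=1, max_value=100), min_size=1, max_size=50),
        st.floats(min_value=1, max_value=10),
        st.floats(min_value=0, max_value=10),
    )
    def test_monotone_in_k(self, folds, k, dk):
        rows = [make_row(f) for f in folds]
        assert pct_within(rows, k + dk) >= pct_within(rows, k)

    def test_naive_loop_oracle_equivalence(self):
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            folds = 10 ** rng.uniform(0, 2, size=rng.integers(1, 40))
            k = float(rng.uniform(1, 10))
            naive = 0
            for f in folds:
                if f <= k:
                    naive += 1
            expected = 100.0 * naive / len(folds)
            assert pct_within([make_row(f) for f in folds], k) == pytest.approx(
                expected
            )


class TestEvaluate:
    def test_bsa_exact_prediction(self):
        rows = evaluate(
            [make_record("a", ModalityClass.SM_PO, 37.0, 3.0)], Method.BSA
        )
        assert rows[0].fold_error == pytest.approx(1.0)
        assert rows[0].within_2x and rows[0].within_3x

    def test_bw_exact_prediction(self):
        rows = evaluate(
            [make_record("b", ModalityClass.MAB, 2.0, 2.0, mw=150.0)], Method.BW
        )
        assert rows[0].fold_error == pytest.approx(1.0)

    def test_bsa_overprediction(self):
        rows = evaluate(
            [make_record("c", ModalityClass.SM_PO, 10.0, 0.09)], Method.BSA
        )
        assert rows[0].fold_error == pytest.approx((10 * 3 / 37) / 0.09)
        assert not rows[0].within_3x

    def test_auto_uses_mw_cutoff(self):
        records = [
            make_record("small", ModalityClass.SM_PO, 10.0, 1.0, mw=0.5),
            make_record("big", ModalityClass.MAB, 10.0, 1.0, mw=150.0),
            make_record("noMW", ModalityClass.SM_PO, 10.0, 1.0),
        ]
        rows = evaluate(records, "auto")
        assert [r.method for r in rows] == [Method.BSA, Method.BW, Method.BSA]

    def test_bw_rows_carry_no_conversion_constant(self):
        # BW fold errors equal fold_error(mouse mg/kg, clinical mg/kg) directly
        rng = np.random.default_rng(7)
        records = [
            make_record(f"d{i}", ModalityClass.MAB,
                        float(10 ** rng.uniform(-1, 2)),
                        float(10 ** rng.uniform(-1, 2)), mw=150.0)
            for i in range(20)
        ]
        rows = evaluate(records, Method.BW)
        for rec, row in zip(records, rows):
            assert row.fold_error == pytest.approx(
                fold_error(rec.nonclinical_dose.amount,
                           rec.clinical_dose_low.amount)
            )

    def test_error_carries_drug_name(self):
        with pytest.raises(DoseDomainError, match="zeroclin"):
            evaluate([make_record("zeroclin", ModalityClass.SM_PO, 10.0, 0.0)])


class TestSummarize:
    def test_single_group_matches_pct_within(self):
        rows = [make_row(f) for f in (1.0, 2.5, 9.0)]
        [summary] = summarize(rows, [("All", "all", lambda c: True, False)])
        assert summary.pct_within_2x_bsa == pytest.approx(pct_within(rows, 2))
        assert summary.pct_within_3x_bsa == pytest.approx(pct_within(rows, 3))

    def test_standard_grouping_layout(self):
        rows = (
            [make_row(1.0, modality=ModalityClass.SM_IV)] * 2
            + [make_row(9.0, modality=ModalityClass.SM_PO)] * 1
            + [make_row(1.0, Method.BW, ModalityClass.MAB)] * 3
            + [make_row(1.0, Method.BSA, ModalityClass.MAB)] * 3
        )
        summaries = {s.subclass_label: s for s in summarize(rows)}
        assert summaries["IV"].n == 2
        assert summaries["IV + PO"].n == 3
        assert summaries["IV + PO"].pct_within_3x_bsa == pytest.approx(100 * 2 / 3)
        # BW columns reported for large molecules only
        assert summaries["IV"].pct_within_2x_bw is None
        assert summaries["mAb"].pct_within_3x_bw == pytest.approx(100.0)
        assert "ADC" not in summaries  # empty groups omitted

    def test_seven_of_nine_displays_77_8(self):
        rows = [make_row(1.0, Method.BW, ModalityClass.ADC)] * 7 + [
            make_row(9.0, Method.BW, ModalityClass.ADC)
        ] * 2
        summaries = {s.subclass_label: s for s in summarize(rows)}
        assert format_pct(summaries["ADC"].pct_within_3x_bw) == "77.8"

    def test_pct3_at_least_pct2_per_method(self):
        rng = np.random.default_rng(11)
        rows = [make_row(float(10 ** rng.uniform(0, 1.2))) for _ in range(30)]
        [summary] = summarize(rows, [("All", "all", lambda c: True, False)])
        assert summary.pct_within_3x_bsa >= summary.pct_within_2x_bsa


class TestBootstrapCi:
    def test_degenerate_all_within(self):
        rows = [make_row(1.5)] * 10
        assert bootstrap_ci(rows, 2, seed=1) == (100.0, 100.0)

    def test_degenerate_none_within(self):
        rows = [make_row(9.0)] * 10
        assert bootstrap_ci(rows, 2, seed=1) == (0.0, 0.0)

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        rows = [make_row(float(10 ** abs(rng.normal(0, 0.4)))) for _ in range(30)]
        low, high = bootstrap_ci(rows, 3, n_boot=500, seed=2)
        assert low <= pct_within(rows, 3) <= high

    def test_reproducible_and_nboot_floor(self):
        rows = [make_row(1.0), make_row(4.0)]
        assert bootstrap_ci(rows, 2, seed=3) == bootstrap_ci(rows, 2, seed=3)
        with pytest.raises(ValueError):
            bootstrap_ci(rows, 2, n_boot=50, seed=3)


class TestExportScatter:
    def test_csv_and_figure_written(self, tmp_path):
        rows = [make_row(float(f), name=f"d{i}") for i, f in enumerate((1, 2, 4))]
        csv_path = tmp_path / "scatter.csv"
        png_path = tmp_path / "scatter.png"
        frame = export_scatter(rows, csv_path, png_path)
        assert len(frame) == 3
        assert csv_path.exists() and png_path.exists()

    def test_empty_after_filtering_rejected(self, tmp_path):
        bad = EvaluationRow("z", Method.BSA, 0.0, 1.0, 1.0, True, True,
                            ModalityClass.SM_PO)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                export_scatter([bad], tmp_path / "s.csv")
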