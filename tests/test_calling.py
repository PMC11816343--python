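"""The four alteration-calling rules and event unification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tka
from tka.calling import BENIGN_CLASSES, IMPACTS, ONCOGENICITY_CLASSES


def brute_force_upper_outliers(values, multiplier=1.5):
    """Independent quartile-fence oracle: sort, interpolate quartiles by
    hand, apply the fence. Returns the flagged indices."""
    xs = sorted(values)
    n = len(xs)

    def quantile(q):
        pos = q * (n - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return xs[lo] * (1 - frac) + xs[hi] * frac

    q1, q3 = quantile(0.25), quantile(0.75)
    fence = q3 + multiplier * (q3 - q1)
    return {i for i, v in enumerate(values) if v > fence}


class TestCallAmplifications:
    @pytest.mark.parametrize(
        ("copy_number", "expected_events"), [(6.0, 1), (5.0, 0), (2.0, 0)]
    )
    def test_strict_threshold(self, copy_number, expected_events):
        events = tka.call_amplifications(
            [tka.CnvRecord("P1", "PDGFRA", copy_number)]
        )
        assert len(events) == expected_events
        if events:
            assert events[0].kind == "amplification"
            assert events[0].oncogenic

    def test_duplicates_keep_maximum(self):
        events = tka.call_amplifications(
            [
                tka.CnvRecord("P1", "PDGFRA", 6.0),
                tka.CnvRecord("P1", "PDGFRA", 11.0),
            ]
        )
        assert len(events) == 1
        assert "copy_number=11" in events[0].detail

    def test_negative_copy_number_rejected(self):
        with pytest.raises(tka.ValidationError):
            tka.CnvRecord("P1", "PDGFRA", -1.0)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["P1", "P2", "P3"]),
                st.sampled_from(["KDR", "KIT"]),
                st.floats(min_value=0, max_value=20),
            ),
            max_size=20,
        ),
        st.randoms(use_true_random=False),
    )
    @settings(derandomize=True, max_examples=60)
    def test_row_order_invariance(self, rows, rnd):
        records = [tka.CnvRecord(p, g, c) for p, g, c in rows]
        shuffled = records[:]
        rnd.shuffle(shuffled)
        assert tka.call_amplifications(records) == tka.call_amplifications(shuffled)


class TestCallOverexpression:
    def test_single_extreme_value_flagged(self):
        expr = tka.ExpressionMatrix.from_arrays(
            ["KDR"], ["S1", "S2", "S3", "S4", "S5"],
            np.array([[1.0, 2.0, 3.0, 4.0, 100.0]]),
        )
        events = tka.call_overexpression(expr)
        assert [(e.patient_id, e.gene) for e in events] == [("S5", "KDR")]

    def test_fence_is_exclusive_bound(self):
        # values 1..5: Q1=2, Q3=4, fence=7 -> nothing flagged
        expr = tka.ExpressionMatrix.from_arrays(
            ["KDR"], [f"S{i}" for i in range(5)],
            np.array([[1.0, 2.0, 3.0, 4.0, 5.0]]),
        )
        assert tka.call_overexpression(expr) == []

    def test_constant_vector_yields_nothing(self):
        expr = tka.ExpressionMatrix.from_arrays(
            ["KDR"], [f"S{i}" for i in range(5)], np.full((1, 5), 5.0)
        )
        assert tka.call_overexpression(expr) == []

    def test_too_few_samples_refused(self):
        expr = tka.ExpressionMatrix.from_arrays(
            ["KDR"], ["S1", "S2", "S3"], np.zeros((1, 3))
        )
        with pytest.raises(tka.TooFewSamplesError):
            tka.call_overexpression(expr)

    def test_underexpression_never_flagged(self):
        expr = tka.ExpressionMatrix.from_arrays(
            ["KDR"], [f"S{i}" for i in range(6)],
            np.array([[-100.0, 5.0, 5.1, 5.2, 5.3, 5.4]]),
        )
        assert all(e.patient_id != "S0" for e in tka.call_overexpression(expr))

    @given(st.data())
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_matches_bruteforce_oracle(self, data):
        n_genes = data.draw(st.integers(1, 5))
        n_samples = data.draw(st.integers(4, 30))
        values = data.draw(
            st.lists(
                st.lists(
                    st.floats(min_value=-50, max_value=50),
                    min_size=n_samples, max_size=n_samples,
                ),
                min_size=n_genes, max_size=n_genes,
            )
        )
        genes = [f"G{i}" for i in range(n_genes)]
        samples = [f"S{j}" for j in range(n_samples)]
        expr = tka.ExpressionMatrix.from_arrays(genes, samples, np.array(values))
        events = tka.call_overexpression(expr)
        called = {(e.gene, e.patient_id) for e in events}
        expected = {
            (genes[i], samples[j])
            for i in range(n_genes)
            for j in brute_force_upper_outliers(values[i])
        }
        assert called == expected

    @given(
        values=st.lists(
            st.floats(min_value=-30, max_value=30), min_size=5, max_size=25
        ),
        shift=st.floats(min_value=-100, max_value=100),
    )
    @settings(derandomize=True, max_examples=60)
    def test_shift_equivariance(self, values, shift):
        """Adding a constant to a gene's expression leaves the flagged set
        unchanged (the fence is location-equivariant)."""
        samples = [f"S{j}" for j in range(len(values))]

        def flagged(vals):
            expr = tka.ExpressionMatrix.from_arrays(["G"], samples, np.array([vals]))
            return {e.patient_id for e in tka.call_overexpression(expr)}

        assert flagged(values) == flagged([v + shift for v in values])


class TestScreenMutations:
    @pytest.mark.parametrize(
        ("impact", "onco", "emitted", "oncogenic"),
        [
            ("MODERATE", "oncogenic", True, True),
            ("MODERATE", "likely_oncogenic", True, True),
            ("MODERATE", "vus", True, False),
            ("HIGH", "vus_nmd", True, False),
            ("HIGH", "benign", False, None),
            ("MODERATE", "likely_benign", False, None),
            ("LOW", "oncogenic", False, None),
            ("MODIFIER", "vus", False, None),
        ],
    )
    def test_screening_matrix(self, impact, onco, emitted, oncogenic):
        events = tka.screen_mutations(
            [tka.MutationRecord("P1", "BRAF", impact, onco)]
        )
        assert bool(events) == emitted
        if emitted:
            assert events[0].oncogenic is oncogenic

    def test_unknown_class_rejected_with_allowed_values(self):
        with pytest.raises(tka.ValidationError, match="oncogenic"):
            tka.MutationRecord("P1", "BRAF", "MODERATE", "pathogenic")

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["P1", "P2"]),
                st.sampled_from(["BRAF", "KDR", "TEK"]),
                st.sampled_from(IMPACTS),
                st.sampled_from(ONCOGENICITY_CLASSES),
            ),
            max_size=30,
        )
    )
    @settings(derandomize=True, max_examples=80)
    def test_benign_classes_never_emitted(self, rows):
        events = tka.screen_mutations(
            [tka.MutationRecord(p, g, i, o) for p, g, i, o in rows]
        )
        assert all(e.detail.split(";")[0] not in BENIGN_CLASSES for e in events)
        assert all(
            e.oncogenic == (e.detail.split(";")[0] in ("oncogenic", "likely_oncogenic"))
            for e in events
        )


class TestCollectFusions:
    def test_single_catalog_partner(self, sets):
        events = tka.collect_fusions(
            [tka.FusionRecord("P1", "ABL1", "SZRD1", "ABL1::SZRD1")], sets
        )
        assert [(e.gene, e.detail) for e in events] == [("ABL1", "ABL1::SZRD1")]

    def test_no_catalog_partner_no_event(self, sets):
        assert tka.collect_fusions(
            [tka.FusionRecord("P1", "AAA", "BBB", "AAA::BBB")], sets
        ) == []

    def test_two_catalog_partners_two_events(self, sets):
        events = tka.collect_fusions(
            [tka.FusionRecord("P1", "KDR", "PDGFRA", "KDR::PDGFRA")], sets
        )
        assert sorted(e.gene for e in events) == ["KDR", "PDGFRA"]


class TestUnifyAlterations:
    def test_exact_duplicates_collapse(self):
        ev = tka.AlterationEvent("P1", "PDGFRA", "amplification", True, "")
        frame = tka.unify_alterations([ev], [ev])
        assert len(frame) == 1

    def test_distinct_kinds_kept(self):
        frame = tka.unify_alterations(
            [
                tka.AlterationEvent("P1", "PDGFRA", "amplification"),
                tka.AlterationEvent("P1", "PDGFRA", "overexpression"),
            ]
        )
        assert sorted(frame["kind"]) == ["amplification", "overexpression"]

    def test_distinct_mutations_in_one_gene_kept(self):
        frame = tka.unify_alterations(
            [
                tka.AlterationEvent("P1", "TEK", "mutation", False, "vus;p.A1T"),
                tka.AlterationEvent("P1", "TEK", "mutation", False, "vus;p.G2S"),
            ]
        )
        assert len(frame) == 2

    def test_empty_inputs(self):
        frame = tka.unify_alterations([])
        assert frame.empty
        assert list(frame.columns) == [
            "patient_id", "gene", "kind", "oncogenic", "detail"
        ]

    def test_deterministic_under_input_order(self):
        events = [
            tka.AlterationEvent("P2", "KDR", "mutation", False, "vus"),
            tka.AlterationEvent("P1", "TEK", "mutation", False, "vus"),
            tka.AlterationEvent("P1", "ABL1", "fusion", True, "ABL1::SZRD1"),
        ]
        a = tka.unify_alterations(events)
        b = tka.unify_alterations(list(reversed(events)))
        pd.testing.assert_frame_equal(a, b)
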