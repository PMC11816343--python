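"""Patient verdicts, cohort/gene summaries, and their invariants."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tka
from tka.assessment import SET_NAMES, percentage


def make_manifest(ids, rnaseq=()):
    return [tka.ManifestEntry(p, has_wes=True, has_rnaseq=p in rnaseq) for p in ids]


class TestBuildPatientProfiles:
    def test_mixed_non_oncogenic_mut_with_overexpression(self, sets):
        """A non-oncogenic FLT4 mutation plus SLK and MAP2K5 overexpression:
        target present in the 46- and 23-gene sets but not the 18-gene set."""
        events = [
            tka.AlterationEvent("P1", "FLT4", "mutation", False, "vus"),
            tka.AlterationEvent("P1", "SLK", "overexpression"),
            tka.AlterationEvent("P1", "MAP2K5", "overexpression"),
        ]
        [profile] = tka.build_patient_profiles(events, make_manifest(["P1"]), sets)
        putative = {k: v.putative_oncogenic for k, v in profile.verdicts.items()}
        assert putative == {"full": True, "achievable": False, "extended": True}

    def test_out_of_focus_genes_only(self, sets):
        events = [
            tka.AlterationEvent("P1", "HIPK4", "overexpression"),
            tka.AlterationEvent("P1", "MUSK", "overexpression"),
        ]
        [profile] = tka.build_patient_profiles(events, make_manifest(["P1"]), sets)
        putative = {k: v.putative_oncogenic for k, v in profile.verdicts.items()}
        assert putative == {"full": True, "achievable": False, "extended": False}

    def test_alteration_free_patient_all_false(self, sets):
        [profile] = tka.build_patient_profiles([], make_manifest(["P1"]), sets)
        assert all(
            not v.any_alteration and not v.putative_oncogenic
            for v in profile.verdicts.values()
        )

    def test_unknown_patient_rejected(self, sets):
        events = [tka.AlterationEvent("P9", "KDR", "amplification")]
        with pytest.raises(tka.ManifestMismatchError, match="P9"):
            tka.build_patient_profiles(events, make_manifest(["P1"]), sets)


class TestSummarizeCohort:
    def test_fixture_counts(self, event_mode_result):
        per_set = event_mode_result.cohort_summary.per_set
        assert per_set["full"]["n_oncogenic"] == 34
        assert per_set["achievable"]["n_oncogenic"] == 26
        assert per_set["extended"]["n_oncogenic"] == 30

    def test_empty_cohort_percentages_undefined(self):
        summary = tka.summarize_cohort([])
        assert summary.n_patients == 0
        for row in summary.per_set.values():
            assert row["n_any"] == 0
            assert row["pct_any"] is None  # undefined, not 0.0

    def test_single_event_free_patient(self, sets):
        profiles = tka.build_patient_profiles([], make_manifest(["P1"]), sets)
        summary = tka.summarize_cohort(profiles)
        assert all(row["n_any"] == 0 for row in summary.per_set.values())
        assert all(v == 0 for v in summary.modality_counts.values())

    def test_matches_bruteforce_recount(self, event_mode_result, sets):
        """Independent recount: iterate patients × events × sets directly."""
        profiles = event_mode_result.profiles
        for name, members in sets.named().items():
            n_any = sum(
                1 for p in profiles
                if any(e.gene in members for e in p.events)
            )
            n_onco = sum(
                1 for p in profiles
                if any(e.gene in members and e.oncogenic for e in p.events)
            )
            row = event_mode_result.cohort_summary.per_set[name]
            assert (row["n_any"], row["n_oncogenic"]) == (n_any, n_onco)


class TestSummarizeGenes:
    def test_pdgfra_totals(self, event_mode_result):
        row = event_mode_result.gene_summaries.loc["PDGFRA"]
        assert row["n_any"] == 15
        assert row["n_oncogenic"] == 14
        assert row["n_amplifications"] == 9

    def test_unaltered_gene_zero_filled(self, event_mode_result):
        row = event_mode_result.gene_summaries.loc["CDK19"]
        assert row.sum() == 0

    def test_empty_events_all_zero(self, sets):
        frame = tka.summarize_genes([], sets)
        assert len(frame) == 46
        assert (frame == 0).all().all()

    def test_n_any_is_kind_sum(self, event_mode_result):
        gs = event_mode_result.gene_summaries
        assert (
            gs["n_any"]
            == gs[["n_mutations", "n_amplifications", "n_overexpressions",
                   "n_fusions"]].sum(axis=1)
        ).all()
        assert (gs["n_oncogenic"] <= gs["n_any"]).all()


class TestPartitionEffectiveTargets:
    NOT_CONFIRMED = frozenset({"NTRK1", "FGFR2", "FGFR3", "FGFR4"})

    def test_rescued_by_confirmed_overexpression(self, sets):
        events = [
            tka.AlterationEvent("P1", "NTRK1", "mutation", True, "oncogenic"),
            tka.AlterationEvent("P1", "FGFR4", "mutation", True, "oncogenic"),
            tka.AlterationEvent("P1", "RAF1", "overexpression"),
        ]
        [profile] = tka.build_patient_profiles(events, make_manifest(["P1"]), sets)
        part = tka.partition_effective_targets(profile, self.NOT_CONFIRMED)
        assert "RAF1" in part.confirmed_target_genes
        assert not part.unconfirmed_only

    def test_no_putative_targets(self, sets):
        [profile] = tka.build_patient_profiles([], make_manifest(["P1"]), sets)
        part = tka.partition_effective_targets(profile, self.NOT_CONFIRMED)
        assert not part.unconfirmed_only
        assert not part.confirmed_target_genes and not part.unconfirmed_target_genes

    def test_unconfirmed_only(self, sets):
        events = [tka.AlterationEvent("P1", "FGFR3", "mutation", True, "oncogenic")]
        [profile] = tka.build_patient_profiles(events, make_manifest(["P1"]), sets)
        part = tka.partition_effective_targets(profile, self.NOT_CONFIRMED)
        assert part.unconfirmed_only
        assert part.unconfirmed_target_genes == {"FGFR3"}

    def test_not_confirmed_default_from_catalog(self, catalog):
        assert catalog.not_confirmed_set() == self.NOT_CONFIRMED


class TestAffinityComparison:
    def test_fgfr1_and_tek_not_inhibited(self, event_mode_result, catalog):
        table = tka.compare_alterations_to_affinity(
            event_mode_result.gene_summaries, catalog
        )
        assert table.loc["FGFR1", "inhibition_status"] == "not_inhibited"
        assert table.loc["FGFR1", "min_affinity_nM"] == 202
        assert table.loc["TEK", "min_affinity_nM"] == 311
        assert table.loc["TEK", "inhibition_status"] == "not_inhibited"

    def test_gene_without_data_still_reported(self, event_mode_result, catalog):
        table = tka.compare_alterations_to_affinity(
            event_mode_result.gene_summaries, catalog
        )
        assert table.loc["SLK", "inhibition_status"] == "unknown"
        assert table.loc["SLK", "n_any"] > 0


class TestPercentage:
    @pytest.mark.parametrize(
        ("count", "n", "expected"),
        [(17, 103, 16.5), (34, 103, 33.0), (15, 46, 32.6), (1, 16, 6.3), (0, 7, 0.0)],
    )
    def test_one_decimal_half_away_from_zero(self, count, n, expected):
        assert percentage(count, n) == expected

    def test_zero_denominator_undefined(self):
        assert percentage(0, 0) is None


@st.composite
def fuzzed_cohorts(draw):
    genes = draw(
        st.lists(
            st.sampled_from(
                ["KDR", "PDGFRA", "SLK", "MAP2K5", "HIPK4", "TEK", "MAPK9", "CDK8"]
            ),
            min_size=0, max_size=8,
        )
    )
    patients = [f"P{i}" for i in range(1, draw(st.integers(1, 6)) + 1)]
    events = []
    for g in genes:
        p = draw(st.sampled_from(patients))
        kind = draw(st.sampled_from(["mutation", "amplification", "overexpression"]))
        onco = True if kind != "mutation" else draw(st.booleans())
        events.append(tka.AlterationEvent(p, g, kind, onco, f"d{len(events)}"))
    return patients, events


class TestInvariants:
    @given(fuzzed_cohorts())
    @settings(derandomize=True, max_examples=80)
    def test_verdict_nesting_monotonicity(self, sets, cohort):
        """Growing the gene set can only turn verdicts on, never off."""
        patients, events = cohort
        profiles = tka.build_patient_profiles(events, make_manifest(patients), sets)
        for p in profiles:
            v = p.verdicts
            assert v["achievable"].any_alteration <= v["extended"].any_alteration
            assert v["extended"].any_alteration <= v["full"].any_alteration
            assert (
                v["achievable"].putative_oncogenic
                <= v["extended"].putative_oncogenic
                <= v["full"].putative_oncogenic
            )
            for name in SET_NAMES:
                assert v[name].putative_oncogenic <= v[name].any_alteration

    def test_counts_bounded_by_cohort(self, event_mode_result):
        summary = event_mode_result.cohort_summary
        for row in summary.per_set.values():
            assert 0 <= row["n_oncogenic"] <= row["n_any"] <= summary.n_patients
        for v in summary.modality_counts.values():
            assert 0 <= v <= summary.n_patients

    def test_report_byte_identical_under_event_permutation(
        self, catalog, fixture_cohort
    ):
        events = list(fixture_cohort.events)
        forward = tka.assess_events(catalog, fixture_cohort.manifest, events)
        backward = tka.assess_events(
            catalog, fixture_cohort.manifest, list(reversed(events))
        )
        assert json.dumps(forward.report, sort_keys=True) == json.dumps(
            backward.report, sort_keys=True
        )
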