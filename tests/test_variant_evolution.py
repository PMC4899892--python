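"""Acquisition/selection rules and A/B/C triage against independent oracles."""

import itertools

import pytest

from taxevo.errors import ValidationError, VocabularyError
from taxevo.stage_io import AnnotatedConsequence, Stage, StageSeries, VariantObservation
from taxevo.variant_evolution import (
    CONSEQUENCE_VOCABULARY,
    call_acquired,
    call_selected,
    classify_annotation,
    classify_variant,
    tally_consequences,
    triage_class,
)

# per-stage observation states used throughout:
#   "called"      — variant called, good depth, alt reads present
#   "absent_ok"   — not called, depth >= 5, zero alt reads (assessable absence)
#   "absent_low"  — not called, depth < 5 (unassessable absence)
STATES = {
    "called": (True, 30, 15),
    "absent_ok": (False, 30, 0),
    "absent_low": (False, 3, 0),
}


def make_series(n=6):
    roles = ["parental"] + ["intermediate"] * (n - 2) + ["final"]
    return StageSeries(
        stages=tuple(Stage(f"S{i}", float(i), r) for i, r in enumerate(roles))
    )


def make_variant(states, depths=None, alts=None):
    called, depth, alt = zip(*(STATES[s] for s in states))
    if depths is not None:
        depth = depths
    if alts is not None:
        alt = alts
    return VariantObservation(
        chrom="1", pos=100, ref="G", alt="A",
        called=tuple(called), depth=tuple(depth), alt_depth=tuple(alt),
    )


def brute_force_classify(states):
    """Literal re-statement of the acquisition and persistence rules.

    A variant is acquired at the earliest stage where it is called, was not
    called in the preceding stage, and the preceding stage has depth greater
    than four with zero reads supporting the alternative allele.  It is
    selected if it is then called in all following stages including the
    final one; acquired but not selected is transient.  If the only
    call/no-call transitions sit on unassessable absences, the variant
    cannot be classified.
    """
    n = len(states)
    called = [STATES[s][0] for s in states]
    if called[0]:
        return {"acquired": None, "assessable": True, "selected": False, "transient": False}
    acquired = None
    unassessable = False
    for i in range(1, n):
        if not called[i] or called[i - 1]:
            continue
        prev = states[i - 1]
        depth_ok = STATES[prev][1] > 4
        alt_zero = STATES[prev][2] == 0
        if depth_ok and alt_zero:
            acquired = i
            break
        unassessable = True
    if acquired is None:
        return {
            "acquired": None,
            "assessable": not unassessable,
            "selected": False,
            "transient": False,
        }
    selected = all(called[j] for j in range(acquired + 1, n))
    return {
        "acquired": acquired,
        "assessable": True,
        "selected": selected,
        "transient": not selected,
    }


class TestAcquisitionRule:
    def test_simple_acquisition(self):
        v = make_variant(["absent_ok", "absent_ok", "called", "called", "called", "called"])
        call = call_acquired(v, make_series())
        assert call.acquired_stage == 2 and call.assessable

    def test_low_preceding_depth_is_unassessable(self):
        v = make_variant(["absent_ok", "absent_low", "called", "called", "called", "called"])
        call = call_acquired(v, make_series())
        assert call.acquired_stage is None and not call.assessable

    def test_prior_alt_evidence_blocks_acquisition(self):
        v = make_variant(["absent_ok", "absent_ok", "called", "called", "called", "called"],
                         alts=(0, 1, 15, 15, 15, 15))
        call = call_acquired(v, make_series())
        assert call.acquired_stage is None and call.assessable

    def test_unknown_preceding_depth_is_unassessable(self):
        v = make_variant(["absent_ok", "absent_ok", "called", "called", "called", "called"],
                         depths=(30, None, 30, 30, 30, 30), alts=(0, None, 15, 15, 15, 15))
        call = call_acquired(v, make_series())
        assert call.acquired_stage is None and not call.assessable

    def test_parental_call_is_never_acquired(self):
        v = make_variant(["called", "absent_ok", "called", "called", "called", "called"])
        call = call_acquired(v, make_series())
        assert call.acquired_stage is None and call.assessable

    def test_missense_appearing_in_penultimate_stage(self):
        # the chr7 IRF5-like pattern: absent with depth 20/alt 0 through the
        # fourth stage, called from the fifth onward
        v = VariantObservation(
            chrom="7", pos=128587374, ref="G", alt="A",
            called=(False, False, False, False, True, True),
            depth=(20, 20, 20, 20, 40, 40),
            alt_depth=(0, 0, 0, 0, 18, 20),
        )
        call = classify_variant(v, make_series())
        assert call.acquired_stage == 4 and call.selected


class TestSelectionRule:
    def test_persisting_to_final_is_selected(self):
        v = make_variant(["absent_ok", "absent_ok", "called", "called", "called", "called"])
        call = classify_variant(v, make_series())
        assert call.selected and not call.transient

    def test_gap_after_acquisition_is_transient(self):
        v = make_variant(["absent_ok", "absent_ok", "called", "absent_ok", "called", "called"])
        call = classify_variant(v, make_series())
        assert call.acquired_stage == 2 and call.transient and not call.selected

    def test_acquisition_at_final_stage_is_vacuously_selected(self):
        v = make_variant(["absent_ok", "absent_ok", "absent_ok", "absent_ok", "absent_ok", "called"])
        call = classify_variant(v, make_series())
        assert call.acquired_stage == 5 and call.selected


class TestOracleEquivalence:
    def test_all_stage_patterns_match_brute_force(self):
        """Exhaustive check over all 3^6 per-stage observation patterns."""
        series = make_series(6)
        for states in itertools.product(STATES, repeat=6):
            v = make_variant(states)
            call = call_selected(call_acquired(v, series), v, series)
            expect = brute_force_classify(states)
            got = {
                "acquired": call.acquired_stage,
                "assessable": call.assessable,
                "selected": call.selected,
                "transient": call.transient,
            }
            assert got == expect, f"pattern {states}: {got} != {expect}"


def ann(term, sift="absent", polyphen="absent", in_domain=False, key="1:100:G:A"):
    return AnnotatedConsequence(
        variant_key=key, gene_id="G1", transcript_id="G1.t0",
        consequence_term=term, sift=sift, polyphen=polyphen, in_domain=in_domain,
    )


class TestTriage:
    @pytest.mark.parametrize(
        "annotation, expected",
        [
            (ann("missense_variant", sift="deleterious"), "A"),
            (ann("missense_variant", polyphen="possibly_damaging"), "A"),
            (ann("missense_variant", in_domain=True), "A"),
            (ann("missense_variant", sift="tolerated", polyphen="benign"), "B"),
            (ann("stop_gained"), "A"),
            (ann("splice_donor_variant"), "A"),
            (ann("TF_binding_site_variant"), "A"),
            (ann("inframe_deletion"), "B"),
            (ann("splice_region_variant"), "B"),
            (ann("NMD_transcript_variant"), "B"),
            (ann("synonymous_variant"), "C"),
            (ann("stop_retained_variant"), "C"),
            (ann("intron_variant"), "C"),
            (ann("intergenic_variant"), "C"),
        ],
    )
    def test_per_annotation_class(self, annotation, expected):
        assert classify_annotation(annotation) == expected

    def test_variant_label_is_min_severity_over_all_pairs(self):
        """Brute force: for every pair of annotations the variant label is
        the more severe of the two per-annotation classes."""
        exemplars = [
            ann("stop_gained"),
            ann("missense_variant", sift="deleterious"),
            ann("missense_variant"),
            ann("splice_region_variant"),
            ann("synonymous_variant"),
            ann("intron_variant"),
        ]
        order = {"A": 0, "B": 1, "C": 2}
        for a, b in itertools.product(exemplars, repeat=2):
            expected = min(classify_annotation(a), classify_annotation(b), key=order.__getitem__)
            assert triage_class([a, b]) == expected

    def test_unknown_term_rejected(self):
        bad = AnnotatedConsequence(
            variant_key="k", gene_id="g", transcript_id="t",
            consequence_term="weird_variant",
        )
        with pytest.raises(VocabularyError):
            classify_annotation(bad)

    def test_empty_annotation_list_rejected(self):
        with pytest.raises(ValidationError):
            triage_class([])

    def test_adding_class_a_annotation_never_demotes(self):
        base = [ann("synonymous_variant"), ann("intron_variant")]
        order = {"A": 0, "B": 1, "C": 2}
        before = triage_class(base)
        after = triage_class(base + [ann("stop_gained")])
        assert order[after] <= order[before]


class TestTally:
    def test_empty_event_set(self):
        tally = tally_consequences([], "S1")
        assert tally.total == 0 and all(c == 0 for c in tally.counts.values())

    def test_counts_per_annotation(self):
        events = [
            ("v1", [ann("synonymous_variant"), ann("missense_variant")]),
            ("v2", [ann("synonymous_variant")]),
        ]
        tally = tally_consequences(events, "S1")
        assert tally.counts["synonymous_variant"] == 2
        assert tally.counts["missense_variant"] == 1
        assert tally.total == 3

    def test_total_conserves_annotation_count(self, default_output):
        by_variant = {}
        for a in default_output.annotations:
            by_variant.setdefault(a.variant_key, []).append(a)
        events = list(by_variant.items())
        tally = tally_consequences(events, "all")
        assert tally.total == len(default_output.annotations)
        assert sum(tally.counts.values()) == tally.total

    def test_vocabulary_is_closed(self):
        assert "missense_variant" in CONSEQUENCE_VOCABULARY
        assert "made_up_variant" not in CONSEQUENCE_VOCABULARY
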