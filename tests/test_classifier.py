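"""The four-class decision procedure, checked against the published systems."""

import copy

import pytest

from taclass.classifier import SynthesisRates, classify
from taclass.coverage_quant import RatioSummary
from taclass.operon_model import GeneModel, OperonModel, Promoter
from taclass.profile_evidence import ChangepointCall
from taclass.tir_consensus import ConsensusCall, ANTITOXIN_HIGHER, TOXIN_HIGHER


def ratio_summary(median, included=True):
    return RatioSummary("op", {}, median_ratio=median, sd_ratio=0.1,
                        n_datasets=13, included=included)


def operon(promoter_layout="1ex", toxin_first=False, gap=5):
    first_role = "toxin" if toxin_first else "antitoxin"
    second_role = "antitoxin" if toxin_first else "toxin"
    g1 = GeneModel(f"op_{first_role}", first_role, 60, 360)
    g2 = GeneModel(f"op_{second_role}", second_role, 360 + gap, 360 + gap + 250)
    promoters = [Promoter("p1", 5)]
    if promoter_layout == "2ex":
        promoters.append(Promoter("p2", 40))
    elif promoter_layout == "2ex_distal":
        promoters.append(Promoter("p2", 1))  # second TSS far from the CDS start
    elif promoter_layout == "1ex+1in":
        promoters.append(Promoter("pin", 200))
    return OperonModel("op", [g1, g2], promoters)


def cons(verdict):
    return {"P1": ConsensusCall("op", "P1", 3, verdict)}


class TestPublishedSystems:
    def test_relbe_like_single_transcript(self):
        a = classify(operon(), ratio_summary(0.95), consensus_by_variant=cons(ANTITOXIN_HIGHER))
        assert a.assigned_class == 1 and a.mechanism == "translational"

    def test_dinj_yafq_like_clear_antitoxin_excess(self):
        a = classify(operon(), ratio_summary(2.89))
        assert a.assigned_class == 3 and a.mechanism == "transcript_truncation"

    def test_hicab_like_proximal_second_external_promoter(self):
        a = classify(operon("2ex", toxin_first=True, gap=40), ratio_summary(0.93),
                     consensus_by_variant=cons(TOXIN_HIGHER))
        assert a.assigned_class == 2
        assert a.mechanism == "transcriptional_and_translational"

    def test_rnlab_like_internal_promoter_with_anomaly(self):
        synth = SynthesisRates("op", 1.0, 2.0, 1000, 1000)
        a = classify(operon("1ex+1in", toxin_first=True), ratio_summary(1.01),
                     synthesis=synth)
        assert a.assigned_class == 4 and a.mechanism == "internal_promoter"
        assert "synthesis_ratio_below_one" in a.anomaly_flags

    def test_yafno_like_borderline_with_toxin_higher_consensus(self):
        a = classify(operon(), ratio_summary(2.08),
                     consensus_by_variant=cons(TOXIN_HIGHER))
        assert a.assigned_class == 3

    def test_ficat_like_borderline_with_antitoxin_higher_consensus(self):
        a = classify(operon(), ratio_summary(1.99),
                     consensus_by_variant=cons(ANTITOXIN_HIGHER))
        assert a.assigned_class == 1


class TestRules:
    def test_excluded_ratio_is_unclassified(self):
        a = classify(operon(), ratio_summary(1.5, included=False))
        assert a.assigned_class == "unclassified" and a.mechanism == "unknown"

    def test_borderline_without_tir_support_is_unclassified(self):
        a = classify(operon(), ratio_summary(2.0))
        assert a.assigned_class == "unclassified"

    def test_down_changepoint_in_toxin_cds_gives_class3(self):
        op = operon()  # toxin CDS is [365, 615)
        cp = ChangepointCall(position=450, direction="down", fold=0.3,
                             delta_bic=50.0, significant=True)
        a = classify(op, ratio_summary(1.4), changepoint=cp)
        assert a.assigned_class == 3

    def test_up_changepoint_upstream_of_antitoxin_gives_class4(self):
        op = operon(toxin_first=True)  # antitoxin CDS starts at 365
        cp = ChangepointCall(position=200, direction="up", fold=3.0,
                             delta_bic=80.0, significant=True)
        a = classify(op, ratio_summary(1.0), changepoint=cp)
        assert a.assigned_class == 4

    def test_up_changepoint_inside_antitoxin_does_not_give_class4(self):
        op = operon(toxin_first=True)
        cp = ChangepointCall(position=500, direction="up", fold=3.0,
                             delta_bic=80.0, significant=True)
        a = classify(op, ratio_summary(1.0), consensus_by_variant=cons(ANTITOXIN_HIGHER))
        assert a.assigned_class != 4

    def test_distal_second_promoter_does_not_give_class2(self):
        a = classify(operon("2ex_distal"), ratio_summary(1.2))
        assert a.assigned_class == 1

    def test_internal_promoter_beats_proximal_second_external(self):
        op = operon("2ex", toxin_first=True, gap=40)
        op.promoters.append(Promoter("pin", 200))
        a = classify(op, ratio_summary(1.0))
        assert a.assigned_class == 4
        assert any("contradiction" in e for e in a.evidence)

    def test_synthesis_advisory_never_changes_class(self):
        synth = SynthesisRates("op", 1.0, 3.0, 1000, 1000)  # confident ratio < 1
        a = classify(operon(), ratio_summary(0.9), synthesis=synth)
        assert a.assigned_class == 1
        assert "synthesis_ratio_below_one" in a.anomaly_flags

    def test_low_confidence_synthesis_never_flags(self):
        synth = SynthesisRates("op", 1.0, 3.0, 64, 1000)  # under 128 reads
        assert synth.low_confidence
        a = classify(operon(), ratio_summary(0.9), synthesis=synth)
        assert a.anomaly_flags == []

    def test_determinism(self):
        args = (operon(), ratio_summary(2.1))
        kwargs = dict(consensus_by_variant=cons(TOXIN_HIGHER))
        a1 = classify(*copy.deepcopy(args), **copy.deepcopy(kwargs))
        a2 = classify(*copy.deepcopy(args), **copy.deepcopy(kwargs))
        assert (a1.assigned_class, a1.mechanism, a1.evidence) == \
               (a2.assigned_class, a2.mechanism, a2.evidence)

    def test_monotonicity_in_median_ratio(self):
        """Raising the median (no promoter evidence) never moves class 3 -> 1."""
        classes = []
        for median in [x / 20 for x in range(10, 80)]:
            a = classify(operon(), ratio_summary(median),
                         consensus_by_variant=cons(ANTITOXIN_HIGHER))
            classes.append(a.assigned_class)
        seen3 = False
        for c in classes:
            if c == 3:
                seen3 = True
            assert not (seen3 and c == 1), classes


class TestFixtureFidelity:
    def test_all_ten_published_classes_reproduced(self, fixture_data, fixture_consensus):
        got = {}
        for op in fixture_data.operons:
            a = classify(op, fixture_data.ratios[op.operon_id],
                         consensus_by_variant=fixture_consensus.get(op.operon_id),
                         synthesis=fixture_data.synthesis.get(op.operon_id))
            got[op.operon_id] = a.assigned_class
        assert got == fixture_data.expected_class
        counts = sorted(got.values())
        assert counts == [1, 1, 1, 1, 1, 1, 2, 3, 3, 4]
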