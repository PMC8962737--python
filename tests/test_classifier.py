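"""Gates, consensus voting, routing and their invariants."""

import numpy as np
import pytest

import varprio as vp
from varprio.classify import Route, gate_variant
from conftest import random_variant


def snv(**overrides):
    rng = np.random.default_rng(0)
    base = dict(
        variant_class=vp.VariantClass.nonsynonymous_SNV,
        depth=50,
        exac_eas_freq=None,
    )
    base.update(overrides)
    return random_variant(rng, **base)


class TestGate:
    def test_depth_exactly_10_fails_strict_inequality(self):
        assert not gate_variant(snv(depth=10)).passed
        assert gate_variant(snv(depth=11)).passed

    def test_frequency_boundary_is_inclusive(self):
        assert gate_variant(snv(depth=11, exac_eas_freq=0.01)).passed
        assert not gate_variant(snv(depth=11, exac_eas_freq=0.0101)).passed

    def test_synonymous_fails_class_gate_by_default(self):
        v = snv(variant_class=vp.VariantClass.synonymous_SNV)
        gate = gate_variant(v)
        assert not gate.passed
        assert any("class" in r and "fail" in r for r in gate.reasons)

    def test_missing_frequency_passes_by_default_and_is_switchable(self):
        v = snv(exac_eas_freq=None)
        assert gate_variant(v).passed
        strict = vp.DEFAULT_CONFIG.replace(missing_freq_passes=False)
        assert not gate_variant(v, strict).passed


class TestVotes:
    def damaging_calls(self):
        calls = {}
        for tool, rule in vp.DEFAULT_REGISTRY.items():
            if rule.mode == "categorical":
                calls[tool] = sorted(rule.damaging_categories)[0]
            else:
                calls[tool] = rule.threshold  # boundary damaging
        return calls

    def test_all_fifteen_damaging_saturates(self):
        v = snv(predictor_calls=self.damaging_calls())
        assert vp.count_damaging_votes(v) == 15

    def test_all_missing_gives_zero(self):
        assert vp.count_damaging_votes(snv(predictor_calls={})) == 0

    def test_three_damaging_twelve_benign(self):
        calls = {t: "T" for t, r in vp.DEFAULT_REGISTRY.items()
                 if r.mode == "categorical"}
        calls.update({"VEST3": 0.1, "CADD": 5.0, "fitCons": 0.2})  # benign scores
        calls.update({"SIFT": "D", "MetaSVM": "D", "CADD": 35.0})
        assert vp.count_damaging_votes(snv(predictor_calls=calls)) == 3

    def test_unregistered_tool_warned_and_ignored(self):
        calls = {"SIFT": "D", "NotATool": "D"}
        with pytest.warns(UserWarning, match="NotATool"):
            assert vp.count_damaging_votes(snv(predictor_calls=calls)) == 1

    def test_vote_count_matches_brute_force_tally(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            v = random_variant(rng)
            brute = sum(
                vp.DEFAULT_REGISTRY[t].is_damaging(v.predictor_calls.get(t))
                for t in vp.PREDICTOR_TOOLS
            )
            assert vp.count_damaging_votes(v) == brute


def make_calls(n_damaging: int) -> dict:
    calls = {}
    for i, (tool, rule) in enumerate(vp.DEFAULT_REGISTRY.items()):
        if i < n_damaging:
            calls[tool] = (
                sorted(rule.damaging_categories)[0]
                if rule.mode == "categorical"
                else rule.threshold
            )
        else:
            calls[tool] = "T" if rule.mode == "categorical" else 0.0
    return calls


class TestClassifyRoutes:
    def test_thirteen_votes_is_deleterious_snv(self):
        v = snv(predictor_calls=make_calls(13))
        verdict = vp.classify(v)
        assert verdict.deleterious and verdict.route is Route.snv_consensus
        assert verdict.votes_damaging == 13

    def test_twelve_votes_is_not_enough(self):
        verdict = vp.classify(snv(predictor_calls=make_calls(12)))
        assert not verdict.deleterious and verdict.votes_damaging == 12

    def test_vest_boundaries_inclusive_for_nonframeshift_indel(self):
        v = snv(
            variant_class=vp.VariantClass.nonframeshift_indel,
            vest_indel_score=0.85,
            vest_indel_p=0.01,
        )
        verdict = vp.classify(v)
        assert verdict.deleterious and verdict.route is Route.indel_vest
        assert verdict.votes_damaging is None

    def test_vest_missing_fails_with_reason(self):
        v = snv(
            variant_class=vp.VariantClass.nonframeshift_indel,
            vest_indel_score=None,
            vest_indel_p=None,
        )
        verdict = vp.classify(v)
        assert not verdict.deleterious
        assert "vest_missing" in verdict.reasons

    def test_stoploss_retained_unconditionally_post_gate(self):
        v = snv(variant_class=vp.VariantClass.stoploss, predictor_calls={},
                vest_indel_score=None, vest_indel_p=None)
        verdict = vp.classify(v)
        assert verdict.deleterious and verdict.route is Route.stoploss_retained
        # but never past a failed gate
        v10 = snv(variant_class=vp.VariantClass.stoploss, depth=10)
        assert not vp.classify(v10).deleterious

    def test_frameshift_qualifies_via_haploinsufficiency_or_vest(self):
        fs = snv(
            variant_class=vp.VariantClass.frameshift_indel,
            vest_indel_score=0.2,
            vest_indel_p=0.5,
            gene="FLNA",
        )
        assert vp.classify(fs, hi_table={"FLNA": 3}).deleterious
        assert not vp.classify(fs, hi_table={"FLNA": 1}).deleterious
        assert not vp.classify(fs, hi_table={}).deleterious
        rescued = snv(
            variant_class=vp.VariantClass.frameshift_indel,
            vest_indel_score=0.9,
            vest_indel_p=0.001,
            gene="FLNA",
        )
        assert vp.classify(rescued, hi_table={}).deleterious

    def test_gate_failure_short_circuits_to_rejected(self):
        v = snv(depth=5, predictor_calls=make_calls(15))
        verdict = vp.classify(v)
        assert not verdict.deleterious and verdict.route is Route.rejected_gate


def naive_classify(v, cfg, hi_table):
    """Independent re-evaluation of all criteria, no routing shortcuts."""
    depth_ok = v.depth is not None and v.depth > cfg.min_depth_exclusive
    class_ok = v.variant_class in cfg.allowed_classes
    freq_ok = (
        cfg.missing_freq_passes
        if v.exac_eas_freq is None
        else v.exac_eas_freq <= cfg.max_pop_freq
    )
    if not (depth_ok and class_ok and freq_ok):
        return False
    vest_ok = (
        v.vest_indel_score is not None
        and v.vest_indel_p is not None
        and v.vest_indel_score >= cfg.vest_score_min
        and v.vest_indel_p <= cfg.vest_p_max
    )
    hi_ok = hi_table.get(v.gene) in cfg.hi_ratings_accepted
    votes = sum(
        vp.DEFAULT_REGISTRY[t].is_damaging(v.predictor_calls.get(t))
        for t in vp.PREDICTOR_TOOLS
    )
    cls = v.variant_class
    if cls in (vp.VariantClass.nonsynonymous_SNV, vp.VariantClass.synonymous_SNV):
        return votes >= cfg.min_votes
    if cls in (vp.VariantClass.frameshift_indel, vp.VariantClass.stopgain):
        return hi_ok or vest_ok
    if cls is vp.VariantClass.nonframeshift_indel:
        return vest_ok
    if cls is vp.VariantClass.stoploss:
        return True
    return False


class TestInvariants:
    def test_oracle_equivalence_on_random_variants(self):
        rng = np.random.default_rng(7)
        hi = {f"G{i}": r for i, r in enumerate(rng.integers(0, 4, 50))}
        hi = {g: int(r) for g, r in hi.items()}
        cfg = vp.DEFAULT_CONFIG
        for _ in range(1000):
            v = random_variant(rng)
            assert vp.classify(v, cfg, hi_table=hi).deleterious == naive_classify(
                v, cfg, hi
            )

    def test_stricter_thresholds_never_enlarge_deleterious_set(self):
        rng = np.random.default_rng(11)
        variants = [random_variant(rng) for _ in range(400)]
        base = vp.DEFAULT_CONFIG.replace(min_votes=10, max_pop_freq=0.05,
                                         min_depth_exclusive=5)

        def deleterious_set(cfg):
            return {
                id(v) for v in variants if vp.classify(v, cfg, hi_table={}).deleterious
            }

        reference = deleterious_set(base)
        for stricter in (
            base.replace(min_votes=13),
            base.replace(max_pop_freq=0.01),
            base.replace(min_depth_exclusive=10),
            base.replace(min_votes=15, max_pop_freq=0.001, min_depth_exclusive=30),
        ):
            assert deleterious_set(stricter) <= reference

    def test_routes_partition_all_verdicts(self):
        rng = np.random.default_rng(13)
        verdicts = [vp.classify(random_variant(rng)) for _ in range(500)]
        for verdict in verdicts:
            assert isinstance(verdict.route, Route)
            assert (verdict.votes_damaging is not None) == (
                verdict.route is Route.snv_consensus
            )
            if verdict.deleterious:
                assert verdict.route is not Route.rejected_gate

    def test_min_votes_16_rejects_every_snv(self):
        cfg = vp.DEFAULT_CONFIG.replace(min_votes=16)
        v = snv(predictor_calls=make_calls(15))
        assert not vp.classify(v, cfg).deleterious


class TestSummarize:
    def test_hand_counted_fixture(self):
        rng = np.random.default_rng(3)
        deleterious = [
            vp.classify(snv(predictor_calls=make_calls(15))),
            vp.classify(snv(predictor_calls=make_calls(14))),
            vp.classify(snv(variant_class=vp.VariantClass.stoploss)),
        ]
        rejected = [vp.classify(snv(depth=2)) for _ in range(3)]
        summary = vp.summarize_by_class(deleterious + rejected)
        prim = summary["primary"]
        assert prim["nonsynonymous_SNV"] == 2
        assert prim["stoploss"] == 1
        assert prim["total"] == 3
        assert summary["metastatic"]["total"] == 0

    def test_empty_input_all_zeros(self):
        summary = vp.summarize_by_class([])
        assert all(c == 0 for counts in summary.values() for c in counts.values())

    def test_per_class_counts_sum_to_total(self):
        rng = np.random.default_rng(5)
        verdicts = [vp.classify(random_variant(rng)) for _ in range(300)]
        summary = vp.summarize_by_class(verdicts)
        for group in ("primary", "metastatic"):
            counts = summary[group]
            assert counts["total"] == sum(
                n for k, n in counts.items() if k != "total"
            )
        n_deleterious = sum(v.deleterious for v in verdicts)
        assert (
            summary["primary"]["total"] + summary["metastatic"]["total"]
            == n_deleterious
        )
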