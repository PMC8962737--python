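"""Consensus deleteriousness classification of annotated somatic variants.

A variant first has to clear three gates — sequencing depth strictly above
10 reads, a functional class among the allowed non-synonymous types, and an
East-Asian population frequency (ExAC_EAS) of at most 1% (absent = rare) —
and is then routed by its class:

* nonsynonymous SNV: consensus voting over the 15 registered pathogenicity
  predictors; deleterious when at least ``min_votes`` (default 13, i.e.
  "more than twelve") call it damaging.  Missing predictions count as
  non-damaging, so the denominator stays 15.
* frameshift indel / stopgain: deleterious when the gene is rated
  haploinsufficient (rating in the accepted set, default {3}) OR the
  VEST-Indel thresholds are met.
* non-frameshift indel: deleterious when VEST-Indel score >= 0.85 and
  p-value <= 0.01 (both bounds inclusive).
* stoploss: retained unconditionally once past the gates — a read-through
  appends sequence and is taken as obviously harmful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Iterable, Mapping, Sequence

from .io import PREDICTOR_TOOLS, AnnotatedVariant, TumorGroup, VariantClass

__all__ = [
    "PredictorRule",
    "FilterConfig",
    "Route",
    "DeleteriousVerdict",
    "DEFAULT_REGISTRY",
    "DEFAULT_CONFIG",
    "gate_variant",
    "count_damaging_votes",
    "classify",
    "classify_all",
    "summarize_by_class",
]


@dataclass(frozen=True)
class PredictorRule:
    """How one tool's raw call or score is read as damaging / benign.

    Exactly one mode is populated: *categorical* rules match the call string
    against ``damaging_categories``; *threshold* rules compare a numeric
    score against ``threshold`` in the given ``direction`` (``"ge"`` means
    scores at or above the threshold are damaging).
    """

    tool: str
    mode: str  # "categorical" | "threshold"
    damaging_categories: frozenset[str] | None = None
    threshold: float | None = None
    direction: str = "ge"

    def __post_init__(self) -> None:
        if self.mode == "categorical":
            if not self.damaging_categories or self.threshold is not None:
                raise ValueError(f"{self.tool}: categorical rule needs categories only")
        elif self.mode == "threshold":
            if self.threshold is None or self.damaging_categories is not None:
                raise ValueError(f"{self.tool}: threshold rule needs a threshold only")
            if self.direction not in ("ge", "le"):
                raise ValueError(f"{self.tool}: direction must be 'ge' or 'le'")
        else:
            raise ValueError(f"{self.tool}: unknown mode {self.mode!r}")

    def is_damaging(self, call: Any) -> bool:
        """Apply the rule to a raw call; a missing call is never damaging."""
        if call is None:
            return False
        if self.mode == "categorical":
            return str(call).strip() in self.damaging_categories
        try:
            score = float(call)
        except (TypeError, ValueError):
            return False
        return score >= self.threshold if self.direction == "ge" else score <= self.threshold


def _cat(tool: str, *categories: str) -> PredictorRule:
    return PredictorRule(tool, "categorical", damaging_categories=frozenset(categories))


#: Default damaging conventions, following the dbNSFP categorical codes for
#: the call-based tools and conventional cutoffs for the score-only tools.
#: Every rule can be overridden through configuration.
DEFAULT_REGISTRY: dict[str, PredictorRule] = {
    "SIFT": _cat("SIFT", "D"),
    "Polyphen2_HDIV": _cat("Polyphen2_HDIV", "D", "P"),
    "Polyphen2_HVAR": _cat("Polyphen2_HVAR", "D", "P"),
    "LRT": _cat("LRT", "D"),
    "MutationTaster": _cat("MutationTaster", "A", "D"),
    "MutationAssessor": _cat("MutationAssessor", "H", "M"),
    "FATHMM": _cat("FATHMM", "D"),
    "PROVEAN": _cat("PROVEAN", "D"),
    "VEST3": PredictorRule("VEST3", "threshold", threshold=0.5),
    "MetaSVM": _cat("MetaSVM", "D"),
    "MetaLR": _cat("MetaLR", "D"),
    "M-CAP": _cat("M-CAP", "D"),
    "CADD": PredictorRule("CADD", "threshold", threshold=20.0),
    "FATHMM-MKL": _cat("FATHMM-MKL", "D"),
    "fitCons": PredictorRule("fitCons", "threshold", threshold=0.7),
}
assert tuple(DEFAULT_REGISTRY) == PREDICTOR_TOOLS

#: Variant classes admitted by the type gate: the four non-synonymous
#: mutation types (stopgain and stoploss counting as one type of truncating
#: point change each).
DEFAULT_ALLOWED_CLASSES = frozenset(
    {
        VariantClass.nonsynonymous_SNV,
        VariantClass.frameshift_indel,
        VariantClass.nonframeshift_indel,
        VariantClass.stopgain,
        VariantClass.stoploss,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the deleteriousness filter.

    ``min_depth_exclusive`` is strict (a depth of exactly 10 fails);
    ``max_pop_freq`` and the VEST bounds are inclusive, exactly as the
    comparators are conventionally printed.  ``missing_freq_passes``
    treats absence from ExAC_EAS as rarity.
    """

    min_depth_exclusive: int = 10
    max_pop_freq: float = 0.01
    min_votes: int = 13
    vest_score_min: float = 0.85
    vest_p_max: float = 0.01
    allowed_classes: frozenset[VariantClass] = DEFAULT_ALLOWED_CLASSES
    missing_freq_passes: bool = True
    missing_depth_passes: bool = False
    hi_ratings_accepted: frozenset[int] = frozenset({3})

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_pop_freq <= 1.0:
            raise ValueError("max_pop_freq must be in [0, 1]")
        if not 1 <= self.min_votes <= len(PREDICTOR_TOOLS) + 1:
            raise ValueError("min_votes must be in [1, 16]")
        for name, v in (("vest_score_min", self.vest_score_min),
                        ("vest_p_max", self.vest_p_max)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def replace(self, **kwargs: Any) -> "FilterConfig":
        if "allowed_classes" in kwargs:
            kwargs["allowed_classes"] = frozenset(
                VariantClass(c) for c in kwargs["allowed_classes"]
            )
        if "hi_ratings_accepted" in kwargs:
            kwargs["hi_ratings_accepted"] = frozenset(
                int(r) for r in kwargs["hi_ratings_accepted"]
            )
        return replace(self, **kwargs)


DEFAULT_CONFIG = FilterConfig()


class Route(str, Enum):
    """Which decision path produced a verdict."""

    snv_consensus = "snv_consensus"
    indel_vest = "indel_vest"
    truncation_haploinsufficiency = "truncation_haploinsufficiency"
    stoploss_retained = "stoploss_retained"
    rejected_gate = "rejected_gate"


@dataclass
class DeleteriousVerdict:
    """Classification outcome for one variant, with an auditable trail.

    ``votes_damaging`` is populated exactly when the consensus-voting route
    was taken; ``reasons`` records every criterion evaluated, in order.
    """

    variant: AnnotatedVariant
    deleterious: bool
    route: Route
    votes_damaging: int | None = None
    reasons: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GateResult:
    passed: bool
    reasons: tuple[str, ...]


def gate_variant(v: AnnotatedVariant, cfg: FilterConfig = DEFAULT_CONFIG) -> GateResult:
    """Evaluate the depth, class and population-frequency gates.

    Total function: never raises on a well-formed variant.  All three gates
    are always evaluated so the reason trail is complete even on failure.
    """
    reasons: list[str] = []
    ok = True

    if v.depth is None:
        depth_ok = cfg.missing_depth_passes
        reasons.append(f"depth missing: {'pass' if depth_ok else 'fail'}")
    else:
        depth_ok = v.depth > cfg.min_depth_exclusive
        reasons.append(
            f"depth {v.depth} > {cfg.min_depth_exclusive}: "
            f"{'pass' if depth_ok else 'fail'}"
        )
    ok &= depth_ok

    class_ok = v.variant_class in cfg.allowed_classes
    reasons.append(f"class {v.variant_class.value}: {'pass' if class_ok else 'fail'}")
    ok &= class_ok

    if v.exac_eas_freq is None:
        freq_ok = cfg.missing_freq_passes
        reasons.append(f"ExAC_EAS missing: {'pass' if freq_ok else 'fail'}")
    else:
        freq_ok = v.exac_eas_freq <= cfg.max_pop_freq
        reasons.append(
            f"ExAC_EAS {v.exac_eas_freq:g} <= {cfg.max_pop_freq:g}: "
            f"{'pass' if freq_ok else 'fail'}"
        )
    ok &= freq_ok

    return GateResult(bool(ok), tuple(reasons))


def count_damaging_votes(
    v: AnnotatedVariant,
    registry: Mapping[str, PredictorRule] = DEFAULT_REGISTRY,
) -> int:
    """Count how many registered predictors call the variant damaging.

    Missing calls contribute no vote; calls under tool names absent from the
    registry raise a warning and are ignored.
    """
    unknown = set(v.predictor_calls) - set(registry)
    if unknown:
        warnings.warn(
            f"unregistered predictor keys ignored: {sorted(unknown)}", stacklevel=2
        )
    return sum(
        1
        for tool, rule in registry.items()
        if rule.is_damaging(v.predictor_calls.get(tool))
    )


def _vest_ok(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.vest_indel_score is None or v.vest_indel_p is None:
        return False, "vest_missing"
    ok = v.vest_indel_score >= cfg.vest_score_min and v.vest_indel_p <= cfg.vest_p_max
    return ok, (
        f"VEST score {v.vest_indel_score:g} >= {cfg.vest_score_min:g} and "
        f"p {v.vest_indel_p:g} <= {cfg.vest_p_max:g}: {'pass' if ok else 'fail'}"
    )


def classify(
    v: AnnotatedVariant,
    cfg: FilterConfig = DEFAULT_CONFIG,
    registry: Mapping[str, PredictorRule] = DEFAULT_REGISTRY,
    hi_table: Mapping[str, int] | None = None,
) -> DeleteriousVerdict:
    """Full per-variant decision: gates first, then the class-specific route.

    ``hi_table`` maps gene symbol to a haploinsufficiency rating; genes
    absent from the table are treated as not established haploinsufficient
    (they may still qualify via VEST-Indel).
    """
    gate = gate_variant(v, cfg)
    reasons = list(gate.reasons)
    if not gate.passed:
        return DeleteriousVerdict(v, False, Route.rejected_gate, reasons=reasons)

    vc = v.variant_class
    if vc in (VariantClass.nonsynonymous_SNV, VariantClass.synonymous_SNV):
        # synonymous rows only reach here when explicitly allowed in config
        votes = count_damaging_votes(v, registry)
        hit = votes >= cfg.min_votes
        reasons.append(f"votes {votes} >= {cfg.min_votes}: {'pass' if hit else 'fail'}")
        return DeleteriousVerdict(v, hit, Route.snv_consensus, votes, reasons)

    if vc in (VariantClass.frameshift_indel, VariantClass.stopgain):
        rating = (hi_table or {}).get(v.gene)
        hi_ok = rating is not None and rating in cfg.hi_ratings_accepted
        reasons.append(
            f"haploinsufficiency rating {rating}: {'pass' if hi_ok else 'fail'}"
        )
        vest_ok, vest_reason = _vest_ok(v, cfg)
        reasons.append(vest_reason)
        return DeleteriousVerdict(
            v, hi_ok or vest_ok, Route.truncation_haploinsufficiency, reasons=reasons
        )

    if vc is VariantClass.nonframeshift_indel:
        vest_ok, vest_reason = _vest_ok(v, cfg)
        reasons.append(vest_reason)
        return DeleteriousVerdict(v, vest_ok, Route.indel_vest, reasons=reasons)

    if vc is VariantClass.stoploss:
        reasons.append("stoploss: retained")
        return DeleteriousVerdict(v, True, Route.stoploss_retained, reasons=reasons)

    # a class admitted by a permissive config but with no decision route
    reasons.append(f"no route for class {vc.value}: fail")
    return DeleteriousVerdict(v, False, Route.rejected_gate, reasons=reasons)


def classify_all(
    variants: Iterable[AnnotatedVariant],
    cfg: FilterConfig = DEFAULT_CONFIG,
    registry: Mapping[str, PredictorRule] = DEFAULT_REGISTRY,
    hi_table: Mapping[str, int] | None = None,
) -> list[DeleteriousVerdict]:
    return [classify(v, cfg, registry, hi_table) for v in variants]


def summarize_by_class(
    verdicts: Sequence[DeleteriousVerdict],
) -> dict[str, dict[str, int]]:
    """Counts of deleterious variants by class within each tumor group.

    Every group and class key is always present (zeros included) and class
    order is fixed, so the summary serializes deterministically.
    """
    summary: dict[str, dict[str, int]] = {}
    for group in TumorGroup:
        counts = {vc.value: 0 for vc in VariantClass}
        for verd in verdicts:
            if verd.deleterious and verd.variant.tumor_group is group:
                counts[verd.variant.variant_class.value] += 1
        counts["total"] = sum(counts.values())
        summary[group.value] = counts
    return summary
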