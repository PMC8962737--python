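"""Recurrence-based susceptible-gene identification.

Deleterious verdicts are aggregated per gene to the set of distinct
patients carrying at least one qualifying variant in each tumor group.
A gene is *susceptible* within a group when at least ``min_patients``
(default 2) distinct patients carry it there; the default ``shared`` mode
keeps genes susceptible in both the primary and the metastatic group.

In a matched-pair design each patient contributes exactly one sample per
group, so "at least two samples" and "at least two patients" coincide; a
sample-level counting unit is available for unpaired data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .classify import DeleteriousVerdict
from .io import TumorGroup

__all__ = ["GeneRecurrence", "tally_gene_patients", "call_susceptible"]


@dataclass
class GeneRecurrence:
    """Per-gene recurrence across the two tumor groups."""

    gene: str
    patients_primary: frozenset[str]
    patients_metastatic: frozenset[str]
    susceptible_primary: bool
    susceptible_metastatic: bool
    shared: bool

    @property
    def total_patients(self) -> int:
        return len(self.patients_primary) + len(self.patients_metastatic)


def tally_gene_patients(
    verdicts: Iterable[DeleteriousVerdict],
    unit: str = "patient",
) -> dict[str, tuple[frozenset[str], frozenset[str]]]:
    """Map each gene to its (primary, metastatic) carrier sets.

    Only deleterious verdicts contribute.  A carrier is counted once per
    gene per group no matter how many qualifying variants it has, so
    duplicated variant rows never change a tally.

    ``unit="sample"`` counts sample ids instead of patient ids (for
    unpaired cohorts where one patient may contribute several samples per
    group).
    """
    if unit not in ("patient", "sample"):
        raise ValueError(f"unknown counting unit {unit!r}")
    acc: dict[str, tuple[set[str], set[str]]] = {}
    for verd in verdicts:
        if not verd.deleterious:
            continue
        v = verd.variant
        carrier = v.patient_id if unit == "patient" else v.sample_id
        prim, met = acc.setdefault(v.gene, (set(), set()))
        (prim if v.tumor_group is TumorGroup.primary else met).add(carrier)
    return {
        gene: (frozenset(prim), frozenset(met))
        for gene, (prim, met) in acc.items()
    }


def call_susceptible(
    tallies: Mapping[str, tuple[frozenset[str], frozenset[str]]],
    min_patients: int = 2,
    mode: str = "shared",
) -> list[GeneRecurrence]:
    """Call susceptible genes from per-gene carrier tallies.

    ``mode="shared"`` returns genes meeting the threshold in BOTH groups;
    ``mode="either"`` returns genes meeting it in at least one group.
    Output is sorted by decreasing total carrier count, ties broken by gene
    symbol.
    """
    if min_patients < 1:
        raise ValueError("min_patients must be >= 1")
    if mode not in ("shared", "either"):
        raise ValueError(f"unknown mode {mode!r}")

    out: list[GeneRecurrence] = []
    for gene, (prim, met) in tallies.items():
        sus_p = len(prim) >= min_patients
        sus_m = len(met) >= min_patients
        keep = (sus_p and sus_m) if mode == "shared" else (sus_p or sus_m)
        if keep:
            out.append(
                GeneRecurrence(
                    gene=gene,
                    patients_primary=prim,
                    patients_metastatic=met,
                    susceptible_primary=sus_p,
                    susceptible_metastatic=sus_m,
                    shared=sus_p and sus_m,
                )
            )
    out.sort(key=lambda g: (-g.total_patients, g.gene))
    return out
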