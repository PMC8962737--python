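"""Reading and writing the tabular formats the pipeline touches.

Annotated somatic variant tables (ANNOVAR-style multianno TSV or a generic
TSV with canonical column names), per-patient clinical tables, and the
report bundle written at the end of a run.  Heterogeneous annotation
conventions are normalized into the internal data model here so that
downstream modules never see raw strings.

Coordinates are 1-based inclusive (the ANNOVAR convention).  Indels use
``"-"`` for the absent allele; both ASCII and typographic dashes are
accepted on input and normalized to ``"-"``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TumorGroup",
    "VariantClass",
    "PREDICTOR_TOOLS",
    "AnnotatedVariant",
    "ClinicalRecord",
    "VariantTableFormatError",
    "ClinicalValidationError",
    "read_variant_table",
    "read_clinical_table",
    "read_hi_table",
    "write_variant_table",
    "write_clinical_table",
    "write_report",
]

#: The fixed registry of pathogenicity predictors expected on SNV rows.
PREDICTOR_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "PROVEAN",
    "VEST3",
    "MetaSVM",
    "MetaLR",
    "M-CAP",
    "CADD",
    "FATHMM-MKL",
    "fitCons",
)

#: Strings treated as missing values on input.
MISSING_TOKENS = frozenset({".", "", "na", "n.a.", "nan", "none", "null"})

#: Dash glyphs accepted for the absent allele of an indel.
_DASHES = {"-", "–", "—", "−"}


class TumorGroup(str, Enum):
    """Which member of the matched tumor pair a sample comes from."""

    primary = "primary"
    metastatic = "metastatic"


class VariantClass(str, Enum):
    """Functional consequence classes, collapsed to filter granularity."""

    nonsynonymous_SNV = "nonsynonymous_SNV"
    synonymous_SNV = "synonymous_SNV"
    frameshift_indel = "frameshift_indel"
    nonframeshift_indel = "nonframeshift_indel"
    stopgain = "stopgain"
    stoploss = "stoploss"
    other = "other"


class VariantTableFormatError(ValueError):
    """A variant table is missing mandatory structure (named column, ...)."""


class ClinicalValidationError(ValueError):
    """A clinical table violates a validity constraint (negative DFS, ...)."""


def _norm_missing(cell: Any) -> Any:
    """Map the missing-value conventions (".", "", "N.A.", NaN) to None."""
    if cell is None:
        return None
    if isinstance(cell, float) and pd.isna(cell):
        return None
    s = str(cell).strip()
    if s.lower() in MISSING_TOKENS:
        return None
    return s


def _norm_allele(cell: Any) -> str:
    s = _norm_missing(cell)
    if s is None:
        return "-"
    return "-" if s in _DASHES else s


def _to_float(cell: Any) -> float | None:
    s = _norm_missing(cell)
    if s is None:
        return None
    try:
        return float(s)
    except (TypeError, ValueError):
        return None


def _to_int(cell: Any, default: int | None = None) -> int | None:
    v = _to_float(cell)
    if v is None:
        return default
    return int(v)


def normalize_variant_class(raw: Any) -> VariantClass:
    """Collapse an annotation string (ANNOVAR ExonicFunc or free text) to a
    :class:`VariantClass`.

    "Frameshift deletion", "frameshift insertion" and "frameshift
    substitution" all collapse to ``frameshift_indel``; the "non-"/"non"
    spelling variants are accepted.
    """
    s = _norm_missing(raw)
    if s is None:
        return VariantClass.other
    key = s.lower().replace("-", " ").replace("_", " ").strip()
    if key in ("nonsynonymous snv", "non synonymous snv", "nonsynonymous"):
        return VariantClass.nonsynonymous_SNV
    if key in ("synonymous snv", "synonymous"):
        return VariantClass.synonymous_SNV
    if key.startswith("frameshift"):
        return VariantClass.frameshift_indel
    if key.startswith(("nonframeshift", "non frameshift")):
        return VariantClass.nonframeshift_indel
    if key == "stopgain":
        return VariantClass.stopgain
    if key == "stoploss":
        return VariantClass.stoploss
    return VariantClass.other


def split_sample_id(sample_id: str) -> tuple[str, TumorGroup | None]:
    """Derive (patient_id, tumor_group) from the ``-P`` / ``-M`` suffix
    convention used for matched tumor pairs (e.g. ``Patient1-M``)."""
    s = sample_id.strip()
    upper = s.upper()
    if upper.endswith("-P"):
        return s[:-2], TumorGroup.primary
    if upper.endswith("-M"):
        return s[:-2], TumorGroup.metastatic
    return s, None


@dataclass
class AnnotatedVariant:
    """One annotated somatic variant observed in one sample.

    Carries every field the deleteriousness filter consults: locus and
    alleles, gene symbol, collapsed functional class, sequencing depth,
    East-Asian population frequency (ExAC_EAS), the raw calls/scores of the
    15 registered pathogenicity predictors, and the VEST-Indel score and
    p-value for indels.  Missing annotations are ``None``, never zero.
    """

    sample_id: str
    patient_id: str
    tumor_group: TumorGroup
    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    gene: str
    variant_class: VariantClass
    depth: int | None = None
    exac_eas_freq: float | None = None
    predictor_calls: dict[str, Any] = field(default_factory=dict)
    vest_indel_score: float | None = None
    vest_indel_p: float | None = None
    aa_change: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"variant {self.chrom}:{self.start}-{self.end}: start > end"
            )
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")
        for name, value in (
            ("exac_eas_freq", self.exac_eas_freq),
            ("vest_indel_score", self.vest_indel_score),
            ("vest_indel_p", self.vest_indel_p),
        ):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} outside [0, 1]")

    @property
    def locus_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.start, self.ref, self.alt)


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and the disease-free survival time.

    ``dfs_months`` is the months from initial treatment to relapse (or to
    last follow-up when ``event`` is False).  Receptor statuses are kept as
    the free-text grades of the source table (``-``, ``+``, ``++`` ...).
    """

    patient_id: str
    dfs_months: float
    age: float | None = None
    tnm: str | None = None
    er: str | None = None
    pr: str | None = None
    her2: str | None = None
    event: bool = True

    def __post_init__(self) -> None:
        if self.dfs_months < 0:
            raise ClinicalValidationError(
                f"patient {self.patient_id}: negative DFS {self.dfs_months}"
            )


# ---------------------------------------------------------------------------
# Dialects: canonical field -> column name, plus predictor tool -> column.
# ---------------------------------------------------------------------------

GENERIC_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "tumor_group": "tumor_group",
    "patient_id": "patient_id",
    "chrom": "chrom",
    "start": "start",
    "end": "end",
    "ref": "ref",
    "alt": "alt",
    "gene": "gene",
    "variant_class": "variant_class",
    "depth": "depth",
    "exac_eas_freq": "exac_eas_freq",
    "vest_indel_score": "vest_indel_score",
    "vest_indel_p": "vest_indel_p",
    "aa_change": "aa_change",
}
GENERIC_PREDICTOR_COLUMNS: dict[str, str] = {t: t for t in PREDICTOR_TOOLS}

# Column names as emitted by table_annovar with dbNSFP; the depth and sample
# columns are the conventional additions when per-sample tables are exported.
ANNOVAR_COLUMNS: dict[str, str] = {
    "sample_id": "Sample",
    "tumor_group": "Tumor_Group",
    "patient_id": "Patient",
    "chrom": "Chr",
    "start": "Start",
    "end": "End",
    "ref": "Ref",
    "alt": "Alt",
    "gene": "Gene.refGene",
    "variant_class": "ExonicFunc.refGene",
    "depth": "DP",
    "exac_eas_freq": "ExAC_EAS",
    "vest_indel_score": "VEST_indel_score",
    "vest_indel_p": "VEST_indel_pvalue",
    "aa_change": "AAChange.refGene",
}
ANNOVAR_PREDICTOR_COLUMNS: dict[str, str] = {
    "SIFT": "SIFT_pred",
    "Polyphen2_HDIV": "Polyphen2_HDIV_pred",
    "Polyphen2_HVAR": "Polyphen2_HVAR_pred",
    "LRT": "LRT_pred",
    "MutationTaster": "MutationTaster_pred",
    "MutationAssessor": "MutationAssessor_pred",
    "FATHMM": "FATHMM_pred",
    "PROVEAN": "PROVEAN_pred",
    "VEST3": "VEST3_score",
    "MetaSVM": "MetaSVM_pred",
    "MetaLR": "MetaLR_pred",
    "M-CAP": "M-CAP_pred",
    "CADD": "CADD_phred",
    "FATHMM-MKL": "fathmm-MKL_coding_pred",
    "fitCons": "integrated_fitCons_score",
}

DIALECTS: dict[str, tuple[dict[str, str], dict[str, str]]] = {
    "generic_tsv": (GENERIC_COLUMNS, GENERIC_PREDICTOR_COLUMNS),
    "annovar_multianno": (ANNOVAR_COLUMNS, ANNOVAR_PREDICTOR_COLUMNS),
}

_MANDATORY_FIELDS = ("sample_id", "chrom", "start", "end", "gene", "variant_class")


def read_variant_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    column_map: Mapping[str, str] | None = None,
    predictor_column_map: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> list[AnnotatedVariant]:
    """Read an annotated variant table into :class:`AnnotatedVariant` rows.

    Parameters
    ----------
    path
        TSV/CSV file with a header row.
    dialect
        ``"generic_tsv"`` (canonical column names) or
        ``"annovar_multianno"`` (ANNOVAR/dbNSFP column names).
    column_map, predictor_column_map
        Overrides for individual columns, merged on top of the dialect
        defaults (canonical field -> column, tool -> column).

    Unparseable numeric cells and the tokens ``"."``/empty/``"N.A."``
    become missing, never zero.  Rows duplicated on
    (sample, chrom, start, ref, alt) raise a warning and keep the first.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; options: {sorted(DIALECTS)}")
    cols, pred_cols = DIALECTS[dialect]
    cols = {**cols, **(column_map or {})}
    pred_cols = {**pred_cols, **(predictor_column_map or {})}

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    for fld in _MANDATORY_FIELDS:
        if cols[fld] not in df.columns:
            raise VariantTableFormatError(
                f"mandatory column {cols[fld]!r} (field {fld!r}) absent from {path}"
            )

    def cell(row: pd.Series, fld: str) -> Any:
        col = cols.get(fld)
        return row[col] if col in df.columns else None

    variants: list[AnnotatedVariant] = []
    seen: set[tuple[str, str, int, str, str]] = set()
    for idx, row in df.iterrows():
        sample_id = _norm_missing(cell(row, "sample_id"))
        if sample_id is None:
            warnings.warn(f"{path}: row {idx}: empty sample id, row skipped")
            continue
        derived_patient, derived_group = split_sample_id(sample_id)

        group_cell = _norm_missing(cell(row, "tumor_group"))
        if group_cell is not None:  # explicit column overrides the suffix
            tumor_group = TumorGroup(group_cell.lower())
        elif derived_group is not None:
            tumor_group = derived_group
        else:
            warnings.warn(
                f"{path}: row {idx}: sample {sample_id!r} has no -P/-M suffix "
                "and no tumor_group column, row skipped"
            )
            continue
        patient_cell = _norm_missing(cell(row, "patient_id"))
        patient_id = patient_cell if patient_cell is not None else derived_patient

        start = _to_int(cell(row, "start"))
        end = _to_int(cell(row, "end"))
        if start is None or end is None:
            warnings.warn(f"{path}: row {idx}: unparseable coordinates, row skipped")
            continue

        calls: dict[str, Any] = {}
        for tool, col in pred_cols.items():
            if col not in df.columns:
                continue
            raw = _norm_missing(row[col])
            if raw is None:
                continue
            try:
                calls[tool] = float(raw)
            except ValueError:
                calls[tool] = raw

        v = AnnotatedVariant(
            sample_id=sample_id,
            patient_id=patient_id,
            tumor_group=tumor_group,
            chrom=str(_norm_missing(cell(row, "chrom"))),
            start=start,
            end=end,
            ref=_norm_allele(cell(row, "ref")),
            alt=_norm_allele(cell(row, "alt")),
            gene=str(_norm_missing(cell(row, "gene"))),
            variant_class=normalize_variant_class(cell(row, "variant_class")),
            depth=_to_int(cell(row, "depth")),
            exac_eas_freq=_to_float(cell(row, "exac_eas_freq")),
            predictor_calls=calls,
            vest_indel_score=_to_float(cell(row, "vest_indel_score")),
            vest_indel_p=_to_float(cell(row, "vest_indel_p")),
            aa_change=_norm_missing(cell(row, "aa_change")),
        )
        if v.locus_key in seen:
            warnings.warn(
                f"{path}: duplicated variant row {v.locus_key}; keeping first"
            )
            continue
        seen.add(v.locus_key)
        variants.append(v)
    return variants


def write_variant_table(
    variants: Iterable[AnnotatedVariant], path: str | Path
) -> None:
    """Write variants as a generic-dialect TSV (round-trips losslessly)."""
    rows = []
    for v in variants:
        row: dict[str, Any] = {
            "sample_id": v.sample_id,
            "patient_id": v.patient_id,
            "tumor_group": v.tumor_group.value,
            "chrom": v.chrom,
            "start": v.start,
            "end": v.end,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene,
            "variant_class": v.variant_class.value,
            "depth": "." if v.depth is None else v.depth,
            "exac_eas_freq": "." if v.exac_eas_freq is None else repr(v.exac_eas_freq),
            "vest_indel_score": "."
            if v.vest_indel_score is None
            else repr(v.vest_indel_score),
            "vest_indel_p": "." if v.vest_indel_p is None else repr(v.vest_indel_p),
            "aa_change": "." if v.aa_change is None else v.aa_change,
        }
        for tool in PREDICTOR_TOOLS:
            call = v.predictor_calls.get(tool)
            row[tool] = "." if call is None else (
                repr(call) if isinstance(call, float) else str(call)
            )
        rows.append(row)
    columns = list(GENERIC_COLUMNS) + list(PREDICTOR_TOOLS)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

_CLINICAL_ALIASES: dict[str, tuple[str, ...]] = {
    "patient_id": ("patient_id", "sample id", "sample_id", "patient"),
    "age": ("age",),
    "tnm": ("tnm", "tnm of initial diagnosis"),
    "er": ("er",),
    "pr": ("pr",),
    "her2": ("her2",),
    "dfs_months": ("dfs_months", "dfs (months)", "dfs"),
    "event": ("event", "relapse"),
}


def read_clinical_table(path: str | Path, sep: str = "\t") -> list[ClinicalRecord]:
    """Read a per-patient clinical table.

    Columns are matched case-insensitively against the conventional names
    (``patient_id``/``Sample ID``, ``Age``, ``TNM``, ``ER``, ``PR``,
    ``HER2``, ``DFS (months)``, optional ``event``).  ``N.A.`` maps to
    missing; when no event column exists every relapse is assumed observed,
    which is the design of a recurrence cohort.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    lower = {c.lower().strip(): c for c in df.columns}

    def col_for(fld: str) -> str | None:
        for alias in _CLINICAL_ALIASES[fld]:
            if alias in lower:
                return lower[alias]
        return None

    for fld in ("patient_id", "dfs_months"):
        if col_for(fld) is None:
            raise VariantTableFormatError(
                f"mandatory clinical column for {fld!r} absent from {path}"
            )

    records: list[ClinicalRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        pid = _norm_missing(row[col_for("patient_id")])
        if pid is None:
            continue
        if pid in seen:
            raise ClinicalValidationError(f"duplicate patient id {pid!r}")
        seen.add(pid)

        def get(fld: str) -> Any:
            c = col_for(fld)
            return _norm_missing(row[c]) if c is not None else None

        dfs = _to_float(row[col_for("dfs_months")])
        if dfs is None:
            raise ClinicalValidationError(f"patient {pid!r}: missing DFS")
        event_raw = get("event")
        event = True
        if event_raw is not None:
            event = str(event_raw).strip().lower() in ("1", "true", "yes", "relapse")
        records.append(
            ClinicalRecord(
                patient_id=pid,
                dfs_months=dfs,
                age=_to_float(row[col_for("age")]) if col_for("age") else None,
                tnm=get("tnm"),
                er=get("er"),
                pr=get("pr"),
                her2=get("her2"),
                event=event,
            )
        )
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "age": "." if r.age is None else repr(r.age),
            "tnm": "." if r.tnm is None else r.tnm,
            "er": "." if r.er is None else r.er,
            "pr": "." if r.pr is None else r.pr,
            "her2": "." if r.her2 is None else r.her2,
            "dfs_months": repr(float(r.dfs_months)),
            "event": int(r.event),
        }
        for r in records
    ]
    cols = ["patient_id", "age", "tnm", "er", "pr", "her2", "dfs_months", "event"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_hi_table(path: str | Path, sep: str = "\t") -> dict[str, int]:
    """Read a two-column gene -> haploinsufficiency-rating table."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise VariantTableFormatError(f"{path}: expected two columns (gene, rating)")
    gene_col, rating_col = df.columns[:2]
    table: dict[str, int] = {}
    for _, row in df.iterrows():
        gene = _norm_missing(row[gene_col])
        rating = _to_int(row[rating_col])
        if gene is not None and rating is not None:
            table[gene] = rating
    return table


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def write_report(
    verdicts: Sequence,
    recurrences: Sequence,
    survival_results: Sequence,
    path: str | Path,
) -> dict[str, Path]:
    """Write the machine-readable report bundle for a run.

    Produces, under directory *path*:

    ``summary.json``
        counts of deleterious variants by class and tumor group, the
        susceptible-gene list, and the survival test statistics;
    ``variants_audit.tsv``
        one row per classified variant with its verdict, route, vote count
        and ordered reason trail;
    ``genes.tsv``
        per-gene patient counts and susceptibility flags.

    Output is deterministic: byte-identical across runs on equal input.
    """
    # local import: classify/recurrence/survival all import the data model
    # from this module, so the report writer binds to them lazily.
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    audit_rows = []
    for verd in verdicts:
        v = verd.variant
        audit_rows.append(
            {
                "sample_id": v.sample_id,
                "patient_id": v.patient_id,
                "tumor_group": v.tumor_group.value,
                "chrom": v.chrom,
                "start": v.start,
                "end": v.end,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "variant_class": v.variant_class.value,
                "deleterious": int(verd.deleterious),
                "route": verd.route.value,
                "votes_damaging": "."
                if verd.votes_damaging is None
                else verd.votes_damaging,
                "reasons": ";".join(verd.reasons),
            }
        )
    audit_cols = [
        "sample_id", "patient_id", "tumor_group", "chrom", "start", "end",
        "ref", "alt", "gene", "variant_class", "deleterious", "route",
        "votes_damaging", "reasons",
    ]
    audit_path = out / "variants_audit.tsv"
    pd.DataFrame(audit_rows, columns=audit_cols).to_csv(
        audit_path, sep="\t", index=False
    )

    gene_rows = [
        {
            "gene": g.gene,
            "n_primary": len(g.patients_primary),
            "n_metastatic": len(g.patients_metastatic),
            "susceptible_primary": int(g.susceptible_primary),
            "susceptible_metastatic": int(g.susceptible_metastatic),
            "shared": int(g.shared),
        }
        for g in recurrences
    ]
    genes_path = out / "genes.tsv"
    pd.DataFrame(
        gene_rows,
        columns=[
            "gene", "n_primary", "n_metastatic",
            "susceptible_primary", "susceptible_metastatic", "shared",
        ],
    ).to_csv(genes_path, sep="\t", index=False)

    from .classify import summarize_by_class  # deferred: avoids import cycle

    summary = {
        "n_variants": len(verdicts),
        "n_deleterious": sum(1 for vr in verdicts if vr.deleterious),
        "deleterious_by_class": summarize_by_class(verdicts),
        "genes": gene_rows,
        "susceptible_genes": [g.gene for g in recurrences if g.shared],
        "survival": [
            {
                "gene": s.gene,
                "n_mutant": len(s.group_mutant),
                "n_wildtype": len(s.group_wildtype),
                "mean_mutant": s.mean_mutant,
                "mean_wildtype": s.mean_wildtype,
                "u_statistic": s.u_statistic,
                "p_two_tailed": s.p_two_tailed,
                "method": s.method,
            }
            for s in survival_results
        ],
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return {"summary": summary_path, "audit": audit_path, "genes": genes_path}
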