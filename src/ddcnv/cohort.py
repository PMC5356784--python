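"""Cohort-level summaries and association tests for the 36-sample series.

The packaged fixture transcribes the published clinical table: 12 DNT
(dysembryoplastic neuroepithelial tumor), 2 PTO, 3 PDA, 14 GG and 5 PA, each
with BRAF V600E status, the ddPCR duplication call, p-FGFR1
immunohistochemistry and FGFR1 exon 12/14 sequencing results.  The
summaries reproduce the headline cohort arithmetic — duplication in 5/12
DNT (41.7%), 13 BRAF V600E carriers, a single FGFR1 missense carrier, the
MAPK-pathway alteration fraction per diagnosis, and the mutual exclusivity
of BRAF V600E and FGFR1 alterations — and the diagnosis×duplication
association is tested with Fisher's exact test (2×2) or chi-square (r×2).

"FGFR1 alteration" means duplication or a missense point mutation; silent
substitutions (same residue, e.g. L548L) are parsed but not counted as
activating.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, SchemaError

__all__ = [
    "DIAGNOSES",
    "CohortRecord",
    "CohortSummary",
    "AssociationResult",
    "classify_mutation",
    "load_cohort",
    "summarize_cohort",
    "association_test",
]

DIAGNOSES = ("DNT", "PTO", "PDA", "GG", "PA")
_BRAF_VALUES = {"V600E": "V600E", "Non-mutated": "non_mutated", "NA": "unknown"}
_DUP_VALUES = {"Yes": "yes", "No": "no", "Inconclusive": "inconclusive"}
_IHC_VALUES = {"Positive": "positive", "+/-": "plus_minus", "Negative": "negative", "NA": "NA"}
_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z*])$")


@dataclass(frozen=True)
class CohortRecord:
    """One row of the clinical table (follow-up fields carried in ``extras``)."""

    sample_id: str
    diagnosis: str
    braf_status: str
    fgfr1_duplication: str
    fgfr1_exon12: str
    fgfr1_exon14: str
    ihc_pfgfr1: str
    extras: dict = field(default_factory=dict)

    @property
    def has_missense(self) -> bool:
        return "missense" in (
            classify_mutation(self.fgfr1_exon12),
            classify_mutation(self.fgfr1_exon14),
        )

    @property
    def has_fgfr1_alteration(self) -> bool:
        """Duplication or missense point mutation (silent changes excluded)."""
        return self.fgfr1_duplication == "yes" or self.has_missense

    @property
    def mapk_altered(self) -> bool:
        """Any MAPK-pathway alteration: BRAF V600E or an FGFR1 alteration."""
        return self.braf_status == "V600E" or self.has_fgfr1_alteration


@dataclass(frozen=True)
class CohortSummary:
    """Deterministic cohort arithmetic (counts, percentages, exclusivity)."""

    n: int
    duplication_by_diagnosis: dict
    duplication_pct_by_diagnosis: dict
    braf_count: int
    braf_by_diagnosis: dict
    missense_carriers: tuple[str, ...]
    mapk_altered_fraction: dict
    exclusivity_overlap: int


@dataclass(frozen=True)
class AssociationResult:
    table: tuple
    statistic: Optional[float]
    p_value: float
    method: str


def classify_mutation(value: str) -> str:
    """Classify a free-text mutation field.

    Returns one of ``missense``, ``silent``, ``non_mutated``, ``unknown``.
    A token like G539R is missense; L548L (reference and variant residue
    identical) is silent.
    """
    v = (value or "").strip()
    if v in ("", "NA", "nan"):
        return "unknown"
    if v.lower() in ("non-mutated", "non_mutated"):
        return "non_mutated"
    m = _MUTATION_RE.match(v)
    if m:
        return "silent" if m.group(1) == m.group(3) else "missense"
    raise SchemaError(f"unrecognized mutation annotation: {value!r}")


def _fixture_path():
    return resources.files("ddcnv").joinpath("data/table1.csv")


def load_cohort(path=None) -> list[CohortRecord]:
    """Load a clinical sample table; defaults to the packaged transcription.

    Required columns: ``patient, braf_status, fgfr1_duplication, ihc_pfgfr1,
    fgfr1_exon12, fgfr1_exon14`` (any others are carried through as extras).
    The diagnosis is the letter prefix of the patient id and must be one of
    DNT/PTO/PDA/GG/PA.  Closed-vocabulary violations raise
    :class:`SchemaError` naming the row and column.
    """
    source = _fixture_path() if path is None else path
    try:
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("cohort table is empty") from exc
    required = ["patient", "braf_status", "fgfr1_duplication", "ihc_pfgfr1",
                "fgfr1_exon12", "fgfr1_exon14"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    if len(df) == 0:
        raise SchemaError("cohort table has a header but no rows")
    records = []
    for idx, row in df.iterrows():
        sample_id = row["patient"].strip()
        m = re.match(r"^([A-Za-z]+)", sample_id)
        diagnosis = m.group(1).upper() if m else ""
        if diagnosis not in DIAGNOSES:
            raise SchemaError(f"row {idx} (patient): unknown diagnosis prefix in {sample_id!r}")

        def decode(column: str, mapping: dict) -> str:
            raw = row[column].strip()
            if raw not in mapping:
                raise SchemaError(
                    f"row {idx} ({column}): value {raw!r} not in {sorted(mapping)}"
                )
            return mapping[raw]

        rec = CohortRecord(
            sample_id=sample_id,
            diagnosis=diagnosis,
            braf_status=decode("braf_status", _BRAF_VALUES),
            fgfr1_duplication=decode("fgfr1_duplication", _DUP_VALUES),
            fgfr1_exon12=row["fgfr1_exon12"].strip(),
            fgfr1_exon14=row["fgfr1_exon14"].strip(),
            ihc_pfgfr1=decode("ihc_pfgfr1", _IHC_VALUES),
            extras={c: row[c] for c in df.columns if c not in required},
        )
        # validate the free-text mutation fields eagerly
        classify_mutation(rec.fgfr1_exon12)
        classify_mutation(rec.fgfr1_exon14)
        records.append(rec)
    return records


def summarize_cohort(records: Sequence[CohortRecord]) -> CohortSummary:
    """Cohort summary statistics.

    Duplication percentages use the full per-diagnosis denominator (the
    inconclusive sample counts against the denominator but not the
    numerator, matching 5/12 = 41.7% for DNT).  The MAPK-altered fraction
    is the per-diagnosis share of samples with BRAF V600E, duplication or an
    FGFR1 missense mutation; the exclusivity overlap counts samples carrying
    both BRAF V600E and an FGFR1 alteration.
    """
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    dup_by_dx: dict = {}
    pct_by_dx: dict = {}
    braf_by_dx: dict = {}
    mapk_by_dx: dict = {}
    for dx in DIAGNOSES:
        group = [r for r in records if r.diagnosis == dx]
        if not group:
            continue
        n = len(group)
        counts = {
            "n": n,
            "yes": sum(r.fgfr1_duplication == "yes" for r in group),
            "no": sum(r.fgfr1_duplication == "no" for r in group),
            "inconclusive": sum(r.fgfr1_duplication == "inconclusive" for r in group),
        }
        dup_by_dx[dx] = counts
        pct_by_dx[dx] = 100.0 * counts["yes"] / n
        braf_by_dx[dx] = sum(r.braf_status == "V600E" for r in group)
        mapk_by_dx[dx] = sum(r.mapk_altered for r in group) / n
    return CohortSummary(
        n=len(records),
        duplication_by_diagnosis=dup_by_dx,
        duplication_pct_by_diagnosis=pct_by_dx,
        braf_count=sum(r.braf_status == "V600E" for r in records),
        braf_by_diagnosis=braf_by_dx,
        missense_carriers=tuple(r.sample_id for r in records if r.has_missense),
        mapk_altered_fraction=mapk_by_dx,
        exclusivity_overlap=sum(
            r.braf_status == "V600E" and r.has_fgfr1_alteration for r in records
        ),
    )


def _contingency(records, grouping: str, call_handling: str):
    if call_handling == "exclude_inconclusive":
        records = [r for r in records if r.fgfr1_duplication != "inconclusive"]
        as_yes = lambda r: r.fgfr1_duplication == "yes"
    elif call_handling == "as_negative":
        as_yes = lambda r: r.fgfr1_duplication == "yes"
    else:
        raise ValueError("call_handling must be exclude_inconclusive or as_negative")
    if grouping == "dnt_vs_rest":
        groups = [
            [r for r in records if r.diagnosis == "DNT"],
            [r for r in records if r.diagnosis != "DNT"],
        ]
    elif grouping == "by_diagnosis":
        groups = [[r for r in records if r.diagnosis == dx] for dx in DIAGNOSES]
        groups = [g for g in groups if g]
    else:
        raise ValueError("grouping must be dnt_vs_rest or by_diagnosis")
    table = [
        (sum(as_yes(r) for r in g), sum(not as_yes(r) for r in g)) for g in groups
    ]
    rows_ok = all(sum(row) > 0 for row in table)
    cols_ok = all(sum(col) > 0 for col in zip(*table))
    if len(table) < 2 or not rows_ok or not cols_ok:
        raise DegenerateTableError(f"contingency table has an empty margin: {table}")
    return tuple(table)


def association_test(
    records: Sequence[CohortRecord],
    grouping: str = "dnt_vs_rest",
    call_handling: str = "exclude_inconclusive",
) -> AssociationResult:
    """Two-sided test of diagnosis × duplication-status association.

    ``dnt_vs_rest`` builds a 2×2 table and uses Fisher's exact test;
    ``by_diagnosis`` builds an r×2 table and uses the chi-square test.
    ``call_handling`` controls whether the inconclusive sample is dropped
    from the denominators or counted as non-duplicated.
    """
    table = _contingency(list(records), grouping, call_handling)
    if len(table) == 2:
        res = stats.fisher_exact(table, alternative="two-sided")
        return AssociationResult(table, None, float(res.pvalue), "fisher_exact")
    chi2 = stats.chi2_contingency(table, correction=False)
    return AssociationResult(table, float(chi2.statistic), float(chi2.pvalue), "chi_square")
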