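"""MHC-affinity cutoff auditing.

Most prediction-first neoantigen screens discard peptides whose predicted
MHC I binding IC50 exceeds 500 nM.  Given a table of predicted affinities and
the set of peptides that were *functionally* validated (elicited IFN-γ in
vitro), this module measures how efficiently that cutoff would have captured
the validated epitopes — i.e. what fraction of true positives a
prediction-first protocol retains.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PredictionRecord",
    "EfficiencyResult",
    "apply_affinity_cutoff",
    "screening_efficiency",
    "read_prediction_table",
]


class AuditError(ValueError):
    """Invalid prediction-audit input."""


@dataclass(frozen=True)
class PredictionRecord:
    """One predicted peptide–MHC affinity (IC50 in nM; lower binds stronger)."""

    peptide_id: str
    sequence: str
    allele: str
    ic50_nm: float

    def __post_init__(self) -> None:
        if not self.ic50_nm > 0:
            raise AuditError(
                f"prediction for {self.peptide_id!r}: ic50_nm must be positive, "
                f"got {self.ic50_nm}"
            )


@dataclass(frozen=True)
class EfficiencyResult:
    """Cutoff capture efficiency over the validated epitope set.

    ``percent`` is truncated to a whole percent for reporting; ``fraction``
    preserves the exact ratio captured/validated.
    """

    percent: int
    fraction: Fraction
    n_captured: int
    n_validated: int
    captured_ids: tuple
    missed_ids: tuple


def apply_affinity_cutoff(
    records: Sequence[PredictionRecord], cutoff_nm: float = 500.0
) -> tuple[list[PredictionRecord], list[PredictionRecord]]:
    """Partition records into (pass, fail) at the cutoff; boundary values pass.

    Both lists preserve input order.
    """
    if not cutoff_nm > 0:
        raise AuditError(f"cutoff_nm must be positive, got {cutoff_nm}")
    passed = [r for r in records if r.ic50_nm <= cutoff_nm]
    failed = [r for r in records if r.ic50_nm > cutoff_nm]
    return passed, failed


def screening_efficiency(
    validated_ids: Iterable[str],
    records: Sequence[PredictionRecord],
    cutoff_nm: float = 500.0,
) -> EfficiencyResult:
    """Percentage of functionally validated epitopes the affinity cutoff retains.

    Every validated id must have a prediction record.  The headline percentage
    is truncated toward zero (2/3 reports as 66); the exact fraction is also
    returned.
    """
    validated = list(dict.fromkeys(str(v) for v in validated_ids))
    if not validated:
        raise AuditError("validated_ids must be non-empty")
    by_id: dict[str, PredictionRecord] = {}
    for r in records:
        by_id.setdefault(r.peptide_id, r)
    missing = [v for v in validated if v not in by_id]
    if missing:
        raise AuditError(f"validated ids without prediction records: {missing}")
    passed, _ = apply_affinity_cutoff([by_id[v] for v in validated], cutoff_nm)
    captured = [r.peptide_id for r in passed]
    missed = [v for v in validated if v not in set(captured)]
    frac = Fraction(len(captured), len(validated))
    return EfficiencyResult(
        percent=int(100 * len(captured)) // len(validated),
        fraction=frac,
        n_captured=len(captured),
        n_validated=len(validated),
        captured_ids=tuple(captured),
        missed_ids=tuple(missed),
    )


def read_prediction_table(path) -> list[PredictionRecord]:
    """Read a tab-delimited table: peptide_id, sequence, allele, ic50_nm."""
    df = pd.read_csv(path, sep="\t")
    needed = {"peptide_id", "sequence", "allele", "ic50_nm"}
    missing = needed - set(df.columns)
    if missing:
        raise AuditError(f"prediction table is missing columns: {sorted(missing)}")
    return [
        PredictionRecord(
            peptide_id=str(r["peptide_id"]),
            sequence=str(r["sequence"]),
            allele=str(r["allele"]),
            ic50_nm=float(r["ic50_nm"]),
        )
        for r in df.to_dict("records")
    ]
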