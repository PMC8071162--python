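"""Subject-level score assembly, FIB-4 and fibrosis staging.

The combined imaging score is the product L_Het x L_Nod. Repeated
measurements of one subject are averaged field-wise (the combined score
is recomputed from the averaged factors, not averaged itself). The
FIB-4 serologic index,

    FIB-4 = (age [y] * AST [U/L]) / (platelets [10^9/L] * sqrt(ALT [U/L])),

assigns the fibrosis stage used as the reference standard:
mild (F1) below 1.45, significant (F2) from 1.45 to 3.25 inclusive,
advanced (F3) above 3.25. F0 (no fibrosis) cannot be produced by FIB-4;
it is an external, biopsy-proven label.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DomainError, IdentityError

FIB4_LOW = 1.45
FIB4_HIGH = 3.25
STAGES = ("F0", "F1", "F2", "F3")


@dataclass
class ClinicalRecord:
    """Serologic inputs to FIB-4; all strictly positive."""

    age_years: float
    ast_u_per_l: float
    alt_u_per_l: float
    platelets_1e9_per_l: float

    def __post_init__(self) -> None:
        for name in ("age_years", "ast_u_per_l", "alt_u_per_l", "platelets_1e9_per_l"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass
class SubjectScores:
    subject_id: str
    lhet: float
    lnod: float
    combined: float
    n_measurements: int = 1
    fib4: Optional[float] = None
    stage: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lhet < 0 or self.lnod < 0:
            raise DomainError("scores must be non-negative")
        if self.stage is not None and self.stage not in STAGES:
            raise DomainError(f"stage must be one of {STAGES}, got {self.stage!r}")


def combined_score(lhet: float, lnod: float) -> float:
    """Product of the heterogeneity and nodularity scores."""
    if lhet < 0 or lnod < 0:
        raise DomainError("scores must be non-negative")
    return lhet * lnod


def make_subject_scores(
    subject_id: str,
    lhet: float,
    lnod: float,
    n_measurements: int = 1,
    fib4: Optional[float] = None,
    biopsy_f0: bool = False,
) -> SubjectScores:
    """Assemble a SubjectScores record, staging from FIB-4 when given."""
    stage = None
    if biopsy_f0:
        stage = "F0"
    elif fib4 is not None:
        stage = stage_from_fib4(fib4)
    return SubjectScores(
        subject_id=subject_id,
        lhet=lhet,
        lnod=lnod,
        combined=combined_score(lhet, lnod),
        n_measurements=n_measurements,
        fib4=fib4,
        stage=stage,
    )


def average_measurements(scores: list[SubjectScores]) -> SubjectScores:
    """Average repeated measurements of one subject.

    L_Het and L_Nod are averaged arithmetically; the combined score is
    recomputed from the averaged factors.
    """
    if not scores:
        raise IdentityError("no measurements to average")
    ids = {s.subject_id for s in scores}
    if len(ids) != 1:
        raise IdentityError(f"measurements span multiple subjects: {sorted(ids)}")
    lhet = float(np.mean([s.lhet for s in scores]))
    lnod = float(np.mean([s.lnod for s in scores]))
    return replace(
        scores[0],
        lhet=lhet,
        lnod=lnod,
        combined=combined_score(lhet, lnod),
        n_measurements=len(scores),
    )


def compute_fib4(rec: ClinicalRecord) -> float:
    """FIB-4 = (age * AST) / (platelets * sqrt(ALT))."""
    return (rec.age_years * rec.ast_u_per_l) / (
        rec.platelets_1e9_per_l * np.sqrt(rec.alt_u_per_l)
    )


def stage_from_fib4(fib4: float) -> str:
    """Map a FIB-4 value to a fibrosis stage label.

    Below 1.45 is F1 (mild); 1.45 through 3.25 inclusive is F2
    (significant); above 3.25 is F3 (advanced). F0 is never returned.
    """
    if fib4 < 0:
        raise DomainError("FIB-4 must be non-negative")
    if fib4 < FIB4_LOW:
        return "F1"
    if fib4 <= FIB4_HIGH:
        return "F2"
    return "F3"
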