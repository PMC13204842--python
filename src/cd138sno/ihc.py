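"""Compartment-specific CD138 immunohistochemistry scoring and grouping.

CD138 (syndecan-1) staining is graded separately in the tumor epithelial and
stromal compartments on the usual semi-quantitative 0-3+ intensity scale
(0 negative, 1+ weak, 2+ moderate, 3+ strong) together with the percentage of
positive cells/area. Each compartment is dichotomized on intensity — tumor
positive at scores 2-3, stroma positive at scores 1-3, cutoffs selected by
ROC analysis against the recurrence endpoint — and the two binary calls
define four groups:

    Group 0  tumor(-) / stroma(-)
    Group 1  tumor(+) / stroma(-)   (the aggressive phenotype)
    Group 2  tumor(-) / stroma(+)
    Group 3  tumor(+) / stroma(+)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_TUMOR_CUT = 2
DEFAULT_STROMA_CUT = 1

VALID_INTENSITIES = frozenset({0, 1, 2, 3})


class CD138Group(IntEnum):
    GROUP0 = 0
    GROUP1 = 1
    GROUP2 = 2
    GROUP3 = 3


# (tumor_positive, stroma_positive) -> group
_GROUP_BY_POSITIVITY = {
    (False, False): CD138Group.GROUP0,
    (True, False): CD138Group.GROUP1,
    (False, True): CD138Group.GROUP2,
    (True, True): CD138Group.GROUP3,
}


@dataclass(frozen=True)
class IHCObservation:
    """One compartment's CD138 staining read-out for one case."""

    case_id: str
    compartment: str  # "tumor" | "stroma"
    intensity: int
    proportion: float = 0.0
    localization: Optional[frozenset] = None  # e.g. {"membranous","nuclear"}

    def __post_init__(self) -> None:
        if self.compartment not in ("tumor", "stroma"):
            raise ValueError(f"compartment must be tumor|stroma, got {self.compartment!r}")
        _validate_intensity(self.intensity, self.compartment)
        if not 0.0 <= self.proportion <= 100.0:
            raise ValueError(f"proportion must be in [0, 100], got {self.proportion}")
        if self.intensity == 0 and self.proportion != 0:
            raise ValueError("intensity 0 implies proportion 0")


@dataclass(frozen=True)
class CD138Class:
    group: CD138Group
    tumor_positive: bool
    stroma_positive: bool


@dataclass
class CutoffResult:
    """An ROC-derived binary cutoff: positive iff score >= threshold."""

    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    roc_points: list = field(default_factory=list)  # (threshold, sens, spec)


def _validate_intensity(value, compartment: str) -> int:
    iv = int(value)
    if iv != value or iv not in VALID_INTENSITIES:
        raise ValueError(
            f"{compartment} intensity must be one of 0,1,2,3, got {value!r}"
        )
    return iv


def classify_case(
    tumor_intensity: int,
    stroma_intensity: int,
    tumor_cut: int = DEFAULT_TUMOR_CUT,
    stroma_cut: int = DEFAULT_STROMA_CUT,
) -> CD138Class:
    """Assign the four-group CD138 class from the two compartment intensities.

    With the default cutoffs, tumor is positive at intensity 2-3 and stroma at
    1-3. The proportion of positive cells is recorded upstream but plays no
    role in the binary rule, which is defined on intensity scores only.
    """
    t = _validate_intensity(tumor_intensity, "tumor")
    s = _validate_intensity(stroma_intensity, "stroma")
    tumor_positive = t >= tumor_cut
    stroma_positive = s >= stroma_cut
    return CD138Class(
        group=_GROUP_BY_POSITIVITY[(tumor_positive, stroma_positive)],
        tumor_positive=tumor_positive,
        stroma_positive=stroma_positive,
    )


def derive_cutoff_youden(scores: Sequence[float], outcome: Sequence[int]) -> CutoffResult:
    """Choose the binary cutoff on ``scores`` that maximizes Youden's J.

    Candidate thresholds are the distinct observed score values under the rule
    "positive iff score >= threshold", with the event class of ``outcome`` as
    the positive class. J = sensitivity + specificity - 1; ties are broken
    toward the smallest threshold (the more sensitive cutoff).
    """
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if scores.shape != outcome.shape or scores.ndim != 1:
        raise ValueError("scores and outcome must be 1-D and of equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if set(np.unique(outcome)) - {0, 1}:
        raise ValueError("outcome must be binary 0/1")
    n_pos = int(outcome.sum())
    n_neg = int(len(outcome) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: outcome contains a single class")

    best: Optional[CutoffResult] = None
    points = []
    for thr in np.unique(scores):  # ascending, so ties resolve to smallest
        called_pos = scores >= thr
        sens = float((called_pos & (outcome == 1)).sum() / n_pos)
        spec = float((~called_pos & (outcome == 0)).sum() / n_neg)
        points.append((float(thr), sens, spec))
        j = sens + spec - 1.0
        if best is None or j > best.youden_j + 1e-12:
            best = CutoffResult(float(thr), j, sens, spec)
    assert best is not None
    best.roc_points = points
    return best


def classify_cohort(
    observations: Iterable[IHCObservation],
    tumor_cut: int = DEFAULT_TUMOR_CUT,
    stroma_cut: int = DEFAULT_STROMA_CUT,
) -> tuple[pd.DataFrame, dict[CD138Group, int]]:
    """Classify every case from its tumor/stroma observation pair.

    Returns a per-case table (case_id, tumor_positive, stroma_positive, group)
    in first-appearance order, and the four-group count summary. Each case must
    contribute exactly one tumor and one stroma observation.
    """
    by_case: dict[str, dict[str, IHCObservation]] = {}
    order: list[str] = []
    for obs in observations:
        slot = by_case.setdefault(obs.case_id, {})
        if obs.compartment in slot:
            raise ValueError(f"case {obs.case_id!r}: duplicate {obs.compartment} observation")
        if not slot:
            order.append(obs.case_id)
        slot[obs.compartment] = obs

    rows = []
    for case_id in order:
        slot = by_case[case_id]
        for comp in ("tumor", "stroma"):
            if comp not in slot:
                raise ValueError(f"case {case_id!r}: missing {comp} observation")
        cls = classify_case(
            slot["tumor"].intensity, slot["stroma"].intensity, tumor_cut, stroma_cut
        )
        rows.append(
            {
                "case_id": case_id,
                "tumor_positive": cls.tumor_positive,
                "stroma_positive": cls.stroma_positive,
                "group": int(cls.group),
            }
        )
    table = pd.DataFrame(rows, columns=["case_id", "tumor_positive", "stroma_positive", "group"])
    counts = {g: int((table["group"] == int(g)).sum()) if len(table) else 0 for g in CD138Group}
    return table, counts


def observations_from_clinical(clinical: pd.DataFrame) -> list[IHCObservation]:
    """Build tumor/stroma observation pairs from a clinical table.

    Expects columns case_id, tumor_intensity, tumor_proportion,
    stroma_intensity, stroma_proportion.
    """
    required = [
        "case_id",
        "tumor_intensity",
        "tumor_proportion",
        "stroma_intensity",
        "stroma_proportion",
    ]
    missing = [c for c in required if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    obs = []
    for row in clinical.itertuples(index=False):
        obs.append(
            IHCObservation(
                case_id=str(row.case_id),
                compartment="tumor",
                intensity=int(row.tumor_intensity),
                proportion=float(row.tumor_proportion),
            )
        )
        obs.append(
            IHCObservation(
                case_id=str(row.case_id),
                compartment="stroma",
                intensity=int(row.stroma_intensity),
                proportion=float(row.stroma_proportion),
            )
        )
    return obs
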