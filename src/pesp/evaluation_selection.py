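"""Scoring alarms against seizures, and distance-based model selection.

Performance indices follow the standard seizure-prediction definitions:

* sensitivity  SS = Nc / Nt, the fraction of seizures preceded by at
  least one alarm inside the prediction horizon ``[onset - horizon,
  onset)``;
* false prediction rate  FPR = Nf / NT, false alarms per hour, where NT
  is the *total* record time (interictal and preictal alike — note that
  some of the literature divides by interictal time only);
* SPH, the seizure prediction horizon, is the interval between the
  first in-horizon alarm and onset.  Later in-horizon alarms are
  neither hits nor false alarms.

Candidate models are compared by the Euclidean distance from the ideal
operating point (SS = 100 %, FPR = 0):

    fprn(u) = fpr(u) / max_v fpr(v) * 100
    ed(u)   = sqrt((ss%(u) - 100)^2 + fprn(u)^2)

FPR is normalised across the candidate set because raw rates crowd
near zero; the model with minimum ed is selected, ties broken by
higher sensitivity then lower raw FPR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd

from .alarm_postprocess import AlarmSequence
from .errors import ValidationError
from .signal_io import SeizureAnnotation

__all__ = [
    "EvaluationReport",
    "ModelScore",
    "CHANCE_FPR_PER_HOUR",
    "score_alarms",
    "sensitivity",
    "false_prediction_rate",
    "normalized_fpr",
    "euclidean_distance",
    "select_best_model",
    "score_candidates",
    "aggregate_report",
]

# Commonly cited chance-level false prediction rate for this problem.
CHANCE_FPR_PER_HOUR = 0.15


@dataclass
class EvaluationReport:
    """Counts and indices for one alarm sequence against annotations."""

    Nc: int
    Nt: int
    Nf: int
    NT_hours: float
    SPH_list_min: List[float] = field(default_factory=list)

    @property
    def SS(self) -> float:
        return sensitivity(self.Nc, self.Nt)

    @property
    def FPR(self) -> float:
        return false_prediction_rate(self.Nf, self.NT_hours)

    @property
    def mean_SPH_min(self) -> float:
        return float(np.mean(self.SPH_list_min)) if self.SPH_list_min else math.nan

    @property
    def below_chance_fpr(self) -> bool:
        return self.FPR < CHANCE_FPR_PER_HOUR

    def __add__(self, other: "EvaluationReport") -> "EvaluationReport":
        return EvaluationReport(
            self.Nc + other.Nc,
            self.Nt + other.Nt,
            self.Nf + other.Nf,
            self.NT_hours + other.NT_hours,
            self.SPH_list_min + other.SPH_list_min,
        )


@dataclass
class ModelScore:
    """Selection-ready score of one candidate model."""

    ss_pct: float
    fpr: float
    fprn: float
    ed: float
    label: str = ""


def sensitivity(Nc: int, Nt: int) -> float:
    """SS = Nc / Nt."""
    if Nt < 1:
        raise ValidationError("Nt must be >= 1")
    if not 0 <= Nc <= Nt:
        raise ValidationError(f"need 0 <= Nc <= Nt, got Nc={Nc}, Nt={Nt}")
    return Nc / Nt


def false_prediction_rate(Nf: int, NT_hours: float) -> float:
    """FPR = Nf / NT (false alarms per hour of total record time)."""
    if NT_hours <= 0:
        raise ValidationError("NT_hours must be positive")
    return Nf / NT_hours


def score_alarms(
    alarms: AlarmSequence,
    annotations: Sequence[SeizureAnnotation],
    horizon_min: float,
    total_hours: float,
) -> EvaluationReport:
    """Count hits, false alarms and SPHs for one test segment.

    A seizure is predicted iff at least one alarm lies in
    ``[onset - horizon, onset)``; its SPH is measured from the first
    such alarm.  Every alarm outside all preictal intervals is false.
    """
    if total_hours <= 0:
        raise ValidationError("total_hours must be positive")
    horizon_s = horizon_min * 60.0
    times = np.sort(np.asarray(alarms.alarm_times, dtype=float))
    anns = sorted(annotations, key=lambda a: a.onset)

    Nc, sph = 0, []
    in_horizon = np.zeros(times.size, dtype=bool)
    for a in anns:
        mask = (times >= a.onset - horizon_s) & (times < a.onset)
        in_horizon |= mask
        if mask.any():
            Nc += 1
            sph.append((a.onset - times[mask][0]) / 60.0)
    Nf = int(np.sum(~in_horizon))
    return EvaluationReport(Nc=Nc, Nt=len(anns), Nf=Nf, NT_hours=total_hours, SPH_list_min=sph)


def normalized_fpr(fprs: Sequence[float]) -> np.ndarray:
    """Scale each FPR by 100 / max over the candidate set.

    An all-zero candidate set maps to all zeros (the ideal corner).
    """
    fprs = np.asarray(fprs, dtype=float)
    if np.any(fprs < 0):
        raise ValidationError("FPR values must be non-negative")
    fpr_max = fprs.max() if fprs.size else 0.0
    if fpr_max == 0:
        return np.zeros_like(fprs)
    return fprs / fpr_max * 100.0


def euclidean_distance(ss_pct: float, fprn: float) -> float:
    """Distance from the ideal point (SS = 100 %, normalised FPR = 0)."""
    if not 0 <= ss_pct <= 100:
        raise ValidationError("ss_pct must be in [0, 100]")
    if fprn < 0:
        raise ValidationError("fprn must be non-negative")
    return math.hypot(ss_pct - 100.0, fprn)


def score_candidates(
    reports: Sequence[EvaluationReport], labels: Sequence[str] | None = None
) -> List[ModelScore]:
    """Build ModelScores for a candidate set (shared FPR normalisation)."""
    fprn = normalized_fpr([r.FPR for r in reports])
    labels = list(labels) if labels is not None else [""] * len(reports)
    return [
        ModelScore(
            ss_pct=r.SS * 100.0,
            fpr=r.FPR,
            fprn=float(fn),
            ed=euclidean_distance(r.SS * 100.0, float(fn)),
            label=lab,
        )
        for r, fn, lab in zip(reports, fprn, labels)
    ]


def select_best_model(scores: Sequence[ModelScore]) -> int:
    """Index of the minimum-distance candidate.

    Ties resolve to the higher sensitivity, then the lower raw FPR.
    """
    if not scores:
        raise ValidationError("empty candidate list")
    order = sorted(range(len(scores)), key=lambda i: (scores[i].ed, -scores[i].ss_pct, scores[i].fpr))
    return order[0]


def aggregate_report(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Append an unweighted-mean 'Avg.' row to a per-patient results table.

    Expects columns among {SS, FPR, SPH, distance} (any subset); means
    are plain arithmetic means across patients.
    """
    if per_patient.empty:
        raise ValidationError("empty per-patient table")
    numeric = per_patient.select_dtypes("number")
    avg = numeric.mean(axis=0)
    out = per_patient.copy()
    out.loc["Avg."] = avg
    return out
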