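"""Per-IR classification, patient voting, screening metrics and ROC sweep.

A network output o ∈ (0,1) is classed OP when it lies within τ of the
OP teacher value 0, OK when within τ of 1, and AMBIGUOUS otherwise
(o = 0.5 is always ambiguous — the osteopenia middle ground).  A
patient's diagnosis is the majority of their non-ambiguous IR
decisions; ties go to OP because a screening test prefers false
positives over missed cases.  Metrics are the standard screening
quantities — sensitivity TPR = TP/P, FPR = FP/N, specificity
SPC = 1 − FPR, accuracy ACC = (TP+TN)/(P+N) — plus the merit ratio
r = FPR/TPR.  The threshold sweep re-classifies the validation outputs
under the symmetric pair (τ, 1−τ) for τ from 0.2 to 0.5 and emits one
row of IR-level and patient-level metrics per τ, forming a discrete
(quasi-)ROC without interpolation or area computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import groupby

import numpy as np
import pandas as pd

from . import neuralnet

OP = "OP"
OK = "OK"
AMBIGUOUS = "AMBIGUOUS"
UNDETERMINED = "UNDETERMINED"

DEFAULT_TAU = 0.4


@dataclass
class IRDecision:
    output: float
    decided: str  # OP | OK | AMBIGUOUS
    tau: float


@dataclass
class PatientDiagnosis:
    patient_id: str
    n_op: int
    n_ok: int
    n_ambiguous: int
    final: str  # OP | OK | UNDETERMINED


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "ConfusionMetrics":
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def tpr(self) -> float:
        """Sensitivity TP/P."""
        return self.tp / self.p if self.p else math.nan

    sen = tpr

    @property
    def fpr(self) -> float:
        return self.fp / self.n if self.n else math.nan

    @property
    def spc(self) -> float:
        """Specificity TN/N = 1 − FPR."""
        return 1.0 - self.fpr

    @property
    def acc(self) -> float:
        total = self.p + self.n
        return (self.tp + self.tn) / total if total else math.nan

    @property
    def r(self) -> float:
        """Merit ratio FPR/TPR; undefined (NaN) when TPR is 0 or NaN."""
        tpr = self.tpr
        if not tpr or math.isnan(tpr):
            return math.nan
        return self.fpr / tpr


def classify_output(o: float, tau: float = DEFAULT_TAU) -> str:
    """Symmetric ambiguity-band rule: within τ of a teacher value, else AMBIGUOUS.

    Boundaries are inclusive; o = 0.5 is ambiguous for every τ (even 0.5).
    """
    if not (0.0 <= o <= 1.0):
        raise ValueError("network output must lie in [0, 1]")
    if not (0.0 < tau <= 0.5):
        raise ValueError("threshold must satisfy 0 < tau <= 0.5")
    if o == 0.5:
        return AMBIGUOUS
    if o <= tau:
        return OP
    if o >= 1.0 - tau:
        return OK
    return AMBIGUOUS


def classify_outputs(outputs: np.ndarray, tau: float = DEFAULT_TAU) -> list[str]:
    return [classify_output(float(o), tau) for o in outputs]


def vote_patient(decisions: list[IRDecision | str],
                 patient_id: str = "") -> PatientDiagnosis:
    """Majority vote over non-ambiguous IR decisions; tie → OP; none → UNDETERMINED."""
    if not decisions:
        raise ValueError("need at least one IR decision")
    classes = [d.decided if isinstance(d, IRDecision) else d for d in decisions]
    n_op = classes.count(OP)
    n_ok = classes.count(OK)
    n_amb = classes.count(AMBIGUOUS)
    if n_op + n_ok + n_amb != len(classes):
        raise ValueError("decisions must be OP, OK or AMBIGUOUS")
    if n_op == n_ok == 0:
        final = UNDETERMINED
    elif n_op >= n_ok:  # tie prefers the positive (screening) class
        final = OP
    else:
        final = OK
    return PatientDiagnosis(patient_id=patient_id, n_op=n_op, n_ok=n_ok,
                            n_ambiguous=n_amb, final=final)


def compute_metrics(predicted: list[str], truth: list[str],
                    positive: str = OP) -> tuple[ConfusionMetrics, int]:
    """Confusion counts over decided entries; returns (metrics, n_excluded).

    AMBIGUOUS / UNDETERMINED predictions are excluded from the counts
    and reported separately, so P = TP + FN and N = TN + FP hold over
    the decided subset.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must have equal length")
    tp = fp = tn = fn = excluded = 0
    for pred, true in zip(predicted, truth):
        if pred in (AMBIGUOUS, UNDETERMINED):
            excluded += 1
            continue
        if true == positive:
            tp += pred == positive
            fn += pred != positive
        else:
            fp += pred == positive
            tn += pred != positive
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn), excluded


def max_misclassification_rate(error_energy: float, n_examples: int) -> float:
    """Worst-case misclassified fraction implied by a half-squared error bound.

    A completely inverted example contributes at most ½·1² to the error
    energy, so at most 2E of the M examples can be fully wrong:
    rate = min(1, 2E/M).  E = 50 over 330 examples bounds the error
    rate at ~30%.
    """
    if n_examples <= 0:
        raise ValueError("need a positive number of examples")
    if error_energy < 0:
        raise ValueError("error energy cannot be negative")
    return min(1.0, 2.0 * error_energy / n_examples)


def _sweep_taus(tau_start: float, tau_end: float, step: float) -> np.ndarray:
    if step <= 0 or tau_start > tau_end:
        raise ValueError("invalid threshold range")
    n = int(round((tau_end - tau_start) / step)) + 1
    taus = tau_start + step * np.arange(n)
    return taus[taus <= tau_end + 1e-12]


def evaluate_outputs(outputs: np.ndarray, teachers: np.ndarray,
                     patient_ids: list[str], tau: float):
    """IR and patient metrics of a set of outputs at one threshold."""
    ir_classes = classify_outputs(outputs, tau)
    ir_truth = [OP if t == 0.0 else OK for t in teachers]
    ir_metrics, ir_excluded = compute_metrics(ir_classes, ir_truth)

    order = sorted(range(len(patient_ids)), key=lambda i: patient_ids[i])
    pat_pred, pat_truth, diagnoses = [], [], []
    for pid, idx in groupby(order, key=lambda i: patient_ids[i]):
        idx = list(idx)
        diag = vote_patient([ir_classes[i] for i in idx], patient_id=pid)
        diagnoses.append(diag)
        pat_pred.append(diag.final)
        pat_truth.append(ir_truth[idx[0]])
    pat_metrics, pat_undet = compute_metrics(pat_pred, pat_truth)
    return {
        "ir": ir_metrics, "ir_ambiguous": ir_excluded,
        "patient": pat_metrics, "patient_undetermined": pat_undet,
        "diagnoses": diagnoses,
    }


def threshold_sweep(model, dataset, tau_start: float = 0.2, tau_end: float = 0.5,
                    step: float = 0.005, outputs: np.ndarray | None = None,
                    ) -> pd.DataFrame:
    """Re-classify a validation set across the symmetric threshold sweep.

    `dataset` is (X, teachers, patient_ids); `model` may be None when
    pre-computed `outputs` are supplied.  One row per τ with IR-level
    and patient-level metrics.
    """
    X, teachers, patient_ids = dataset
    if outputs is None:
        outputs = neuralnet.predict(model, X)
    teachers = np.asarray(teachers, float)
    rows = []
    for tau in _sweep_taus(tau_start, tau_end, step):
        ev = evaluate_outputs(outputs, teachers, list(patient_ids), float(tau))
        ir, pat = ev["ir"], ev["patient"]
        rows.append({
            "threshold": round(float(tau), 3),
            "ir_tpr": ir.tpr, "ir_fpr": ir.fpr, "ir_spc": ir.spc,
            "ir_acc": ir.acc, "ir_r": ir.r, "ir_ambiguous": ev["ir_ambiguous"],
            "pat_tpr": pat.tpr, "pat_fpr": pat.fpr, "pat_spc": pat.spc,
            "pat_acc": pat.acc, "pat_r": pat.r,
            "pat_undetermined": ev["patient_undetermined"],
        })
    return pd.DataFrame(rows)


def best_sweep_row(sweep: pd.DataFrame, level: str = "pat") -> pd.Series:
    """Row with the minimum defined merit ratio r.

    r judges maximum sensitivity and minimum FPR together, so ties in r
    (typically several all-specific rows with r = 0) break towards the
    higher sensitivity, then the lower threshold.
    """
    r = sweep[f"{level}_r"]
    if r.notna().any():
        cand = sweep[r == r.min()]
        cand = cand[cand[f"{level}_tpr"] == cand[f"{level}_tpr"].max()]
        return cand.iloc[0]
    # no defined ratio anywhere: fall back to maximum sensitivity, or the
    # first row when sensitivity is undefined everywhere too
    tpr = sweep[f"{level}_tpr"]
    if tpr.notna().any():
        return sweep.loc[tpr.idxmax()]
    return sweep.iloc[0]


def export_roc(sweep: pd.DataFrame, path, meta: dict | None = None) -> pd.DataFrame:
    """Write the discrete ROC table: (τ, SEN, 1−SPC) at IR and patient level.

    Rows where a rate is undefined (e.g. everything ambiguous) keep a
    NaN and are flagged, never dropped.  No interpolation, no AUC.
    """
    from .signal_io import write_table

    if sweep.empty:
        raise ValueError("sweep result is empty")
    roc = pd.DataFrame({
        "threshold": sweep["threshold"],
        "ir_sen": sweep["ir_tpr"].round(4),
        "ir_one_minus_spc": sweep["ir_fpr"].round(4),
        "pat_sen": sweep["pat_tpr"].round(4),
        "pat_one_minus_spc": sweep["pat_fpr"].round(4),
    })
    roc["defined"] = ~(sweep[["ir_tpr", "ir_fpr", "pat_tpr", "pat_fpr"]]
                       .isna().any(axis=1))
    write_table(roc, path, meta=meta)
    return roc


def sweep_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Four-decimal summary with the conventional column layout."""
    out = sweep[["threshold", "ir_tpr", "ir_fpr", "pat_tpr", "pat_fpr"]].copy()
    for col in out.columns[1:]:
        out[col] = out[col].round(4)
    return out
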