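"""Diagnostic rules and screening-cascade execution.

Diabetes is diagnosed from plasma glucose: fasting plasma glucose (FPG)
>= 7.0 mmol/L or 2-h post-load plasma glucose (2hPG) >= 11.1 mmol/L.
Diabetics split into three glycemic subtypes by which analyte is in the
diagnostic range: isolated post-load (normal FPG, diagnostic 2hPG),
isolated fasting (the converse), or combined.

A screening cascade is a per-person flowchart:

1. If the strategy has a screening lab (FPG, 2hPG or HbA1c), that test is
   performed on everyone; a result in the diagnostic range ends the trail
   with the person detected.
2. Otherwise a risk model (trained classifier or questionnaire point
   score) is applied; screen-negatives stop undetected.
3. Screen-positives receive the confirmatory test (a full OGTT, or only
   the analyte the screening lab did not already measure) and detection
   follows the diagnostic rule over every analyte observed in the trail.

``run_cascade`` executes this flow vectorised over a cohort and returns a
per-person record table from which confusion counts and per-test cost
ledgers are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticThresholds",
    "CascadeSpec",
    "ConfusionCounts",
    "NON_DM",
    "ISOLATED_FASTING",
    "ISOLATED_POSTLOAD",
    "COMBINED",
    "SUBTYPES",
    "diagnose",
    "subtype",
    "run_cascade",
    "tally",
]

NON_DM = "NON_DM"
ISOLATED_FASTING = "ISOLATED_FASTING"
ISOLATED_POSTLOAD = "ISOLATED_POSTLOAD"
COMBINED = "COMBINED"
SUBTYPES = (NON_DM, ISOLATED_FASTING, ISOLATED_POSTLOAD, COMBINED)

SCREENING_LABS = ("NONE", "FPG", "P2HPG", "HBA1C")
CONFIRMATORY_TESTS = ("OGTT", "P2HPG_ONLY", "FPG_ONLY")
TARGET_CONDITIONS = ("ANY_DM", "ISOLATED_POSTLOAD", "ISOLATED_FASTING")

#: lab column in a population table per screening-lab code
LAB_COLUMN = {"FPG": "fpg", "P2HPG": "p2hpg", "HBA1C": "hba1c"}


class CascadeError(ValueError):
    """Invalid cascade specification or missing inputs."""


@dataclass(frozen=True)
class DiagnosticThresholds:
    """Diagnostic and 'seemingly normal' boundaries, in natural units.

    A single threshold per analyte plays both roles: values at or above it
    are diagnostic, values strictly below are 'seemingly normal'.
    """

    fpg_dm: float = 7.0
    p2hpg_dm: float = 11.1
    fpg_normal_lt: float = 7.0
    p2hpg_normal_lt: float = 11.1
    hba1c_normal_lt: float = 6.5

    def __post_init__(self) -> None:
        vals = (self.fpg_dm, self.p2hpg_dm, self.fpg_normal_lt,
                self.p2hpg_normal_lt, self.hba1c_normal_lt)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise CascadeError("all diagnostic thresholds must be positive and finite")
        if self.fpg_normal_lt > self.fpg_dm or self.p2hpg_normal_lt > self.p2hpg_dm:
            raise CascadeError("normal boundary may not exceed the diagnostic threshold")


def _check_glucose(fpg, p2hpg):
    fpg = np.asarray(fpg, dtype=float)
    p2hpg = np.asarray(p2hpg, dtype=float)
    for name, arr in (("fpg", fpg), ("p2hpg", p2hpg)):
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise CascadeError(f"{name} values must be finite and positive")
    return fpg, p2hpg


def diagnose(fpg, p2hpg, thresholds: DiagnosticThresholds | None = None):
    """Diabetes diagnosis: FPG >= 7.0 mmol/L or 2hPG >= 11.1 mmol/L.

    Accepts scalars or arrays; returns a bool (or bool array).
    """
    thr = thresholds or DiagnosticThresholds()
    scalar = np.isscalar(fpg) and np.isscalar(p2hpg)
    fpg, p2hpg = _check_glucose(fpg, p2hpg)
    out = (fpg >= thr.fpg_dm) | (p2hpg >= thr.p2hpg_dm)
    return bool(out) if scalar else out


def subtype(fpg, p2hpg, thresholds: DiagnosticThresholds | None = None):
    """Glycemic subtype from the two analytes.

    NON_DM if neither analyte is diagnostic; ISOLATED_POSTLOAD if only
    2hPG is; ISOLATED_FASTING if only FPG is; COMBINED if both are.
    """
    thr = thresholds or DiagnosticThresholds()
    scalar = np.isscalar(fpg) and np.isscalar(p2hpg)
    fpg, p2hpg = _check_glucose(fpg, p2hpg)
    f_hi = fpg >= thr.fpg_dm
    p_hi = p2hpg >= thr.p2hpg_dm
    out = np.where(
        f_hi & p_hi, COMBINED,
        np.where(f_hi, ISOLATED_FASTING, np.where(p_hi, ISOLATED_POSTLOAD, NON_DM)),
    )
    return str(out[()]) if scalar else out


def default_confirmatory(screening_lab: str) -> str:
    """Confirmatory test implied by the screening lab.

    The analyte already measured at the screening step is not repeated:
    no-lab and HbA1c strategies confirm with a full OGTT, an FPG screen
    confirms with 2hPG alone, a 2hPG screen with FPG alone.
    """
    return {"NONE": "OGTT", "HBA1C": "OGTT",
            "FPG": "P2HPG_ONLY", "P2HPG": "FPG_ONLY"}[screening_lab]


def default_target(screening_lab: str) -> str:
    return {"NONE": "ANY_DM", "HBA1C": "ANY_DM",
            "FPG": "ISOLATED_POSTLOAD", "P2HPG": "ISOLATED_FASTING"}[screening_lab]


@dataclass
class CascadeSpec:
    """One detection strategy: optional screening lab, risk model, confirmatory test.

    ``model`` is anything with a ``predict_risk(pop) -> array`` method (a
    fitted :class:`~dmscreen.riskmodels.RiskModel`) or a
    :class:`~dmscreen.riskmodels.ScoreTable`; ``decision_threshold``
    overrides the model's own cutoff when given (probability for a
    classifier, integer points for a score table). Positivity is
    ``score >= threshold``.
    """

    name: str
    model: object
    screening_lab: str = "NONE"
    decision_threshold: float | None = None
    confirmatory_test: str | None = None
    target_condition: str | None = None

    def __post_init__(self) -> None:
        if self.screening_lab not in SCREENING_LABS:
            raise CascadeError(f"unknown screening_lab {self.screening_lab!r}; "
                               f"expected one of {SCREENING_LABS}")
        if self.confirmatory_test is None:
            self.confirmatory_test = default_confirmatory(self.screening_lab)
        if self.confirmatory_test not in CONFIRMATORY_TESTS:
            raise CascadeError(f"unknown confirmatory_test {self.confirmatory_test!r}; "
                               f"expected one of {CONFIRMATORY_TESTS}")
        if self.target_condition is None:
            self.target_condition = default_target(self.screening_lab)
        if self.target_condition not in TARGET_CONDITIONS:
            raise CascadeError(f"unknown target_condition {self.target_condition!r}")
        # structural consistency between stages
        if self.screening_lab == "NONE" and (
                self.confirmatory_test != "OGTT" or self.target_condition != "ANY_DM"):
            raise CascadeError("a no-lab cascade confirms with OGTT and targets ANY_DM")
        if self.screening_lab == "FPG" and self.target_condition != "ISOLATED_POSTLOAD":
            raise CascadeError("an FPG-screen cascade targets ISOLATED_POSTLOAD")
        if self.screening_lab == "P2HPG" and self.target_condition != "ISOLATED_FASTING":
            raise CascadeError("a 2hPG-screen cascade targets ISOLATED_FASTING")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _scores_and_flags(spec: CascadeSpec, pop: pd.DataFrame,
                      scores: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Risk scores and positivity flags for every row of ``pop``."""
    model = spec.model
    if scores is None:
        scores = np.asarray(model.predict_risk(pop), dtype=float)
    if spec.decision_threshold is not None:
        cutoff = float(spec.decision_threshold)
    elif hasattr(model, "cutoff"):
        cutoff = float(model.cutoff)
    else:
        raise CascadeError(f"cascade {spec.name!r}: no decision_threshold and the "
                           "model has no cutoff")
    return scores, scores >= cutoff


_CONFIRM_ANALYTES = {"OGTT": ("fpg", "p2hpg"), "P2HPG_ONLY": ("p2hpg",),
                     "FPG_ONLY": ("fpg",)}


def run_cascade(pop: pd.DataFrame, spec: CascadeSpec,
                thresholds: DiagnosticThresholds | None = None,
                scores: np.ndarray | None = None) -> pd.DataFrame:
    """Execute one detection strategy over a cohort.

    Returns one record per person with columns: ``person_id``, ``tests``
    (semicolon-joined trail), ``screen_diagnosed`` (screening lab already
    diagnostic), ``screen_positive`` (risk model flagged, among persons
    the model was applied to), ``confirmatory`` (confirmatory test
    performed), ``predicted`` (flagged by the strategy: screening lab
    diagnostic or model positive), ``detected`` (diabetes actually found
    by a test in the trail), ``truth`` (true diabetes status), and
    ``outcome`` in {TP, FP, TN, FN}.

    The confusion outcome compares the strategy's *flag* against truth —
    a flagged non-diabetic is a false positive even though the
    confirmatory test will clear them (that cleared visit is exactly the
    cost a better screen avoids). For every true diabetic the flag and
    the eventual detection coincide, because each cascade's confirmatory
    test measures whichever analyte the screening step has not ruled out.

    ``scores`` short-circuits the model call with precomputed risk
    scores (used when sweeping thresholds over one scored cohort).
    """
    thr = thresholds or DiagnosticThresholds()
    n = len(pop)
    if spec.screening_lab != "NONE":
        col = LAB_COLUMN[spec.screening_lab]
        if col not in pop.columns:
            raise CascadeError(f"cascade {spec.name!r} screens with {spec.screening_lab} "
                               f"but the population has no {col!r} column")
    for col in ("fpg", "p2hpg"):
        if col not in pop.columns:
            raise CascadeError(f"population lacks the true lab column {col!r} needed "
                               "to adjudicate detection and truth")

    fpg = pop["fpg"].to_numpy(dtype=float)
    p2hpg = pop["p2hpg"].to_numpy(dtype=float)
    truth = diagnose(fpg, p2hpg, thr)

    # step (a): screening lab, possibly already diagnostic
    if spec.screening_lab == "NONE":
        screen_diag = np.zeros(n, dtype=bool)
    elif spec.screening_lab == "FPG":
        screen_diag = fpg >= thr.fpg_dm
    elif spec.screening_lab == "P2HPG":
        screen_diag = p2hpg >= thr.p2hpg_dm
    else:  # HBA1C
        hba1c = pop["hba1c"].to_numpy(dtype=float)
        screen_diag = hba1c >= thr.hba1c_normal_lt

    # step (b): risk model on everyone not already diagnosed at screening
    _, flags = _scores_and_flags(spec, pop, scores)
    screen_positive = flags & ~screen_diag

    # step (c): confirmatory test for the screen-positives
    confirmatory = screen_positive.copy()
    analytes = _CONFIRM_ANALYTES[spec.confirmatory_test]
    observed_diag = np.zeros(n, dtype=bool)
    if spec.screening_lab == "FPG":
        observed_diag |= fpg >= thr.fpg_dm
    elif spec.screening_lab == "P2HPG":
        observed_diag |= p2hpg >= thr.p2hpg_dm
    conf_diag = np.zeros(n, dtype=bool)
    if "fpg" in analytes:
        conf_diag |= fpg >= thr.fpg_dm
    if "p2hpg" in analytes:
        conf_diag |= p2hpg >= thr.p2hpg_dm
    detected = screen_diag | (confirmatory & (observed_diag | conf_diag))

    conf_name = {"OGTT": "OGTT", "P2HPG_ONLY": "P2HPG", "FPG_ONLY": "FPG"}[spec.confirmatory_test]
    if spec.screening_lab != "NONE":
        trails = np.where(confirmatory, spec.screening_lab + ";" + conf_name,
                          spec.screening_lab)
    else:
        trails = np.where(confirmatory, conf_name, "")

    predicted = screen_diag | screen_positive
    outcome = np.where(predicted & truth, "TP",
                       np.where(predicted & ~truth, "FP",
                                np.where(~predicted & truth, "FN", "TN")))
    ids = pop["person_id"].to_numpy() if "person_id" in pop.columns else np.arange(n)
    return pd.DataFrame({
        "person_id": ids,
        "tests": trails,
        "screen_diagnosed": screen_diag,
        "screen_positive": screen_positive,
        "confirmatory": confirmatory,
        "predicted": predicted,
        "detected": detected,
        "truth": truth,
        "outcome": outcome,
    })


def tally(records: pd.DataFrame) -> ConfusionCounts:
    """Confusion counts from a cascade record table; N is conserved."""
    if len(records) == 0:
        raise CascadeError("cannot tally an empty record set")
    counts = records["outcome"].value_counts()
    out = ConfusionCounts(tp=int(counts.get("TP", 0)), fp=int(counts.get("FP", 0)),
                          tn=int(counts.get("TN", 0)), fn=int(counts.get("FN", 0)))
    if out.n != len(records):
        raise CascadeError("outcome labels do not partition the records")
    return out
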