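"""Metabolic response classification and cohort statistics.

FDG response follows lean-mass-corrected SUV (SUL) change rules: an overall
response (OR) is a >= 20 % reduction in every lesion present at baseline with
no new lesions; progressive disease (PD) is a >= 15 % increase in any lesion
or any new lesion; a mixed response is the coexistence of OR-level and
PD-level lesions.  Cohort comparisons use a one-sided unequal-variance
(Welch) t-test, a one-sample z-test against a fixed drug-trough reference,
and Pearson correlation with a Fisher-z 95 % confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError


class ResponseLabel(str, Enum):
    OR = "OR"        # overall (partial metabolic) response
    PD = "PD"        # progressive disease
    MIXED = "MIXED"  # responding and progressing lesions coexist
    SD = "SD"        # stable disease (residual category)


@dataclass(frozen=True)
class LesionChange:
    """Percent change in lean-corrected SUV of one lesion vs baseline."""

    lesion_id: str
    percent_change: float

    def __post_init__(self):
        if not np.isfinite(self.percent_change):
            raise ParameterError("lesion percent change must be finite")


#: Inclusive response thresholds on percent SUL change.
OR_THRESHOLD = -20.0
PD_THRESHOLD = 15.0


def suv_lean(concentration_kbq_ml: float, injected_dose_mbq: float,
             lean_body_mass_kg: float) -> float:
    """Lean-body-mass-normalised standardised uptake value (SUL, g/mL).

    SUL = C [kBq/mL] * LBM [kg] / dose [MBq]; the kilo/mega prefixes cancel so
    the expression is unit-consistent as written.
    """
    if concentration_kbq_ml <= 0 or injected_dose_mbq <= 0 or lean_body_mass_kg <= 0:
        raise ParameterError("concentration, dose and lean body mass must be positive")
    return concentration_kbq_ml * lean_body_mass_kg / injected_dose_mbq


def classify_fdg_response(changes, new_lesions: bool = False) -> ResponseLabel:
    """Classify a patient's metabolic response from per-lesion SUL changes.

    New lesions dominate (PD).  Otherwise, OR-level (<= -20 %) and PD-level
    (>= +15 %) lesions coexisting give MIXED; any PD-level lesion alone gives
    PD; all lesions at OR level give OR; anything else is SD.
    """
    changes = list(changes)
    if len(changes) == 0:
        raise ParameterError("need at least one lesion")
    pct = np.array([c.percent_change if isinstance(c, LesionChange) else float(c)
                    for c in changes])
    if new_lesions:
        return ResponseLabel.PD
    has_or = bool(np.any(pct <= OR_THRESHOLD))
    has_pd = bool(np.any(pct >= PD_THRESHOLD))
    if has_or and has_pd:
        return ResponseLabel.MIXED
    if has_pd:
        return ResponseLabel.PD
    if np.all(pct <= OR_THRESHOLD):
        return ResponseLabel.OR
    return ResponseLabel.SD


@dataclass(frozen=True)
class WelchTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False


def welch_t_one_sided(group_a, group_b) -> WelchTestResult:
    """Welch's t-test with Satterthwaite degrees of freedom.

    One-sided alternative: mean(group_a) < mean(group_b).  The fully
    degenerate case (zero variance in both groups, equal means) returns
    p = 0.5 by symmetry convention and is flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least two values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0:
        if a.mean() == b.mean():
            return WelchTestResult(t=0.0, df=float(na + nb - 2), p=0.5, degenerate=True)
        t = -np.inf if a.mean() < b.mean() else np.inf
        return WelchTestResult(t=float(t), df=float(na + nb - 2),
                               p=0.0 if t < 0 else 1.0, degenerate=True)
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return WelchTestResult(t=float(t), df=float(df), p=float(stats.t.cdf(t, df)))


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    n: int


def pearson_with_ci(x, y, confidence: float = 0.95) -> PearsonResult:
    """Pearson product-moment correlation with a Fisher-z confidence interval.

    CI: tanh(atanh(r) +/- z* / sqrt(n - 3)); degenerate at |r| = 1 or n = 3,
    where the interval collapses to the full admissible range/point.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ParameterError("need >= 3 paired observations")
    if x.var() == 0 or y.var() == 0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    n = x.size
    if abs(r) >= 1.0 - 1e-15:
        return PearsonResult(r=float(np.sign(r)), ci_low=float(np.sign(r)),
                             ci_high=float(np.sign(r)), n=n)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    if n > 3:
        half = zcrit / np.sqrt(n - 3)
        lo, hi = np.tanh(np.arctanh(r) - half), np.tanh(np.arctanh(r) + half)
    else:
        lo, hi = -1.0, 1.0
    return PearsonResult(r=r, ci_low=float(lo), ci_high=float(hi), n=n)


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p: float
    mean: float
    reference: float


def ztest_vs_reference(values, reference: float) -> ZTestResult:
    """One-sample z-test of mean > reference, using the sample standard
    deviation (n - 1 divisor) as the scale estimate."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ParameterError("need at least two values")
    s = v.std(ddof=1)
    if s == 0:
        raise DegenerateInputError("zero variance: z-test undefined")
    z = (v.mean() - reference) / (s / np.sqrt(v.size))
    return ZTestResult(z=float(z), p=float(stats.norm.sf(z)),
                       mean=float(v.mean()), reference=float(reference))
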