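"""Method-agreement statistics for paired measurements.

The toolkit mirrors standard method-comparison practice: a Shapiro-Wilk
normality gate choosing between a two-tailed paired t-test and a Wilcoxon
signed-rank test, ICC(2,1) (two-way random effects, absolute agreement,
single measure) with an F-based 95% CI, Bland-Altman bias with 1.96-SD limits
of agreement, and per-pair percent differences relative to a stated reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError, UndefinedICCError

NORMALITY_ALPHA = 0.05


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length paired measurement vectors."""

    x: np.ndarray
    y: np.ndarray
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise DomainError("paired sample needs two equal-length 1-D vectors")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DomainError("paired sample must not contain missing/non-finite values")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def differences(self) -> np.ndarray:
        return self.x - self.y


@dataclass(frozen=True)
class AgreementReport:
    """One row of a method-comparison table."""

    label_x: str
    label_y: str
    n: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    mean_diff: float
    sd_diff: float
    mean_pct_diff: float
    sd_pct_diff: float
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_low: float
    loa_high: float
    test_used: str
    p_value: float


def paired_compare(s: PairedSample, alpha: float = NORMALITY_ALPHA) -> dict:
    """Normality-gated paired comparison.

    Shapiro-Wilk is run on the paired differences; if its p-value exceeds
    ``alpha`` a two-tailed paired t-test is used, otherwise the Wilcoxon
    signed-rank test. Returns which test fired along with both p-values.
    """
    if s.n < 3:
        raise InsufficientDataError(f"paired comparison needs n >= 3, got {s.n}")
    d = s.differences
    if np.ptp(d) == 0:
        raise DomainError("paired differences are all identical (zero variance)")
    sw_p = float(sps.shapiro(d).pvalue)
    if sw_p > alpha:
        test_used = "paired_t"
        p = float(sps.ttest_rel(s.x, s.y).pvalue)
    else:
        test_used = "wilcoxon"
        p = float(sps.wilcoxon(s.x, s.y).pvalue)
    return {"test_used": test_used, "p_value": p, "shapiro_p": sw_p}


def icc_agreement(s: PairedSample) -> dict:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    The 95% CI is the F-distribution-based interval. Zero between-subject
    variance leaves the coefficient undefined.
    """
    if s.n < 2:
        raise InsufficientDataError("ICC needs at least 2 subjects")
    if np.ptp(s.x) == 0 and np.ptp(s.y) == 0:
        raise UndefinedICCError("no between-subject variance; ICC undefined")
    long = pd.DataFrame(
        {
            "subject": np.tile(np.arange(s.n), 2),
            "rater": np.repeat([s.label_x, s.label_y], s.n),
            "score": np.concatenate([s.x, s.y]),
        }
    )
    table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
    row = table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
    ci_col = "CI95" if "CI95" in table.columns else "CI95%"
    ci = tuple(float(v) for v in row[ci_col])
    return {"icc": float(row["ICC"]), "ci_low": ci[0], "ci_high": ci[1]}


def bland_altman(s: PairedSample) -> dict:
    """Bias (mean x - y) and 1.96-sample-SD limits of agreement."""
    if s.n < 2:
        raise InsufficientDataError("Bland-Altman needs n >= 2")
    d = s.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd}


def percent_difference(s: PairedSample, reference: str = "x") -> dict:
    """Per-pair percent difference relative to the reference vector.

    Computed as 100*(ref_i - other_i)/ref_i per pair, then summarized as mean
    and sample SD across pairs.
    """
    if reference not in ("x", "y"):
        raise DomainError("reference must be 'x' or 'y'")
    ref, other = (s.x, s.y) if reference == "x" else (s.y, s.x)
    zero = np.nonzero(ref == 0)[0]
    if zero.size:
        raise DomainError(f"zero reference value at pair index {zero[0]}")
    pct = 100.0 * (ref - other) / ref
    return {"mean_pct": float(np.mean(pct)), "sd_pct": float(np.std(pct, ddof=1))}


def agreement_report(s: PairedSample, reference: str = "x") -> AgreementReport:
    """Full method-comparison row: group stats, differences, ICC, B-A, test."""
    comp = paired_compare(s)
    icc = icc_agreement(s)
    ba = bland_altman(s)
    pct = percent_difference(s, reference=reference)
    d = s.differences
    return AgreementReport(
        label_x=s.label_x,
        label_y=s.label_y,
        n=s.n,
        mean_x=float(np.mean(s.x)),
        sd_x=float(np.std(s.x, ddof=1)),
        mean_y=float(np.mean(s.y)),
        sd_y=float(np.std(s.y, ddof=1)),
        mean_diff=float(np.mean(d)),
        sd_diff=float(np.std(d, ddof=1)),
        mean_pct_diff=pct["mean_pct"],
        sd_pct_diff=pct["sd_pct"],
        icc=icc["icc"],
        icc_ci=(icc["ci_low"], icc["ci_high"]),
        bias=ba["bias"],
        loa_low=ba["loa_low"],
        loa_high=ba["loa_high"],
        test_used=comp["test_used"],
        p_value=comp["p_value"],
    )
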