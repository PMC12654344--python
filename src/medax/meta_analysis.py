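"""Random-effects meta-analysis of odds ratios reported with 95% CIs.

Each study contributes an odds ratio with a 95% confidence interval; the
log odds ratio and its standard error are recovered as

    y_i  = ln(OR_i),        se_i = (ln(hi_i) - ln(lo_i)) / (2 * 1.959964)

Fixed-effect inverse-variance weights give Cochran's Q and
I² = max(0, (Q − df)/Q)·100.  Between-study variance tau² is estimated by
DerSimonian–Laird moments (default) or restricted maximum likelihood, and
the pooled estimate uses weights 1/(se_i² + tau²), with the CI built on the
log scale and exponentiated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ValidationError

Z95 = 1.959964


@dataclass(frozen=True)
class MetaStudy:
    """One study's odds ratio and 95% CI, with derived log-scale quantities."""

    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.ci_low <= 0 or self.odds_ratio <= 0:
            raise ValidationError(f"{self.label}: OR and CI bounds must be positive")
        if not self.ci_low <= self.odds_ratio <= self.ci_high:
            raise ValidationError(f"{self.label}: CI does not bracket the OR")
        if self.ci_high <= self.ci_low:
            raise ValidationError(f"{self.label}: upper CI bound must exceed lower")

    @property
    def log_or(self) -> float:
        return math.log(self.odds_ratio)

    @property
    def se(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * Z95)


@dataclass
class MetaResult:
    """Pooled random-effects summary with heterogeneity diagnostics."""

    pooled_log_or: float
    pooled_se: float
    pooled_or: float
    ci_low: float
    ci_high: float
    pvalue: float
    tau2: float
    tau2_method: str
    q: float
    q_df: int
    q_pvalue: float
    i2: float                       # percent
    fixed_weights: np.ndarray = field(repr=False, default=None)
    random_weights: np.ndarray = field(repr=False, default=None)
    n_studies: int = 0
    single_study: bool = False


def tau2_dersimonian_laird(y: np.ndarray, se: np.ndarray) -> float:
    """Closed-form DerSimonian–Laird moment estimate of tau²."""
    w = 1.0 / se**2
    mu_fixed = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_fixed) ** 2)
    df = y.size - 1
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - df) / c))


def tau2_reml(y: np.ndarray, se: np.ndarray) -> float:
    """Restricted-maximum-likelihood tau² by bounded 1-D optimisation."""

    def neg_restricted_ll(t2: float) -> float:
        w = 1.0 / (se**2 + t2)
        mu = np.sum(w * y) / np.sum(w)
        return -0.5 * (np.sum(np.log(w)) - np.log(np.sum(w)) - np.sum(w * (y - mu) ** 2))

    hi = max(1e-6, 10.0 * float(np.var(y)))
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-12})
    return float(res.x)


def pool_random_effects(
    studies: Sequence[MetaStudy], tau2_method: str = "DL"
) -> MetaResult:
    """Pool study odds ratios under an inverse-variance random-effects model.

    Parameters
    ----------
    studies : sequence of MetaStudy
        At least two studies; a single study passes through with tau² = 0
        and ``single_study`` flagged.
    tau2_method : {"DL", "REML"}
        Between-study variance estimator: DerSimonian–Laird moments
        (default) or iterative restricted maximum likelihood.
    """
    if tau2_method not in ("DL", "REML"):
        raise ValidationError(f"unknown tau2 method {tau2_method!r}")
    if len(studies) == 0:
        raise ValidationError("pool_random_effects: no studies")
    y = np.array([s.log_or for s in studies])
    se = np.array([s.se for s in studies])
    w_fixed = 1.0 / se**2

    if len(studies) == 1:
        mu, pse = float(y[0]), float(se[0])
        return MetaResult(
            pooled_log_or=mu, pooled_se=pse, pooled_or=math.exp(mu),
            ci_low=math.exp(mu - Z95 * pse), ci_high=math.exp(mu + Z95 * pse),
            pvalue=2.0 * stats.norm.sf(abs(mu) / pse),
            tau2=0.0, tau2_method=tau2_method, q=0.0, q_df=0, q_pvalue=1.0, i2=0.0,
            fixed_weights=w_fixed, random_weights=np.array([1.0]),
            n_studies=1, single_study=True,
        )

    mu_fixed = float(np.sum(w_fixed * y) / np.sum(w_fixed))
    q = float(np.sum(w_fixed * (y - mu_fixed) ** 2))
    df = len(studies) - 1
    q_pvalue = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    tau2 = tau2_dersimonian_laird(y, se) if tau2_method == "DL" else tau2_reml(y, se)
    w_rand = 1.0 / (se**2 + tau2)
    mu = float(np.sum(w_rand * y) / np.sum(w_rand))
    pse = float(1.0 / math.sqrt(np.sum(w_rand)))
    return MetaResult(
        pooled_log_or=mu,
        pooled_se=pse,
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - Z95 * pse),
        ci_high=math.exp(mu + Z95 * pse),
        pvalue=float(2.0 * stats.norm.sf(abs(mu) / pse)),
        tau2=tau2,
        tau2_method=tau2_method,
        q=q,
        q_df=df,
        q_pvalue=q_pvalue,
        i2=float(i2),
        fixed_weights=w_fixed,
        random_weights=w_rand / w_rand.sum(),
        n_studies=len(studies),
    )


def read_study_table(path: str | Path) -> list[MetaStudy]:
    """Read a TSV of (LABEL, OR, CI_LOW, CI_HIGH) study rows."""
    df = pd.read_csv(path, sep="\t")
    for col in ("LABEL", "OR", "CI_LOW", "CI_HIGH"):
        if col not in df.columns:
            raise ValidationError(f"study table lacks column {col}")
    return [
        MetaStudy(str(r.LABEL), float(r.OR), float(r.CI_LOW), float(r.CI_HIGH))
        for r in df.itertuples(index=False)
    ]


def forest_table(studies: Sequence[MetaStudy], result: MetaResult) -> pd.DataFrame:
    """Per-study rows plus a pooled row, forest-plot style."""
    rows = [
        {
            "LABEL": s.label,
            "OR": s.odds_ratio,
            "CI_LOW": s.ci_low,
            "CI_HIGH": s.ci_high,
            "WEIGHT_PCT": 100.0 * float(wr),
        }
        for s, wr in zip(studies, result.random_weights)
    ]
    rows.append(
        {
            "LABEL": f"Pooled (random effects, {result.tau2_method})",
            "OR": result.pooled_or,
            "CI_LOW": result.ci_low,
            "CI_HIGH": result.ci_high,
            "WEIGHT_PCT": 100.0,
        }
    )
    return pd.DataFrame(rows)
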