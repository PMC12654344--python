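"""Two-sample summary-data Mendelian randomization estimators.

Given an :class:`~medax.instruments.InstrumentSet` of harmonized per-SNP
effects (β̂_x, β̂_y with standard errors), the battery computes:

* **IVW** — inverse-variance-weighted regression of β̂_y on β̂_x through the
  origin; the primary estimator.  The default multiplicative random-effects
  variant inflates the standard error by ``max(1, sqrt(Q / (n−1)))`` so
  heterogeneity never deflates uncertainty.
* **MR-Egger** — the same regression with an unconstrained intercept;
  a nonzero intercept flags directional pleiotropy.
* **Weighted median** — the 50th weight percentile of per-SNP Wald ratios;
  consistent when at least half the weight comes from valid instruments.
* **Simple mode** — the argmax of a kernel-density smooth of the ratios.
* **Cochran's Q / MR-PRESSO** — heterogeneity and outlier diagnostics.

A link is declared *reliable* when the IVW p-value clears alpha and the
IVW, weighted-median, Egger-slope and PRESSO-corrected estimates agree in
sign; this cross-method concordance rule is what the bidirectional wrapper
applies in each direction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .instruments import InstrumentSet

logger = logging.getLogger(__name__)

Z95 = 1.959964  # two-sided 95% normal quantile, software convention


@dataclass(frozen=True)
class MREstimate:
    """A method-tagged causal estimate with normal-theory 95% CI."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(f"{self.method}: se must be > 0, got {self.se}")
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ValidationError(f"{self.method}: CI does not bracket the estimate")


def _estimate(method: str, beta: float, se: float, n_snp: int, pvalue: float | None = None) -> MREstimate:
    if pvalue is None:
        pvalue = 2.0 * stats.norm.sf(abs(beta) / se)
    pvalue = min(max(pvalue, np.nextafter(0, 1)), 1.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(pvalue),
        n_snp=n_snp,
    )


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy and outlier diagnostics for one link."""

    q: float
    q_df: int
    q_pvalue: float
    egger_intercept: MREstimate | None = None
    presso_global_pvalue: float | None = None
    presso_outliers: list[str] = field(default_factory=list)
    presso_corrected: MREstimate | None = None


@dataclass
class BatteryReport:
    """All estimators plus diagnostics and the cross-method verdict."""

    exposure_name: str
    outcome_name: str
    estimates: dict[str, MREstimate]
    sensitivity: SensitivityReport | None
    reliable: bool
    degraded: list[str] = field(default_factory=list)

    @property
    def ivw(self) -> MREstimate:
        return self.estimates["ivw"]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "METHOD": est.method,
                "BETA": est.beta,
                "SE": est.se,
                "CI_LOW": est.ci_low,
                "CI_HIGH": est.ci_high,
                "P": est.pvalue,
                "N_SNP": est.n_snp,
            }
            for est in self.estimates.values()
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d: dict = {
            "exposure": self.exposure_name,
            "outcome": self.outcome_name,
            "reliable": self.reliable,
            "degraded": self.degraded,
            "estimates": {k: vars(v) for k, v in self.estimates.items()},
        }
        if self.sensitivity is not None:
            s = self.sensitivity
            d["sensitivity"] = {
                "q": s.q,
                "q_df": s.q_df,
                "q_pvalue": s.q_pvalue,
                "egger_intercept": vars(s.egger_intercept) if s.egger_intercept else None,
                "presso_global_pvalue": s.presso_global_pvalue,
                "presso_outliers": s.presso_outliers,
                "presso_corrected": vars(s.presso_corrected) if s.presso_corrected else None,
            }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def wald_ratio(instr: InstrumentSet) -> MREstimate:
    """Single-SNP Wald ratio β_y/β_x; first-order delta se = se_y/|β_x|."""
    if instr.n_snp != 1:
        raise ValidationError("wald_ratio requires exactly one SNP")
    p = instr.pairs[0]
    if p.beta_exposure == 0:
        raise ValidationError("wald_ratio undefined for beta_exposure = 0")
    beta = p.beta_outcome / p.beta_exposure
    se = p.se_outcome / abs(p.beta_exposure)
    return _estimate("wald", beta, se, 1)


def ivw(instr: InstrumentSet, variant: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate (origin-constrained weighted LS).

    ``variant`` is ``"fixed"`` or ``"multiplicative_random"`` (default); the
    random-effects variant scales the fixed-effect se by
    ``max(1, sqrt(Q/(n−1)))`` so it is never smaller than the fixed one.
    A single-SNP set delegates to :func:`wald_ratio`.
    """
    if instr.n_snp == 0:
        raise ValidationError("ivw: empty instrument set")
    if instr.n_snp == 1:
        return wald_ratio(instr)
    if variant not in ("fixed", "multiplicative_random"):
        raise ValidationError(f"unknown IVW variant {variant!r}")
    bx, _, by, sy = instr.arrays()
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0:
        raise ValidationError("ivw: all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se = math.sqrt(1.0 / denom)
    if variant == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (instr.n_snp - 1)))
    return _estimate("ivw", beta, se, instr.n_snp)


def egger(instr: InstrumentSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger: weighted regression of β_y on β_x with an intercept.

    Inputs are re-oriented so every exposure beta is nonnegative before the
    fit (the estimator is defined up to allele orientation).  Standard
    errors use the multiplicative random-effects convention (residual scale
    floored at 1); p-values are two-sided normal.

    Returns ``(slope, intercept)`` estimates; the intercept is the
    directional-pleiotropy diagnostic.
    """
    if instr.n_snp < 3:
        raise ValidationError("egger requires at least 3 SNPs")
    bx, _, by, sy = instr.arrays()
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = instr.n_snp - 2
    sigma2 = float(np.sum(w * resid**2)) / dof
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    slope = _estimate("egger_slope", coef[1], se_slope, instr.n_snp)
    intercept = _estimate("egger_intercept", coef[0], se_int, instr.n_snp)
    return slope, intercept


def _ratio_arrays(instr: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Wald ratios and their first-order-delta weights; zero-β_x SNPs logged out."""
    bx, _, by, sy = instr.arrays()
    ok = bx != 0
    if not ok.all():
        for p in np.asarray(instr.snp_ids())[~ok]:
            logger.info("ratio estimate: excluded %s (beta_exposure = 0)", p)
    bx, by, sy = bx[ok], by[ok], sy[ok]
    ratios = by / bx
    weights = bx**2 / sy**2  # inverse of first-order ratio variance se_y^2/beta_x^2
    return ratios, weights


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weight-interpolated 50th percentile of ratio estimates."""
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint convention
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    i = int(np.searchsorted(cum, 0.5))
    frac = (0.5 - cum[i - 1]) / (cum[i] - cum[i - 1])
    return float(r[i - 1] + frac * (r[i] - r[i - 1]))


def weighted_median(instr: InstrumentSet, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with a seeded SNP-resampling bootstrap se."""
    if instr.n_snp < 3:
        raise ValidationError("weighted_median requires at least 3 SNPs")
    ratios, weights = _ratio_arrays(instr)
    if ratios.size < 3:
        raise ValidationError("weighted_median: fewer than 3 usable ratios")
    beta = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    k = ratios.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, k, size=k)
        boots[b] = _weighted_median(ratios[idx], weights[idx])
    se = float(np.std(boots, ddof=1))
    if se == 0:  # degenerate (all ratios identical)
        se = np.finfo(float).tiny
        est = MREstimate("weighted_median", beta, 1e-300, beta, beta, np.nextafter(0, 1), instr.n_snp)
        return est
    return _estimate("weighted_median", beta, se, instr.n_snp)


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        return 0.0
    return 0.9 * spread * x.size ** (-0.2)


def mode_estimate(
    instr: InstrumentSet, bandwidth_factor: float = 1.0, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Simple mode-based estimate: argmax of a normal-kernel density of ratios.

    The bandwidth is ``bandwidth_factor`` times the Silverman plug-in rule on
    the ratio estimates; the se comes from a seeded SNP bootstrap.
    """
    if instr.n_snp < 3:
        raise ValidationError("mode_estimate requires at least 3 SNPs")
    ratios, weights = _ratio_arrays(instr)
    if ratios.size < 3:
        raise ValidationError("mode_estimate: fewer than 3 usable ratios")

    def kde_argmax(r: np.ndarray) -> float:
        h = bandwidth_factor * _silverman_bandwidth(r)
        if h == 0:
            return float(r[0])
        grid = np.linspace(r.min(), r.max(), 512)
        dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2).sum(axis=1)
        return float(grid[np.argmax(dens)])

    beta = kde_argmax(ratios)
    rng = np.random.default_rng(seed)
    k = ratios.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = kde_argmax(ratios[rng.integers(0, k, size=k)])
    se = float(np.std(boots, ddof=1))
    if se == 0:
        return MREstimate("mode", beta, 1e-300, beta, beta, np.nextafter(0, 1), instr.n_snp)
    return _estimate("mode", beta, se, instr.n_snp)


def cochran_q(instr: InstrumentSet, beta_ref: float) -> tuple[float, int, float]:
    """Cochran's Q about a reference slope.

    Q = Σ w_j (β_yj − beta_ref·β_xj)² with w_j = 1/se_yj²; df = n−1;
    p from the chi-square upper tail.
    """
    if instr.n_snp < 2:
        raise ValidationError("cochran_q requires at least 2 SNPs")
    bx, _, by, sy = instr.arrays()
    w = 1.0 / sy**2
    q = float(np.sum(w * (by - beta_ref * bx) ** 2))
    df = instr.n_snp - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_ivw_betas(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, one per SNP (vectorized)."""
    s_xy = np.sum(w * bx * by)
    s_xx = np.sum(w * bx**2)
    return (s_xy - w * bx * by) / (s_xx - w * bx**2)


def mr_presso(
    instr: InstrumentSet,
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> tuple[float, list[str], MREstimate | None]:
    """MR-PRESSO-style global pleiotropy test and outlier removal.

    The observed residual sum of squares is computed from leave-one-out IVW
    fits (each SNP's residual taken against the slope fitted without it,
    inverse-variance weighted).  Its null distribution comes from ``n_sim``
    parametric draws of β_y ~ N(β_loo·β_x, se_y²) under the fitted model.
    The global p-value uses the (1+count)/(n_sim+1) permutation convention.
    Per-SNP outlier p-values are Bonferroni-corrected over n_snp; when
    outliers are found, an outlier-free IVW re-estimate is returned.

    Returns ``(global_pvalue, outlier_snp_ids, corrected_ivw_or_None)``.
    """
    if instr.n_snp < 4:
        raise ValidationError(
            "mr_presso requires at least 4 SNPs (leave-one-out fits need 3 remaining)"
        )
    bx, _, by, sy = instr.arrays()
    w = 1.0 / sy**2
    beta_loo = _loo_ivw_betas(bx, by, w)
    obs_terms = w * (by - beta_loo * bx) ** 2
    rss_obs = float(obs_terms.sum())

    rng = np.random.default_rng(seed)
    mu = beta_loo * bx
    sim_by = rng.normal(loc=mu, scale=sy, size=(n_sim, instr.n_snp))
    s_xy = np.sum(w * bx * sim_by, axis=1)
    s_xx = float(np.sum(w * bx**2))
    sim_loo = (s_xy[:, None] - w * bx * sim_by) / (s_xx - w * bx**2)
    sim_terms = w * (sim_by - sim_loo * bx) ** 2
    sim_rss = sim_terms.sum(axis=1)

    global_p = (1.0 + float(np.sum(sim_rss >= rss_obs))) / (n_sim + 1.0)

    outliers: list[str] = []
    ids = instr.snp_ids()
    per_snp_p = (1.0 + np.sum(sim_terms >= obs_terms[None, :], axis=0)) / (n_sim + 1.0)
    for j, p in enumerate(per_snp_p):
        if p * instr.n_snp < outlier_alpha:
            outliers.append(ids[j])
            logger.info("mr_presso: %s flagged as outlier (corrected p=%.3g)", ids[j], p * instr.n_snp)

    corrected = None
    if outliers:
        reduced = instr.subset([s for s in ids if s not in outliers])
        if reduced.n_snp >= 1:
            corrected = ivw(reduced)
    return global_p, outliers, corrected


def run_battery(
    instr: InstrumentSet,
    alpha: float = 0.05,
    seed: int = 0,
    n_boot: int = 1000,
    presso_sims: int = 1000,
    ivw_variant: str = "multiplicative_random",
) -> BatteryReport:
    """Run every estimator plus diagnostics and apply the concordance rule.

    The verdict is ``reliable`` iff the IVW p-value is below ``alpha`` AND
    the IVW, weighted-median, Egger-slope and (when produced)
    PRESSO-corrected estimates share a sign.  Sets too small for a method
    degrade gracefully: the skipped methods are listed in ``degraded`` and
    excluded from the concordance check.
    """
    if instr.n_snp == 0:
        raise ValidationError("run_battery: empty instrument set")
    estimates: dict[str, MREstimate] = {}
    degraded: list[str] = []
    sensitivity: SensitivityReport | None = None

    estimates["ivw"] = ivw(instr, variant=ivw_variant)

    if instr.n_snp >= 3:
        slope, intercept = egger(instr)
        estimates["egger_slope"] = slope
        estimates["weighted_median"] = weighted_median(instr, n_boot=n_boot, seed=seed)
        estimates["mode"] = mode_estimate(instr, n_boot=n_boot, seed=seed + 1)
        q, df, qp = cochran_q(instr, estimates["ivw"].beta)
        sensitivity = SensitivityReport(q=q, q_df=df, q_pvalue=qp, egger_intercept=intercept)
    else:
        degraded += ["egger", "weighted_median", "mode"]
        if instr.n_snp >= 2:
            q, df, qp = cochran_q(instr, estimates["ivw"].beta)
            sensitivity = SensitivityReport(q=q, q_df=df, q_pvalue=qp)

    if instr.n_snp >= 4:
        gp, outliers, corrected = mr_presso(
            instr, n_sim=presso_sims, seed=seed + 2, outlier_alpha=alpha
        )
        assert sensitivity is not None
        sensitivity.presso_global_pvalue = gp
        sensitivity.presso_outliers = outliers
        sensitivity.presso_corrected = corrected
        if corrected is not None:
            estimates["presso_corrected"] = corrected
    else:
        degraded.append("mr_presso")

    concordant_methods = [
        m for m in ("ivw", "weighted_median", "egger_slope", "presso_corrected") if m in estimates
    ]
    signs = {np.sign(estimates[m].beta) for m in concordant_methods}
    reliable = estimates["ivw"].pvalue < alpha and len(signs) == 1
    return BatteryReport(
        exposure_name=instr.exposure_name,
        outcome_name=instr.outcome_name,
        estimates=estimates,
        sensitivity=sensitivity,
        reliable=reliable,
        degraded=degraded,
    )


@dataclass
class BidirectionalReport:
    """Paired forward/reverse battery reports with an interpretation flag."""

    forward: BatteryReport | None
    reverse: BatteryReport | None
    interpretation: str


def bidirectional(
    forward: InstrumentSet | None,
    reverse: InstrumentSet | None,
    alpha: float = 0.05,
    seed: int = 0,
    **battery_kwargs,
) -> BidirectionalReport:
    """Run the battery in both causal directions and interpret the pair.

    A direction with an empty (or missing) instrument set is reported as
    ``no instruments`` without affecting the other.  The flag is
    ``unidirectional`` when the forward link is reliable and the reverse is
    not significant, ``bidirectional`` when both are reliable, and
    ``null`` / descriptive strings otherwise.
    """
    fwd = (
        run_battery(forward, alpha=alpha, seed=seed, **battery_kwargs)
        if forward is not None and forward.n_snp > 0
        else None
    )
    rev = (
        run_battery(reverse, alpha=alpha, seed=seed + 1000, **battery_kwargs)
        if reverse is not None and reverse.n_snp > 0
        else None
    )
    fwd_ok = fwd is not None and fwd.reliable
    rev_sig = rev is not None and rev.ivw.pvalue < alpha
    if rev is None and fwd is None:
        interp = "no instruments"
    elif rev is None:
        interp = "unidirectional (reverse: no instruments)" if fwd_ok else "null"
    elif fwd_ok and not rev_sig:
        interp = "unidirectional"
    elif fwd_ok and rev_sig:
        interp = "bidirectional"
    elif rev_sig:
        interp = "reverse only"
    else:
        interp = "null"
    return BidirectionalReport(forward=fwd, reverse=rev, interpretation=interp)
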