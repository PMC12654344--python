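"""Two-step mediation decomposition of a total causal effect.

The total exposure-on-outcome effect β_all splits into an indirect
(mediated) component, the product of coefficients β₁·β₂ from the
exposure→mediator and mediator→outcome links, and the remaining direct
component β_all − β₁·β₂.  The proportion mediated is (β₁·β₂)/β_all,
reported here as a magnitude percentage with a sign-consistency flag
(indirect and total effects of opposite sign mean "inconsistent
mediation", where the proportion has no clean interpretation).  The
standard error of the proportion comes from the delta method on the
product and the ratio; the 95% interval is truncated to [0, 100]%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .mr_engine import Z95, BatteryReport


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition and the proportion mediated."""

    beta_total: float
    se_total: float
    beta1: float
    se1: float
    beta2: float
    se2: float
    indirect: float
    direct: float
    indirect_se: float
    proportion: float | None          # percent, magnitude
    proportion_se: float | None       # percent
    proportion_ci: tuple[float, float] | None  # percent, floor 0 / ceiling 100
    sign_consistent: bool
    proportion_defined: bool

    def to_row(self) -> dict:
        return {
            "BETA1": self.beta1,
            "BETA2": self.beta2,
            "BETA_TOTAL": self.beta_total,
            "INDIRECT": self.indirect,
            "DIRECT": self.direct,
            "PROPORTION_PCT": self.proportion,
            "CI_LOW_PCT": self.proportion_ci[0] if self.proportion_ci else None,
            "CI_HIGH_PCT": self.proportion_ci[1] if self.proportion_ci else None,
            "SIGN_CONSISTENT": self.sign_consistent,
        }


def decompose(
    beta_total: float,
    se_total: float,
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
) -> MediationResult:
    """Decompose a total effect into direct and mediated components.

    indirect = β₁·β₂; direct = β_all − indirect (additivity is exact by
    construction); proportion = |indirect/β_all|·100 with a delta-method se
    and a [0, 100]%-truncated 95% CI.  A zero total effect leaves the
    proportion undefined (flagged) while the other fields are still
    returned.
    """
    for name, se in (("se_total", se_total), ("se1", se1), ("se2", se2)):
        if not se > 0:
            raise ValidationError(f"{name} must be > 0, got {se}")
    indirect = beta1 * beta2
    direct = beta_total - indirect
    # Sobel variance of the product of two independent estimates
    var_indirect = beta2**2 * se1**2 + beta1**2 * se2**2
    indirect_se = math.sqrt(var_indirect)

    if beta_total == 0:
        return MediationResult(
            beta_total, se_total, beta1, se1, beta2, se2,
            indirect, direct, indirect_se,
            proportion=None, proportion_se=None, proportion_ci=None,
            sign_consistent=False, proportion_defined=False,
        )

    ratio = indirect / beta_total
    sign_consistent = ratio >= 0
    # delta method on the ratio of two independent estimates
    var_ratio = (var_indirect + ratio**2 * se_total**2) / beta_total**2
    prop_se = math.sqrt(var_ratio) * 100.0
    prop = abs(ratio) * 100.0
    lo = max(0.0, prop - Z95 * prop_se)
    hi = min(100.0, prop + Z95 * prop_se)
    return MediationResult(
        beta_total, se_total, beta1, se1, beta2, se2,
        indirect, direct, indirect_se,
        proportion=prop, proportion_se=prop_se, proportion_ci=(lo, hi),
        sign_consistent=sign_consistent, proportion_defined=True,
    )


@dataclass
class TwoStepResult:
    """Mediation result gated on the reliability of both causal links."""

    result: MediationResult | None
    step1_reliable: bool
    step2_reliable: bool
    eligible: bool


def two_step(
    exposure_mediator: BatteryReport,
    mediator_outcome: BatteryReport,
    exposure_outcome: BatteryReport,
) -> TwoStepResult:
    """Mediation from three MR batteries (each link on its own instruments).

    β₁, β₂ and β_all are the IVW estimates of the exposure→mediator,
    mediator→outcome and exposure→outcome batteries.  The decomposition is
    attempted only when both step links pass the cross-method reliability
    rule; the flags record which links passed.
    """
    for name, rep in (
        ("exposure_mediator", exposure_mediator),
        ("mediator_outcome", mediator_outcome),
        ("exposure_outcome", exposure_outcome),
    ):
        if rep is None:
            raise ValidationError(f"two_step: missing battery {name}")
    s1, s2 = exposure_mediator.reliable, mediator_outcome.reliable
    eligible = s1 and s2
    if not eligible:
        return TwoStepResult(result=None, step1_reliable=s1, step2_reliable=s2, eligible=False)
    res = decompose(
        beta_total=exposure_outcome.ivw.beta,
        se_total=exposure_outcome.ivw.se,
        beta1=exposure_mediator.ivw.beta,
        se1=exposure_mediator.ivw.se,
        beta2=mediator_outcome.ivw.beta,
        se2=mediator_outcome.ivw.se,
    )
    return TwoStepResult(result=res, step1_reliable=s1, step2_reliable=s2, eligible=True)


def mediation_table(rows: dict[str, MediationResult]) -> pd.DataFrame:
    """Stack labelled mediation results into a report table."""
    out = []
    for label, res in rows.items():
        row = {"PATHWAY": label}
        row.update(res.to_row())
        out.append(row)
    return pd.DataFrame(out)
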