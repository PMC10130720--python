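"""GREML-style power calculations for SNP-based h2 and genetic correlation.

Follows the GCTA-GREML power-calculator approach: the sampling variance of a
SNP-heritability estimate in a sample of n individuals is approximately

    var(h2_hat) = 2 / (n^2 * var_rel)

where ``var_rel`` is the variance of the off-diagonal relatedness values
(2e-5 is the conventional figure for conventionally unrelated samples; a
sample containing relatives, like a wild plant population with sibships, has
a larger value and hence more power — pass the empirical GRM to use it).
The h2 test uses a 1-df non-central chi-squared with ncp = h2^2 / var(h2_hat).

For the genetic correlation between two traits measured on the same
individuals, a delta-method approximation of the sampling variance of
r_g = cov_g / sqrt(v1 v2) is used (covariance cross-terms neglected):

    var(rg_hat) = V (1 + rp^2) / (h1^2 h2^2) + rg^2 V / 2 (1/h1^4 + 1/h2^4)

with V = 1 / (n^2 var_rel) and rp the phenotypic correlation (defaulting to
the purely genetic value rg * h1 * h2), tested against a standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .relatedness import RelatednessMatrix

#: conventional variance of relatedness among unrelated individuals
DEFAULT_VAR_REL = 2e-5


@dataclass
class PowerSpec:
    """Inputs for a GREML power calculation."""

    n: int
    h2: float = 0.1
    var_rel: float = DEFAULT_VAR_REL
    alpha: float = 0.05
    # bivariate (genetic correlation) settings
    h2_second: float | None = None
    rg: float = 0.0
    rp: float | None = None  # None -> rg * h1 * h2
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if self.h2_second is not None and not 0.0 <= self.h2_second <= 1.0:
            raise ValueError("h2_second must be in [0, 1]")
        if not self.var_rel > 0:
            raise ValueError("var_rel must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not -1.0 <= self.rg <= 1.0:
            raise ValueError("rg must be in [-1, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def var_rel_from_grm(grm: RelatednessMatrix) -> float:
    """Empirical variance of the off-diagonal relatedness values."""
    return float(grm.off_diagonal().var(ddof=1))


def greml_power_h2(spec: PowerSpec) -> dict:
    """Power to detect non-zero h2 at the given design.

    Returns the standard error of h2_hat, the non-centrality parameter and
    the power of the (default) 1-df chi-squared test at ``alpha``.
    """
    se = float(np.sqrt(2.0 / (spec.n**2 * spec.var_rel)))
    ncp = float((spec.h2 / se) ** 2)
    if spec.one_sided:
        zcrit = stats.norm.ppf(1.0 - spec.alpha)
        power = float(stats.norm.sf(zcrit - spec.h2 / se))
    else:
        crit = stats.chi2.ppf(1.0 - spec.alpha, df=1)
        power = float(stats.ncx2.sf(crit, df=1, nc=ncp))
    return {"se_h2": se, "ncp": ncp, "power": power}


def greml_power_rg(spec: PowerSpec) -> dict:
    """Power to detect a non-zero genetic correlation (overlapping samples)."""
    if spec.h2_second is None:
        raise ValueError("h2_second required for a genetic-correlation power")
    h1sq, h2sq = spec.h2, spec.h2_second
    if h1sq * h2sq == 0.0:
        if spec.rg != 0.0:
            raise ValueError("r_G undefined when either h2 is zero")
        return {"se_rg": float("inf"), "power": spec.alpha}
    V = 1.0 / (spec.n**2 * spec.var_rel)
    rp = spec.rp if spec.rp is not None else spec.rg * np.sqrt(h1sq * h2sq)
    var_rg = V * (1.0 + rp**2) / (h1sq * h2sq) + spec.rg**2 * V / 2.0 * (
        1.0 / h1sq**2 + 1.0 / h2sq**2
    )
    se = float(np.sqrt(var_rg))
    if spec.rg == 0.0:
        # the normal test has size alpha exactly under the null
        return {"se_rg": se, "power": spec.alpha}
    zcrit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    shift = spec.rg / se
    power = float(stats.norm.sf(zcrit - shift) + stats.norm.cdf(-zcrit - shift))
    return {"se_rg": se, "power": power}
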