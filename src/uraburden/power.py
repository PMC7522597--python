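"""Prospective power for a gene's burden test.

The one-sided binomial burden test is approximated by the one-sample
proportion test with Cohen's arcsine effect size

    h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p0)),

giving power = Phi(h sqrt(n) - z_{1-alpha}) and the sample size required
for a target power by inverting the same formula.  p0 is the expected
carrier probability under the rescaled null and p1 the alternative carrier
probability (e.g. the observed carrier fraction); alpha is typically a
Bonferroni-corrected level (0.05 divided by the joint universe size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerSpec", "proportion_power", "required_n", "arcsine_effect_size"]


@dataclass(frozen=True)
class PowerSpec:
    p0: float
    p1: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < self.p1 < 1.0:
            raise ValueError(
                f"need 0 < p0 < p1 < 1 for a one-sided greater test, "
                f"got p0={self.p0}, p1={self.p1}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")


def arcsine_effect_size(p0: float, p1: float) -> float:
    """Cohen's h for proportions."""
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p0))


def proportion_power(spec: PowerSpec, n: int) -> float:
    """Normal-approximation power of the one-sided one-sample proportion test."""
    if n < 1:
        raise ValueError("n must be >= 1")
    h = arcsine_effect_size(spec.p0, spec.p1)
    return float(norm.cdf(h * math.sqrt(n) - norm.ppf(1.0 - spec.alpha)))


def required_n(spec: PowerSpec, target_power: float = 0.8) -> int:
    """Smallest integer sample size reaching ``target_power``.

    The closed-form n = ((z_{1-alpha} + z_power) / h)^2 is rounded up and
    then verified against :func:`proportion_power`, stepping by one if
    rounding lands on the wrong side.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target power {target_power} outside (0, 1)")
    h = arcsine_effect_size(spec.p0, spec.p1)
    n = math.ceil(((norm.ppf(1.0 - spec.alpha) + norm.ppf(target_power)) / h) ** 2)
    n = max(n, 1)
    while proportion_power(spec, n) < target_power:
        n += 1
    while n > 1 and proportion_power(spec, n - 1) >= target_power:
        n -= 1
    return n
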