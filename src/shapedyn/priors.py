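"""Prior specification for the joint phylodynamic model.

Default choices:

* birth, death and sampling rates: Exp(10) per interval (mean 0.1 / ka),
  reflecting the order of magnitude typical of macroevolutionary rates;
* origin time: improper uniform on (0, inf), contributing zero log density
  (the origin must still exceed the root age);
* Brownian-motion root values: Normal(0, 2) per trait;
* per-trait variance rate sigma^2: LogNormal with log-space location 1 and
  log-space scale 0.3 (a real-space parameterization is available via
  ``lognormal_real_space``);
* among-character correlation: Uniform(-1, 1), with states whose implied
  covariance matrix is not positive definite rejected (-inf);
* relaxed-clock hyperpriors: Exp(10) on the mean rate and Gamma(0.54,
  scale 0.38) on the log-scale s.d. of the lognormal clock (mean 0.2); the
  two-category clock uses Exp(5) on each rate value and a uniform category
  assignment (log 1/2 per branch);
* tip ages: uniform within the per-sample calibrated one-sigma interval.

``Exp(k)`` is parameterized by its rate (mean 1/k); ``Gamma(a, s)`` by
shape and scale (mean a*s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["PriorSpec"]


def _expon(rate: float):
    return stats.expon(scale=1.0 / rate)


def lognormal_log_space(location: float, scale: float):
    """LogNormal with mean and s.d. of log(x) given directly."""
    return stats.lognorm(s=scale, scale=np.exp(location))


def lognormal_real_space(mean: float, scale: float):
    """LogNormal with a real-space mean and log-space s.d."""
    return stats.lognorm(s=scale, scale=mean * np.exp(-0.5 * scale ** 2))


@dataclass
class PriorSpec:
    """Bundle of frozen scipy distributions for every model block."""

    birth: object = field(default_factory=lambda: _expon(10.0))
    death: object = field(default_factory=lambda: _expon(10.0))
    sampling: object = field(default_factory=lambda: _expon(10.0))
    root_value: object = field(default_factory=lambda: stats.norm(0.0, 2.0))
    sigma2: object = field(default_factory=lambda: lognormal_log_space(1.0, 0.3))
    corr: object = field(default_factory=lambda: stats.uniform(-1.0, 2.0))
    clock_mean: object = field(default_factory=lambda: _expon(10.0))
    clock_sd: object = field(default_factory=lambda: stats.gamma(0.54, scale=0.38))
    ncat_rate: object = field(default_factory=lambda: _expon(5.0))

    def logpdf_origin(self, origin_age: float, root_age: float) -> float:
        """Improper U(0, inf) prior: zero contribution on its support."""
        return 0.0 if origin_age > max(root_age, 0.0) else -np.inf

    @staticmethod
    def logpdf_tip_age(age: float, lo: float, hi: float) -> float:
        if hi < lo:
            raise ValueError("tip age bounds out of order")
        if hi == lo:
            return 0.0 if age == lo else -np.inf
        if lo <= age <= hi:
            return -np.log(hi - lo)
        return -np.inf
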