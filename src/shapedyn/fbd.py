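"""Fossilized birth-death (FBD) process densities with piecewise-constant
(skyline) rates and sampled ancestors.

The FBD process starts with one lineage at the origin time and runs toward
the present (age 0).  Lineages branch at rate lambda, terminate at rate mu,
and are sampled (without termination) at rate psi; extant lineages are
additionally sampled at the present with probability rho (zero throughout
this package, since every sample predates the present).  The observed
("sampled") tree contains exactly the lineages ancestral to at least one
sample; samples with sampled descendants appear as degree-2 sampled
ancestors.

Rates are per ka because ages are in ka BP.  Interval boundaries are ages
(strictly decreasing); a boundary age belongs to the *older* interval,
matching the climate-bin convention used elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tree import SATree

__all__ = [
    "FBDParams",
    "fbd_log_density",
    "diversification_rate",
    "turnover_rate",
]


@dataclass
class FBDParams:
    """Skyline FBD parameters.

    ``lam``, ``mu``, ``psi`` have one entry per interval (oldest first);
    ``boundaries`` holds the interval edges in ka BP, strictly decreasing,
    with ``len(boundaries) == n_intervals - 1``.  A constant-rate model is
    the special case of one interval and no boundaries.
    """

    lam: np.ndarray
    mu: np.ndarray
    psi: np.ndarray
    boundaries: np.ndarray = field(default_factory=lambda: np.array([]))
    rho: float = 0.0

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.psi = np.atleast_1d(np.asarray(self.psi, dtype=float))
        self.boundaries = np.atleast_1d(np.asarray(self.boundaries, dtype=float)) \
            if np.size(self.boundaries) else np.empty(0)
        m = len(self.lam)
        if not (len(self.mu) == len(self.psi) == m):
            raise ValueError("lam, mu, psi must have equal length")
        if len(self.boundaries) != m - 1:
            raise ValueError("need exactly n_intervals - 1 boundaries")
        if m > 1 and not np.all(np.diff(self.boundaries) < 0):
            raise ValueError("boundaries must be strictly decreasing (ka BP)")
        if np.any(self.lam < 0) or np.any(self.mu < 0) or np.any(self.psi < 0):
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")

    @property
    def n_intervals(self) -> int:
        return len(self.lam)

    def interval_index(self, age: float) -> int:
        """Interval containing ``age``; a boundary belongs to the older side."""
        return int(np.searchsorted(-self.boundaries, -age, side="left"))


# ---------------------------------------------------------------------------
# p0 / q machinery
# ---------------------------------------------------------------------------
#
# Within an interval with constant (lam, mu, psi) and with p0 known at the
# interval's younger edge, both the extinction-or-never-sampled probability
# p0(t) and the observed-lineage factor q(t) have closed forms (the Riccati
# equation solved piecewise).  Writing s = t - t_young,
#
#   A = sqrt((lam - mu - psi)^2 + 4 lam psi)
#   B = ((1 - 2 p0(t_young)) lam + mu + psi) / A
#   p0(t) = (lam + mu + psi
#            - A (e^{As}(1+B) - (1-B)) / (e^{As}(1+B) + (1-B))) / (2 lam)
#   q(t)  = 4 e^{As} / (e^{As}(1+B) + (1-B))^2          (q(t_young) = 1)
#
# so log q accumulates across intervals.  Degenerate corners (lam = 0, or
# A = 0) fall back to the limiting solutions.


class _PQ:
    """Piecewise p0 / log-q evaluator for a skyline parameterization."""

    def __init__(self, params: FBDParams):
        self.params = params
        m = params.n_intervals
        # younger edge age of each interval, oldest interval first
        self.t_young = np.concatenate([params.boundaries, [0.0]])
        self.p_young = np.empty(m)      # p0 at each interval's younger edge
        self.logq_young = np.empty(m)   # accumulated log q at younger edge
        p = 1.0 - params.rho
        logq = 0.0
        for j in range(m - 1, -1, -1):
            self.p_young[j] = p
            self.logq_young[j] = logq
            if j > 0:
                span = params.boundaries[j - 1] - self.t_young[j]
                p = self._p0_in(j, span, p)
                logq = logq + self._logq_in(j, span, self.p_young[j])

    # closed-form pieces -----------------------------------------------------
    def _consts(self, j: int, p_init: float):
        lam = self.params.lam[j]
        mu = self.params.mu[j]
        psi = self.params.psi[j]
        A = np.sqrt((lam - mu - psi) ** 2 + 4.0 * lam * psi)
        if A > 0:
            B = ((1.0 - 2.0 * p_init) * lam + mu + psi) / A
        else:
            B = 0.0
        return lam, mu, psi, A, B

    def _p0_in(self, j: int, s, p_init: float):
        lam, mu, psi, A, B = self._consts(j, p_init)
        s = np.asarray(s, dtype=float)
        if lam == 0.0:
            tot = mu + psi
            if tot == 0.0:
                return np.broadcast_to(p_init, s.shape).copy() if s.ndim else p_init
            c = mu / tot
            return c + (p_init - c) * np.exp(-tot * s)
        if A == 0.0:
            # lam = mu, psi = 0: p0' = lam (1 - p0)^2
            u0 = 1.0 - p_init
            return 1.0 - u0 / (1.0 + lam * u0 * s)
        e = np.exp(A * s)
        return (lam + mu + psi
                - A * (e * (1.0 + B) - (1.0 - B)) / (e * (1.0 + B) + (1.0 - B))
                ) / (2.0 * lam)

    def _logq_in(self, j: int, s, p_init: float):
        lam, mu, psi, A, B = self._consts(j, p_init)
        s = np.asarray(s, dtype=float)
        if lam == 0.0:
            return -(mu + psi) * s
        if A == 0.0:
            u0 = 1.0 - p_init
            return -2.0 * np.log1p(lam * u0 * s)
        return (np.log(4.0) + A * s
                - 2.0 * np.log(np.exp(A * s) * (1.0 + B) + (1.0 - B)))

    # public evaluation -------------------------------------------------------
    def _intervals_of(self, age: np.ndarray) -> np.ndarray:
        b = self.params.boundaries
        if b.size == 0:
            return np.zeros(age.shape, dtype=int)
        return np.searchsorted(-b, -age, side="left")

    def p0(self, age):
        age = np.asarray(age, dtype=float)
        scalar = age.ndim == 0
        age = np.atleast_1d(age)
        js = self._intervals_of(age)
        out = np.empty_like(age)
        for j in np.unique(js):
            m = js == j
            out[m] = self._p0_in(j, age[m] - self.t_young[j], self.p_young[j])
        return float(out[0]) if scalar else out

    def logq(self, age):
        age = np.asarray(age, dtype=float)
        scalar = age.ndim == 0
        age = np.atleast_1d(age)
        js = self._intervals_of(age)
        out = np.empty_like(age)
        for j in np.unique(js):
            m = js == j
            out[m] = (self.logq_young[j]
                      + self._logq_in(j, age[m] - self.t_young[j], self.p_young[j]))
        return float(out[0]) if scalar else out


def fbd_log_density(tree: SATree, params: FBDParams,
                    condition_on_sampling: bool = True) -> float:
    """Log density of a sampled tree under the skyline FBD process.

    The density is conditioned on the origin time and, by default, on
    observing at least one sample.  Sampled ancestors contribute a
    psi-sampling factor without terminating their lineage; sampled tips
    additionally carry the probability that their continuing (unobserved)
    lineage left no further samples.

    Raises on structurally impossible input (tree older than the origin, a
    sample at age <= 0 while rho = 0); returns ``-inf`` for zero-probability
    but well-formed configurations (e.g. a fossil sample in an interval with
    psi = 0).
    """
    if tree.root.age > tree.origin_age:
        raise ValueError("tree root is older than the origin")
    samples = tree.samples()
    if params.rho == 0.0:
        bad = [n for n in samples if n.age <= 0.0]
        if bad:
            raise ValueError("sample at age <= 0 with rho = 0")

    pq = _PQ(params)

    birth_ages = np.array([n.age for n in tree.bifurcations()])
    tip_ages = np.array([n.age for n in samples if n.is_tip])
    sa_ages = np.array([n.age for n in samples if not n.is_tip])

    with np.errstate(divide="ignore"):
        logf = pq.logq(tree.origin_age)
        if birth_ages.size:
            lam_at = params.lam[pq._intervals_of(birth_ages)]
            if np.any(lam_at <= 0.0):
                return -np.inf
            logf += np.sum(np.log(lam_at) + pq.logq(birth_ages))
        if tip_ages.size:
            psi_at = params.psi[pq._intervals_of(tip_ages)]
            if np.any(psi_at <= 0.0):
                return -np.inf
            p0s = pq.p0(tip_ages)
            logf += np.sum(np.log(psi_at) + np.log(p0s) - pq.logq(tip_ages))
        if sa_ages.size:
            psi_at = params.psi[pq._intervals_of(sa_ages)]
            if np.any(psi_at <= 0.0):
                return -np.inf
            logf += np.sum(np.log(psi_at))
        if condition_on_sampling:
            p0_origin = pq.p0(tree.origin_age)
            if p0_origin >= 1.0:
                return -np.inf
            logf -= np.log1p(-p0_origin)
    return float(logf)


def diversification_rate(lam, mu):
    """Net diversification d = lambda - mu (the rate at which the tree grows)."""
    return np.asarray(lam, dtype=float) - np.asarray(mu, dtype=float)


def turnover_rate(lam, mu):
    """Turnover t = mu / lambda (the rate at which lineages are replaced)."""
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(lam == 0.0):
        raise ValueError("turnover undefined for lambda = 0")
    return mu / lam
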