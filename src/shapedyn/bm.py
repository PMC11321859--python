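"""Multivariate Brownian-motion trait model and relaxed clocks.

Traits evolve along the tree as a correlated random walk: over a branch of
duration ``tau`` with clock rate ``r`` the trait vector gains a multivariate
normal increment with covariance ``tau * r * Sigma``, where ``Sigma`` is an
equicorrelation matrix built from per-trait variance rates sigma^2 and a
single shared among-character correlation.  The root trait values are free
parameters; the overall clock rate is shared across traits.

The log likelihood is computed by a pruning (post-order message-passing)
pass.  Because ``Sigma`` is shared along the whole tree, the traits are
first decorrelated through the eigenbasis of ``Sigma``; each transformed
trait is then an independent univariate Brownian motion, and the messages
are vectorized across traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .priors import PriorSpec, lognormal_log_space, lognormal_real_space
from .tree import Node, SATree

__all__ = [
    "BMParams",
    "ClockState",
    "bm_log_likelihood",
    "clock_log_prior",
    "evaluate_priors",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class BMParams:
    """Root values, per-trait variance rates, shared correlation."""

    root: np.ndarray
    sigma2: np.ndarray
    corr: float = 0.0

    def __post_init__(self):
        self.root = np.atleast_1d(np.asarray(self.root, dtype=float))
        self.sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        if len(self.root) != len(self.sigma2):
            raise ValueError("root and sigma2 must have equal length")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be positive")

    @property
    def k(self) -> int:
        return len(self.sigma2)

    def sigma_matrix(self) -> np.ndarray:
        sd = np.sqrt(self.sigma2)
        sigma = self.corr * np.outer(sd, sd)
        np.fill_diagonal(sigma, self.sigma2)
        return sigma

    def is_positive_definite(self) -> bool:
        """Equicorrelation is PD iff -1/(k-1) < corr < 1 (k > 1)."""
        if self.k == 1:
            return True
        return -1.0 / (self.k - 1) < self.corr < 1.0


@dataclass
class ClockState:
    """Branch-rate model shared across traits.

    * ``ulnc`` — uncorrelated lognormal clock: each branch rate is an
      independent lognormal draw with real-space mean ``mean`` and log-space
      s.d. ``sd``; the rates themselves live on the tree nodes.
    * ``ncat2`` — two estimated rate values; each branch carries a category
      assignment (on the tree nodes) with uniform prior.
    * ``strict`` — a single shared rate (``mean``).
    """

    model: str = "strict"
    mean: float = 1.0
    sd: float = 0.1
    rates: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0]))

    def __post_init__(self):
        if self.model not in ("strict", "ulnc", "ncat2"):
            raise ValueError(f"unknown clock model {self.model!r}")
        self.rates = np.asarray(self.rates, dtype=float)

    def branch_rate(self, node: Node) -> float:
        if self.model == "ulnc":
            return node.rate
        if self.model == "ncat2":
            return float(self.rates[node.rate_cat])
        return self.mean

    def draw_rates(self, tree: SATree, rng: np.random.Generator) -> None:
        """Populate per-branch rates/categories on the tree (simulation).

        Every node owns the branch above it; the root owns the stem branch
        from the origin, which carries a rate under the clock prior even
        though no trait evolution is modelled above the root.
        """
        for node in tree.nodes():
            if self.model == "ulnc":
                mu = np.log(self.mean) - 0.5 * self.sd ** 2
                node.rate = float(np.exp(rng.normal(mu, self.sd)))
            elif self.model == "ncat2":
                node.rate_cat = int(rng.integers(0, 2))


def _branch_time(tree: SATree, node: Node, clock: Optional[ClockState]) -> float:
    dur = tree.duration(node)
    rate = clock.branch_rate(node) if clock is not None else 1.0
    return dur * rate


def bm_log_likelihood(tree: SATree, traits, bm: BMParams,
                      clock: Optional[ClockState] = None) -> float:
    """Pruning-pass log likelihood of observed trait rows at all samples.

    Equivalent to the joint multivariate normal density of the sample trait
    values with mean equal to the root values and covariance given by the
    Kronecker product of the clock-scaled shared-path-length matrix with
    ``Sigma``.  ``traits`` is any object with ``taxa`` and ``values``
    attributes (e.g. :class:`~shapedyn.morpho.TraitMatrix`).
    """
    if not bm.is_positive_definite():
        raise ValueError("trait covariance matrix is not positive definite")
    sigma = bm.sigma_matrix()
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals <= 0):
        raise ValueError("trait covariance matrix is not positive definite")

    row = {t: i for i, t in enumerate(traits.taxa)}
    values = np.asarray(traits.values, dtype=float)
    for node in tree.samples():
        if node.taxon not in row:
            raise ValueError(f"missing trait row for sample {node.taxon!r}")
    z = values @ evecs              # decorrelated traits, one row per taxon
    root_z = evecs.T @ bm.root
    k = bm.k

    logf = 0.0
    msg: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder():
        if node.is_tip:
            msg[id(node)] = (z[row[node.taxon]], np.zeros(k))
            continue
        # propagate child messages over their branches
        child_msgs = []
        for c in node.children:
            m, v = msg.pop(id(c))
            child_msgs.append((m, v + _branch_time(tree, c, clock) * evals))
        if node.is_sampled_ancestor:
            (m, v), = child_msgs
            obs = z[row[node.taxon]]
            if np.any(v <= 0):
                return -np.inf
            logf += float(np.sum(-0.5 * (_LOG_2PI + np.log(v))
                                 - 0.5 * (obs - m) ** 2 / v))
            msg[id(node)] = (obs, np.zeros(k))
        else:
            (m1, v1), (m2, v2) = child_msgs
            v = v1 + v2
            if np.any(v <= 0):
                return -np.inf
            logf += float(np.sum(-0.5 * (_LOG_2PI + np.log(v))
                                 - 0.5 * (m1 - m2) ** 2 / v))
            msg[id(node)] = ((m1 * v2 + m2 * v1) / v, v1 * v2 / v)

    mean, var = msg[id(tree.root)]
    if np.any(var <= 0):
        # a sample sitting exactly at the root pins the root state: the
        # density is degenerate there, which the sampler treats as -inf
        return -np.inf
    logf += float(np.sum(-0.5 * (_LOG_2PI + np.log(var))
                         - 0.5 * (root_z - mean) ** 2 / var))
    return logf


def clock_log_prior(tree: SATree, clock: ClockState,
                    spec: Optional[PriorSpec] = None) -> float:
    """Log prior of the clock state, including hyperpriors.

    ULNC: lognormal log density of every branch rate given (mean, sd), plus
    Exp(10) on the mean and Gamma(0.54, 0.38) on the sd.  nCat2: Exp(5) on
    each rate value plus log(1/2) per branch assignment.
    """
    spec = spec or PriorSpec()
    if clock.model == "strict":
        return float(spec.clock_mean.logpdf(clock.mean))
    # every node owns the branch above it, the root owning the origin stem
    branch_nodes = tree.nodes()
    if clock.model == "ncat2":
        lp = float(np.sum(spec.ncat_rate.logpdf(clock.rates)))
        lp += len(branch_nodes) * np.log(0.5)
        return lp
    # ulnc
    if clock.mean <= 0 or clock.sd <= 0:
        return -np.inf
    rates = np.array([n.rate for n in branch_nodes])
    if np.any(rates <= 0):
        return -np.inf
    dist = lognormal_real_space(clock.mean, clock.sd)
    lp = float(np.sum(dist.logpdf(rates)))
    lp += float(spec.clock_mean.logpdf(clock.mean))
    lp += float(spec.clock_sd.logpdf(clock.sd))
    return lp


def evaluate_priors(tree: SATree, fbd_params, bm: Optional[BMParams],
                    clock: Optional[ClockState], spec: PriorSpec,
                    tip_bounds: Optional[dict] = None) -> float:
    """Joint log prior of a full model state.

    Sums the per-interval rate priors, the (improper, flat) origin prior,
    the Brownian-motion parameter priors, the clock prior, and uniform tip
    age priors within their calibrated intervals.  Returns ``-inf`` for any
    parameter off its support, including correlation values whose implied
    covariance is not positive definite.
    """
    lp = float(np.sum(spec.birth.logpdf(fbd_params.lam))
               + np.sum(spec.death.logpdf(fbd_params.mu))
               + np.sum(spec.sampling.logpdf(fbd_params.psi)))
    lp += spec.logpdf_origin(tree.origin_age, tree.root.age)
    if bm is not None:
        if not bm.is_positive_definite():
            return -np.inf
        lp += float(np.sum(spec.root_value.logpdf(bm.root)))
        lp += float(np.sum(spec.sigma2.logpdf(bm.sigma2)))
        lp += float(spec.corr.logpdf(bm.corr))
    if clock is not None:
        lp += clock_log_prior(tree, clock, spec)
    if tip_bounds:
        for node in tree.samples():
            if node.taxon in tip_bounds:
                lo, hi = tip_bounds[node.taxon]
                lp += spec.logpdf_tip_age(node.age, lo, hi)
    return lp
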