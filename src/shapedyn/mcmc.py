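"""Metropolis-Hastings sampler over trees, tip ages, skyline rates, trait
and clock parameters.

The target density is the product of the FBD skyline tree density, the
Brownian-motion trait likelihood and the parameter priors; following the
convention of Bayesian phylogenetic log files, the "prior" column of the
trace contains the parameter priors *plus* the tree process density, so an
under-the-prior run (trait likelihood disabled, likelihood column constant
zero) still estimates diversification rates from the sampling times alone.

Proposal tuning is fixed (no auto-adaptation) so the chain is a plain
Metropolis-Hastings kernel, reproducible from its seed.  The move set is a
minimal ergodic collection: scale moves on all positive parameters, sliding
moves on node, tip and origin ages, narrow exchange and age-respecting
subtree-prune-regraft on the topology, a reversible-jump toggle between
terminal samples and sampled ancestors, and clock-specific moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bm import BMParams, ClockState, bm_log_likelihood
from .calib import CLIMATE_BOUNDARIES, DatedSample
from .fbd import FBDParams, fbd_log_density
from .priors import PriorSpec
from .tree import Node, SATree, write_nexus_trees

__all__ = [
    "MCMCConfig",
    "PosteriorTrace",
    "run_mcmc",
    "ess",
    "combine_logs",
    "convergence_report",
    "shift_for_inference",
]

_EPS_AGE = 1e-9
_LOG_2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# configuration & trace
# ---------------------------------------------------------------------------

_DEFAULT_WEIGHTS = {
    "scale_birth": 3.0, "scale_death": 3.0, "scale_sampling": 3.0,
    "draw_rate_from_prior": 3.0,
    "scale_sigma2": 2.0, "slide_corr": 1.0, "slide_root_value": 2.0,
    "scale_clock_mean": 2.0, "scale_clock_sd": 2.0, "scale_branch_rate": 4.0,
    "scale_cat_rate": 2.0, "flip_category": 3.0,
    "slide_tip_age": 4.0, "slide_node_age": 6.0, "slide_origin": 1.0,
    "scale_tree_heights": 2.0, "swap_rate_variance": 2.0,
    "narrow_exchange": 4.0, "spr": 2.0, "sa_toggle": 2.0,
}


@dataclass
class MCMCConfig:
    """Desk-scale sampler settings (tens to hundreds of thousands of
    generations, not the cluster scale of full empirical analyses)."""

    n_generations: int = 50_000
    sample_every: int = 50
    seed: int = 1
    move_weights: Optional[dict] = None
    under_prior: bool = False
    sample_priors_only: bool = False
    fixed_tree: bool = False
    fixed_tip_ages: bool = False
    fixed_origin: bool = False
    clock_model: str = "ulnc"
    burnin_fraction: float = 0.20
    ess_threshold: float = 200.0
    condition_on_sampling: bool = True
    scale_delta: float = 1.2          # log-scale window of scale moves
    slide_sigma: float = 0.4          # s.d. of root-value random walk
    corr_window: float = 0.3
    init_cap: int = 100

    def __post_init__(self):
        if self.n_generations <= 0:
            raise ValueError("n_generations must be positive")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burnin_fraction must lie in [0, 1)")


@dataclass
class PosteriorTrace:
    """Equally spaced MCMC samples plus the matching tree log."""

    df: pd.DataFrame
    trees: list
    seed: int = 0
    burnin_fraction: float = 0.20
    move_stats: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = self.df.columns
        for name in ("generation", "posterior", "likelihood", "prior"):
            if name not in cols:
                raise ValueError(f"trace is missing the {name} column")
        resid = (self.df["posterior"]
                 - self.df["likelihood"] - self.df["prior"]).abs()
        if len(self.df) and resid.max() > 1e-8:
            raise ValueError("posterior != likelihood + prior in the trace")

    def __len__(self):
        return len(self.df)

    def burned(self, burnin_fraction: Optional[float] = None) -> pd.DataFrame:
        frac = self.burnin_fraction if burnin_fraction is None else burnin_fraction
        return self.df.iloc[int(frac * len(self.df)):]

    # -- I/O (BEAST-style tab log with a comment header) -------------------
    def to_log(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# shapedyn trace seed={self.seed}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_log(cls, path, seed: int = 0) -> "PosteriorTrace":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df, trees=[], seed=seed)

    def trees_to_nexus(self, path) -> None:
        write_nexus_trees(self.trees, path)


# ---------------------------------------------------------------------------
# fast prior evaluation (numeric twins of the PriorSpec distributions)
# ---------------------------------------------------------------------------

def _expon_logpdf(x, rate):
    x = np.asarray(x, dtype=float)
    out = np.where(x >= 0, np.log(rate) - rate * x, -np.inf)
    return out

def _norm_logpdf(x, mean, sd):
    x = np.asarray(x, dtype=float)
    return -0.5 * (_LOG_2PI + 2.0 * np.log(sd)) - 0.5 * ((x - mean) / sd) ** 2

def _lognorm_logpdf(x, loc, scale):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.log(x)
        out = np.where(
            x > 0,
            -lx - np.log(scale) - 0.5 * _LOG_2PI
            - 0.5 * ((lx - loc) / scale) ** 2,
            -np.inf)
    return out

def _gamma_logpdf(x, shape, scale):
    if x <= 0:
        return -np.inf
    return ((shape - 1.0) * math.log(x) - x / scale
            - shape * math.log(scale) - math.lgamma(shape))


@dataclass
class _FastPriors:
    """Numeric hyperparameters mirroring a :class:`PriorSpec`."""

    rate_rate: float = 10.0
    root_mean: float = 0.0
    root_sd: float = 2.0
    sigma2_loc: float = 1.0
    sigma2_scale: float = 0.3
    clock_mean_rate: float = 10.0
    clock_sd_shape: float = 0.54
    clock_sd_scale: float = 0.38
    ncat_rate: float = 5.0

    @classmethod
    def from_spec(cls, spec: PriorSpec) -> "_FastPriors":
        def expon_rate(d):
            return 1.0 / d.kwds.get("scale", 1.0)

        def norm_params(d):
            args = list(d.args) + [d.kwds.get("loc"), d.kwds.get("scale")]
            vals = [a for a in args if a is not None]
            return float(vals[0]), float(vals[1])

        mean, sd = norm_params(spec.root_value)
        return cls(
            rate_rate=expon_rate(spec.birth),
            root_mean=mean, root_sd=sd,
            sigma2_loc=float(np.log(spec.sigma2.kwds.get("scale", np.e))),
            sigma2_scale=float(spec.sigma2.args[0]
                               if spec.sigma2.args else spec.sigma2.kwds["s"]),
            clock_mean_rate=expon_rate(spec.clock_mean),
            clock_sd_shape=float(spec.clock_sd.args[0]),
            clock_sd_scale=float(spec.clock_sd.kwds.get("scale", 1.0)),
            ncat_rate=expon_rate(spec.ncat_rate),
        )


# ---------------------------------------------------------------------------
# sampler state
# ---------------------------------------------------------------------------

class _State:
    def __init__(self, tree: SATree, fbd: FBDParams, bm: Optional[BMParams],
                 clock: ClockState, traits, tip_bounds: dict,
                 fp: _FastPriors, config: MCMCConfig):
        self.tree = tree
        self.fbd = fbd
        self.bm = bm
        self.clock = clock
        self.traits = traits
        self.tip_bounds = tip_bounds
        self.fp = fp
        self.config = config
        self.P = self.F = self.L = -np.inf

    # -- target pieces ------------------------------------------------------
    def compute_P(self) -> float:
        fp, fbd, tree = self.fp, self.fbd, self.tree
        lp = float(np.sum(_expon_logpdf(fbd.lam, fp.rate_rate))
                   + np.sum(_expon_logpdf(fbd.mu, fp.rate_rate))
                   + np.sum(_expon_logpdf(fbd.psi, fp.rate_rate)))
        if not tree.origin_age > max(tree.root.age, 0.0):
            return -np.inf
        bm = self.bm
        if bm is not None:
            if not bm.is_positive_definite():
                return -np.inf
            lp += float(np.sum(_norm_logpdf(bm.root, fp.root_mean, fp.root_sd)))
            lp += float(np.sum(_lognorm_logpdf(bm.sigma2, fp.sigma2_loc,
                                               fp.sigma2_scale)))
            if not -1.0 < bm.corr < 1.0:
                return -np.inf
            lp += -np.log(2.0)
        clock = self.clock
        nodes = tree.nodes()
        if clock.model == "ulnc":
            if clock.mean <= 0 or clock.sd <= 0:
                return -np.inf
            rates = np.array([n.rate for n in nodes])
            if np.any(rates <= 0):
                return -np.inf
            loc = np.log(clock.mean) - 0.5 * clock.sd ** 2
            lp += float(np.sum(_lognorm_logpdf(rates, loc, clock.sd)))
            lp += float(_expon_logpdf(clock.mean, fp.clock_mean_rate))
            lp += _gamma_logpdf(clock.sd, fp.clock_sd_shape, fp.clock_sd_scale)
        elif clock.model == "ncat2":
            lp += float(np.sum(_expon_logpdf(clock.rates, fp.ncat_rate)))
            lp += len(nodes) * np.log(0.5)
        else:
            lp += float(_expon_logpdf(clock.mean, fp.clock_mean_rate))
        for node in nodes:
            if node.taxon is not None and node.taxon in self.tip_bounds:
                lo, hi = self.tip_bounds[node.taxon]
                if hi > lo:
                    if not lo <= node.age <= hi:
                        return -np.inf
                    lp -= np.log(hi - lo)
                elif abs(node.age - lo) > 1e-9:
                    return -np.inf
        return lp

    def compute_F(self) -> float:
        if self.config.sample_priors_only:
            return 0.0
        return fbd_log_density(self.tree, self.fbd,
                               self.config.condition_on_sampling)

    def compute_L(self) -> float:
        if self.config.under_prior or self.traits is None or self.bm is None:
            return 0.0
        return bm_log_likelihood(self.tree, self.traits, self.bm, self.clock)

    def refresh(self) -> None:
        self.P = self.compute_P()
        self.F = self.compute_F() if np.isfinite(self.P) else -np.inf
        self.L = self.compute_L() if np.isfinite(self.P) else -np.inf

    @property
    def log_target(self) -> float:
        return self.P + self.F + self.L


# ---------------------------------------------------------------------------
# moves: each returns (log_hastings, changed_pieces, undo) or None
# ---------------------------------------------------------------------------

def _scale(rng: np.random.Generator, delta: float) -> float:
    return float(np.exp(delta * (rng.random() - 0.5)))


def _upper_age(state: _State, node: Node) -> float:
    return node.parent.age if node.parent is not None else state.tree.origin_age


def _mv_scale_rate(state, rng, which):
    arr = getattr(state.fbd, which)
    i = int(rng.integers(0, len(arr)))
    c = _scale(rng, state.config.scale_delta)
    old = arr[i]
    arr[i] = old * c

    def undo():
        arr[i] = old
    return math.log(c), ("P", "F"), undo


def _mv_draw_rate_from_prior(state, rng):
    """Independence proposal: redraw one skyline rate from its exponential
    prior.  The Hastings ratio cancels the prior ratio exactly, so the move
    accepts on the tree-density ratio alone — this mixes the weakly
    informed rates (and the low tail near zero) far better than
    multiplicative scaling."""
    which = ("lam", "mu", "psi")[int(rng.integers(0, 3))]
    arr = getattr(state.fbd, which)
    i = int(rng.integers(0, len(arr)))
    old = arr[i]
    new = rng.exponential(1.0 / state.fp.rate_rate)
    arr[i] = new
    hr = state.fp.rate_rate * (new - old)

    def undo():
        arr[i] = old
    return hr, ("P", "F"), undo


def _mv_scale_sigma2(state, rng):
    bm = state.bm
    if bm is None:
        return None
    i = int(rng.integers(0, bm.k))
    c = _scale(rng, state.config.scale_delta)
    old = bm.sigma2[i]
    bm.sigma2[i] = old * c

    def undo():
        bm.sigma2[i] = old
    return math.log(c), ("P", "L"), undo


def _mv_slide_corr(state, rng):
    bm = state.bm
    if bm is None or bm.k < 2:
        return None
    old = bm.corr
    new = old + rng.uniform(-state.config.corr_window, state.config.corr_window)
    if new > 1.0:
        new = 2.0 - new
    elif new < -1.0:
        new = -2.0 - new
    bm.corr = new

    def undo():
        bm.corr = old
    return 0.0, ("P", "L"), undo


def _mv_slide_root_value(state, rng):
    bm = state.bm
    if bm is None:
        return None
    i = int(rng.integers(0, bm.k))
    old = bm.root[i]
    bm.root[i] = old + rng.normal(0.0, state.config.slide_sigma)

    def undo():
        bm.root[i] = old
    return 0.0, ("P", "L"), undo


def _mv_scale_clock_mean(state, rng):
    c = _scale(rng, state.config.scale_delta)
    old = state.clock.mean
    state.clock.mean = old * c

    def undo():
        state.clock.mean = old
    return math.log(c), ("P",), undo


def _mv_scale_clock_sd(state, rng):
    if state.clock.model != "ulnc":
        return None
    c = _scale(rng, state.config.scale_delta)
    old = state.clock.sd
    state.clock.sd = old * c

    def undo():
        state.clock.sd = old
    return math.log(c), ("P",), undo


def _mv_scale_branch_rate(state, rng):
    if state.clock.model != "ulnc":
        return None
    nodes = state.tree.nodes()
    node = nodes[int(rng.integers(0, len(nodes)))]
    c = _scale(rng, state.config.scale_delta)
    old = node.rate
    node.rate = old * c

    def undo():
        node.rate = old
    return math.log(c), ("P", "L"), undo


def _mv_scale_cat_rate(state, rng):
    if state.clock.model != "ncat2":
        return None
    i = int(rng.integers(0, 2))
    c = _scale(rng, state.config.scale_delta)
    old = state.clock.rates[i]
    state.clock.rates[i] = old * c

    def undo():
        state.clock.rates[i] = old
    return math.log(c), ("P", "L"), undo


def _mv_flip_category(state, rng):
    if state.clock.model != "ncat2":
        return None
    nodes = state.tree.nodes()
    node = nodes[int(rng.integers(0, len(nodes)))]
    node.rate_cat = 1 - node.rate_cat

    def undo():
        node.rate_cat = 1 - node.rate_cat
    return 0.0, ("L",), undo


def _mv_slide_tip_age(state, rng):
    if state.config.fixed_tip_ages:
        return None
    movable = [n for n in state.tree.preorder()
               if n.taxon is not None and n.taxon in state.tip_bounds
               and state.tip_bounds[n.taxon][1] > state.tip_bounds[n.taxon][0]]
    if not movable:
        return None
    node = movable[int(rng.integers(0, len(movable)))]
    lo, hi = state.tip_bounds[node.taxon]
    lo = max(lo, _EPS_AGE, max((c.age for c in node.children), default=-np.inf))
    hi = min(hi, _upper_age(state, node))
    if hi <= lo:
        return None
    old = node.age
    node.age = rng.uniform(lo, hi)

    def undo():
        node.age = old
    return 0.0, ("F", "L"), undo


def _mv_slide_node_age(state, rng):
    nodes = [n for n in state.tree.preorder() if n.is_bifurcation]
    if not nodes:
        return None
    node = nodes[int(rng.integers(0, len(nodes)))]
    lo = max(c.age for c in node.children)
    hi = _upper_age(state, node)
    if hi <= lo:
        return None
    old = node.age
    node.age = rng.uniform(lo, hi)

    def undo():
        node.age = old
    return 0.0, ("F", "L"), undo


def _mv_slide_origin(state, rng):
    tree = state.tree
    gap = tree.origin_age - tree.root.age
    if gap <= 0:
        return None
    c = _scale(rng, state.config.scale_delta)
    old = tree.origin_age
    tree.origin_age = tree.root.age + gap * c

    def undo():
        tree.origin_age = old
    return math.log(c), ("F",), undo


def _mv_scale_tree_heights(state, rng):
    """Scale every bifurcation age (and the origin unless fixed) by a
    common factor, keeping sample ages put; decorrelates tree height from
    the diversification rates."""
    tree = state.tree
    nodes = [n for n in tree.preorder() if n.is_bifurcation]
    if not nodes:
        return None
    c = _scale(rng, 0.25)
    old_ages = [n.age for n in nodes]
    old_origin = tree.origin_age
    n_scaled = len(nodes)
    for n in nodes:
        n.age *= c
    if not state.config.fixed_origin:
        tree.origin_age *= c
        n_scaled += 1

    def undo():
        for n, a in zip(nodes, old_ages):
            n.age = a
        tree.origin_age = old_origin

    # validity: every parent must stay older than its children
    for n in tree.preorder():
        if n.parent is not None and n.parent.age < n.age:
            undo()
            return None
    if tree.origin_age < tree.root.age:
        undo()
        return None
    return n_scaled * math.log(c), ("F", "L"), undo


def _mv_swap_rate_variance(state, rng):
    """Scale all branch rates up and all trait variance rates down by the
    same factor; the trait likelihood is invariant, so the move walks the
    rate-variance ridge at prior cost only."""
    bm = state.bm
    if bm is None or state.clock.model == "ncat2":
        return None
    c = _scale(rng, 0.8)
    clock = state.clock
    nodes = state.tree.nodes()
    old_mean = clock.mean
    old_sigma2 = bm.sigma2.copy()
    n_up = 1  # clock mean
    clock.mean *= c
    if clock.model == "ulnc":
        for n in nodes:
            n.rate *= c
        n_up += len(nodes)
    bm.sigma2 /= c

    def undo():
        clock.mean = old_mean
        bm.sigma2[:] = old_sigma2
        if clock.model == "ulnc":
            for n in nodes:
                n.rate /= c

    hr = (n_up - bm.k) * math.log(c)
    return hr, ("P", "L"), undo


def _mv_narrow_exchange(state, rng):
    tree = state.tree
    cands = []
    for g in tree.preorder():
        if len(g.children) != 2:
            continue
        for p in g.children:
            if p.is_bifurcation:
                cands.append((g, p))
    if not cands:
        return None
    g, p = cands[int(rng.integers(0, len(cands)))]
    u = g.children[0] if g.children[1] is p else g.children[1]
    c = p.children[int(rng.integers(0, 2))]
    if u.age >= p.age:
        return None
    backup = tree.copy()
    # swap u and c
    g.children[g.children.index(u)] = c
    c.parent = g
    p.children[p.children.index(c)] = u
    u.parent = p

    def undo():
        state.tree = backup
    return 0.0, ("L",), undo


def _eligible_spr_nodes(tree: SATree) -> list[Node]:
    return [n for n in tree.preorder()
            if n.parent is not None and n.parent.is_bifurcation]


def _mv_spr(state, rng):
    tree = state.tree
    elig = _eligible_spr_nodes(tree)
    if not elig:
        return None
    n_elig_old = len(elig)
    s = elig[int(rng.integers(0, n_elig_old))]
    p = s.parent
    sib = p.children[0] if p.children[0] is not s else p.children[1]
    gp = p.parent
    window_old = _upper_age(state, p) - max(s.age, sib.age)
    backup = tree.copy()

    # detach: splice p out
    if gp is None:
        tree.root = sib
        sib.parent = None
    else:
        gp.children[gp.children.index(p)] = sib
        sib.parent = gp

    targets = list(tree.preorder())  # s-subtree is no longer reachable
    v = targets[int(rng.integers(0, len(targets)))]
    upper = v.parent.age if v.parent is not None else tree.origin_age
    lo = max(s.age, v.age)
    if upper <= lo:
        state.tree = backup
        return None
    new_age = rng.uniform(lo, upper)

    # re-insert p (keeps its clock rate) above v
    vp = v.parent
    p.age = new_age
    p.children = [v, s]
    v.parent = p
    s.parent = p
    if vp is None:
        p.parent = None
        tree.root = p
    else:
        p.parent = vp
        vp.children[vp.children.index(v)] = p

    n_elig_new = len(_eligible_spr_nodes(tree))
    hr = (math.log(upper - lo) - math.log(window_old)
          + math.log(n_elig_old) - math.log(n_elig_new))

    def undo():
        state.tree = backup
    return hr, ("F", "L"), undo


def _lognorm_logpdf_scalar(x: float, mean: float, sd: float) -> float:
    loc = math.log(mean) - 0.5 * sd ** 2
    return (-math.log(x) - math.log(sd) - 0.5 * _LOG_2PI
            - 0.5 * ((math.log(x) - loc) / sd) ** 2)


def _mv_sa_toggle(state, rng):
    """Reversible-jump toggle between a terminal sample and a sampled
    ancestor at the same age."""
    tree = state.tree
    samples = tree.samples()
    node = samples[int(rng.integers(0, len(samples)))]
    clock = state.clock
    if node.is_tip:
        # collapse: tip -> sampled ancestor on the sibling's lineage
        p = node.parent
        if p is None or not p.is_bifurcation:
            return None
        sib = p.children[0] if p.children[0] is not node else p.children[1]
        if node.age <= sib.age:
            return None
        backup = tree.copy()
        gp = p.parent
        removed_rate = p.rate
        node.children = [sib]
        sib.parent = node
        if gp is None:
            tree.root = node
            node.parent = None
        else:
            gp.children[gp.children.index(p)] = node
            node.parent = gp
        window = _upper_age(state, node) - node.age
        if window <= 0:
            state.tree = backup
            return None
        hr = -math.log(window)
        if clock.model == "ulnc":
            hr += _lognorm_logpdf_scalar(removed_rate, clock.mean, clock.sd)
        elif clock.model == "ncat2":
            hr += -math.log(2.0)

        def undo():
            state.tree = backup
        return hr, ("P", "F", "L"), undo
    else:
        # expand: sampled ancestor -> terminal sample on a new bifurcation
        child = node.children[0]
        upper = _upper_age(state, node)
        window = upper - node.age
        if window <= 0:
            return None
        backup = tree.copy()
        gp = node.parent
        new_age = rng.uniform(node.age, upper)
        p = Node(new_age)
        node.children = []
        p.add_child(node)
        p.add_child(child)
        if gp is None:
            tree.root = p
            p.parent = None
        else:
            gp.children[gp.children.index(node)] = p
            p.parent = gp
        hr = math.log(window)
        if clock.model == "ulnc":
            p.rate = float(np.exp(rng.normal(
                math.log(clock.mean) - 0.5 * clock.sd ** 2, clock.sd)))
            hr -= _lognorm_logpdf_scalar(p.rate, clock.mean, clock.sd)
        elif clock.model == "ncat2":
            p.rate_cat = int(rng.integers(0, 2))
            hr += math.log(2.0)

        def undo():
            state.tree = backup
        return hr, ("P", "F", "L"), undo


_MOVES = {
    "scale_birth": lambda s, r: _mv_scale_rate(s, r, "lam"),
    "scale_death": lambda s, r: _mv_scale_rate(s, r, "mu"),
    "scale_sampling": lambda s, r: _mv_scale_rate(s, r, "psi"),
    "draw_rate_from_prior": _mv_draw_rate_from_prior,
    "scale_sigma2": _mv_scale_sigma2,
    "slide_corr": _mv_slide_corr,
    "slide_root_value": _mv_slide_root_value,
    "scale_clock_mean": _mv_scale_clock_mean,
    "scale_clock_sd": _mv_scale_clock_sd,
    "scale_branch_rate": _mv_scale_branch_rate,
    "scale_cat_rate": _mv_scale_cat_rate,
    "flip_category": _mv_flip_category,
    "slide_tip_age": _mv_slide_tip_age,
    "slide_node_age": _mv_slide_node_age,
    "slide_origin": _mv_slide_origin,
    "scale_tree_heights": _mv_scale_tree_heights,
    "swap_rate_variance": _mv_swap_rate_variance,
    "narrow_exchange": _mv_narrow_exchange,
    "spr": _mv_spr,
    "sa_toggle": _mv_sa_toggle,
}

_TREE_MOVES = ("slide_tip_age", "slide_node_age", "slide_origin",
               "scale_tree_heights", "narrow_exchange", "spr", "sa_toggle")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _initial_tree(samples: Sequence[DatedSample], step: float = 0.02,
                  origin_age: Optional[float] = None) -> SATree:
    """Deterministic ladder tree consistent with the tip ages."""
    ages = [s.median_age for s in samples]
    if origin_age is not None:
        # keep the whole ladder below a prescribed origin
        room = origin_age - max(ages)
        if room <= 0:
            raise ValueError("origin_age is younger than the oldest sample")
        step = min(step, 0.5 * room / len(samples))
    nodes = [Node(s.median_age, s.taxon_id) for s in samples]
    nodes.sort(key=lambda n: (-n.age, n.taxon))
    current = nodes[0]
    for nxt in nodes[1:]:
        parent = Node(max(current.age, nxt.age) + step)
        parent.add_child(current)
        parent.add_child(nxt)
        current = parent
    return SATree(current, origin_age if origin_age is not None
                  else current.age + 1.0)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def run_mcmc(traits, samples: Sequence[DatedSample],
             config: MCMCConfig,
             boundaries: Sequence[float] = CLIMATE_BOUNDARIES,
             spec: Optional[PriorSpec] = None,
             init_tree: Optional[SATree] = None,
             origin_age: Optional[float] = None) -> PosteriorTrace:
    """Sample the joint posterior of tree, ages and rates.

    ``traits`` may be ``None`` for runs without a trait model; ``samples``
    supplies taxa with median ages and age bounds.  Ages must be positive
    (use :func:`shift_for_inference` when the observation window does not
    close at the present).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least two dated samples")
    if traits is not None:
        missing = {s.taxon_id for s in samples} - set(traits.taxa)
        if missing:
            raise ValueError(f"samples without trait rows: {sorted(missing)}")

    fp = _FastPriors() if spec is None else _FastPriors.from_spec(spec)
    rng = np.random.default_rng(config.seed)
    boundaries = np.asarray(boundaries, dtype=float)
    m = len(boundaries) + 1

    tree = init_tree.copy() if init_tree is not None \
        else _initial_tree(samples, origin_age=origin_age)
    tip_bounds = {s.taxon_id: (s.age_min, s.age_max) for s in samples}

    fbd = FBDParams(np.full(m, 1.0 / fp.rate_rate),
                    np.full(m, 1.0 / fp.rate_rate),
                    np.full(m, 1.0 / fp.rate_rate), boundaries)
    clock = ClockState(config.clock_model,
                       mean=1.0 / fp.clock_mean_rate,
                       sd=fp.clock_sd_shape * fp.clock_sd_scale,
                       rates=np.full(2, 1.0 / fp.ncat_rate))
    if traits is not None:
        k = traits.k
        # method-of-moments start: trait variance ~ sigma2 * clock * depth
        depth = max(np.mean([tree.root.age - n.age for n in tree.tips()]),
                    1e-3)
        start_rate = (clock.mean if config.clock_model != "ncat2"
                      else float(clock.rates[0]))
        sigma2_0 = np.clip(traits.values.var(axis=0) / (depth * start_rate),
                           1e-6, 1e3)
        bm = BMParams(traits.values.mean(axis=0), sigma2_0, 0.0)
    else:
        bm = None
    for node in tree.nodes():
        node.rate = clock.mean

    state = _State(tree, fbd, bm, clock, traits, tip_bounds, fp, config)
    state.refresh()
    attempt = 0
    while not np.isfinite(state.log_target):
        attempt += 1
        if attempt > config.init_cap:
            raise RuntimeError("no finite-density starting state found")
        for node in state.tree.bifurcations():
            node.age += 0.01 * attempt * rng.random()
        state.tree.origin_age = state.tree.root.age + 1.0
        state.refresh()

    weights = dict(_DEFAULT_WEIGHTS)
    if config.move_weights:
        weights.update(config.move_weights)
    if config.clock_model != "ulnc":
        weights["scale_clock_sd"] = weights["scale_branch_rate"] = 0.0
    if config.clock_model != "ncat2":
        weights["scale_cat_rate"] = weights["flip_category"] = 0.0
    if config.clock_model == "strict":
        pass  # scale_clock_mean stays active
    if config.fixed_tree or config.sample_priors_only:
        for name in _TREE_MOVES:
            weights[name] = 0.0
    if config.fixed_origin:
        weights["slide_origin"] = 0.0
    if traits is None:
        for name in ("scale_sigma2", "slide_corr", "slide_root_value"):
            weights[name] = 0.0
    names = [n for n, w in weights.items() if w > 0]
    probs = np.array([weights[n] for n in names])
    probs = probs / probs.sum()

    rows = []
    trees_out = []
    stats = {n: [0, 0] for n in names}

    def record(gen: int):
        row = {"generation": gen, "posterior": state.L + state.P + state.F,
               "likelihood": state.L, "prior": state.P + state.F,
               "origin": state.tree.origin_age,
               "root_age": state.tree.root.age,
               "n_sampled_ancestors": len(state.tree.sampled_ancestors())}
        for i in range(m):
            row[f"lambda_{i}"] = state.fbd.lam[i]
            row[f"mu_{i}"] = state.fbd.mu[i]
            row[f"psi_{i}"] = state.fbd.psi[i]
        if state.bm is not None:
            for j in range(state.bm.k):
                row[f"sigma2_{j}"] = state.bm.sigma2[j]
                row[f"root_{j}"] = state.bm.root[j]
            row["corr"] = state.bm.corr
        if state.clock.model == "ulnc":
            row["clock_mean"] = state.clock.mean
            row["clock_sd"] = state.clock.sd
        elif state.clock.model == "ncat2":
            row["clock_rate1"] = state.clock.rates[0]
            row["clock_rate2"] = state.clock.rates[1]
        else:
            row["clock_mean"] = state.clock.mean
        for node in state.tree.samples():
            row[f"age_{node.taxon}"] = node.age
        rows.append(row)
        trees_out.append((gen, state.tree.copy()))

    record(0)
    for gen in range(1, config.n_generations + 1):
        name = names[int(rng.choice(len(names), p=probs))]
        stats[name][0] += 1
        res = _MOVES[name](state, rng)
        if res is not None:
            hr, changed, undo = res
            new = {}
            ok = True
            for piece in changed:
                val = getattr(state, "compute_" + piece)()
                new[piece] = val
                if not np.isfinite(val):
                    ok = False
                    break
            if ok:
                delta = sum(new[p] - getattr(state, p) for p in new) + hr
                if delta >= 0 or math.log(rng.random()) < delta:
                    for piece, val in new.items():
                        setattr(state, piece, val)
                    stats[name][1] += 1
                else:
                    undo()
            else:
                undo()
        if gen % config.sample_every == 0:
            record(gen)

    df = pd.DataFrame(rows)
    return PosteriorTrace(df, trees_out, seed=config.seed,
                          burnin_fraction=config.burnin_fraction,
                          move_stats={k: tuple(v) for k, v in stats.items()})


# ---------------------------------------------------------------------------
# diagnostics & log combining
# ---------------------------------------------------------------------------

def ess(series) -> float:
    """Effective sample size from the autocorrelation spectrum.

    Constant (degenerate) series report their length — there is no
    autocorrelation structure to correct for.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples for an ESS estimate")
    if np.allclose(x, x[0]):
        return float(len(x))
    import arviz as az
    return float(az.ess(x))


def convergence_report(traces, threshold: float = 200.0) -> pd.DataFrame:
    """Per-column ESS table with a pass flag.

    The flag requires prior, posterior and likelihood ESS all at or above
    the threshold, the standard stopping rule for phylogenetic MCMC.
    """
    if isinstance(traces, PosteriorTrace):
        traces = [traces]
    if not traces:
        raise ValueError("need at least one trace")
    frames = [t.df if isinstance(t, PosteriorTrace) else t for t in traces]
    rows = []
    for i, df in enumerate(frames):
        for col in df.columns:
            if col == "generation":
                continue
            rows.append({"chain": i, "column": col,
                         "ess": ess(df[col].to_numpy())})
    out = pd.DataFrame(rows)
    key = out[out["column"].isin(["prior", "posterior", "likelihood"])]
    out.attrs["pass"] = bool((key["ess"] >= threshold).all())
    out.attrs["threshold"] = threshold
    return out


def combine_logs(traces: Sequence[PosteriorTrace],
                 burnin_fraction: float = 0.20) -> PosteriorTrace:
    """Concatenate chains after discarding each chain's leading burn-in."""
    if not traces:
        raise ValueError("no traces to combine")
    cols = list(traces[0].df.columns)
    for t in traces[1:]:
        if list(t.df.columns) != cols:
            raise ValueError("trace column schemas differ")
    dfs, trees = [], []
    for t in traces:
        start = int(burnin_fraction * len(t.df))
        dfs.append(t.df.iloc[start:])
        trees.extend(t.trees[start:])
    df = pd.concat(dfs, ignore_index=True)
    return PosteriorTrace(df, trees, seed=traces[0].seed,
                          burnin_fraction=0.0)


def shift_for_inference(samples: Sequence[DatedSample],
                        boundaries: Sequence[float] = CLIMATE_BOUNDARIES,
                        present: Optional[float] = None):
    """Re-express ages relative to the close of the observation window.

    The FBD process treats age 0 as the moment observation stops.  When a
    study window closes before the present (e.g. at 11 ka BP), ages and
    skyline boundaries are shifted so the youngest possible sample age maps
    just above zero.  Returns (shifted samples, shifted boundaries, shift).
    """
    samples = list(samples)
    min_lo = min(s.age_min for s in samples)
    if present is None:
        present = min_lo - 0.001
    elif present >= min_lo:
        present = min_lo - 0.001
    if present < 0:
        present = 0.0
    shifted = [DatedSample(s.taxon_id, s.locale_id,
                           s.median_age - present,
                           s.age_min - present, s.age_max - present,
                           bin=s.bin)
               for s in samples]
    new_bounds = tuple(b - present for b in boundaries if b - present > 0)
    return shifted, new_bounds, present
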