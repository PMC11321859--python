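"""Posterior post-processing: clade supports, maximum clade credibility
trees, highest-posterior-density intervals, skyline rate summaries, and the
taxa-trait benchmarking grid.

Clades are taxon sets; sampled ancestors count as members of the clade they
attach to, so trees with different sampled-ancestor renderings of the same
relationships agree on their clades.  The MCC tree is chosen among the
*sampled* trees (no consensus construction), maximizing the product of its
clade posterior probabilities, with node heights kept from the selected
tree by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calib import CLIMATE_BINS, CLIMATE_BOUNDARIES
from .fbd import diversification_rate, turnover_rate
from .mcmc import MCMCConfig, PosteriorTrace, run_mcmc, shift_for_inference
from .tree import SATree

__all__ = [
    "MCCTree",
    "clade_probabilities",
    "mcc_tree",
    "hpd_interval",
    "skyline_summary",
    "tree_metrics",
    "run_grid",
]


def _as_trees(trees) -> list[SATree]:
    out = []
    for t in trees:
        if isinstance(t, tuple):
            t = t[1]
        out.append(t)
    return out


def clade_probabilities(trees) -> dict[frozenset, float]:
    """Frequency of every clade (taxon set) across a posterior tree sample."""
    trees = _as_trees(trees)
    if not trees:
        raise ValueError("empty tree sample")
    taxa = frozenset(trees[0].taxa())
    counts: dict[frozenset, int] = {}
    for tree in trees:
        if frozenset(tree.taxa()) != taxa:
            raise ValueError("trees carry inconsistent taxon sets")
        seen = set(tree.clades().values())
        for clade in seen:
            counts[clade] = counts.get(clade, 0) + 1
    n = len(trees)
    return {c: k / n for c, k in counts.items()}


@dataclass
class MCCTree:
    """An annotated maximum clade credibility tree."""

    tree: SATree
    clade_pp: dict = field(default_factory=dict)
    clade_age_hpd: dict = field(default_factory=dict)
    branch_length_median: dict = field(default_factory=dict)
    branch_rate_median: dict = field(default_factory=dict)
    log_clade_credibility: float = 0.0


def _log_credibility(tree: SATree, probs: dict) -> float:
    score = 0.0
    for node, clade in tree.clades().items():
        if len(clade) < 2:
            continue
        score += np.log(probs.get(clade, 0.0))
    return float(score)


def mcc_tree(trees, keep_target_heights: bool = True) -> MCCTree:
    """The sampled tree maximizing the product of its clade probabilities.

    With ``keep_target_heights`` the node ages of the selected tree are kept
    as-is; otherwise every matched clade's age is replaced by the median age
    of that clade across the sample.  Either way the tree is annotated with
    clade posterior probabilities, 95% HPD age ranges, and median branch
    lengths and clock rates of matching clades.
    """
    trees = _as_trees(trees)
    if not trees:
        raise ValueError("empty tree sample")
    probs = clade_probabilities(trees)
    scores = [_log_credibility(t, probs) for t in trees]
    best = trees[int(np.argmax(scores))].copy()

    # per-clade statistics across the sample
    ages: dict[frozenset, list] = {}
    lengths: dict[frozenset, list] = {}
    rates: dict[frozenset, list] = {}
    for tree in trees:
        for node, clade in tree.clades().items():
            ages.setdefault(clade, []).append(node.age)
            lengths.setdefault(clade, []).append(tree.duration(node))
            rates.setdefault(clade, []).append(node.rate)

    best_clades = best.clades()
    pp, hpds, blm, brm = {}, {}, {}, {}
    for node, clade in best_clades.items():
        pp[clade] = probs.get(clade, 0.0)
        a = np.asarray(ages.get(clade, [node.age]))
        lo, hi = (hpd_interval(a, 0.95) if len(a) >= 10
                  else (float(a.min()), float(a.max())))
        lo, hi = min(lo, node.age), max(hi, node.age)
        hpds[clade] = (lo, hi)
        blm[clade] = float(np.median(lengths.get(clade, [best.duration(node)])))
        brm[clade] = float(np.median(rates.get(clade, [node.rate])))
    if not keep_target_heights:
        for node, clade in best_clades.items():
            if clade in ages:
                node.age = float(np.median(ages[clade]))
    return MCCTree(best, pp, hpds, blm, brm,
                   log_clade_credibility=float(np.max(scores)))


def hpd_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``level`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples for an HPD interval")
    m = int(np.ceil(level * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def skyline_summary(trace, boundaries: Sequence[float] = CLIMATE_BOUNDARIES,
                    level: float = 0.95,
                    labels: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Median and HPD of birth, death, sampling, diversification and
    turnover rates per skyline interval.

    Diversification (d = lambda - mu) and turnover (t = mu / lambda) are
    recomputed row-wise from the trace before summarizing.
    """
    df = trace.burned() if isinstance(trace, PosteriorTrace) else trace
    m = len(boundaries) + 1
    if labels is None:
        labels = CLIMATE_BINS if tuple(boundaries) == CLIMATE_BOUNDARIES \
            else [f"interval_{i}" for i in range(m)]
    elif len(labels) != m:
        raise ValueError("need one label per interval")
    rows = []
    for i in range(m):
        try:
            lam = df[f"lambda_{i}"].to_numpy()
            mu = df[f"mu_{i}"].to_numpy()
            psi = df[f"psi_{i}"].to_numpy()
        except KeyError as exc:
            raise ValueError(f"trace lacks skyline columns for interval {i}"
                             ) from exc
        series = {
            "birth": lam, "death": mu, "sampling": psi,
            "diversification": diversification_rate(lam, mu),
            "turnover": turnover_rate(lam, mu),
        }
        for name, vals in series.items():
            lo, hi = hpd_interval(vals, level)
            rows.append({"interval": labels[i], "parameter": name,
                         "median": float(np.median(vals)),
                         "hpd_lo": lo, "hpd_hi": hi})
    return pd.DataFrame(rows)


def tree_metrics(mcc: MCCTree) -> pd.DataFrame:
    """Long-format table of the four MCC-tree metric families.

    Families: posterior clade probabilities (internal clades), 95% HPD age
    range widths (internal nodes), median branch lengths and median branch
    rates (all branches).  Summary rows (median and mean per family) are
    appended with item labels ``summary_median`` / ``summary_mean``.
    """
    rows = []
    clades = mcc.tree.clades()
    for node, clade in clades.items():
        label = "|".join(sorted(clade))
        if len(clade) >= 2:
            rows.append({"metric": "clade_pp", "item": label,
                         "value": mcc.clade_pp.get(clade, 0.0)})
            lo, hi = mcc.clade_age_hpd.get(clade, (node.age, node.age))
            rows.append({"metric": "node_age_hpd_width", "item": label,
                         "value": hi - lo})
        rows.append({"metric": "branch_length_median", "item": label,
                     "value": mcc.branch_length_median.get(
                         clade, mcc.tree.duration(node))})
        rows.append({"metric": "branch_rate_median", "item": label,
                     "value": mcc.branch_rate_median.get(clade, node.rate)})
    df = pd.DataFrame(rows)
    extra = []
    for metric, group in df.groupby("metric"):
        extra.append({"metric": metric, "item": "summary_median",
                      "value": float(group["value"].median())})
        extra.append({"metric": metric, "item": "summary_mean",
                      "value": float(group["value"].mean())})
    return pd.concat([df, pd.DataFrame(extra)], ignore_index=True)


# ---------------------------------------------------------------------------
# taxa-trait grid
# ---------------------------------------------------------------------------

def run_grid(taxa_counts: Sequence[int], trait_counts: Sequence[int],
             base_config: MCMCConfig, result,
             seed: int = 0) -> pd.DataFrame:
    """Benchmark inference across combinations of taxa and trait counts.

    ``result`` supplies the largest taxa set (a
    :class:`~shapedyn.simulate.SimResult` or any object with ``traits`` and
    ``samples``).  Trait subsets are nested prefixes of the PC axes; taxa
    subsets are stratified by climate bin with a shared shuffling seed so
    that larger sets contain smaller ones.  Each cell runs a scaled-down
    inference and records the posterior median and variance of the overall
    clock rate plus the MCC-tree metric summaries; per-cell failures are
    recorded and the grid continues.
    """
    from .calib import stratified_subsample

    rows = []
    all_samples = list(result.samples)
    for ti, n_taxa in enumerate(taxa_counts):
        if n_taxa > len(all_samples):
            raise ValueError(f"{n_taxa} taxa requested, "
                             f"{len(all_samples)} available")
        if n_taxa == len(all_samples):
            cell_samples = all_samples
        else:
            cell_samples = stratified_subsample(all_samples,
                                                max(n_taxa // 4, 1), seed)
        taxa = [s.taxon_id for s in cell_samples]
        for tj, n_traits in enumerate(trait_counts):
            cell_seed = seed + 1000 * ti + tj + 1
            row = {"n_taxa": len(taxa), "n_traits": n_traits,
                   "seed": cell_seed}
            try:
                traits = result.traits.subset(taxa, min(n_traits,
                                                        result.traits.k))
                shifted, bounds, _ = shift_for_inference(cell_samples)
                cfg = MCMCConfig(
                    n_generations=base_config.n_generations,
                    sample_every=base_config.sample_every,
                    seed=cell_seed,
                    under_prior=base_config.under_prior,
                    clock_model=base_config.clock_model,
                    burnin_fraction=base_config.burnin_fraction)
                trace = run_mcmc(traits, shifted, cfg, boundaries=bounds)
                post = trace.burned()
                clock_col = ("clock_mean" if "clock_mean" in post.columns
                             else "clock_rate1")
                row["median_clock_rate"] = float(post[clock_col].median())
                row["clock_rate_variance"] = float(post[clock_col].var())
                mcc = mcc_tree(trace.trees[int(
                    base_config.burnin_fraction * len(trace.trees)):])
                metrics = tree_metrics(mcc)
                for metric, group in metrics[
                        ~metrics["item"].str.startswith("summary")
                        ].groupby("metric"):
                    row[f"mean_{metric}"] = float(group["value"].mean())
                row["error"] = ""
            except Exception as exc:  # keep the grid going
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_skyline(summary: pd.DataFrame, path) -> None:
    """Panel of per-bin medians and HPD bars for each rate family."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = ["death", "birth", "diversification", "turnover"]
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for ax, param in zip(axes.ravel(), params):
        sub = summary[summary["parameter"] == param]
        x = np.arange(len(sub))
        ax.errorbar(x, sub["median"],
                    yerr=[sub["median"] - sub["hpd_lo"],
                          sub["hpd_hi"] - sub["median"]],
                    fmt="o", capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels(sub["interval"], rotation=45)
        ax.set_title(param)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_grid_heatmap(grid: pd.DataFrame, value: str, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = grid.pivot(index="n_taxa", columns="n_traits", values=value)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("traits")
    ax.set_ylabel("taxa")
    ax.set_title(value)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
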