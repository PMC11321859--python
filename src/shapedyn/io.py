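"""Plain-text readers and writers for the pipeline's artefacts.

Outlines travel as long-format CSV (specimen, point index, x, y); lab dates
as CSV with ages in radiocarbon years BP; per-locale age tables and trait
matrices as CSV/TSV with ages in ka BP; trees as Newick with sampled
ancestors rendered as zero-length side branches.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calib import DatedSample
from .morpho import Outline, TraitMatrix
from .tree import SATree

__all__ = [
    "write_outlines_csv", "read_outlines_csv",
    "write_dates_csv", "read_dates_csv",
    "write_samples_csv", "read_samples_csv",
    "write_traits_tsv", "read_traits_tsv",
    "write_tree_newick", "read_tree_newick",
]


def write_outlines_csv(outlines: Sequence[Outline], path) -> None:
    rows = []
    for o in outlines:
        for i, (x, y) in enumerate(o.points):
            rows.append((o.specimen_id, i, x, y))
    pd.DataFrame(rows, columns=["specimen_id", "point_index", "x", "y"]) \
        .to_csv(path, index=False)


def read_outlines_csv(path) -> list[Outline]:
    df = pd.read_csv(path)
    out = []
    for sid, group in df.groupby("specimen_id", sort=False):
        group = group.sort_values("point_index")
        out.append(Outline(str(sid), group[["x", "y"]].to_numpy()))
    return out


def write_dates_csv(c14_tables: dict, path) -> None:
    """Lab dates per locale; ages stored in radiocarbon years BP."""
    rows = []
    for locale, dates in c14_tables.items():
        for i, (age_ka, err_ka) in enumerate(dates):
            rows.append((locale, f"{locale}_d{i}",
                         round(age_ka * 1000.0, 1), round(err_ka * 1000.0, 1)))
    pd.DataFrame(rows, columns=["locale_id", "lab_id", "c14_age", "error"]) \
        .to_csv(path, index=False)


def read_dates_csv(path) -> dict:
    df = pd.read_csv(path)
    tables: dict[str, list] = {}
    for _, row in df.iterrows():
        tables.setdefault(str(row["locale_id"]), []).append(
            (float(row["c14_age"]) / 1000.0, float(row["error"]) / 1000.0))
    return tables


def write_samples_csv(samples: Sequence[DatedSample], path) -> None:
    pd.DataFrame(
        [(s.taxon_id, s.locale_id, s.median_age, s.age_min, s.age_max, s.bin)
         for s in samples],
        columns=["taxon_id", "locale_id", "median_age", "age_min",
                 "age_max", "bin"]).to_csv(path, index=False)


def read_samples_csv(path) -> list[DatedSample]:
    df = pd.read_csv(path)
    return [DatedSample(str(r.taxon_id), str(r.locale_id),
                        float(r.median_age), float(r.age_min),
                        float(r.age_max), str(r.bin))
            for r in df.itertuples()]


def write_traits_tsv(traits: TraitMatrix, path) -> None:
    df = pd.DataFrame(traits.values, index=traits.taxa,
                      columns=[f"PC{i + 1}" for i in range(traits.k)])
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_traits_tsv(path) -> TraitMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return TraitMatrix([str(t) for t in df.index], df.to_numpy())


def write_tree_newick(tree: SATree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_tree_newick(path, origin_age: Optional[float] = None) -> SATree:
    with open(path) as fh:
        return SATree.from_newick(fh.read().strip(), origin_age=origin_age)
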