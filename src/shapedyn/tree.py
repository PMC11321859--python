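"""Time-calibrated sampled trees with sampled ancestors.

Ages are in ka BP (present = 0, increasing into the past).  Sampled
ancestors are represented as degree-2 nodes carrying a sample label; the
zero-length side branch often seen in Newick files is only an I/O
rendering and is collapsed on read.
"""

from __future__ import annotations

import io
from typing import Iterator, Optional

import dendropy


class Node:
    """A node of a sampled tree.

    A node is a *sample* iff it carries a taxon label.  A sample with one
    child is a sampled ancestor; a sample with no children is a tip.
    Unlabelled nodes are bifurcations (exactly two children), except that
    transiently-built trees may hold other arities before validation.
    """

    __slots__ = ("age", "parent", "children", "taxon", "rate", "rate_cat")

    def __init__(self, age: float, taxon: Optional[str] = None):
        self.age = float(age)
        self.parent: Optional[Node] = None
        self.children: list[Node] = []
        self.taxon = taxon
        self.rate = 1.0       # clock rate of the branch above this node
        self.rate_cat = 0     # two-category clock assignment (0 or 1)

    # -- structure ---------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_sample(self) -> bool:
        return self.taxon is not None

    @property
    def is_tip(self) -> bool:
        return not self.children

    @property
    def is_sampled_ancestor(self) -> bool:
        return self.taxon is not None and len(self.children) == 1

    @property
    def is_bifurcation(self) -> bool:
        return len(self.children) == 2

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "SA" if self.is_sampled_ancestor else ("tip" if self.is_tip else "int")
        return f"<Node {self.taxon or ''} {kind} age={self.age:.4g}>"


class SATree:
    """A sampled tree with an origin time.

    The origin is the stem age of the process; ``origin_age >= root.age``
    always.  The branch between origin and root is part of the observed
    tree for the purposes of the tree process density.
    """

    def __init__(self, root: Node, origin_age: float):
        if origin_age < root.age:
            raise ValueError(
                f"origin age {origin_age} is younger than root age {root.age}"
            )
        self.root = root
        self.origin_age = float(origin_age)

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return reversed(out)

    def nodes(self) -> list[Node]:
        return list(self.preorder())

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    def samples(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_sample]

    def sampled_ancestors(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_sampled_ancestor]

    def bifurcations(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_bifurcation]

    def branch_nodes(self) -> list[Node]:
        """Nodes owning a branch (everything below the root)."""
        return [n for n in self.preorder() if n.parent is not None]

    def taxa(self) -> list[str]:
        return sorted(n.taxon for n in self.samples())

    def n_samples(self) -> int:
        return sum(1 for _ in self.samples())

    # -- ages & durations --------------------------------------------------
    def duration(self, node: Node) -> float:
        if node.parent is None:
            return self.origin_age - node.age
        return node.parent.age - node.age

    def total_branch_length(self) -> float:
        return sum(self.duration(n) for n in self.branch_nodes())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for node in self.preorder():
            if node.parent is not None:
                if node.parent.age < node.age:
                    raise ValueError(
                        f"node at {node.age} older than its parent at {node.parent.age}"
                    )
            n_children = len(node.children)
            if node.taxon is None and n_children not in (2,):
                raise ValueError("unlabelled node must be a bifurcation")
            if node.taxon is not None and n_children > 1:
                raise ValueError("a sample node may have at most one child")
            for c in node.children:
                if c.parent is not node:
                    raise ValueError("broken parent link")
        if self.origin_age < self.root.age:
            raise ValueError("origin younger than root")

    # -- clades ------------------------------------------------------------
    def clades(self) -> dict[Node, frozenset]:
        """Taxon set below (and at) each node.

        Sampled ancestors count as members of the clade they attach to.
        """
        out: dict[Node, frozenset] = {}
        for node in self.postorder():
            s = set()
            if node.taxon is not None:
                s.add(node.taxon)
            for c in node.children:
                s |= out[c]
            out[node] = frozenset(s)
        return out

    # -- copying -----------------------------------------------------------
    def copy(self) -> "SATree":
        mapping: dict[int, Node] = {}

        def rec(node: Node) -> Node:
            new = Node(node.age, node.taxon)
            new.rate = node.rate
            new.rate_cat = node.rate_cat
            for c in node.children:
                new.add_child(rec(c))
            mapping[id(node)] = new
            return new

        return SATree(rec(self.root), self.origin_age)

    # -- newick I/O --------------------------------------------------------
    def to_newick(self, decimals: int = 10, annotate_rates: bool = False) -> str:
        """Newick string with sampled ancestors as zero-length side tips."""

        fmt = f"%.{decimals}g"

        def meta(node: Node) -> str:
            return f"[&rate={node.rate:.10g}]" if annotate_rates else ""

        def rec(node: Node, parent_age: float) -> str:
            length = fmt % (parent_age - node.age)
            if node.is_tip:
                return f"{node.taxon}{meta(node)}:{length}"
            if node.is_sampled_ancestor:
                child = rec(node.children[0], node.age)
                return f"({child},{node.taxon}{meta(node)}:0){meta(node)}:{length}"
            parts = ",".join(rec(c, node.age) for c in node.children)
            return f"({parts}){meta(node)}:{length}"

        return rec(self.root, self.origin_age) + ";"

    @classmethod
    def from_newick(cls, newick: str, origin_age: Optional[float] = None) -> "SATree":
        """Parse a Newick string; zero-length side tips become sampled ancestors.

        Node ages are reconstructed from branch lengths with the youngest
        sample placed at age 0 unless tip dates are encoded elsewhere; for
        round trips through :meth:`to_newick` the root branch length gives
        the origin unless ``origin_age`` is supplied.
        """
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  suppress_internal_node_taxa=False)
        edge: dict[int, float] = {}

        def rec(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(0.0, label if not dnode.child_nodes() or label else None)
            edge[id(node)] = (dnode.edge.length
                              if dnode.edge.length is not None else 0.0)
            for c in dnode.child_nodes():
                node.add_child(rec(c))
            return node

        root = rec(dtree.seed_node)

        # collapse zero-length side tips into sampled-ancestor labels
        def collapse(node: Node) -> Node:
            node.children = [collapse(c) for c in node.children]
            if len(node.children) == 2 and node.taxon is None:
                for c in list(node.children):
                    if c.is_tip and edge[id(c)] == 0.0 and c.taxon is not None:
                        other = (node.children[0] if node.children[1] is c
                                 else node.children[1])
                        node.taxon = c.taxon
                        node.children = [other]
                        other.parent = node
                        break
            return node

        root = collapse(root)

        # assign ages from branch lengths, youngest node at depth = max depth
        depths: dict[int, float] = {}

        def set_depth(node: Node, d: float) -> None:
            depths[id(node)] = d
            for c in node.children:
                set_depth(c, d + edge[id(c)])

        set_depth(root, 0.0)
        max_depth = max(depths.values())
        for node in _preorder(root):
            node.age = max_depth - depths[id(node)]
        if origin_age is None:
            origin_age = root.age + edge[id(root)]
        return cls(root, origin_age)


def _preorder(node: Node) -> Iterator[Node]:
    stack = [node]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# NEXUS tree logs (BEAST-style)
# ---------------------------------------------------------------------------

def write_nexus_trees(trees: list[tuple[int, SATree]], path,
                      annotate_rates: bool = True) -> None:
    """Write a tree log: STATE_<gen> entries, sampled ancestors rendered
    as zero-length side tips."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBegin trees;\n")
        for gen, tree in trees:
            fh.write(f"tree STATE_{gen} = "
                     f"{tree.to_newick(annotate_rates=annotate_rates)}\n")
        fh.write("End;\n")


def read_nexus_trees(path) -> list[tuple[int, SATree]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.lower().startswith("tree "):
                continue
            name, _, newick = line[5:].partition("=")
            gen_str = name.strip().rsplit("_", 1)[-1]
            try:
                gen = int(gen_str)
            except ValueError:
                gen = len(out)
            newick = newick.strip()
            rates = _extract_rates(newick)
            clean = _strip_comments(newick)
            tree = SATree.from_newick(clean)
            if rates:
                _apply_rates(tree, rates)
            out.append((gen, tree))
    return out


def _strip_comments(newick: str) -> str:
    out, depth = [], 0
    for ch in newick:
        if ch == "[":
            depth += 1
        elif ch == "]":
            depth -= 1
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _extract_rates(newick: str) -> dict[str, float]:
    """Map taxon label -> annotated branch rate (tip/SA annotations only)."""
    import re

    rates = {}
    for m in re.finditer(r"([\w.\-|]+)\[&rate=([0-9eE+.\-]+)\]", newick):
        rates[m.group(1)] = float(m.group(2))
    return rates


def _apply_rates(tree: SATree, rates: dict[str, float]) -> None:
    for node in tree.preorder():
        if node.taxon is not None and node.taxon in rates:
            node.rate = rates[node.taxon]
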