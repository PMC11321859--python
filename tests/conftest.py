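import numpy as np
import pytest

from shapedyn.tree import Node, SATree


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def circle_outline(n_points: int = 360, radius: float = 1.0,
                   center=(0.0, 0.0)) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def random_sa_tree(rng: np.random.Generator, n_tips: int,
                   p_sa: float = 0.3) -> SATree:
    """Random serially sampled tree, optionally with sampled ancestors."""
    nodes = [Node(rng.uniform(0.05, 1.0), f"t{i}") for i in range(n_tips)]
    label = n_tips
    while len(nodes) > 1:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        p = Node(max(a.age, b.age) + rng.uniform(0.05, 0.8))
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
        # never wrap the final root: a sample at the root pins the root
        # state and degenerates the trait model
        if len(nodes) > 1 and rng.random() < p_sa:
            # turn the new node's parent edge into a sampled-ancestor site
            sa = Node(p.age + rng.uniform(0.05, 0.3), f"t{label}")
            label += 1
            sa.add_child(p)
            nodes[-1] = sa
    root = nodes[0]
    tree = SATree(root, root.age + rng.uniform(0.2, 1.0))
    tree.validate()
    return tree


def shared_path_matrix(tree: SATree, clock=None) -> tuple[list, np.ndarray]:
    """Clock-scaled shared-path-length matrix between all samples."""
    samples = tree.samples()

    def ancestors(n):
        out = []
        while n is not None:
            out.append(n)
            n = n.parent
        return out

    def path(node):
        tot, n = 0.0, node
        while n.parent is not None:
            r = clock.branch_rate(n) if clock is not None else 1.0
            tot += (n.parent.age - n.age) * r
            n = n.parent
        return tot

    C = np.zeros((len(samples), len(samples)))
    for i, a in enumerate(samples):
        ids = set(map(id, ancestors(a)))
        for j, b in enumerate(samples):
            n = b
            while id(n) not in ids:
                n = n.parent
            C[i, j] = path(n)
    return [n.taxon for n in samples], C
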