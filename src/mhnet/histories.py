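"""Most-likely event-order reconstruction and cohort trajectory trees.

Cross-sectional data reveal which events a tumor has accumulated but not in
which order. Given a trained MHN, the probability that the chain takes one
specific path (ordering) sigma_1, ..., sigma_m from healthy to the observed
genotype x and is then observed is

    P(path) = prod_{s=1..m} lambda_{sigma_s}(x_{s-1}) / R(x_{s-1})
              * omega(x_m) / R(x_m),

and summing over all m! orderings recovers p(x) exactly (the path
decomposition of the absorption probability). The most likely ordering is
found by dynamic programming over the 2^k subsets of the active events;
conditioning on the final genotype would divide every path by the same p(x)
and so leaves the maximizer unchanged.

At cohort level, the most likely orderings of all genotypes shared by at
least ``min_count`` patients are merged prefix-by-prefix into a rooted
trajectory tree whose node and edge weights count patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._lattice import build_lattice
from .model import Dataset, MutualHazardNetwork, ValidationError, as_genotype

__all__ = [
    "OrderReconstruction",
    "TrajectoryTree",
    "TreeNode",
    "order_probability",
    "most_likely_order",
    "build_trajectory_tree",
    "tree_to_dot",
]

#: DP limit: the subset lattice has 2^k states, each storing its best path.
DP_EVENT_LIMIT = 25


@dataclass
class OrderReconstruction:
    """A genotype's most probable accumulation order and the path probability."""

    ordering: tuple[int, ...]  # event indices, chronological
    probability: float

    def labels(self, model: MutualHazardNetwork) -> tuple[str, ...]:
        return tuple(model.catalog.names[i] for i in self.ordering)


def order_probability(model: MutualHazardNetwork, ordering: Sequence[int]) -> float:
    """Joint probability of one exact accumulation path ending in observation."""
    ordering = tuple(int(i) for i in ordering)
    if len(set(ordering)) != len(ordering):
        raise ValidationError(f"ordering repeats an event: {ordering}")
    x = np.zeros(model.n, dtype=np.int8)
    prob = 1.0
    for i in ordering:
        if not 0 <= i < model.n:
            raise ValidationError(f"event index {i} out of range")
        prob *= model.event_rate(x, i) / model.total_exit_rate(x)
        x[i] = 1
    return prob * model.observation_rate(x) / model.total_exit_rate(x)


def most_likely_order(model: MutualHazardNetwork, x) -> OrderReconstruction:
    """Highest-probability ordering of a genotype's events, by subset DP.

    ``best(S)`` is the largest probability of any path from healthy through
    exactly the events in S; transitions extend the best sub-path one event
    at a time. Exact float ties are broken toward the ordering with the
    smallest event index at the earliest differing step, so results are
    reproducible.
    """
    x = as_genotype(x, model.n)
    active = np.flatnonzero(x)
    k = active.size
    if k > DP_EVENT_LIMIT:
        raise ValidationError(
            f"most-likely-order DP is limited to {DP_EVENT_LIMIT} active events"
        )
    lat = build_lattice(model.log_theta, model.kind, active)
    # best[s]: (probability of best path reaching subset s, that path)
    best: list[tuple[float, tuple[int, ...]]] = [(0.0, ())] * lat.size
    best[0] = (1.0, ())
    for s in range(1, lat.size):
        cand_p, cand_path = -1.0, ()
        t = s
        while t:
            b = (t & -t).bit_length() - 1
            ps = s & ~(1 << b)
            pp, ppath = best[ps]
            p = pp * lat.lam_act[ps, b] / lat.R[ps]
            path = ppath + (int(active[b]),)
            if p > cand_p or (p == cand_p and path < cand_path):
                cand_p, cand_path = p, path
            t &= t - 1
        best[s] = (cand_p, cand_path)
    top = lat.size - 1
    p, path = best[top]
    return OrderReconstruction(path, p * lat.omega[top] / lat.R[top])


@dataclass
class TreeNode:
    """One node of a trajectory tree: a prefix of an event ordering."""

    prefix: tuple[int, ...]
    count: int = 0
    terminal: bool = False  # an observed cohort genotype's ordering ends here
    children: dict[int, "TreeNode"] = field(default_factory=dict)


@dataclass
class TrajectoryTree:
    """Most likely orderings of the common cohort genotypes, merged by prefix."""

    root: TreeNode
    model: MutualHazardNetwork
    min_count: int
    total_patients: int  # patients in genotype groups passing the filter

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children[e] for e in sorted(node.children, reverse=True))
        return out

    def to_json_dict(self) -> dict:
        names = self.model.catalog.names
        ids = {node.prefix: i for i, node in enumerate(self.nodes())}
        nodes = [
            {
                "id": ids[nd.prefix],
                "prefix": [names[e] for e in nd.prefix],
                "count": nd.count,
                "terminal": nd.terminal,
            }
            for nd in self.nodes()
        ]
        edges = [
            {
                "from": ids[nd.prefix],
                "to": ids[child.prefix],
                "event": names[e],
                "count": child.count,
            }
            for nd in self.nodes()
            for e, child in sorted(nd.children.items())
        ]
        return {"min_count": self.min_count, "nodes": nodes, "edges": edges}


def build_trajectory_tree(
    model: MutualHazardNetwork, data: Dataset, min_count: int = 3
) -> TrajectoryTree:
    """Aggregate most-likely orderings of genotypes shared by >= min_count patients.

    The filter applies to genotype groups (identical bit vectors), not tree
    nodes. Each qualifying genotype contributes its reconstruction as a
    root-to-node path weighted by the group count; shared prefixes merge and
    node counts accumulate along the path.
    """
    uniq, counts = data.aggregate()
    root = TreeNode(prefix=())
    total = 0
    for row, c in zip(uniq, counts):
        if c < min_count:
            continue
        total += int(c)
        rec = most_likely_order(model, row)
        root.count += int(c)
        node = root
        for e in rec.ordering:
            node = node.children.setdefault(e, TreeNode(node.prefix + (e,)))
            node.count += int(c)
        node.terminal = True
    return TrajectoryTree(root, model, min_count, total)


def tree_to_dot(tree: TrajectoryTree) -> str:
    """Render the trajectory tree in DOT, node size and edge width scaling
    linearly with patient counts."""
    names = tree.model.catalog.names
    ids = {node.prefix: i for i, node in enumerate(tree.nodes())}
    total = max(tree.root.count, 1)
    lines = [
        "digraph trajectories {",
        "  rankdir=TB;",
        '  node [shape=circle, style=filled, fillcolor=white];',
    ]
    for nd in tree.nodes():
        label = names[nd.prefix[-1]] if nd.prefix else ""
        width = 0.4 + 1.1 * nd.count / total
        pen = 3.0 if nd.terminal else 1.0
        lines.append(
            f'  n{ids[nd.prefix]} [label="{label}", width={width:.2f}, '
            f"penwidth={pen:.1f}, "
            f'tooltip="{nd.count} patients"];'
        )
    for nd in tree.nodes():
        for e, child in sorted(nd.children.items()):
            pen = 0.5 + 5.0 * child.count / total
            lines.append(
                f"  n{ids[nd.prefix]} -> n{ids[child.prefix]} "
                f'[penwidth={pen:.2f}, label="{child.count}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
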