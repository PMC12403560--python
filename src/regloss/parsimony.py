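"""Gain/loss parsimony for binary characters on rooted species trees.

Two reconstruction modes are provided:

* **Dollo** — a character originates exactly once (on the edge above the
  last common ancestor of the taxa carrying it) and may be lost any number
  of times below that edge.  Appropriate for homologous gene families and
  for dating the origin of a homologous target site.
* **Wagner** — multiple gains are allowed; gains and losses carry
  (possibly asymmetric) unit costs and the minimum-cost ancestral
  labelling is found by Sankoff dynamic programming.  With a gain cost
  that exceeds any achievable number of losses, Wagner collapses to Dollo.

The tree is rooted; a virtual ancestor in state "absent" sits above the
root, so a labelling that marks the root "present" pays one gain on the
root branch (the character predates the in-group radiation).
"""

from __future__ import annotations

import math
from typing import Iterable

from .trees import Node, SpeciesTree, TreeError

_INF = math.inf


def _present_set(tree: SpeciesTree, present: Iterable[str]) -> frozenset[str]:
    pres = frozenset(present)
    if not pres:
        raise ValueError("character is absent from every taxon: nothing to place")
    missing = pres - tree.root.leaves
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    return pres


def dollo_gain_losses(
    tree: SpeciesTree, present: Iterable[str]
) -> tuple[Node, list[Node]]:
    """Single-gain (Dollo) placement of a binary character.

    Returns ``(gain_node, loss_nodes)``: the gain sits on the edge above
    ``gain_node`` (the LCA of all carriers) and each loss on the edge above
    a maximal subtree whose leaves all lack the character.
    """
    pres = _present_set(tree, present)
    gain = tree.lca(pres)
    losses: list[Node] = []

    def collect(node: Node) -> None:
        if not (node.leaves & pres):
            losses.append(node)
            return
        for child in node.children:
            collect(child)

    for child in gain.children:
        collect(child)
    losses.sort(key=lambda n: n.branch_id)
    return gain, losses


def _sankoff_up(
    tree: SpeciesTree,
    pres: frozenset[str],
    gain_cost: float,
    loss_cost: float,
    overrides: dict[Node, int],
) -> dict[Node, tuple[float, float]]:
    """Bottom-up Sankoff pass; cost of each subtree given its root state."""

    def edge(parent_state: int, child_state: int) -> float:
        if parent_state == child_state:
            return 0.0
        return gain_cost if child_state == 1 else loss_cost

    up: dict[Node, tuple[float, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            observed = 1 if node.label in pres else 0
            costs = [0.0 if s == observed else _INF for s in (0, 1)]
        else:
            costs = []
            for s in (0, 1):
                total = 0.0
                for child in node.children:
                    c0, c1 = up[child]
                    total += min(edge(s, 0) + c0, edge(s, 1) + c1)
                costs.append(total)
        forced = overrides.get(node)
        if forced is not None:
            costs[1 - forced] = _INF
        up[node] = (costs[0], costs[1])
    return up


def _wagner_cost(
    tree: SpeciesTree,
    pres: frozenset[str],
    gain_cost: float,
    loss_cost: float,
    overrides: dict[Node, int],
) -> float:
    up = _sankoff_up(tree, pres, gain_cost, loss_cost, overrides)
    c0, c1 = up[tree.root]
    return min(c0, c1 + gain_cost)


def _traceback(
    tree: SpeciesTree,
    pres: frozenset[str],
    gain_cost: float,
    loss_cost: float,
    overrides: dict[Node, int],
) -> dict[Node, int]:
    """One minimum-cost labelling honouring ``overrides`` (ties keep the
    parent's state, so event counts are never inflated by tie-breaking)."""

    def edge(ps: int, cs: int) -> float:
        if ps == cs:
            return 0.0
        return gain_cost if cs == 1 else loss_cost

    up = _sankoff_up(tree, pres, gain_cost, loss_cost, overrides)
    state: dict[Node, int] = {}
    c0, c1 = up[tree.root]
    state[tree.root] = 0 if c0 <= c1 + gain_cost else 1
    for node in tree.preorder():
        if node is tree.root:
            continue
        ps = state[node.parent]
        cands = []
        for s in (0, 1):
            cands.append((edge(ps, s) + up[node][s], 0 if s == ps else 1, s))
        cands.sort()
        state[node] = cands[0][2]
    return state


def wagner_gain_losses(
    tree: SpeciesTree,
    present: Iterable[str],
    gain_cost: float = 2.0,
    loss_cost: float = 1.0,
) -> tuple[Node, list[Node], float]:
    """Asymmetric Wagner parsimony placement of a binary character.

    Returns ``(gain_node, loss_nodes, cost)`` where ``gain_node`` is the
    root-most gain edge realised by some minimum-cost labelling (ties among
    equally old branches broken lexicographically by branch id), and
    ``loss_nodes`` the loss edges of one such labelling.
    """
    if gain_cost <= 0 or loss_cost <= 0:
        raise ValueError("gain_cost and loss_cost must be positive")
    pres = _present_set(tree, present)
    best = _wagner_cost(tree, pres, gain_cost, loss_cost, {})

    gain_node: Node | None = None
    chosen_overrides: dict[Node, int] = {}
    for node in sorted(tree.preorder(), key=lambda n: (n.depth, n.branch_id)):
        overrides = {node: 1}
        if node.parent is not None:
            overrides[node.parent] = 0
        cost = _wagner_cost(tree, pres, gain_cost, loss_cost, overrides)
        if abs(cost - best) < 1e-9:
            gain_node = node
            chosen_overrides = overrides
            break
    assert gain_node is not None, "some gain edge must realise the optimum"

    state = _traceback(tree, pres, gain_cost, loss_cost, chosen_overrides)
    losses = [
        node
        for node in tree.preorder()
        if node.parent is not None and state[node.parent] == 1 and state[node] == 0
    ]
    losses.sort(key=lambda n: n.branch_id)
    return gain_node, losses, best
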