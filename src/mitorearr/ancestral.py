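"""Ancestral gene-order mapping on a fixed rooted phylogeny.

Tip gene orders are mapped onto the tree by Sankoff parsimony over a
finite candidate state set.  The candidate pool is the set of distinct
observed tip orders plus every intermediate state that appears on a
minimal event path between two observed orders (the "unsampled
intermediates" a manual parsimony reconstruction posits, e.g. the
pre-inversion Trematominae arrangement).  Pairwise transition costs are
taken from the bounded path searches and completed by shortest paths
through the pool graph, so a transition that needs several events is
priced as the sum of its single-event steps.

All co-optimal root states are reported; the primary assignment used for
tabulation breaks ties deterministically (lexicographic state name).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy

from .events import (EventModel, RearrangementEvent, enumerate_events,
                     events_between, invertible_neighbors)
from .gene_order import GeneOrder, region_slice
from .inference import DEFAULT_REGION, EventPath

INF = math.inf


class ReconstructionError(ValueError):
    pass


@dataclass
class AncestralAssignment:
    tree: dendropy.Tree
    node_states: dict  # node -> state name
    edge_paths: dict  # (parent name/id, child name/id) -> EventPath
    total_cost: float
    state_orders: dict  # state name -> element tuple
    co_optimal_roots: list
    homoplasies: list = field(default_factory=list)

    def events(self) -> list[RearrangementEvent]:
        return [ev for p in self.edge_paths.values() for ev in p.events]


def _node_key(node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return f"node{id(node)}"


def _notation(elements) -> str:
    return ",".join(("-" if s < 0 else "") + lab for lab, s in elements)


class _StatePool:
    """Candidate states, transition costs and representative step events."""

    def __init__(self, model: EventModel, search_depth: int):
        self.model = model
        self.search_depth = search_depth
        self.names: dict[tuple, str] = {}
        self.edges: dict[tuple[tuple, tuple], list[RearrangementEvent]] = {}

    def add_state(self, elements: tuple, name: str | None = None):
        if elements not in self.names or (name and not self._is_named(elements)):
            self.names[elements] = name or _notation(elements)

    def _is_named(self, elements) -> bool:
        return "," not in self.names.get(elements, ",")

    def add_edge(self, u: tuple, v: tuple, ev: RearrangementEvent):
        self.add_state(u)
        self.add_state(v)
        self.edges.setdefault((u, v), [])
        if ev not in self.edges[(u, v)]:
            self.edges[(u, v)].append(ev)

    def connect(self, observed: list[tuple], max_intermediates_per_pair: int = 3):
        """Pairwise bounded searches among observed states.

        Expansion sets are shared per source; minimal paths up to
        ``search_depth`` events contribute their intermediate states and
        single-event edges to the pool graph.  Co-minimal intermediates
        are capped per pair (deterministically, by notation string) to
        keep the pool compact; alternatives beyond the cap change neither
        costs nor reachability.
        """
        model = self.model
        for src in observed:
            targets = [t for t in observed if t != src]
            if not targets:
                continue
            # depth-1 hops
            pend = set(targets)
            for tgt in list(pend):
                evs = events_between(src, tgt, model)
                for ev in evs:
                    self.add_edge(src, tgt, ev)
                if evs:
                    pend.discard(tgt)
            if not pend or self.search_depth < 2:
                continue
            # depth-2: expand one level, then hop
            succ: dict[tuple, list[RearrangementEvent]] = {}
            for ev, res in enumerate_events(src, model):
                if res != src:
                    succ.setdefault(res, []).append(ev)
            for tgt in pend:
                tgt_inv = invertible_neighbors(tgt, model)
                found = []
                for mid, evs_in in succ.items():
                    if mid == tgt:
                        continue
                    evs_out = events_between(mid, tgt, model,
                                             inv_neighbors_b=tgt_inv)
                    if evs_out:
                        found.append((mid, evs_in, evs_out))
                found.sort(key=lambda rec: _notation(rec[0]))
                for mid, evs_in, evs_out in found[:max_intermediates_per_pair]:
                    for e1 in evs_in:
                        self.add_edge(src, mid, e1)
                    for e2 in evs_out:
                        self.add_edge(mid, tgt, e2)

    def cost_matrix(self):
        """All-pairs costs through the pool graph (Floyd-Warshall)."""
        import numpy as np
        from scipy.sparse.csgraph import shortest_path

        states = sorted(self.names, key=lambda s: self.names[s])
        idx = {s: i for i, s in enumerate(states)}
        n = len(states)
        mat = np.full((n, n), np.inf)
        np.fill_diagonal(mat, 0.0)
        for (u, v), evs in self.edges.items():
            w = min(self.model.cost(e) for e in evs)
            i, j = idx[u], idx[v]
            if w < mat[i, j]:
                mat[i, j] = w
        dist, pred = shortest_path(mat, method="FW", directed=True,
                                   return_predecessors=True)
        return states, idx, dist, pred

    def step_event(self, u: tuple, v: tuple) -> RearrangementEvent:
        evs = self.edges[(u, v)]
        return sorted(evs, key=lambda e: (e.display_kind, e.start, e.end))[0]


def reconstruct(tree, tips: dict[str, GeneOrder], model: EventModel | None = None,
                state_pool_depth: int = 2, region=DEFAULT_REGION) -> AncestralAssignment:
    """Sankoff parsimony reconstruction of ancestral gene orders.

    ``tips`` maps tip labels to gene orders; ``state_pool_depth`` bounds the
    number of events allowed per pairwise search stage (pairwise searches
    run to ``state_pool_depth`` events; longer transitions are composed
    through pool intermediates).
    """
    model = model or EventModel()
    tree = _as_tree(tree)
    tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = sorted(tip_labels - set(tips))
    if missing:
        raise ReconstructionError(f"tips without gene order: {missing}")

    def to_elements(order: GeneOrder) -> tuple:
        o = region_slice(order, *region) if (region and order.circular) else (
            order.canonicalize() if order.circular else order)
        return o.elements

    tip_elements = {lab: to_elements(tips[lab]) for lab in tip_labels}
    pool = _StatePool(model, search_depth=state_pool_depth)
    observed = []
    for lab in sorted(tip_labels):
        e = tip_elements[lab]
        pool.add_state(e, tips[lab].name or None)
        if e not in observed:
            observed.append(e)
    pool.connect(observed)
    states, idx, dist, pred = pool.cost_matrix()
    import numpy as np

    for a, b in itertools.combinations(observed, 2):
        if np.isinf(dist[idx[a], idx[b]]) and np.isinf(dist[idx[b], idx[a]]):
            raise ReconstructionError(
                "tip pair unreachable within search depth: "
                f"{pool.names[a]} / {pool.names[b]}")

    n = len(states)
    # Sankoff bottom-up
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            e = tip_elements[node.taxon.label]
            vec = np.full(n, INF)
            vec[idx[e]] = 0.0
            cost[node] = vec
        else:
            acc = np.zeros(n)
            for child in node.child_nodes():
                acc = acc + np.min(dist + cost[child][None, :], axis=1)
            cost[node] = acc

    root = tree.seed_node
    total = float(np.min(cost[root]))
    if np.isinf(total):
        raise ReconstructionError("no finite assignment over the state pool")
    co_roots = sorted(pool.names[states[i]] for i in range(n)
                      if cost[root][i] == total)

    # top-down primary pick, lexicographic tie-break on state name
    node_states_idx: dict = {}

    def name_of(i):
        return pool.names[states[i]]

    root_i = min((i for i in range(n) if cost[root][i] == total),
                 key=name_of)
    node_states_idx[root] = root_i
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        pi = node_states_idx[node.parent_node]
        through = dist[pi] + cost[node]
        best = float(np.min(through))
        j = min((j for j in range(n) if through[j] == best), key=name_of)
        node_states_idx[node] = j

    node_states = {_node_key(node): name_of(i) for node, i in node_states_idx.items()}

    # per-edge event paths through the pool graph
    edge_paths = {}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        pi, ci = node_states_idx[node.parent_node], node_states_idx[node]
        if pi == ci:
            continue
        path_states = [ci]
        k = ci
        while k != pi:
            k = int(pred[pi, k])
            if k < 0:
                raise ReconstructionError(
                    f"no pool path {name_of(pi)} -> {name_of(ci)}")
            path_states.append(k)
        path_states.reverse()
        events = []
        for a, b in zip(path_states, path_states[1:]):
            ev = pool.step_event(states[a], states[b])
            events.append(ev)
        p = EventPath(states[pi], states[ci], tuple(events),
                      sum(model.cost(e) for e in events))
        edge_paths[(_node_key(node.parent_node), _node_key(node))] = p

    assignment = AncestralAssignment(
        tree=tree, node_states={k: v for k, v in node_states.items()},
        edge_paths=edge_paths, total_cost=total,
        state_orders={pool.names[s]: s for s in states},
        co_optimal_roots=co_roots)
    assignment.node_states_by_node = node_states_idx  # type: ignore[attr-defined]
    assignment.homoplasies = detect_homoplasy(assignment)
    return assignment


def _as_tree(tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick",
                             preserve_underscores=True)


def count_events(assignment: AncestralAssignment):
    """Total event count and per-mechanism breakdown across all edges."""
    breakdown: dict[str, int] = {}
    total = 0
    for path in assignment.edge_paths.values():
        for ev in path.events:
            breakdown[ev.display_kind] = breakdown.get(ev.display_kind, 0) + 1
            total += 1
    return total, breakdown


def detect_homoplasy(assignment: AncestralAssignment) -> list[tuple[str, list[str]]]:
    """Gene orders derived independently on two or more branches.

    A state is homoplastic when it is derived (child differs from parent)
    on at least two edges whose child nodes are not on one root-to-tip
    path (neither origin is ancestral to the other).
    """
    tree = assignment.tree
    states = getattr(assignment, "node_states_by_node", None)
    if states is None:  # pragma: no cover - defensive
        raise ReconstructionError("assignment lacks node state indices")
    origins: dict[int, list] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        s, ps = states[node], states[node.parent_node]
        if s != ps:
            origins.setdefault(s, []).append(node)
    name_by_idx = {}
    for node, i in states.items():
        name_by_idx[i] = assignment.node_states[_node_key(node)]
    out = []
    for s, nodes in origins.items():
        independent = []
        for a, b in itertools.combinations(nodes, 2):
            if not (_is_ancestor(a, b) or _is_ancestor(b, a)):
                independent.append((a, b))
        if independent:
            out.append((name_by_idx[s], [_origin_label(nd) for nd in nodes]))
    out.sort()
    return out


def _is_ancestor(a, b) -> bool:
    node = b.parent_node
    while node is not None:
        if node is a:
            return True
        node = node.parent_node
    return False


def _origin_label(node) -> str:
    if node.is_leaf():
        return node.taxon.label
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return f"mrca({leaves[0]}+{len(leaves) - 1})"


def run_on_alternative_topology(tree_a, tree_b, tips, model=None,
                                state_pool_depth: int = 2,
                                region=DEFAULT_REGION):
    """Reconstruct on two topologies sharing a tip set and compare."""
    ta, tb = _as_tree(tree_a), _as_tree(tree_b)
    la = {l.taxon.label for l in ta.leaf_node_iter()}
    lb = {l.taxon.label for l in tb.leaf_node_iter()}
    if la != lb:
        raise ReconstructionError(f"tip sets differ: {sorted(la ^ lb)}")
    ra = reconstruct(ta, tips, model, state_pool_depth, region)
    rb = reconstruct(tb, tips, model, state_pool_depth, region)

    def pathway_set(r):
        out = []
        for (p, c), path in r.edge_paths.items():
            out.append((r.node_states[p], r.node_states[c],
                        tuple(ev.display_kind for ev in path.events)))
        return sorted(out)

    identical = (ra.total_cost == rb.total_cost
                 and pathway_set(ra) == pathway_set(rb))
    return {"assignment_a": ra, "assignment_b": rb,
            "total_cost_a": ra.total_cost, "total_cost_b": rb.total_cost,
            "pathways_identical": identical}
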