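"""Minimal rearrangement-path inference between two gene orders.

The search is a breadth-first expansion over single-event successors with
state deduplication, plus a "directed hop": at every depth, each frontier
state is tested analytically for a single event that lands exactly on the
target.  The hop test covers every mechanism in the model, including
triplications and duplications longer than the enumeration cap, so those
are recognized as the final step of a path even when they are too costly
to enumerate blindly.  All co-minimal paths are reconstructed from the
predecessor graph and returned in a deterministic order.

Circular orders are compared through their canonical linearization; events
never span the *cox1* anchor (the anchor region is structurally stable in
the data this models).  Inference is typically run on a region slice, the
*nad5*-*trnF* hot spot by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import (EventModel, RearrangementEvent, apply_to_elements,
                     enumerate_events, events_between, invertible_neighbors,
                     Elements)
from .gene_order import GeneOrder, region_slice

DEFAULT_REGION = ("nad5", "F")


class SearchCapExceeded(RuntimeError):
    """Raised when the BFS state space exceeds the model's node cap."""


@dataclass(frozen=True)
class EventPath:
    """A minimal series of events transforming source into target."""

    source: Elements
    target: Elements
    events: tuple[RearrangementEvent, ...]
    cost: float

    def __post_init__(self):
        cur = self.source
        for ev in self.events:
            cur = apply_to_elements(cur, ev)
        if cur != self.target:
            raise ValueError("event path does not replay onto its target")

    @property
    def states(self) -> tuple[Elements, ...]:
        out = [self.source]
        for ev in self.events:
            out.append(apply_to_elements(out[-1], ev))
        return tuple(out)

    def display(self) -> str:
        return " -> ".join(ev.display_kind for ev in self.events) or "(identity)"


def _sort_key(path: EventPath):
    return tuple((ev.display_kind, ev.start, ev.end, ev.insertion or -1, ev.keeps)
                 for ev in path.events)


def _as_elements(order: GeneOrder | Elements, region) -> Elements:
    if isinstance(order, GeneOrder):
        if region is not None and order.circular:
            order = region_slice(order, *region)
        elif order.circular:
            order = order.canonicalize()
        return order.elements
    return tuple(order)


def infer_events(source, target, model: EventModel | None = None,
                 max_depth: int = 3, region=DEFAULT_REGION) -> list[EventPath]:
    """All minimal-cost event paths from source to target (unit costs).

    ``region=None`` searches whole orders; otherwise both orders are
    restricted to the named slice before searching.  Returns an empty list
    when no path exists within ``max_depth`` events.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    model = model or EventModel()
    src = _as_elements(source, region)
    tgt = _as_elements(target, region)
    if src == tgt:
        return [EventPath(src, tgt, (), 0.0)]

    # predecessor graph: state -> list of (previous state, event), recorded
    # only at the state's minimal depth so every reconstruction is minimal
    preds: dict[Elements, list[tuple[Elements, RearrangementEvent]]] = {src: []}
    depth_of: dict[Elements, int] = {src: 0}
    frontier: list[Elements] = [src]
    hits: list[tuple[Elements, RearrangementEvent]] = []
    tgt_inv = invertible_neighbors(tgt, model)

    for depth in range(1, max_depth + 1):
        for s in frontier:
            for ev in events_between(s, tgt, model, inv_neighbors_b=tgt_inv):
                hits.append((s, ev))
        if hits:
            break
        if depth == max_depth:
            return []
        nxt: dict[Elements, list[tuple[Elements, RearrangementEvent]]] = {}
        for s in frontier:
            for ev, res in enumerate_events(s, model):
                if res in depth_of:
                    continue
                nxt.setdefault(res, []).append((s, ev))
            if len(depth_of) + len(nxt) > model.node_cap:
                raise SearchCapExceeded(
                    f"search exceeded {model.node_cap} states at depth {depth}")
        for res, plist in nxt.items():
            depth_of[res] = depth
            preds[res] = plist
        frontier = list(nxt.keys())
        if not frontier:
            return []

    # reconstruct all minimal paths
    paths: list[EventPath] = []

    def walk(state: Elements) -> list[tuple[RearrangementEvent, ...]]:
        if state == src:
            return [()]
        out = []
        for prev, ev in preds[state]:
            for head in walk(prev):
                out.append(head + (ev,))
        return out

    seen = set()
    for s, ev in hits:
        for head in walk(s):
            evs = head + (ev,)
            if evs in seen:
                continue
            seen.add(evs)
            cost = sum(model.cost(e) for e in evs)
            paths.append(EventPath(src, tgt, evs, cost))
    paths.sort(key=_sort_key)
    return paths


def event_distance(source, target, model: EventModel | None = None,
                   max_depth: int = 3, region=DEFAULT_REGION) -> float | None:
    """Minimal event count between two orders, or None if unreached."""
    paths = infer_events(source, target, model, max_depth, region)
    if not paths:
        return None
    return paths[0].cost
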