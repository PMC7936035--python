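"""Rearrangement operators on gene orders.

The mechanism taxonomy follows the standard mitogenomics nomenclature:

* inversion (``I``) -- a contiguous segment is reversed and every element
  in it moves to the opposite strand;
* transposition (``t``) -- a contiguous segment moves elsewhere on the
  same strand (the single-gene case is classically produced by a
  tandem duplication / random loss, ``tdrl``);
* inverse transposition (``it``) -- move plus strand flip;
* loss -- a contiguous segment is deleted;
* tandem duplication / random loss (``TDRL``) -- a contiguous block is
  duplicated in tandem and one copy of each redundant element is lost.
  When losses are incomplete (some elements retain both copies) the event
  is a tandem duplication / *partial* random loss (``TD-PRL``); when no
  copy is lost at all it is a plain tandem duplication (``TD``).  The
  triplication variants (``TriD`` / ``Tri-PRL``) duplicate the block twice.

A duplication-loss event is represented by its segment plus one keep
vector per copy; a completed TDRL keeps exactly one copy of every element,
and the whole duplication+loss is counted as ONE event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .gene_order import Element, GeneOrder, GeneOrderError
from .vocab import UNSIGNED_LABELS

Elements = tuple[Element, ...]


class EventError(ValueError):
    pass


def _invert_seg(seg: Elements) -> Elements:
    return tuple(
        (lab, sign if lab in UNSIGNED_LABELS else -sign)
        for lab, sign in reversed(seg)
    )


@dataclass(frozen=True)
class RearrangementEvent:
    """One rearrangement; ``start:end`` is the segment in the source order.

    ``insertion`` is the target position for (inverse) transpositions,
    expressed in source coordinates and outside the segment.  ``keeps``
    holds one boolean keep-vector per tandem copy for duplication-loss
    events (1 vector entry per segment element; an element must be kept in
    at least one copy).
    """

    kind: str  # inversion | transposition | inverse_transposition | loss | PRL | tdrl | tdrl3
    start: int
    end: int
    insertion: int | None = None
    keeps: tuple[tuple[bool, ...], ...] = ()

    def __post_init__(self):
        if self.kind not in ("inversion", "transposition", "inverse_transposition",
                             "loss", "PRL", "tdrl", "tdrl3"):
            raise EventError(f"unknown event kind {self.kind!r}")
        if self.kind in ("transposition", "inverse_transposition") and self.insertion is None:
            raise EventError(f"{self.kind} requires an insertion point")
        if self.kind == "PRL":
            k = self.end - self.start
            if len(self.keeps) != 1 or len(self.keeps[0]) != k:
                raise EventError("PRL requires one keep vector over its span")
            if all(self.keeps[0]):
                raise EventError("PRL must drop at least one element")
        if self.kind in ("tdrl", "tdrl3"):
            ncopies = 2 if self.kind == "tdrl" else 3
            k = self.end - self.start
            if len(self.keeps) != ncopies or any(len(v) != k for v in self.keeps):
                raise EventError("keep vectors do not match duplication arity")
            for pos in range(k):
                if not any(v[pos] for v in self.keeps):
                    raise EventError("loss pattern leaves zero copies of an element")

    @property
    def display_kind(self) -> str:
        """Paper-style mechanism label (TD, TDRL, TD-PRL, TriD, Tri-PRL...)."""
        if self.kind == "tdrl":
            if all(all(v) for v in self.keeps):
                return "TD"
            if all(sum(v[pos] for v in self.keeps) == 1
                   for pos in range(self.end - self.start)):
                return "tdrl" if self.end - self.start == 1 else "TDRL"
            return "TD-PRL"
        if self.kind == "tdrl3":
            if all(all(v) for v in self.keeps):
                return "TriD"
            return "Tri-PRL"
        return {"inversion": "I", "transposition": "t",
                "inverse_transposition": "it", "loss": "loss",
                "PRL": "PRL"}[self.kind]


def apply_to_elements(elements: Elements, ev: RearrangementEvent) -> Elements:
    """Apply an event to a linear element tuple."""
    n = len(elements)
    i, j = ev.start, ev.end
    if not (0 <= i < j <= n):
        raise EventError(f"segment [{i}:{j}) not contiguous within order of length {n}")
    pre, seg, post = elements[:i], elements[i:j], elements[j:]
    if ev.kind == "inversion":
        return pre + _invert_seg(seg) + post
    if ev.kind == "loss":
        out = pre + post
        if not out:
            raise EventError("loss would empty the order")
        return out
    if ev.kind in ("transposition", "inverse_transposition"):
        k = ev.insertion
        if k is None or not (0 <= k <= n) or (i <= k <= j):
            raise EventError("insertion point missing or inside segment")
        body = _invert_seg(seg) if ev.kind == "inverse_transposition" else seg
        rest_pre = elements[:k] if k <= i else pre + elements[j:k]
        rest_post = elements[k:i] + post if k <= i else elements[k:]
        return rest_pre + body + rest_post
    if ev.kind == "PRL":
        keep = ev.keeps[0]
        out = pre + tuple(e for e, kp in zip(seg, keep) if kp) + post
        dropped = [e for e, kp in zip(seg, keep) if not kp]
        survivors = Counter(out)
        for e in dropped:
            if survivors.get(e, 0) < 1:
                raise EventError(
                    f"PRL drops the last copy of {e[0]}; use a loss event")
        return out
    # duplication-loss kinds
    copies = [tuple(e for e, keep in zip(seg, v) if keep) for v in ev.keeps]
    mid = tuple(x for c in copies for x in c)
    return pre + mid + post


def apply_event(order: GeneOrder, ev: RearrangementEvent) -> GeneOrder:
    """Apply one event to a gene order (re-canonicalized if circular).

    On circular orders the event acts on the canonical linearization (the
    *cox1* anchor itself is never rearranged in this dataset).
    """
    base = order.canonicalize() if order.circular else order
    out = apply_to_elements(base.elements, ev)
    try:
        res = GeneOrder(out, name="", circular=order.circular, partial=order.partial)
    except GeneOrderError as exc:
        raise EventError(str(exc)) from exc
    return res.canonicalize() if order.circular else res


# ---------------------------------------------------------------------------
# successor enumeration
# ---------------------------------------------------------------------------

DEFAULT_KINDS = ("tdrl", "loss", "PRL", "inversion", "transposition")


@dataclass(frozen=True)
class EventModel:
    """Event kinds, costs and search limits for rearrangement inference.

    Unit cost per event of any kind is the default: published event counts
    treat a completed duplication-loss as a single rearrangement and never
    weight mechanisms.  ``max_dup_len`` caps the segment length for which
    duplication-loss events are exhaustively enumerated; longer
    duplications are still recognized when they connect two known orders
    (directed check).

    ``contiguous_keeps`` restricts duplication-loss events so that each
    tandem copy retains one contiguous block of the duplicated segment
    (the random-loss phase excises runs); arbitrary keep patterns would
    let a single event emulate any interleaving of two subsequences,
    collapsing distances that the mechanism taxonomy keeps distinct.
    """

    kinds: tuple[str, ...] = DEFAULT_KINDS
    costs: tuple[tuple[str, float], ...] = ()
    max_dup_len: int = 8
    #: segment-length bound for recognizing a duplication between two given
    #: orders (directed check); may exceed ``max_dup_len``
    max_dup_len_directed: int = 10
    node_cap: int = 500_000
    allow_triplication: bool = True
    contiguous_keeps: bool = True

    def cost(self, ev: RearrangementEvent) -> float:
        return dict(self.costs).get(ev.kind, 1.0)


TOY_MODEL = EventModel(kinds=("inversion", "transposition", "loss"))

#: scenario model for the notothenioid reconstruction: duplication-type
#: events (gains) weighted 2 against 1 for losses, inversions and
#: transpositions -- a Dollo-leaning weighting (structure is easier to
#: lose than to regain) under which the mapped pathways match the
#: spacer-corroborated reconstruction; event *counts* stay unweighted.
NOTOTHENIOID_MODEL = EventModel(costs=(("tdrl", 2.0), ("tdrl3", 2.0)),
                                max_dup_len=6)


def enumerate_events(elements: Elements, model: EventModel):
    """Yield ``(event, result_elements)`` for every enumerable single event."""
    n = len(elements)
    kinds = set(model.kinds)
    if "loss" in kinds:
        for i in range(n):
            for j in range(i + 1, n + 1):
                if j - i == n:
                    continue
                ev = RearrangementEvent("loss", i, j)
                yield ev, elements[:i] + elements[j:]
    if "inversion" in kinds:
        for i in range(n):
            for j in range(i + 1, n + 1):
                ev = RearrangementEvent("inversion", i, j)
                res = elements[:i] + _invert_seg(elements[i:j]) + elements[j:]
                if res != elements:
                    yield ev, res
    for kind in ("transposition", "inverse_transposition"):
        if kind not in kinds:
            continue
        for i in range(n):
            for j in range(i + 1, n + 1):
                seg = elements[i:j]
                body = _invert_seg(seg) if kind == "inverse_transposition" else seg
                for k in list(range(0, i)) + list(range(j + 1, n + 1)):
                    ev = RearrangementEvent(kind, i, j, insertion=k)
                    res = apply_to_elements(elements, ev)
                    if res != elements:
                        yield ev, res
    if "PRL" in kinds:
        yield from _enumerate_prl(elements)
    if "tdrl" in kinds:
        yield from _enumerate_tdrl(elements, model)


def _is_run(keep: tuple[bool, ...]) -> bool:
    idxs = [i for i, kp in enumerate(keep) if kp]
    return not idxs or idxs[-1] - idxs[0] + 1 == len(idxs)


def _keep_pairs(k: int, contiguous: bool):
    """Keep-vector pairs for a tandem duplication of k elements."""
    if contiguous:
        out = []
        for a1 in range(k):
            for b1 in range(a1 + 1, k + 1):
                for a2 in range(k):
                    for b2 in range(a2 + 1, k + 1):
                        if min(a1, a2) != 0 or max(b1, b2) != k:
                            continue
                        if (a2 if a1 <= a2 else a1) > (b1 if a1 <= a2 else b2):
                            continue  # gap in coverage
                        keep1 = tuple(a1 <= p < b1 for p in range(k))
                        keep2 = tuple(a2 <= p < b2 for p in range(k))
                        out.append((keep1, keep2))
        return out
    out = []
    for code in range(3 ** k):
        c, choices = code, []
        for _ in range(k):
            choices.append(c % 3)
            c //= 3
        keep1 = tuple(ch != 1 for ch in choices)
        keep2 = tuple(ch != 0 for ch in choices)
        out.append((keep1, keep2))
    return out


def _enumerate_tdrl(elements: Elements, model: EventModel):
    n = len(elements)
    for i in range(n):
        for j in range(i + 1, min(n, i + model.max_dup_len) + 1):
            k = j - i
            seg = elements[i:j]
            pre, post = elements[:i], elements[j:]
            for keep1, keep2 in _keep_pairs(k, model.contiguous_keeps):
                if all(keep1) and not any(keep2):
                    continue  # identity
                if all(keep2) and not any(keep1):
                    continue  # identity
                if any(not (kp1 or kp2) for kp1, kp2 in zip(keep1, keep2)):
                    continue  # an element would lose every copy
                ev = RearrangementEvent("tdrl", i, j, keeps=(keep1, keep2))
                res = (pre
                       + tuple(e for e, kp in zip(seg, keep1) if kp)
                       + tuple(e for e, kp in zip(seg, keep2) if kp)
                       + post)
                if res != elements:
                    yield ev, res


def _enumerate_prl(elements: Elements, max_droppable: int = 14):
    """Standalone partial random loss: drop a set of redundant copies.

    Droppable positions are those whose (label, orientation) occurs more
    than once; any drop set leaving at least one copy per element is one
    PRL event.  Single contiguous drop runs are plain losses and excluded
    here to avoid double-listing.
    """
    counts = Counter(elements)
    droppable = [p for p, e in enumerate(elements) if counts[e] > 1]
    if not droppable or len(droppable) > max_droppable:
        return
    n = len(droppable)
    for mask in range(1, 2 ** n):
        drop = [droppable[t] for t in range(n) if mask >> t & 1]
        if len(drop) == drop[-1] - drop[0] + 1:
            continue  # single contiguous run: that is a loss event
        dropped_counts = Counter(elements[p] for p in drop)
        if any(dropped_counts[e] >= counts[e] for e in dropped_counts):
            continue
        i, j = drop[0], drop[-1] + 1
        keep = tuple(p not in drop for p in range(i, j))
        ev = RearrangementEvent("PRL", i, j, keeps=(keep,))
        dset = set(drop)
        res = tuple(e for p, e in enumerate(elements) if p not in dset)
        yield ev, res


# ---------------------------------------------------------------------------
# directed single-event search: all events transforming a into b
# ---------------------------------------------------------------------------

def _diff_window(a: Elements, b: Elements) -> tuple[int, int]:
    """First and last differing index over the common length."""
    n = min(len(a), len(b))
    l = 0
    while l < n and a[l] == b[l]:
        l += 1
    r_a, r_b = len(a) - 1, len(b) - 1
    while r_a >= l and r_b >= l and a[r_a] == b[r_b]:
        r_a -= 1
        r_b -= 1
    return l, r_a


def _embeddings(part: Elements, seg: Elements, cap: int = 64,
                step_cap: int = 4000):
    """All increasing position-tuples embedding `part` in `seg`.

    Bounded: at most ``cap`` embeddings are returned and the backtracking
    explores at most ``step_cap`` nodes (repetitive segments would
    otherwise be combinatorial; hitting the bound can only drop redundant
    parameterizations of the same duplication-loss transition).
    """
    out: list[tuple[int, ...]] = []
    steps = 0

    def rec(pi: int, si: int, acc: list[int]):
        nonlocal steps
        steps += 1
        if len(out) >= cap or steps > step_cap:
            return
        if pi == len(part):
            out.append(tuple(acc))
            return
        for s in range(si, len(seg) - (len(part) - pi) + 1):
            if seg[s] == part[pi]:
                rec(pi + 1, s + 1, acc + [s])

    rec(0, 0, [])
    return out


def _common_flanks(a: Elements, b: Elements) -> tuple[int, int]:
    """Lengths of the longest common prefix and suffix of two orders."""
    na, nb = len(a), len(b)
    n = min(na, nb)
    p = 0
    while p < n and a[p] == b[p]:
        p += 1
    s = 0
    while s < n - 0 and s < na and s < nb and a[na - 1 - s] == b[nb - 1 - s]:
        s += 1
    return p, s


def _dup_loss_events(a: Elements, b: Elements, ncopies: int, kind: str,
                     contiguous: bool = True, embed_cap: int = 64,
                     seg_cap: int = 10):
    """Duplication-loss events (2 or 3 tandem copies) mapping a onto b.

    The flanks outside the duplicated segment are untouched, so segment
    candidates are bounded by the longest common prefix/suffix.
    """
    na, nb = len(a), len(b)
    if nb < na:
        return
    pref, suf = _common_flanks(a, b)
    seen = set()
    for i in range(min(pref, na - 1) + 1):
        for j in range(max(i + 1, na - suf), min(na, i + seg_cap) + 1):
            tail = na - j
            seg = a[i:j]
            mid = b[i: nb - tail]
            if len(mid) < len(seg) or len(mid) > ncopies * len(seg):
                continue
            cseg = Counter(seg)
            cmid = Counter(mid)
            if any(cmid[e] < c for e, c in cseg.items()):
                continue  # every segment element must survive somewhere
            if any(cmid[e] > ncopies * cseg.get(e, 0) for e in cmid):
                continue
            # split mid into ncopies ordered parts, each a subsequence of seg
            for splits in _splits(len(mid), ncopies):
                parts = [mid[s:e] for s, e in splits]
                if any(len(p) > len(seg) for p in parts):
                    continue
                emb_sets = []
                ok = True
                for p in parts:
                    cp = Counter(p)
                    if any(cp[e] > cseg.get(e, 0) for e in cp):
                        ok = False
                        break
                    embs = _embeddings(p, seg, cap=embed_cap)
                    if not embs:
                        ok = False
                        break
                    emb_sets.append(embs)
                if not ok:
                    continue
                for combo in _product_capped(emb_sets, embed_cap):
                    keeps = []
                    for emb in combo:
                        v = [False] * len(seg)
                        for pos in emb:
                            v[pos] = True
                        keeps.append(tuple(v))
                    if any(not any(v[pos] for v in keeps)
                           for pos in range(len(seg))):
                        continue
                    if contiguous and not all(_is_run(v) for v in keeps):
                        continue
                    key = (i, j, tuple(keeps))
                    if key in seen:
                        continue
                    seen.add(key)
                    yield RearrangementEvent(kind, i, j, keeps=tuple(keeps))


def _splits(n: int, parts: int):
    if parts == 2:
        for s in range(n + 1):
            yield ((0, s), (s, n))
    else:
        for s in range(n + 1):
            for t in range(s, n + 1):
                yield ((0, s), (s, t), (t, n))


def _product_capped(sets, cap):
    count = 0

    def rec(idx, acc):
        nonlocal count
        if count >= cap:
            return
        if idx == len(sets):
            count += 1
            yield tuple(acc)
            return
        for item in sets[idx]:
            yield from rec(idx + 1, acc + [item])

    yield from rec(0, [])


INVERTIBLE_KINDS = ("inversion", "transposition", "inverse_transposition")


def invertible_neighbors(elements: Elements, model: EventModel) -> frozenset:
    """States one inversion / (inverse) transposition away.

    These mechanisms are their own inverses (up to parameters), so
    membership of ``x`` in the neighbor set of ``y`` certifies a single
    such event in either direction.  Used as an O(1) pre-filter when many
    candidate states are hop-tested against one target.
    """
    kinds = tuple(k for k in INVERTIBLE_KINDS if k in model.kinds)
    if not kinds:
        return frozenset()
    sub = EventModel(kinds=kinds)
    return frozenset(res for _, res in enumerate_events(elements, sub))


def events_between(a: Elements, b: Elements, model: EventModel,
                   inv_neighbors_b: frozenset | None = None) -> list[RearrangementEvent]:
    """All single events in the model transforming ``a`` exactly into ``b``.

    ``inv_neighbors_b`` may carry :func:`invertible_neighbors` of ``b``;
    when given, the cubic transposition scan is skipped for states that
    are provably not one invertible event away.
    """
    if a == b:
        return []
    out: list[RearrangementEvent] = []
    kinds = set(model.kinds)
    na, nb = len(a), len(b)
    if "loss" in kinds and nb < na:
        d = na - nb
        pref, suf = _common_flanks(a, b)
        for i in range(max(0, na - d - suf), min(pref, nb) + 1):
            out.append(RearrangementEvent("loss", i, i + d))
    if "PRL" in kinds and nb < na:
        out.extend(_prl_events(a, b))
    if na == nb and (inv_neighbors_b is None or a in inv_neighbors_b):
        l, r = _diff_window(a, b)
        if "inversion" in kinds and Counter(lab for lab, _ in a) == Counter(lab for lab, _ in b):
            for i in range(l + 1):
                for j in range(r + 1, na + 1):
                    if a[:i] + _invert_seg(a[i:j]) + a[j:] == b:
                        out.append(RearrangementEvent("inversion", i, j))
        same_signed = Counter(a) == Counter(b)
        for kind in ("transposition", "inverse_transposition"):
            if kind not in kinds:
                continue
            if kind == "transposition" and not same_signed:
                continue
            for i in range(l, r + 2):
                for j in range(i + 1, r + 2):
                    for k in list(range(l, i)) + list(range(j + 1, r + 2)):
                        ev = RearrangementEvent(kind, i, j, insertion=k)
                        try:
                            if apply_to_elements(a, ev) == b:
                                out.append(ev)
                        except EventError:
                            continue
    if "tdrl" in kinds and nb >= na:
        cap = model.max_dup_len_directed
        out.extend(_dup_loss_events(a, b, 2, "tdrl", model.contiguous_keeps,
                                    seg_cap=cap))
        if model.allow_triplication:
            out.extend(_dup_loss_events(a, b, 3, "tdrl3",
                                        model.contiguous_keeps, seg_cap=cap))
    return out


def _prl_events(a: Elements, b: Elements, embed_cap: int = 32):
    """Partial-random-loss events mapping a onto b (b a subsequence of a)."""
    counts = Counter(a)
    target = Counter(b)
    # every dropped element must survive: multiset(b) must contain >= 1 of it
    diff = counts - target
    if any(target.get(e, 0) < 1 for e in diff):
        return []
    out = []
    seen = set()
    for emb in _embeddings(b, a, cap=embed_cap):
        kept = set(emb)
        drop = sorted(p for p in range(len(a)) if p not in kept)
        if not drop or len(drop) == drop[-1] - drop[0] + 1:
            continue  # contiguous run: plain loss
        key = tuple(drop)
        if key in seen:
            continue
        seen.add(key)
        i, j = drop[0], drop[-1] + 1
        dset = set(drop)
        keep = tuple(p not in dset for p in range(i, j))
        out.append(RearrangementEvent("PRL", i, j, keeps=(keep,)))
    return out
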