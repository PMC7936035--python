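"""Minimal-path inference: paper transitions, oracle equivalence, properties."""

import numpy as np
import pytest

from mitorearr.events import EventModel, TOY_MODEL
from mitorearr.fixtures import (DISSOGO, NOTO1GO, NOTO2GO, NOTO3GO, TREMAGO,
                                TREMA_INTERMEDIATE, VERTGO)
from mitorearr.inference import SearchCapExceeded, event_distance, infer_events

# ---------------------------------------------------------------------------
# independent brute-force oracle (inversion / transposition / loss only)
# ---------------------------------------------------------------------------


def o_invert(seq, i, j):
    return seq[:i] + tuple((l, -s) for l, s in reversed(seq[i:j])) + seq[j:]


def o_loss(seq, i, j):
    return seq[:i] + seq[j:]


def o_transpose(seq, i, j, k):
    block, rest = seq[i:j], seq[:i] + seq[j:]
    k2 = k if k <= i else k - (j - i)
    return rest[:k2] + block + rest[k2:]


def oracle_successors(seq):
    out = set()
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n + 1):
            r = o_invert(seq, i, j)
            if r != seq:
                out.add(r)
            if j - i < n:
                out.add(o_loss(seq, i, j))
            for k in list(range(0, i)) + list(range(j + 1, n + 1)):
                r = o_transpose(seq, i, j, k)
                if r != seq:
                    out.add(r)
    return out


def oracle_distance(src, tgt, max_depth):
    """Plain BFS over oracle successors; None if unreached."""
    if src == tgt:
        return 0
    frontier, seen = {src}, {src}
    for depth in range(1, max_depth + 1):
        nxt = set()
        for s in frontier:
            for r in oracle_successors(s):
                if r == tgt:
                    return depth
                if r not in seen:
                    seen.add(r)
                    nxt.add(r)
        frontier = nxt
    return None


def random_order(rng, n):
    labels = ["cox1", "a", "b", "c", "d", "e", "f"][:n]
    perm = ["cox1"] + list(rng.permutation(labels[1:]))
    signs = [1] + [int(s) for s in rng.choice([1, -1], size=n - 1)]
    return tuple(zip(perm, signs))


# ---------------------------------------------------------------------------


class TestPaperTransitions:
    def test_identity_path(self):
        paths = infer_events(VERTGO, VERTGO, max_depth=2)
        assert len(paths) == 1 and paths[0].cost == 0 and not paths[0].events

    def test_single_event_transitions(self):
        cases = [
            (VERTGO, NOTO1GO, {"TD-PRL"}),
            (NOTO1GO, DISSOGO, {"loss"}),
            (NOTO2GO, NOTO3GO, {"loss"}),
        ]
        for src, dst, kinds in cases:
            paths = infer_events(src, dst, max_depth=2)
            assert paths and len(paths[0].events) == 1
            assert kinds & {p.events[0].display_kind for p in paths}

    def test_trematominae_inversion(self):
        paths = infer_events(TREMA_INTERMEDIATE, TREMAGO, max_depth=2,
                             region=("nad5", "M"))
        assert paths[0].display() == "I"
        assert len(paths[0].events) == 1

    def test_event_distance_basics(self):
        assert event_distance(NOTO1GO, NOTO1GO) == 0
        assert event_distance(NOTO1GO, DISSOGO) == 1
        assert event_distance(NOTO1GO, NOTO2GO) == 1  # one PRL event

    def test_unreachable_returns_empty(self):
        assert infer_events(VERTGO, TREMAGO, max_depth=1,
                            region=("nad5", "M")) == []
        assert event_distance(VERTGO, TREMAGO, max_depth=1,
                              region=("nad5", "M")) is None

    def test_paths_replay_onto_target(self):
        from mitorearr.events import apply_to_elements

        for p in infer_events(VERTGO, NOTO1GO, max_depth=2):
            cur = p.source
            for ev in p.events:
                cur = apply_to_elements(cur, ev)
            assert cur == p.target


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_on_toy_orders(self, seed):
        """Minimal cost equals an independent exhaustive BFS (<= 6 elements)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        src, tgt = random_order(rng, n), random_order(rng, n)
        want = oracle_distance(src, tgt, max_depth=2)
        paths = infer_events(src, tgt, model=TOY_MODEL, max_depth=2,
                             region=None)
        got = len(paths[0].events) if paths else None
        assert got == want

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_with_losses(self, seed):
        rng = np.random.default_rng(100 + seed)
        src = random_order(rng, 6)
        # walk two random oracle steps to guarantee reachability
        succ1 = sorted(oracle_successors(src))
        mid = succ1[rng.integers(0, len(succ1))]
        succ2 = sorted(oracle_successors(mid)) or [mid]
        tgt = succ2[rng.integers(0, len(succ2))]
        want = oracle_distance(src, tgt, max_depth=2)
        paths = infer_events(src, tgt, model=TOY_MODEL, max_depth=2,
                             region=None)
        got = len(paths[0].events) if paths else None
        assert got == want

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetry_for_invertible_models(self, seed):
        model = EventModel(kinds=("inversion", "transposition"))
        rng = np.random.default_rng(200 + seed)
        src, tgt = random_order(rng, 5), random_order(rng, 5)
        d1 = event_distance(src, tgt, model=model, max_depth=2, region=None)
        d2 = event_distance(tgt, src, model=model, max_depth=2, region=None)
        assert d1 == d2

    def test_search_cap_raises(self):
        model = EventModel(node_cap=10)
        with pytest.raises(SearchCapExceeded):
            infer_events(VERTGO, TREMAGO, model=model, max_depth=3,
                         region=("nad5", "M"))
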