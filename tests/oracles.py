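"""Independent brute-force helpers shared by oracle-equivalence tests."""

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
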