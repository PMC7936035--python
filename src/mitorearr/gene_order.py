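"""Signed circular gene-order model with canonical linearization.

A mitochondrial gene order is a circular arrangement of labeled, oriented
elements (genes, the Control Region, the L-strand origin).  Because a
circular DNA molecule has no intrinsic start and can be read from either
strand, a single arrangement has ``2 * n`` equivalent readings (rotations
times reading directions).  :func:`canonicalize` maps all of them onto one
normal form: the reading is chosen so that ``cox1`` is on the H-strand
(orientation ``+``) and the list is rotated so ``cox1`` comes first.

Elements are stored as ``(label, sign)`` pairs with ``sign`` in ``{+1, -1}``
(+ = H-strand, - = L-strand).  Copy tags for duplicated elements (the ``a`` /
``b`` subscripts and ``CoRe1`` / ``CoRe2`` of the literature) are *derived*
from the canonical traversal order, never stored: two orders that differ
only in their input copy tags are therefore equal after canonicalization.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .vocab import UNSIGNED_LABELS

Element = tuple[str, int]


class GeneOrderError(ValueError):
    pass


def _mirror(elements: tuple[Element, ...]) -> tuple[Element, ...]:
    """The same circular molecule read from the complementary strand."""
    return tuple(
        (lab, sign if lab in UNSIGNED_LABELS else -sign)
        for lab, sign in reversed(elements)
    )


@dataclass(frozen=True)
class GeneOrder:
    """A gene order; circular by default, linear for region slices."""

    elements: tuple[Element, ...]
    name: str = ""
    circular: bool = True
    partial: bool = False
    metadata: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if not self.elements:
            raise GeneOrderError("gene order must be nonempty")
        for lab, sign in self.elements:
            if sign not in (1, -1):
                raise GeneOrderError(f"bad orientation {sign!r} for {lab}")
        if sum(1 for lab, _ in self.elements if lab == "cox1") > 1:
            raise GeneOrderError("at most one cox1 allowed")

    # -- representation ----------------------------------------------------

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.elements)

    def copy_tags(self) -> tuple[str | None, ...]:
        """Copy tags by traversal order: a/b/c for genes, 1/2/3 for CoRe.

        A tag is present iff the label occurs more than once.
        """
        counts = Counter(self.labels)
        seen: dict[str, int] = defaultdict(int)
        tags: list[str | None] = []
        for lab in self.labels:
            if counts[lab] > 1:
                i = seen[lab]
                tags.append(str(i + 1) if lab == "CoRe" else "abcdefgh"[i])
                seen[lab] += 1
            else:
                tags.append(None)
        return tuple(tags)

    def notation(self) -> str:
        """Linearized plain-text notation, e.g. ``cox1,-S2,...,T(a),-P(a)``."""
        parts = []
        for (lab, sign), tag in zip(self.elements, self.copy_tags()):
            s = ("-" if sign < 0 else "") + lab
            if tag is not None:
                s += f"({tag})"
            parts.append(s)
        return ",".join(parts)

    def __str__(self):  # pragma: no cover - convenience
        return f"{self.name or 'GeneOrder'}[{self.notation()}]"

    # -- core operations ---------------------------------------------------

    def canonicalize(self, start: str = "cox1") -> "GeneOrder":
        """Normal form: rotate (and mirror if needed) so `start` is first, +.

        For partial orders missing cox1 an alternative ``start`` label may
        be supplied (the result is flagged partial).  Idempotent.
        """
        if not self.circular:
            return self
        elems = self.elements
        partial = self.partial
        if start not in [lab for lab, _ in elems]:
            raise GeneOrderError(f"cannot canonicalize: no {start!r} present")
        if start != "cox1":
            partial = True
        idx = next(i for i, (lab, _) in enumerate(elems) if lab == start)
        if elems[idx][1] < 0 and start not in UNSIGNED_LABELS:
            elems = _mirror(elems)
            idx = next(i for i, (lab, _) in enumerate(elems) if lab == start)
        rotated = elems[idx:] + elems[:idx]
        return GeneOrder(rotated, name=self.name, circular=True,
                         partial=partial, metadata=dict(self.metadata))

    def key(self) -> tuple[Element, ...]:
        return self.canonicalize().elements if self.circular else self.elements


def parse_notation(text: str, name: str = "", circular: bool = True) -> GeneOrder:
    """Parse the comma-separated linearized notation (copy tags ignored)."""
    elements: list[Element] = []
    for raw in text.replace("\n", ",").split(","):
        tok = raw.strip()
        if not tok:
            continue
        sign = 1
        if tok.startswith("-"):
            sign = -1
            tok = tok[1:]
        if "(" in tok:
            tok = tok[: tok.index("(")]
        elements.append((tok.strip(), sign))
    return GeneOrder(tuple(elements), name=name, circular=circular)


def orders_equal(a: GeneOrder, b: GeneOrder) -> bool:
    """Equality of canonical element lists (labels + orientations)."""
    if a.circular != b.circular:
        return False
    return a.key() == b.key()


def distinct_orders(orders: list[GeneOrder]):
    """Number of equivalence classes under :func:`orders_equal`.

    Returns ``(count, classes)`` where ``classes`` maps a representative
    name (first member's name or its notation) to the list of members.
    """
    classes: dict[tuple, list[GeneOrder]] = {}
    for o in orders:
        classes.setdefault(o.key(), []).append(o)
    rep_map = {}
    for members in classes.values():
        rep = members[0]
        rep_map[rep.name or rep.canonicalize().notation() if rep.circular else rep.notation()] = members
    return len(classes), rep_map


def extract_gene_order(genome, fallback_start: str = "cox1") -> GeneOrder:
    """Gene order of an annotated genome, canonicalized from cox1.

    ``genome`` is any object with ``identifier`` and a ``features`` list of
    records carrying ``label``, ``strand`` and ``start``.  Partial genomes
    missing cox1 may canonicalize from ``fallback_start`` and are flagged.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    spans = set()
    for f in feats:
        base = (f.label, f.feature_type, f.start, f.end)
        if base in spans:
            raise GeneOrderError(
                f"{genome.identifier}: overlapping identical features {base}")
        spans.add(base)
    elements = tuple((f.label, 1 if f.strand == "H" else -1) for f in feats)
    order = GeneOrder(elements, name=genome.identifier, circular=True)
    labels = [lab for lab, _ in elements]
    start = "cox1" if "cox1" in labels else fallback_start
    return order.canonicalize(start=start)


def region_slice(order: GeneOrder, from_label: str, to_label: str) -> GeneOrder:
    """Contiguous circular slice from `from_label` to `to_label`, inclusive.

    Operates on the canonical form; endpoints are matched by label
    irrespective of orientation (the Trematominae inversion leaves *trnF*
    on the L-strand, but the slice endpoint is still found).
    """
    o = order.canonicalize() if order.circular else order
    labels = o.labels
    if from_label not in labels:
        raise GeneOrderError(f"label {from_label!r} absent from order")
    if to_label not in labels:
        raise GeneOrderError(f"label {to_label!r} absent from order")
    i = labels.index(from_label)
    n = len(labels)
    for k in range(n):
        j = (i + k) % n
        if labels[j] == to_label:
            break
    if j >= i:
        sub = o.elements[i : j + 1]
    else:
        if not order.circular:
            raise GeneOrderError("slice wraps around a linear order")
        sub = o.elements[i:] + o.elements[: j + 1]
    return GeneOrder(sub, name=f"{o.name}[{from_label}..{to_label}]" if o.name else "",
                     circular=False, partial=o.partial)
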