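"""Synthetic mitogenome evolution with planted rearrangements.

The generator emulates the statistical structure the analyses assume:
a ~16.5 kb circular vertebrate-style mitogenome (37 genes + Control
Region + O_L in the typical vertebrate order), strand-asymmetric point
substitution, per-gene purifying selection on protein-coding genes,
scripted rearrangement events on a phylogeny, and decaying pseudogene
remnants left in spacers by duplication-loss events.  Every emitted
genome is accompanied by a machine-readable truth log (planted events,
per-node gene orders, remnant registry) so each pipeline stage can be
tested against known ground truth.

Substitution model.  Sites evolve independently with an HKY-like rate
scheme (transition bias ``kappa``) plus two strand-asymmetry multipliers
for the deamination channels A->G and C->T acting on the strand that is
left single-stranded during replication.  With the standard replication
polarity this enriches the majority-coding sense strand in A and C,
which is exactly the observed positive AT-skew / negative GC-skew at
synonymous third positions; a Control-Region inversion can flip the
polarity (``flip_polarity``) and with it the expected skew signs.
Protein-coding genes accept nonsynonymous changes with per-gene
probability omega (and never accept in-frame stops), which is crude but
sufficient to plant a recoverable Ka/Ks ranking.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from Bio.Seq import Seq

from .fixtures import VERTGO
from .gene_order import GeneOrder
from .genome_io import AnnotatedGenome, FeatureRecord
from .spacers import Spacer
from .vocab import feature_type_of

VERTEBRATE_MITO_TABLE = 2

#: realistic element lengths (bp); protein-coding lengths are multiples
#: of three (ATG ... sense codons ... TAA)
GENE_LENGTHS = {
    "cox1": 1551, "cox2": 690, "cox3": 783, "atp6": 681, "atp8": 165,
    "cob": 1140, "nad1": 972, "nad2": 1044, "nad3": 348, "nad4": 1380,
    "nad4L": 294, "nad5": 1836, "nad6": 522,
    "rrnS": 950, "rrnL": 1680, "CoRe": 900, "OL": 34,
}
TRNA_LENGTH = 70

#: per-gene nonsynonymous acceptance probabilities; the ranking (cox1
#: most constrained; atp8 and nad6 least) mirrors fish mitogenomes
DEFAULT_OMEGA = {
    "cox1": 0.03, "cox2": 0.06, "cox3": 0.06, "cob": 0.07,
    "atp6": 0.09, "nad1": 0.12, "nad2": 0.15, "nad3": 0.15,
    "nad4": 0.15, "nad4L": 0.15, "nad5": 0.15, "nad6": 0.35, "atp8": 0.45,
}


@dataclass
class SimConfig:
    seed: int
    tree: str = "(A:0.05,B:0.05);"
    kappa: float = 4.0
    #: deamination multipliers (A->G, C->T) on the single-stranded strand
    asym_AG: float = 4.0
    asym_CT: float = 4.0
    rate: float = 1.0  # substitutions/site per unit branch length (scaling)
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    #: branch name -> list of event specs (see ``apply_scripted_event``)
    events: dict = field(default_factory=dict)
    remnant_rate_multiplier: float = 3.0
    #: deletion events per site per unit branch length in remnants; strong
    #: (mitogenome compaction removes redundant material quickly)
    remnant_deletion_rate: float = 0.1
    remnant_deletion_mean: float = 6.0
    #: A, C, G, T on the majority-coding sense strand; skewed toward the
    #: uninverted mutational equilibrium (AT-skew > 0, GC-skew < 0)
    base_freqs: tuple = (0.32, 0.27, 0.13, 0.28)
    #: branch length of ancestor burn-in: the root genome is pre-evolved
    #: to the mutational equilibrium of the substitution model, so skew
    #: signs at the tips reflect the process, not the draw of the root
    burn_in: float = 3.0


@dataclass
class Segment:
    label: str
    kind: str  # gene | remnant
    strand: str  # H | L (reference vs complement)
    seq: str  # sense orientation for genes, reference orientation for remnants
    source: str = ""  # donor gene for remnants

    @property
    def reference_seq(self) -> str:
        if self.kind == "gene" and self.strand == "L":
            return str(Seq(self.seq).reverse_complement())
        return self.seq


@dataclass
class TruthLog:
    root_order: GeneOrder
    node_orders: dict = field(default_factory=dict)
    branch_events: dict = field(default_factory=dict)  # node -> [(spec, summary)]
    remnants: dict = field(default_factory=dict)  # genome -> [registry entries]
    polarity: dict = field(default_factory=dict)  # node -> +1 / -1
    composition: dict = field(default_factory=dict)


def _rng(seed: int, *keys) -> np.random.Generator:
    """Named substream: deterministic per (seed, keys)."""
    tags = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


# ---------------------------------------------------------------------------
# ancestor construction
# ---------------------------------------------------------------------------

_SENSE_CODONS = None


def _sense_codons():
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        from Bio.Data import CodonTable
        table = CodonTable.unambiguous_dna_by_id[VERTEBRATE_MITO_TABLE]
        _SENSE_CODONS = sorted(table.forward_table)
    return _SENSE_CODONS


def simulate_ancestor(config: SimConfig) -> tuple[list[Segment], AnnotatedGenome]:
    """A VertGO genome with realistic element lengths and valid ORFs."""
    rng = _rng(config.seed, "ancestor")
    freqs = np.array(config.base_freqs)
    segments = []
    for label, sign in VERTGO.elements:
        ftype = feature_type_of(label)
        strand = "H" if sign > 0 else "L"
        if ftype == "PCG":
            n_codons = GENE_LENGTHS[label] // 3
            codons = _sense_codons()
            weights = np.array([np.prod([freqs["ACGT".index(b)] for b in c])
                                for c in codons])
            weights /= weights.sum()
            body = rng.choice(codons, size=n_codons - 2, p=weights)
            seq = "ATG" + "".join(body) + "TAA"
        else:
            length = GENE_LENGTHS.get(label, TRNA_LENGTH)
            seq = "".join(rng.choice(list("ACGT"), size=length, p=freqs))
        segments.append(Segment(label=label, kind="gene", strand=strand, seq=seq))
    if config.burn_in > 0:
        for seg in segments:
            srng = _rng(config.seed, "burnin", seg.label)
            om = config.omega.get(seg.label) \
                if feature_type_of(seg.label) == "PCG" else None
            seg.seq = mutate_sequence(seg.seq, config.burn_in, config, srng,
                                      deaminated_sense=(seg.strand == "L"),
                                      omega=om)
    genome = emit_genome(segments, identifier="ancestor")
    return segments, genome


def emit_genome(segments: list[Segment], identifier: str) -> AnnotatedGenome:
    """Concatenate segments into an annotated genome (remnants = spacers)."""
    seq_parts = []
    features = []
    pos = 0
    for seg in segments:
        ref = seg.reference_seq
        if seg.kind == "gene" and ref:
            features.append(FeatureRecord(
                label=seg.label, strand=seg.strand, start=pos,
                end=pos + len(ref), feature_type=feature_type_of(seg.label)))
        if ref:
            seq_parts.append(ref)
            pos += len(ref)
    return AnnotatedGenome(identifier=identifier, sequence="".join(seq_parts),
                           features=features)


def segments_order(segments: list[Segment], name: str = "") -> GeneOrder:
    elements = tuple((s.label, 1 if s.strand == "H" else -1)
                     for s in segments if s.kind == "gene")
    return GeneOrder(elements, name=name, circular=True).canonicalize()


# ---------------------------------------------------------------------------
# substitution
# ---------------------------------------------------------------------------

def _rate_weights(kappa: float, mult_AG: float, mult_CT: float) -> dict:
    """base -> (targets, weights); transitions get kappa, deamination extra."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    out = {}
    for b in "ACGT":
        targets = [x for x in "ACGT" if x != b]
        w = []
        for x in targets:
            r = kappa if (b, x) in transitions else 1.0
            if (b, x) == ("A", "G"):
                r *= mult_AG
            elif (b, x) == ("C", "T"):
                r *= mult_CT
            w.append(r)
        out[b] = (targets, np.array(w))
    return out


def mutate_sequence(seq: str, bl: float, config: SimConfig,
                    rng: np.random.Generator, deaminated_sense: bool,
                    omega: float | None = None) -> str:
    """Evolve one sense-strand sequence along a branch of length ``bl``.

    ``deaminated_sense`` says whether the deamination channels act on this
    sequence's own strand (True) or on its complement (False; the
    multipliers then apply to T->C and G->A as seen from this strand).
    ``omega`` activates codon-level accept/reject for coding sequences.
    """
    if not seq or bl <= 0:
        return seq
    # long branches are split into rounds so sites can substitute
    # repeatedly and composition can approach the mutational equilibrium
    if bl * config.rate > 0.5:
        rounds = int(np.ceil(bl * config.rate / 0.5))
        for _ in range(rounds):
            seq = mutate_sequence(seq, bl / rounds, config, rng,
                                  deaminated_sense, omega)
        return seq
    if deaminated_sense:
        weights = _rate_weights(config.kappa, config.asym_AG, config.asym_CT)
    else:
        base = _rate_weights(config.kappa, 1.0, 1.0)
        weights = {}
        for b, (targets, w) in base.items():
            w = w.copy()
            for i, x in enumerate(targets):
                if (b, x) == ("T", "C"):
                    w[i] *= config.asym_CT
                elif (b, x) == ("G", "A"):
                    w[i] *= config.asym_AG
            weights[b] = (targets, w)
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1").copy()
    total = {b: weights[b][1].sum() for b in "ACGT"}
    mean_rate = np.mean([total[b] for b in "ACGT"])
    p = np.array([total.get(b, 0.0) / mean_rate for b in arr]) * bl * config.rate
    p = np.clip(p, 0, 0.95)
    hit = rng.random(len(arr)) < p
    idxs = np.nonzero(hit)[0]
    if omega is None:
        for i in idxs:
            b = arr[i]
            if b not in "ACGT":
                continue
            targets, w = weights[b]
            arr[i] = rng.choice(targets, p=w / w.sum())
        return "".join(arr)
    # codon-aware path for protein-coding genes
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_dna_by_id[VERTEBRATE_MITO_TABLE]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    s = list(seq)
    for i in idxs:
        b = s[i]
        if b not in "ACGT":
            continue
        targets, w = weights[b]
        new = rng.choice(targets, p=w / w.sum())
        ci = i - i % 3
        old_codon = "".join(s[ci:ci + 3])
        if len(old_codon) < 3:
            continue
        new_codon = old_codon[: i % 3] + new + old_codon[i % 3 + 1:]
        if aa.get(new_codon, "*") == "*":
            continue  # never accept stops
        if aa[new_codon] != aa.get(old_codon):
            if rng.random() >= omega:
                continue
        s[i] = new
    return "".join(s)


def decay_remnant(seq: str, bl: float, config: SimConfig,
                  rng: np.random.Generator) -> str:
    """Neutral decay of a pseudogene remnant: fast substitution + deletions."""
    if not seq or bl <= 0:
        return seq
    boosted = replace(config, rate=config.rate * config.remnant_rate_multiplier)
    seq = mutate_sequence(seq, bl, boosted, rng, deaminated_sense=False)
    n_del = rng.poisson(config.remnant_deletion_rate * bl * len(seq))
    for _ in range(n_del):
        if len(seq) <= 1:
            break
        size = min(len(seq) - 1, 1 + rng.geometric(1.0 / config.remnant_deletion_mean))
        start = rng.integers(0, len(seq) - size + 1)
        seq = seq[:start] + seq[start + size:]
    return seq


# ---------------------------------------------------------------------------
# scripted events on the segment list
# ---------------------------------------------------------------------------

class EventScriptError(ValueError):
    pass


def _span_indices(segments, from_label, to_label):
    genes = [i for i, s in enumerate(segments)]
    starts = [i for i, s in enumerate(segments)
              if s.kind == "gene" and s.label == from_label]
    if not starts:
        raise EventScriptError(f"label {from_label!r} absent")
    i = starts[0]
    for j in range(i, len(segments)):
        if segments[j].kind == "gene" and segments[j].label == to_label:
            return i, j + 1
    raise EventScriptError(f"label {to_label!r} not found after {from_label!r}")


def _keep_run(copy: list[Segment], spec):
    """Kept segments of one tandem copy; spec: 'all', (), or (from, to)."""
    if spec == "all":
        return list(range(len(copy)))
    if not spec:
        return []
    frm, to = spec
    idx = [k for k, s in enumerate(copy) if s.kind == "gene"]
    start = next(k for k in idx if copy[k].label == frm)
    end = next(k for k in idx if k >= start and copy[k].label == to)
    return list(range(start, end + 1))


def _drop_to_remnants(copy, kept, make_remnants):
    """Replace dropped runs of a copy by remnant segments."""
    out = []
    run = []

    def flush():
        if run and make_remnants:
            seq = "".join(s.reference_seq for s in run)
            src = "+".join(s.label for s in run if s.kind == "gene")
            out.append(Segment(label=f"psi_{src}", kind="remnant", strand="H",
                               seq=seq, source=src))
        run.clear()

    for k, seg in enumerate(copy):
        if k in kept:
            flush()
            out.append(seg)
        else:
            run.append(seg)
    flush()
    return out


def apply_scripted_event(segments: list[Segment], spec: dict) -> list[Segment]:
    """Apply one scripted rearrangement to the segment list.

    Spec forms (labels refer to the current arrangement):

    * ``{"kind": "tdrl", "segment": (from, to), "keep1": run, "keep2": run,
      "remnants": True}`` -- tandem duplication; each ``run`` is ``"all"``,
      ``()`` or a ``(from, to)`` label pair; dropped material becomes
      decaying remnants when ``remnants`` is set.
    * ``{"kind": "loss", "segment": (from, to), "remnants": bool}``
    * ``{"kind": "PRL", "drop": [(label, occurrence), ...], "remnants": bool}``
    * ``{"kind": "inversion", "segment": (from, to), "flip_polarity": bool}``
    * ``{"kind": "transposition", "segment": (from, to), "before": label}``
    """
    kind = spec["kind"]
    make_remnants = bool(spec.get("remnants", True))
    segs = list(segments)
    if kind == "tdrl":
        i, j = _span_indices(segs, *spec["segment"])
        block = segs[i:j]
        copy1 = [replace(s) for s in block]
        copy2 = [replace(s) for s in block]
        kept1 = _keep_run(copy1, spec.get("keep1", "all"))
        kept2 = _keep_run(copy2, spec.get("keep2", "all"))
        mid = (_drop_to_remnants(copy1, kept1, make_remnants)
               + _drop_to_remnants(copy2, kept2, make_remnants))
        return segs[:i] + mid + segs[j:]
    if kind == "loss":
        i, j = _span_indices(segs, *spec["segment"])
        dropped = _drop_to_remnants(segs[i:j], [], make_remnants)
        return segs[:i] + dropped + segs[j:]
    if kind == "PRL":
        drops = set()
        for label, occ in spec["drop"]:
            hits = [k for k, s in enumerate(segs)
                    if s.kind == "gene" and s.label == label]
            if occ >= len(hits):
                raise EventScriptError(f"no occurrence {occ} of {label}")
            drops.add(hits[occ])
        out = []
        for k, seg in enumerate(segs):
            if k in drops:
                rem = _drop_to_remnants([seg], [], make_remnants)
                out.extend(rem)
            else:
                out.append(seg)
        return out
    if kind == "inversion":
        i, j = _span_indices(segs, *spec["segment"])
        block = []
        for s in reversed(segs[i:j]):
            s = replace(s)
            if s.kind == "gene":
                s.strand = "L" if s.strand == "H" else "H"
            else:
                s.seq = str(Seq(s.seq).reverse_complement())
            block.append(s)
        return segs[:i] + block + segs[j:]
    if kind == "transposition":
        i, j = _span_indices(segs, *spec["segment"])
        block = segs[i:j]
        rest = segs[:i] + segs[j:]
        before = spec["before"]
        k = next(k for k, s in enumerate(rest)
                 if s.kind == "gene" and s.label == before)
        return rest[:k] + block + rest[k:]
    raise EventScriptError(f"unknown scripted event kind {kind!r}")


def event_summary(spec: dict, before: list[Segment]) -> dict:
    """Truth-log record of a scripted event: mechanism + affected labels."""
    kind = spec["kind"]
    if "segment" in spec:
        i, j = _span_indices(list(before), *spec["segment"])
        labels = tuple(s.label for s in before[i:j] if s.kind == "gene")
    else:
        labels = tuple(lab for lab, _ in spec.get("drop", ()))
    display = {"tdrl": "TD-PRL", "loss": "loss", "PRL": "PRL",
               "inversion": "I", "transposition": "t"}[kind]
    if kind == "tdrl" and spec.get("keep1") == "all" and spec.get("keep2") == "all":
        display = "TD"
    return {"kind": display, "labels": labels}


# ---------------------------------------------------------------------------
# evolution along a tree
# ---------------------------------------------------------------------------

def evolve_on_tree(config: SimConfig):
    """Evolve a VertGO ancestor along the configured tree.

    Returns ``(tip_genomes, truth_log)``.  Scripted events are keyed by
    the child-node name: a tip label, or for internal branches the name
    ``mrca(tipA,tipB,...)`` with the alphabetically sorted leaf labels.
    """
    tree = dendropy.Tree.get(data=config.tree, schema="newick",
                             preserve_underscores=True)
    root_segments, root_genome = simulate_ancestor(config)
    log = TruthLog(root_order=segments_order(root_segments, "root"))
    log.node_orders["root"] = log.root_order
    log.polarity["root"] = 1
    tips: dict[str, AnnotatedGenome] = {}
    pending_events = dict(config.events)

    def node_name(node):
        if node.taxon is not None:
            return node.taxon.label
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return f"mrca({','.join(leaves)})"

    def descend(node, segments, polarity):
        for child in node.child_nodes():
            name = node_name(child)
            bl = child.edge.length or 0.0
            rng = _rng(config.seed, "branch", name)
            segs = []
            for si, seg in enumerate(list(segments)):
                seg = replace(seg)
                srng = _rng(config.seed, "branch", name, "seg", si, seg.label)
                if seg.kind == "remnant":
                    seg.seq = decay_remnant(seg.seq, bl, config, srng)
                else:
                    deaminated = (seg.strand == ("L" if polarity > 0 else "H"))
                    om = config.omega.get(seg.label) \
                        if feature_type_of(seg.label) == "PCG" else None
                    seg.seq = mutate_sequence(seg.seq, bl, config, srng,
                                              deaminated_sense=deaminated,
                                              omega=om)
                segs.append(seg)
            pol = polarity
            events = pending_events.pop(name, [])
            recorded = []
            for spec in events:
                recorded.append(event_summary(spec, segs))
                segs = apply_scripted_event(segs, spec)
                if spec.get("flip_polarity"):
                    pol = -pol
            log.branch_events[name] = recorded
            log.node_orders[name] = segments_order(segs, name)
            log.polarity[name] = pol
            if child.is_leaf():
                genome = emit_genome(segs, identifier=name)
                tips[name] = genome
                log.remnants[name] = [
                    {"source": s.source, "length": len(s.seq)}
                    for s in segs if s.kind == "remnant" and s.seq]
                log.composition[name] = {
                    s.label: {b: s.seq.count(b) for b in "ACGT"}
                    for s in segs if s.kind == "gene"}
            else:
                descend(child, segs, pol)

    descend(tree.seed_node, root_segments, 1)
    if pending_events:
        raise EventScriptError(
            f"event script references absent branches: {sorted(pending_events)}")
    return tips, log


# ---------------------------------------------------------------------------
# null spacers
# ---------------------------------------------------------------------------

def make_null_spacers(n: int, length: int, seed: int,
                      composition=(0.25, 0.25, 0.25, 0.25)) -> list[Spacer]:
    """i.i.d. random spacers for scanner false-positive calibration."""
    rng = _rng(seed, "null_spacers")
    freqs = np.array(composition, dtype=float)
    freqs = freqs / freqs.sum()
    out = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGT"), size=length, p=freqs))
        out.append(Spacer(genome_id=f"null{i}", flank_upstream="x",
                          flank_downstream="y", start=0, end=length,
                          sequence=seq))
    return out
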