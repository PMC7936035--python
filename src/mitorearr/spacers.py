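"""Intergenic-spacer extraction and gene-remnant scanning.

Mitochondrial intergenic spacers come in two flavors: standard spacers
(STD-ISP), short slippage products with no recognizable ancestry, and
rearrangement-linked spacers (GR-ISP), which are decaying relicts of
genes duplicated and lost during a gene-order rearrangement.  A spacer is
classified GR-ISP when a Smith-Waterman local alignment against the
genome's own genes (both strands, Control Region included) produces a hit
passing the detection thresholds; for protein-coding targets the remnant
can additionally be translated in the donor gene's frame and compared
with the protein (the classic check being a spacer that still encodes the
C-terminus of apocytochrome b).

Default thresholds (alignment >= 15 nt with >= 70% identity, or an exact
match >= 12 nt) are calibrated against i.i.d. random spacers so that
length-matched nulls score a hit in < 1% of trials; they are exposed as
configuration, since no universal cutoff exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

VERTEBRATE_MITO_TABLE = 2


@dataclass(frozen=True)
class ScanThresholds:
    """Hit acceptance: (score AND length AND identity) OR long exact match.

    Calibrated on i.i.d. null spacers against a whole-mitogenome gene
    library (~33 kb over both strands): with the BLASTN-like scoring
    below, chance local alignments reach scores near
    ln(K*m*n)/lambda ~ 20, so ``min_score`` = 30 keeps the false-positive
    rate under 1% while a 20 nt remnant with 10% divergence (score >= 30)
    is still accepted.  A perfect 15-mer (expected < 0.01 by chance per
    spacer) passes unconditionally.
    """

    min_score: float = 30.0
    min_length: int = 15
    min_identity: float = 70.0  # percent
    exact_min: int = 15
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


@dataclass
class Spacer:
    genome_id: str
    flank_upstream: str
    flank_downstream: str
    start: int
    end: int  # may exceed genome length for origin-spanning spacers
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SpacerHit:
    spacer: Spacer
    target_gene: str
    strand: str  # H: matches the gene's coding sense; L: reverse complement
    score: float
    alignment_length: int
    identity: float  # percent
    longest_exact: int
    spacer_span: tuple[int, int]
    target_span: tuple[int, int]
    target_region: str  # 5'-terminal | 3'-terminal | internal | full
    peptide_match: dict | None = None


@dataclass
class SpacerClassification:
    spacer: Spacer
    spacer_class: str  # STD_ISP | GR_ISP
    hits: list = field(default_factory=list)
    corroborates: list = field(default_factory=list)


def extract_spacers(genome, min_length: int = 10) -> list[Spacer]:
    """All inter-feature gaps of at least ``min_length`` nt.

    The gap between the last and first feature wraps around the origin.
    Overlapping features produce no spacer.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    if not feats:
        return []
    from .genome_io import _copy_tags

    tags = _copy_tags(feats)
    names = [f.label + (f"_{t}" if t else "") for f, t in zip(feats, tags)]
    L = genome.length
    out = []
    for i, feat in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        start = feat.end % L if feat.end >= L else feat.end
        if i + 1 < len(feats):
            gap = nxt.start - feat.end
            end = nxt.start
        else:
            gap = (nxt.start + L) - feat.end
            end = feat.end + gap
        if gap < min_length:
            continue
        if end <= L:
            seq = genome.sequence[start:end]
        else:
            seq = genome.sequence[start:] + genome.sequence[: end % L]
        out.append(Spacer(genome_id=genome.identifier,
                          flank_upstream=names[i],
                          flank_downstream=names[(i + 1) % len(feats)],
                          start=start, end=end, sequence=seq))
    return out


def _aligner(t: ScanThresholds) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.match_score = t.match
    al.mismatch_score = t.mismatch
    al.open_gap_score = t.gap_open
    al.extend_gap_score = t.gap_extend
    return al


def _align_stats(alignment):
    """(aligned columns, matches, longest exact run, query span, target span)."""
    q, t = alignment.sequences
    blocks_q, blocks_t = alignment.aligned
    cols = matches = longest = 0
    first_q = last_q = first_t = last_t = None
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        run = 0
        for k in range(qe - qs):
            cols += 1
            if q[qs + k] == t[ts + k]:
                matches += 1
                run += 1
                longest = max(longest, run)
            else:
                run = 0
        if first_q is None:
            first_q, first_t = qs, ts
        last_q, last_t = qe, te
    # count gap columns between blocks
    for i in range(1, len(blocks_q)):
        cols += (blocks_q[i][0] - blocks_q[i - 1][1])
        cols += (blocks_t[i][0] - blocks_t[i - 1][1])
    return cols, matches, longest, (int(first_q), int(last_q)), (int(first_t), int(last_t))


def _region(span: tuple[int, int], gene_len: int, margin: int = 6) -> str:
    s, e = span
    if s <= margin and e >= gene_len - margin:
        return "full"
    if e >= gene_len - margin:
        return "3'-terminal"
    if s <= margin:
        return "5'-terminal"
    return "internal"


def scan_spacer(spacer: Spacer, gene_library: dict[str, str],
                thresholds: ScanThresholds | None = None) -> list[SpacerHit]:
    """Local-align a spacer against every gene (both strands) of a library.

    ``gene_library`` maps gene names to coding-sense sequences.  Hits
    passing the thresholds are returned sorted by score (descending), ties
    broken by gene name.
    """
    if not gene_library:
        raise ValueError("empty gene library")
    t = thresholds or ScanThresholds()
    al = _aligner(t)
    hits = []
    for gene, gseq in sorted(gene_library.items()):
        for strand, target in (("H", gseq),
                               ("L", str(Seq(gseq).reverse_complement()))):
            if not spacer.sequence or not target:
                continue
            try:
                best = al.align(spacer.sequence, target)[0]
            except (IndexError, ValueError):
                continue
            cols, matches, longest, qspan, tspan = _align_stats(best)
            if cols == 0:
                continue
            identity = 100.0 * matches / cols
            if not ((best.score >= t.min_score and cols >= t.min_length
                     and identity >= t.min_identity)
                    or longest >= t.exact_min):
                continue
            if strand == "L":
                # report the span on the coding-sense coordinates
                glen = len(gseq)
                tspan = (glen - tspan[1], glen - tspan[0])
            hits.append(SpacerHit(
                spacer=spacer, target_gene=gene, strand=strand,
                score=float(best.score), alignment_length=cols,
                identity=identity, longest_exact=longest,
                spacer_span=qspan, target_span=tspan,
                target_region=_region(tspan, len(gseq))))
    hits.sort(key=lambda h: (-h.score, h.target_gene, h.strand))
    return hits


def peptide_check(hit: SpacerHit, protein: str | None = None,
                  gene_sequence: str | None = None) -> dict | None:
    """Translate a remnant in its donor gene's frame and compare proteins.

    Returns a dict with the translated remnant peptide, the corresponding
    protein segment and the longest identical amino-acid run, or None for
    non-coding targets.  ``protein`` defaults to the translation of
    ``gene_sequence``.
    """
    if gene_sequence is None:
        return None
    if protein is None:
        trimmed = gene_sequence[: len(gene_sequence) - len(gene_sequence) % 3]
        protein = str(Seq(trimmed).translate(table=VERTEBRATE_MITO_TABLE)).rstrip("*")
    ts, te = hit.target_span
    qs, qe = hit.spacer_span
    segment = hit.spacer.sequence[qs:qe]
    if hit.strand == "L":
        segment = str(Seq(segment).reverse_complement())
    # advance to the donor gene's codon frame
    shift = (-ts) % 3
    ts += shift
    segment = segment[shift:]
    length = min(te - ts, len(segment))
    length -= length % 3
    if length < 3:
        return {"identical_run": 0, "remnant_peptide": "", "protein_segment": ""}
    segment = segment[:length]
    pep = str(Seq(segment).translate(table=VERTEBRATE_MITO_TABLE))
    prot_seg = protein[ts // 3: ts // 3 + len(pep)]
    run = best = 0
    for x, y in zip(pep, prot_seg):
        run = run + 1 if x == y else 0
        best = max(best, run)
    return {"identical_run": best, "remnant_peptide": pep,
            "protein_segment": prot_seg}


def classify_spacers(genomes, thresholds: ScanThresholds | None = None,
                     min_length: int = 10, event_losses=None):
    """Per-spacer STD-ISP / GR-ISP classification over a genome set.

    ``event_losses`` optionally maps genome id to a set of (gene label,
    flank pair) records of duplicated-and-lost elements from reconstructed
    rearrangement pathways; a GR-ISP corroborates a pathway when its best
    remnant matches a gene the pathway lost near that position.
    """
    out = []
    for genome in genomes:
        library = genome.gene_sequences(include_control_region=True)
        for spacer in extract_spacers(genome, min_length=min_length):
            hits = scan_spacer(spacer, library, thresholds)
            cls = "GR_ISP" if hits else "STD_ISP"
            corroborates = []
            if hits and event_losses:
                lost = event_losses.get(genome.identifier, set())
                for h in hits:
                    base = h.target_gene.split("_")[0]
                    if base in lost:
                        corroborates.append(base)
            out.append(SpacerClassification(
                spacer=spacer, spacer_class=cls, hits=hits,
                corroborates=sorted(set(corroborates))))
    return out
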