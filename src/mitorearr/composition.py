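"""Strand compositional-bias statistics for mitogenomes.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C) quantify the
asymmetric base composition that the strand-displacement replication of
the mitogenome imprints: hydrolytic deamination on the transiently
single-stranded H-strand (A->G and C->T) makes the H-strand GT-rich and
the L-strand AC-rich.  The least-constrained view of this mutation
pressure is obtained from the synonymous third positions of two-fold
(NNR2 + NNY2) and four-fold (NNN4) degenerate codons: their composition
is shaped by mutation alone, so a Control-Region inversion that flips the
replication polarity is expected to flip the skew signs at these sites.

Strand symmetry (P(A) = P(T), P(G) = P(C) among pooled synonymous third
positions) is tested with a two-sided binomial normal approximation,
z = (nA - nT)/sqrt(nA + nT); a *full* reversal of the compositional bias
is called only when the skew signs oppose the uninverted expectation AND
strand symmetry is rejected at alpha for both base pairs, in both
degeneracy classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from Bio.Data import CodonTable

VERTEBRATE_MITO_TABLE = 2
BASES = "ACGT"


@dataclass
class SkewReport:
    unit: str
    nA: int
    nC: int
    nG: int
    nT: int
    AT_skew: float | None = field(init=False)
    GC_skew: float | None = field(init=False)

    def __post_init__(self):
        at, gc = self.nA + self.nT, self.nG + self.nC
        self.AT_skew = (self.nA - self.nT) / at if at else None
        self.GC_skew = (self.nG - self.nC) / gc if gc else None


def skew(sequence: str, unit: str = "sequence") -> SkewReport:
    """Base counts and skews of a sequence; non-ACGT symbols are ignored."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return SkewReport(unit=unit, nA=s.count("A"), nC=s.count("C"),
                      nG=s.count("G"), nT=s.count("T"))


PARTITIONS = ("full", "pos1", "pos2", "pos3", "rRNA", "genome")


def per_gene_skew_table(genomes, partitions=("full", "pos1", "pos2", "pos3",
                                             "rRNA", "genome")) -> pd.DataFrame:
    """Skew table: one row per genome x unit x partition.

    Codon-position partitions apply to protein-coding genes (sequences in
    mRNA sense, frame starting at 0); ``rRNA`` rows cover the two
    ribosomal genes and ``genome`` the whole deposited (H) strand.
    """
    rows = []
    for g in genomes:
        for feat in g.features:
            seq = g.feature_sequence(feat)
            if feat.feature_type == "PCG":
                if "full" in partitions:
                    rows.append(_row(g.identifier, feat.label, "full", seq))
                for p in (1, 2, 3):
                    name = f"pos{p}"
                    if name in partitions:
                        rows.append(_row(g.identifier, feat.label, name,
                                         seq[p - 1::3]))
            elif feat.feature_type == "rRNA" and "rRNA" in partitions:
                rows.append(_row(g.identifier, feat.label, "rRNA", seq))
        if "genome" in partitions:
            rows.append(_row(g.identifier, "genome", "genome", g.sequence))
    return pd.DataFrame(rows)


def _row(genome_id, unit, partition, seq):
    r = skew(seq, unit=unit)
    return {"genome": genome_id, "unit": unit, "partition": partition,
            "nA": r.nA, "nC": r.nC, "nG": r.nG, "nT": r.nT,
            "AT_skew": r.AT_skew, "GC_skew": r.GC_skew}


# ---------------------------------------------------------------------------
# codon degeneracy under the vertebrate mitochondrial code
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _code(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


def classify_codon_degeneracy(codon: str, table_id: int = VERTEBRATE_MITO_TABLE) -> str:
    """NNN4 / NNR2 / NNY2 / other for a codon's third position.

    NNN4: all four third-position variants are synonymous; NNR2 / NNY2:
    exactly the purine / pyrimidine pair is synonymous.  Stop codons and
    codons containing ambiguous bases are ``other``.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return "other"
    aa = _code(table_id)
    if aa[codon] == "*":
        return "other"
    family = {b: aa[codon[:2] + b] for b in BASES}
    if len(set(family.values())) == 1:
        return "NNN4"
    mine = aa[codon]
    purines, pyrimidines = ("A", "G"), ("C", "T")
    if codon[2] in purines:
        if (family["A"] == family["G"] == mine
                and mine not in (family["C"], family["T"])):
            return "NNR2"
    else:
        if (family["C"] == family["T"] == mine
                and mine not in (family["A"], family["G"])):
            return "NNY2"
    return "other"


@dataclass
class DegenerateSiteSet:
    site_class: str  # NNN4 | NNR2_NNY2
    counts: dict  # base -> pooled third-position count
    n_codons: int
    excluded_genes: list = field(default_factory=list)


def extract_degenerate_sets(gene_sequences: dict[str, str],
                            exclude: tuple[str, ...] = (),
                            table_id: int = VERTEBRATE_MITO_TABLE):
    """Pooled third-position counts of degenerate codons across PCGs.

    ``gene_sequences`` maps gene label to its in-frame coding sequence
    (mRNA sense).  Genes in ``exclude`` (e.g. a gene translocated to the
    opposite strand, whose sites would mix the two mutational regimes)
    are skipped.  Returns ``(NNN4 set, NNR2+NNY2 set)``.
    """
    pools = {"NNN4": {b: 0 for b in BASES}, "NNR2_NNY2": {b: 0 for b in BASES}}
    ncod = {"NNN4": 0, "NNR2_NNY2": 0}
    excluded = [g for g in gene_sequences if g in exclude]
    for gene, seq in gene_sequences.items():
        if gene in exclude:
            continue
        seq = seq.upper()
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i:i + 3]
            cls = classify_codon_degeneracy(codon, table_id)
            if cls == "NNN4":
                pools["NNN4"][codon[2]] += 1
                ncod["NNN4"] += 1
            elif cls in ("NNR2", "NNY2"):
                pools["NNR2_NNY2"][codon[2]] += 1
                ncod["NNR2_NNY2"] += 1
    return (DegenerateSiteSet("NNN4", pools["NNN4"], ncod["NNN4"], excluded),
            DegenerateSiteSet("NNR2_NNY2", pools["NNR2_NNY2"],
                              ncod["NNR2_NNY2"], excluded))


# ---------------------------------------------------------------------------
# strand symmetry and reversal decision
# ---------------------------------------------------------------------------

@dataclass
class SymmetryTestResult:
    comparison: str  # A_vs_T | G_vs_C
    statistic: float
    p_value: float
    rejected: bool
    skew_sign: int  # sign of the corresponding skew
    low_power: bool = False

    @property
    def rejected_at_0_05(self) -> bool:  # pragma: no cover - alias
        return self.rejected


def strand_symmetry_test(siteset: DegenerateSiteSet, alpha: float = 0.05,
                         min_sites: int = 10):
    """Two-sided tests of P(A)=P(T) and P(G)=P(C) among pooled sites.

    Normal approximation to the symmetric binomial:
    z = (nA - nT) / sqrt(nA + nT), p = 2 * (1 - Phi(|z|)).
    """
    out = []
    c = siteset.counts
    for comparison, x, y in (("A_vs_T", c["A"], c["T"]),
                             ("G_vs_C", c["G"], c["C"])):
        n = x + y
        if n == 0:
            raise ValueError(f"no sites for {comparison}")
        z = (x - y) / np.sqrt(n)
        p = 2 * stats.norm.sf(abs(z))
        out.append(SymmetryTestResult(
            comparison=comparison, statistic=float(z), p_value=float(p),
            rejected=bool(p < alpha), skew_sign=int(np.sign(x - y)),
            low_power=n < min_sites))
    return tuple(out)


def compare_skew_groups(group_a, group_b):
    """Two-sample Student's t (pooled variance) on absolute skew values.

    Returns ``(t, p)``; degenerate zero-variance equal-mean input gives
    p = 1.
    """
    a = np.abs(np.asarray(group_a, dtype=float))
    b = np.abs(np.asarray(group_b, dtype=float))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class ReversalDecision:
    genome_id: str
    decision: str  # none | partial | full
    sign_opposed: dict  # site class -> bool (both skews opposite to expected)
    symmetry_rejected: dict  # site class -> bool (both pairs rejected)
    tests: dict


#: expected skew signs at synonymous third positions of H-strand genes in
#: an uninverted vertebrate mitogenome: AT-skew positive, GC-skew negative
EXPECTED_SIGNS = {"AT": 1, "GC": -1}


def decide_reversal(genome_id: str, nnn4: DegenerateSiteSet,
                    nn2: DegenerateSiteSet, alpha: float = 0.05,
                    expected_signs=None) -> ReversalDecision:
    """Full / partial / none decision on strand compositional reversal.

    *full* requires, for both the NNN4 and the NNR2+NNY2 pools: (1) AT-
    and GC-skew signs opposite to the uninverted expectation, and (2)
    strand symmetry rejected at ``alpha`` for both A-vs-T and G-vs-C.
    Any proper subset of those four criteria gives *partial*.
    """
    expected = expected_signs or EXPECTED_SIGNS
    sign_opposed, rejected, tests = {}, {}, {}
    any_opposition = False
    for siteset in (nnn4, nn2):
        cls = siteset.site_class
        at, gc = strand_symmetry_test(siteset, alpha=alpha)
        tests[cls] = {"A_vs_T": at, "G_vs_C": gc}
        opp_at = at.skew_sign != 0 and at.skew_sign == -expected["AT"]
        opp_gc = gc.skew_sign != 0 and gc.skew_sign == -expected["GC"]
        any_opposition = any_opposition or opp_at or opp_gc
        sign_opposed[cls] = bool(opp_at and opp_gc)
        rejected[cls] = bool(at.rejected and gc.rejected)
    # symmetry rejection with skews in the *expected* orientation is the
    # ordinary strand bias; only sign opposition signals a reversal
    if all(sign_opposed[c] and rejected[c] for c in sign_opposed):
        decision = "full"
    elif any_opposition:
        decision = "partial"
    else:
        decision = "none"
    return ReversalDecision(genome_id=genome_id, decision=decision,
                            sign_opposed=sign_opposed,
                            symmetry_rejected=rejected, tests=tests)
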