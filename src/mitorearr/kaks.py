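"""Pairwise Ka/Ks (Nei-Gojobori 1986) for mitochondrial protein-coding genes.

Ka is the number of nonsynonymous substitutions per nonsynonymous site and
Ks the number of synonymous substitutions per synonymous site; Ka/Ks < 1
indicates purifying selection.  Counting follows NG86: synonymous site
fractions are computed per codon position from the genetic code
(vertebrate mitochondrial, translation table 2, by default), observed
differences between a codon pair are averaged over all shortest
substitution paths with equal weights, and the proportions are corrected
for multiple hits with the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3).
Changes to or through stop codons are excluded.

Distribution summaries group the 13 PCGs by OXPHOS complex
(I: nad1-6, nad4L; III: cob; IV: cox1-3; V: atp6, atp8).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

VERTEBRATE_MITO_TABLE = 2
BASES = "ACGT"

GENE_COMPLEX = {
    "nad1": "I", "nad2": "I", "nad3": "I", "nad4": "I", "nad4L": "I",
    "nad5": "I", "nad6": "I",
    "cob": "III",
    "cox1": "IV", "cox2": "IV", "cox3": "IV",
    "atp6": "V", "atp8": "V",
}
COMPLEX_ORDER = ("I", "III", "IV", "V")


class KaKsError(ValueError):
    pass


@dataclass
class KaKsResult:
    gene: str
    pair: tuple[str, str]
    Ka: float | None
    Ks: float | None
    ratio: float | None
    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    saturated: bool = False


@lru_cache(maxsize=4)
def _aa_table(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


@lru_cache(maxsize=None)
def _codon_sites(codon: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon (NG86).

    Each position contributes one site, split by the fraction of possible
    single-base changes that are synonymous; changes to stop codons are
    excluded from the possibilities.
    """
    aa = _aa_table(table_id)
    if aa[codon] == "*":
        raise KaKsError(f"stop codon {codon} in frame")
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if aa[alt] == "*":
                continue
            valid += 1
            if aa[alt] == aa[codon]:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_diffs(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over shortest paths."""
    aa = _aa_table(table_id)
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in perm:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if aa[nxt] == "*":
                ok = False
                break
            if aa[nxt] == aa[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        # every path passes through a stop; count all changes nonsynonymous
        return 0.0, float(len(positions))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jc(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4.0 * p / 3.0)


def pairwise_kaks(seq_a: str, seq_b: str, gene: str = "",
                  pair: tuple[str, str] = ("a", "b"),
                  table_id: int = VERTEBRATE_MITO_TABLE) -> KaKsResult:
    """NG86 Ka and Ks for two aligned in-frame coding sequences.

    Codons containing gaps, ambiguity symbols or in-frame stops (terminal
    stops included) are dropped pairwise.
    """
    if len(seq_a) != len(seq_b):
        raise KaKsError("sequences differ in length")
    if len(seq_a) % 3:
        raise KaKsError("alignment length is not a multiple of 3")
    aa = _aa_table(table_id)
    a, b = seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        c1, c2 = a[i:i + 3], b[i:i + 3]
        if any(x not in BASES for x in c1 + c2):
            continue
        if aa[c1] == "*" or aa[c2] == "*":
            continue
        s1, n1 = _codon_sites(c1, table_id)
        s2, n2 = _codon_sites(c2, table_id)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _codon_diffs(c1, c2, table_id)
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons == 0:
        raise KaKsError("no comparable codons")
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    Ks, Ka = _jc(pS), _jc(pN)
    saturated = Ks is None or Ka is None
    ratio = None
    if not saturated and Ks is not None and Ks > 0 and Ka is not None:
        ratio = Ka / Ks
    return KaKsResult(gene=gene, pair=pair, Ka=Ka, Ks=Ks, ratio=ratio,
                      S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_codons,
                      saturated=saturated)


def all_pairs_kaks(alignment: dict[str, str], gene: str = "",
                   table_id: int = VERTEBRATE_MITO_TABLE) -> list[KaKsResult]:
    """Pairwise Ka/Ks over every pair of sequences in one gene alignment."""
    names = sorted(alignment)
    out = []
    for x, y in itertools.combinations(names, 2):
        out.append(pairwise_kaks(alignment[x], alignment[y], gene=gene,
                                 pair=(x, y), table_id=table_id))
    return out


def kaks_distribution(gene_alignments: dict[str, dict[str, str]],
                      table_id: int = VERTEBRATE_MITO_TABLE) -> pd.DataFrame:
    """Per-gene Ka/Ks distribution summary, ordered by OXPHOS complex.

    One row per gene: median, mean, quartiles, 1.5 x IQR whiskers,
    outliers beyond the whiskers, and the number of undefined ratios
    (Ks = 0 or saturated) excluded from the distribution.
    """
    rows = []
    for gene, aln in gene_alignments.items():
        if len(aln) < 2:
            raise KaKsError(f"gene {gene}: need at least two sequences")
        results = all_pairs_kaks(aln, gene=gene, table_id=table_id)
        ratios = np.array([r.ratio for r in results if r.ratio is not None])
        n_undef = sum(1 for r in results if r.ratio is None)
        row = {"gene": gene, "complex": GENE_COMPLEX.get(gene, "?"),
               "n_pairs": len(results), "n_undefined": n_undef}
        if len(ratios):
            q1, q2, q3 = np.percentile(ratios, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            row.update(median=float(q2), mean=float(ratios.mean()),
                       q1=float(q1), q3=float(q3),
                       whisker_low=float(ratios[ratios >= lo].min()),
                       whisker_high=float(ratios[ratios <= hi].max()),
                       outliers=sorted(float(r) for r in ratios
                                       if r < lo or r > hi))
        else:
            row.update(median=None, mean=None, q1=None, q3=None,
                       whisker_low=None, whisker_high=None, outliers=[])
        rows.append(row)
    df = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(COMPLEX_ORDER)}
    return df.sort_values(["complex", "gene"],
                          key=lambda s: s.map(lambda v: order.get(v, v))
                          if s.name == "complex" else s).reset_index(drop=True)
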