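"""Controlled vocabulary for vertebrate mitochondrial genome elements.

Element labels follow the compact nomenclature used in fish mitogenomics:
the 13 protein-coding genes (PCGs), the two ribosomal RNA genes, the 22
tRNAs abbreviated by the one-letter code of their amino acid (with L1/L2
and S1/S2 distinguishing the two leucine and serine isoacceptors), the
Control Region (``CoRe``, origin of H-strand replication) and the L-strand
replication origin (``OL``).
"""

from __future__ import annotations

PCGS = (
    "cox1", "cox2", "cox3",
    "atp6", "atp8",
    "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)

RRNAS = ("rrnS", "rrnL")

# one-letter tRNA labels; L1 reads the CTN codon family, L2 the TTR family,
# S1 the AGN family, S2 the TCN family
TRNAS = (
    "F", "V", "L1", "L2", "I", "Q", "M", "W", "A", "N", "C", "Y",
    "S1", "S2", "D", "K", "G", "R", "H", "E", "T", "P",
)

CONTROL_REGION = "CoRe"
ORIGIN_L = "OL"

ALL_LABELS = frozenset(PCGS) | frozenset(RRNAS) | frozenset(TRNAS) | {CONTROL_REGION, ORIGIN_L}

#: elements whose strand is not meaningful for order comparison.  The
#: L-strand replication origin is a short structural element inside the
#: WANCY tRNA cluster and is never reported as inverted.
UNSIGNED_LABELS = frozenset({ORIGIN_L})

FEATURE_TYPES = ("PCG", "rRNA", "tRNA", "control_region", "origin")


def feature_type_of(label: str) -> str:
    if label in PCGS:
        return "PCG"
    if label in RRNAS:
        return "rRNA"
    if label in TRNAS:
        return "tRNA"
    if label == CONTROL_REGION:
        return "control_region"
    if label == ORIGIN_L:
        return "origin"
    raise KeyError(f"unknown element label: {label!r}")


# mapping from heterogeneous GenBank-style names onto the closed vocabulary
_AA3_TO_1 = {
    "Phe": "F", "Val": "V", "Ile": "I", "Gln": "Q", "Met": "M", "Trp": "W",
    "Ala": "A", "Asn": "N", "Cys": "C", "Tyr": "Y", "Asp": "D", "Lys": "K",
    "Gly": "G", "Arg": "R", "His": "H", "Glu": "E", "Thr": "T", "Pro": "P",
}

SYNONYMS: dict[str, str] = {}


def _add(canonical: str, *names: str) -> None:
    for n in names:
        SYNONYMS[n.lower()] = canonical


_add("cox1", "COX1", "COXI", "COI", "CO1", "cytochrome c oxidase subunit 1",
     "cytochrome c oxidase subunit I")
_add("cox2", "COX2", "COXII", "COII", "CO2", "cytochrome c oxidase subunit 2",
     "cytochrome c oxidase subunit II")
_add("cox3", "COX3", "COXIII", "COIII", "CO3", "cytochrome c oxidase subunit 3",
     "cytochrome c oxidase subunit III")
_add("atp6", "ATP6", "ATPase6", "ATPase 6", "ATP synthase F0 subunit 6")
_add("atp8", "ATP8", "ATPase8", "ATPase 8", "ATP synthase F0 subunit 8")
_add("cob", "CYTB", "COB", "cytb", "cytochrome b", "apocytochrome b")
for _i in (1, 2, 3, 4, 5, 6):
    _add(f"nad{_i}", f"ND{_i}", f"NADH{_i}", f"NADH dehydrogenase subunit {_i}")
_add("nad4L", "ND4L", "NADH dehydrogenase subunit 4L")
_add("rrnS", "12S", "12S rRNA", "12S ribosomal RNA", "s-rRNA", "srRNA",
     "small subunit ribosomal RNA", "rrn12")
_add("rrnL", "16S", "16S rRNA", "16S ribosomal RNA", "l-rRNA", "lrRNA",
     "large subunit ribosomal RNA", "rrn16")
_add("CoRe", "D-loop", "control region", "D loop", "putative control region",
     "CR", "mitochondrial control region")
_add("OL", "OL", "O_L", "L-strand origin", "origin of L-strand replication",
     "rep_origin", "light strand replication origin")
_add("L1", "tRNA-Leu(CUN)", "trnL(cun)", "trnL1", "tRNA-Leu (CUN)")
_add("L2", "tRNA-Leu(UUR)", "trnL(uur)", "trnL2", "tRNA-Leu (UUR)", "tRNA-Leu(UUA/G)")
_add("S1", "tRNA-Ser(AGN)", "trnS(agn)", "trnS1", "tRNA-Ser (AGN)", "tRNA-Ser(AGC/U)", "tRNA-Ser(AGY)")
_add("S2", "tRNA-Ser(UCN)", "trnS(ucn)", "trnS2", "tRNA-Ser (UCN)")
for _aa3, _one in _AA3_TO_1.items():
    _add(_one, f"tRNA-{_aa3}", f"trn{_one}")
for _lab in ALL_LABELS:
    SYNONYMS.setdefault(_lab.lower(), _lab)


def normalize_label(name: str) -> tuple[str, bool]:
    """Map a raw feature name onto the controlled vocabulary.

    Returns ``(label, known)``; unknown names are passed through unchanged
    with ``known=False`` so that callers can keep them with a warning flag.
    """
    key = name.strip().lower()
    if key in SYNONYMS:
        return SYNONYMS[key], True
    return name.strip(), False
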