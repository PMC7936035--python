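"""Named gene orders and the 28-taxon notothenioid reference scenario.

``VERTGO`` is the typical vertebrate mitochondrial gene order linearized
from *cox1*.  The eight nototheniid gene orders are encoded from their
published linearized layouts; all of them differ from VertGO only inside
the *nad5*-*trnF* hot-spot region, except ``TremaGO`` whose inverted block
(CoRe through *trnI*, all moved to the opposite strand) extends into the
IQM tRNA cluster.

``RacoGO`` and ``GymnGO`` are transcribed from figure panels rather than
from an explicit linearized string in the text; their fixture metadata
carries ``figure_derived=True``.

The 28-species tip table and the rooted reference topology (plus the
alternative topology differing in the placement of *Pleuragramma
antarctica*) are transcriptions of the published phylogeny at the
resolution needed for gene-order mapping; branch lengths are not used by
the parsimony reconstruction and are omitted.
"""

from __future__ import annotations

from .gene_order import GeneOrder, parse_notation

# the typical vertebrate mitochondrial gene order, linearized from cox1
VERTGO = parse_notation(
    "cox1,-S2,D,cox2,K,atp8,atp6,cox3,G,nad3,R,nad4L,nad4,H,S1,L1,"
    "nad5,-nad6,-E,cob,T,-P,CoRe,F,rrnS,V,rrnL,L2,nad1,I,-Q,M,"
    "nad2,W,-A,-N,OL,-C,-Y",
    name="VertGO",
)

_PREFIX = "cox1,-S2,D,cox2,K,atp8,atp6,cox3,G,nad3,R,nad4L,nad4,H,S1,L1,nad5,"
_SUFFIX_F = ",F,rrnS,V,rrnL,L2,nad1,I,-Q,M,nad2,W,-A,-N,OL,-C,-Y"
_SUFFIX_IQM = ",-Q,M,nad2,W,-A,-N,OL,-C,-Y"


def _go(name: str, hotspot: str, suffix: str = _SUFFIX_F, **meta) -> GeneOrder:
    order = parse_notation(_PREFIX + hotspot + suffix, name=name)
    order.metadata.update(meta)
    return order


# ancestral nototheniid arrangement: one tandem duplication of the
# nad6..CoRe block with partial random loss leaves two copies of
# trnT, trnP and CoRe and transposes cob and nad6+trnE
NOTO1GO = _go("Noto1GO", "T,-P,CoRe,-nad6,-E,cob,T,-P,CoRe")

# Noto1GO minus trnP(a) and trnT(b)
NOTO2GO = _go("Noto2GO", "T,CoRe,-nad6,-E,cob,-P,CoRe")

# Noto2GO minus CoRe1
NOTO3GO = _go("Noto3GO", "T,-nad6,-E,cob,-P,CoRe")

# Noto1GO minus the trnT-trnP pair (T_b-P_b) downstream of trnE
DISSOGO = _go("DissoGO", "T,-P,CoRe,-nad6,-E,cob,CoRe")

# Noto1GO minus CoRe1 and T_b-P_b (the unsampled Trematominae
# intermediate), followed by inversion of the block CoRe..trnI
TREMA_INTERMEDIATE = _go("TremaIntermediateGO", "T,-P,-nad6,-E,cob,CoRe")
TREMAGO = _go(
    "TremaGO",
    "T,-P,-nad6,-E,cob,-I,-nad1,-L2,-rrnL,-V,-rrnS,-F,-CoRe",
    suffix=_SUFFIX_IQM,
)

# full duplication of the nad6..CoRe block of Noto3GO, no loss
CHAMGO = _go("ChamGO", "T,-nad6,-E,cob,-P,CoRe,-nad6,-E,cob,-P,CoRe")

# Noto3GO after triplication of nad6-trnE (keeping E_a, nad6, E_b) and
# tandem duplication of trnP-CoRe (losing the downstream CoRe copy);
# retains two copies of trnE and trnP
GYMNGO = _go("GymnGO", "T,-E,-nad6,-E,cob,-P,CoRe,-P", figure_derived=True)

# Noto3GO after a tandem duplication / partial random loss of the
# nad6..CoRe block that retains duplicated trnP and CoRe
RACOGO = _go("RacoGO", "T,-nad6,-E,cob,-P,CoRe,-P,CoRe", figure_derived=True)

# Noto1GO with the trnT_a..trnE segment tandemly duplicated (reported for
# a species published after the main analysis; optional fixture tip)
ROSSGO = _go("RossGO",
             "T,-P,CoRe,-nad6,-E,T,-P,CoRe,-nad6,-E,cob,T,-P,CoRe",
             figure_derived=True)

NAMED_ORDERS: dict[str, GeneOrder] = {
    o.name: o
    for o in (
        VERTGO, NOTO1GO, NOTO2GO, NOTO3GO, DISSOGO,
        TREMAGO, TREMA_INTERMEDIATE, CHAMGO, GYMNGO, RACOGO, ROSSGO,
    )
}

# ---------------------------------------------------------------------------
# 28-taxon scenario: species -> gene order name
# ---------------------------------------------------------------------------

#: the three early-diverging, non-Antarctic lineages all carry VertGO
OUTGROUP_TIPS = {
    "Bovichtus_angustifrons": "VertGO",
    "Pseudaphritis_urvillii": "VertGO",
    "Eleginops_maclovinus": "VertGO",
}

#: the 25 Antarctic (Nototheniidae) species; eight distinct gene orders
NOTOTHENIID_TIPS = {
    "Pleuragramma_antarctica": "Noto1GO",
    "Aethotaxis_mitopteryx": "Noto1GO",
    "Dissostichus_eleginoides": "DissoGO",
    "Dissostichus_mawsoni": "DissoGO",
    "Notothenia_angustata": "Noto1GO",
    "Notothenia_coriiceps": "Noto2GO",
    "Trematomus_bernacchii": "TremaGO",
    "Trematomus_borchgrevinki": "TremaGO",
    "Trematomus_newnesi": "TremaGO",
    "Trematomus_hansoni": "TremaGO",
    "Trematomus_eulepidotus": "TremaGO",
    "Trematomus_pennellii": "TremaGO",
    "Lindbergichthys_nudifrons": "TremaGO",
    "Harpagifer_antarcticus": "Noto2GO",
    "Artedidraco_skottsbergi": "Noto3GO",
    "Pogonophryne_scotti": "Noto3GO",
    "Dolloidraco_longedorsalis": "Noto3GO",
    "Histiodraco_velifer": "Noto3GO",
    "Akarotaxis_nudiceps": "Noto3GO",
    "Racovitzia_glacialis": "RacoGO",
    "Gymnodraco_acuticeps": "GymnGO",
    "Cygnodraco_mawsoni": "Noto3GO",
    "Champsocephalus_gunnari": "ChamGO",
    "Chionodraco_hamatus": "Noto3GO",
    "Chionodraco_myersi": "Noto3GO",
}

TIP_ORDERS: dict[str, str] = {**OUTGROUP_TIPS, **NOTOTHENIID_TIPS}

_TREMATOMINAE = (
    "(((((Trematomus_bernacchii,Trematomus_pennellii),Trematomus_hansoni),"
    "(Trematomus_borchgrevinki,Trematomus_newnesi)),Trematomus_eulepidotus),"
    "Lindbergichthys_nudifrons)"
)

_NODE_B = (
    "((Harpagifer_antarcticus,"
    "(Artedidraco_skottsbergi,(Pogonophryne_scotti,"
    "(Dolloidraco_longedorsalis,Histiodraco_velifer)))),"
    "((Akarotaxis_nudiceps,Racovitzia_glacialis),"
    "(Gymnodraco_acuticeps,(Cygnodraco_mawsoni,"
    "(Champsocephalus_gunnari,(Chionodraco_hamatus,Chionodraco_myersi))))))"
)

_CORE = (
    "((Notothenia_angustata,Notothenia_coriiceps),"
    "(((Aethotaxis_mitopteryx,(Dissostichus_eleginoides,Dissostichus_mawsoni)),"
    + _TREMATOMINAE + "),"
    + _NODE_B + "))"
)

#: reference topology (heterotachy tree): P. antarctica is the sister of
#: all other Nototheniidae
REFERENCE_TREE_NEWICK = (
    "(Bovichtus_angustifrons,(Pseudaphritis_urvillii,(Eleginops_maclovinus,"
    "(Pleuragramma_antarctica," + _CORE + "))));"
)

_CORE_ALT = (
    "((Notothenia_angustata,Notothenia_coriiceps),"
    "((Pleuragramma_antarctica,"
    "((Aethotaxis_mitopteryx,(Dissostichus_eleginoides,Dissostichus_mawsoni)),"
    + _TREMATOMINAE + ")),"
    + _NODE_B + "))"
)

#: alternative topology (best partition scheme): P. antarctica is the
#: sister of Dissostichinae + Trematominae
ALTERNATIVE_TREE_NEWICK = (
    "(Bovichtus_angustifrons,(Pseudaphritis_urvillii,(Eleginops_maclovinus,"
    + _CORE_ALT + ")));"
)

#: species published after the study; optional extra tips excluded from the
#: reference reconstruction (N. rossii carries a Noto1GO modification with a
#: duplicated trnT_a..trnE segment)
LATE_ADDITION_TIPS = {
    "Chionobathyscus_dewitti": "Noto3GO",
    "Pogonophryne_albipinna": "Noto3GO",
    "Trematomus_loennbergii": "TremaGO",
    "Notothenia_rossii": "RossGO",
}


def tip_gene_orders(include_late_additions: bool = False) -> dict[str, GeneOrder]:
    """Tip name -> GeneOrder map for the reference scenario."""
    table = dict(TIP_ORDERS)
    if include_late_additions:
        table.update(LATE_ADDITION_TIPS)
    return {sp: NAMED_ORDERS[goname] for sp, goname in table.items()}
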