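"""Reading and writing annotated mitogenomes, trees and result tables.

Coordinate convention: 0-based, half-open, circular.  A feature may span
the sequence origin, in which case ``end`` exceeds the genome length and
is interpreted modulo the length.  Strands are ``H`` (the deposited
reference strand) and ``L`` (its reverse complement), the standard
vertebrate mitogenome nomenclature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

from . import vocab
from .gene_order import GeneOrder

VERTEBRATE_MITO_TABLE = 2


class ParseError(ValueError):
    pass


@dataclass
class FeatureRecord:
    label: str
    strand: str  # H | L
    start: int
    end: int
    feature_type: str
    known_label: bool = True
    origin_spanning: bool = False

    def __post_init__(self):
        if self.strand not in ("H", "L"):
            raise ParseError(f"strand must be H or L, got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ParseError(
                f"bad coordinates for {self.label}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    identifier: str
    sequence: str
    features: list[FeatureRecord] = field(default_factory=list)
    completeness: str = "complete"

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start >= len(self.sequence):
                raise ParseError(
                    f"{self.identifier}: feature {f.label} starts at {f.start} "
                    f"beyond genome length {len(self.sequence)}")
            if f.end > len(self.sequence) and not f.origin_spanning:
                f.origin_spanning = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feat: FeatureRecord) -> str:
        """Feature sequence in its own (mRNA-sense) orientation."""
        if feat.end <= self.length:
            s = self.sequence[feat.start:feat.end]
        else:  # origin-spanning
            s = self.sequence[feat.start:] + self.sequence[: feat.end % self.length]
        if feat.strand == "L":
            s = str(Seq(s).reverse_complement())
        return s

    def gene_sequences(self, include_control_region: bool = True) -> dict[str, str]:
        out = {}
        tags = _copy_tags(self.features)
        for feat, tag in zip(self.features, tags):
            if feat.feature_type == "control_region" and not include_control_region:
                continue
            name = feat.label + (f"_{tag}" if tag else "")
            out[name] = self.feature_sequence(feat)
        return out

    def validate_translations(self) -> list[str]:
        """Check PCGs translate without internal stops (warnings, not errors)."""
        problems = []
        for feat in self.features:
            if feat.feature_type != "PCG":
                continue
            seq = self.feature_sequence(feat)
            aa = str(Seq(seq[: len(seq) - len(seq) % 3]).translate(
                table=VERTEBRATE_MITO_TABLE))
            if "*" in aa[:-1]:
                problems.append(
                    f"{self.identifier}:{feat.label} has internal stop codons")
        if problems and self.completeness == "complete":
            warnings.warn("; ".join(problems))
        return problems


def _copy_tags(features: list[FeatureRecord]) -> list[str | None]:
    from collections import Counter, defaultdict

    counts = Counter(f.label for f in features)
    seen: dict[str, int] = defaultdict(int)
    tags: list[str | None] = []
    for f in features:
        if counts[f.label] > 1:
            i = seen[f.label]
            tags.append(str(i + 1) if f.label == "CoRe" else "abcdefgh"[i])
            seen[f.label] += 1
        else:
            tags.append(None)
    return tags


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def convert_coordinates(start: int, end: int, source: str, target: str):
    """Convert between 0-based half-open and 1-based closed coordinates."""
    conventions = ("zero_half_open", "one_closed")
    if source not in conventions or target not in conventions:
        raise ValueError(f"coordinate conventions are {conventions}")
    if source == target:
        return start, end
    if source == "one_closed":  # -> zero_half_open
        return start - 1, end
    return start + 1, end  # zero_half_open -> one_closed


def read_feature_table(path, dialect: str = "tsv", sequence: str | None = None,
                       fasta_path=None, identifier: str | None = None,
                       completeness: str = "complete",
                       coords: str = "zero_half_open") -> AnnotatedGenome:
    """Read an annotated mitogenome.

    ``dialect`` is ``tsv`` (columns: label, strand, start, end, type) or
    ``genbank_flat``.  TSV coordinates follow ``coords`` (0-based
    half-open by default; ``one_closed`` for 1-based closed dialects).
    For TSV the sequence comes from ``sequence`` or ``fasta_path``.
    """
    path = Path(path)
    if dialect == "genbank_flat":
        return _read_genbank(path, completeness)
    if dialect != "tsv":
        raise ParseError(f"unknown dialect {dialect!r}")
    if sequence is None:
        if fasta_path is None:
            raise ParseError("TSV dialect requires a sequence or fasta_path")
        rec = next(SeqIO.parse(str(fasta_path), "fasta"))
        sequence = str(rec.seq)
        identifier = identifier or rec.id
    features = []
    seen = set()
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("label\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(f"{path}:{ln}: expected 5 tab-separated columns")
        raw_label, strand, start_s, end_s, ftype = parts[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: malformed coordinates") from exc
        start, end = convert_coordinates(start, end, coords, "zero_half_open")
        label, known = vocab.normalize_label(raw_label)
        if not known:
            warnings.warn(f"{path}:{ln}: unknown label {raw_label!r} kept as-is")
        key = (label, strand, start, end)
        if key in seen:
            raise ParseError(f"{path}:{ln}: duplicate feature {key}")
        seen.add(key)
        features.append(FeatureRecord(
            label=label, strand=strand, start=start, end=end,
            feature_type=ftype if not known else vocab.feature_type_of(label),
            known_label=known))
    return AnnotatedGenome(identifier=identifier or path.stem,
                           sequence=sequence, features=features,
                           completeness=completeness)


_GENBANK_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                 "D-loop": "control_region", "rep_origin": "origin",
                 "misc_feature": "control_region"}


def _read_genbank(path: Path, completeness: str) -> AnnotatedGenome:
    rec = SeqIO.read(str(path), "genbank")
    features = []
    for f in rec.features:
        if f.type not in _GENBANK_TYPE:
            continue
        quals = f.qualifiers
        raw = (quals.get("gene") or quals.get("product")
               or quals.get("note") or [f.type])[0]
        if f.type == "D-loop":
            raw = "D-loop"
        if f.type == "rep_origin":
            raw = "OL"
        label, known = vocab.normalize_label(raw)
        if not known:
            warnings.warn(f"{path}: unknown feature name {raw!r} kept as-is")
        strand = "L" if f.location.strand == -1 else "H"
        features.append(FeatureRecord(
            label=label, strand=strand,
            start=int(f.location.start), end=int(f.location.end),
            feature_type=vocab.feature_type_of(label) if known else f.type,
            known_label=known))
    return AnnotatedGenome(identifier=rec.id or path.stem,
                           sequence=str(rec.seq), features=features,
                           completeness=completeness)


def write_feature_table(genome: AnnotatedGenome, path, fasta_path=None,
                        coords: str = "zero_half_open") -> None:
    lines = ["label\tstrand\tstart\tend\ttype"]
    for f in genome.features:
        s, e = convert_coordinates(f.start, f.end, "zero_half_open", coords)
        lines.append(f"{f.label}\t{f.strand}\t{s}\t{e}\t{f.feature_type}")
    Path(path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None:
        Path(fasta_path).write_text(
            f">{genome.identifier}\n{genome.sequence}\n")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_newick(path_or_string, genome_ids=None) -> dendropy.Tree:
    """Read a rooted newick tree; validates tips against ``genome_ids``."""
    data = str(path_or_string)
    if "(" in data:
        tree = dendropy.Tree.get(data=data, schema="newick",
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(path=data, schema="newick",
                                 preserve_underscores=True)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        raise ParseError("duplicate tip names in tree")
    if genome_ids is not None:
        missing = sorted(set(tips) - set(genome_ids))
        if missing:
            raise ParseError(f"tree tips not in genome set: {missing}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(tables: dict, path, format: str = "json") -> None:
    """Loss-free serialization of result tables (dict of records/frames)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_jsonable(tables), indent=2, sort_keys=True))
    elif format == "tsv":
        lines = []
        for name, table in tables.items():
            rows = _rows_of(table)
            header = sorted({k for r in rows for k in r}) if rows else []
            lines.append(f"# {name}")
            lines.append("\t".join(header))
            for r in rows:
                lines.append("\t".join(str(r.get(h, "")) for h in header))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _rows_of(table):
    import dataclasses

    import pandas as pd

    if isinstance(table, pd.DataFrame):
        return table.to_dict("records")
    if isinstance(table, dict):
        return [table]
    rows = list(table)
    return [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else r
            for r in rows]


def _jsonable(obj):
    import numpy as np
    import pandas as pd

    if isinstance(obj, pd.DataFrame):
        return obj.to_dict("records")
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, GeneOrder):
        return obj.notation()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(getattr(obj, k)) for k in obj.__dataclass_fields__}
    return obj
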