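"""Reading, writing and quality control of annotated mitogenome records in
GenBank flat-file format.

Coordinates are 1-based inclusive throughout (GenBank convention).  A feature
whose ``start`` exceeds its ``end`` spans the replication origin of a circular
molecule; in flat files such features are rendered as ``join(a..L,1..b)``.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .vocab import (
    CATEGORY_CR,
    CATEGORY_PCG,
    CATEGORY_RRNA,
    CATEGORY_TRNA,
    CONTROL_REGION,
    GENE_TOKENS,
    TOKEN_CATEGORY,
    TRNA_TOKENS,
)

__all__ = [
    "GeneFeature",
    "MitogenomeRecord",
    "AnnotationAnomaly",
    "GenBankParseError",
    "UnknownGeneNameError",
    "normalize_gene_name",
    "parse_genbank_record",
    "write_genbank_record",
    "validate_annotation",
    "anomalies_to_tsv",
]


class GenBankParseError(ValueError):
    """Raised when a flat file cannot be interpreted as one mitogenome record."""


class UnknownGeneNameError(KeyError):
    """Raised when an annotation label cannot be mapped onto the vocabulary."""

    def __init__(self, raw: str):
        super().__init__(raw)
        self.raw = raw

    def __str__(self) -> str:  # KeyError repr-quotes its arg; keep it readable
        return f"unmappable gene label: {self.raw!r}"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, named by its canonical gene token.

    ``start > end`` denotes an origin-spanning feature on a circular record
    when ``wraps`` is set; without ``wraps`` it is an annotation defect
    (inverted coordinates).  ``start``/``end`` of ``None`` mean the annotation
    named the gene but carried no usable position.
    """

    name: Optional[str]
    category: str
    start: Optional[int]
    end: Optional[int]
    strand: int
    raw_label: str = ""
    wraps: bool = False

    def span(self, record_length: int) -> Optional[int]:
        """Feature length in bases on a circular molecule of the given size."""
        if self.start is None or self.end is None:
            return None
        if self.start <= self.end:
            return self.end - self.start + 1
        return record_length - self.start + 1 + self.end


@dataclass
class MitogenomeRecord:
    """An annotated (usually circular) mitochondrial genome."""

    record_id: str
    taxon: str
    length: int
    circular: bool = True
    group: str = ""
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    parse_anomalies: list["AnnotationAnomaly"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(
            self.features,
            key=lambda f: (f.start if f.start is not None else 0, f.end or 0),
        )

    def feature_sequence(self, feat: GeneFeature) -> str:
        """Strand-resolved nucleotide sequence of a feature (wrap-aware)."""
        if self.sequence is None:
            raise ValueError(f"{self.record_id}: record carries no sequence")
        if feat.start is None or feat.end is None:
            raise ValueError(f"{self.record_id}: feature {feat.name} has no coordinates")
        if feat.start <= feat.end:
            sub = self.sequence[feat.start - 1 : feat.end]
        else:
            sub = self.sequence[feat.start - 1 :] + self.sequence[: feat.end]
        if feat.strand < 0:
            sub = str(Seq(sub).reverse_complement())
        return sub


ANOMALY_KINDS = (
    "missing-gene",
    "duplicated-gene",
    "inverted-coordinates",
    "missing-coordinates",
    "out-of-range",
    "unknown-name",
)


@dataclass(frozen=True)
class AnnotationAnomaly:
    record_id: str
    kind: str
    gene: str
    detail: str = ""
    severity: str = "defect"  # "defect" or "info" (tolerated biology)

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly kind: {self.kind}")


# ---------------------------------------------------------------------------
# Gene-name normalization
# ---------------------------------------------------------------------------

_SYNONYMS: dict[str, str] = {}


def _add(token: str, *names: str) -> None:
    for n in names:
        _SYNONYMS[n.lower()] = token


_add("atp6", "atp6", "atpase6", "atpase 6", "atp synthase f0 subunit 6",
     "atp synthase subunit 6", "atp-6")
_add("atp8", "atp8", "atpase8", "atpase 8", "atp synthase f0 subunit 8",
     "atp synthase subunit 8", "atp-8")
_add("cob", "cob", "cytb", "cyt b", "cyb", "cytochrome b", "cytochrome-b",
     "cytochrome b apoenzyme")
_add("cox1", "cox1", "coi", "co1", "cox i", "coxi",
     "cytochrome c oxidase subunit 1", "cytochrome c oxidase subunit i",
     "cytochrome oxidase subunit 1", "cytochrome oxidase subunit i")
_add("cox2", "cox2", "coii", "co2", "coxii",
     "cytochrome c oxidase subunit 2", "cytochrome c oxidase subunit ii",
     "cytochrome oxidase subunit 2", "cytochrome oxidase subunit ii")
_add("cox3", "cox3", "coiii", "co3", "coxiii",
     "cytochrome c oxidase subunit 3", "cytochrome c oxidase subunit iii",
     "cytochrome oxidase subunit 3", "cytochrome oxidase subunit iii")
for _i in ("1", "2", "3", "4", "5", "6"):
    _add(f"nad{_i}", f"nad{_i}", f"nd{_i}", f"nadh{_i}",
         f"nadh dehydrogenase subunit {_i}", f"nadh dehydrogenase subunit{_i}")
_add("nad4l", "nad4l", "nd4l", "nadh4l", "nadh dehydrogenase subunit 4l",
     "nadh dehydrogenase subunit 4 l")
_add("rrnS", "rrns", "srrna", "s-rrna", "12s", "12s rrna", "12s ribosomal rna",
     "rrn12", "small subunit ribosomal rna", "ssu rrna", "rns", "mtssu")
_add("rrnL", "rrnl", "lrrna", "l-rrna", "16s", "16s rrna", "16s ribosomal rna",
     "rrn16", "large subunit ribosomal rna", "lsu rrna", "rnl", "mtlsu")
_add("CR", "cr", "d-loop", "dloop", "control region", "putative control region",
     "at-rich region", "a+t-rich region", "at rich region",
     "large non-coding region", "non-coding region")

_TRNA_AA = {
    "ala": "trnA", "a": "trnA", "cys": "trnC", "c": "trnC",
    "asp": "trnD", "d": "trnD", "glu": "trnE", "e": "trnE",
    "phe": "trnF", "f": "trnF", "gly": "trnG", "g": "trnG",
    "his": "trnH", "h": "trnH", "ile": "trnI", "i": "trnI",
    "lys": "trnK", "k": "trnK", "met": "trnM", "m": "trnM",
    "asn": "trnN", "n": "trnN", "pro": "trnP", "p": "trnP",
    "gln": "trnQ", "q": "trnQ", "arg": "trnR", "r": "trnR",
    "thr": "trnT", "t": "trnT", "val": "trnV", "v": "trnV",
    "trp": "trnW", "w": "trnW", "tyr": "trnY", "y": "trnY",
}

for _t in TRNA_TOKENS:
    _SYNONYMS[_t.lower()] = _t

# Codon-group / anticodon disambiguation for the duplicated-isotype tRNAs.
_LEU_SER_GROUPS = {
    "uur": "trnL2", "uua": "trnL2", "uug": "trnL2", "taa": "trnL2", "uaa": "trnL2",
    "cun": "trnL1", "tag": "trnL1", "uag": "trnL1",
    "agn": "trnS1", "agy": "trnS1", "gct": "trnS1", "gcu": "trnS1",
    "ucn": "trnS2", "tcn": "trnS2", "tga": "trnS2", "uga": "trnS2",
}

_TRNA_RE = re.compile(r"^trna[-_ ]?([a-z]{1,3})\s*(?:\(([a-z]{3})\))?$")


def normalize_gene_name(raw: str) -> str:
    """Map an annotation label onto the canonical 38-token vocabulary.

    Deterministic and case-insensitive; idempotent on canonical tokens.
    Raises :class:`UnknownGeneNameError` for unmappable labels, including
    ``tRNA-Leu``/``tRNA-Ser`` without an anticodon or codon-group qualifier.
    """
    if not raw or not raw.strip():
        raise UnknownGeneNameError(raw)
    key = raw.strip().lower()
    if key in _SYNONYMS:
        return _SYNONYMS[key]
    m = _TRNA_RE.match(key)
    if m:
        aa, group = m.groups()
        if aa in ("leu", "l", "ser", "s"):
            if group and group in _LEU_SER_GROUPS:
                return _LEU_SER_GROUPS[group]
            if group in ("l1", "l2", "s1", "s2"):  # pragma: no cover - defensive
                return "trn" + group.upper()
            raise UnknownGeneNameError(raw)
        if aa in _TRNA_AA:
            return _TRNA_AA[aa]
    # MITOS-style "trnL2-uaa" etc.
    m = re.match(r"^(trn[a-z][12]?)[-_(].*$", key)
    if m and m.group(1) in _SYNONYMS:
        return _SYNONYMS[m.group(1)]
    raise UnknownGeneNameError(raw)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene")

_CR_HINT = re.compile(r"control\s*region|d-?loop|a\+?t[- ]rich|non-?coding", re.I)


def _feature_label(feat: SeqFeature) -> Optional[str]:
    for key in ("gene", "product", "note", "standard_name"):
        vals = feat.qualifiers.get(key)
        if vals:
            return str(vals[0])
    return None


def _location_bounds(feat: SeqFeature, length: int) -> tuple[int, int, int, bool]:
    """(start, end, strand, wraps) in 1-based inclusive coordinates."""
    loc = feat.location
    strand = -1 if loc.strand == -1 else 1
    parts = sorted(loc.parts, key=lambda p: int(p.start))
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
        # join(a..L,1..b): spans the origin
        return int(parts[1].start) + 1, int(parts[0].end), strand, True
    return int(loc.start) + 1, int(loc.end), strand, False


def parse_genbank_record(text: str) -> MitogenomeRecord:
    """Parse exactly one GenBank flat-file record into a MitogenomeRecord.

    Gene-bearing features (gene/CDS/tRNA/rRNA/D-loop and control-region
    misc_features) are mapped onto the canonical vocabulary with
    :func:`normalize_gene_name`.  Unmappable labels and out-of-range
    coordinates are attached to the record as anomalies rather than raised.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            seqrecs = list(SeqIO.parse(io.StringIO(text), "genbank"))
        except ValueError as exc:
            raise GenBankParseError(f"malformed GenBank text: {exc}") from exc
    if len(seqrecs) != 1:
        raise GenBankParseError(f"expected exactly one record, found {len(seqrecs)}")
    rec = seqrecs[0]
    length = len(rec.seq)
    if length == 0:
        raise GenBankParseError("record declares zero length")
    circular = rec.annotations.get("topology", "circular") == "circular"
    taxon = rec.annotations.get("organism", "") or ""
    if taxon in (".", "unknown"):
        taxon = ""
    keywords = [k for k in rec.annotations.get("keywords", []) if k and k != "."]
    group = keywords[0] if keywords else ""

    try:
        sequence: Optional[str] = str(rec.seq).upper() if rec.seq.defined else None
    except AttributeError:  # pragma: no cover - older biopython
        sequence = str(rec.seq).upper()
    record = MitogenomeRecord(
        record_id=rec.id if rec.id and rec.id != "<unknown id>" else rec.name,
        taxon=taxon,
        group=group,
        length=length,
        circular=circular,
        sequence=sequence,
    )

    seen: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        label = _feature_label(feat)
        if feat.type == "D-loop":
            label = label or "D-loop"
        if label is None:
            continue
        if feat.type == "misc_feature" and not _CR_HINT.search(label):
            continue
        try:
            token = normalize_gene_name(label)
        except UnknownGeneNameError:
            record.parse_anomalies.append(
                AnnotationAnomaly(record.record_id, "unknown-name", label,
                                  f"feature type {feat.type}")
            )
            continue
        start, end, strand, wraps = _location_bounds(feat, length)
        if start < 1 or end > length or start > length:
            record.parse_anomalies.append(
                AnnotationAnomaly(record.record_id, "out-of-range", token,
                                  f"location {start}..{end} outside 1..{length}")
            )
        gf = GeneFeature(
            name=token,
            category=TOKEN_CATEGORY[token],
            start=start,
            end=end,
            strand=strand,
            raw_label=label,
            wraps=wraps,
        )
        # RefSeq entries usually carry both a `gene` and a CDS/tRNA/rRNA
        # feature for the same gene; keep the more specific one.
        dup = next((g for g in seen if g.name == token and g.start == gf.start
                    and g.strand == gf.strand), None)
        if dup is not None:
            if feat.type != "gene":
                seen[seen.index(dup)] = gf
            continue
        seen.append(gf)

    record.features = sorted(seen, key=lambda f: (f.start, f.end))
    return record


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_WRITE_TYPES = {
    CATEGORY_PCG: "CDS",
    CATEGORY_RRNA: "rRNA",
    CATEGORY_TRNA: "tRNA",
    CATEGORY_CR: "D-loop",
}


def _make_location(feat: GeneFeature, length: int) -> SimpleLocation | CompoundLocation:
    strand = feat.strand
    if feat.start <= feat.end:
        return SimpleLocation(feat.start - 1, feat.end, strand=strand)
    p1 = SimpleLocation(feat.start - 1, length, strand=strand)
    p2 = SimpleLocation(0, feat.end, strand=strand)
    parts = [p1, p2] if strand >= 0 else [p2, p1]
    return CompoundLocation(parts)


def write_genbank_record(record: MitogenomeRecord) -> str:
    """Render a record as a GenBank flat file; inverse of the parser.

    Refuses records without features.  Features lacking coordinates cannot be
    expressed in the format and are refused as well.
    """
    if not record.features:
        raise ValueError(f"{record.record_id}: refusing to write a record without features")
    for f in record.features:
        if f.start is None or f.end is None:
            raise ValueError(
                f"{record.record_id}: feature {f.name or f.raw_label} lacks coordinates"
            )
    seq = Seq(record.sequence) if record.sequence is not None else Seq(None, length=record.length)
    rec = SeqRecord(
        seq,
        id=record.record_id,
        name=record.record_id.split(".")[0].replace(" ", "_")[:16],
        description=f"{record.taxon} mitochondrion".strip(),
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    rec.annotations["data_file_division"] = "INV"
    if record.taxon:
        rec.annotations["organism"] = record.taxon
        rec.annotations["source"] = record.taxon
    if record.group:
        rec.annotations["keywords"] = [record.group]
    rec.features.append(
        SeqFeature(SimpleLocation(0, record.length, strand=1), type="source")
    )
    for f in record.sorted_features():
        loc = _make_location(f, record.length)
        ftype = _WRITE_TYPES[f.category]
        quals: dict[str, list[str]] = {}
        label = f.raw_label or f.name
        if f.category == CATEGORY_CR:
            ftype = "D-loop"
            quals["note"] = [label]
        elif f.category == CATEGORY_PCG:
            quals["gene"] = [label]
            quals["codon_start"] = ["1"]
            quals["transl_table"] = ["5"]
        else:
            quals["gene"] = [label]
            quals["product"] = [label]
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Validation / QC
# ---------------------------------------------------------------------------

#: Duplications documented as real biology; reported as informational only.
TOLERATED_DUPLICATIONS = ("trnQ",)


def validate_annotation(record: MitogenomeRecord) -> list[AnnotationAnomaly]:
    """Screen a record for the annotation-defect classes seen in public
    databases: missing or duplicated genes, inverted or absent coordinates,
    out-of-range locations, unmappable names.

    Always returns a (possibly empty) list, sorted by (kind, gene).
    """
    anomalies: list[AnnotationAnomaly] = list(record.parse_anomalies)
    rid = record.record_id

    named = [f for f in record.features if f.name and f.name != CONTROL_REGION]
    counts: dict[str, int] = {}
    for f in named:
        counts[f.name] = counts.get(f.name, 0) + 1

    for token in GENE_TOKENS:
        if counts.get(token, 0) == 0:
            anomalies.append(
                AnnotationAnomaly(rid, "missing-gene", token,
                                  "expected gene absent from annotation")
            )
    for token, n in counts.items():
        if n > 1:
            severity = "info" if token in TOLERATED_DUPLICATIONS else "defect"
            note = "documented duplication, tolerated" if severity == "info" else \
                f"{n} copies annotated"
            anomalies.append(
                AnnotationAnomaly(rid, "duplicated-gene", token, note, severity)
            )

    feats = record.sorted_features()
    for i, f in enumerate(feats):
        name = f.name or f.raw_label
        if f.name is None:
            a = AnnotationAnomaly(rid, "unknown-name", f.raw_label,
                                  "label not mappable to the gene vocabulary")
            if a not in anomalies:
                anomalies.append(a)
        if f.start is None or f.end is None:
            anomalies.append(
                AnnotationAnomaly(rid, "missing-coordinates", name,
                                  "gene named but no usable position")
            )
            continue
        if f.start > f.end:
            span = f.span(record.length)
            if not record.circular or not f.wraps:
                anomalies.append(
                    AnnotationAnomaly(rid, "inverted-coordinates", name,
                                      f"start {f.start} > end {f.end}")
                )
            elif f.category != CATEGORY_CR and span is not None and span > record.length // 2:
                # A swapped start/end pair on a circular record reads as an
                # origin-spanning feature covering most of the molecule.
                anomalies.append(
                    AnnotationAnomaly(rid, "inverted-coordinates", name,
                                      f"origin-spanning feature of {span} bp "
                                      f"({f.start}..{f.end}) suggests swapped coordinates")
                )
        if f.end is not None and (f.end > record.length or (f.start or 0) < 1):
            a = AnnotationAnomaly(rid, "out-of-range", name,
                                  f"location {f.start}..{f.end} outside 1..{record.length}")
            if a not in anomalies:
                anomalies.append(a)
        # An rRNA running against the strand of both flanking features is the
        # signature of inverted coordinates in submitted annotations.
        if f.category == CATEGORY_RRNA and len(feats) >= 3:
            left = feats[i - 1]
            right = feats[(i + 1) % len(feats)]
            if (left.category == CATEGORY_RRNA) != (right.category == CATEGORY_RRNA):
                pass  # the paired rRNA neighbour carries the block strand
            if f.strand != left.strand and f.strand != right.strand and \
                    left.strand == right.strand:
                a = AnnotationAnomaly(rid, "inverted-coordinates", name,
                                      "strand contradicts both flanking features")
                if not any(x.kind == "inverted-coordinates" and x.gene == name
                           for x in anomalies):
                    anomalies.append(a)

    unique = sorted(set(anomalies), key=lambda a: (a.kind, a.gene, a.detail))
    return unique


def anomalies_to_tsv(anomalies: Iterable[AnnotationAnomaly]) -> str:
    """Render anomalies as a TSV report (record_id, kind, gene, detail, severity)."""
    lines = ["record_id\tkind\tgene\tdetail\tseverity"]
    for a in anomalies:
        lines.append(f"{a.record_id}\t{a.kind}\t{a.gene}\t{a.detail}\t{a.severity}")
    return "\n".join(lines) + "\n"


def strip_gene(record: MitogenomeRecord, token: str) -> MitogenomeRecord:
    """Return a copy of the record with every feature named ``token`` removed."""
    new = replace(record)
    new.features = [f for f in record.features if f.name != token]
    new.parse_anomalies = list(record.parse_anomalies)
    return new
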