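"""Synthetic annotated mitogenomes for end-to-end testing without downloads.

Records are laid out on the pancrustacean ground pattern, optionally
rearranged by scripted events, with coding sequences drawn from planted
per-group codon profiles, AT-rich non-coding stretches, and (optionally)
planted annotation defects mimicking the error classes seen in public
databases.  Everything is driven by one integer seed: identical config plus
seed yields byte-identical records, manifest and tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genbank_io import GeneFeature, MitogenomeRecord
from .gene_order import (
    GROUND_PATTERN,
    RearrangementEvent,
    SignedGeneOrder,
    apply_events,
    block_inversion,
    duplication,
    translocation,
)
from .vocab import (
    CATEGORY_CR,
    CATEGORY_PCG,
    CONTROL_REGION,
    DEFAULT_FAMILIES,
    SENSE_CODONS,
    TOKEN_CATEGORY,
)

__all__ = [
    "GroupSpec",
    "GeneratorConfig",
    "StudyFixture",
    "default_config",
    "default_pattern_scripts",
    "table_style_defects",
    "profile_from_at3_bias",
    "simulate_cds",
    "build_ground_record",
    "build_record",
    "apply_event_script",
    "make_study_fixture",
]

Bias = Union[float, Mapping[str, float]]


@dataclass(frozen=True)
class GroupSpec:
    """One study group: size and planted codon-usage profile."""

    label: str
    n_taxa: int
    at3_bias: Bias = 0.70
    codon_probs: Optional[tuple[float, ...]] = None  # explicit 62-vector
    outgroup: bool = False


@dataclass
class GeneratorConfig:
    seed: int = 0
    groups: list[GroupSpec] = field(default_factory=list)
    pattern_scripts: dict[str, list[RearrangementEvent]] = field(default_factory=dict)
    taxon_patterns: dict[str, str] = field(default_factory=dict)
    defects: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    pcg_codons_mean: int = 300
    pcg_codons_jitter: int = 20
    trna_length: int = 68
    rrn_lengths: tuple[int, int] = (800, 1300)  # (rrnS, rrnL)
    cr_length: int = 800
    cr_at: float = 0.80
    noncoding_at: float = 0.72
    spacer_max: int = 20
    monophyletic: bool = True


@dataclass
class StudyFixture:
    records: list[MitogenomeRecord]
    manifest: pd.DataFrame  # record_id, taxon, group, pattern
    tree_newick: str


# ---------------------------------------------------------------------------
# Codon profiles and coding sequences
# ---------------------------------------------------------------------------

def profile_from_at3_bias(bias: Bias,
                          families: Mapping[str, tuple[str, ...]] = DEFAULT_FAMILIES,
                          ) -> np.ndarray:
    """Probability vector over the 62 sense codons with uniform amino-acid
    usage and, within each synonymous family, the given probability mass on
    codons ending in A or T.

    ``bias`` may be a single value or a per-amino-acid mapping.
    """
    probs = np.zeros(len(SENSE_CODONS))
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    n_aa = len(families)
    for aa, codons in families.items():
        b = float(bias[aa]) if isinstance(bias, Mapping) else float(bias)
        if not 0.0 < b < 1.0:
            raise ValueError(f"third-position AT bias must be in (0,1), got {b}")
        at3 = [c for c in codons if c[2] in "AT"]
        gc3 = [c for c in codons if c[2] not in "AT"]
        for c in at3:
            probs[index[c]] = (1.0 / n_aa) * b / len(at3)
        for c in gc3:
            probs[index[c]] = (1.0 / n_aa) * (1.0 - b) / len(gc3)
    return probs


def _as_probs(spec: GroupSpec) -> np.ndarray:
    if spec.codon_probs is not None:
        p = np.asarray(spec.codon_probs, dtype=float)
        if p.shape != (len(SENSE_CODONS),):
            raise ValueError(f"codon_probs must have {len(SENSE_CODONS)} entries")
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("codon_probs must be a probability vector")
        return p / p.sum()
    return profile_from_at3_bias(spec.at3_bias)


def simulate_cds(profile: Sequence[float], n_codons: int,
                 rng: np.random.Generator) -> str:
    """A coding sequence of ``n_codons`` sense codons plus a terminal TAA."""
    p = np.asarray(profile, dtype=float)
    if p.shape != (len(SENSE_CODONS),) or (p < 0).any() or not np.isclose(p.sum(), 1.0):
        raise ValueError("profile must be a probability vector over the 62 sense codons")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    draws = rng.choice(len(SENSE_CODONS), size=n_codons, p=p / p.sum())
    return "".join(SENSE_CODONS[i] for i in draws) + "TAA"


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _random_bases(rng: np.random.Generator, n: int, at: float) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


# ---------------------------------------------------------------------------
# Record construction
# ---------------------------------------------------------------------------

def apply_event_script(order: SignedGeneOrder,
                       events: Sequence[RearrangementEvent]) -> SignedGeneOrder:
    """Apply scripted rearrangement events left-to-right (see
    :func:`mitokit.gene_order.apply_events`)."""
    return apply_events(order, events)


def build_record(config: GeneratorConfig, taxon: str, group: str = "",
                 record_id: Optional[str] = None,
                 pattern: Optional[str] = None,
                 rng: Optional[np.random.Generator] = None,
                 codon_probs: Optional[np.ndarray] = None) -> MitogenomeRecord:
    """Build one fully annotated synthetic record.

    The gene order is the ground pattern transformed by the event script of
    ``pattern`` (if any); sequences honour the planted codon profile, and
    strands follow the signed order.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if codon_probs is None:
        spec = next((g for g in config.groups if g.label == group), None)
        codon_probs = _as_probs(spec) if spec else profile_from_at3_bias(0.70)

    order = GROUND_PATTERN
    if pattern and pattern in config.pattern_scripts:
        order = apply_event_script(order, config.pattern_scripts[pattern])

    pieces: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for tok, sign in order.tokens:
        base = tok.split(".")[0]
        category = TOKEN_CATEGORY[base]
        if category == CATEGORY_PCG:
            jitter = int(rng.integers(-config.pcg_codons_jitter,
                                      config.pcg_codons_jitter + 1))
            seq = simulate_cds(codon_probs, config.pcg_codons_mean + jitter, rng)
        elif base == "rrnS":
            seq = _random_bases(rng, config.rrn_lengths[0], config.noncoding_at)
        elif base == "rrnL":
            seq = _random_bases(rng, config.rrn_lengths[1], config.noncoding_at)
        elif category == CATEGORY_CR:
            seq = _random_bases(rng, config.cr_length, config.cr_at)
        else:
            seq = _random_bases(rng, config.trna_length, config.noncoding_at)
        if sign < 0:
            seq = _revcomp(seq)
        start = pos
        end = pos + len(seq) - 1
        features.append(GeneFeature(name=base, category=category, start=start,
                                    end=end, strand=1 if sign > 0 else -1,
                                    raw_label=base))
        pieces.append(seq)
        pos = end + 1
        gap = int(rng.integers(0, config.spacer_max + 1))
        if gap:
            pieces.append(_random_bases(rng, gap, config.noncoding_at))
            pos += gap

    sequence = "".join(pieces)
    rid = record_id or f"SYN_{taxon}"
    return MitogenomeRecord(
        record_id=rid, taxon=taxon, group=group, length=len(sequence),
        circular=True, features=features, sequence=sequence,
    )


def build_ground_record(config: GeneratorConfig, taxon: str,
                        **kwargs) -> MitogenomeRecord:
    """A clean record on the unmodified ground pattern."""
    return build_record(config, taxon, pattern=None, **kwargs)


# ---------------------------------------------------------------------------
# Defect planting
# ---------------------------------------------------------------------------

def plant_defects(record: MitogenomeRecord,
                  defects: Sequence[tuple[str, str]]) -> MitogenomeRecord:
    """Return a copy of the record with annotation defects planted.

    Supported kinds: missing-gene (feature deleted), duplicated-gene (an
    extra copy dropped inside the control region), inverted-coordinates
    (start/end swapped), missing-coordinates (positions erased), out-of-range
    (end pushed past the molecule), unknown-name (label garbled).
    """
    rec = replace(record)
    rec.features = list(record.features)
    rec.parse_anomalies = list(record.parse_anomalies)
    for kind, gene in defects:
        idx = next((i for i, f in enumerate(rec.features) if f.name == gene), None)
        if kind == "missing-gene":
            if idx is None:
                raise ValueError(f"cannot remove absent gene {gene}")
            del rec.features[idx]
            continue
        if idx is None:
            raise ValueError(f"no feature {gene} to corrupt")
        f = rec.features[idx]
        if kind == "duplicated-gene":
            cr = next((x for x in rec.features if x.category == CATEGORY_CR), None)
            if cr is None or cr.start is None:
                raise ValueError("duplicated-gene planting needs a control region")
            span = min((f.span(rec.length) or 68), (cr.span(rec.length) or 68) - 10)
            start = cr.start + 5
            rec.features.append(replace(f, start=start, end=start + span - 1))
        elif kind == "inverted-coordinates":
            rec.features[idx] = replace(f, start=f.end, end=f.start)
        elif kind == "missing-coordinates":
            rec.features[idx] = replace(f, start=None, end=None)
        elif kind == "out-of-range":
            rec.features[idx] = replace(f, end=rec.length + 50)
        elif kind == "unknown-name":
            rec.features[idx] = replace(f, name=None, raw_label=f"orf{f.start}")
        else:
            raise ValueError(f"unknown defect kind {kind}")
    rec.features.sort(key=lambda f: (f.start if f.start is not None else 0, f.end or 0))
    return rec


def table_style_defects() -> list[list[tuple[str, str]]]:
    """Four defect scripts mirroring the anomaly classes corrected in public
    RefSeq mitogenomes: a missing protein gene plus a duplicated tRNA, two
    records with swapped rRNA/tRNA coordinates, and absent rRNA annotations."""
    return [
        [("missing-gene", "nad2"), ("duplicated-gene", "trnS1")],
        [("inverted-coordinates", "rrnS"), ("inverted-coordinates", "rrnL")],
        [("inverted-coordinates", "trnI"), ("inverted-coordinates", "trnQ")],
        [("missing-gene", "rrnS"), ("missing-gene", "rrnL")],
    ]


def random_event_script(order: SignedGeneOrder, n_events: int,
                        rng: np.random.Generator,
                        anchor: str = "cox1") -> list[RearrangementEvent]:
    """A random, sequentially applicable event script (for replay testing).

    The anchor gene is never moved, lost or duplicated so canonical frames
    stay well-defined.
    """
    events: list[RearrangementEvent] = []
    current = order
    for _ in range(n_events):
        tokens = list(current.tokens)
        names = [t for t, _ in tokens]
        movable = [t for t in names if t != anchor]
        kind = rng.choice(
            ["translocation", "translocation+inversion", "inversion",
             "block-inversion", "duplication", "loss"],
            p=[0.30, 0.15, 0.10, 0.25, 0.10, 0.10])
        if kind in ("translocation", "translocation+inversion", "duplication"):
            g = movable[int(rng.integers(len(movable)))]
            i = names.index(g)
            sign = tokens[i][1]
            if kind == "translocation+inversion":
                sign = -sign
            elif kind == "duplication":
                sign = int(rng.choice([1, -1]))
            for _try in range(50):
                j = int(rng.integers(len(tokens)))
                l, r = names[j], names[(j + 1) % len(tokens)]
                if g not in (l, r):
                    break
            else:  # pragma: no cover - tiny orders
                continue
            if kind == "duplication":
                base = g.split(".")[0]
                k = 2
                while f"{base}.{k}" in names:
                    k += 1
                ev = duplication(f"{base}.{k}", sign, l, r)
            else:
                ev = translocation(g, sign, l, r,
                                   invert=(kind == "translocation+inversion"))
        elif kind == "inversion":
            g = movable[int(rng.integers(len(movable)))]
            i = names.index(g)
            ev = RearrangementEvent("inversion", ((g, -tokens[i][1]),))
        elif kind == "loss":
            if len(tokens) <= 4:
                continue
            g = movable[int(rng.integers(len(movable)))]
            ev = RearrangementEvent("loss", ((g, 0),))
        else:  # block-inversion
            max_len = min(6, len(tokens) - 2)
            if max_len < 2:
                continue
            length = int(rng.integers(2, max_len + 1))
            start = int(rng.integers(len(tokens)))
            block = [tokens[(start + k) % len(tokens)] for k in range(length)]
            if anchor in [t for t, _ in block]:
                continue
            ev = block_inversion(block)
        try:
            current = apply_events(current, [ev])
        except ValueError:  # pragma: no cover - unresolvable context
            continue
        events.append(ev)
    return events


# ---------------------------------------------------------------------------
# Pattern scripts and the paper-like default study design
# ---------------------------------------------------------------------------

def default_pattern_scripts() -> dict[str, list[RearrangementEvent]]:
    """Scripted derived gene orders: minor tRNA shuffles for the true-shrimp
    patterns, multi-gene rearrangements (including a block inversion) for the
    mud/ghost-shrimp patterns."""
    ax1 = [
        translocation("trnL1", 1, "cox1", "trnL2", invert=True),
        translocation("trnV", 1, "trnM", "nad2", invert=True),
        translocation("cox3", 1, "nad3", "trnA"),
    ]
    ax2 = ax1 + [
        block_inversion((("nad1", -1), ("rrnL", -1), ("rrnS", -1))),
        translocation("trnD", -1, "trnS2", "rrnS", invert=True),
    ]
    return {
        "Pa": [translocation("trnG", 1, "trnA", "trnR")],
        "Ap1": [translocation("trnE", -1, "trnT", "trnP", invert=True)],
        "Ap2": [translocation("trnE", -1, "trnT", "trnP", invert=True),
                translocation("trnN", 1, "cob", "trnS2")],
        "Up": [translocation("trnT", 1, "trnW", "trnC"),
               translocation("trnR", -1, "nad6", "cob", invert=True),
               translocation("trnH", 1, "trnQ", "trnM", invert=True)],
        "Ax1": ax1,
        "Ax2": ax2,
    }


#: Pattern assignment used by the default study-like design, per group:
#: (pattern label, how many taxa), remaining taxa stay on the ground pattern.
_DEFAULT_PATTERN_PLAN: dict[str, list[tuple[str, int]]] = {
    "Axiidea": [("Ax1", 5), ("Ax2", 3)],
    "Gebiidea": [("Up", 4)],
    "Caridea": [("Pa", 3), ("Ap1", 1), ("Ap2", 1)],
}


def default_config(seed: int = 0, with_defects: bool = False) -> GeneratorConfig:
    """The study-like design: three focal ingroup infraorders of 8 + 5 + 20
    mitogenomes plus a 12-strong outgroup, with group-specific third-position
    AT bias (strongest in the burrowing-shrimp groups) and clade-confined
    derived gene-order patterns."""
    groups = [
        GroupSpec("Axiidea", 8, at3_bias=0.90),
        GroupSpec("Gebiidea", 5, at3_bias=0.80),
        GroupSpec("Caridea", 20, at3_bias=0.58),
        GroupSpec("Dendrobranchiata", 12, at3_bias=0.70, outgroup=True),
    ]
    cfg = GeneratorConfig(seed=seed, groups=groups,
                          pattern_scripts=default_pattern_scripts())
    for spec in groups:
        plan = list(_DEFAULT_PATTERN_PLAN.get(spec.label, []))
        taxa = [f"{spec.label}_sp{i + 1:02d}" for i in range(spec.n_taxa)]
        i = 0
        for label, count in plan:
            for _ in range(count):
                cfg.taxon_patterns[taxa[i]] = label
                i += 1
        for t in taxa[i:]:
            cfg.taxon_patterns[t] = "Gr"
    if with_defects:
        scripts = table_style_defects()
        carriers = ["Caridea_sp05", "Caridea_sp06", "Axiidea_sp04", "Axiidea_sp05"]
        for taxon, script in zip(carriers, scripts):
            cfg.defects[taxon] = script
    return cfg


# ---------------------------------------------------------------------------
# Fixture assembly: records + manifest + tree
# ---------------------------------------------------------------------------

def _caterpillar(leaves: list[str]) -> str:
    if len(leaves) == 1:
        return leaves[0]
    out = f"({leaves[0]},{leaves[1]})"
    for leaf in leaves[2:]:
        out = f"({out},{leaf})"
    return out


def _group_clade(members_by_pattern: dict[str, list[str]],
                 rng: np.random.Generator) -> str:
    clades = []
    for pat in sorted(members_by_pattern):
        leaves = sorted(members_by_pattern[pat])
        rng.shuffle(leaves)
        clades.append(_caterpillar(leaves))
    rng.shuffle(clades)
    return _caterpillar(clades)


def make_study_fixture(config: GeneratorConfig) -> StudyFixture:
    """Build the full synthetic study: one record per taxon, a manifest, and
    a seeded binary Newick tree in which every scripted pattern is
    clade-confined (set ``config.monophyletic = False`` to plant a violation
    for negative tests)."""
    root = np.random.SeedSequence(config.seed)
    taxa: list[tuple[str, GroupSpec]] = []
    for spec in config.groups:
        for i in range(spec.n_taxa):
            taxa.append((f"{spec.label}_sp{i + 1:02d}", spec))
    streams = root.spawn(len(taxa) + 1)
    tree_rng = np.random.default_rng(streams[-1])

    records: list[MitogenomeRecord] = []
    rows = []
    for idx, (taxon, spec) in enumerate(taxa):
        rng = np.random.default_rng(streams[idx])
        pattern = config.taxon_patterns.get(taxon, "Gr")
        rid = f"SYN{idx + 1:04d}.1"
        rec = build_record(config, taxon, group=spec.label, record_id=rid,
                           pattern=pattern if pattern != "Gr" else None, rng=rng)
        if taxon in config.defects:
            rec = plant_defects(rec, config.defects[taxon])
        records.append(rec)
        rows.append({"record_id": rid, "taxon": taxon, "group": spec.label,
                     "pattern": pattern,
                     "role": "outgroup" if spec.outgroup else "ingroup"})
    manifest = pd.DataFrame(rows)

    by_id = {r["taxon"]: r["record_id"] for r in rows}
    ingroup_clades = []
    outgroup_clades = []
    for spec in config.groups:
        members: dict[str, list[str]] = {}
        for taxon, s in taxa:
            if s.label != spec.label:
                continue
            members.setdefault(config.taxon_patterns.get(taxon, "Gr"), []).append(
                by_id[taxon])
        clade = _group_clade(members, tree_rng)
        (outgroup_clades if spec.outgroup else ingroup_clades).append(clade)
    tree = _caterpillar(outgroup_clades + [_caterpillar(ingroup_clades)]) + ";"

    if not config.monophyletic:
        # swap one derived-pattern leaf with a ground-pattern leaf so the
        # derived pattern stops being clade-confined
        derived = manifest[manifest["pattern"] != "Gr"]["record_id"]
        ground = manifest[manifest["pattern"] == "Gr"]["record_id"]
        if len(derived) and len(ground):
            a, b = derived.iloc[0], ground.iloc[0]
            tree = (tree.replace(a, "@@TMP@@").replace(b, a)
                        .replace("@@TMP@@", b))
    return StudyFixture(records=records, manifest=manifest, tree_newick=tree)
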