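"""Signed circular gene orders: extraction, canonicalization, breakpoint
distances, rearrangement-event inference, pattern clustering, and
pattern-vs-phylogeny consistency.

A gene order is a circular sequence of strand-signed tokens.  Orders are
compared in a canonical frame: the order is mirror-normalized so the anchor
gene (cox1 by default) lies on the plus strand, then rotated so the anchor
comes first.  Rearrangement inference is an explicit greedy heuristic — it
returns a deterministic, replayable event list, not a provably minimal one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .genbank_io import MitogenomeRecord
from .vocab import CONTROL_REGION

__all__ = [
    "SignedGeneOrder",
    "RearrangementEvent",
    "GeneOrderPattern",
    "PhyloTree",
    "ConsistencyReport",
    "GROUND_PATTERN",
    "extract_gene_order",
    "canonicalize",
    "breakpoint_distance",
    "infer_events",
    "apply_events",
    "group_patterns",
    "parse_newick",
    "pattern_tree_consistency",
    "EventInferenceError",
    "translocation",
    "inversion",
    "block_inversion",
    "duplication",
    "loss",
]

SignedToken = tuple[str, int]


def _base(token: str) -> str:
    """Strip the ordinal suffix used to disambiguate duplicated tokens."""
    return token.split(".")[0]


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular, strand-signed gene order.

    ``tokens`` is the order read from an arbitrary origin; two orders are
    considered equal when their canonical forms coincide (rotation and
    whole-molecule mirror are annotation artefacts, not rearrangements).
    """

    tokens: tuple[SignedToken, ...]
    include_cr: bool = True

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("gene order must be non-empty")

    def __len__(self) -> int:
        return len(self.tokens)

    def names(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.tokens)

    def canonical_key(self) -> tuple[SignedToken, ...]:
        anchor = _auto_anchor(self)
        if anchor is None:
            return self.tokens
        return _canonical_tokens(self.tokens, anchor)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGeneOrder):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())


@dataclass(frozen=True)
class RearrangementEvent:
    """One classified difference between two gene orders.

    ``genes`` holds the involved tokens with the signs they carry *after* the
    event (for a block inversion: the block as it reads once inverted).
    Contexts are (left flank, right flank) token pairs.
    """

    kind: str
    genes: tuple[SignedToken, ...]
    source_context: Optional[tuple[str, str]] = None
    target_context: Optional[tuple[str, str]] = None

    KINDS = ("translocation", "inversion", "translocation+inversion",
             "block-inversion", "duplication", "loss")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown event kind: {self.kind}")
        if not self.genes:
            raise ValueError("event must involve at least one gene")
        if self.kind == "block-inversion" and len(self.genes) < 2:
            raise ValueError("block-inversion requires >= 2 contiguous genes")


# Script-authoring helpers -------------------------------------------------

def translocation(token: str, sign: int, left: str, right: str,
                  invert: bool = False) -> RearrangementEvent:
    kind = "translocation+inversion" if invert else "translocation"
    return RearrangementEvent(kind, ((token, sign),), target_context=(left, right))


def inversion(token: str, new_sign: int) -> RearrangementEvent:
    return RearrangementEvent("inversion", ((token, new_sign),))


def block_inversion(current_block: Sequence[SignedToken]) -> RearrangementEvent:
    """Invert a contiguous block given as it currently reads."""
    after = tuple((t, -s) for t, s in reversed(list(current_block)))
    return RearrangementEvent("block-inversion", after)


def duplication(token: str, sign: int, left: str, right: str) -> RearrangementEvent:
    return RearrangementEvent("duplication", ((token, sign),), target_context=(left, right))


def loss(token: str) -> RearrangementEvent:
    return RearrangementEvent("loss", ((token, 0),))


@dataclass
class GeneOrderPattern:
    """An equivalence class of identical canonical gene orders."""

    label: str
    canonical_order: SignedGeneOrder
    members: list[str]
    events_vs_ground: list[RearrangementEvent] = field(default_factory=list)
    breakpoints_vs_ground: Optional[int] = None


class EventInferenceError(RuntimeError):
    """The greedy heuristic could not linearize the difference."""

    def __init__(self, message: str, partial: list[RearrangementEvent]):
        super().__init__(message)
        self.partial = partial


# ---------------------------------------------------------------------------
# The pancrustacean ground pattern (37 genes + control-region marker)
# ---------------------------------------------------------------------------

GROUND_PATTERN = SignedGeneOrder(tokens=(
    ("cox1", 1), ("trnL2", 1), ("cox2", 1), ("trnK", 1), ("trnD", 1),
    ("atp8", 1), ("atp6", 1), ("cox3", 1), ("trnG", 1), ("nad3", 1),
    ("trnA", 1), ("trnR", 1), ("trnN", 1), ("trnS1", 1), ("trnE", 1),
    ("trnF", -1), ("nad5", -1), ("trnH", -1), ("nad4", -1), ("nad4l", -1),
    ("trnT", 1), ("trnP", -1), ("nad6", 1), ("cob", 1), ("trnS2", 1),
    ("nad1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
    (CONTROL_REGION, 1), ("trnI", 1), ("trnQ", -1), ("trnM", 1), ("nad2", 1),
    ("trnW", 1), ("trnC", -1), ("trnY", -1),
))


def ground_pattern(include_cr: bool = True) -> SignedGeneOrder:
    """The ground pattern, with or without the control-region marker."""
    if include_cr:
        return GROUND_PATTERN
    return SignedGeneOrder(
        tokens=tuple(t for t in GROUND_PATTERN.tokens if t[0] != CONTROL_REGION),
        include_cr=False,
    )


# ---------------------------------------------------------------------------
# Extraction and canonicalization
# ---------------------------------------------------------------------------

def extract_gene_order(record: MitogenomeRecord, include_cr: bool = True) -> SignedGeneOrder:
    """Read the signed circular gene order off a record's annotation.

    Features are taken in genome order (origin-spanning features sort by
    start); duplicated tokens are disambiguated with an ordinal suffix in
    genome order (``trnQ``, ``trnQ.2``).
    """
    feats = [f for f in record.sorted_features()
             if f.name is not None and f.start is not None]
    if not include_cr:
        feats = [f for f in feats if f.name != CONTROL_REGION]
    if not feats:
        raise ValueError(f"{record.record_id}: no usable features to order")
    counts: dict[str, int] = {}
    tokens: list[SignedToken] = []
    for f in feats:
        n = counts.get(f.name, 0) + 1
        counts[f.name] = n
        tok = f.name if n == 1 else f"{f.name}.{n}"
        tokens.append((tok, 1 if f.strand >= 0 else -1))
    return SignedGeneOrder(tokens=tuple(tokens), include_cr=include_cr)


def _auto_anchor(order: SignedGeneOrder) -> Optional[str]:
    names = order.names()
    if "cox1" in names:
        return "cox1"
    unique = sorted(n for n in names if names.count(n) == 1)
    return unique[0] if unique else None


def _mirror(tokens: Sequence[SignedToken]) -> tuple[SignedToken, ...]:
    return tuple((t, -s) for t, s in reversed(list(tokens)))


def _rotate_to(tokens: Sequence[SignedToken], anchor: str) -> tuple[SignedToken, ...]:
    idx = next(i for i, (t, _) in enumerate(tokens) if t == anchor)
    return tuple(tokens[idx:]) + tuple(tokens[:idx])


def _canonical_tokens(tokens: Sequence[SignedToken], anchor: str) -> tuple[SignedToken, ...]:
    sign = next(s for t, s in tokens if t == anchor)
    toks = _mirror(tokens) if sign < 0 else tuple(tokens)
    return _rotate_to(toks, anchor)


def canonicalize(order: SignedGeneOrder, anchor: str = "cox1") -> SignedGeneOrder:
    """Rotate (and mirror, if the anchor reads on the minus strand) an order
    into its canonical frame.  Deterministic and idempotent.
    """
    names = order.names()
    if anchor not in names:
        raise ValueError(
            f"order lacks anchor gene {anchor!r}; supply an anchor present in the order"
        )
    if names.count(anchor) > 1:
        raise ValueError(f"anchor gene {anchor!r} is not unique in the order")
    return SignedGeneOrder(
        tokens=_canonical_tokens(order.tokens, anchor),
        include_cr=order.include_cr,
    )


# ---------------------------------------------------------------------------
# Breakpoint distance
# ---------------------------------------------------------------------------

def _adjacency(a: SignedToken, b: SignedToken) -> tuple[SignedToken, SignedToken]:
    """Orientation-normalized signed adjacency: (x,y) is identified with (-y,-x)."""
    alt = ((b[0], -b[1]), (a[0], -a[1]))
    return min((a, b), alt)


def _adjacency_set(tokens: Sequence[SignedToken]) -> set:
    n = len(tokens)
    return {_adjacency(tokens[i], tokens[(i + 1) % n]) for i in range(n)}


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of signed circular adjacencies of ``a`` absent from ``b``.

    Requires equal token multisets; symmetric; 0 iff canonical forms agree.
    """
    ma, mb = sorted(a.names()), sorted(b.names())
    if ma != mb:
        only_a = sorted(set(ma) - set(mb))
        only_b = sorted(set(mb) - set(ma))
        raise ValueError(
            f"token multisets differ: only in first {only_a}, only in second {only_b}"
        )
    return len(_adjacency_set(a.tokens) - _adjacency_set(b.tokens))


def _distance_tokens(x: Sequence[SignedToken], y: Sequence[SignedToken]) -> int:
    return len(_adjacency_set(x) - _adjacency_set(y))


# ---------------------------------------------------------------------------
# Event application (replay) and inference
# ---------------------------------------------------------------------------

def _find_token(tokens: Sequence[SignedToken], name: str) -> int:
    for i, (t, _) in enumerate(tokens):
        if t == name:
            return i
    raise ValueError(f"token {name!r} not present in order")


def _insert_after_context(tokens: list[SignedToken], item: SignedToken,
                          context: tuple[str, str]) -> list[SignedToken]:
    left, right = context
    names = [t for t, _ in tokens]
    if left in names:
        i = names.index(left)
        return tokens[: i + 1] + [item] + tokens[i + 1 :]
    if right in names:
        i = names.index(right)
        return tokens[:i] + [item] + tokens[i:]
    return tokens + [item]


def _apply_one(tokens: list[SignedToken], ev: RearrangementEvent) -> list[SignedToken]:
    if ev.kind == "loss":
        i = _find_token(tokens, ev.genes[0][0])
        return tokens[:i] + tokens[i + 1 :]
    if ev.kind == "inversion":
        name, new_sign = ev.genes[0]
        i = _find_token(tokens, name)
        out = list(tokens)
        out[i] = (name, new_sign if new_sign != 0 else -out[i][1])
        return out
    if ev.kind == "duplication":
        if ev.target_context is None:
            raise ValueError(f"duplication of {ev.genes[0][0]} lacks a target context")
        return _insert_after_context(list(tokens), ev.genes[0], ev.target_context)
    if ev.kind in ("translocation", "translocation+inversion"):
        if ev.target_context is None:
            raise ValueError(f"{ev.kind} of {ev.genes[0][0]} lacks a target context")
        name, sign = ev.genes[0]
        i = _find_token(tokens, name)
        rest = tokens[:i] + tokens[i + 1 :]
        return _insert_after_context(rest, (name, sign), ev.target_context)
    if ev.kind == "block-inversion":
        pre = _mirror(ev.genes)  # the block as it reads before inversion
        n, k = len(tokens), len(pre)
        doubled = list(tokens) + list(tokens)
        for i in range(n):
            if tuple(doubled[i : i + k]) == pre:
                rotated = doubled[i : i + n]
                rotated[0:k] = list(ev.genes)
                return rotated
        raise ValueError(
            f"block {[t for t, _ in pre]} not contiguous in order; cannot invert"
        )
    raise ValueError(f"unknown event kind {ev.kind}")  # pragma: no cover


def apply_events(order: SignedGeneOrder,
                 events: Iterable[RearrangementEvent]) -> SignedGeneOrder:
    """Apply events left-to-right.  Unresolvable events raise ValueError."""
    tokens = list(order.tokens)
    for ev in events:
        try:
            tokens = _apply_one(tokens, ev)
        except ValueError as exc:
            raise ValueError(f"cannot apply event {ev.kind} on "
                             f"{[g for g, _ in ev.genes]}: {exc}") from exc
    return SignedGeneOrder(tokens=tuple(tokens), include_cr=order.include_cr)


def _contexts(tokens: Sequence[SignedToken], idx: int) -> tuple[str, str]:
    n = len(tokens)
    return tokens[(idx - 1) % n][0], tokens[(idx + 1) % n][0]


def _neg(t: SignedToken) -> SignedToken:
    return (t[0], -t[1])


def _apply_block(work: list[SignedToken], start: int, length: int) -> list[SignedToken]:
    """Invert the circular segment of ``length`` tokens beginning at ``start``.

    Returns a rotation beginning at the inverted segment; rotations are
    equivalent under the circular semantics used throughout.
    """
    rot = work[start:] + work[:start]
    return [_neg(t) for t in reversed(rot[:length])] + rot[length:]


def _best_block_inversion(work: list[SignedToken], target: list[SignedToken],
                          d0: int) -> Optional[tuple[int, int, int]]:
    """Best (reduction, start, length) block inversion (length >= 2) of
    ``work``, or None if no inversion reduces the distance to ``target``.

    Scored incrementally: only the two boundary adjacencies change under a
    block inversion, so candidate reductions are O(1).  Preference: maximal
    reduction, then shortest block (a block and its circular complement reach
    the same mirror-equivalent order; the shorter description wins), then
    leftmost start.
    """
    n = len(work)
    tset = _adjacency_set(target)
    best: Optional[tuple[int, int, int]] = None
    best_key: Optional[tuple[int, int, int]] = None
    for start in range(n):
        rot = work[start:] + work[:start]
        prev = rot[-1]
        a1_missing = _adjacency(prev, rot[0]) not in tset
        for length in range(2, n):
            a2 = _adjacency(rot[length - 1], rot[length])
            b1 = _adjacency(prev, _neg(rot[length - 1]))
            b2 = _adjacency(_neg(rot[0]), rot[length])
            red = (a1_missing + (a2 not in tset)
                   - (b1 not in tset) - (b2 not in tset))
            if red <= 0:
                continue
            key = (red, -length, -start)
            if best_key is None or key > best_key:
                best_key = key
                best = (red, start, length)
    if best is None:
        return None
    # verify with an exact recount (boundary scoring ignores rare collisions)
    red, start, length = best
    exact = d0 - _distance_tokens(_apply_block(work, start, length), target)
    if exact <= 0:
        return None
    return (exact, start, length)


def infer_events(reference: SignedGeneOrder,
                 derived: SignedGeneOrder) -> list[RearrangementEvent]:
    """Greedy, deterministic inference of rearrangement events turning
    ``reference`` into ``derived``.

    Order of operations: losses and duplications first, then repeated rounds
    choosing the candidate move (block inversion, or single-gene
    translocation/inversion anchored at its flanks in the derived order) that
    maximally reduces the breakpoint distance.  Ties go to longer blocks and
    leftmost genome positions.  Replaying the returned list on ``reference``
    reproduces ``derived``'s canonical form.
    """
    events: list[RearrangementEvent] = []
    work = list(reference.tokens)
    target = list(derived.tokens)

    # 1) losses / duplications from the token multiset difference
    work_names = [t for t, _ in work]
    target_names = [t for t, _ in target]
    for name in sorted(set(work_names) - set(target_names)):
        i = _find_token(work, name)
        events.append(RearrangementEvent("loss", ((name, work[i][1]),),
                                         source_context=_contexts(work, i)))
        work = work[:i] + work[i + 1 :]
    for name in sorted(set(target_names) - set(work_names)):
        j = _find_token(target, name)
        ctx = _contexts(target, j)
        item = target[j]
        ev = RearrangementEvent("duplication", (item,), target_context=ctx)
        work = _insert_after_context(work, item, ctx)
        events.append(ev)

    if sorted(t for t, _ in work) != sorted(t for t, _ in target):
        raise EventInferenceError("token multisets irreconcilable", events)

    max_iter = 2 * len(work) + len(events) + 2
    for _ in range(max_iter):
        d0 = _distance_tokens(work, target)
        if d0 == 0:
            break

        blk = _best_block_inversion(work, target, d0)
        best_single = _best_single_move(work, target, d0, exhaustive=False)
        blk_red = blk[0] if blk else 0
        single_red = best_single[0][0] if best_single else 0

        if blk and blk_red >= single_red:
            red, start, length = blk
            new_work = _apply_block(work, start, length)
            events.append(RearrangementEvent("block-inversion",
                                             tuple(new_work[:length])))
            work = new_work
        elif best_single:
            _, cand, ev = best_single
            events.append(ev)
            work = cand
        else:
            found = _best_single_move(work, target, d0, exhaustive=True)
            if found is None:
                raise EventInferenceError(
                    f"no single move reduces breakpoint distance {d0}", events)
            _, cand, ev = found
            events.append(ev)
            work = cand
    else:
        raise EventInferenceError("did not converge within iteration budget", events)

    return events


def _classify_single(work: list[SignedToken], cand: list[SignedToken],
                     name: str, old_sign: int, new_sign: int) -> str:
    if [t for t, _ in cand] == [t for t, _ in work]:
        return "inversion"
    return "translocation" if new_sign == old_sign else "translocation+inversion"


def _best_single_move(work: list[SignedToken], target: list[SignedToken],
                      d0: int, exhaustive: bool):
    """Best single-gene candidate as ``(key, new_tokens, event)`` or None.

    Non-exhaustive mode only tries, for each gene, the positions flanking its
    neighbours in the target order (plus an in-place strand flip); exhaustive
    mode tries every insertion point and sign.  Ties break toward the leftmost
    genome position.
    """
    best = None
    for i, (name, sign) in enumerate(work):
        rest = work[:i] + work[i + 1 :]
        names_rest = [t for t, _ in rest]
        src = _contexts(work, i)
        j = _find_token(target, name)
        tsign = target[j][1]
        candidates: list[tuple[list[SignedToken], int]] = []
        if exhaustive:
            for pos in range(len(rest) + 1):
                for s in (1, -1):
                    candidates.append((rest[:pos] + [(name, s)] + rest[pos:], pos))
        else:
            tl, tr = _contexts(target, j)
            if tl in names_rest:
                k = names_rest.index(tl)
                candidates.append((rest[: k + 1] + [(name, tsign)] + rest[k + 1 :], k + 1))
            if tr in names_rest:
                k = names_rest.index(tr)
                candidates.append((rest[:k] + [(name, tsign)] + rest[k:], k))
            if tsign != sign:
                flipped = list(work)
                flipped[i] = (name, tsign)
                candidates.append((flipped, i))
        for cand, pos in candidates:
            if cand == work:
                continue
            red = d0 - _distance_tokens(cand, target)
            if red <= 0:
                continue
            k = _find_token(cand, name)
            new_sign = cand[k][1]
            kind = _classify_single(work, cand, name, sign, new_sign)
            ev = RearrangementEvent(kind, ((name, new_sign),),
                                    source_context=src,
                                    target_context=_contexts(cand, k))
            key = (red, -i, -pos)
            if best is None or key > best[0]:
                best = (key, cand, ev)
    return best


# ---------------------------------------------------------------------------
# Pattern clustering
# ---------------------------------------------------------------------------

def group_patterns(orders: Mapping[str, SignedGeneOrder],
                   labels: Optional[Mapping[str, str]] = None,
                   ground: Optional[SignedGeneOrder] = None,
                   infer: bool = True) -> list[GeneOrderPattern]:
    """Partition records by canonical gene-order equality.

    The class matching the ground pattern is labelled ``Gr``; other classes
    take the label supplied for their members (if unanimous) or ``P1``,
    ``P2``… in discovery order of the sorted record ids.  Each derived class
    carries the inferred events and breakpoint count versus the ground
    pattern.
    """
    if not orders:
        raise ValueError("at least one order is required")
    include_cr = next(iter(orders.values())).include_cr
    if ground is None:
        ground = ground_pattern(include_cr)
    classes: dict[tuple, list[str]] = {}
    reps: dict[tuple, SignedGeneOrder] = {}
    for rid in sorted(orders):
        key = orders[rid].canonical_key()
        classes.setdefault(key, []).append(rid)
        reps.setdefault(key, orders[rid])
    ground_key = ground.canonical_key()

    patterns: list[GeneOrderPattern] = []
    auto = itertools.count(1)
    used: set[str] = set()
    for key, members in classes.items():
        rep = reps[key]
        if key == ground_key:
            label = "Gr"
        else:
            cand = None
            if labels:
                got = {labels[m] for m in members if m in labels}
                if len(got) == 1:
                    cand = got.pop()
            while cand is None or cand in used:
                cand = f"P{next(auto)}"
            label = cand
        used.add(label)
        events: list[RearrangementEvent] = []
        bp: Optional[int] = None
        if key != ground_key:
            try:
                bp = (breakpoint_distance(ground, rep)
                      if sorted(ground.names()) == sorted(rep.names()) else None)
            except ValueError:
                bp = None
            if infer:
                events = infer_events(ground, rep)
        else:
            bp = 0
        patterns.append(GeneOrderPattern(label=label, canonical_order=rep,
                                         members=members, events_vs_ground=events,
                                         breakpoints_vs_ground=bp))
    patterns.sort(key=lambda p: (p.label != "Gr", p.label))
    return patterns


# ---------------------------------------------------------------------------
# Trees: parsing and Fitch-parsimony consistency
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """A rooted tree with uniquely labelled leaves (branch lengths ignored)."""

    tree: dendropy.Tree

    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; duplicate leaf labels are an error."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(labels) != len(set(labels)):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dups}")
    if any(lf.taxon is None for lf in tree.leaf_node_iter()):
        raise ValueError("unlabelled leaf in tree")
    tree.is_rooted = True
    return PhyloTree(tree=tree)


@dataclass
class ConsistencyReport:
    steps: int
    min_steps: int
    consistent: bool
    monophyletic: dict[str, bool]


def _fitch_steps(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    steps = 0
    sets: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sets[id(node)] = frozenset([states[node.taxon.label]])
            continue
        acc: Optional[frozenset] = None
        for child in node.child_nodes():
            s = sets[id(child)]
            if acc is None:
                acc = s
            else:
                inter = acc & s
                if inter:
                    acc = inter
                else:
                    acc = acc | s
                    steps += 1
        sets[id(node)] = acc if acc is not None else frozenset()
    return steps


def pattern_tree_consistency(tree: PhyloTree,
                             assignment: Mapping[str, str]) -> ConsistencyReport:
    """Treat the pattern label as one unordered multistate character and test
    whether it could have arisen without homoplasy on the tree.

    ``steps`` is the Fitch parsimony count; the minimum possible is
    (number of distinct labels - 1); a pattern is monophyletic iff its leaves
    form an exact clade.  Consistent iff steps equals the minimum.
    """
    leaves = tree.leaf_labels()
    missing = sorted(set(leaves) - set(assignment))
    if missing:
        raise ValueError(f"leaves without a pattern assignment: {missing}")
    labels = sorted({assignment[l] for l in leaves})
    min_steps = max(len(labels) - 1, 0)
    steps = _fitch_steps(tree.tree, assignment) if len(labels) > 1 else 0

    mono: dict[str, bool] = {}
    t = tree.tree
    for lab in labels:
        member_leaves = {l for l in leaves if assignment[l] == lab}
        if len(member_leaves) == 1:
            mono[lab] = True
            continue
        taxa = [lf.taxon for lf in t.leaf_node_iter()
                if lf.taxon.label in member_leaves]
        mrca = t.mrca(taxa=taxa)
        clade = {lf.taxon.label for lf in mrca.leaf_iter()}
        mono[lab] = clade == member_leaves
    return ConsistencyReport(steps=steps, min_steps=min_steps,
                             consistent=steps == min_steps, monophyletic=mono)
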