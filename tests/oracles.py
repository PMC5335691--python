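"""Independent oracles, kept free of the implementation paths they check."""

from __future__ import annotations

from mitokit.gene_order import SignedGeneOrder


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def naive_adjacency_set(tokens):
    """Brute-force signed adjacency set; (x,y) identified with (-y,-x)."""
    pairs = set()
    n = len(tokens)
    for i in range(n):
        x, y = tokens[i], tokens[(i + 1) % n]
        flipped = ((y[0], -y[1]), (x[0], -x[1]))
        pairs.add(min((x, y), flipped))
    return pairs


def naive_breakpoints(a, b):
    return len(naive_adjacency_set(a.tokens) - naive_adjacency_set(b.tokens))


def bfs_min_events(reference: SignedGeneOrder, derived: SignedGeneOrder,
                   max_depth: int) -> int | None:
    """Minimum number of single events (one-gene move with either sign, or a
    block inversion) from reference to derived, by breadth-first search over
    canonical forms.  Returns None if not reachable within max_depth."""
    target = derived.canonical_key()

    def successors(tokens):
        n = len(tokens)
        for i in range(n):
            name, _ = tokens[i]
            rest = tokens[:i] + tokens[i + 1:]
            for pos in range(len(rest) + 1):
                for s in (1, -1):
                    yield rest[:pos] + [(name, s)] + rest[pos:]
        for start in range(n):
            rot = tokens[start:] + tokens[:start]
            for length in range(2, n):
                yield [(t, -s) for t, s in reversed(rot[:length])] + rot[length:]

    start = list(reference.tokens)
    key0 = SignedGeneOrder(tokens=tuple(start)).canonical_key()
    if key0 == target:
        return 0
    seen = {key0}
    frontier = [start]
    for depth in range(1, max_depth + 1):
        nxt = []
        for state in frontier:
            for cand in successors(state):
                k = SignedGeneOrder(tokens=tuple(cand)).canonical_key()
                if k == target:
                    return depth
                if k not in seen:
                    seen.add(k)
                    nxt.append(cand)
        frontier = nxt
    return None
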