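"""Codon counting under the invertebrate mitochondrial code, relative
synonymous codon usage (RSCU), per-amino-acid chi-square comparisons among
groups, and classical (Torgerson) multidimensional scaling of RSCU profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .genbank_io import MitogenomeRecord
from .vocab import (
    CATEGORY_PCG,
    DEFAULT_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
)

__all__ = [
    "CodonCountTable",
    "RscuProfile",
    "AAComparisonResult",
    "MdsConfiguration",
    "GENETIC_CODE_ID",
    "pcg_sequences",
    "count_codons",
    "pool_counts",
    "compute_rscu",
    "chi_square_per_aa",
    "rscu_distance_matrix",
    "classical_mds",
]

GENETIC_CODE_ID = "invertebrate-mitochondrial-5"


@dataclass
class CodonCountTable:
    """Codon counts over the fixed 62-sense-codon vocabulary."""

    owner: str
    counts: dict[str, int]
    genetic_code: str = GENETIC_CODE_ID
    n_skipped: int = 0          # codons containing N
    n_internal_stops: int = 0   # TAA/TAG seen before the sequence end

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.counts)
        extra = set(self.counts) - set(SENSE_CODONS)
        if missing or extra:
            raise ValueError(
                f"counts must cover exactly the 62 sense codons "
                f"(missing {sorted(missing)[:3]}..., extra {sorted(extra)[:3]}...)"
            )

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())


@dataclass
class RscuProfile:
    """Per-codon relative synonymous usage; zero-total families are flagged."""

    owner: str
    rscu: dict[str, float]
    flagged_families: tuple[str, ...] = ()

    def vector(self) -> np.ndarray:
        return np.array([self.rscu[c] for c in SENSE_CODONS], dtype=float)


@dataclass
class AAComparisonResult:
    amino_acid: str
    codons: tuple[str, ...]
    groups: tuple[str, ...]
    table: np.ndarray
    statistic: Optional[float]
    df: Optional[int]
    p_value: Optional[float]
    computable: bool = True
    significant: Optional[bool] = None
    note: str = ""


@dataclass
class MdsConfiguration:
    owners: tuple[str, ...]
    coordinates: np.ndarray      # (n, k), column means 0
    eigenvalues: np.ndarray      # all eigenvalues, descending
    explained: float             # positive-eigenvalue mass captured by the k axes
    warning: str = ""


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def pcg_sequences(record: MitogenomeRecord) -> list[str]:
    """Strand-resolved coding sequences of all protein-coding features."""
    return [record.feature_sequence(f) for f in record.sorted_features()
            if f.category == CATEGORY_PCG and f.start is not None]


def count_codons(cds_list: Iterable[str], owner: str = "") -> CodonCountTable:
    """Count sense codons over in-frame coding sequences.

    Reading is in non-overlapping triplets from the first base.  A trailing
    partial codon (the truncated-stop case) is dropped, complete terminal
    stops are excluded, codons containing N are tallied separately, and TGA /
    AGA / AGG are counted as sense codons per the invertebrate mitochondrial
    code.  Internal stops are excluded from the table but counted as warnings.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    skipped = 0
    internal_stops = 0
    for seq in cds_list:
        s = seq.upper()
        if len(s) < 3:
            raise ValueError(f"coding sequence shorter than one codon: {s!r}")
        n_full = len(s) // 3
        for i in range(n_full):
            codon = s[3 * i : 3 * i + 3]
            if codon in STOP_CODONS:
                if i != n_full - 1:
                    internal_stops += 1
                continue
            if codon in counts:
                counts[codon] += 1
            else:
                skipped += 1
    return CodonCountTable(owner=owner, counts=counts,
                           n_skipped=skipped, n_internal_stops=internal_stops)


def pool_counts(tables: Sequence[CodonCountTable],
                grouping: Mapping[str, str]) -> tuple[dict[str, CodonCountTable], list[str]]:
    """Element-wise per-group sums.  Returns (pooled tables, excluded owners).

    Owners absent from ``grouping`` are excluded and reported; a group that
    ends up with no member tables is an error.
    """
    codes = {t.genetic_code for t in tables}
    if len(codes) > 1:
        raise ValueError(f"tables mix genetic codes: {sorted(codes)}")
    pooled: dict[str, CodonCountTable] = {}
    excluded: list[str] = []
    for t in tables:
        group = grouping.get(t.owner)
        if group is None:
            excluded.append(t.owner)
            continue
        if group not in pooled:
            pooled[group] = CodonCountTable(owner=group,
                                            counts={c: 0 for c in SENSE_CODONS})
        acc = pooled[group]
        for c, n in t.counts.items():
            acc.counts[c] += n
        acc.n_skipped += t.n_skipped
        acc.n_internal_stops += t.n_internal_stops
    empty = sorted(set(grouping.values()) - set(pooled))
    if empty:
        raise ValueError(f"groups with no member tables: {empty}")
    return pooled, sorted(excluded)


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

def compute_rscu(table: CodonCountTable,
                 families: Mapping[str, tuple[str, ...]] = DEFAULT_FAMILIES) -> RscuProfile:
    """RSCU = observed count / (family total / family size).

    Families with zero total get RSCU 0 for every member and are flagged, so
    profiles remain comparable 62-vectors.
    """
    rscu: dict[str, float] = {}
    flagged: list[str] = []
    for aa, codons in families.items():
        total = sum(table.counts[c] for c in codons)
        if total == 0:
            flagged.append(aa)
            for c in codons:
                rscu[c] = 0.0
            continue
        expected = total / len(codons)
        for c in codons:
            rscu[c] = table.counts[c] / expected
    return RscuProfile(owner=table.owner, rscu=rscu,
                       flagged_families=tuple(sorted(flagged)))


# ---------------------------------------------------------------------------
# Per-amino-acid chi-square comparison
# ---------------------------------------------------------------------------

def chi_square_per_aa(pooled: Mapping[str, CodonCountTable],
                      alpha: float = 0.001,
                      families: Mapping[str, tuple[str, ...]] = DEFAULT_FAMILIES,
                      ) -> list[AAComparisonResult]:
    """Pearson chi-square on the groups x synonymous-codons table, per amino
    acid, sorted by amino acid.  Groups with zero family total are dropped
    with a note; fewer than two usable rows marks the result not-computable.
    """
    if len(pooled) < 2:
        raise ValueError("at least two groups are required")
    groups = tuple(sorted(pooled))
    results: list[AAComparisonResult] = []
    for aa, codons in sorted(families.items()):
        full = np.array([[pooled[g].counts[c] for c in codons] for g in groups],
                        dtype=float)
        row_ok = full.sum(axis=1) > 0
        note = ""
        if not row_ok.all():
            dropped = [g for g, ok in zip(groups, row_ok) if not ok]
            note = f"dropped zero-total groups: {','.join(dropped)}"
        used_groups = tuple(g for g, ok in zip(groups, row_ok) if ok)
        table = full[row_ok]
        if len(used_groups) < 2:
            results.append(AAComparisonResult(
                aa, codons, used_groups, table, None, None, None,
                computable=False, note=note or "fewer than two usable groups"))
            continue
        col_ok = table.sum(axis=0) > 0
        used_codons = tuple(c for c, ok in zip(codons, col_ok) if ok)
        table = table[:, col_ok]
        if table.shape[1] < 2:
            results.append(AAComparisonResult(
                aa, codons, used_groups, table, None, None, None,
                computable=False,
                note=(note + "; " if note else "") + "fewer than two used codons"))
            continue
        if note and table.shape[1] < len(codons):
            note += f"; dropped unused codons"
        stat, p, df, _ = stats.chi2_contingency(table, correction=False)
        results.append(AAComparisonResult(
            aa, used_codons, used_groups, table, float(stat), int(df), float(p),
            computable=True, significant=bool(p < alpha), note=note))
    return results


# ---------------------------------------------------------------------------
# Distances and classical MDS
# ---------------------------------------------------------------------------

def rscu_distance_matrix(profiles: Sequence[RscuProfile]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Pairwise Euclidean distances between 62-codon RSCU vectors."""
    if len(profiles) < 2:
        raise ValueError("at least two profiles are required")
    keysets = {tuple(sorted(p.rscu)) for p in profiles}
    if len(keysets) > 1:
        raise ValueError("profiles carry different codon key sets")
    x = np.vstack([p.vector() for p in profiles])
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return d, tuple(p.owner for p in profiles)


def classical_mds(d: np.ndarray, k: int = 2,
                  owners: Optional[Sequence[str]] = None) -> MdsConfiguration:
    """Torgerson metric MDS: double-center -d^2/2, eigendecompose, embed.

    Deterministic: axes are ordered by descending eigenvalue and each axis is
    oriented so its largest-magnitude loading is positive.  If fewer than
    ``k`` positive eigenvalues exist, the configuration is padded with zero
    axes and a warning recorded.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    tol = max(n, 1) * np.finfo(float).eps * max(abs(evals[0]), 1.0)
    n_pos = int((evals > tol).sum())
    warning = ""
    k_eff = min(k, n_pos)
    if k_eff < k:
        warning = (f"only {n_pos} positive eigenvalues; "
                   f"padding {k - k_eff} axes with zeros")
    coords = np.zeros((n, k))
    for axis in range(k_eff):
        v = evecs[:, axis] * math.sqrt(evals[axis])
        if abs(v.min()) > abs(v.max()):
            v = -v
        coords[:, axis] = v
    coords -= coords.mean(axis=0, keepdims=True)

    pos_mass = float(evals[evals > tol].sum())
    captured = float(evals[:k_eff][evals[:k_eff] > tol].sum()) if k_eff else 0.0
    explained = captured / pos_mass if pos_mass > 0 else 0.0
    return MdsConfiguration(
        owners=tuple(owners) if owners is not None else tuple(str(i) for i in range(n)),
        coordinates=coords,
        eigenvalues=evals,
        explained=explained,
        warning=warning,
    )
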