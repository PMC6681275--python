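"""Protein-alignment utilities: motif-region extraction anchored on a
reference row, p-distances, and a neighbor-joining tree.

The tree method is deliberately simple and fully specified: proportion
of mismatched residues (pairwise gap deletion) followed by canonical
neighbor joining with the Q-criterion and Saitou–Nei branch lengths,
deterministic tie-breaking by the lowest index pair.  This is a
reimplementation choice for distance trees over protein MSAs, not a
claim of bit-identity with any particular Clustal-W output.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from skbio import TreeNode

from .errors import FormatError, InvariantError

GAP_CHARS = frozenset("-.")

#: motif-region strings seen in WRI1-family alignments
KNOWN_VARIANTS = ("VYL", "IYL", "GCL", "GVSA")


@dataclass
class ProteinAlignment:
    """An ordered multiple protein alignment ('-' or '.' for gaps)."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InvariantError("alignment needs at least 2 records")
        self.records = [(i, s.upper()) for i, s in self.records]
        n = len(self.records[0][1])
        if any(len(s) != n for _, s in self.records):
            raise InvariantError("aligned strings differ in length")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            raise InvariantError("duplicate record ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, record_id: str) -> str:
        for i, s in self.records:
            if i == record_id:
                return s
        raise KeyError(record_id)

    @classmethod
    def read(cls, path: str | os.PathLike, fmt: str = "fasta") -> "ProteinAlignment":
        """Read an aligned FASTA ('fasta') or Clustal ('clustal') file."""
        try:
            aln = AlignIO.read(str(path), fmt)
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        return cls([(r.id, str(r.seq)) for r in aln])


def locate_anchor(
    aln: ProteinAlignment, reference_id: str, motif: str
) -> tuple[int, int]:
    """Column interval (0-based, half-open) spelling ``motif`` in the reference.

    Reference gaps are skipped when reading residues, but gap columns
    that fall inside the motif span are included in the interval.  The
    first occurrence wins; extra occurrences raise a warning.
    """
    motif = motif.upper()
    row = aln.row(reference_id)
    cols = [c for c, ch in enumerate(row) if ch not in GAP_CHARS]
    degapped = "".join(row[c] for c in cols)
    starts = [
        i for i in range(len(degapped) - len(motif) + 1)
        if degapped[i : i + len(motif)] == motif
    ]
    if not starts:
        raise FormatError(
            f"motif {motif!r} not found in reference {reference_id!r}"
        )
    if len(starts) > 1:
        warnings.warn(
            f"motif {motif!r} occurs {len(starts)} times in {reference_id!r}; "
            "using the first occurrence",
            stacklevel=2,
        )
    i = starts[0]
    return cols[i], cols[i + len(motif) - 1] + 1


@dataclass(frozen=True)
class MotifRow:
    record_id: str
    region: str  # gaps preserved
    label: str


@dataclass
class AnchoredMotifTable:
    """Per-record motif regions extracted at fixed anchor columns."""

    anchor_columns: tuple[int, int]
    rows: list[MotifRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.record_id, r.region, r.label) for r in self.rows],
            columns=["record_id", "region", "label"],
        )


def extract_motif_table(
    aln: ProteinAlignment, anchor: tuple[int, int]
) -> AnchoredMotifTable:
    """Extract the anchor-column region from every record.

    The label is the degapped region ("absent" when all-gap); known
    variant strings such as VYL/IYL/GCL/GVSA therefore label themselves.
    """
    s, e = anchor
    if not (0 <= s < e <= aln.length):
        raise InvariantError(f"anchor {anchor} outside alignment columns")
    rows = []
    for rid, row in aln.records:
        region = row[s:e]
        degapped = "".join(ch for ch in region if ch not in GAP_CHARS)
        rows.append(MotifRow(rid, region, degapped if degapped else "absent"))
    return AnchoredMotifTable((s, e), rows)


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = tuple(self.ids)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise InvariantError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise InvariantError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise InvariantError("distance matrix diagonal must be zero")
        if np.any(v < 0):
            raise InvariantError("distances must be nonnegative")
        self.values = v

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.values[i, j])


def p_distance(aln: ProteinAlignment, gaps: str = "pairwise") -> DistanceMatrix:
    """Proportion of mismatched residues per pair.

    ``gaps="pairwise"`` (default) compares columns where both records are
    ungapped; ``gaps="complete"`` restricts to columns ungapped in every
    record.  A pair with zero comparable columns is an error.
    """
    if gaps not in {"pairwise", "complete"}:
        raise ValueError("gaps must be 'pairwise' or 'complete'")
    arr = np.array([list(s) for _, s in aln.records])
    ungapped = ~np.isin(arr, list(GAP_CHARS))
    if gaps == "complete":
        keep = ungapped.all(axis=0)
        arr = arr[:, keep]
        ungapped = ungapped[:, keep]
    n = len(aln.records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise FormatError(
                    f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
                )
            d[i, j] = d[j, i] = float((arr[i, both] != arr[j, both]).sum()) / m
    return DistanceMatrix(tuple(aln.ids), d)


@dataclass
class Tree:
    """An unrooted tree (trifurcating root node) with branch lengths."""

    root: TreeNode
    negative_clamped: bool = False

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.root.write(buf, format="newick")
        return buf.getvalue().strip()

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        return cls(TreeNode.read(io.StringIO(newick), format="newick"))

    def tip_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def tip_distances(self) -> DistanceMatrix:
        dm = self.root.tip_tip_distances()
        return DistanceMatrix(tuple(dm.ids), np.asarray(dm.data))

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the tip set on one side."""
        all_tips = frozenset(self.tip_names())
        out = set()
        for node in self.root.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                out.add(min(side, all_tips - side, key=sorted))
        return out


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Canonical neighbor joining (Q-criterion, Saitou–Nei branch lengths).

    Ties in the Q matrix break deterministically on the lowest index
    pair.  Negative branch lengths are clamped to zero and flagged via
    ``Tree.negative_clamped``.
    """
    n = len(d.ids)
    if n < 3:
        raise InvariantError("neighbor joining needs at least 3 taxa")
    D = d.values.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in d.ids]
    clamped = False

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(nodes) > 2:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major first minimum = lowest index pair
        i, j = divmod(flat, k)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (k - 2))
        lj = D[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = _clamp(li)
        child_j.length = _clamp(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(k) if x not in (i, j)]
        D2 = np.empty((k - 1, k - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = new_row[keep]
        D2[:-1, -1] = new_row[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [parent]

    a, b = nodes
    dist = _clamp(float(D[0, 1]))
    if len(a.children) == 0:  # pragma: no cover - n >= 3 keeps one internal
        a, b = b, a
    b.length = dist
    a.append(b)
    return Tree(a, clamped)


def write_newick(tree: Tree, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
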