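"""Alignment and clock-tree I/O.

Alignments are nucleotide matrices whose rows carry sampling ages parsed from
the sequence labels (suffix after a delimiter, interpreted either as a
calendar year or as an age before present).  Ages are normalised so the most
recent tip has age 0.  Columns are compressed to unique site patterns with
weights; every likelihood downstream operates on patterns.

Clock trees are rooted binary trees whose nodes carry ages in years before
the most recent tip; a branch's duration is the age difference between its
parent and child.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import dendropy
from Bio import AlignIO, SeqIO

__all__ = [
    "DateSpec",
    "Alignment",
    "ClockTree",
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "write_results",
    "read_results",
]

# IUPAC nucleotide codes as bitmasks over (A, C, G, T).
_A, _C, _G, _T = 1, 2, 4, 8
IUPAC_MASKS = {
    "A": _A, "C": _C, "G": _G, "T": _T, "U": _T,
    "R": _A | _G, "Y": _C | _T, "S": _C | _G, "W": _A | _T,
    "K": _G | _T, "M": _A | _C,
    "B": _C | _G | _T, "D": _A | _G | _T, "H": _A | _C | _T, "V": _A | _C | _G,
    "N": _A | _C | _G | _T, "-": _A | _C | _G | _T, "?": _A | _C | _G | _T,
    ".": _A | _C | _G | _T, "X": _A | _C | _G | _T,
}
_MASK_TO_CHAR = {_A: "A", _C: "C", _G: "G", _T: "T", 15: "N"}
for _ch, _m in IUPAC_MASKS.items():
    if _ch in "ACGTRYSWKMBDHV":
        _MASK_TO_CHAR.setdefault(_m, _ch)

BASES = "ACGT"


class AlignmentFormatError(ValueError):
    """Raised when sequences cannot be assembled into a rectangular alignment."""


class DateParseError(ValueError):
    """Raised when a tip date cannot be parsed from a label."""


class InvalidClockTreeError(ValueError):
    """Raised when node ages violate the parent-older-than-child ordering."""


@dataclass(frozen=True)
class DateSpec:
    """Rule for extracting a tip date from a sequence label.

    kind: "year" (calendar year, later = younger) or "age" (years before
    present, larger = older).  The date is the token after the last
    ``delimiter`` in the label.
    """

    kind: str = "age"
    delimiter: str = "|"

    def parse(self, label: str) -> float:
        if self.delimiter not in label:
            raise DateParseError(f"no date field in label {label!r}")
        token = label.rsplit(self.delimiter, 1)[1]
        try:
            return float(token)
        except ValueError as exc:
            raise DateParseError(f"unparseable date {token!r} in label {label!r}") from exc

    def to_ages(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.kind == "year":
            ages = values.max() - values
        elif self.kind == "age":
            ages = values - values.min()
        else:
            raise ValueError(f"unknown date kind {self.kind!r}")
        return ages


@dataclass
class Alignment:
    """A nucleotide alignment with per-taxon sampling ages and compressed patterns.

    ``codes`` holds IUPAC bitmasks (A=1, C=2, G=4, T=8, unions for ambiguity
    codes and gaps), shape (n_taxa, n_sites).
    """

    taxon_labels: list[str]
    ages: np.ndarray
    codes: np.ndarray
    patterns: np.ndarray = field(init=False)
    pattern_weights: np.ndarray = field(init=False)
    pattern_index: np.ndarray = field(init=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxon_labels):
            raise AlignmentFormatError("codes must be (n_taxa, n_sites)")
        if np.any(self.ages < 0):
            raise ValueError("ages must be non-negative")
        if self.n_taxa and not np.isclose(self.ages.min(), 0.0):
            raise ValueError("youngest tip must have age 0 (normalise first)")
        pats, idx, wts = np.unique(
            self.codes, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = pats
        self.pattern_index = idx.ravel()
        self.pattern_weights = wts

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]

    @classmethod
    def from_sequences(cls, labels, sequences, ages) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        if len(labels) != len(sequences):
            raise AlignmentFormatError("labels and sequences differ in number")
        n = len(labels)
        L = lengths.pop() if lengths else 0
        codes = np.empty((n, L), dtype=np.uint8)
        for i, seq in enumerate(sequences):
            for j, ch in enumerate(str(seq).upper()):
                try:
                    codes[i, j] = IUPAC_MASKS[ch]
                except KeyError as exc:
                    raise AlignmentFormatError(
                        f"invalid nucleotide {ch!r} in sequence {labels[i]!r}"
                    ) from exc
        return cls(list(labels), np.asarray(ages, dtype=float), codes)

    def sequence_str(self, i: int) -> str:
        return "".join(_MASK_TO_CHAR[m] for m in self.codes[i])

    def empirical_freqs(self) -> np.ndarray:
        """Base frequencies from unambiguous sites only; uniform fallback."""
        counts = np.zeros(4)
        for b, mask in enumerate((_A, _C, _G, _T)):
            counts[b] = np.count_nonzero(self.codes == mask)
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()

    def tip_partials(self) -> np.ndarray:
        """(n_taxa, n_patterns, 4) indicator partials over compatible states."""
        masks = self.patterns  # (n_taxa, n_patterns)
        out = np.empty(masks.shape + (4,), dtype=float)
        for b in range(4):
            out[..., b] = (masks >> b) & 1
        return out


def read_alignment(path, fmt: str = "fasta", date_spec: DateSpec | None = None) -> Alignment:
    """Read a FASTA or NEXUS alignment and parse tip ages from labels."""
    date_spec = date_spec or DateSpec()
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
    elif fmt == "nexus":
        records = list(AlignIO.read(path, "nexus"))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if not records:
        raise AlignmentFormatError(f"no sequences found in {path}")
    labels = [r.id if fmt == "fasta" else r.id for r in records]
    raw = np.array([date_spec.parse(lb) for lb in labels])
    ages = date_spec.to_ages(raw)
    return Alignment.from_sequences(labels, [str(r.seq) for r in records], ages)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(aln.taxon_labels):
            fh.write(f">{label}\n{aln.sequence_str(i)}\n")


class ClockTree:
    """Rooted binary tree with node ages in years before the most recent tip.

    Nodes are indexed 0..2n-2: tips 0..n-1 (in ``labels`` order), internal
    nodes n..2n-2.  ``parent[root] == -1``.
    """

    def __init__(self, labels: list[str], parent: np.ndarray, ages: np.ndarray):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.ages = np.asarray(ages, dtype=float)
        n = len(self.labels)
        self.n_tips = n
        self.n_nodes = 2 * n - 1 if n > 1 else 1
        if self.parent.shape[0] != self.n_nodes or self.ages.shape[0] != self.n_nodes:
            raise InvalidClockTreeError("parent/ages length must be 2*n_tips-1")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise InvalidClockTreeError("tree must have exactly one root")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(self.n_nodes):
            if v != self.root:
                self.children[self.parent[v]].append(v)
        for v in range(n):
            if self.children[v]:
                raise InvalidClockTreeError(f"tip {v} has children")
        for v in range(n, self.n_nodes):
            if len(self.children[v]) != 2:
                raise InvalidClockTreeError(f"internal node {v} is not binary")
        self.validate()
        self.postorder = self._postorder()

    def _postorder(self) -> np.ndarray:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.array(order[::-1], dtype=np.int64)

    def validate(self) -> None:
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and self.ages[p] < self.ages[v] - 1e-9:
                raise InvalidClockTreeError(
                    f"node {v} (age {self.ages[v]:g}) older than parent {p} "
                    f"(age {self.ages[p]:g})"
                )

    def durations(self) -> np.ndarray:
        """Per-node branch duration to its parent (root entry is 0)."""
        d = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        d[mask] = self.ages[self.parent[mask]] - self.ages[mask]
        return np.maximum(d, 0.0)

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def tree_length(self) -> float:
        """Sum of branch durations in years."""
        return float(self.durations().sum())

    def copy(self) -> "ClockTree":
        return ClockTree(self.labels, self.parent.copy(), self.ages.copy())

    # -- newick conversion -------------------------------------------------

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            if v < self.n_tips:
                core = self.labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core + ";"
            return f"{core}:{self.ages[self.parent[v]] - self.ages[v]:.10g}"

        return rec(self.root)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, tip_ages: dict[str, float] | None = None) -> "ClockTree":
        """Build from a dendropy tree whose edge lengths are time durations."""
        tips = [lf for lf in tree.leaf_node_iter()]
        labels = [lf.taxon.label if lf.taxon else lf.label for lf in tips]
        n = len(labels)
        index = {}
        for i, lf in enumerate(tips):
            index[id(lf)] = i
        nxt = n
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                continue
            index[id(nd)] = nxt
            nxt += 1
        parent = np.full(2 * n - 1, -1, dtype=np.int64)
        depth = np.zeros(2 * n - 1)
        for nd in tree.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                el = nd.edge.length if nd.edge.length is not None else 0.0
                depth[i] = depth[parent[i]] + el
        tip_ids = np.arange(n)
        tip_depth = depth[tip_ids]
        # youngest tip (deepest from root) has age 0
        root_age = tip_depth.max()
        ages = root_age - depth
        if np.any(ages < -1e-9):
            raise InvalidClockTreeError("edge durations imply a negative node age")
        ages = np.maximum(ages, 0.0)
        ct = cls(labels, parent, ages)
        if tip_ages is not None:
            for i, lb in enumerate(labels):
                want = tip_ages.get(lb)
                if want is not None and abs(want - ages[i]) > 1e-6 * max(1.0, root_age):
                    raise InvalidClockTreeError(
                        f"tip {lb!r}: newick age {ages[i]:g} != supplied age {want:g}"
                    )
        return ct


def read_tree(path_or_string, tip_ages: dict[str, float] | None = None) -> ClockTree:
    """Read a newick clock tree; branch lengths are time durations."""
    src = str(path_or_string)
    if src.strip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema="newick")
    else:
        tree = dendropy.Tree.get(path=src, schema="newick")
    return ClockTree.from_dendropy(tree, tip_ages=tip_ages)


def write_tree(tree: ClockTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def write_results(records: list[dict], path, columns: list[str] | None = None) -> None:
    """Write a list of records as a TSV with a deterministic column order."""
    if columns is None:
        columns = list(records[0].keys()) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for rec in records:
            fh.write("\t".join(_fmt(rec.get(c)) for c in columns) + "\n")


def read_results(path) -> list[dict]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        return []
    cols = lines[0].split("\t")
    out = []
    for ln in lines[1:]:
        if not ln:
            continue
        vals = ln.split("\t")
        rec = {}
        for c, v in zip(cols, vals):
            try:
                rec[c] = int(v)
            except ValueError:
                try:
                    rec[c] = float(v)
                except ValueError:
                    rec[c] = v
        out.append(rec)
    return out


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)
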