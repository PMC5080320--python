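"""Readers/writers for trees, alignments, fitted models and per-site score tables.

Alphabet convention used throughout the package: symbols are encoded as small
integers in the order A=0, C=1, G=2, T=3, gap=4; code 5 marks an unknown
residue (``N`` and all IUPAC ambiguity codes), i.e. missing data that is a
residue of some kind but definitely not a gap.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

logger = logging.getLogger("indelphase")

ALPHABET = "ACGT-"
A, C, G, T, GAP, UNKNOWN = 0, 1, 2, 3, 4, 5

_AMBIGUITY = set("NRYSWKMBDHV")

#: symbol -> integer code
SYMBOL_CODES: dict[str, int] = {
    "A": A, "C": C, "G": G, "T": T, "U": T,
    "-": GAP, ".": GAP, "*": GAP,
}
SYMBOL_CODES.update({c: UNKNOWN for c in _AMBIGUITY})


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree stored as parent-pointer arrays in preorder.

    ``parent[i]`` is the parent index of node ``i`` (-1 for the root, which is
    always node 0); ``lengths[i]`` is the length of the branch above node ``i``
    in expected substitutions per site (0.0 for the root); ``labels[i]`` is the
    leaf name, or ``None`` for internal nodes.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=np.float64)
        n = len(self.parent)
        if n == 0:
            raise ValueError("empty tree")
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise ValueError("tree must have exactly one root at index 0")
        if not np.all(np.isfinite(self.lengths)) or np.any(self.lengths < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            p = int(self.parent[i])
            if not 0 <= p < i:
                raise ValueError("nodes must be listed in preorder")
            self.children[p].append(i)
        labels = [lab for lab in self.labels if lab is not None]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        for i in range(n):
            if not self.children[i] and self.labels[i] is None:
                raise ValueError(f"leaf node {i} has no label")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    @property
    def preorder(self) -> list[int]:
        return list(range(self.n_nodes))

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths.copy(), list(self.labels))

    def scale_lengths(self, factor: float) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths * factor, list(self.labels))

    def node_depths(self) -> np.ndarray:
        """Path length from the root to every node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.lengths[i]
        return d

    # -- newick -------------------------------------------------------------

    def newick(self) -> str:
        def fmt(i: int) -> str:
            if self.is_leaf(i):
                body = self.labels[i]
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[i]) + ")"
            if i == 0:
                return body
            return f"{body}:{self.lengths[i]:.12g}"

        return fmt(0) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels: list = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise ValueError("missing branch length in newick input")
            lengths[i] = float(nd.edge.length)
        if nd.is_leaf():
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
            else:
                raise ValueError("unlabeled leaf in newick input")
    return PhyloTree(parent, lengths, labels)


def read_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths.

    Polytomies are resolved arbitrarily into binary nodes joined by
    zero-length branches (logged).  Malformed input raises ``ValueError``
    naming the offending position where the underlying parser provides one.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several error types
        offset = ""
        col = getattr(exc, "col_num", None)
        if col is not None:
            offset = f" at column {col}"
        raise ValueError(f"newick parse error{offset}: {exc}") from exc
    n_poly = sum(1 for nd in dtree if len(nd.child_nodes()) > 2)
    if n_poly:
        dtree.resolve_polytomies(limit=2, update_bipartitions=False)
        for nd in dtree:
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = 0.0
        logger.info("resolved %d polytomies with zero-length branches", n_poly)
    # dendropy may leave a unifurcating root from "(...)extra;" forms
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, path: str | Path | None = None) -> str:
    text = tree.newick()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A gapped DNA alignment for one gene family (integer-coded matrix)."""

    family_id: str
    names: list[str]
    data: np.ndarray  # int8 (n_seqs, n_cols), codes 0..5
    n_dropped_allgap: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.names):
            raise ValueError("alignment matrix shape does not match names")
        if self.data.size and not np.all((self.data >= 0) & (self.data <= UNKNOWN)):
            raise ValueError("invalid symbol code in alignment")

    @property
    def n_seqs(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def row_strings(self) -> list[str]:
        table = np.array(list(ALPHABET + "N"))
        return ["".join(table[row]) for row in self.data]

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.names, self.row_strings()):
                fh.write(f">{name}\n{row}\n")


def encode_sequence(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        code = SYMBOL_CODES.get(ch)
        if code is None:
            raise ValueError(f"unsupported symbol {ch!r} in sequence")
        out[i] = code
    return out


def drop_allgap_columns(data: np.ndarray) -> tuple[np.ndarray, int]:
    if data.size == 0:
        return data, 0
    allgap = np.all(data == GAP, axis=0)
    n = int(allgap.sum())
    if n:
        data = data[:, ~allgap]
    return data, n


def make_alignment(family_id: str, names: Sequence[str], rows: Sequence[str]) -> Alignment:
    """Build an alignment from raw sequence strings, applying the
    normalization and all-gap-column rules of :func:`read_fasta_alignment`."""
    if not names:
        raise ValueError("empty alignment")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        bad = [n for n, r in zip(names, rows) if len(r) != len(rows[0])]
        raise ValueError(f"ragged alignment: sequences {bad} differ in length")
    data = np.stack([encode_sequence(r) for r in rows])
    data, n_dropped = drop_allgap_columns(data)
    if n_dropped:
        logger.info("%s: dropped %d all-gap columns", family_id, n_dropped)
    return Alignment(family_id, list(names), data, n_dropped)


def read_fasta_alignment(path: str | Path, family_id: str | None = None) -> Alignment:
    """Read a FASTA alignment; symbols are uppercased, ``.``/``*`` become
    gaps, and ambiguity codes map to unknown.  All-gap columns are dropped."""
    path = Path(path)
    if family_id is None:
        family_id = path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    names = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return make_alignment(family_id, names, rows)


@dataclass
class AlignmentSet:
    """A list of (alignment, tree) pairs forming one analysis dataset."""

    families: list[tuple[Alignment, PhyloTree]]

    def __post_init__(self) -> None:
        for aln, tree in self.families:
            missing = set(aln.names) - set(tree.leaf_labels)
            if missing:
                raise ValueError(
                    f"{aln.family_id}: sequences {sorted(missing)} not in tree")

    @property
    def total_sites(self) -> int:
        return sum(aln.n_cols for aln, _ in self.families)

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[tuple[Alignment, PhyloTree]]:
        return iter(self.families)


def max_gap_run(row: np.ndarray) -> int:
    """Length of the longest run of gap codes in one sequence row."""
    gaps = np.concatenate(([0], (row == GAP).astype(np.int8), [0]))
    d = np.diff(gaps)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return int((ends - starts).max()) if starts.size else 0


def filter_dataset(
    pairs: Iterable[tuple[Alignment, PhyloTree]],
    max_gap_run_len: int = 30,
    min_sequences: int = 5,
    required_species: str | None = None,
) -> tuple[AlignmentSet, dict[str, int]]:
    """Keep alignments that contain the required species, have at least
    ``min_sequences`` rows, and whose every sequence's gap runs are all
    strictly shorter than ``max_gap_run_len``.

    Returns the retained set and per-criterion rejection counts.
    """
    if max_gap_run_len < 1:
        raise ValueError("max_gap_run_len must be >= 1")
    kept: list[tuple[Alignment, PhyloTree]] = []
    rejected = {"missing_species": 0, "too_few_sequences": 0, "long_gap_run": 0}
    for aln, tree in pairs:
        if required_species is not None and required_species not in aln.names:
            rejected["missing_species"] += 1
            continue
        if aln.n_seqs < min_sequences:
            rejected["too_few_sequences"] += 1
            continue
        if any(max_gap_run(row) >= max_gap_run_len for row in aln.data):
            rejected["long_gap_run"] += 1
            continue
        kept.append((aln, tree))
    if not kept:
        logger.warning("filter_dataset: no alignments retained")
    return AlignmentSet(kept), rejected


# ---------------------------------------------------------------------------
# per-site score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("family_id", "column", "test",
                 "lnl_null", "lnl_alt", "scale", "pvalue", "score")


@dataclass
class SiteScore:
    """One per-column likelihood-ratio test result.

    ``column`` is 1-based within the family's alignment.  ``test`` is
    ``"subst"`` or ``"indel"``.  ``score`` is the signed log10 p-value
    (positive = accelerated under the default sign convention).
    """

    family_id: str
    column: int
    test: str
    lnl_null: float
    lnl_alt: float
    scale: float
    pvalue: float
    score: float


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_site_scores(scores: Iterable[SiteScore], path: str | Path) -> int:
    """Stream score records to a TSV file; returns the number written."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for s in scores:
            fh.write(
                f"{s.family_id}\t{s.column}\t{s.test}\t{_fmt(s.lnl_null)}\t"
                f"{_fmt(s.lnl_alt)}\t{_fmt(s.scale)}\t{_fmt(s.pvalue)}\t"
                f"{_fmt(s.score)}\n")
            n += 1
    return n


def read_site_scores(path: str | Path) -> Iterator[SiteScore]:
    """Lazily iterate score records from a TSV file (constant memory)."""
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != SCORE_COLUMNS:
            unknown = set(header) - set(SCORE_COLUMNS)
            raise ValueError(f"unknown score table columns: {sorted(unknown)}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            yield SiteScore(f[0], int(f[1]), f[2], float(f[3]), float(f[4]),
                            float(f[5]), float(f[6]), float(f[7]))


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

_MODEL_PARAMS = {
    "F84": {"alpha", "beta"},
    "HKYG": {"kappa", "sigma"},
    "F84E_RELAXED": {"alpha", "beta", "lambda", "mu", "p"},
}


@dataclass
class ModelFile:
    """On-disk representation of a fitted model (key-value text format)."""

    model: str
    params: dict
    frequencies: np.ndarray
    provenance: dict
    di_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODEL_PARAMS:
            raise ValueError(f"unknown model {self.model!r}")
        expect = _MODEL_PARAMS[self.model]
        if set(self.params) != expect:
            raise ValueError(
                f"{self.model} expects parameters {sorted(expect)}, "
                f"got {sorted(self.params)}")
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        if not self.provenance:
            raise ValueError("provenance block is mandatory")


def dataset_hash(aset: AlignmentSet) -> str:
    h = hashlib.sha256()
    for aln, tree in aset:
        h.update(aln.family_id.encode())
        h.update(aln.data.tobytes())
        h.update(tree.newick().encode())
    return h.hexdigest()[:16]


def write_model_file(mf: ModelFile, path: str | Path) -> None:
    lines = [f"model\t{mf.model}"]
    for k in sorted(mf.params):
        lines.append(f"{k}\t{mf.params[k]:.12g}")
    tags = "ACGT-"[: len(mf.frequencies)]
    for sym, f in zip(tags, mf.frequencies):
        lines.append(f"freq_{sym}\t{f:.12g}")
    if mf.di_ratio is not None:
        lines.append(f"di_ratio\t{mf.di_ratio:.12g}")
    for k in sorted(mf.provenance):
        lines.append(f"prov_{k}\t{mf.provenance[k]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_model_file(path: str | Path) -> ModelFile:
    params: dict = {}
    freqs: dict = {}
    prov: dict = {}
    model = None
    di_ratio = None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition("\t")
        if key == "model":
            model = value
        elif key.startswith("freq_"):
            freqs[key[5:]] = float(value)
        elif key.startswith("prov_"):
            prov[key[5:]] = value
        elif key == "di_ratio":
            di_ratio = float(value)
        else:
            params[key] = float(value)
    if model is None:
        raise ValueError(f"{path}: missing 'model' line")
    order = "ACGT-"[: len(freqs)]
    frequencies = np.array([freqs[s] for s in order])
    return ModelFile(model, params, frequencies, prov, di_ratio)
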