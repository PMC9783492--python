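"""Sequence-level characterization of EF-hand domains.

This module covers the sequence track of the analysis: extracting EF-hand
domains from channel sequences, classifying residue chemistry (Zappo-style
classes), computing pairwise identity/similarity matrices from a multiple
alignment, average-linkage (UPGMA) clustering of the domains, and scanning
for the canonical 12-residue EF-hand Ca2+-binding loop motif.

Coordinates are 1-based and inclusive throughout sequence space, following
the ``accession:start-end`` convention used for protein subsequence ranges.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

from .errors import AlignmentError, FastaFormatError, SpanError

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_ALLOWED = STANDARD_AA | {"X"}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class ResidueClass(Enum):
    """Physicochemical residue classes (Zappo colouring scheme)."""

    NEGATIVE = "negative"      # D, E
    POSITIVE = "positive"      # K, R, H
    POLAR = "polar"            # S, T, N, Q
    AROMATIC = "aromatic"      # F, W, Y
    HYDROPHOBIC = "hydrophobic"  # A, V, L, I, M
    CYSTEINE = "cysteine"      # C
    PRO_GLY = "pro_gly"        # P, G
    UNKNOWN = "unknown"        # X or anything non-standard


_CLASS_OF: dict[str, ResidueClass] = {}
for _letters, _cls in [
    ("DE", ResidueClass.NEGATIVE),
    ("KRH", ResidueClass.POSITIVE),
    ("STNQ", ResidueClass.POLAR),
    ("FWY", ResidueClass.AROMATIC),
    ("AVLIM", ResidueClass.HYDROPHOBIC),
    ("C", ResidueClass.CYSTEINE),
    ("PG", ResidueClass.PRO_GLY),
]:
    for _aa in _letters:
        _CLASS_OF[_aa] = _cls

#: Formal charge per residue class (side-chain, integer convention).
FORMAL_CHARGE = {ResidueClass.NEGATIVE: -1, ResidueClass.POSITIVE: +1}


def classify_residue(aa: str) -> ResidueClass:
    """Map a one-letter residue code to its chemical class.

    Histidine is counted as positive. Unknown letters (including ``X``)
    return :attr:`ResidueClass.UNKNOWN`; non-standard letters additionally
    emit a warning.
    """
    aa = aa.upper()
    try:
        return _CLASS_OF[aa]
    except KeyError:
        if aa != "X":
            warnings.warn(f"unknown residue letter {aa!r}; classified UNKNOWN")
        return ResidueClass.UNKNOWN


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence with an accession-like identifier."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("sequence id must be non-empty")
        if not self.residues:
            raise FastaFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise FastaFormatError(
                f"sequence {self.id!r} contains non-standard letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainSpan:
    """A 1-based inclusive residue range on a parent sequence."""

    parent_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise SpanError(f"invalid span {self.start}-{self.end} (need 1 <= start <= end)")

    def __len__(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Residues are uppercased and trailing ``*`` stop codons stripped.
    Duplicate ids and content before the first header are format errors
    naming the offending line/record.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaFormatError(f"{path}: line {lineno} precedes the first '>' header")
        break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaFormatError(f"{path}: record {i} has an empty header")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate sequence id {rec.id!r} (record {i})")
        seen.add(rec.id)
        residues = str(rec.seq).upper().rstrip("*")
        records.append(SequenceRecord(id=rec.id, residues=residues, description=rec.description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description and rec.description != rec.id else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def extract_domain(record: SequenceRecord, span: DomainSpan) -> SequenceRecord:
    """Extract the subsequence covered by ``span`` (1-based inclusive).

    The returned record's id encodes parent and range, e.g. ``AT4G03560.1:322-398``.
    """
    if span.parent_id != record.id:
        raise SpanError(f"span parent {span.parent_id!r} does not match record {record.id!r}")
    if span.end > len(record):
        raise SpanError(
            f"span {span.start}-{span.end} exceeds length {len(record)} of {record.id!r}"
        )
    residues = record.residues[span.start - 1 : span.end]
    return SequenceRecord(
        id=f"{record.id}:{span.start}-{span.end}",
        residues=residues,
        description=f"domain {span.start}-{span.end} of {record.id}",
    )


@dataclass(frozen=True)
class SiteComposition:
    """Chemical-class composition of a set of designated site positions."""

    counts: dict
    net_charge: int

    def count(self, cls: ResidueClass) -> int:
        return self.counts.get(cls, 0)


def site_composition(domain: SequenceRecord, site_positions: Sequence[int]) -> SiteComposition:
    """Count residue classes at the given 1-based positions and the net formal charge.

    Net charge counts NEGATIVE residues as -1 and POSITIVE as +1 (His included,
    consistent with :func:`classify_residue`); all other classes are neutral.
    """
    counts: Counter = Counter()
    net = 0
    for pos in site_positions:
        if not (1 <= pos <= len(domain)):
            raise SpanError(f"site position {pos} outside 1..{len(domain)} of {domain.id!r}")
        cls = classify_residue(domain.residues[pos - 1])
        counts[cls] += 1
        net += FORMAL_CHARGE.get(cls, 0)
    return SiteComposition(counts=dict(counts), net_charge=net)


@dataclass(frozen=True)
class MultipleAlignment:
    """A gapped multiple sequence alignment ('-' is the gap character)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


def read_alignment(path: str | Path, fmt: str = "fasta") -> MultipleAlignment:
    """Read an aligned-FASTA (``fmt='fasta'``) or Clustal (``fmt='clustal'``) alignment."""
    aln = AlignIO.read(str(path), fmt)
    return MultipleAlignment(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
    )


@dataclass(frozen=True)
class IdentitySimilarityMatrix:
    """Pairwise percent identity and similarity for an alignment.

    ``identity[i, j]`` and ``similarity[i, j]`` are percentages in [0, 100];
    both matrices are symmetric with 100 on the diagonal and
    ``similarity >= identity`` elementwise.
    """

    ids: tuple[str, ...]
    identity: np.ndarray
    similarity: np.ndarray

    def to_csv(self, path: str | Path, which: str = "identity") -> None:
        import pandas as pd

        mat = self.identity if which == "identity" else self.similarity
        pd.DataFrame(mat, index=list(self.ids), columns=list(self.ids)).to_csv(path)


def pairwise_identity_similarity(alignment: MultipleAlignment) -> IdentitySimilarityMatrix:
    """Percent identity and similarity for every sequence pair in an alignment.

    For a pair of rows, the denominator is the number of columns where at
    least one of the two rows is non-gap.  Identity counts columns where both
    rows carry the identical non-gap residue; similarity counts columns where
    both are non-gap and the residue pair is identical or has a positive
    BLOSUM62 score.  Pairs with an empty denominator score 0/0 -> 100 only on
    the diagonal; off-diagonal empty pairs are reported as 0.
    """
    n = len(alignment.ids)
    if n < 2:
        raise AlignmentError("need at least two rows for pairwise comparison")
    rows = alignment.rows
    identity = np.full((n, n), 100.0)
    similarity = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            denom = ident = simil = 0
            for ca, cb in zip(a, b):
                if ca == "-" and cb == "-":
                    continue
                denom += 1
                if ca == "-" or cb == "-":
                    continue
                same = ca == cb
                if same:
                    ident += 1
                if same or _BLOSUM62[ca, cb] > 0:
                    simil += 1
            pid = 100.0 * ident / denom if denom else 0.0
            psim = 100.0 * simil / denom if denom else 0.0
            identity[i, j] = identity[j, i] = pid
            similarity[i, j] = similarity[j, i] = psim
    return IdentitySimilarityMatrix(ids=alignment.ids, identity=identity, similarity=similarity)


@dataclass(frozen=True)
class ClusterTree:
    """A UPGMA merge tree.

    ``merges`` lists, in merge order, tuples ``(left_leaves, right_leaves,
    height)`` where the leaf sets are sorted tuples of ids and ``height`` is
    the average-linkage distance at which the two clusters were joined.
    """

    leaf_ids: tuple[str, ...]
    merges: tuple[tuple[tuple[str, ...], tuple[str, ...], float], ...]

    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depths are merge height / 2."""
        node_of: dict[tuple[str, ...], tuple[str, float]] = {
            (leaf,): (leaf, 0.0) for leaf in self.leaf_ids
        }
        last = None
        for left, right, height in self.merges:
            depth = height / 2.0
            ltxt, ldepth = node_of.pop(left)
            rtxt, rdepth = node_of.pop(right)
            txt = f"({ltxt}:{depth - ldepth:.6g},{rtxt}:{depth - rdepth:.6g})"
            key = tuple(sorted(left + right))
            node_of[key] = (txt, depth)
            last = key
        if last is None:  # single leaf, no merges
            return f"{self.leaf_ids[0]};"
        return node_of[last][0] + ";"


def cluster_upgma(matrix: IdentitySimilarityMatrix) -> ClusterTree:
    """UPGMA (average-linkage) clustering on distance = 100 - identity.

    Deterministic: among equally close cluster pairs the lexicographically
    smallest pair of cluster labels (sorted leaf-id tuples) is merged first.
    """
    ids = matrix.ids
    n = len(ids)
    if n < 2:
        raise AlignmentError("need at least two leaves to cluster")
    dist: dict[frozenset, float] = {}
    clusters: dict[tuple[str, ...], frozenset[str]] = {(i,): frozenset([i]) for i in ids}
    sizes: dict[tuple[str, ...], int] = {(i,): 1 for i in ids}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset([(ids[i],), (ids[j],)])] = 100.0 - matrix.identity[i, j]
    merges = []
    while len(clusters) > 1:
        labels = sorted(clusters)
        best = None
        for ai in range(len(labels)):
            for bi in range(ai + 1, len(labels)):
                a, b = labels[ai], labels[bi]
                d = dist[frozenset([a, b])]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        new = tuple(sorted(a + b))
        na, nb = sizes[a], sizes[b]
        for other in labels:
            if other in (a, b):
                continue
            da = dist.pop(frozenset([a, other]))
            db = dist.pop(frozenset([b, other]))
            dist[frozenset([new, other])] = (na * da + nb * db) / (na + nb)
        dist.pop(frozenset([a, b]))
        del clusters[a], clusters[b], sizes[a], sizes[b]
        clusters[new] = frozenset(new)
        sizes[new] = na + nb
        merges.append((a, b, d))
    return ClusterTree(leaf_ids=tuple(sorted(ids)), merges=tuple(merges))


# Canonical EF-hand Ca2+-binding loop: 12 residues, PROSITE PS00018-style.
# Position 1 anchors the loop with Asp; positions 1,3,5,7,9,12 supply the
# coordinating oxygens in calmodulin-family EF-hands.
EF_LOOP_PATTERN = re.compile(
    r"D"            # 1: invariant Asp (x coordination)
    r"."            # 2
    r"[DNS]"        # 3: y coordination
    r"[^ILVFYW]"    # 4
    r"[DENSTG]"     # 5: z coordination
    r"[DENQGHRK]"   # 6
    r"[^GP]"        # 7
    r"[LIVMC]"      # 8
    r"[DENQSTAGC]"  # 9
    r".."           # 10, 11
    r"[DE]"         # 12: bidentate -z coordination
)

EF_LOOP_LENGTH = 12


@dataclass(frozen=True)
class MotifHit:
    """A canonical EF-hand loop match."""

    parent_id: str
    loop_start: int  # 1-based
    loop_sequence: str


def scan_ef_loops(record: SequenceRecord) -> list[MotifHit]:
    """Find all (possibly overlapping) canonical EF-hand loop windows.

    An empty list is a legitimate result — degenerate EF-hand-like domains
    (TPC1b-type) are expected to yield no hits — and is returned, not raised.
    """
    hits = []
    seq = record.residues
    for start in range(0, len(seq) - EF_LOOP_LENGTH + 1):
        window = seq[start : start + EF_LOOP_LENGTH]
        if EF_LOOP_PATTERN.fullmatch(window):
            hits.append(MotifHit(parent_id=record.id, loop_start=start + 1, loop_sequence=window))
    return hits
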