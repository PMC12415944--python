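"""Alignment containers, FASTA I/O, concatenation, haplotype deduplication.

An :class:`Alignment` is a rectangular nucleotide character matrix with named
gene partitions (0-based half-open column ranges).  Columns are stored as a
``numpy`` byte matrix so that downstream distance and site-count operations
vectorise over the whole alignment.

This module also provides the building blocks of the gene-to-genome scaling
experiment: seeded random-order concatenation of per-gene alignments, the
logarithmic ladder of sub-alignment sizes, and prefix subsetting so that
smaller sub-alignments are nested inside larger ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "AlignmentFormatError",
    "GenePartition",
    "HaplotypeMap",
    "read_fasta_alignment",
    "read_gene_alignments",
    "write_fasta",
    "write_partitions_raxml",
    "write_partitions_tsv",
    "concatenate",
    "split_by_partitions",
    "deduplicate_haplotypes",
    "size_ladder",
    "subset_prefix",
]

GAP = ord("-")


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments, duplicate ids and similar format faults."""


@dataclass(frozen=True)
class GenePartition:
    """A named, 0-based half-open column range of an alignment."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"partition {self.name!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Alignment:
    """Rectangular character matrix over samples, with optional gene partitions.

    Parameters
    ----------
    sample_ids:
        Ordered unique sample identifiers, one per row.
    matrix:
        ``uint8`` array of shape ``(n_samples, n_columns)`` holding uppercase
        ASCII codes (``A C G T - N`` and IUPAC ambiguity letters).
    partitions:
        Non-overlapping named column ranges (may be empty).
    """

    sample_ids: list[str]
    matrix: np.ndarray
    partitions: list[GenePartition] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentFormatError(
                f"{len(self.sample_ids)} ids for {self.matrix.shape[0]} rows"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise AlignmentFormatError(f"duplicate sample ids: {dupes}")
        ends = sorted((p.start, p.end, p.name) for p in self.partitions)
        for (s0, e0, n0), (s1, e1, n1) in zip(ends, ends[1:]):
            if s1 < e0:
                raise AlignmentFormatError(
                    f"partitions {n0!r} and {n1!r} overlap"
                )
        for p in self.partitions:
            if p.end > self.n_columns:
                raise AlignmentFormatError(
                    f"partition {p.name!r} ends at {p.end} beyond "
                    f"alignment width {self.n_columns}"
                )
        names = [p.name for p in self.partitions]
        if len(set(names)) != len(names):
            raise AlignmentFormatError("duplicate partition names")

    @classmethod
    def from_strings(
        cls,
        sample_ids: Sequence[str],
        rows: Sequence[str],
        partitions: Iterable[GenePartition] = (),
    ) -> "Alignment":
        rows = [r.upper() for r in rows]
        if len({len(r) for r in rows}) > 1:
            raise AlignmentFormatError("rows have unequal lengths")
        mat = np.frombuffer("".join(rows).encode(), dtype=np.uint8)
        mat = mat.reshape(len(rows), -1) if rows else mat.reshape(0, 0)
        return cls(list(sample_ids), mat.copy(), list(partitions))

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return self.matrix[i].tobytes().decode()

    def rows(self) -> list[str]:
        return [self.matrix[i].tobytes().decode() for i in range(self.n_samples)]

    def gene(self, name: str) -> "Alignment":
        """Extract one gene partition as a stand-alone alignment."""
        for p in self.partitions:
            if p.name == name:
                return Alignment(
                    list(self.sample_ids),
                    self.matrix[:, p.start : p.end].copy(),
                    [GenePartition(p.name, 0, p.length)],
                )
        raise KeyError(name)


#: representative sample id -> ids of identical rows collapsed into it
HaplotypeMap = dict[str, list[str]]


def read_fasta_alignment(path: str | os.PathLike, name: str | None = None) -> Alignment:
    """Read one FASTA file as a rectangular alignment.

    Sample ids are the header token before the first whitespace; sequences are
    uppercased.  Ragged records or duplicate ids raise
    :class:`AlignmentFormatError` naming the file.
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise AlignmentFormatError(f"{path}: duplicate sequence ids {dupes}")
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        bad = ids[[len(r) for r in rows].index(max(lengths))]
        raise AlignmentFormatError(
            f"{path}: ragged alignment (e.g. record {bad!r}); "
            f"lengths seen: {sorted(lengths)}"
        )
    gene = name or os.path.splitext(os.path.basename(str(path)))[0]
    part = [GenePartition(gene, 0, len(rows[0]))]
    return Alignment.from_strings(ids, rows, part)


def read_gene_alignments(paths: Sequence[str | os.PathLike]) -> list[Alignment]:
    """Read several per-gene FASTA files (one :class:`Alignment` each)."""
    return [read_fasta_alignment(p) for p in paths]


def write_fasta(aln: Alignment, path: str | os.PathLike, wrap: int = 80) -> None:
    """Write FASTA wrapped at ``wrap`` columns."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sample_ids, aln.rows())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_partitions_raxml(aln: Alignment, path: str | os.PathLike) -> None:
    """RAxML-style partition table: ``DNA, name = start-end`` (1-based inclusive)."""
    with open(path, "w") as fh:
        for p in aln.partitions:
            fh.write(f"DNA, {p.name} = {p.start + 1}-{p.end}\n")


def write_partitions_tsv(aln: Alignment, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\n")
        for p in aln.partitions:
            fh.write(f"{p.name}\t{p.start}\t{p.end}\n")


def _union_sample_ids(genes: Sequence[Alignment]) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        for s in g.sample_ids:
            seen.setdefault(s)
    return list(seen)


def concatenate(
    genes: Sequence[Alignment],
    order: str = "given",
    seed: int | None = None,
) -> Alignment:
    """Concatenate per-gene alignments into a supermatrix.

    ``order="random"`` shuffles the gene order with a seeded uniform shuffle
    (the randomisation device of the scaling experiment).  Samples missing
    from a gene are padded with ``-`` across that gene's columns; pairwise
    deletion downstream makes the padding inert.
    """
    if not genes:
        raise ValueError("cannot concatenate an empty gene list")
    if order not in ("given", "random"):
        raise ValueError(f"unknown order {order!r}")
    idx = np.arange(len(genes))
    if order == "random":
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(genes))
    ordered = [genes[i] for i in idx]

    samples = _union_sample_ids(ordered)
    total = sum(g.n_columns for g in ordered)
    mat = np.full((len(samples), total), GAP, dtype=np.uint8)
    parts: list[GenePartition] = []
    col = 0
    for g in ordered:
        gname = g.partitions[0].name if g.partitions else f"gene{col}"
        row_of = {s: i for i, s in enumerate(g.sample_ids)}
        for i, s in enumerate(samples):
            j = row_of.get(s)
            if j is not None:
                mat[i, col : col + g.n_columns] = g.matrix[j]
        parts.append(GenePartition(gname, col, col + g.n_columns))
        col += g.n_columns
    return Alignment(samples, mat, parts)


def split_by_partitions(aln: Alignment) -> list[Alignment]:
    """Inverse of :func:`concatenate` under ``order="given"``."""
    return [aln.gene(p.name) for p in aln.partitions]


def deduplicate_haplotypes(
    aln: Alignment, ambiguity_aware: bool = False
) -> tuple[Alignment, HaplotypeMap]:
    """Collapse duplicate rows onto their first occurrence.

    By default two rows are duplicates only when identical as exact strings
    (gaps and ambiguity codes included) -- the simplest reproducible rule.
    With ``ambiguity_aware=True`` a row also collapses onto an earlier
    representative when it matches it at every *unambiguous* position
    (columns where either row has a gap, N, ? or an IUPAC ambiguity letter
    are skipped); note this relation is not transitive, so the result
    depends on input order, which the first-occurrence rule pins down.
    Returns the reduced alignment and a map
    ``representative -> collapsed duplicates``.
    """
    keep: list[int] = []
    hmap: HaplotypeMap = {}
    if not ambiguity_aware:
        key_to_rep: dict[bytes, int] = {}
        for i in range(aln.n_samples):
            key = aln.matrix[i].tobytes()
            rep = key_to_rep.get(key)
            if rep is None:
                key_to_rep[key] = i
                keep.append(i)
                hmap[aln.sample_ids[i]] = []
            else:
                hmap[aln.sample_ids[rep]].append(aln.sample_ids[i])
    else:
        from .stats import encode_bases

        codes = encode_bases(aln.matrix)
        valid = codes != 255
        for i in range(aln.n_samples):
            rep = None
            for j in keep:
                both = valid[i] & valid[j]
                if not np.any((codes[i] != codes[j]) & both):
                    rep = j
                    break
            if rep is None:
                keep.append(i)
                hmap[aln.sample_ids[i]] = []
            else:
                hmap[aln.sample_ids[rep]].append(aln.sample_ids[i])
    out = Alignment(
        [aln.sample_ids[i] for i in keep],
        aln.matrix[keep].copy(),
        list(aln.partitions),
    )
    return out, hmap


def size_ladder(
    e_min: float = 2.5, e_max: float = 5.0, step: float = 0.25
) -> list[int]:
    """Sub-alignment lengths 10**e for e in [e_min, e_max] in steps of ``step``.

    The default spans 316 nt (10**2.5) to 100,000 nt (10**5) over 11 rungs.
    Lengths are rounded half-to-even.
    """
    if e_min > e_max:
        raise ValueError("e_min > e_max")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((e_max - e_min) / step)) + 1
    exps = [e_min + i * step for i in range(n)]
    lengths = [int(np.round(10.0**e)) for e in exps if e <= e_max + 1e-12]
    for a, b in zip(lengths, lengths[1:]):
        if b <= a:
            raise ValueError("ladder is not strictly increasing")
    return lengths


def subset_prefix(aln: Alignment, length: int) -> Alignment:
    """First ``min(length, width)`` columns, with partitions clipped.

    Prefixes of the same (shuffled) concatenation are nested, which is what
    lets the scaling experiment compare sizes on strictly nested data.
    """
    if length < 1:
        raise ValueError("prefix length must be >= 1")
    L = min(length, aln.n_columns)
    parts = [
        GenePartition(p.name, p.start, min(p.end, L))
        for p in aln.partitions
        if p.start < L
    ]
    return Alignment(list(aln.sample_ids), aln.matrix[:, :L].copy(), parts)
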