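"""Alignment informativeness statistics and uncorrected p-distances.

Distances use pairwise deletion: for each sequence pair only the columns
where both sequences carry an unambiguous base (A, C, G or T) are compared.
Gaps, N, ? and IUPAC ambiguity codes are treated as missing, both here and in
the variable-site / parsimony-informative-site (PIS) counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment

__all__ = [
    "DistanceMatrix",
    "DivergenceSummary",
    "CategorySummary",
    "GeneStats",
    "p_distance_matrix",
    "jc_corrected",
    "count_sites",
    "count_indel_events",
    "gene_relative_rate",
    "mean_pairwise_distance",
    "divergence_summary",
    "gene_stats",
]

_BASES = b"ACGT"
# 255 = missing/ambiguous
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[_b] = _i


def encode_bases(matrix: np.ndarray) -> np.ndarray:
    """Map ASCII codes to 0..3 for A,C,G,T and 255 for anything else."""
    return _CODE[matrix]


@dataclass
class DistanceMatrix:
    """Symmetric uncorrected p-distance matrix with pairwise overlap counts."""

    sample_ids: list[str]
    d: np.ndarray  # (n, n) float, in [0, 1], zero diagonal
    overlap: np.ndarray  # (n, n) int, jointly unambiguous site counts

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return DistanceMatrix(
            list(ids), self.d[np.ix_(idx, idx)].copy(), self.overlap[np.ix_(idx, idx)].copy()
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, s in enumerate(self.sample_ids):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{s}  {row}\n")


def p_distance_matrix(
    aln: Alignment, min_overlap: int = 1, ambiguity: str = "missing"
) -> DistanceMatrix:
    """Uncorrected p-distances under pairwise deletion.

    Gaps and ambiguity codes are treated as missing by default;
    ``ambiguity="state"`` instead compares every non-gap character literally
    (a sensitivity-check mode; an R in one sequence then mismatches an A in
    the other).  Raises ``ValueError`` naming the offending pair when the
    number of jointly comparable sites falls below ``min_overlap``.
    """
    if aln.n_samples < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    if ambiguity not in ("missing", "state"):
        raise ValueError("ambiguity must be 'missing' or 'state'")
    if ambiguity == "state":
        codes = aln.matrix.copy()
        codes[(codes == ord("-")) | (codes == ord("?"))] = 255
    else:
        codes = encode_bases(aln.matrix)
    valid = codes != 255
    n = aln.n_samples
    d = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        ov = both.sum(axis=1)
        mism = ((codes[i] != codes[i + 1 :]) & both).sum(axis=1)
        overlap[i, i + 1 :] = ov
        overlap[i + 1 :, i] = ov
        if np.any(ov < min_overlap):
            j = i + 1 + int(np.argmin(ov))
            raise ValueError(
                f"pair ({aln.sample_ids[i]!r}, {aln.sample_ids[j]!r}) has "
                f"overlap {int(ov.min())} < min_overlap={min_overlap}"
            )
        with np.errstate(invalid="ignore"):
            pd_ = np.where(ov > 0, mism / np.maximum(ov, 1), 0.0)
        d[i, i + 1 :] = pd_
        d[i + 1 :, i] = pd_
    overlap[np.diag_indices(n)] = valid.sum(axis=1)
    return DistanceMatrix(list(aln.sample_ids), d, overlap)


def _state_counts(aln: Alignment) -> np.ndarray:
    """(4, n_columns) counts of unambiguous A,C,G,T per column."""
    codes = encode_bases(aln.matrix)
    return np.stack([(codes == k).sum(axis=0) for k in range(4)])


def count_sites(aln: Alignment, ambiguity: str = "missing") -> tuple[int, int]:
    """Return (variable sites, parsimony-informative sites).

    A column is variable when >= 2 distinct unambiguous states occur; it is
    parsimony-informative when >= 2 distinct states each occur in >= 2 rows.
    ``ambiguity="state"`` counts each ambiguity letter as its own state
    (sensitivity-check mode); gaps are never states.
    """
    if ambiguity not in ("missing", "state"):
        raise ValueError("ambiguity must be 'missing' or 'state'")
    if ambiguity == "state":
        symbols = np.unique(aln.matrix)
        symbols = symbols[(symbols != ord("-")) & (symbols != ord("?"))]
        counts = np.stack([(aln.matrix == c).sum(axis=0) for c in symbols])
    else:
        counts = _state_counts(aln)
    n_variable = int(((counts >= 1).sum(axis=0) >= 2).sum())
    n_pis = int(((counts >= 2).sum(axis=0) >= 2).sum())
    return n_variable, n_pis


def count_indel_events(aln: Alignment) -> int:
    """Number of maximal gap runs summed over rows (terminal runs included)."""
    gaps = aln.matrix == ord("-")
    if aln.n_columns == 0:
        return 0
    starts = gaps[:, :1].sum() + (gaps[:, 1:] & ~gaps[:, :-1]).sum()
    return int(starts)


def jc_corrected(dist: DistanceMatrix) -> DistanceMatrix:
    """Jukes-Cantor corrected distances: ``-(3/4) ln(1 - 4p/3)``.

    Saturated pairs (p >= 0.75) map to infinity.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 1.0 - 4.0 * dist.d / 3.0
        d = np.where(arg > 0, -0.75 * np.log(np.maximum(arg, 1e-300)), np.inf)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(dist.sample_ids), d, dist.overlap.copy())


def mean_pairwise_distance(dist: DistanceMatrix) -> float:
    """Mean of the upper-triangle p-distances."""
    return float(dist.condensed().mean())


def gene_relative_rate(gene_aln: Alignment, reference_mean_distance: float) -> float:
    """Mean pairwise p-distance of the gene relative to a reference mean.

    The reference is typically the mean pairwise distance of the concatenated
    alignment; an invariant gene yields 0.0.
    """
    if not (reference_mean_distance > 0):
        raise ValueError("reference mean distance must be > 0")
    return mean_pairwise_distance(p_distance_matrix(gene_aln)) / reference_mean_distance


@dataclass
class GeneStats:
    gene: str
    length: int
    n_variable: int
    n_pis: int
    n_indel_events: int
    relative_rate: float


def gene_stats(gene_aln: Alignment, reference_mean_distance: float) -> GeneStats:
    v, p = count_sites(gene_aln)
    name = gene_aln.partitions[0].name if gene_aln.partitions else "gene"
    return GeneStats(
        gene=name,
        length=gene_aln.n_columns,
        n_variable=v,
        n_pis=p,
        n_indel_events=count_indel_events(gene_aln),
        relative_rate=gene_relative_rate(gene_aln, reference_mean_distance),
    )


@dataclass
class CategorySummary:
    """Min/mean/max p-distance over one category of sample pairs."""

    n_pairs: int
    min: float = math.nan
    mean: float = math.nan
    max: float = math.nan

    @property
    def defined(self) -> bool:
        return self.n_pairs > 0


@dataclass
class DivergenceSummary:
    """Within- (intra) and between-species (inter) divergence summaries."""

    intra: CategorySummary = field(default_factory=lambda: CategorySummary(0))
    inter: CategorySummary = field(default_factory=lambda: CategorySummary(0))


def divergence_summary(
    dist: DistanceMatrix, partition: dict[str, str]
) -> DivergenceSummary:
    """Summarise p-distances within and between the species of ``partition``.

    Every sample in ``dist`` must carry a species label.  Pairs with the same
    label are intra-specific, all others inter-specific.  Empty categories are
    reported with ``n_pairs = 0`` and NaN statistics.
    """
    missing = [s for s in dist.sample_ids if s not in partition]
    if missing:
        raise ValueError(f"samples missing from partition: {missing}")
    labels = np.array([partition[s] for s in dist.sample_ids])
    iu = np.triu_indices(dist.n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    vals = dist.d[iu]

    def summarise(v: np.ndarray) -> CategorySummary:
        if v.size == 0:
            return CategorySummary(0)
        return CategorySummary(
            int(v.size), float(v.min()), float(v.mean()), float(v.max())
        )

    return DivergenceSummary(intra=summarise(vals[same]), inter=summarise(vals[~same]))
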