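"""Experiment orchestration: method suites, the size-ladder scaling
experiment, gene-by-gene comparison, and Poisson regression of species
counts on gene features.

The central experiment mirrors a gene-to-genome scaling design: genes are
concatenated in seeded random order, the concatenation is subset into a
logarithmic ladder of prefix lengths, and each sub-alignment is analysed
with the three delimitation methods, before and after haplotype
deduplication.  Species counts are computed on the unique haplotypes that
were actually analysed; collapsed duplicates are mapped back into their
representative's species for the reported membership.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import (
    Alignment,
    concatenate,
    deduplicate_haplotypes,
    size_ladder,
    split_by_partitions,
    subset_prefix,
)
from .asap import run_asap
from .gmyc import fit_gmyc
from .ptp import fit_ptp
from .stats import (
    count_sites,
    gene_relative_rate,
    mean_pairwise_distance,
    p_distance_matrix,
)
from .trees import nj_tree, root_on_longest_branch, upgma_tree

__all__ = [
    "MethodResult",
    "ScalingRecord",
    "GeneDelimitationRecord",
    "run_method_suite",
    "run_scaling_experiment",
    "aggregate_scaling",
    "gene_by_gene",
    "method_summary",
    "fit_poisson_glm",
    "poisson_regression_species",
    "records_to_dataframe",
]

METHODS = ("asap", "ptp", "gmyc")


@dataclass
class MethodResult:
    method: str
    n_species: int  # counted on the analysed (possibly deduplicated) samples
    partition: dict[str, str]  # membership over all input samples
    lambda_coal: float | None = None
    diagnostics: object | None = None
    warnings: list[str] = field(default_factory=list)


def _expand_partition(partition: dict[str, str], hmap: dict[str, list[str]]):
    full = dict(partition)
    for rep, dupes in hmap.items():
        for d in dupes:
            full[d] = partition[rep]
    return full


def _trivial_result(method: str, samples: list[str], msg: str) -> MethodResult:
    return MethodResult(
        method=method,
        n_species=1,
        partition={s: "sp1" for s in samples},
        warnings=[msg],
    )


def run_method_suite(
    aln: Alignment,
    methods: Sequence[str] = METHODS,
    dedup: bool = True,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, MethodResult]:
    """Apply the requested delimitation methods to one alignment.

    ASAP runs on the p-distance matrix, PTP on the neighbor-joining tree
    rooted on its longest branch, GMYC on the UPGMA tree.  With ``dedup``
    duplicate haplotypes are removed first; species are counted on the
    analysed haplotypes and the collapsed duplicates inherit their
    representative's species in the returned membership.
    """
    all_samples = list(aln.sample_ids)
    work, hmap = deduplicate_haplotypes(aln) if dedup else (aln, {s: [] for s in all_samples})
    results: dict[str, MethodResult] = {}

    degenerate = None
    if work.n_samples < 4:
        degenerate = (
            f"only {work.n_samples} unique haplotypes; delimitation is "
            "degenerate, reporting a single species"
        )
    else:
        dist = p_distance_matrix(work)
        if dist.condensed().max() == 0.0:
            degenerate = "all analysed sequences identical; reporting one species"

    if degenerate is not None:
        for m in methods:
            results[m] = _trivial_result(m, all_samples, degenerate)
        return results

    rng = np.random.default_rng(seed)
    method_seeds = {m: int(rng.integers(2**31 - 1)) for m in METHODS}

    for m in methods:
        if m == "asap":
            res = run_asap(dist, n_perm=n_perm, seed=method_seeds[m])
            best = res.best
            results[m] = MethodResult(
                method=m,
                n_species=best.n_species,
                partition=_expand_partition(best.partition, hmap),
                diagnostics=res,
            )
        elif m == "ptp":
            tree = root_on_longest_branch(nj_tree(dist))
            fit = fit_ptp(tree, mode="greedy")
            results[m] = MethodResult(
                method=m,
                n_species=fit.n_species,
                partition=_expand_partition(fit.partition, hmap),
                diagnostics=fit,
            )
        elif m == "gmyc":
            tree = upgma_tree(dist)
            fit = fit_gmyc(tree, seed=method_seeds[m])
            results[m] = MethodResult(
                method=m,
                n_species=fit.n_entities,
                partition=_expand_partition(fit.partition, hmap),
                lambda_coal=fit.lambda_coal,
                diagnostics=fit,
                warnings=list(fit.warnings),
            )
        else:
            raise ValueError(f"unknown method {m!r}")
    return results


@dataclass
class ScalingRecord:
    replicate: int
    length: int
    dedup: bool
    method: str
    n_species: int
    lambda_coal: float | None
    n_unique_haplotypes: int
    runtime_s: float


def run_scaling_experiment(
    genes: Sequence[Alignment],
    n_replicates: int = 10,
    ladder: Sequence[int] | None = None,
    methods: Sequence[str] = METHODS,
    n_perm: int = 199,
    seed: int = 0,
) -> list[ScalingRecord]:
    """The gene-order-randomised size-ladder experiment.

    For each replicate the genes are concatenated in a fresh seeded random
    order; each ladder length is taken as a prefix of that concatenation and
    analysed with every method, both with and without haplotype
    deduplication.  Yields ``replicates x rungs x 2 x methods`` records.
    """
    if ladder is None:
        ladder = size_ladder()
    base = np.random.default_rng(seed)
    records: list[ScalingRecord] = []
    for r in range(1, n_replicates + 1):
        rep_seed = int(base.integers(2**31 - 1))
        concat = concatenate(genes, order="random", seed=rep_seed)
        for L in ladder:
            if L > concat.n_columns:
                warnings.warn(
                    f"ladder length {L} exceeds alignment width "
                    f"{concat.n_columns}; using the full alignment"
                )
            sub = subset_prefix(concat, L)
            for dedup in (False, True):
                uniq, _ = deduplicate_haplotypes(sub)
                t0 = time.perf_counter()
                suite = run_method_suite(
                    sub, methods=methods, dedup=dedup, n_perm=n_perm, seed=rep_seed
                )
                dt = time.perf_counter() - t0
                for m in methods:
                    res = suite[m]
                    records.append(
                        ScalingRecord(
                            replicate=r,
                            length=min(L, concat.n_columns),
                            dedup=dedup,
                            method=m,
                            n_species=res.n_species,
                            lambda_coal=res.lambda_coal,
                            n_unique_haplotypes=uniq.n_samples,
                            runtime_s=dt,
                        )
                    )
    return records


def records_to_dataframe(records: Sequence) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def aggregate_scaling(records: Sequence[ScalingRecord]) -> pd.DataFrame:
    """Mean and standard error per (length, method, dedup) cell."""
    df = records_to_dataframe(records)

    def se(x):
        x = x.dropna()
        return x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else math.nan

    out = (
        df.groupby(["length", "method", "dedup"])
        .agg(
            mean_n_species=("n_species", "mean"),
            se_n_species=("n_species", se),
            mean_lambda_coal=("lambda_coal", "mean"),
            se_lambda_coal=("lambda_coal", se),
            n=("n_species", "size"),
        )
        .reset_index()
    )
    return out


@dataclass
class GeneDelimitationRecord:
    gene: str
    length: int
    n_pis: int
    relative_rate: float
    n_species: dict[str, int]


def gene_by_gene(
    genes: Sequence[Alignment],
    min_len: int = 450,
    methods: Sequence[str] = METHODS,
    n_perm: int = 199,
    seed: int = 0,
    dedup: bool = True,
) -> list[GeneDelimitationRecord]:
    """Per-gene delimitation for genes longer than ``min_len`` nucleotides.

    Gene relative rates are measured against the mean pairwise p-distance of
    the full concatenation (all genes, not only the analysed subset).
    """
    concat = concatenate(genes, order="given")
    reference = mean_pairwise_distance(p_distance_matrix(concat))
    records: list[GeneDelimitationRecord] = []
    base = np.random.default_rng(seed)
    for g in genes:
        gene_seed = int(base.integers(2**31 - 1))
        if g.n_columns <= min_len:
            continue
        _, n_pis = count_sites(g)
        rate = gene_relative_rate(g, reference)
        suite = run_method_suite(
            g, methods=methods, dedup=dedup, n_perm=n_perm, seed=gene_seed
        )
        name = g.partitions[0].name if g.partitions else "gene"
        records.append(
            GeneDelimitationRecord(
                gene=name,
                length=g.n_columns,
                n_pis=n_pis,
                relative_rate=rate,
                n_species={m: suite[m].n_species for m in methods},
            )
        )
    return records


def method_summary(records: Sequence[GeneDelimitationRecord]) -> pd.DataFrame:
    """Mean and standard deviation of gene-level species counts per method."""
    rows = []
    methods = sorted({m for r in records for m in r.n_species})
    for m in methods:
        counts = np.array([r.n_species[m] for r in records], dtype=float)
        rows.append(
            {
                "method": m,
                "mean": counts.mean(),
                "sd": counts.std(ddof=1) if len(counts) > 1 else math.nan,
                "min": counts.min(),
                "max": counts.max(),
                "n_genes": len(counts),
            }
        )
    return pd.DataFrame(rows)


def fit_poisson_glm(counts: Sequence[float], predictors: pd.DataFrame):
    """Log-link Poisson GLM (IRLS) with Wald z tests; statsmodels result."""
    import statsmodels.api as sm

    X = sm.add_constant(predictors, has_constant="add")
    model = sm.GLM(np.asarray(counts, dtype=float), X, family=sm.families.Poisson())
    return model.fit()


def poisson_regression_species(
    records: Sequence[GeneDelimitationRecord],
    methods: Sequence[str] = METHODS,
) -> dict[str, pd.DataFrame]:
    """Poisson regression of per-gene species counts on log10(PIS) and rate.

    Returns, per method, a coefficient table with standard errors, Wald z
    statistics and two-sided p-values.  Zero-variance predictors are dropped
    with a warning.
    """
    if len(records) < 10:
        raise ValueError("need >= 10 gene records per method")
    X = pd.DataFrame(
        {
            "log10_pis": [math.log10(max(r.n_pis, 1)) for r in records],
            "relative_rate": [r.relative_rate for r in records],
        }
    )
    keep = [c for c in X.columns if X[c].std() > 0]
    if len(keep) < len(X.columns):
        warnings.warn(f"dropping zero-variance predictors: {set(X.columns) - set(keep)}")
    X = X[keep]
    out: dict[str, pd.DataFrame] = {}
    for m in methods:
        y = [r.n_species[m] for r in records]
        res = fit_poisson_glm(y, X)
        out[m] = pd.DataFrame(
            {
                "coef": res.params,
                "se": res.bse,
                "z": res.tvalues,
                "p_value": res.pvalues,
            }
        )
    return out
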