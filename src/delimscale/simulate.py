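"""Multispecies-coalescent synthetic data with known species membership.

The generator emulates the statistical structure of a chloroplast-genome
species-delimitation dataset: a handful of deeply separated species, a few
dozen samples, on the order of a hundred genes of heterogeneous length and
rate, very small within-species divergence (so that short prefixes of the
concatenation contain many identical haplotypes), and clearly larger
between-species divergence.

Model
-----
* Species tree: Yule (pure birth), root age rescaled to ``root_height``.
  Time is measured in expected substitutions per site, so tree heights
  translate directly into sequence divergence.
* Gene genealogy: the standard neutral coalescent embedded in the species
  tree; within a species-tree branch, ``j`` lineages coalesce at rate
  ``j (j - 1) / theta``, where ``theta`` is the expected pairwise
  within-species divergence.  No migration, no recombination.  Because an
  organelle chromosome is a single non-recombining locus, all genes share
  one genealogy by default (``shared_genealogy=True``); independent per-gene
  genealogies are available for power experiments.
* Sites: Jukes-Cantor, independent sites, per-gene rate multipliers
  (log-normal across genes when not supplied).  No indels are simulated.

All stochastic choices flow from a single integer seed; identical
configuration + seed reproduces the output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import Alignment, GenePartition, concatenate

__all__ = [
    "SimConfig",
    "TrueAssignment",
    "paper_like_config",
    "yule_species_tree",
    "msc_genealogy",
    "evolve_jc",
    "generate_dataset",
]

#: sample id -> true species label
TrueAssignment = dict[str, str]


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``root_height`` and ``theta`` are both in expected substitutions/site;
    ``theta`` equals the expected pairwise divergence within a species.
    ``min_split_frac`` deepens the Yule species tree so that its shallowest
    species split sits at least at that fraction of the root age (an affine
    compression of internal node ages towards the root, keeping topology
    and age order), emulating datasets whose species are all deeply
    separated.
    """

    n_species: int
    samples_per_species: list[int]
    birth_rate: float
    root_height: float
    theta: float
    n_genes: int
    gene_lengths: list[int]
    rate_multipliers: list[float] | None = None
    rate_sigma: float = 0.5
    seed: int = 0
    shared_genealogy: bool = True
    min_split_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if len(self.samples_per_species) != self.n_species:
            raise ValueError("samples_per_species length != n_species")
        if any(s < 1 for s in self.samples_per_species):
            raise ValueError("samples_per_species entries must be positive")
        for name in ("birth_rate", "root_height", "theta", "rate_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.gene_lengths) != self.n_genes:
            raise ValueError("gene_lengths length != n_genes")
        if any(L < 1 for L in self.gene_lengths):
            raise ValueError("gene lengths must be positive")
        if self.rate_multipliers is not None:
            if len(self.rate_multipliers) != self.n_genes:
                raise ValueError("rate_multipliers length != n_genes")
            if any(m < 0 for m in self.rate_multipliers):
                raise ValueError("rate multipliers must be >= 0")
        if not (0.0 <= self.min_split_frac < 1.0):
            raise ValueError("min_split_frac must be in [0, 1)")
        if self.n_species >= 2 and self.root_height <= self.theta:
            warnings.warn(
                "root_height <= theta: species will not be separated from "
                "within-species variation",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_species)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def paper_like_config(seed: int = 0, n_genes: int = 100, total_length: int = 100_000) -> SimConfig:
    """Default study conditions: 7 species, 38 samples, ~100 kb over 100 genes.

    Gene lengths are drawn log-uniformly on [150, 5000] nt and rescaled to
    the requested total.  Divergence scales emulate a chloroplast
    super-barcode dataset: mean within-species p-distance 0.3 %
    (``theta = 0.003``; maxima just under 1 %), between-species p-distances
    roughly 2.5-8 % (root height 0.04 with species splits deepened to at
    least 30 % of the root), i.e. a barcode gap of roughly three-fold --
    clearly present but far from trivial.  Within-species pairs share
    identical haplotypes at short alignment lengths.
    """
    rng = np.random.default_rng(seed)
    raw = np.exp(rng.uniform(np.log(150.0), np.log(5000.0), size=n_genes))
    lengths = np.maximum(150, np.round(raw * total_length / raw.sum()).astype(int))
    return SimConfig(
        n_species=7,
        samples_per_species=[9, 2, 2, 9, 6, 5, 5],
        birth_rate=1.0,
        root_height=0.04,
        theta=0.003,
        n_genes=n_genes,
        gene_lengths=[int(x) for x in lengths],
        rate_multipliers=None,
        rate_sigma=0.5,
        seed=seed,
        shared_genealogy=True,
        min_split_frac=0.30,
    )


class _SimNode:
    __slots__ = ("children", "age", "label")

    def __init__(self, label: str | None = None, age: float = 0.0):
        self.children: list[_SimNode] = []
        self.age = age
        self.label = label


def _to_dendropy(root: _SimNode) -> dendropy.Tree:
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def build(sim: _SimNode, dnode: dendropy.Node) -> None:
        dnode.age = sim.age
        if not sim.children:
            dnode.taxon = ns.require_taxon(label=sim.label)
            return
        for ch in sim.children:
            child = dnode.new_child(edge_length=max(sim.age - ch.age, 0.0))
            build(ch, child)

    build(root, tree.seed_node)
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def yule_species_tree(
    n_species: int,
    birth_rate: float,
    root_height: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Ultrametric Yule species tree with tips ``sp1..spN``.

    For ``n_species >= 2`` the root age is rescaled to exactly
    ``root_height``.  A single species yields a single-tip tree of height 0.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if n_species == 1:
        return _to_dendropy(_SimNode("sp1", 0.0))
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0 for n_species >= 2")

    t = 0.0
    active = [_SimNode()]
    root: _SimNode | None = None
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node = active[i]
        node.age = t  # forward split time; converted to an age below
        a, b = _SimNode(), _SimNode()
        node.children = [a, b]
        if root is None:
            root = node  # the first lineage to split is the root
        active[i : i + 1] = [a, b]
    present = t + rng.exponential(1.0 / (n_species * birth_rate))
    for j, tip in enumerate(active):
        tip.label = f"sp{j + 1}"
        tip.age = present

    def to_age(n: _SimNode) -> None:
        n.age = present - n.age
        for c in n.children:
            to_age(c)

    assert root is not None
    to_age(root)
    scale = root_height / root.age if root.age > 0 else 0.0

    def rescale(n: _SimNode) -> None:
        n.age *= scale
        for c in n.children:
            rescale(c)

    rescale(root)
    return _to_dendropy(root)


def msc_genealogy(
    species_tree: dendropy.Tree,
    samples_per_species: dict[str, int] | list[int],
    theta: float,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Coalescent gene tree embedded in ``species_tree``.

    ``samples_per_species`` maps species-tip labels to sample counts (a list
    is matched against the sorted tip labels).  Samples are labelled
    ``<species>_<k>``.  With ``theta = 0`` all lineages of a species coalesce
    immediately at the species-tip age (a documented limit, not an error).
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    tips = sorted(lf.taxon.label for lf in species_tree.leaf_node_iter())
    if isinstance(samples_per_species, dict):
        counts = dict(samples_per_species)
    else:
        if len(samples_per_species) != len(tips):
            raise ValueError("sample counts not aligned with species-tree tips")
        counts = dict(zip(tips, samples_per_species))
    missing = [t for t in tips if t not in counts]
    if missing:
        raise ValueError(f"no sample count for species {missing}")

    from .trees import node_ages

    ages = node_ages(species_tree, force_tip_zero=False)

    def coalesce(lineages: list[_SimNode], t_start: float, t_end: float) -> list[_SimNode]:
        t = t_start
        lineages = list(lineages)
        while len(lineages) > 1:
            j = len(lineages)
            if theta == 0.0:
                pass  # immediate coalescence: waiting time 0
            else:
                t_next = t + rng.exponential(theta / (j * (j - 1)))
                if t_next >= t_end:
                    return lineages
                t = t_next
            i1, i2 = sorted(rng.choice(j, size=2, replace=False))
            parent = _SimNode(age=t)
            parent.children = [lineages[i1], lineages[i2]]
            lineages[i1] = parent
            del lineages[i2]
        return lineages

    def walk(snode) -> list[_SimNode]:
        label = snode.taxon.label if snode.is_leaf() else None
        if snode.is_leaf():
            start = ages[snode]
            lineages = [
                _SimNode(f"{label}_{k + 1}", start) for k in range(counts[label])
            ]
        else:
            lineages = []
            for ch in snode.child_nodes():
                lineages.extend(walk(ch))
            start = ages[snode]
        if snode.parent_node is None:
            return coalesce(lineages, start, np.inf)
        return coalesce(lineages, start, ages[snode.parent_node])

    root_lineages = walk(species_tree.seed_node)
    assert len(root_lineages) == 1
    return _to_dendropy(root_lineages[0])


_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


def evolve_jc(
    gene_tree: dendropy.Tree,
    n_sites: int,
    rate_multiplier: float = 1.0,
    rng: np.random.Generator | None = None,
) -> Alignment:
    """Evolve one gene along ``gene_tree`` under Jukes-Cantor.

    The root sequence is uniform over {A,C,G,T}; along a branch of scaled
    length ``d`` each site substitutes with probability
    ``(3/4)(1 - exp(-4 d / 3))``, uniformly to one of the three other bases.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rate_multiplier < 0:
        raise ValueError("rate_multiplier must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    seqs: dict = {}
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for node in gene_tree.preorder_node_iter():
        if node.parent_node is None:
            seq = rng.integers(0, 4, size=n_sites, dtype=np.uint8)
        else:
            d = (node.edge.length or 0.0) * rate_multiplier
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            seq = seqs[node.parent_node].copy()
            if p > 0:
                hit = rng.random(n_sites) < p
                n_hit = int(hit.sum())
                if n_hit:
                    shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
                    seq[hit] = (seq[hit] + shift) % 4
        seqs[node] = seq
        if node.is_leaf():
            ids.append(node.taxon.label)
            rows.append(_ACGT[seq])
    mat = np.vstack(rows)
    return Alignment(ids, mat, [GenePartition("gene", 0, n_sites)])


def _deepen_splits(tree: dendropy.Tree, min_frac: float) -> None:
    """Affinely compress internal node ages into [min_frac * root, root].

    Tip ages stay at 0; topology and the relative order of split ages are
    preserved; the root age is unchanged.  Emulates an old radiation whose
    species are all separated by deep splits.
    """
    from .trees import node_ages

    ages = node_ages(tree, force_tip_zero=False)
    root_age = ages[tree.seed_node]
    if root_age <= 0:
        return
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        node.age = root_age * min_frac + (1.0 - min_frac) * ages[node]
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        child_age = node.age if not node.is_leaf() else 0.0
        node.edge.length = max(node.parent_node.age - child_age, 0.0)


def generate_dataset(config: SimConfig) -> tuple[Alignment, TrueAssignment]:
    """Simulate a full multi-gene dataset.

    Returns the concatenated alignment (gene partitions recorded in the
    declared order) and the true sample -> species assignment.
    """
    rng = np.random.default_rng(config.seed)
    species_tree = yule_species_tree(
        config.n_species, config.birth_rate, config.root_height, rng
    )
    if config.n_species >= 2 and config.min_split_frac > 0:
        _deepen_splits(species_tree, config.min_split_frac)

    counts = {
        f"sp{i + 1}": c for i, c in enumerate(config.samples_per_species)
    }
    if config.rate_multipliers is not None:
        mults = list(config.rate_multipliers)
    else:
        sigma = config.rate_sigma
        mults = list(
            np.exp(rng.normal(-0.5 * sigma**2, sigma, size=config.n_genes))
        )

    shared = None
    if config.shared_genealogy:
        shared = msc_genealogy(species_tree, counts, config.theta, rng)

    genes: list[Alignment] = []
    for g in range(config.n_genes):
        gtree = shared
        if gtree is None:
            gtree = msc_genealogy(species_tree, counts, config.theta, rng)
        gene = evolve_jc(gtree, config.gene_lengths[g], mults[g], rng)
        gene.partitions = [
            GenePartition(f"gene{g + 1:03d}", 0, config.gene_lengths[g])
        ]
        genes.append(gene)

    aln = concatenate(genes, order="given")
    assignment: TrueAssignment = {}
    for sp, c in counts.items():
        for k in range(c):
            assignment[f"{sp}_{k + 1}"] = sp
    # samples present in the alignment and the assignment must agree
    assert set(assignment) == set(aln.sample_ids)
    return aln, assignment


def write_assignment_tsv(assignment: TrueAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tspecies\n")
        for s in sorted(assignment):
            fh.write(f"{s}\t{assignment[s]}\n")
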