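"""Refugium population models, coalescent gene-tree simulation and unit conversions.

A refugium model is a small rooted population tree whose leaves are putative
Pleistocene refugia.  Each branch carries an effective population size
(a share of the total Ne) and each internal node a divergence time in
generations before present.  Gene trees are simulated under the neutral
coalescent constrained within the model: lineages coalesce only with other
lineages in the same branch, and surviving lineages are pooled when branches
join at a divergence node.

Time-scale convention
---------------------
For a maternally inherited locus the scaled diversity is theta = 2*Ne*mu,
which fixes the coalescent rate at 1/Ne per lineage pair per generation
(E[T2] = Ne generations), so that the expected pairwise diversity equals
theta.  All branch lengths are in generations.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RateSet",
    "RefugiumModel",
    "GeneTree",
    "theta_to_ne",
    "ne_to_theta",
    "modulate_rate",
    "scaled_time_to_years",
    "build_model",
    "simulate_gene_tree",
    "simulate_growth_gene_tree",
]

#: Sampling populations (demes) of the study design and their sample sizes.
TABLE1_DEME_SIZES: dict[str, int] = {
    "DL": 11, "ZD": 14, "WX": 7, "QL": 5, "HB": 5,
    "BC": 7, "YA": 8, "MK": 14, "CD": 7, "RT": 2,
}

#: Unique mitochondrial haplotypes carried per deme.  The observed
#: genealogy is a haplotype tree (67 unique haplotypes), so null genealogies
#: simulated for the sorting test carry one tip per haplotype: the per-deme
#: haplotype counts, with the three extra copies of haplotypes shared
#: between neighbouring demes removed from the larger carrier (ZD, MK, CD).
TABLE1_HAPLOTYPE_SIZES: dict[str, int] = {
    "DL": 10, "ZD": 12, "WX": 5, "QL": 5, "HB": 5,
    "BC": 7, "YA": 7, "MK": 9, "CD": 5, "RT": 2,
}

#: Deme -> eco-subregion membership (southern / eastern / northern).
SUBREGION_OF_DEME: dict[str, str] = {
    "DL": "S", "ZD": "S",
    "WX": "E", "QL": "E", "HB": "E", "BC": "E", "YA": "E",
    "MK": "N", "CD": "N", "RT": "N",
}


class ModelError(ValueError):
    """Raised for an inconsistent refugium-model specification."""


@dataclass(frozen=True)
class RateSet:
    """Mutation rates and generation time used for unit conversions.

    Parameters
    ----------
    mu_site_cytb : float
        Cytochrome-b substitution rate per site per year (avian
        mitochondrial clock; default 1e-8).
    mu_site_combined : float
        Rate per site per year for the combined mitochondrial fragments,
        usually obtained from :func:`modulate_rate`.
    locus_length : int
        Length of the combined mitochondrial alignment in sites.
    msat_mu : float
        Microsatellite stepwise mutation rate per generation.
    generation_time : float
        Generation time in years (default 1).
    """

    mu_site_cytb: float = 1e-8
    mu_site_combined: float = 0.78e-8
    locus_length: int = 4029
    msat_mu: float = 1e-5
    generation_time: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mu_site_cytb", "mu_site_combined", "locus_length",
                     "msat_mu", "generation_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def theta_to_ne(theta: float, mu_locus_per_gen: float) -> float:
    """Effective size from scaled diversity, theta = 2*Ne*mu (maternal locus)."""
    if theta <= 0 or mu_locus_per_gen <= 0:
        raise ValueError("theta and mutation rate must be positive")
    return theta / (2.0 * mu_locus_per_gen)


def ne_to_theta(ne: float, mu_locus_per_gen: float) -> float:
    """Inverse of :func:`theta_to_ne`."""
    if ne <= 0 or mu_locus_per_gen <= 0:
        raise ValueError("Ne and mutation rate must be positive")
    return 2.0 * ne * mu_locus_per_gen


def modulate_rate(mu_cytb: float, mean_dist_combined: float,
                  mean_dist_cytb: float) -> float:
    """Scale a cytochrome-b clock rate to the combined fragments.

    The combined-fragment rate is the cyt-b rate multiplied by the ratio of
    mean sequence divergence of the combined alignment to that of cyt-b
    alone.
    """
    if mean_dist_combined <= 0 or mean_dist_cytb <= 0:
        raise ValueError("distances must be positive")
    return mu_cytb * (mean_dist_combined / mean_dist_cytb)


def scaled_time_to_years(t: float, rates: RateSet, marker: str = "mtdna") -> float:
    """Convert a mutation-scaled divergence time to calendar years.

    For mtDNA the scaled time is in units of mutations per locus
    (years = t / (mu_site * L)); for microsatellites in units of mutations
    per locus per generation (years = t / msat_mu * generation_time).
    """
    if t < 0:
        raise ValueError("scaled time must be non-negative")
    if marker == "mtdna":
        return t / (rates.mu_site_combined * rates.locus_length)
    if marker == "msat":
        return (t / rates.msat_mu) * rates.generation_time
    raise ValueError(f"unknown marker {marker!r}; use 'mtdna' or 'msat'")


# ---------------------------------------------------------------------------
# Population model


@dataclass
class RefugiumModel:
    """Rooted population tree over refugium units with Ne-scaled branches.

    Nodes are indexed 0..k-1; leaves first.  ``node_time[i]`` is the
    divergence time (generations before present) at which node i's children
    merge; leaves have time 0.  ``branch_ne[i]`` is the effective size of
    the branch extending rootward from node i (the root branch extends to
    the coalescence of all lineages).
    """

    names: list[str]
    parent: list[int]            # -1 for root
    node_time: list[float]       # 0.0 for leaves
    branch_ne: list[float]
    deme_to_refugium: dict[str, str]
    total_ne: float

    def __post_init__(self) -> None:
        k = len(self.names)
        if not (len(self.parent) == len(self.node_time) == len(self.branch_ne) == k):
            raise ModelError("node arrays must have equal length")
        if sum(1 for p in self.parent if p == -1) != 1:
            raise ModelError("exactly one root required")
        for i, p in enumerate(self.parent):
            if p != -1 and self.node_time[i] >= self.node_time[p]:
                raise ModelError(
                    f"node {self.names[i]} at t={self.node_time[i]} is not "
                    f"younger than its parent {self.names[p]}")
        if any(ne <= 0 for ne in self.branch_ne):
            raise ModelError("every branch Ne must be positive")
        leaves = set(self.leaf_names())
        for deme, ref in self.deme_to_refugium.items():
            if ref not in leaves:
                raise ModelError(f"deme {deme!r} maps to unknown leaf {ref!r}")

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parent) if p == i]

    @property
    def root(self) -> int:
        return self.parent.index(-1)

    def is_leaf(self, i: int) -> bool:
        return not self.children(i)

    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in range(len(self.names)) if self.is_leaf(i)]

    @property
    def n_internal(self) -> int:
        return sum(1 for i in range(len(self.names)) if not self.is_leaf(i))


def build_model(hypothesis: str,
                total_ne: float,
                deme_sizes: dict[str, int] | None = None,
                proportions: dict[str, float] | None = None,
                divergence_times_years: dict[str, float] | None = None,
                rates: RateSet | None = None,
                subregion_of_deme: dict[str, str] | None = None) -> RefugiumModel:
    """Construct one of the three refugium hypotheses as a population tree.

    ``single``       one panmictic population (divergence time 0);
    ``two_refugia``  southern (S) vs north-eastern (NE) split, default
                     0.1 mya;
    ``three_refugia``northern (N) vs eastern (E) split (default 0.015 mya)
                     nested within the 0.1-mya southern split.

    Branch Ne values are shares of ``total_ne``.  Leaf shares default to the
    sample-size proportions of their member demes; an ancestral branch
    carries the summed share of its descendants (the refugial-population
    constraint), so the root branch carries the full ``total_ne``.
    Divergence times in years are converted to generations via ``rates``.
    """
    rates = rates or RateSet()
    deme_sizes = dict(deme_sizes or TABLE1_DEME_SIZES)
    sub = dict(subregion_of_deme or SUBREGION_OF_DEME)
    times = dict(divergence_times_years or {})
    gen = rates.generation_time
    n_total = sum(deme_sizes.values())

    def share(refugium_demes: list[str]) -> float:
        if proportions is not None:
            return sum(proportions[d] for d in refugium_demes)
        return sum(deme_sizes[d] for d in refugium_demes) / n_total

    if proportions is not None:
        s = sum(proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ModelError(f"proportions sum to {s}, expected 1")

    if hypothesis == "single":
        return RefugiumModel(
            names=["ROOT"], parent=[-1], node_time=[0.0],
            branch_ne=[total_ne],
            deme_to_refugium={d: "ROOT" for d in deme_sizes},
            total_ne=total_ne)

    demes_by_sub: dict[str, list[str]] = {"S": [], "E": [], "N": []}
    for d in deme_sizes:
        if d not in sub:
            raise ModelError(f"deme {d!r} has no subregion assignment")
        demes_by_sub[sub[d]].append(d)

    t_root = times.get("root_years", 100_000.0) / gen
    if hypothesis == "two_refugia":
        s_demes = demes_by_sub["S"]
        ne_demes = demes_by_sub["E"] + demes_by_sub["N"]
        mapping = {d: ("S" if d in s_demes else "NE") for d in deme_sizes}
        return RefugiumModel(
            names=["S", "NE", "ROOT"], parent=[2, 2, -1],
            node_time=[0.0, 0.0, t_root],
            branch_ne=[share(s_demes) * total_ne,
                       share(ne_demes) * total_ne,
                       total_ne],
            deme_to_refugium=mapping, total_ne=total_ne)

    if hypothesis == "three_refugia":
        t_ne = times.get("ne_split_years", 15_000.0) / gen
        if t_ne >= t_root:
            raise ModelError("nested N/E split must be younger than the root split")
        s_demes, e_demes, n_demes = (demes_by_sub[k] for k in ("S", "E", "N"))
        mapping = {d: sub[d] for d in deme_sizes}
        # nodes: S, E, N leaves; NE ancestor; root
        return RefugiumModel(
            names=["S", "E", "N", "NE", "ROOT"],
            parent=[4, 3, 3, 4, -1],
            node_time=[0.0, 0.0, 0.0, t_ne, t_root],
            branch_ne=[share(s_demes) * total_ne,
                       share(e_demes) * total_ne,
                       share(n_demes) * total_ne,
                       share(e_demes + n_demes) * total_ne,
                       total_ne],
            deme_to_refugium=mapping, total_ne=total_ne)

    raise ModelError(f"unknown hypothesis {hypothesis!r}")


# ---------------------------------------------------------------------------
# Gene trees


class GeneTree:
    """Binary ultrametric genealogy with branch lengths in generations.

    Tips are nodes ``0..n-1`` (time 0); internal nodes ``n..2n-2`` are
    stored in coalescence order, so iterating internal nodes in index order
    visits children before parents.
    """

    __slots__ = ("n_tips", "left", "right", "time", "tip_demes", "tip_ids")

    def __init__(self, n_tips: int, left: np.ndarray, right: np.ndarray,
                 time: np.ndarray, tip_demes: list[str],
                 tip_ids: list[str] | None = None):
        self.n_tips = n_tips
        self.left = left          # (n_tips-1,) child ids of internal nodes
        self.right = right
        self.time = time          # (2*n_tips-1,) node ages
        self.tip_demes = tip_demes
        self.tip_ids = tip_ids or [f"t{i}" for i in range(n_tips)]

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])

    def coalescent_intervals(self) -> tuple[np.ndarray, np.ndarray]:
        """(lineage count k, duration w_k) per inter-coalescent interval.

        Assumes all tips contemporary (ultrametric tree).  Interval i runs
        between the (i-1)-th and i-th coalescence and holds n - i lineages.
        """
        ct = np.sort(self.time[self.n_tips:])
        bounds = np.concatenate([[0.0], ct])
        w = np.diff(bounds)
        k = np.arange(self.n_tips, 1, -1)
        return k, w

    def newick(self, include_deme: bool = True) -> str:
        n = self.n_tips
        label = [
            f"{self.tip_ids[i]}@{self.tip_demes[i]}" if include_deme else self.tip_ids[i]
            for i in range(n)
        ]
        out = io.StringIO()

        def write(node: int, parent_time: float) -> None:
            if node < n:
                out.write(label[node])
            else:
                j = node - n
                out.write("(")
                write(int(self.left[j]), self.time[node])
                out.write(",")
                write(int(self.right[j]), self.time[node])
                out.write(")")
            out.write(f":{parent_time - self.time[node]:.10g}")

        root = 2 * n - 2
        out.write("(")
        write(int(self.left[root - n]), self.time[root])
        out.write(",")
        write(int(self.right[root - n]), self.time[root])
        out.write(");")
        return out.getvalue()

    @classmethod
    def from_dendropy(cls, tree, deme_of_sample: dict[str, str] | None = None,
                      label_sep: str = "@") -> "GeneTree":
        """Build from a rooted binary dendropy tree with ultrametric depths.

        Tip demes come from ``deme_of_sample`` keyed by taxon label, or from
        labels of the form ``sample@deme`` when no map is given.
        """
        leaves = [lf for lf in tree.leaf_node_iter()]
        n = len(leaves)
        tree.calc_node_ages(ultrametricity_precision=False)
        ids, demes = [], []
        index = {}
        for i, lf in enumerate(leaves):
            lab = lf.taxon.label if lf.taxon else lf.label
            if deme_of_sample is not None:
                sid, deme = lab, deme_of_sample.get(lab)
                if deme is None:
                    raise KeyError(f"no deme recorded for tip {lab!r}")
            elif label_sep in lab:
                sid, deme = lab.rsplit(label_sep, 1)
            else:
                raise KeyError(f"tip {lab!r} carries no deme label")
            ids.append(sid)
            demes.append(deme)
            index[id(lf)] = i
        internals = sorted(
            (nd for nd in tree.preorder_node_iter() if not nd.is_leaf()),
            key=lambda nd: nd.age)
        left = np.empty(n - 1, dtype=np.int64)
        right = np.empty(n - 1, dtype=np.int64)
        time = np.zeros(2 * n - 1)
        for j, nd in enumerate(internals):
            ch = nd.child_nodes()
            if len(ch) != 2:
                raise ValueError("gene tree must be binary; resolve polytomies first")
            node_id = n + j
            index[id(nd)] = node_id
            left[j] = index[id(ch[0])]
            right[j] = index[id(ch[1])]
            time[node_id] = nd.age
        if len(internals) != n - 1:
            raise ValueError("tree is not a binary rooted genealogy")
        return cls(n, left, right, time, demes, ids)


def _coalesce_in_branch(lineages: list[int], ne: float, t0: float, t1: float,
                        left: np.ndarray, right: np.ndarray, time: np.ndarray,
                        next_id: int, rng: np.random.Generator) -> tuple[float, int]:
    """Run a Kingman coalescent among ``lineages`` from t0 until t1 or MRCA.

    Pair-coalescence rate 1/ne per generation.  Mutates the tree arrays and
    the lineage list in place; returns (current time, next free node id).
    """
    t = t0
    k = len(lineages)
    while k > 1:
        rate = k * (k - 1) / 2.0 / ne
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > t1:
            return t1, next_id
        t = t_next
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        time[next_id] = t
        left[next_id - (len(time) + 1) // 2] = a
        right[next_id - (len(time) + 1) // 2] = b
        # replace i with the new lineage, remove j by swap-pop
        lineages[i] = next_id
        lineages[j] = lineages[k - 1]
        lineages.pop()
        next_id += 1
        k -= 1
    return t, next_id


def simulate_growth_gene_tree(n: int, ne0: float, growth_rate: float,
                              rng: np.random.Generator,
                              deme: str = "POP") -> GeneTree:
    """Panmictic coalescent genealogy under exponential growth.

    Ne(t) = ne0 * exp(-growth_rate * t), t in generations before present;
    positive rates mean the population has grown toward the present.  With
    k lineages at time t the next coalescence time solves the
    time-inhomogeneous exponential by inversion.
    """
    if n < 2:
        raise ValueError("need at least two tips")
    if ne0 <= 0:
        raise ValueError("ne0 must be positive")
    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    lineages = list(range(n))
    t = 0.0
    next_id = n
    g = growth_rate
    while len(lineages) > 1:
        k = len(lineages)
        c = k * (k - 1) / 2.0
        e = rng.exponential()
        if abs(g) < 1e-14:
            t = t + e * ne0 / c
        else:
            arg = math.exp(g * t) + g * ne0 * e / c
            if arg <= 0:  # declining population that never coalesces: restart tail
                t = t + e * ne0 * math.exp(-g * t) / c
            else:
                t = math.log(arg) / g
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        time[next_id] = t
        left[next_id - n] = lineages[i]
        right[next_id - n] = lineages[j]
        lineages[i] = next_id
        lineages[j] = lineages[k - 1]
        lineages.pop()
        next_id += 1
    return GeneTree(n, left, right, time, [deme] * n)


def simulate_gene_tree(model: RefugiumModel,
                       deme_sizes: dict[str, int],
                       rng: np.random.Generator) -> GeneTree:
    """Simulate one gene tree under the neutral coalescent within ``model``.

    Each sampled deme contributes ``deme_sizes[deme]`` contemporary tips in
    its mapped refugium; coalescence proceeds independently within each
    branch (rate 1/Ne_branch per pair) and surviving lineages pool at
    divergence nodes.  No migration between contemporaneous branches.
    """
    for d in deme_sizes:
        if d not in model.deme_to_refugium:
            raise ModelError(f"deme {d!r} not mapped to any refugium leaf")
        if deme_sizes[d] < 1:
            raise ModelError(f"deme {d!r} has size {deme_sizes[d]} < 1")

    tip_demes: list[str] = []
    for d, sz in deme_sizes.items():
        tip_demes.extend([d] * sz)
    n = len(tip_demes)
    left = np.empty(n - 1, dtype=np.int64)
    right = np.empty(n - 1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    next_id = n

    # tips per refugium leaf
    name_to_node = {nm: i for i, nm in enumerate(model.names)}
    pool: dict[int, list[int]] = {i: [] for i in range(len(model.names))}
    for tip, d in enumerate(tip_demes):
        pool[name_to_node[model.deme_to_refugium[d]]].append(tip)

    # process model nodes from the tips rootward
    order = sorted(range(len(model.names)), key=lambda i: model.node_time[i])
    root = model.root
    for i in order:
        t0 = model.node_time[i]
        if i == root:
            t1 = math.inf
        else:
            t1 = model.node_time[model.parent[i]]
        lineages = pool[i]
        _, next_id = _coalesce_in_branch(
            lineages, model.branch_ne[i], t0, t1, left, right, time, next_id, rng)
        if i != root:
            pool[model.parent[i]].extend(lineages)
            pool[i] = []
    return GeneTree(n, left, right, time, tip_demes)
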