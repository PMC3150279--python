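"""Synthetic study data with the statistical structure the analyses assume.

Generates mitochondrial-style alignments (finite-sites Jukes-Cantor
mutation on coalescent gene trees), diploid microsatellite tables
(stepwise mutation with reflecting allele-size boundaries), and per-location
environmental predictor tables with a tunable association between the
subregion structure and a latent genetic gradient.  Defaults mirror the
study design: ten demes with the published sample sizes grouped into three
eco-subregions, a 4,029-site alignment with per-site diversity of order
0.004, and ten microsatellite loci with a nine-state allele range.

All generators are deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dbrda import PredictorTable
from .models import (
    GeneTree, RefugiumModel, SUBREGION_OF_DEME, TABLE1_DEME_SIZES,
    simulate_gene_tree,
)
from .msat import GenotypeTable
from .seqstats import HaplotypeAlignment

__all__ = [
    "SyntheticStudyConfig", "simulate_sequences", "simulate_microsats",
    "simulate_env_table", "write_fixtures",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SyntheticStudyConfig:
    """Parameters of the synthetic study.

    ``mu_site`` is the per-site per-generation mutation rate; when left
    ``None`` it is derived from ``theta_target`` (per-site scaled
    diversity, theta = 2*Ne*mu) and the refugium model's total Ne at
    simulation time.  Microsatellite alleles follow a stepwise model
    reflected into [``msat_min_allele``, ``msat_max_allele``] (nine repeat
    states by default).
    """

    deme_names: list[str] = field(default_factory=lambda: list(TABLE1_DEME_SIZES))
    deme_sizes: dict[str, int] = field(default_factory=lambda: dict(TABLE1_DEME_SIZES))
    seq_length: int = 4029
    mu_site: float | None = None
    theta_target: float = 0.004
    infinite_sites: bool = False
    n_loci_msat: int = 10
    msat_mu: float = 1e-4
    msat_min_allele: int = 10
    msat_max_allele: int = 18
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.deme_names) != set(self.deme_sizes):
            raise ValueError("deme_names and deme_sizes disagree")
        if any(v < 1 for v in self.deme_sizes.values()):
            raise ValueError("deme sizes must be >= 1")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        if self.mu_site is not None and self.mu_site < 0:
            raise ValueError("mu_site must be non-negative")
        if self.msat_min_allele < 1 or self.msat_max_allele < self.msat_min_allele:
            raise ValueError("invalid allele-size bounds")

    @property
    def n_samples(self) -> int:
        return sum(self.deme_sizes.values())

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def site_rate(self, total_ne: float) -> float:
        if self.mu_site is not None:
            return self.mu_site
        return self.theta_target / (2.0 * total_ne)


def _sample_ids(config: SyntheticStudyConfig) -> list[str]:
    ids = []
    for d in config.deme_names:
        ids.extend(f"{d}_{i+1:02d}" for i in range(config.deme_sizes[d]))
    return ids


def _mutate_jc(tree: GeneTree, mu_site: float, length: int,
               rng: np.random.Generator) -> np.ndarray:
    """Finite-sites Jukes-Cantor evolution down a gene tree.

    Returns a (n_tips, length) array of base indices 0..3.  Mutation events
    are Poisson on each branch; each picks a uniform site and replaces the
    current base with one of the other three (multiple hits allowed).
    """
    n = tree.n_tips
    total = 2 * n - 1
    root = total - 1
    seqs = np.empty((total, length), dtype=np.uint8)
    seqs[root] = rng.integers(0, 4, size=length, dtype=np.uint8)
    # preorder: internal nodes in decreasing index order have parents after
    # them in coalescence order, so walk from the root down.
    children_of = {}
    for j in range(n - 1):
        children_of[n + j] = (int(tree.left[j]), int(tree.right[j]))
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        for child in children_of[node]:
            blen = tree.time[node] - tree.time[child]
            seq = seqs[node].copy()
            n_mut = rng.poisson(mu_site * length * blen)
            if n_mut:
                sites = rng.integers(0, length, size=n_mut)
                shifts = rng.integers(1, 4, size=n_mut).astype(np.uint8)
                for s, sh in zip(sites, shifts):
                    seq[s] = (seq[s] + sh) % 4
            seqs[child] = seq
            stack.append(child)
    return seqs[:n]


def _mutate_infinite_sites(tree: GeneTree, mu_site: float, length: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Infinite-sites variant: every mutation hits a previously unused site."""
    n = tree.n_tips
    root = 2 * n - 1 - 1
    seqs = np.zeros((2 * n - 1, length), dtype=np.uint8)
    seqs[root] = rng.integers(0, 4, size=length, dtype=np.uint8)
    used: set[int] = set()
    children_of = {n + j: (int(tree.left[j]), int(tree.right[j]))
                   for j in range(n - 1)}
    stack = [root]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        for child in children_of[node]:
            blen = tree.time[node] - tree.time[child]
            seq = seqs[node].copy()
            n_mut = rng.poisson(mu_site * length * blen)
            for _ in range(n_mut):
                free = length - len(used)
                if free == 0:
                    raise ValueError("alignment too short for infinite-sites run")
                s = int(rng.integers(0, length))
                while s in used:
                    s = int(rng.integers(0, length))
                used.add(s)
                seq[s] = (seq[s] + rng.integers(1, 4)) % 4
            seqs[child] = seq
            stack.append(child)
    return seqs[:n]


def simulate_sequences(model: RefugiumModel, config: SyntheticStudyConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[HaplotypeAlignment, GeneTree]:
    """One mitochondrial-style sequence per sample on a simulated genealogy.

    Returns the alignment together with the underlying gene tree (useful
    for demographic analyses on the true genealogy).
    """
    rng = rng if rng is not None else config.rng()
    tree = simulate_gene_tree(model, config.deme_sizes, rng)
    mu = config.site_rate(model.total_ne)
    if mu == 0:
        mat = np.tile(rng.integers(0, 4, size=config.seq_length, dtype=np.uint8),
                      (tree.n_tips, 1))
    elif config.infinite_sites:
        mat = _mutate_infinite_sites(tree, mu, config.seq_length, rng)
    else:
        mat = _mutate_jc(tree, mu, config.seq_length, rng)
    ids = _sample_ids(config)
    # tips are grouped by deme in config order, matching _sample_ids
    seqs = ["".join(_BASES[row].astype("U1")) for row in mat]
    deme_of = {sid: sid.rsplit("_", 1)[0] for sid in ids}
    tree.tip_ids = list(ids)
    return HaplotypeAlignment(seqs, ids, deme_of), tree


def _smm_branch(allele: int, n_mut: int, lo: int, hi: int,
                rng: np.random.Generator) -> int:
    for _ in range(n_mut):
        step = 1 if rng.random() < 0.5 else -1
        allele += step
        if allele > hi:
            allele = hi - 1 if hi > lo else hi  # reflect
        elif allele < lo:
            allele = lo + 1 if hi > lo else lo
    return allele


def simulate_microsats(model: RefugiumModel, config: SyntheticStudyConfig,
                       rng: np.random.Generator | None = None) -> GenotypeTable:
    """Diploid stepwise-mutation genotypes on per-locus gene trees.

    Each locus gets an independent genealogy of 2 gene copies per
    individual; mutations are +-1 repeat steps reflected at the configured
    allele-size boundaries.
    """
    if config.msat_mu < 0:
        raise ValueError("msat_mu must be non-negative")
    rng = rng if rng is not None else config.rng()
    ids = _sample_ids(config)
    n = len(ids)
    copy_sizes = {d: 2 * s for d, s in config.deme_sizes.items()}
    lo, hi = config.msat_min_allele, config.msat_max_allele
    root_allele = (lo + hi) // 2
    alleles = np.empty((n, config.n_loci_msat, 2), dtype=np.int64)
    for locus in range(config.n_loci_msat):
        tree = simulate_gene_tree(model, copy_sizes, rng)
        total = 2 * tree.n_tips - 1
        state = np.empty(total, dtype=np.int64)
        root = total - 1
        state[root] = root_allele
        children_of = {tree.n_tips + j: (int(tree.left[j]), int(tree.right[j]))
                       for j in range(tree.n_tips - 1)}
        stack = [root]
        while stack:
            node = stack.pop()
            if node < tree.n_tips:
                continue
            for child in children_of[node]:
                blen = tree.time[node] - tree.time[child]
                n_mut = rng.poisson(config.msat_mu * blen)
                state[child] = _smm_branch(int(state[node]), n_mut, lo, hi, rng)
                stack.append(child)
        # tips are grouped by deme in config order: copies 2i, 2i+1 -> sample i
        tip = 0
        sample = 0
        for d in config.deme_names:
            for _ in range(config.deme_sizes[d]):
                alleles[sample, locus, 0] = state[tip]
                alleles[sample, locus, 1] = state[tip + 1]
                tip += 2
                sample += 1
    demes = [sid.rsplit("_", 1)[0] for sid in ids]
    loci = [f"locus_{j+1}" for j in range(config.n_loci_msat)]
    return GenotypeTable(alleles, np.zeros((n, config.n_loci_msat), bool),
                         ids, demes, loci)


_VEG_TYPES = ["alpine_steppe", "alpine_meadow_shrub", "subalpine_shrub",
              "temperate_shrub", "subtropical_shrub"]
_SUBREGIONS = ["S", "E", "N"]


def simulate_env_table(locations: list[str], effect: float,
                       rng: np.random.Generator,
                       subregion_of: dict[str, str] | None = None
                       ) -> tuple[PredictorTable, pd.Series]:
    """Environmental predictors plus a latent genetic gradient.

    Returns the six predictor sets of the landscape analysis (coordinates,
    five one-hot vegetation states, three one-hot subregion states,
    elevation, three temperatures, rainfall) and a latent per-location
    gradient whose association with subregion is controlled by ``effect``
    (0 = independent; larger = subregion drives the gradient).
    """
    k = len(locations)
    if k < 3:
        raise ValueError("need at least three locations")
    if subregion_of is None:
        if all(loc in SUBREGION_OF_DEME for loc in locations):
            subregion_of = {loc: SUBREGION_OF_DEME[loc] for loc in locations}
        else:  # contiguous thirds
            subregion_of = {loc: _SUBREGIONS[min(3 * i // k, 2)]
                            for i, loc in enumerate(locations)}
    sub_idx = np.array([_SUBREGIONS.index(subregion_of[loc]) for loc in locations])

    # geography: subregional cluster centres with local scatter
    lat_centre = np.array([27.0, 31.0, 33.0])[sub_idx]
    lon_centre = np.array([100.0, 104.0, 99.0])[sub_idx]
    lat = lat_centre + rng.normal(0, 0.8, k)
    lon = lon_centre + rng.normal(0, 0.8, k)
    elevation = rng.normal(3000.0, 350.0, k)
    t_ann = 20.0 - 0.45 * lat - 0.004 * (elevation - 2500) + rng.normal(0, 0.7, k)
    t_jan = t_ann - 8.0 + rng.normal(0, 0.7, k)
    t_jul = t_ann + 9.0 + rng.normal(0, 0.7, k)
    rainfall = 900.0 - 0.08 * (elevation - 2500) + rng.normal(0, 120.0, k)

    veg = np.zeros((k, 5))
    # vegetation follows elevation bands with noise
    band = np.clip(((elevation - 2100.0) / 450.0).astype(int), 0, 4)
    band = np.clip(band + rng.integers(-1, 2, k), 0, 4)
    veg[np.arange(k), band] = 1.0
    sub_onehot = np.zeros((k, 3))
    sub_onehot[np.arange(k), sub_idx] = 1.0

    latent = pd.Series(effect * (sub_idx - 1.0) + rng.normal(0, 1.0, k),
                       index=locations, name="latent_gradient")

    df = pd.DataFrame({"lat": lat, "lon": lon, "elevation": elevation,
                       "t_annual": t_ann, "t_january": t_jan, "t_july": t_jul,
                       "rainfall": rainfall}, index=pd.Index(locations, name="location"))
    for j, v in enumerate(_VEG_TYPES):
        df[v] = veg[:, j]
    for j, s in enumerate(_SUBREGIONS):
        df[f"subregion_{s}"] = sub_onehot[:, j]
    sets = {
        "coordinate": ["lat", "lon"],
        "vegetation": list(_VEG_TYPES),
        "subregion": [f"subregion_{s}" for s in _SUBREGIONS],
        "elevation": ["elevation"],
        "temperature": ["t_annual", "t_january", "t_july"],
        "rainfall": ["rainfall"],
    }
    return PredictorTable(df, sets), latent


def write_fixtures(outputs: dict, directory: str | Path) -> list[Path]:
    """Write generated objects as plain-text fixtures; returns written paths.

    Recognized keys: ``alignment`` (FASTA + metadata TSV), ``gene_tree``
    (newick), ``genotypes`` (TSV), ``predictors`` (TSV), ``config``
    (JSON: every generator parameter and the seed).
    """
    from . import io as sio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    def mark(p: Path) -> Path:
        written.append(p)
        return p

    if "alignment" in outputs:
        aln: HaplotypeAlignment = outputs["alignment"]
        sio.write_fasta_alignment(aln, mark(directory / "sequences.fasta"))
        sio.write_metadata(aln.deme_of_sample, SUBREGION_OF_DEME,
                           mark(directory / "samples.tsv"))
    if "gene_tree" in outputs:
        tree = outputs["gene_tree"]
        text = tree.newick() if isinstance(tree, GeneTree) else tree
        sio.write_newick(text, mark(directory / "gene_tree.nwk"))
    if "genotypes" in outputs:
        sio.write_genotypes(outputs["genotypes"], mark(directory / "genotypes.tsv"))
    if "predictors" in outputs:
        sio.write_predictors(outputs["predictors"], mark(directory / "predictors.tsv"))
    if "config" in outputs:
        cfg = outputs["config"]
        payload = asdict(cfg) if isinstance(cfg, SyntheticStudyConfig) else dict(cfg)
        mark(directory / "generator_config.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return written
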