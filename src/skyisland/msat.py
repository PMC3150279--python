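"""Microsatellite diversity summaries, distances and assignment testing.

Implements per-deme, per-locus variation summaries (allele number, rarefied
allelic richness, observed and unbiased expected heterozygosity, F_IS), a
Monte-Carlo exact test of Hardy-Weinberg proportions, Nei's standard
genetic distance and pairwise F_ST between demes, and the frequency-based
assignment test with Monte-Carlo exclusion used to flag admixed
individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable", "LocusSummary", "locus_summaries", "hwe_exact",
    "bonferroni", "genetic_distances", "assignment_exclusion",
]


@dataclass
class GenotypeTable:
    """Diploid allele-size matrix: (n_samples, n_loci, 2) integer repeats.

    Missing genotypes are encoded by ``mask`` (True = missing); allele
    sizes are positive integers (repeat counts or fragment lengths).
    """

    alleles: np.ndarray              # (n, L, 2) int
    mask: np.ndarray                 # (n, L) bool, True = missing
    samples: list[str]
    demes: list[str]
    loci: list[str]

    def __post_init__(self) -> None:
        n, L, two = self.alleles.shape
        if two != 2:
            raise ValueError("two alleles per sample x locus required")
        if self.mask.shape != (n, L):
            raise ValueError("mask shape mismatch")
        if len(self.samples) != n or len(self.demes) != n or len(self.loci) != L:
            raise ValueError("metadata length mismatch")
        if (self.alleles[~self.mask] <= 0).any():
            raise ValueError("allele sizes must be positive integers")
        if self.mask.all(axis=0).any():
            bad = [self.loci[j] for j in np.flatnonzero(self.mask.all(axis=0))]
            raise ValueError(f"loci with 100% missing data: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def deme_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.demes:
            seen.setdefault(d, None)
        return list(seen)

    def deme_indices(self, deme: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.demes) == deme)

    def gene_copies(self, deme: str, locus_idx: int) -> np.ndarray:
        """Non-missing allele copies for one deme at one locus."""
        idx = self.deme_indices(deme)
        ok = idx[~self.mask[idx, locus_idx]]
        return self.alleles[ok, locus_idx, :].ravel()

    def to_frame(self) -> pd.DataFrame:
        """Tab-file layout: sample, deme, <locus>_a/<locus>_b columns; NA missing."""
        data: dict[str, list] = {"sample": self.samples, "deme": self.demes}
        for j, loc in enumerate(self.loci):
            for k, suffix in enumerate(("a", "b")):
                col = [(str(self.alleles[i, j, k]) if not self.mask[i, j] else "NA")
                       for i in range(self.n_samples)]
                data[f"{loc}_{suffix}"] = col
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        cols = list(df.columns)
        loci = sorted({c[:-2] for c in cols if c.endswith("_a")},
                      key=lambda loc: cols.index(f"{loc}_a"))
        n, L = len(df), len(loci)
        alleles = np.ones((n, L, 2), dtype=np.int64)
        mask = np.zeros((n, L), dtype=bool)
        for j, loc in enumerate(loci):
            for k, suffix in enumerate(("a", "b")):
                col = df[f"{loc}_{suffix}"].astype(str).to_numpy()
                miss = (col == "NA") | (col == "nan") | (col == "<NA>")
                mask[:, j] |= miss
                vals = np.where(miss, "1", col).astype(np.int64)
                alleles[:, j, k] = vals
        return cls(alleles, mask, df["sample"].tolist(), df["deme"].tolist(), loci)


@dataclass(frozen=True)
class LocusSummary:
    deme: str
    locus: str
    n_typed: int                 # genotyped individuals
    n_alleles: int
    allelic_richness: float      # rarefied
    observed_het: float
    expected_het: float          # unbiased
    f_is: float | None           # None when H_E = 0


def _allele_freqs(copies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, counts = np.unique(copies, return_counts=True)
    return vals, counts / len(copies)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a subsample of g gene copies (ElMousadik/Petit)."""
    N = counts.sum()
    g = min(g, int(N))
    total = 0.0
    for c in counts:
        if N - c >= g:
            total += 1.0 - math.comb(int(N - c), g) / math.comb(int(N), g)
        else:
            total += 1.0
    return total


def locus_summaries(table: GenotypeTable,
                    rarefaction: str = "min-gene-count") -> list[LocusSummary]:
    """Per deme x locus summaries mirroring a standard variation table.

    H_E is the unbiased estimator (2n/(2n-1))(1 - sum p^2); allelic
    richness is rarefied to the smallest per-deme gene count among demes
    typed at that locus; F_IS = 1 - H_O/H_E (None when H_E = 0).  Deme x
    locus cells with no genotyped individual are omitted.
    """
    out = []
    demes = table.deme_names()
    for j, locus in enumerate(table.loci):
        gene_counts = []
        for d in demes:
            copies = table.gene_copies(d, j)
            if len(copies):
                gene_counts.append(len(copies))
        g = min(gene_counts) if rarefaction == "min-gene-count" else None
        for d in demes:
            copies = table.gene_copies(d, j)
            if len(copies) == 0:
                continue
            idx = table.deme_indices(d)
            typed = idx[~table.mask[idx, j]]
            n_ind = len(typed)
            vals, freqs = _allele_freqs(copies)
            counts = np.array([(copies == v).sum() for v in vals])
            two_n = len(copies)
            sum_p2 = float(freqs @ freqs)
            he = 0.0 if two_n < 2 else (two_n / (two_n - 1)) * (1.0 - sum_p2)
            ho = float(np.mean(table.alleles[typed, j, 0] != table.alleles[typed, j, 1]))
            fis = None if he == 0 else 1.0 - ho / he
            ar = _rarefied_richness(counts, g if g is not None else two_n)
            out.append(LocusSummary(d, locus, n_ind, len(vals), ar, ho, he, fis))
    return out


def summaries_frame(summaries: list[LocusSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "deme": s.deme, "locus": s.locus, "n": s.n_typed, "N_A": s.n_alleles,
        "A_R": s.allelic_richness, "H_O": s.observed_het, "H_E": s.expected_het,
        "F_IS": (np.nan if s.f_is is None else s.f_is)} for s in summaries])


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def _genotype_log_weight(genos: np.ndarray) -> float:
    """Variable part of the conditional genotype probability given allele
    counts: 2^H / prod(genotype count factorials)."""
    het = int((genos[:, 0] != genos[:, 1]).sum())
    pairs = [tuple(sorted(g)) for g in genos]
    _, counts = np.unique(np.array(pairs), axis=0, return_counts=True)
    return het * math.log(2.0) - float(sum(math.lgamma(c + 1) for c in counts))


def hwe_exact(table: GenotypeTable, deme: str, locus: str,
              n_mc: int = 2000, rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions.

    Gene copies are reshuffled into diploid genotypes; the P value is the
    proportion of shuffles whose conditional probability does not exceed
    the observed one (add-one corrected).  Monomorphic data give P = 1.
    """
    rng = rng or np.random.default_rng()
    j = table.loci.index(locus)
    idx = table.deme_indices(deme)
    typed = idx[~table.mask[idx, j]]
    if len(typed) < 3:
        raise ValueError(f"{deme}/{locus}: need >=3 genotyped individuals")
    genos = table.alleles[typed, j, :]
    copies = genos.ravel().copy()
    if len(np.unique(copies)) == 1:
        return 1.0
    obs = _genotype_log_weight(genos)
    hits = 0
    for _ in range(n_mc):
        rng.shuffle(copies)
        sim = copies.reshape(-1, 2)
        if _genotype_log_weight(sim) <= obs + 1e-12:
            hits += 1
    return (1 + hits) / (n_mc + 1)


def bonferroni(p_values: dict, alpha: float = 0.05) -> dict:
    """Bonferroni-corrected significance flags across a family of tests."""
    k = len(p_values)
    return {key: p < alpha / k for key, p in p_values.items()}


# ---------------------------------------------------------------------------
# Genetic distances


def _freq_tables(table: GenotypeTable) -> dict[int, dict[str, dict[int, float]]]:
    """locus -> deme -> allele -> frequency (typed copies only)."""
    out: dict[int, dict[str, dict[int, float]]] = {}
    for j in range(table.n_loci):
        out[j] = {}
        for d in table.deme_names():
            copies = table.gene_copies(d, j)
            if len(copies) == 0:
                continue
            vals, freqs = _allele_freqs(copies)
            out[j][d] = dict(zip(vals.tolist(), freqs.tolist()))
    return out


def _nei_standard(freqs: dict[int, dict[str, dict[int, float]]],
                  x: str, y: str) -> float:
    jx = jy = jxy = 0.0
    n_loci = 0
    for j, by_deme in freqs.items():
        if x not in by_deme or y not in by_deme:
            continue
        px, py = by_deme[x], by_deme[y]
        jx += sum(p * p for p in px.values())
        jy += sum(p * p for p in py.values())
        jxy += sum(p * py.get(a, 0.0) for a, p in px.items())
        n_loci += 1
    if n_loci == 0:
        raise ValueError(f"no shared typed loci between {x} and {y}")
    jx, jy, jxy = jx / n_loci, jy / n_loci, jxy / n_loci
    if jxy == 0:
        return float("inf")
    return float(max(-math.log(jxy / math.sqrt(jx * jy)), 0.0))


def _wc_fst_pair(table: GenotypeTable, x: str, y: str) -> float:
    """Weir & Cockerham (1984) theta for two demes, averaged over loci."""
    num = den = 0.0
    r = 2.0
    for j in range(table.n_loci):
        data = []
        for d in (x, y):
            idx = table.deme_indices(d)
            typed = idx[~table.mask[idx, j]]
            if len(typed) == 0:
                data = []
                break
            data.append(table.alleles[typed, j, :])
        if not data:
            continue
        n_i = np.array([len(g) for g in data], dtype=float)
        n_bar = n_i.mean()
        if n_bar == 0:
            continue
        n_c = (n_i.sum() - (n_i ** 2).sum() / n_i.sum()) / (r - 1)
        alleles = np.unique(np.concatenate([g.ravel() for g in data]))
        for a in alleles:
            p_i = np.array([(g == a).mean() for g in data])
            h_i = np.array([((g[:, 0] == a) ^ (g[:, 1] == a)).mean() for g in data])
            p_bar = float((n_i * p_i).sum() / n_i.sum())
            s2 = float((n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar))
            h_bar = float((n_i * h_i).sum() / n_i.sum())
            a_comp = (n_bar / n_c) * (s2 - (1.0 / (n_bar - 1)) *
                                      (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4))
            b_comp = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar)
                                              - (r - 1) / r * s2
                                              - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c_comp = h_bar / 2
            num += a_comp
            den += a_comp + b_comp + c_comp
    if den == 0:
        return 0.0
    return float(max(num / den, 0.0))


def genetic_distances(table: GenotypeTable, kind: str = "nei_standard") -> pd.DataFrame:
    """Deme x deme distance matrix: Nei (1972) standard D or pairwise F_ST."""
    demes = table.deme_names()
    if len(demes) < 2:
        raise ValueError("need at least two demes")
    freqs = _freq_tables(table) if kind == "nei_standard" else None
    k = len(demes)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            if kind == "nei_standard":
                val = _nei_standard(freqs, demes[a], demes[b])
            elif kind == "fst":
                val = _wc_fst_pair(table, demes[a], demes[b])
            else:
                raise ValueError(f"unknown distance kind {kind!r}")
            out[a, b] = out[b, a] = val
    return pd.DataFrame(out, index=demes, columns=demes)


# ---------------------------------------------------------------------------
# Assignment / exclusion


def _log_likelihood(genotype: np.ndarray, missing: np.ndarray,
                    freqs: list[dict[int, float]], floor: float) -> float:
    ll = 0.0
    for j, f in enumerate(freqs):
        if missing[j]:
            continue
        a, b = int(genotype[j, 0]), int(genotype[j, 1])
        pa = f.get(a, floor)
        pb = f.get(b, floor)
        ll += math.log(2 * pa * pb) if a != b else math.log(pa * pa)
    return ll


def assignment_exclusion(table: GenotypeTable,
                         n_sim: int = 1000,
                         alpha: float = 0.01,
                         rng: np.random.Generator | None = None,
                         floor: str | float = "1/(2n+1)") -> pd.DataFrame:
    """Frequency-based assignment with Monte-Carlo exclusion.

    Each individual's genotype log-likelihood is computed in every
    reference deme from allele frequencies (zero-frequency alleles replaced
    by a floor, default 1/(2n+1) with n the deme's gene count).  ``n_sim``
    genotypes per deme, drawn by gamete resampling from the deme's
    frequencies, form the exclusion null: an individual is excluded from
    its sampling deme when its likelihood there falls below the ``alpha``
    quantile of the simulated likelihoods.  Returns one row per individual:
    sampling deme, assigned deme (highest likelihood), excluded flag.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    rng = rng or np.random.default_rng()
    demes = table.deme_names()
    L = table.n_loci

    freq_by_deme: dict[str, list[dict[int, float]]] = {}
    floor_by_deme: dict[str, float] = {}
    for d in demes:
        fl = []
        counts = []
        for j in range(L):
            copies = table.gene_copies(d, j)
            counts.append(len(copies))
            vals, freqs = (np.array([]), np.array([])) if len(copies) == 0 \
                else _allele_freqs(copies)
            fl.append(dict(zip(vals.tolist(), freqs.tolist())))
        freq_by_deme[d] = fl
        n_copies = max(max(counts), 1)
        floor_by_deme[d] = (1.0 / (2 * n_copies + 1)) if floor == "1/(2n+1)" else float(floor)

    # exclusion null per deme
    null_threshold: dict[str, float] = {}
    for d in demes:
        sims = np.empty(n_sim)
        fl = freq_by_deme[d]
        draws = []
        for j in range(L):
            alleles = np.array(list(fl[j]) or [0])
            probs = np.array([fl[j][a] for a in fl[j]] or [1.0])
            draws.append(alleles[rng.choice(len(alleles), size=(n_sim, 2), p=probs)])
        geno = np.stack(draws, axis=1)  # (n_sim, L, 2)
        nomiss = np.zeros(L, dtype=bool)
        for s in range(n_sim):
            sims[s] = _log_likelihood(geno[s], nomiss, fl, floor_by_deme[d])
        null_threshold[d] = float(np.quantile(sims, alpha))

    rows = []
    for i, sample in enumerate(table.samples):
        if table.mask[i].all():
            warnings.warn(f"sample {sample!r} untyped at every locus; skipped")
            continue
        home = table.demes[i]
        lls = {d: _log_likelihood(table.alleles[i], table.mask[i],
                                  freq_by_deme[d], floor_by_deme[d])
               for d in demes}
        assigned = max(lls, key=lls.get)
        rows.append({
            "sample": sample, "sampling_deme": home, "assigned_deme": assigned,
            "log_likelihood_home": lls[home],
            "excluded": bool(lls[home] < null_threshold[home]),
        })
    return pd.DataFrame(rows)
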