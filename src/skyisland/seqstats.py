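"""Sequence-level diversity and neutrality statistics for mtDNA alignments.

Covers the per-population and combined polymorphism summaries (segregating
sites, haplotype number and diversity, nucleotide diversity, Watterson's
theta), Fu's Fs and Fu & Li's D neutrality tests, the McDonald-Kreitman
test for coding fragments, and deme-level genetic distance matrices
(uncorrected p-distance and AMOVA-based Phi_ST) used downstream in the
landscape-genetic regression.

Alignment columns containing gaps or ambiguity codes are removed before any
statistic is computed (complete deletion; pairwise deletion available via a
flag on :func:`polymorphism_summary`).  Haplotypes are exact string matches
on the retained columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

VALID_BASES = frozenset(b"ACGT")


class InsufficientDataError(ValueError):
    """Fewer sequences or polymorphic sites than the statistic needs."""


class UndefinedStatisticError(ValueError):
    """The statistic is undefined on this input (e.g. monomorphic data)."""


@dataclass
class HaplotypeAlignment:
    """Equal-length nucleotide sequences with deme metadata.

    ``sequences`` are upper-case strings over the IUPAC alphabet; anything
    outside A/C/G/T (gaps, N, ambiguity codes) marks its column for removal.
    ``outgroup`` sequences are excluded from ingroup statistics and only
    used to orient mutations.
    """

    sequences: list[str]
    sample_ids: list[str]
    deme_of_sample: dict[str, str]
    outgroup: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.sample_ids):
            raise ValueError("one id per sequence required")
        lengths = {len(s) for s in self.sequences}
        if self.outgroup:
            lengths |= {len(s) for s in self.outgroup.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.outgroup:
            self.outgroup = {k: v.upper() for k, v in self.outgroup.items()}
        missing = [s for s in self.sample_ids if s not in self.deme_of_sample]
        if missing:
            raise ValueError(f"samples without deme metadata: {missing[:5]}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def demes(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.deme_of_sample[s], None)
        return list(seen)

    def subset(self, sample_ids: list[str]) -> "HaplotypeAlignment":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        return HaplotypeAlignment(
            sequences=[self.sequences[idx[s]] for s in sample_ids],
            sample_ids=list(sample_ids),
            deme_of_sample={s: self.deme_of_sample[s] for s in sample_ids},
            outgroup=self.outgroup)

    def matrix(self, include_outgroup: bool = False) -> np.ndarray:
        """Byte matrix (n_seq x L) of the raw alignment."""
        seqs = list(self.sequences)
        if include_outgroup and self.outgroup:
            seqs += list(self.outgroup.values())
        return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)

    def clean_columns(self, include_outgroup: bool = False) -> np.ndarray:
        """Alignment matrix after complete deletion of gap/ambiguity columns."""
        m = self.matrix(include_outgroup=include_outgroup)
        valid = np.isin(m, [b"A", b"C", b"G", b"T"]).all(axis=0)
        return m[:, valid]


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i ** power for i in range(1, n)))


@dataclass(frozen=True)
class PolymorphismSummary:
    scope: str
    n: int
    sites: int                  # retained sites after column deletion
    seg_sites: int
    n_haplotypes: int
    haplotype_diversity: float
    nucleotide_diversity: float
    watterson_theta: float      # per locus

    def as_row(self) -> dict:
        return {
            "scope": self.scope, "n": self.n, "L": self.sites,
            "S": self.seg_sites, "Nhap": self.n_haplotypes,
            "Hd": self.haplotype_diversity, "pi": self.nucleotide_diversity,
            "theta_w": self.watterson_theta,
        }


def _summary_from_matrix(m: np.ndarray, scope: str) -> PolymorphismSummary:
    n, L = m.shape
    if n < 2:
        raise InsufficientDataError(f"scope {scope!r} has n={n} < 2 sequences")
    seg = int((np.ptp(m.view(np.uint8), axis=0) > 0).sum()) if L else 0
    haps = pd.Series(["".join(row.astype(str)) for row in m.astype("U1")])
    counts = haps.value_counts().to_numpy()
    k = len(counts)
    p = counts / n
    hd = 0.0 if k == 1 else n * (1.0 - float(p @ p)) / (n - 1)
    # mean pairwise difference per retained site
    diff_total = 0
    for i, j in combinations(range(n), 2):
        diff_total += int((m[i] != m[j]).sum())
    pi = 0.0 if L == 0 else diff_total / (n * (n - 1) / 2) / L
    theta_w = seg / _harmonic(n)
    return PolymorphismSummary(scope, n, L, seg, k, hd, pi, theta_w)


def polymorphism_summary(alignment: HaplotypeAlignment,
                         scope: str = "all",
                         deletion: str = "complete") -> list[PolymorphismSummary]:
    """Diversity summaries for the whole ingroup or each deme.

    ``scope`` is ``"all"`` or ``"per-deme"``.  S counts segregating sites on
    the retained columns; Hd uses the unbiased estimator n(1-sum p_i^2)/(n-1);
    pi is the mean pairwise difference per retained site; Watterson's theta
    (per locus) is S/a_{n-1}.  ``deletion="pairwise"`` restricts column
    removal to the sequences in each scope rather than the full alignment.
    """
    if scope not in ("all", "per-deme"):
        raise ValueError("scope must be 'all' or 'per-deme'")
    out = []
    if scope == "all":
        groups = [("combined", alignment)]
    else:
        groups = [(d, alignment.subset(
            [s for s in alignment.sample_ids if alignment.deme_of_sample[s] == d]))
            for d in alignment.demes()]
    for name, sub in groups:
        if deletion == "complete" and scope == "per-deme":
            # columns removed with respect to the full ingroup alignment
            full = alignment.matrix()
            valid = np.isin(full, [b"A", b"C", b"G", b"T"]).all(axis=0)
            idx = [alignment.sample_ids.index(s) for s in sub.sample_ids]
            m = full[np.asarray(idx)][:, valid]
        else:
            m = sub.clean_columns()
        out.append(_summary_from_matrix(m, name))
    return out


# ---------------------------------------------------------------------------
# Fu's Fs


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        new[1:m + 1] = row[0:m]
        if m > 1:
            with np.errstate(invalid="ignore"):
                new[1:m] = np.logaddexp(new[1:m], np.log(m - 1) + row[1:m])
        row = new
    return row


def ewens_k_tail(n: int, k_obs: int, theta: float) -> float:
    """Pr(K >= k_obs) for the number of alleles K under the Ewens distribution.

    Pr(K = k) = |s(n,k)| theta^k / theta^(n) with theta^(n) the rising
    factorial; evaluated in log space via the Stirling-number recursion.
    """
    if theta <= 0:
        raise UndefinedStatisticError("theta must be positive")
    ls = _log_stirling_row(n)
    lt = np.log(theta)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    log_pk = ls[1:n + 1] + lt * np.arange(1, n + 1) - log_rising
    return float(np.exp(logsumexp(log_pk[k_obs - 1:])))


def fu_fs(alignment: HaplotypeAlignment) -> float:
    """Fu's Fs: log-odds of seeing at least the observed number of haplotypes.

    With theta estimated by the mean pairwise difference (per locus), the
    Ewens sampling distribution gives S' = Pr(K >= k_obs); Fs = ln(S'/(1-S')).
    Large negative values indicate an excess of haplotypes, the signature of
    population growth (or a selective sweep).
    """
    m = alignment.clean_columns()
    n, L = m.shape
    if n < 2:
        raise InsufficientDataError("Fu's Fs needs at least two sequences")
    summ = _summary_from_matrix(m, "fs")
    theta = summ.nucleotide_diversity * L
    if summ.seg_sites == 0 or theta == 0:
        raise UndefinedStatisticError("Fu's Fs is undefined on monomorphic data")
    sp = ewens_k_tail(n, summ.n_haplotypes, theta)
    if sp <= 0.0 or sp >= 1.0:
        raise UndefinedStatisticError(f"S'={sp} leaves Fs undefined")
    return float(np.log(sp / (1.0 - sp)))


# ---------------------------------------------------------------------------
# Fu & Li's D


def _fu_li_coeffs(n: int) -> tuple[float, float]:
    """(u_D, v_D) weights for Fu & Li's D with an outgroup."""
    a_n = _harmonic(n)
    b_n = _harmonic(n, 2)
    if n == 2:
        c_n = 1.0
    else:
        c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    v = 1.0 + (a_n ** 2 / (b_n + a_n ** 2)) * (c_n - (n + 1) / (n - 1))
    u = a_n - 1.0 - v
    return u, v


def _fu_li_star_coeffs(n: int) -> tuple[float, float]:
    """(u_D*, v_D*) weights for the outgroup-free D* variant."""
    a_n = _harmonic(n)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    b_n = _harmonic(n, 2)
    if n == 2:
        c_n = 1.0
    else:
        c_n = 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    d_n = (c_n + (n - 2) / ((n - 1) ** 2)
           + (2.0 / (n - 1)) * (1.5 - (2.0 * a_n1 - 3.0) / (n - 2) - 1.0 / n))
    nn = n / (n - 1.0)
    v = (nn ** 2 * b_n + a_n ** 2 * d_n - 2.0 * n * a_n * (a_n + 1) / ((n - 1) ** 2)) \
        / (a_n ** 2 + b_n)
    u = nn * (a_n - nn) - v
    return u, v


def _eta_counts(m_in: np.ndarray, out_row: np.ndarray | None) -> tuple[int, int]:
    """(total mutations eta, singleton mutations eta_s) per site-wise count.

    Mutations per site = number of distinct ingroup bases - 1.  A singleton
    is a base carried by exactly one ingroup sequence; with an outgroup row
    only bases differing from the outgroup state count (derived singletons).
    """
    n, L = m_in.shape
    eta = eta_s = 0
    for col in range(L):
        vals, counts = np.unique(m_in[:, col], return_counts=True)
        eta += len(vals) - 1
        if len(vals) == 1:
            continue
        for v, c in zip(vals, counts):
            if c == 1 and (out_row is None or v != out_row[col]):
                eta_s += 1
    return eta, eta_s


def fu_li_d(alignment: HaplotypeAlignment, outgroup_id: str | None = None) -> float:
    """Fu & Li's D, orienting singletons with a designated outgroup sequence.

    D = (eta - a_n * eta_s) / sqrt(u_D * eta + v_D * eta^2); an excess of
    external-branch (singleton) mutations drives D negative.
    """
    if not alignment.outgroup:
        raise ValueError("Fu & Li's D requires an outgroup; use fu_li_d_star")
    if outgroup_id is None:
        outgroup_id = next(iter(alignment.outgroup))
    m = alignment.clean_columns(include_outgroup=True)
    n_in = alignment.n
    og_index = n_in + list(alignment.outgroup).index(outgroup_id)
    m_in, out_row = m[:n_in], m[og_index]
    if n_in < 3:
        raise InsufficientDataError("Fu & Li's D needs at least three sequences")
    eta, eta_s = _eta_counts(m_in, out_row)
    if eta == 0:
        raise UndefinedStatisticError("no polymorphism: Fu & Li's D undefined")
    u, v = _fu_li_coeffs(n_in)
    a_n = _harmonic(n_in)
    return float((eta - a_n * eta_s) / np.sqrt(u * eta + v * eta ** 2))


def fu_li_d_star(alignment: HaplotypeAlignment) -> float:
    """Outgroup-free variant D*: singletons are bases unique to one sequence."""
    m_in = alignment.clean_columns()
    n = alignment.n
    if n < 3:
        raise InsufficientDataError("Fu & Li's D* needs at least three sequences")
    eta, eta_s = _eta_counts(m_in, None)
    if eta == 0:
        raise UndefinedStatisticError("no polymorphism: Fu & Li's D* undefined")
    u, v = _fu_li_star_coeffs(n)
    a_n = _harmonic(n)
    nn = n / (n - 1.0)
    return float((nn * eta - a_n * eta_s) / np.sqrt(u * eta + v * eta ** 2))


# ---------------------------------------------------------------------------
# McDonald-Kreitman


_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def _translate(codon: str, table: dict[str, str]) -> str:
    return table.get(codon, "X")


def mk_test(alignment: HaplotypeAlignment, outgroup_id: str | None = None,
            genetic_code: dict[str, str] | None = None) -> dict:
    """McDonald-Kreitman 2x2 table and two-sided Fisher exact P.

    Variable sites within the ingroup are polymorphisms; sites where the
    ingroup is fixed but differs from the outgroup are fixed differences.
    Each is classified synonymous/nonsynonymous by substituting the variant
    base into the majority-codon background.  With no fixed differences (a
    degenerate margin) P = 1 by convention.
    """
    if alignment.length % 3:
        raise ValueError(f"alignment length {alignment.length} is not a "
                         "multiple of 3; in-frame coding sequence required")
    if not alignment.outgroup:
        raise ValueError("the MK test requires an outgroup")
    if outgroup_id is None:
        outgroup_id = next(iter(alignment.outgroup))
    code = genetic_code or _CODON_TABLE
    m = alignment.matrix(include_outgroup=True)
    n_in = alignment.n
    og = m[n_in + list(alignment.outgroup).index(outgroup_id)]
    m_in = m[:n_in]
    # columns with gap/ambiguity anywhere are masked, frame is kept
    ok = np.isin(m_in, [b"A", b"C", b"G", b"T"]).all(axis=0) \
        & np.isin(og, [b"A", b"C", b"G", b"T"])

    counts = {("syn", "poly"): 0, ("non", "poly"): 0,
              ("syn", "fixed"): 0, ("non", "fixed"): 0}
    L = alignment.length
    for start in range(0, L, 3):
        cols = [start, start + 1, start + 2]
        if not all(ok[c] for c in cols):
            continue
        codons = m_in[:, cols].astype("U1")
        joined = ["".join(row) for row in codons]
        background = max(set(joined), key=joined.count)
        og_codon = "".join(og[cols].astype("U1"))
        for pos in range(3):
            col = start + pos
            bases = set(m_in[:, col].astype("U1"))
            if len(bases) > 1:  # polymorphic within ingroup
                ref = background[pos]
                for b in bases - {ref}:
                    mutant = background[:pos] + b + background[pos + 1:]
                    kind = "syn" if _translate(mutant, code) == _translate(background, code) else "non"
                    counts[(kind, "poly")] += 1
            else:
                b_in = next(iter(bases))
                b_out = og_codon[pos]
                if b_in != b_out:
                    mutant = background[:pos] + b_out + background[pos + 1:]
                    kind = "syn" if _translate(mutant, code) == _translate(background, code) else "non"
                    counts[(kind, "fixed")] += 1

    table = np.array([[counts[("syn", "poly")], counts[("syn", "fixed")]],
                      [counts[("non", "poly")], counts[("non", "fixed")]]])
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "p_value": float(p)}


# ---------------------------------------------------------------------------
# Distance matrices


def _pairwise_diff_matrix(m: np.ndarray) -> np.ndarray:
    """(n x n) counts of differing sites between sequence rows."""
    u = m.view(np.uint8)
    return (u[:, None, :] != u[None, :, :]).sum(axis=2)


def amova_phi_st(diff: np.ndarray, groups: np.ndarray,
                 truncate: bool = True) -> float:
    """Phi_ST from AMOVA variance components on squared pairwise distances.

    ``diff`` holds pairwise differences (used as squared Euclidean
    distances, as is standard for haplotype mismatch counts); ``groups``
    labels each row.  Truncated at 0 unless ``truncate=False`` (useful for
    null calibration, where the untruncated estimator is centred at 0).
    """
    labels = np.unique(groups)
    n_tot = len(groups)
    if len(labels) < 2:
        raise InsufficientDataError("Phi_ST needs at least two demes")
    ssd_total = diff[np.triu_indices(n_tot, 1)].sum() / n_tot
    ssd_within = 0.0
    sizes = []
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sizes.append(len(idx))
        sub = diff[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    sizes = np.asarray(sizes, dtype=float)
    df_a = len(labels) - 1
    df_w = n_tot - len(labels)
    if df_w == 0:
        return 1.0
    sigma_w = ssd_within / df_w
    n_c = (n_tot - float((sizes ** 2).sum()) / n_tot) / df_a
    msd_a = (ssd_total - ssd_within) / df_a
    sigma_a = (msd_a - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0 if truncate else float("nan")
    phi = sigma_a / denom
    return float(max(phi, 0.0)) if truncate else float(phi)


def distance_matrices(alignment: HaplotypeAlignment,
                      kind: str = "p-distance",
                      min_deme_size: int = 2) -> pd.DataFrame:
    """Symmetric deme x deme genetic distance matrix.

    ``kind="p-distance"``: mean between-deme uncorrected p-distance.
    ``kind="phi_st"``: pairwise AMOVA Phi_ST on mismatch counts, truncated
    at 0.  Demes with fewer than ``min_deme_size`` sequences are excluded
    (Phi_ST variance components need within-deme pairs).
    """
    m = alignment.clean_columns()
    L = m.shape[1]
    demes = np.array([alignment.deme_of_sample[s] for s in alignment.sample_ids])
    keep = [d for d in alignment.demes()
            if (demes == d).sum() >= (min_deme_size if kind == "phi_st" else 1)]
    diff = _pairwise_diff_matrix(m)
    k = len(keep)
    out = np.zeros((k, k))
    for a in range(k):
        ia = np.flatnonzero(demes == keep[a])
        for b in range(a + 1, k):
            ib = np.flatnonzero(demes == keep[b])
            if kind == "p-distance":
                val = diff[np.ix_(ia, ib)].mean() / L
            elif kind == "phi_st":
                idx = np.concatenate([ia, ib])
                val = amova_phi_st(diff[np.ix_(idx, idx)],
                                   np.array([0] * len(ia) + [1] * len(ib)))
            else:
                raise ValueError(f"unknown distance kind {kind!r}")
            out[a, b] = out[b, a] = val
    return pd.DataFrame(out, index=keep, columns=keep)
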