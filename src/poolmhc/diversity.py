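"""Per-barcode diversity and selection statistics for pooled amplicon panels.

Implements, from first principles, the statistics reported per colony and
locus in pooled MHC amplicon surveys: segregating sites S, number of
alleles A and A/N, haplotype (allelic) diversity Hd, nucleotide diversity
pi, Tajima's D, Fu's Fs via the Ewens sampling formula, and the
Nei-Gojobori Ka/Ks ratio with Jukes-Cantor correction.

Statistics are computed over reads by default: each retained variant is
weighted by its read count within the barcode, mirroring a workflow in
which the full cleaned read set for a barcode is handed to the statistics
program. An unweighted mode (one copy per distinct allele) is available via
``weighting="alleles"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import pearsonr

from poolmhc._codon import codon_path_differences, codon_sites, is_stop

__all__ = [
    "BarcodePanel",
    "DiversitySummary",
    "segregating_sites",
    "allelic_diversity",
    "nucleotide_diversity",
    "tajimas_d",
    "fus_fs",
    "ka_ks",
    "alleles_per_individual",
    "mean_centered_diversity",
    "diversity_table",
    "tajima_constants",
]

_VALID = frozenset("ACGT")


@dataclass
class BarcodePanel:
    """Aligned retained variants of one locus in one barcode.

    Sequences must share a common length L (gap characters ``-`` are
    permitted for in-frame indels); ``counts[i]`` is the read count backing
    ``sequences[i]`` within this barcode.
    """

    barcode: str
    locus: str
    sequences: list[str]
    counts: np.ndarray
    n_individuals: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.sequences) != len(self.counts):
            raise ValueError("sequences and counts must have equal length")
        if len(self.sequences) == 0:
            raise ValueError("empty panel")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"panel sequences must be aligned to a common length, got {sorted(lengths)}"
            )
        if np.any(self.counts < 1):
            raise ValueError("all variant counts must be >= 1")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("panel sequences must be pairwise distinct")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_alleles(self) -> int:
        return len(self.sequences)

    def weights(self, weighting: str = "reads") -> np.ndarray:
        if weighting == "reads":
            c = self.counts
        elif weighting == "alleles":
            c = np.ones_like(self.counts)
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        return c / c.sum()

    def sample_size(self, weighting: str = "reads") -> int:
        return self.n_reads if weighting == "reads" else self.n_alleles

    def diff_matrix(self) -> np.ndarray:
        """Pairwise nucleotide difference counts between variants.

        Only positions where both sequences carry an unambiguous base
        (ACGT) are compared; gaps and Ns are skipped.
        """
        k = self.n_alleles
        arrs = [np.frombuffer(s.encode(), dtype="S1") for s in self.sequences]
        valid = [np.isin(a, [b.encode() for b in "ACGT"]) for a in arrs]
        d = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                both = valid[i] & valid[j]
                d[i, j] = d[j, i] = np.sum((arrs[i] != arrs[j]) & both)
        return d


def segregating_sites(panel: BarcodePanel) -> int:
    """Number of alignment columns with >= 2 observed bases among variants."""
    cols = np.array([list(s) for s in panel.sequences])
    s = 0
    for j in range(cols.shape[1]):
        states = {b for b in cols[:, j] if b in _VALID}
        if len(states) >= 2:
            s += 1
    return s


def allelic_diversity(counts: Sequence[float]) -> float:
    """Haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2), read-weighted."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    p = c / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def _theta_pi_abs(panel: BarcodePanel, weighting: str = "reads") -> float:
    """Mean pairwise nucleotide differences (per locus, not per site)."""
    n = panel.sample_size(weighting)
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    w = panel.weights(weighting)
    d = panel.diff_matrix()
    return float(n / (n - 1) * w @ d @ w)


def nucleotide_diversity(panel: BarcodePanel, weighting: str = "reads") -> float:
    """Per-site nucleotide diversity pi (mean pairwise differences / L)."""
    return _theta_pi_abs(panel, weighting) / panel.length


@lru_cache(maxsize=256)
def tajima_constants(n: int) -> dict[str, float]:
    """Normalizing constants for Tajima's D as functions of sample size n."""
    if n < 2:
        raise ValueError("n >= 2 required")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(panel: BarcodePanel, weighting: str = "reads") -> float | None:
    """Tajima's D computed from read-weighted pairwise diversity and S.

    Returns None (undefined) when there are no segregating sites.
    """
    s = segregating_sites(panel)
    if s == 0:
        return None
    n = panel.sample_size(weighting)
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 sequences")
    k = _theta_pi_abs(panel, weighting)
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return float((k - s / c["a1"]) / math.sqrt(var))


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    if n == 0:
        return np.array([0.0])
    cur = np.full(2, -np.inf)
    cur[1] = 0.0  # |s(1, 1)| = 1; |s(m, 0)| = 0 for m >= 1
    for m in range(1, n):
        nxt = np.full(m + 2, -np.inf)
        # |s(m+1, k)| = |s(m, k-1)| + m * |s(m, k)|
        nxt[1 : m + 2] = np.logaddexp(cur[0 : m + 1], np.log(m) + np.pad(cur[1:], (0, 1), constant_values=-np.inf))
        cur = nxt
    return cur


def ewens_k_tail_prob(n: int, k_obs: int, theta: float) -> float:
    """Pr(K >= k_obs) for the number of distinct alleles K in an Ewens sample.

    Pr(K = k) = |s(n,k)| theta^k / (theta)_n, with (theta)_n the rising
    factorial; computed in log space via a Stirling-number recurrence.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in [1, n]")
    logrow = _log_stirling_row(n)
    log_theta = math.log(theta)
    log_denom = float(np.sum(np.log(theta + np.arange(n))))
    ks = np.arange(1, n + 1)
    logp = logrow[1:] + ks * log_theta - log_denom
    log_tail = logsumexp(logp[k_obs - 1 :])
    log_total = logsumexp(logp)  # == 0 up to rounding; normalize for safety
    return float(math.exp(log_tail - log_total))


def fus_fs(panel: BarcodePanel, weighting: str = "reads") -> float | None:
    """Fu's Fs = ln(S' / (1 - S')), S' = Pr(K >= k_obs | theta = theta_pi).

    Negative values indicate an excess of alleles relative to the Ewens
    expectation (recent expansion / excess rare variants), positive values
    an allele deficiency. Returns -inf when S' rounds to 1 (e.g. k_obs = 1)
    and None when theta_pi = 0.
    """
    n = panel.sample_size(weighting)
    if n < 2:
        raise ValueError("Fu's Fs needs n >= 2")
    theta = _theta_pi_abs(panel, weighting)
    if theta <= 0:
        return None
    k_obs = panel.n_alleles
    s_prime = ewens_k_tail_prob(n, k_obs, theta)
    if s_prime >= 1.0:
        return float("-inf")
    return float(math.log(s_prime / (1.0 - s_prime)))


def _pair_ng86(seq1: str, seq2: str) -> tuple[float, float, float, float]:
    """Nei-Gojobori site and difference counts for one sequence pair.

    Returns (S_sites, N_sites, S_diffs, N_diffs); codons containing gaps,
    ambiguous bases or stop codons in either sequence are skipped.
    """
    s_sites = n_sites = s_diff = n_diff = 0.0
    ncod = min(len(seq1), len(seq2)) // 3
    for i in range(ncod):
        c1 = seq1[3 * i : 3 * i + 3]
        c2 = seq2[3 * i : 3 * i + 3]
        if not (set(c1) <= _VALID and set(c2) <= _VALID):
            continue
        if is_stop(c1) or is_stop(c2):
            continue
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        sd, nd = codon_path_differences(c1, c2)
        s_diff += sd
        n_diff += nd
    return s_sites, n_sites, s_diff, n_diff


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ka_ks(
    panel: BarcodePanel, weighting: str = "alleles"
) -> tuple[float, float, float | None]:
    """Nei-Gojobori Ka, Ks and omega = Ka/Ks, averaged over variant pairs.

    Pairs are unweighted over distinct variants by default (pass
    ``weighting="reads"`` to weight each pair by the product of read
    frequencies). omega is None when Ks = 0.
    """
    k = panel.n_alleles
    if k < 2:
        return 0.0, 0.0, None
    if weighting == "alleles":
        pw = np.ones(k)
    elif weighting == "reads":
        pw = panel.counts.astype(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    ka_sum = ks_sum = w_sum = 0.0
    saturated = 0
    for i in range(k):
        for j in range(i + 1, k):
            ss, ns, sd, nd = _pair_ng86(panel.sequences[i], panel.sequences[j])
            if ss == 0 and ns == 0:
                continue
            ps = sd / ss if ss > 0 else 0.0
            pn = nd / ns if ns > 0 else 0.0
            ds = jukes_cantor(ps)
            dn = jukes_cantor(pn)
            if math.isnan(ds) or math.isnan(dn):
                saturated += 1  # beyond the Jukes-Cantor domain (p >= 3/4)
                continue
            w = pw[i] * pw[j]
            ka_sum += w * dn
            ks_sum += w * ds
            w_sum += w
    if w_sum == 0:
        if saturated:
            return float("nan"), float("nan"), None
        return 0.0, 0.0, None
    ka = ka_sum / w_sum
    ks = ks_sum / w_sum
    omega = ka / ks if ks > 0 else None
    return ka, ks, omega


def alleles_per_individual(n_alleles: int, n_individuals: int) -> float:
    """Average number of distinct alleles per pooled individual (A/N)."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    return n_alleles / n_individuals


def mean_centered_diversity(
    allele_counts: Sequence[float],
    population_sizes: Sequence[float] | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> dict:
    """Drift check: mean-centered allele counts vs population size.

    Each population's allele count is divided by the across-population mean;
    if ``population_sizes`` is given, the Pearson correlation between the
    centered values and the sizes is returned with a permutation p-value
    (positive correlation is the drift expectation: small populations lose
    alleles).
    """
    a = np.asarray(allele_counts, dtype=float)
    if len(a) < 2:
        raise ValueError("need >= 2 populations")
    m = a.mean()
    if m == 0:
        raise ValueError("zero mean allele count")
    centered = a / m
    out: dict = {"centered": centered}
    if population_sizes is not None:
        sizes = np.asarray(population_sizes, dtype=float)
        if np.std(centered) == 0 or np.std(sizes) == 0:
            out.update(r=None, p=None, note="zero variance")
            return out
        r = float(pearsonr(centered, sizes)[0])
        rng = np.random.default_rng(seed)
        hits = 1
        for _ in range(n_perm):
            rp = np.corrcoef(rng.permutation(centered), sizes)[0, 1]
            if rp >= r - 1e-12:
                hits += 1
        out.update(r=r, p=hits / (n_perm + 1))
    return out


@dataclass
class DiversitySummary:
    """One report row: every per-barcode/locus statistic of the survey table."""

    barcode: str
    locus: str
    n_individuals: int
    n_reads: int
    S: int
    n_alleles: int
    alleles_per_individual: float
    Hd: float
    pi: float
    tajima_D: float | None
    fu_Fs: float | None
    Ka: float
    Ks: float
    omega: float | None


def summarize_panel(panel: BarcodePanel, weighting: str = "reads") -> DiversitySummary:
    counts = panel.counts if weighting == "reads" else np.ones_like(panel.counts)
    ka, ks, omega = ka_ks(panel)
    return DiversitySummary(
        barcode=panel.barcode,
        locus=panel.locus,
        n_individuals=panel.n_individuals,
        n_reads=panel.n_reads,
        S=segregating_sites(panel),
        n_alleles=panel.n_alleles,
        alleles_per_individual=(
            alleles_per_individual(panel.n_alleles, panel.n_individuals)
            if panel.n_individuals
            else float("nan")
        ),
        Hd=allelic_diversity(counts),
        pi=nucleotide_diversity(panel, weighting),
        tajima_D=tajimas_d(panel, weighting),
        fu_Fs=fus_fs(panel, weighting),
        Ka=ka,
        Ks=ks,
        omega=omega,
    )


def diversity_table(
    panels: Iterable[BarcodePanel], weighting: str = "reads"
) -> pd.DataFrame:
    """Survey-table report: one row per barcode x locus, all statistics."""
    rows = [summarize_panel(p, weighting) for p in panels]
    if not rows:
        raise ValueError("no panels supplied")
    df = pd.DataFrame([vars(r) for r in rows])
    return df.sort_values(["locus", "barcode"]).reset_index(drop=True)
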