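"""Independent brute-force implementations used as oracles in tests.

Everything here is deliberately naive: pair enumeration instead of matrix
algebra, exact integer Stirling numbers instead of log-space recurrences,
Biopython translation instead of the package's codon table, and a plain
Needleman-Wunsch instead of the production aligner.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations, permutations

from Bio.Seq import Seq


def expand_reads(seqs, counts):
    out = []
    for s, c in zip(seqs, counts):
        out.extend([s] * int(c))
    return out


def brute_hd(reads) -> float:
    """Haplotype diversity as the fraction of differing unordered read pairs."""
    n = len(reads)
    diff = sum(1 for a, b in combinations(reads, 2) if a != b)
    return diff / math.comb(n, 2)


def brute_pi(reads) -> float:
    """Mean pairwise differences per site over all unordered read pairs."""
    n = len(reads)
    L = len(reads[0])
    tot = sum(
        sum(x != y for x, y in zip(a, b)) for a, b in combinations(reads, 2)
    )
    return tot / math.comb(n, 2) / L


def brute_segregating_sites(seqs) -> int:
    L = len(seqs[0])
    return sum(1 for j in range(L) if len({s[j] for s in seqs}) > 1)


def brute_tajimas_d(reads) -> float | None:
    n = len(reads)
    L = len(reads[0])
    S = brute_segregating_sites(list(set(reads)))
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    k = brute_pi(reads) * L
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def stirling_unsigned(n: int, k: int) -> int:
    """Exact unsigned Stirling number of the first kind."""
    if n == 0:
        return 1 if k == 0 else 0
    if k == 0:
        return 0
    row = [0] * (n + 1)
    row[0] = 1  # row for n=0
    for m in range(1, n + 1):
        new = [0] * (n + 1)
        for j in range(1, n + 1):
            new[j] = row[j - 1] + (m - 1) * row[j]
        row = new
    return row[k]


def brute_fus_fs(reads) -> float | None:
    """Fu's Fs via exact-rational Ewens probabilities (theta = mean pairwise diffs)."""
    n = len(reads)
    L = len(reads[0])
    theta = brute_pi(reads) * L
    if theta <= 0:
        return None
    k_obs = len(set(reads))
    th = Fraction(theta).limit_denominator(10**12)
    denom = math.prod([th + i for i in range(n)], start=Fraction(1))
    probs = [Fraction(stirling_unsigned(n, k)) * th**k / denom for k in range(1, n + 1)]
    total = sum(probs)
    s_prime = float(sum(probs[k_obs - 1 :]) / total)
    if s_prime >= 1.0:
        return float("-inf")
    return math.log(s_prime / (1.0 - s_prime))


_AA_CACHE: dict[str, str] = {}


def _aa(codon: str) -> str:
    aa = _AA_CACHE.get(codon)
    if aa is None:
        aa = _AA_CACHE[codon] = str(Seq(codon).translate())
    return aa


def brute_ng86_pair(s1: str, s2: str):
    """Nei-Gojobori site/difference counts using Biopython translation."""
    S_sites = N_sites = Sd = Nd = 0.0
    for i in range(0, len(s1) - len(s1) % 3, 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if set(c1 + c2) - set("ACGT") or _aa(c1) == "*" or _aa(c2) == "*":
            continue
        for c in (c1, c2):
            for p in range(3):
                syn = valid = 0
                for b in "ACGT":
                    if b == c[p]:
                        continue
                    alt = c[:p] + b + c[p + 1 :]
                    if _aa(alt) == "*":
                        continue
                    valid += 1
                    if _aa(alt) == _aa(c):
                        syn += 1
                frac = syn / valid if valid else 0.0
                S_sites += frac / 2
                N_sites += (1 - frac) / 2
        diffs = [p for p in range(3) if c1[p] != c2[p]]
        if not diffs:
            continue
        path_counts = []
        for order in permutations(diffs):
            cur, sd, nd, stop = c1, 0, 0, False
            for p in order:
                nxt = cur[:p] + c2[p] + cur[p + 1 :]
                if _aa(nxt) == "*":
                    stop = True
                if _aa(nxt) == _aa(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            path_counts.append((sd, nd, stop))
        ok = [(s, n) for s, n, st in path_counts if not st] or [
            (s, n) for s, n, _ in path_counts
        ]
        Sd += sum(s for s, _ in ok) / len(ok)
        Nd += sum(n for _, n in ok) / len(ok)
    return S_sites, N_sites, Sd, Nd


def brute_ka_ks(seqs):
    """Unweighted pairwise NG86 Ka, Ks with Jukes-Cantor correction."""
    ka = ks = npairs = 0
    for a, b in combinations(seqs, 2):
        Ss, Ns, Sd, Nd = brute_ng86_pair(a, b)
        ps = Sd / Ss if Ss else 0.0
        pn = Nd / Ns if Ns else 0.0
        if ps >= 0.75 or pn >= 0.75:
            continue
        ks += -0.75 * math.log(1 - 4 * ps / 3)
        ka += -0.75 * math.log(1 - 4 * pn / 3)
        npairs += 1
    if npairs == 0:
        return None
    return ka / npairs, ks / npairs


def nw_align_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0):
    """Global alignment with free end gaps; returns (score, identity).

    Identity = matches / alignment columns (terminal gap columns included),
    from a single optimal traceback preferring diagonal moves.
    """
    n, m = len(a), len(b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    # free end gaps: first row/col zero
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            score[i][j] = max(score[i - 1][j - 1] + s, score[i - 1][j] + gap, score[i][j - 1] + gap)
    # best end point on last row/col (free terminal gaps)
    best = max(
        [(score[n][j], n, j) for j in range(m + 1)]
        + [(score[i][m], i, m) for i in range(n + 1)]
    )
    sc, i, j = best
    matches = 0
    cols = (n - i) + (m - j)  # terminal overhang columns
    while i > 0 and j > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if score[i][j] == score[i - 1][j - 1] + s:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif score[i][j] == score[i - 1][j] + gap:
            i -= 1
        else:
            j -= 1
        cols += 1
    cols += i + j
    return sc, matches / cols


def brute_phi_st(reads_a, reads_b):
    """Phi_ST from uncorrected mean pairwise differences, read enumeration."""

    def mpd(reads):
        n = len(reads)
        tot = sum(
            sum(x != y for x, y in zip(r1, r2))
            for r1 in reads
            for r2 in reads
        )
        return tot / n**2

    pooled = list(reads_a) + list(reads_b)
    pi_t = mpd(pooled)
    if pi_t == 0:
        return None
    pi_w = (len(reads_a) * mpd(reads_a) + len(reads_b) * mpd(reads_b)) / len(pooled)
    return (pi_t - pi_w) / pi_t
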