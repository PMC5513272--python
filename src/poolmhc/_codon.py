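"""Genetic-code utilities shared by the Ka/Ks estimator and the simulator.

Standard (vertebrate nuclear) code throughout; amplicons are assumed to be
in frame starting at position 0.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

# Standard genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE = dict(standard_dna_table.forward_table)
GENETIC_CODE.update({c: "*" for c in standard_dna_table.stop_codons})
STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def has_stop(seq: str) -> bool:
    return any(is_stop(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3))


def synonymous_fraction(codon: str, pos: int) -> float:
    """Fraction of single-base changes at ``pos`` that are synonymous.

    Changes creating stop codons are excluded from both numerator and
    denominator (Nei-Gojobori convention), so the per-position synonymous
    and nonsynonymous site fractions still sum to 1.
    """
    aa = GENETIC_CODE[codon]
    syn = 0
    valid = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if is_stop(alt):
            continue
        valid += 1
        if GENETIC_CODE[alt] == aa:
            syn += 1
    if valid == 0:
        return 0.0
    return syn / valid


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon; they sum to 3."""
    s = sum(synonymous_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def codon_path_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    All shortest mutational pathways between the codons are enumerated with
    equal weight; pathways passing through a stop codon are discarded unless
    every pathway does.
    """
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if is_stop(nxt):
                through_stop = True
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, through_stop))
    clean = [(s, n) for s, n, stop in paths if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def is_synonymous_change(codon: str, pos: int, new_base: str) -> bool:
    alt = codon[:pos] + new_base + codon[pos + 1 :]
    return GENETIC_CODE[alt] == GENETIC_CODE[codon]
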