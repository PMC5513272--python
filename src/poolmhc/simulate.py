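"""Truth-tracked synthetic data generator for pooled amplicon sequencing.

Emulates the study design the package targets: seven barcodes of 25 pooled
individuals each, two amplicons (a multi-copy 261-bp class I exon and a
single-copy 270-bp class II exon), colonies arranged along a one-dimensional
coastline with stepping-stone migration, codon-aware allele evolution with a
tunable dN/dS bias, and 454-style read noise (substitutions, homopolymer
indels, chimeric reads), with full provenance for every emitted read.

The allele pool is generated on a Kingman coalescent genealogy (exponential
waiting times, rate k(k-1)/2) with Poisson-distributed mutations at rate
theta/2 per unit branch length, so that neutral settings yield samples with
coalescent-shaped frequency spectra. Mutations are proposed uniformly and
accepted with probability min(1, omega) if nonsynonymous and min(1, 1/omega)
if synonymous, which makes the expected realized rate ratio exactly the
requested dN/dS target; proposals creating stop codons are rejected and
resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from poolmhc._codon import BASES, is_stop, is_synonymous_change
from poolmhc.qc import Read

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "AllelePool",
    "TruthTable",
    "synthetic_reference",
    "default_loci",
    "generate_allele_pool",
    "assign_genotypes",
    "simulate_reads",
    "simulate_study",
]


def synthetic_reference(length: int, seed: int) -> str:
    """Deterministic stop-free in-frame nucleotide sequence of given length."""
    if length % 3 != 0:
        raise ValueError("length must be a multiple of 3")
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < length // 3:
        c = "".join(rng.choice(list(BASES), 3))
        if not is_stop(c):
            codons.append(c)
    return "".join(codons)


@dataclass
class LocusSpec:
    """One amplicon: name, length, ploidy-level copy number, reference."""

    name: str
    amplicon_length: int
    copies_per_individual: int
    reference_sequence: str

    def __post_init__(self) -> None:
        if self.amplicon_length % 3 != 0:
            raise ValueError("amplicon_length must be a multiple of 3")
        if self.copies_per_individual < 1:
            raise ValueError("copies_per_individual must be >= 1")
        if len(self.reference_sequence) != self.amplicon_length:
            raise ValueError("reference length != amplicon_length")
        if set(self.reference_sequence) - set(BASES):
            raise ValueError("reference must contain only ACGT")


def default_loci(mhc1_copies: int = 2) -> dict[str, LocusSpec]:
    """The two study amplicons: multi-copy MHC I exon 3 (261 bp) and
    single-copy MHC II exon 2 (270 bp), with synthetic reference sequences.
    """
    return {
        "MHC1ex3": LocusSpec("MHC1ex3", 261, mhc1_copies, synthetic_reference(261, 101)),
        "MHC2ex2": LocusSpec("MHC2ex2", 270, 1, synthetic_reference(270, 102)),
    }


@dataclass
class SimulationConfig:
    """Study-design knobs; defaults reproduce the surveyed design."""

    n_populations: int = 7
    individuals_per_population: int = 25
    coastline_positions: tuple[float, ...] | None = None  # km; default 500-km spacing
    migration_rate: float = 0.1
    theta: float = 10.0
    dnds_target: float = 1.0
    depth_per_individual: int = 20
    # 454 errors are dominated by homopolymer indels; substitutions are rare
    # (~0.1% per base in published GS FLX/Junior error profiles)
    substitution_error_rate: float = 0.001
    homopolymer_indel_rate: float = 0.01
    chimera_rate: float = 0.01
    seed: int = 0
    generations: int = 50
    pool_size: int | None = None  # default: total gene copies sampled
    poisson_depth: bool = False
    depth_skew: float = 0.0  # lognormal sigma of per-individual depth multipliers

    def __post_init__(self) -> None:
        for name in (
            "migration_rate",
            "substitution_error_rate",
            "homopolymer_indel_rate",
            "chimera_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth_per_individual < 1:
            raise ValueError("depth_per_individual must be >= 1")
        if self.coastline_positions is None:
            self.coastline_positions = tuple(500.0 * i for i in range(self.n_populations))
        pos = self.coastline_positions
        if len(pos) != self.n_populations:
            raise ValueError("one coastline position per population required")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("coastline positions must be strictly increasing")
        if self.theta < 0 or self.dnds_target < 0:
            raise ValueError("theta and dnds_target must be >= 0")

    @property
    def barcodes(self) -> list[str]:
        return [f"bc{i + 1}" for i in range(self.n_populations)]


@dataclass
class AllelePool:
    """Allele sequences for one locus plus the genealogy that produced them."""

    locus: LocusSpec
    sequences: list[str]
    genealogy: list[tuple[int, int, float]]  # (child, parent, branch length)
    n_syn_events: int = 0
    n_nonsyn_events: int = 0

    @property
    def n_distinct(self) -> int:
        return len(set(self.sequences))


def _count_mutation_classes(seq: str) -> tuple[int, int]:
    syn = nonsyn = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        for p in range(3):
            for b in BASES:
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if is_stop(alt):
                    continue
                if is_synonymous_change(codon, p, b):
                    syn += 1
                else:
                    nonsyn += 1
    return syn, nonsyn


def _mutate(
    seq: str, omega: float, rng: np.random.Generator, max_tries: int = 10000
) -> tuple[str, bool]:
    """One accepted codon-aware point mutation; returns (seq, is_synonymous)."""
    acc_n = min(1.0, omega)
    acc_s = 1.0 if omega == 0 else min(1.0, 1.0 / omega)
    n = len(seq)
    for _ in range(max_tries):
        pos = int(rng.integers(n))
        old = seq[pos]
        alts = [b for b in BASES if b != old]
        new = alts[int(rng.integers(3))]
        c0 = 3 * (pos // 3)
        codon = seq[c0 : c0 + 3]
        cp = pos - c0
        alt = codon[:cp] + new + codon[cp + 1 :]
        if is_stop(alt):
            continue
        syn = is_synonymous_change(codon, cp, new)
        acc = acc_s if syn else acc_n
        if rng.random() < acc:
            return seq[:pos] + new + seq[pos + 1 :], syn
    raise RuntimeError("no acceptable mutation found (dnds_target infeasible?)")


def generate_allele_pool(
    locus: LocusSpec,
    n_alleles: int,
    theta: float,
    dnds_target: float,
    seed: int,
) -> AllelePool:
    """Evolve ``n_alleles`` in-frame sequences from the locus reference.

    A Kingman coalescent over the alleles is simulated, mutations are
    dropped on branches at Poisson rate theta/2 per unit coalescent time,
    and each mutation is codon-aware with realized dN/dS biased to
    ``dnds_target``. theta = 0 returns identical-to-reference alleles.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    syn_avail, nonsyn_avail = _count_mutation_classes(locus.reference_sequence)
    if theta > 0:
        if dnds_target == 0 and syn_avail == 0:
            raise ValueError("dnds_target=0 impossible: no synonymous changes available")
        if dnds_target > 0 and nonsyn_avail == 0 and syn_avail == 0:
            raise ValueError("no non-stop mutations available")
    rng = np.random.default_rng(seed)

    # Kingman genealogy: tips 0..n-1, internal nodes appended above.
    lineages = list(range(n_alleles))
    node_time = {i: 0.0 for i in lineages}
    parent: dict[int, tuple[int, float]] = {}
    t = 0.0
    nxt = n_alleles
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        node_time[nxt] = t
        parent[a] = (nxt, t - node_time[a])
        parent[b] = (nxt, t - node_time[b])
        lineages = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1
    root = lineages[0]

    children: dict[int, list[tuple[int, float]]] = {}
    for child, (par, blen) in parent.items():
        children.setdefault(par, []).append((child, blen))

    seqs: dict[int, str] = {root: locus.reference_sequence}
    n_syn = n_nonsyn = 0
    stack = [root]
    while stack:
        node = stack.pop()
        for child, blen in sorted(children.get(node, [])):
            s = seqs[node]
            if theta > 0:
                for _ in range(rng.poisson(theta / 2.0 * blen)):
                    s, syn = _mutate(s, dnds_target, rng)
                    if syn:
                        n_syn += 1
                    else:
                        n_nonsyn += 1
            seqs[child] = s
            stack.append(child)
    genealogy = [(c, p, bl) for c, (p, bl) in sorted(parent.items())]
    return AllelePool(
        locus, [seqs[i] for i in range(n_alleles)], genealogy, n_syn, n_nonsyn
    )


@dataclass
class TruthTable:
    """Everything the simulator knows: genotypes, frequencies, provenance."""

    pools: dict[str, AllelePool]
    # (barcode, locus) -> (individuals x slots) array of pool allele indices
    genotypes: dict[tuple[str, str], np.ndarray]
    true_freqs: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    read_provenance: list[dict] = field(default_factory=list)

    def true_allele_sequences(self, barcode: str, locus: str) -> set[str]:
        pool = self.pools[locus]
        g = self.genotypes[(barcode, locus)]
        return {pool.sequences[i] for i in np.unique(g)}

    def true_allele_counts(self, barcode: str, locus: str) -> dict[str, int]:
        """Read-truth counts per distinct allele sequence in a barcode."""
        counts: dict[str, int] = {}
        pool = self.pools[locus]
        for rec in self.read_provenance:
            if rec["barcode"] == barcode and rec["locus"] == locus:
                seq = pool.sequences[rec["source_allele"]]
                counts[seq] = counts.get(seq, 0) + 1
        return counts


def _stepping_stone_frequencies(
    n_pool: int, config: SimulationConfig, copies: int, rng: np.random.Generator
) -> np.ndarray:
    """Forward Wright-Fisher chain with nearest-neighbour migration.

    Populations sit on the 1-D coastline in order; each generation a
    fraction m of every deme's gene pool is exchanged with its neighbours
    (m/2 each side), then the deme of 2 * copies * N gene copies is
    multinomially resampled. All demes start at the uniform pool frequency,
    so divergence accumulates by drift and is damped by migration:
    expected frequency distance grows with chain distance when m is small.
    """
    npop = config.n_populations
    m = config.migration_rate
    size = 2 * copies * config.individuals_per_population
    p = np.full((npop, n_pool), 1.0 / n_pool)
    for _ in range(config.generations):
        if npop > 1 and m > 0:
            q = p.copy()
            for i in range(npop):
                left = p[i - 1] if i > 0 else p[i]
                right = p[i + 1] if i < npop - 1 else p[i]
                q[i] = (1 - m) * p[i] + m / 2.0 * (left + right)
            p = q
        for i in range(npop):
            p[i] = rng.multinomial(size, p[i]) / size
    return p


def assign_genotypes(
    pools: dict[str, AllelePool], config: SimulationConfig
) -> TruthTable:
    """Draw per-individual genotypes from stepping-stone deme frequencies.

    Each individual carries 2 x copies_per_individual allele slots per
    locus, sampled from its deme's frequency vector.
    """
    truth = TruthTable(pools=pools, genotypes={})
    for li, (locus_name, pool) in enumerate(sorted(pools.items())):
        if not pool.sequences:
            raise ValueError("empty allele pool")
        rng = np.random.default_rng([config.seed % (2**31), 7 + li])
        copies = pool.locus.copies_per_individual
        n_pool = len(pool.sequences)
        freqs = _stepping_stone_frequencies(n_pool, config, copies, rng)
        slots = 2 * copies
        for bi, barcode in enumerate(config.barcodes):
            g = rng.choice(
                n_pool,
                size=(config.individuals_per_population, slots),
                p=freqs[bi],
            )
            truth.genotypes[(barcode, locus_name)] = g
            tally = np.bincount(g.ravel(), minlength=n_pool).astype(float)
            truth.true_freqs[(barcode, locus_name)] = tally / tally.sum()
    return truth


_HQ, _LQ = 38, 10


def _apply_homopolymer_indels(
    seq: list[str], quals: list[int], rate: float, rng: np.random.Generator
) -> int:
    """In-place single-base gain/loss per homopolymer run (length >= 2)."""
    if rate <= 0:
        return 0
    events = 0
    i = 0
    s = seq
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        run_len = j - i
        if run_len >= 2 and rng.random() < rate:
            events += 1
            if rng.random() < 0.5:
                s.insert(i, s[i])
                quals.insert(i, _LQ)
                j += 1
            else:
                del s[i]
                del quals[i]
                j -= 1
        i = j
    return events


def simulate_reads(
    truth: TruthTable, config: SimulationConfig
) -> dict[str, list[Read]]:
    """Emit barcoded reads with 454-style noise; provenance goes to truth.

    Per individual, ``depth_per_individual`` reads are emitted with source
    alleles spread as evenly as possible over the individual's allele slots
    (so true frequencies are exact under the default fixed depth). Chimeras
    are formed before base errors; substitution errors are i.i.d. per base;
    homopolymer runs gain or lose one base at the configured rate. Quality
    strings carry Phred 38 for faithful bases and Phred 10 for erroneous
    (substituted or inserted) bases.
    """
    reads_by_barcode: dict[str, list[Read]] = {b: [] for b in config.barcodes}
    serial = 0
    for (barcode, locus_name), genotype in sorted(truth.genotypes.items()):
        pool = truth.pools[locus_name]
        if pool.locus.amplicon_length == 0:
            raise ValueError("zero-length amplicon")
        bi = config.barcodes.index(barcode)
        li = sorted(truth.pools).index(locus_name)
        rng = np.random.default_rng([config.seed % (2**31), 1000 + 31 * bi + li])
        tally = truth.true_freqs[(barcode, locus_name)]
        for ind in range(genotype.shape[0]):
            slots = genotype[ind]
            depth = config.depth_per_individual
            if config.depth_skew > 0:
                depth = max(1, int(round(depth * rng.lognormal(0.0, config.depth_skew))))
            if config.poisson_depth:
                depth = int(rng.poisson(depth))
            base, extra = divmod(depth, len(slots))
            per_slot = np.full(len(slots), base)
            if extra:
                per_slot[rng.choice(len(slots), size=extra, replace=False)] += 1
            for slot_idx, n_reads in enumerate(per_slot):
                src = int(slots[slot_idx])
                for _ in range(int(n_reads)):
                    seq = pool.sequences[src]
                    chimera_parent = None
                    breakpoint_ = None
                    if config.chimera_rate > 0 and rng.random() < config.chimera_rate:
                        chimera_parent = int(rng.choice(len(tally), p=tally))
                        breakpoint_ = int(rng.integers(1, len(seq)))
                        seq = seq[:breakpoint_] + pool.sequences[chimera_parent][breakpoint_:]
                    chars = list(seq)
                    quals = [_HQ] * len(chars)
                    n_indels = _apply_homopolymer_indels(
                        chars, quals, config.homopolymer_indel_rate, rng
                    )
                    n_subs = 0
                    if config.substitution_error_rate > 0:
                        hits = np.nonzero(
                            rng.random(len(chars)) < config.substitution_error_rate
                        )[0]
                        for pos in hits:
                            alts = [b for b in BASES if b != chars[pos]]
                            chars[pos] = alts[int(rng.integers(3))]
                            quals[pos] = _LQ
                            n_subs += 1
                    rid = f"{barcode}:{locus_name}:{serial}"
                    serial += 1
                    reads_by_barcode[barcode].append(
                        Read(rid, barcode, "".join(chars), quals)
                    )
                    truth.read_provenance.append(
                        {
                            "read_id": rid,
                            "barcode": barcode,
                            "locus": locus_name,
                            "source_allele": src,
                            "chimera_parent": chimera_parent,
                            "breakpoint": breakpoint_,
                            "n_substitution_errors": n_subs,
                            "n_homopolymer_indels": n_indels,
                        }
                    )
    return reads_by_barcode


def simulate_study(
    config: SimulationConfig,
    loci: dict[str, LocusSpec] | None = None,
    dnds_by_locus: dict[str, float] | None = None,
):
    """End-to-end simulation of the full study design.

    Returns (reads_by_barcode, truth, manifest rows). The default dN/dS
    targets mirror the survey's contrast: positive selection at the
    multi-copy class I amplicon (omega 3) and near-neutral class II
    (omega 1).
    """
    from poolmhc.io import Manifest

    loci = loci or default_loci()
    dnds = dnds_by_locus or {"MHC1ex3": 3.0, "MHC2ex2": 1.0}
    pools = {}
    for i, (name, spec) in enumerate(sorted(loci.items())):
        n_pool = config.pool_size or (
            2
            * spec.copies_per_individual
            * config.individuals_per_population
            * config.n_populations
        )
        pools[name] = generate_allele_pool(
            spec,
            n_pool,
            config.theta,
            dnds.get(name, config.dnds_target),
            seed=(config.seed % (2**31)) * 97 % (2**31) + i,
        )
    truth = assign_genotypes(pools, config)
    reads = simulate_reads(truth, config)
    manifest = Manifest.synthetic(config)
    return reads, truth, manifest
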