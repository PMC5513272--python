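"""Population differentiation and isolation by distance.

Pairwise FST between barcoded colony panels (Phi_ST from pairwise
nucleotide differences, AMOVA-style, or Hudson's frequency-based FST on
allele identity), permutation significance, great-circle distances, and
the Mantel test with exact enumeration for small numbers of localities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolmhc.diversity import BarcodePanel

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "pairwise_fst",
    "fst_permutation_p",
    "fst_matrix",
    "haversine_km",
    "distance_matrix_km",
    "mantel",
    "ibd_report",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix with zero diagonal (FST or kilometers)."""

    labels: list[str]
    values: np.ndarray
    kind: str = "unspecified"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("matrix shape must match labels")
        if k < 2:
            raise ValueError("need >= 2 labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")

    @property
    def size(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in row-major order."""
        iu = np.triu_indices(self.size, 1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_condensed(cls, labels, condensed, kind="unspecified") -> "DistanceMatrix":
        k = len(labels)
        m = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        m[iu] = condensed
        m[(iu[1], iu[0])] = condensed
        return cls(list(labels), m, kind)


@dataclass
class MantelResult:
    Z: float
    r: float
    p: float
    n_permutations: int | str


def _pi_within(panel: BarcodePanel) -> float:
    """Uncorrected mean pairwise differences: sum_ij w_i w_j d_ij.

    No small-sample correction, so that a population compared against an
    identically composed one gives Phi_ST exactly 0.
    """
    w = panel.weights("reads")
    return float(w @ panel.diff_matrix() @ w)


def _pooled_panel(a: BarcodePanel, b: BarcodePanel) -> BarcodePanel:
    counts: dict[str, float] = {}
    for p in (a, b):
        for s, c in zip(p.sequences, p.counts):
            counts[s] = counts.get(s, 0.0) + c
    seqs = list(counts)
    return BarcodePanel("pooled", a.locus, seqs, np.array([counts[s] for s in seqs]))


def pairwise_fst(a: BarcodePanel, b: BarcodePanel, mode: str = "phi") -> float | None:
    """Pairwise FST between two colony panels of the same locus.

    mode "phi": Phi_ST = (pi_total - pi_within) / pi_total with pi_within
    the read-count-weighted mean of within-colony mean pairwise differences
    and pi_total over the pooled reads. mode "freq": Hudson's FST on allele
    identity, 1 - Hw/Hb. Negative estimates are returned as computed.
    Returns None when total diversity is zero (undefined).
    """
    if a.locus != b.locus:
        raise ValueError("panels must be from the same locus")
    na, nb = a.n_reads, b.n_reads
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 reads per panel")
    if mode == "phi":
        pooled = _pooled_panel(a, b)
        pi_t = _pi_within(pooled)
        if pi_t == 0:
            return None
        pi_w = (na * _pi_within(a) + nb * _pi_within(b)) / (na + nb)
        return float((pi_t - pi_w) / pi_t)
    if mode == "freq":
        seqs = sorted(set(a.sequences) | set(b.sequences))
        idx = {s: i for i, s in enumerate(seqs)}
        pa = np.zeros(len(seqs))
        pb = np.zeros(len(seqs))
        for p, v in ((a, pa), (b, pb)):
            for s, c in zip(p.sequences, p.counts):
                v[idx[s]] = c
        pa /= pa.sum()
        pb /= pb.sum()
        hw = (na * (1 - pa @ pa) + nb * (1 - pb @ pb)) / (na + nb)
        hb = 1 - pa @ pb
        if hb == 0:
            return None
        return float(1 - hw / hb)
    raise ValueError(f"unknown mode {mode!r}")


def fst_permutation_p(
    a: BarcodePanel,
    b: BarcodePanel,
    n_perm: int = 999,
    seed: int | None = None,
    mode: str = "phi",
) -> float:
    """Permutation p-value: reads reshuffled between the two colonies.

    p = (1 + #{permuted FST >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    obs = pairwise_fst(a, b, mode)
    if obs is None:
        raise ValueError("FST undefined (no diversity)")
    reads = []
    for p in (a, b):
        for s, c in zip(p.sequences, p.counts):
            reads.extend([s] * int(c))
    reads = np.array(reads)
    na = a.n_reads
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        rng.shuffle(reads)
        pa = _panel_from_reads(reads[:na], a.locus)
        pb = _panel_from_reads(reads[na:], b.locus)
        val = pairwise_fst(pa, pb, mode)
        if val is not None and val >= obs - 1e-12:
            hits += 1
    return hits / (n_perm + 1)


def _panel_from_reads(read_seqs: np.ndarray, locus: str) -> BarcodePanel:
    uniq, counts = np.unique(read_seqs, return_counts=True)
    return BarcodePanel("perm", locus, [str(u) for u in uniq], counts)


def fst_matrix(
    panels: list[BarcodePanel], mode: str = "phi", labels: list[str] | None = None
) -> DistanceMatrix:
    """All-pairs FST matrix over colony panels of one locus."""
    k = len(panels)
    if labels is None:
        labels = [p.barcode for p in panels]
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            v = pairwise_fst(panels[i], panels[j], mode)
            m[i, j] = m[j, i] = np.nan if v is None else v
    return DistanceMatrix(labels, m, kind="FST")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValueError(f"latitude {lat} out of range")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValueError(f"longitude {lon} out of range")
    p1, l1, p2, l2 = map(math.radians, (lat1, lon1, lat2, lon2))
    h = math.sin((p2 - p1) / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin((l2 - l1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def distance_matrix_km(labels, lats, lons) -> DistanceMatrix:
    k = len(labels)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = haversine_km(lats[i], lons[i], lats[j], lons[j])
    return DistanceMatrix(list(labels), m, kind="kilometers")


def _mantel_r(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    mat_a: DistanceMatrix,
    mat_b: DistanceMatrix,
    n_perm: int = 10000,
    seed: int | None = None,
    exhaustive_below: int = 8,
) -> MantelResult:
    """Mantel test between two labeled distance matrices.

    r is the Pearson correlation over the k(k-1)/2 off-diagonal pairs and
    Z the raw cross-product sum. The one-tailed p (positive association)
    simultaneously permutes rows and columns of one matrix; when
    k < ``exhaustive_below`` all k! permutations are enumerated and p is
    exact, otherwise ``n_perm`` random permutations are drawn and the
    observed labeling counts toward the numerator.
    """
    if mat_a.labels != mat_b.labels:
        raise ValueError("matrix labels must match")
    k = mat_a.size
    if k < 3:
        raise ValueError("Mantel test needs >= 3 localities")
    iu = np.triu_indices(k, 1)
    x = mat_a.values[iu]
    y = mat_b.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    z = float(np.sum(x * y))
    r_obs = _mantel_r(x, y)
    b = mat_b.values
    if k < exhaustive_below:
        rs = []
        for perm in itertools.permutations(range(k)):
            bp = b[np.ix_(perm, perm)]
            rs.append(_mantel_r(x, bp[iu]))
        rs = np.array(rs)
        p = float(np.mean(rs >= r_obs - 1e-12))
        return MantelResult(Z=z, r=r_obs, p=p, n_permutations="exhaustive")
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(k)
        bp = b[np.ix_(perm, perm)]
        if _mantel_r(x, bp[iu]) >= r_obs - 1e-12:
            hits += 1
    return MantelResult(Z=z, r=r_obs, p=hits / (n_perm + 1), n_permutations=n_perm)


def ibd_report(
    fst_by_group: dict[tuple[str, str], DistanceMatrix],
    km_by_species: dict[str, DistanceMatrix],
    n_perm: int = 10000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Isolation-by-distance report: one Mantel row per species x locus.

    ``fst_by_group`` maps (species, locus) to an FST matrix whose labels
    must match the species' geographic matrix in ``km_by_species``.
    """
    rows = []
    for (species, locus), fst in sorted(fst_by_group.items()):
        km = km_by_species[species]
        if fst.size < 3:
            raise ValueError(f"{species}/{locus}: Mantel needs >= 3 localities")
        res = mantel(km, fst, n_perm=n_perm, seed=seed)
        rows.append(
            {
                "species": species,
                "locus": locus,
                "Z": res.Z,
                "r": res.r,
                "p": res.p,
                "n_permutations": res.n_permutations,
                "significant": res.p < alpha,
            }
        )
    return pd.DataFrame(rows)
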