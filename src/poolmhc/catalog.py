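"""Cross-barcode and cross-species allele bookkeeping.

Alleles are identified by exact retained sequence. The catalog answers the
survey's headline questions: how many distinct alleles per locus, which are
private to one colony versus present in several ("mixed locality"), which
are shared between the two species (trans-species alleles), and what the
dominant-allele frequency is in each colony.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolmhc.diversity import BarcodePanel
from poolmhc.io import Manifest
from poolmhc.qc import Variant

__all__ = [
    "AlleleCatalog",
    "shared_alleles",
    "dominant_allele_frequency",
    "private_allele_summary",
    "catalog_report",
]


@dataclass
class AlleleCatalog:
    """Sequence-keyed allele records with per-barcode counts per locus."""

    counts: pd.DataFrame  # index (locus, sequence), one column per barcode
    manifest: Manifest

    @classmethod
    def from_variants(cls, variants: list[Variant], manifest: Manifest) -> "AlleleCatalog":
        barcodes = manifest.barcodes
        rows = {}
        for v in sorted(variants, key=lambda v: (v.locus, v.sequence)):
            rows[(v.locus, v.sequence)] = [v.counts.get(b, 0) for b in barcodes]
        idx = pd.MultiIndex.from_tuples(rows.keys(), names=["locus", "sequence"])
        return cls(pd.DataFrame(list(rows.values()), index=idx, columns=barcodes), manifest)

    def loci(self) -> list[str]:
        return sorted(self.counts.index.get_level_values("locus").unique())

    def presence(self, locus: str, level: str = "locality") -> pd.DataFrame:
        """Boolean presence of each allele per unit (barcode or species)."""
        sub = self.counts.loc[locus] > 0
        if level == "locality":
            return sub
        if level == "species":
            groups = self.manifest.by_species()
            return pd.DataFrame(
                {sp: sub[bcs].any(axis=1) for sp, bcs in sorted(groups.items())}
            )
        raise ValueError(f"unknown level {level!r}")

    def panel(self, barcode: str, locus: str) -> BarcodePanel:
        col = self.counts.loc[locus][barcode]
        col = col[col > 0]
        if col.empty:
            raise ValueError(f"no alleles for {barcode}/{locus}")
        n_ind = int(self.manifest.row(barcode)["n_individuals"])
        return BarcodePanel(barcode, locus, list(col.index), col.to_numpy(), n_ind)


def shared_alleles(catalog: AlleleCatalog, locus: str, level: str = "locality") -> dict:
    """Allele sharing at a level: per-allele unit sets and private/mixed counts."""
    pres = catalog.presence(locus, level)
    if pres.shape[1] < 2:
        raise ValueError("sharing needs >= 2 units")
    unit_sets = {
        seq: frozenset(pres.columns[pres.loc[seq]]) for seq in pres.index
    }
    n_units = pres.sum(axis=1)
    return {
        "units_per_allele": unit_sets,
        "n_private": int((n_units == 1).sum()),
        "n_mixed": int((n_units > 1).sum()),
        "n_total": int(len(pres)),
        "mixed_alleles": sorted(seq for seq, n in n_units.items() if n > 1),
    }


def dominant_allele_frequency(panel: BarcodePanel) -> tuple[float, list[str]]:
    """Frequency of the most frequent allele; all tied alleles are reported."""
    total = panel.counts.sum()
    top = panel.counts.max()
    winners = [s for s, c in zip(panel.sequences, panel.counts) if c == top]
    return float(top / total), winners


def private_allele_summary(catalog: AlleleCatalog, locus: str) -> pd.DataFrame:
    """Per barcode: number of private alleles and their summed read frequency."""
    counts = catalog.counts.loc[locus]
    pres = counts > 0
    n_units = pres.sum(axis=1)
    rows = []
    for b in counts.columns:
        col = counts[b]
        total = col.sum()
        private = pres[b] & (n_units == 1)
        rows.append(
            {
                "barcode": b,
                "n_alleles": int(pres[b].sum()),
                "n_private": int(private.sum()),
                "private_frequency": float(col[private].sum() / total) if total else 0.0,
            }
        )
    return pd.DataFrame(rows)


def catalog_report(catalog: AlleleCatalog) -> dict:
    """Figure-ready tables plus headline counts per locus.

    Returns per-locus allele counts per barcode (bar-chart shape),
    per-barcode allele frequency vectors with shared-allele keys
    (pie-chart shape), and the headline totals: distinct alleles,
    mixed-locality alleles, trans-species alleles.
    """
    out: dict = {"allele_counts": None, "frequencies": {}, "headline": {}}
    count_rows = []
    for locus in catalog.loci():
        counts = catalog.counts.loc[locus]
        pres = counts > 0
        for b in counts.columns:
            count_rows.append({"locus": locus, "barcode": b, "n_alleles": int(pres[b].sum())})
        loc_sharing = shared_alleles(catalog, locus, "locality")
        headline = {
            "n_alleles": loc_sharing["n_total"],
            "n_mixed_locality": loc_sharing["n_mixed"],
        }
        if len(catalog.manifest.by_species()) >= 2:
            sp_sharing = shared_alleles(catalog, locus, "species")
            headline["n_trans_species"] = sp_sharing["n_mixed"]
        out["headline"][locus] = headline
        mixed = set(loc_sharing["mixed_alleles"])
        for b in counts.columns:
            col = counts[b]
            total = col.sum()
            if total == 0:
                continue
            freq = (col[col > 0] / total).sort_values(ascending=False)
            out["frequencies"][(locus, b)] = pd.DataFrame(
                {
                    "sequence": freq.index,
                    "frequency": freq.to_numpy(),
                    "shared": [s in mixed for s in freq.index],
                }
            )
    out["allele_counts"] = pd.DataFrame(count_rows)
    return out
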