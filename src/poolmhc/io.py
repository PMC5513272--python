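"""File formats, manifest handling, and run configuration.

TSV for tables, standard 4-line FASTQ (Sanger Phred+33) and 80-column
FASTA for sequences. Manifest coordinates accept either signed decimal
degrees or degree-minute strings like ``15°22′ S`` (south/west stored as
negative decimal degrees).
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from poolmhc.qc import QCParams, Read, Variant

__all__ = [
    "Manifest",
    "RunConfig",
    "parse_coordinate",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_tsv",
    "variant_table_frame",
    "write_variant_tables",
]

_COORD_RE = re.compile(
    r"""^\s*(-?\d+(?:\.\d+)?)\s*(?:[°ºd]\s*(\d+(?:\.\d+)?)?\s*[′'m]?\s*
        (?:(\d+(?:\.\d+)?)\s*[″"s]?)?)?\s*([NSEWnsew])?\s*$""",
    re.VERBOSE,
)


def parse_coordinate(value) -> float:
    """Parse decimal degrees or a degrees-minutes(-seconds) string.

    ``"15°22′ S"`` -> -15.3667; ``"75°12′ W"`` -> -75.2; plain numbers are
    passed through. S and W hemispheres become negative.
    """
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    m = _COORD_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse coordinate {value!r}")
    deg = float(m.group(1))
    minutes = float(m.group(2) or 0.0)
    seconds = float(m.group(3) or 0.0)
    hemi = (m.group(4) or "").upper()
    sign = -1.0 if (hemi in ("S", "W") or deg < 0) else 1.0
    return sign * (abs(deg) + minutes / 60.0 + seconds / 3600.0)


@dataclass
class Manifest:
    """Barcode manifest: one pooled colony per row.

    Columns: barcode, locality, latitude_dd, longitude_dd, country,
    species, n_individuals.
    """

    frame: pd.DataFrame

    REQUIRED = ["barcode", "locality", "latitude_dd", "longitude_dd", "species", "n_individuals"]

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.frame["barcode"].duplicated().any():
            raise ValueError("duplicate barcodes in manifest")
        if (self.frame["n_individuals"] < 1).any():
            raise ValueError("n_individuals must be >= 1")

    @property
    def barcodes(self) -> list[str]:
        return list(self.frame["barcode"])

    def row(self, barcode: str) -> pd.Series:
        sel = self.frame[self.frame["barcode"] == barcode]
        if sel.empty:
            raise KeyError(f"barcode {barcode!r} not in manifest")
        return sel.iloc[0]

    def species_of(self, barcode: str) -> str:
        return str(self.row(barcode)["species"])

    def by_species(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for _, r in self.frame.iterrows():
            out.setdefault(str(r["species"]), []).append(str(r["barcode"]))
        return out

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def synthetic(cls, config) -> "Manifest":
        """Manifest for a simulated run: colonies along a meridian so that
        great-circle distances equal the configured coastline spacing."""
        km_per_deg = 111.195  # mean meridian arc
        rows = []
        n = config.n_populations
        # two species only when both ranges keep >= 3 colonies (Mantel needs 3)
        n_first = (n + 1) // 2 if n >= 6 else n
        for i, (bc, pos) in enumerate(zip(config.barcodes, config.coastline_positions)):
            rows.append(
                {
                    "barcode": bc,
                    "locality": f"colony_{i + 1}",
                    "latitude_dd": -15.0 - pos / km_per_deg,
                    "longitude_dd": -72.0,
                    "country": "synthetic",
                    "species": "species_A" if i < n_first else "species_B",
                    "n_individuals": config.individuals_per_population,
                }
            )
        return cls(pd.DataFrame(rows))


def read_manifest(path) -> Manifest:
    df = pd.read_csv(path, sep="\t")
    rename = {}
    if "latitude" in df.columns and "latitude_dd" not in df.columns:
        df["latitude_dd"] = df["latitude"].map(parse_coordinate)
    if "longitude" in df.columns and "longitude_dd" not in df.columns:
        df["longitude_dd"] = df["longitude"].map(parse_coordinate)
    df = df.rename(columns=rename)
    if "latitude_dd" in df.columns:
        df["latitude_dd"] = df["latitude_dd"].map(parse_coordinate)
        df["longitude_dd"] = df["longitude_dd"].map(parse_coordinate)
    return Manifest(df)


def read_fastq(path, barcode: str) -> list[Read]:
    """Read one barcode's FASTQ (Phred+33); empty file yields [] + warning."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                barcode=barcode,
                bases=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    if not reads:
        warnings.warn(f"{path}: no reads")
    return reads


def write_fastq(reads: list[Read], path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.qualities if r.qualities is not None else [40] * len(r.bases)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fasta(path, barcode: str | None = None) -> list[Read]:
    """FASTA fallback: reads without qualities (quality filter bypassed)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(Read(rec.id, barcode or "", str(rec.seq).upper(), None))
    return out


def write_fasta(sequences: dict[str, str], path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def variant_table_frame(variants: list[Variant], barcodes: list[str]) -> pd.DataFrame:
    """Wide variant table: variant_id, locus, sequence, one column per barcode."""
    rows = []
    for i, v in enumerate(variants):
        row = {"variant_id": f"var{i + 1:04d}", "locus": v.locus, "sequence": v.sequence}
        for b in barcodes:
            row[b] = v.counts.get(b, 0)
        rows.append(row)
    return pd.DataFrame(rows)


def write_variant_tables(variants: list[Variant], barcodes: list[str], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_locus: dict[str, list[Variant]] = {}
    for v in variants:
        by_locus.setdefault(v.locus, []).append(v)
    for locus, vs in sorted(by_locus.items()):
        frame = variant_table_frame(vs, barcodes)
        write_tsv(frame, outdir / f"variants_{locus}.tsv")
        write_fasta(
            {f"{locus}_var{i + 1:04d}": v.sequence for i, v in enumerate(vs)},
            outdir / f"alleles_{locus}.fasta",
        )


@dataclass
class RunConfig:
    """All pipeline thresholds and mode switches; serialized with outputs."""

    min_length: int = 180
    min_identity: float = 0.70
    min_fraction_hq: float = 0.80
    hq_phred: int = 20
    singleton_scope: str = "per-barcode"
    weighting: str = "reads"
    fst_mode: str = "phi"
    mantel_permutations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must be in [0, 1]")
        if not 0 <= self.min_fraction_hq <= 1:
            raise ValueError("min_fraction_hq must be in [0, 1]")
        if self.min_length < 0 or self.hq_phred < 0 or self.mantel_permutations < 1:
            raise ValueError("invalid threshold")

    def qc_params(self) -> QCParams:
        return QCParams(
            min_length=self.min_length,
            min_identity=self.min_identity,
            min_fraction_hq=self.min_fraction_hq,
            hq_phred=self.hq_phred,
            singleton_scope=self.singleton_scope,
        )

    def dump(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
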