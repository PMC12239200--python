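"""Readers/writers for gene-copy tables, spectra and result records.

Coordinates are 1-based and fully closed (GFF3 convention). CDS sequences are
always stored on the coding strand 5'->3' regardless of genomic strand; the
strand field only orders copies along the haplotype. Signal-peptide prediction
is external: the cleavage offset arrives as a metadata column and
:func:`apply_cleavage` removes that many 5' nucleotides before any
sequence-level analysis of the mature peptide's coding region.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from gametokit.errors import DomainError, FrameError, ParseError

LOCI = ("Tcb1", "Ga1", "Ga2")
ROLES = ("silk", "pollen")

_DNA = set("ACGTN")

METADATA_COLUMNS = [
    "copy_id",
    "genome_id",
    "locus",
    "role",
    "chrom",
    "start",
    "end",
    "strand",
    "cleave_offset",
]


@dataclass(frozen=True)
class GeneCopy:
    """One full-length gametophytic-factor gene copy.

    The atomic unit of haplotype classification and dating: a CDS plus its
    genomic placement and silk/pollen role.
    """

    copy_id: str
    genome_id: str
    locus: str
    role: str
    chrom: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    strand: str  # '+' or '-'
    cds: str  # coding strand, 5'->3'
    cleave_offset: int = 0

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise ParseError(f"{self.copy_id}: unknown locus {self.locus!r}")
        if self.role not in ROLES:
            raise ParseError(f"{self.copy_id}: unknown role {self.role!r}")
        if self.strand not in ("+", "-"):
            raise ParseError(f"{self.copy_id}: strand must be '+' or '-'")
        if self.end < self.start:
            raise ParseError(
                f"{self.copy_id}: end ({self.end}) < start ({self.start})"
            )
        if not self.cds:
            raise ParseError(f"{self.copy_id}: empty CDS")
        bad = set(self.cds.upper()) - _DNA
        if bad:
            raise ParseError(
                f"{self.copy_id}: non-DNA characters {sorted(bad)} in CDS"
            )
        if self.cleave_offset < 0 or self.cleave_offset >= len(self.cds):
            raise ParseError(
                f"{self.copy_id}: cleave_offset {self.cleave_offset} out of range"
            )
        if self.cleave_offset % 3 != 0:
            raise FrameError(
                f"{self.copy_id}: cleave_offset {self.cleave_offset} not a "
                "multiple of 3"
            )


@dataclass(frozen=True)
class RunConfig:
    """Analysis-wide parameters.

    mu is the per-site per-generation mutation rate; the default 3.3e-8 is the
    standard maize rate, with 1 generation per year for an annual species.
    """

    mu: float = 3.3e-8
    generation_time_years: float = 1.0
    identity_threshold: float = 1.0
    gap_threshold_bp: int = 1000
    theta_grid: tuple[float, ...] = tuple(float(t) for t in range(1, 201))
    mc_reps: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise DomainError("mu must be > 0")
        if not 0 < self.identity_threshold <= 1:
            raise DomainError("identity_threshold must be in (0, 1]")
        grid = tuple(self.theta_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise DomainError("theta_grid must be strictly increasing")
        if self.mc_reps < 1:
            raise DomainError("mc_reps must be >= 1")


def read_gene_copy_table(fasta_path, metadata_path) -> list[GeneCopy]:
    """Read a gene-copy table: a CDS FASTA plus a TSV of per-copy metadata.

    Every FASTA record id must appear exactly once in the metadata (matched on
    ``copy_id``); CDS sequences come from the FASTA, everything else from the
    TSV. Raises :class:`ParseError` naming the offending record on duplicate
    ids, missing metadata, coordinate violations or non-DNA characters.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise ParseError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["copy_id"].duplicated().any():
        dup = meta.loc[meta["copy_id"].duplicated(), "copy_id"].iloc[0]
        raise ParseError(f"duplicate metadata copy_id {dup!r}")
    rows = meta.set_index("copy_id")

    copies = []
    for rec in records:
        if rec.id not in rows.index:
            raise ParseError(f"FASTA record {rec.id!r} absent from metadata")
        row = rows.loc[rec.id]
        copies.append(
            GeneCopy(
                copy_id=rec.id,
                genome_id=row["genome_id"],
                locus=row["locus"],
                role=row["role"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                cds=str(rec.seq).upper(),
                cleave_offset=int(row["cleave_offset"]),
            )
        )
    return copies


def write_gene_copy_table(copies: Sequence[GeneCopy], fasta_path, metadata_path) -> None:
    """Inverse of :func:`read_gene_copy_table` (round-trips losslessly)."""
    with open(fasta_path, "w") as fh:
        for c in copies:
            fh.write(f">{c.copy_id}\n{c.cds}\n")
    pd.DataFrame(
        [
            {
                "copy_id": c.copy_id,
                "genome_id": c.genome_id,
                "locus": c.locus,
                "role": c.role,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "strand": c.strand,
                "cleave_offset": c.cleave_offset,
            }
            for c in copies
        ],
        columns=METADATA_COLUMNS,
    ).to_csv(metadata_path, sep="\t", index=False)


def apply_cleavage(copy: GeneCopy) -> str:
    """Return the CDS with the signal-peptide-encoding 5' nucleotides removed.

    The offset must be a whole number of codons so the mature-region reading
    frame is preserved; offset 0 returns the CDS unchanged.
    """
    off = copy.cleave_offset
    if off % 3 != 0:
        raise FrameError(
            f"{copy.copy_id}: cleave_offset {off} not a multiple of 3"
        )
    if off >= len(copy.cds):
        raise FrameError(f"{copy.copy_id}: cleave_offset {off} >= CDS length")
    return copy.cds[off:]


def _as_records(records) -> list[dict]:
    if isinstance(records, pd.DataFrame):
        return records.to_dict(orient="records")
    out = []
    for r in records:
        if dataclasses.is_dataclass(r):
            out.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            out.append(dict(r))
        else:
            raise TypeError(f"cannot serialize record of type {type(r)!r}")
    return out


def write_results(records, path, format: str = "tsv") -> Path:
    """Write a result table (dataclasses, dicts or a DataFrame) as TSV or JSON.

    Round-trips losslessly through :func:`read_results`. An empty table writes
    a header-only file (TSV) or an empty list (JSON); an empty table with no
    discoverable schema is rejected.
    """
    path = Path(path)
    rows = _as_records(records)
    if format == "tsv":
        if isinstance(records, pd.DataFrame):
            df = records
        else:
            df = pd.DataFrame(rows)
        if df.columns.empty:
            raise ValueError("cannot write a table with no columns")
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(rows, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_results(path, format: str = "tsv"):
    """Read back a table written by :func:`write_results`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    raise ValueError(f"unknown format {format!r}")


def read_spectrum_tsv(path) -> "list[tuple[int, int]]":
    """Read a frequency-spectrum TSV with columns ``j`` and ``a_j``."""
    df = pd.read_csv(path, sep="\t")
    if not {"j", "a_j"} <= set(df.columns):
        raise ParseError(f"{path}: spectrum TSV needs columns 'j' and 'a_j'")
    return [(int(j), int(a)) for j, a in zip(df["j"], df["a_j"])]


def write_spectrum_tsv(spectrum, path) -> Path:
    """Write a frequency spectrum as a (j, a_j) TSV, nonzero entries only."""
    rows = [
        {"j": j, "a_j": aj}
        for j, aj in enumerate(spectrum.a, start=1)
        if aj > 0
    ]
    return write_results(rows, path, "tsv")


def read_config_file(path) -> dict:
    """Parse a simple ``key = value`` configuration file (# comments allowed)."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected key = value")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
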