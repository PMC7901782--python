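"""Readers and writers for the external formats the pipeline touches.

All files are UTF-8, tab-delimited where tabular, '.' decimal. FASTQ quality
encoding is fixed to Phred+33 (the modern nanopore default); characters below
'!' are rejected. PAF follows the minimap2 dialect with 12 mandatory columns;
optional SAM-style tags are ignored except an ``AS:i`` alignment score, which
downstream quantification may use as the compatibility weight.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "ReadRecord",
    "AlignmentRecord",
    "TaxonomyEntry",
    "CountTable",
    "FormatError",
    "RANKS",
    "read_fastq",
    "write_fastq",
    "read_paf",
    "write_paf",
    "read_taxonomy",
    "write_taxonomy",
    "read_count_table",
    "write_count_table",
    "read_chemistry",
    "write_chemistry",
    "read_phenotypes",
    "write_phenotypes",
]

#: Taxonomic ranks in lineage order; species/strain are optional trailers.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species", "strain")

_PHRED_OFFSET = 33


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ReadRecord:
    """A single long read with per-base Phred quality scores."""

    read_id: str
    sequence: str
    qualities: np.ndarray  # integer Phred scores, one per base

    def __post_init__(self) -> None:
        q = np.asarray(self.qualities, dtype=np.int64)
        object.__setattr__(self, "qualities", q)
        if len(self.sequence) != q.size:
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {q.size}"
            )
        if q.size and q.min() < 0:
            raise ValueError(f"read {self.read_id!r}: negative quality score")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentRecord:
    """One PAF alignment of a read against a reference sequence."""

    read_id: str
    ref_id: str
    read_len: int
    n_matches: int
    block_len: int
    mapq: int
    strand: str = "+"
    align_score: float | None = None  # AS:i tag when present

    def __post_init__(self) -> None:
        if self.block_len <= 0:
            raise ValueError(f"alignment {self.read_id}->{self.ref_id}: block_len must be > 0")
        if not 0 <= self.n_matches <= self.block_len:
            raise ValueError(
                f"alignment {self.read_id}->{self.ref_id}: "
                f"n_matches {self.n_matches} outside [0, {self.block_len}]"
            )

    @property
    def identity(self) -> float:
        return self.n_matches / self.block_len


@dataclass(frozen=True)
class TaxonomyEntry:
    """Ranked lineage for one reference sequence.

    Missing trailing ranks are stored as None and treated as unassigned.
    """

    ref_id: str
    lineage: tuple[str | None, ...] = field(default=())

    def rank(self, rank: str) -> str | None:
        try:
            i = RANKS.index(rank)
        except ValueError:
            raise KeyError(f"unknown rank {rank!r}; expected one of {RANKS}") from None
        if i < len(self.lineage):
            return self.lineage[i]
        return None

    @property
    def genus(self) -> str | None:
        return self.rank("genus")


class CountTable:
    """Samples x taxa count matrix with per-sample metadata.

    The hub of all downstream statistics. ``counts`` is a pandas DataFrame
    (rows = samples, columns = taxa); ``metadata`` is indexed by sample and
    carries at least tank, compartment, inoculum and day where applicable.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
        counts = counts.copy()
        metadata = metadata.copy()
        if counts.columns.has_duplicates:
            raise ValueError("duplicate taxon ids in count table")
        if counts.index.has_duplicates:
            raise ValueError("duplicate sample ids in count table")
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts in count table")
        missing = counts.index.difference(metadata.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        self.counts = counts
        self.metadata = metadata.loc[counts.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, mask: pd.Series) -> "CountTable":
        """Restrict to samples where the boolean mask is true."""
        keep = self.counts.index[mask.loc[self.counts.index].to_numpy(dtype=bool)]
        return CountTable(self.counts.loc[keep], self.metadata.loc[keep])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.equals(other.metadata)

    def __repr__(self) -> str:
        return f"CountTable({len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa)"


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path | io.TextIOBase) -> Iterator[ReadRecord]:
    """Yield every record of a 4-line FASTQ file (Phred+33).

    Malformed records (length mismatch, truncated file, bad quality
    characters) raise :class:`FormatError` naming the offending line.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "r", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        lineno = 0
        while True:
            header = handle.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise FormatError(f"line {lineno}: expected '@' FASTQ header")
            seq_raw = handle.readline()
            plus_raw = handle.readline()
            qual_raw = handle.readline()
            if seq_raw == "" or plus_raw == "":
                raise FormatError(f"line {lineno}: truncated FASTQ record")
            seq = seq_raw.rstrip("\n")
            if not plus_raw.startswith("+"):
                raise FormatError(f"line {lineno + 2}: expected '+' separator line")
            if qual_raw == "" and seq != "":
                raise FormatError(f"line {lineno + 3}: truncated FASTQ record")
            qual = qual_raw.rstrip("\n")
            if len(qual) != len(seq):
                raise FormatError(
                    f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            quals = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64)
            if quals.size and quals.min() < _PHRED_OFFSET:
                raise FormatError(f"line {lineno + 3}: quality character below '!' (Phred+33)")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            yield ReadRecord(read_id, seq, quals - _PHRED_OFFSET)
            lineno += 3
    finally:
        if close:
            handle.close()


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write records as 4-line FASTQ (Phred+33); returns the record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for read in reads:
            qual = (read.qualities + _PHRED_OFFSET).astype(np.uint8).tobytes().decode("ascii")
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# PAF


def read_paf(path: str | Path | io.TextIOBase) -> list[AlignmentRecord]:
    """Parse a minimap2-style PAF file (>=12 mandatory tab-separated columns).

    Never silently drops lines: every line yields a record or raises.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, "r", encoding="utf-8")
        close = True
    else:
        handle = path
    records: list[AlignmentRecord] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(f"line {lineno}: PAF needs >=12 columns, got {len(cols)}")
            try:
                read_len = int(cols[1])
                n_matches = int(cols[9])
                block_len = int(cols[10])
                mapq = int(cols[11])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-integer numeric column ({exc})") from None
            score = None
            for tag in cols[12:]:
                if tag.startswith("AS:i:"):
                    try:
                        score = float(tag[5:])
                    except ValueError:
                        raise FormatError(f"line {lineno}: malformed AS tag {tag!r}") from None
                    break
            records.append(
                AlignmentRecord(
                    read_id=cols[0],
                    ref_id=cols[5],
                    read_len=read_len,
                    n_matches=n_matches,
                    block_len=block_len,
                    mapq=mapq,
                    strand=cols[4],
                    align_score=score,
                )
            )
    finally:
        if close:
            handle.close()
    return records


def write_paf(alignments: Iterable[AlignmentRecord], path: str | Path) -> int:
    """Write alignments as 12-column PAF (+AS tag when a score is present)."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a in alignments:
            cols = [
                a.read_id,
                str(a.read_len),
                "0",
                str(a.read_len),
                a.strand,
                a.ref_id,
                str(a.block_len),
                "0",
                str(a.block_len),
                str(a.n_matches),
                str(a.block_len),
                str(a.mapq),
            ]
            if a.align_score is not None:
                cols.append(f"AS:i:{int(round(a.align_score))}")
            fh.write("\t".join(cols) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Taxonomy


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyEntry]:
    """Read a two-column TSV (ref_id TAB ';'-separated lineage).

    Missing trailing ranks are marked unassigned (None); duplicated ref_ids
    are an error.
    """
    entries: dict[str, TaxonomyEntry] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: taxonomy TSV needs 2 columns")
            ref_id, lineage_str = parts
            if ref_id in entries:
                raise FormatError(f"line {lineno}: duplicate ref_id {ref_id!r}")
            lineage = tuple(
                (name.strip() or None) for name in lineage_str.split(";")
            )[: len(RANKS)]
            entries[ref_id] = TaxonomyEntry(ref_id, lineage)
    return entries


def write_taxonomy(taxonomy: dict[str, TaxonomyEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ref_id in sorted(taxonomy):
            lineage = ";".join(name or "" for name in taxonomy[ref_id].lineage)
            fh.write(f"{ref_id}\t{lineage}\n")


# ---------------------------------------------------------------------------
# Count tables


def write_count_table(table: CountTable, counts_path: str | Path, meta_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_count_table(counts_path: str | Path, meta_path: str | Path) -> CountTable:
    """Read counts + metadata TSVs; round-trips :func:`write_count_table` exactly."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="sample_id")
    metadata = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    if (counts.to_numpy() < 0).any():
        raise FormatError(f"{counts_path}: negative count")
    missing = counts.index.difference(metadata.index)
    if len(missing):
        raise FormatError(f"{counts_path}: samples absent from metadata: {sorted(missing)[:5]}")
    return CountTable(counts, metadata)


# ---------------------------------------------------------------------------
# Chemistry and phenotype tables (long-format TSVs)

_CHEM_COLS = ["tank", "day", "analyte", "value"]
_PHENO_COLS = ["plant", "tank", "day", "height_cm", "leaves", "root_length_cm"]


def read_chemistry(path: str | Path) -> pd.DataFrame:
    """Read a long-format chemistry TSV with columns tank, day, analyte, value."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_CHEM_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: chemistry TSV missing columns {sorted(missing)}")
    return df[_CHEM_COLS]


def write_chemistry(df: pd.DataFrame, path: str | Path) -> None:
    df[_CHEM_COLS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PHENO_COLS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: phenotype TSV missing columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
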