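"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython; tabular data are plain TSV with a header
row.  All readers validate against the owning module's invariants and name
the offending rows in their error messages.  Interval outputs use 0-based
half-open (BED) coordinates.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zfscreen.growth import GROWTH_COLUMNS, validate_growth_table
from zfscreen.scanner import ScanHit
from zfscreen.transcriptomics import CountMatrix

logger = logging.getLogger("zfscreen")

_IUPAC = set("ACGTNRYSWKMBDHV")


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered {id: uppercase sequence} mapping."""
    path = Path(path)
    seqs: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(
                f"{path}: record {record.id!r} has non-IUPAC characters {bad}"
            )
        if record.id in seqs:
            raise ValueError(f"{path}: duplicate record id {record.id!r}")
        seqs[record.id] = seq
    if not seqs:
        warnings.warn(f"{path}: no FASTA records found")
    return seqs


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA (default 60 columns)."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_counts(counts_path, samples_path) -> CountMatrix:
    """Read a gene x sample counts TSV plus a sample sheet (sample, group).

    Counts must be non-negative integers with unique gene ids; every count
    column must appear in the sample sheet with a group label.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t")
    for col in ("sample", "group"):
        if col not in sheet.columns:
            raise ValueError(f"{samples_path}: missing column {col!r}")
    if sheet["sample"].duplicated().any():
        raise ValueError(f"{samples_path}: duplicated sample names")
    groups = sheet.set_index("sample")["group"]
    neg = counts.lt(0)
    if neg.any().any():
        sample = neg.any().idxmax()
        gene = neg[sample].idxmax()
        raise ValueError(
            f"{counts_path}: negative count for gene {gene!r}, sample {sample!r}"
        )
    return CountMatrix(counts=counts, groups=groups)


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV (gene, length_kbp, optional label columns)."""
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if "length_kbp" not in ann.columns:
        raise ValueError(f"{path}: missing required column 'length_kbp'")
    bad = ann.index[ann["length_kbp"] <= 0]
    if len(bad):
        raise ValueError(f"{path}: nonpositive lengths for genes {list(bad[:5])}")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique()
        raise ValueError(f"{path}: duplicated gene ids {list(dups[:5])}")
    return ann


def read_growth(path) -> pd.DataFrame:
    """Read a long-format growth TSV (plant_id, genotype, day, area)."""
    table = pd.read_csv(path, sep="\t")
    return validate_growth_table(table)


def read_qpcr(path) -> pd.DataFrame:
    """Read a qPCR TSV (sample, gene, cq); Cq values must be positive."""
    table = pd.read_csv(path, sep="\t")
    for col in ("sample", "gene", "cq"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if (table["cq"] <= 0).any():
        bad = table.loc[table["cq"] <= 0]
        raise ValueError(
            f"{path}: nonpositive Cq for {bad.iloc[0]['sample']!r}/"
            f"{bad.iloc[0]['gene']!r}"
        )
    return table


def write_hits_bed(hits: Iterable[ScanHit], path, site: str = "") -> None:
    """Write scan hits as BED-like TSV: seq, start, end, site, strand, mm."""
    with open(path, "w") as fh:
        fh.write("# zfscreen scan hits; coordinates 0-based half-open\n")
        fh.write("#sequence_id\tstart\tend\tsite\tstrand\tmismatches\n")
        for h in hits:
            mm = ",".join(str(m) for m in h.mismatches_used)
            fh.write(
                f"{h.sequence_id}\t{h.offset}\t{h.end}\t{site}\t{h.strand}\t{mm}\n"
            )


def read_bed_intervals(path) -> List[Tuple[str, int, int, str, str]]:
    """Read a 6-column BED file into (chrom, start, end, name, strand) tuples."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{i}: need 6 BED columns, got {len(parts)}")
            chrom, start, end, name, _score, strand = parts[:6]
            out.append((chrom, int(start), int(end), name, strand))
    return out
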