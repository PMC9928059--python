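"""Readers and writers for the pipeline's file formats.

All in-memory coordinates are 0-based half-open.  GFF3 (1-based, closed) is
converted at this boundary; BED-family formats pass through unchanged.
Every writer has a paired reader and the pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval

__all__ = [
    "DataError",
    "read_gff3", "write_gff3",
    "read_bed", "write_bed",
    "read_narrowpeak", "write_narrowpeak",
    "read_broadpeak", "write_broadpeak",
    "read_fasta", "write_fasta",
    "read_counts", "write_counts",
    "read_metadata", "write_metadata",
    "read_manifest", "write_manifest",
    "read_config", "write_config",
]


class DataError(ValueError):
    """Malformed input data (reported with file and line where possible)."""


def _check_coords(df: pd.DataFrame, path) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise DataError(f"{path}: end <= start at line {int(bad[0]) + 1}")


# -- GFF3 -------------------------------------------------------------------

def read_gff3(path) -> pd.DataFrame:
    """Gene annotation from GFF3; 1-based closed converted to half-open."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            try:
                start_i, end_i = int(start) - 1, int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-integer coordinate") from exc
            rows.append(
                (attr.get("ID", f"gene{lineno}"), chrom, start_i, end_i, strand,
                 attr.get("biotype", "protein_coding"),
                 attr.get("tissue_spec", "none"), attr.get("locus_group", "none"))
            )
    ann = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "biotype", "tissue_spec", "group"]
    )
    _check_coords(ann, path)
    return ann


def write_gff3(annotation: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in annotation.iterrows():
            attrs = (
                f"ID={r['gene_id']};biotype={r['biotype']};"
                f"tissue_spec={r['tissue_spec']};locus_group={r['group']}"
            )
            fh.write(
                f"{r['chrom']}\trelocus\tgene\t{r['start'] + 1}\t{r['end']}\t."
                f"\t{r['strand']}\t.\t{attrs}\n"
            )


# -- BED family -------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """BED3+ intervals (columns beyond the sixth ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(
                    parts[0], int(parts[1]), int(parts[2]),
                    parts[5] if len(parts) >= 6 and parts[5] in "+-" else ".",
                )
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path,
              names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def _read_peak(path, extra: int) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6 + extra:
                raise DataError(
                    f"{path}:{lineno}: expected {6 + extra} columns"
                )
            try:
                rows.append(
                    (parts[0], int(parts[1]), int(parts[2]), parts[3],
                     float(parts[6]))
                )
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    _check_coords(df, path)
    return df


def read_narrowpeak(path) -> pd.DataFrame:
    """ENCODE narrowPeak (BED6+4); signalValue carried as 'score'."""
    return _read_peak(path, extra=4)


def read_broadpeak(path) -> pd.DataFrame:
    """ENCODE broadPeak (BED6+3); signalValue carried as 'score'."""
    return _read_peak(path, extra=3)


def _write_peak(peaks: pd.DataFrame, path, narrow: bool) -> None:
    # BED score column clamped to 0-1000; the real-valued signal lives in
    # the signalValue column.
    with open(path, "w") as fh:
        for _, r in peaks.iterrows():
            bed_score = int(min(1000, max(0, round(r["score"]))))
            cols = [r["chrom"], r["start"], r["end"], r["name"], bed_score, ".",
                    r["score"], -1, -1]
            if narrow:
                cols.append(-1)
            fh.write("\t".join(map(str, cols)) + "\n")


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    _write_peak(peaks, path, narrow=True)


def write_broadpeak(peaks: pd.DataFrame, path) -> None:
    _write_peak(peaks, path, narrow=False)


# -- FASTA ------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="")
        for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# -- tables -----------------------------------------------------------------

def read_counts(path, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts < 0).any().any():
        raise DataError(f"{path}: negative counts")
    if metadata is not None:
        missing = set(metadata["sample_id"]) - set(counts.columns)
        if missing:
            raise DataError(
                f"{path}: samples in metadata but not in counts: {sorted(missing)}"
            )
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "tissue", "stage", "genotype", "replicate"}
    missing = required - set(meta.columns)
    if missing:
        raise DataError(f"{path}: missing metadata columns {sorted(missing)}")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh)
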