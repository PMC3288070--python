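"""Standard-format I/O: FASTA, BED, GFF3, RepeatMasker .out, TSV.

All interval coordinates are converted to the internal 0-based,
half-open convention on read: BED is taken as-is, GFF3 and RepeatMasker
.out are 1-based inclusive (start − 1, end unchanged).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "read_bed", "read_gff3",
           "read_repeatmasker_out", "read_intervals", "softmask_intervals",
           "write_tsv"]

INTERVAL_COLUMNS = ["chrom", "start", "end"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {record id: sequence} (uppercased as-is not
    applied: soft-masking case is preserved)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 80) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_bed(path: str | Path) -> pd.DataFrame:
    """First three BED columns; BED is already 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=INTERVAL_COLUMNS,
                     dtype={"chrom": str, "start": int, "end": int})
    _check_intervals(df, path)
    return df


def read_gff3(path: str | Path, feature_types: set[str] | None = None
              ) -> pd.DataFrame:
    """GFF3 feature spans, converted from 1-based inclusive.

    `feature_types` filters on column 3 (e.g. {"gene", "pseudogene"});
    None keeps every feature line.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 2, 3, 4],
                     names=["chrom", "type", "start", "end"],
                     dtype={"chrom": str, "type": str, "start": int, "end": int})
    if feature_types is not None:
        df = df[df["type"].isin(feature_types)]
    out = pd.DataFrame({"chrom": df["chrom"], "start": df["start"] - 1,
                        "end": df["end"]}).reset_index(drop=True)
    _check_intervals(out, path)
    return out


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """RepeatMasker .out repeat spans (columns 5-7, 1-based inclusive)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        fields = line.split()
        if not fields or not fields[0].lstrip("-").isdigit():
            continue  # header/blank lines
        if len(fields) < 7:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker line")
        rows.append({"chrom": fields[4], "start": int(fields[5]) - 1,
                     "end": int(fields[6])})
    df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    _check_intervals(df, path)
    return df


def read_intervals(path: str | Path, fmt: str | None = None,
                   feature_types: set[str] | None = None) -> pd.DataFrame:
    """Dispatch on format (or file extension): bed | gff3 | rmout."""
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"bed": "bed", ".bed": "bed", ".gff3": "gff3", ".gff": "gff3",
               ".out": "rmout"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer interval format from {path.name!r}")
    if fmt == "bed":
        return read_bed(path)
    if fmt == "gff3":
        return read_gff3(path, feature_types)
    if fmt == "rmout":
        return read_repeatmasker_out(path)
    raise ValueError(f"unknown interval format {fmt!r}")


def softmask_intervals(sequence: str, chrom: str = "") -> pd.DataFrame:
    """Lowercase (soft-masked) runs of a sequence as repeat intervals."""
    rows = []
    start = None
    for i, c in enumerate(sequence):
        if c.islower():
            if start is None:
                start = i
        elif start is not None:
            rows.append({"chrom": chrom, "start": start, "end": i})
            start = None
    if start is not None:
        rows.append({"chrom": chrom, "start": start, "end": len(sequence)})
    return pd.DataFrame(rows, columns=INTERVAL_COLUMNS)


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _check_intervals(df: pd.DataFrame, path) -> None:
    bad = df[(df["start"] < 0) | (df["end"] <= df["start"])]
    if len(bad):
        i = bad.index[0]
        raise ValueError(
            f"{path}: invalid interval {bad.loc[i, 'start']}-{bad.loc[i, 'end']}"
            f" on {bad.loc[i, 'chrom']}")
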