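"""Shared file I/O: FASTA/FASTQ via Biopython, GFF3/BED/bedGraph/Ct tables
via pandas, plus run manifests.

Conventions: FASTA wrapped at 60 columns; FASTQ Phred+33; GFF3 1-based
closed on disk (converted to the package's 0-based half-open coordinates
in memory); BED and bedGraph 0-based half-open; tables are TSV with a
header line and '#' comments.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .haplotype import Feature


def read_fasta(path) -> dict[str, str]:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"])))
    return out


def write_fastq(path, records) -> None:
    recs = []
    for name, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=name, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


GFF3_COLUMNS = ["seqid", "source", "type", "start", "end",
                "score", "strand", "phase", "attributes"]


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
        else:
            out.setdefault("Note", part)
    return out


def read_gff3(path) -> list[Feature]:
    """Read GFF3 features (including the CENSOR-output dialect) into
    0-based half-open Features."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=GFF3_COLUMNS, dtype=str)
    features = []
    for i, row in df.iterrows():
        try:
            start, end = int(row["start"]), int(row["end"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed GFF3 record at data line {i + 1}") from exc
        attrs = _parse_attributes(row["attributes"] if isinstance(row["attributes"], str) else "")
        name = attrs.get("Name") or attrs.get("ID") or attrs.get("Target", f"feature{i}")
        strand = row["strand"] if row["strand"] in {"+", "-"} else "."
        features.append(Feature(name, start - 1, end, strand, row["type"],
                                {**attrs, "seqid": row["seqid"],
                                 "source": row["source"]}))
    return features


def write_gff3(path, features: list[Feature], seqid: str = "haplotype",
               source: str = "repeatloop") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(
                [f"Name={f.name}"]
                + [f"{k}={v}" for k, v in f.attributes.items()
                   if k not in {"seqid", "source", "Name"}]
            )
            fh.write("\t".join([
                f.attributes.get("seqid", seqid),
                f.attributes.get("source", source),
                f.kind, str(f.start + 1), str(f.end), ".", f.strand, ".", attrs,
            ]) + "\n")


def write_bed(path, intervals, seqid: str = "haplotype") -> None:
    """``intervals``: iterable of (start, end) or (start, end, name)."""
    with open(path, "w") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            name = iv[2] if len(iv) > 2 else "."
            fh.write(f"{seqid}\t{start}\t{end}\t{name}\n")


def write_bedgraph(path, values, seqid: str = "haplotype") -> None:
    """``values``: iterable of (start, end, value)."""
    with open(path, "w") as fh:
        for start, end, value in values:
            fh.write(f"{seqid}\t{start}\t{end}\t{value:g}\n")


def write_table(path, df: pd.DataFrame, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    from .qpcr import validate_ct_table

    return validate_ct_table(df)


@dataclasses.dataclass
class RunManifest:
    """Provenance record emitted once per pipeline invocation."""

    command: str
    config: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: list[str]
    seed: int | None = None
    version: str = "0.1.0"
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")

    @staticmethod
    def checksum(path) -> str:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
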