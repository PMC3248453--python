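"""FASTA / GFF3 / BED / TSV input-output helpers shared by the pipeline stages.

Coordinates are 0-based half-open everywhere inside the package; GFF3 export
converts to 1-based inclusive, BED input is taken as 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "write_gff3",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-contig) FASTA file into {name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write sequences as 60-column wrapped FASTA."""
    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def _parse_gff3_attributes(field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_intervals(path: str | Path, fmt: str | None = None) -> list[dict]:
    """Read candidate intervals from BED (0-based half-open) or GFF3 (1-based inclusive).

    Returns a list of dicts with keys contig, start, end (0-based half-open),
    source and attributes. Format is inferred from the suffix when ``fmt`` is
    None (``.bed`` vs anything else treated as GFF3).
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed" if path.suffix.lower() == ".bed" else "gff3"
    rows: list[dict] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else "bed"
                rows.append({"contig": contig, "start": start, "end": end,
                             "source": name, "attributes": {}})
            else:
                if len(fields) < 9:
                    raise ValueError(f"malformed GFF3 line: {line!r}")
                contig, source = fields[0], fields[1]
                start, end = int(fields[3]) - 1, int(fields[4])
                rows.append({"contig": contig, "start": start, "end": end,
                             "source": source,
                             "attributes": _parse_gff3_attributes(fields[8])})
    return rows


def write_gff3(features: Iterable[dict], path: str | Path, source: str = "ltrcensus") -> None:
    """Write features as GFF3 (converting 0-based half-open to 1-based inclusive).

    Each feature dict needs contig, start, end; optional type (default
    LTR_retrotransposon), strand, score and attributes (dict).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.get("attributes", {}).items())
            score = f.get("score")
            fh.write("\t".join([
                f["contig"],
                f.get("source", source),
                f.get("type", "LTR_retrotransposon"),
                str(f["start"] + 1),
                str(f["end"]),
                "." if score is None else f"{score:.3f}",
                f.get("strand", "+"),
                ".",
                attrs or ".",
            ]) + "\n")
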