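"""FASTQ/FASTA/TSV/JSON plumbing shared by the pipeline stages.

All sequence I/O goes through Biopython; tables through pandas. Coordinates
in files are 1-based inclusive, internal coordinates 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .preprocess import Read


def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable["Read"]) -> None:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def read_fastq(path: str | Path) -> list["Read"]:
    from .preprocess import Read

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            Read(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
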