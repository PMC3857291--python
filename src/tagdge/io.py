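"""File dialects shared by the pipeline and the CLI.

Everything is plain text: FASTA for transcriptomes (via Biopython),
headered TSV for tag counts / expression / DE tables, JSON for
summaries and reports.  Header metadata lines start with ``#key=``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .mapping import TagCountTable
from .reference import ReferenceTagDB, db_from_frame
from .simulate import SimulationTruth, SyntheticTranscript


# -- FASTA -------------------------------------------------------------------

def write_fasta(transcripts: Iterable, path) -> None:
    records = []
    for t in transcripts:
        if isinstance(t, SeqRecord):
            records.append(t)
        else:
            records.append(SeqRecord(Seq(t.sequence), id=t.gene_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[SyntheticTranscript]:
    return [
        SyntheticTranscript(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_fasta_pairs(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs without SyntheticTranscript validation."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


# -- headered TSV helpers ----------------------------------------------------

def _read_headers(path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, value = line[1:].strip().partition("=")
            if value:
                meta[key] = value
    return meta, n_header


# -- tag count tables --------------------------------------------------------

def write_tag_table(table: TagCountTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_id={table.library_id}\n")
        fh.write(f"#library_size={table.library_size}\n")
        fh.write("tag_sequence\tcount\n")
        for tag in sorted(table.entries):
            fh.write(f"{tag}\t{table.entries[tag]}\n")


def read_tag_table(path) -> TagCountTable:
    meta, n_header = _read_headers(path)
    frame = pd.read_csv(path, sep="\t", skiprows=n_header)
    entries = dict(zip(frame["tag_sequence"], frame["count"].astype(int)))
    library_size = int(meta.get("library_size", sum(entries.values())))
    library_id = meta.get("library_id", Path(path).stem)
    return TagCountTable(library_id, entries, library_size)


# -- expression tables -------------------------------------------------------

def write_expression(frame: pd.DataFrame, path, library_id: str, library_size: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"#library_id={library_id}\n")
        fh.write(f"#library_size={library_size}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_expression(path) -> tuple[pd.DataFrame, str, int]:
    meta, n_header = _read_headers(path)
    frame = pd.read_csv(path, sep="\t", skiprows=n_header)
    return frame, meta.get("library_id", Path(path).stem), int(meta["library_size"])


# -- reference tag DB --------------------------------------------------------

def write_refdb(db: ReferenceTagDB, path, summary_path=None) -> None:
    with open(path, "w") as fh:
        fh.write(f"#n_genes={db.n_genes}\n")
        db.to_frame().to_csv(fh, sep="\t", index=False)
    if summary_path is not None:
        Path(summary_path).write_text(db.summary_json() + "\n")


def read_refdb(path) -> ReferenceTagDB:
    meta, n_header = _read_headers(path)
    frame = pd.read_csv(path, sep="\t", skiprows=n_header)
    n_genes = int(meta["n_genes"]) if "n_genes" in meta else None
    return db_from_frame(frame, n_genes=n_genes)


# -- simulation truth --------------------------------------------------------

def write_truth(truth: SimulationTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#control={truth.control}\n")
        truth.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_truth(path) -> SimulationTruth:
    meta, n_header = _read_headers(path)
    # keep_default_na: the direction label "null" is data, not a missing value
    frame = pd.read_csv(path, sep="\t", skiprows=n_header, keep_default_na=False)
    for col in frame.columns:
        if col.startswith(("baseline", "weight_")):
            frame[col] = frame[col].astype(float)
    return SimulationTruth.from_frame(frame, control=meta.get("control", "control"))


# -- DE tables & JSON --------------------------------------------------------

def write_de_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
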