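"""Reference tag database construction.

Tag-based DGE assays represent each transcript by the 21-nt sequence
(``CATG`` + 17 nt) anchored at an NlaIII restriction site.  The mapping
target is therefore not the transcriptome itself but the set of all
21-mers that start at a CATG site and have a full 17-nt extension, taken
from both the sense strand and the reverse complement of every unigene.
This module enumerates that set and records, per tag, its gene of
origin, strand, site coordinate and whether it is the 3'-most sense tag
(the one an oligo(dT)-primed library actually captures).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import pandas as pd

from ._codec import ANCHOR, TAG_LEN

logger = logging.getLogger(__name__)

_ANCHOR_RE = re.compile(f"(?={ANCHOR})")
_VALID_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReferenceTag:
    """One CATG-anchored 21-mer enumerable from a reference transcript."""

    tag_sequence: str
    gene_id: str
    site_position: int  # 0-based offset of the CATG start on the sense strand
    strand: str  # "sense" | "antisense"
    is_3prime_most: bool = False

    def __post_init__(self) -> None:
        if len(self.tag_sequence) != TAG_LEN:
            raise ValueError(f"tag must be {TAG_LEN} nt: {self.tag_sequence!r}")
        if not self.tag_sequence.startswith(ANCHOR):
            raise ValueError(f"tag must start with {ANCHOR}: {self.tag_sequence!r}")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"unknown strand {self.strand!r}")


class ReferenceTagDB:
    """All reference tags of a transcriptome plus lookup indexes.

    Parameters
    ----------
    tags:
        Every (tag_sequence, gene, strand, position) entry.  The same
        21-mer may occur several times (several sites, genes, strands).
    n_genes:
        Total number of transcripts scanned, including those that
        yielded no usable site.
    """

    def __init__(self, tags: Sequence[ReferenceTag], n_genes: int):
        self.tags: list[ReferenceTag] = list(tags)
        self.n_genes = int(n_genes)
        self._by_sequence: dict[str, list[ReferenceTag]] = {}
        genes_with_sites: set[str] = set()
        for t in self.tags:
            self._by_sequence.setdefault(t.tag_sequence, []).append(t)
            genes_with_sites.add(t.gene_id)
        self.n_genes_with_sites = len(genes_with_sites)
        self.n_reference_tags = len(self.tags)
        self.gene_index: dict[str, frozenset[str]] = {
            seq: frozenset(t.gene_id for t in entries)
            for seq, entries in self._by_sequence.items()
        }
        self.gene_ids: list[str] = sorted(genes_with_sites)

    def lookup(self, tag_sequence: str) -> list[ReferenceTag]:
        return self._by_sequence.get(tag_sequence, [])

    @property
    def ambiguous_tags(self) -> frozenset[str]:
        """Tag sequences shared by two or more distinct genes."""
        return frozenset(s for s, g in self.gene_index.items() if len(g) >= 2)

    def __len__(self) -> int:
        return self.n_reference_tags

    def __iter__(self) -> Iterator[ReferenceTag]:
        return iter(self.tags)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tag_sequence": [t.tag_sequence for t in self.tags],
                "gene_id": [t.gene_id for t in self.tags],
                "position": [t.site_position for t in self.tags],
                "strand": [t.strand for t in self.tags],
                "is_3prime_most": [t.is_3prime_most for t in self.tags],
            }
        )

    def summary(self) -> dict:
        return {
            "n_genes": self.n_genes,
            "n_genes_with_sites": self.n_genes_with_sites,
            "n_reference_tags": self.n_reference_tags,
            "n_distinct_tag_sequences": len(self.gene_index),
            "n_ambiguous_tag_sequences": len(self.ambiguous_tags),
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _as_pairs(transcripts: Iterable) -> list[tuple[str, str]]:
    """Normalise SeqRecords / (id, seq) pairs / objects with gene_id+sequence."""
    pairs = []
    for rec in transcripts:
        if hasattr(rec, "gene_id"):
            pairs.append((rec.gene_id, str(rec.sequence)))
        elif hasattr(rec, "id") and hasattr(rec, "seq"):
            pairs.append((rec.id, str(rec.seq)))
        else:
            gid, seq = rec
            pairs.append((str(gid), str(seq)))
    return pairs


def sense_tag_sites(sequence: str) -> list[int]:
    """0-based starts of CATG sites with a full 17-nt downstream extension."""
    seq = sequence.upper()
    return [
        m.start()
        for m in _ANCHOR_RE.finditer(seq)
        if m.start() + TAG_LEN <= len(seq)
    ]


def extract_reference_tags(transcripts: Iterable) -> ReferenceTagDB:
    """Enumerate every CATG-anchored 21-mer of a transcriptome, both strands.

    Sense tags come from CATG occurrences with at least 17 nt downstream;
    antisense tags are extracted identically from the reverse complement
    and recorded with the sense-strand coordinate of their site.  Sites
    whose 21-mer contains an N are skipped (a 21-mer with N cannot be
    matched under a 1-mismatch budget without inflating ambiguity).
    The sense tag with the largest coordinate per gene is flagged as
    3'-most, which is the site an oligo(dT)-primed protocol captures.
    """
    pairs = _as_pairs(transcripts)
    if not pairs:
        raise ValueError("empty transcriptome")
    seen: set[str] = set()
    tags: list[ReferenceTag] = []
    n_skipped_n = 0
    for gene_id, seq in pairs:
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        seq = seq.upper()
        bad = set(seq) - _VALID_ALPHABET
        if bad:
            raise ValueError(
                f"invalid characters {sorted(bad)} in transcript {gene_id!r}"
            )
        length = len(seq)
        sense: list[ReferenceTag] = []
        for i in sense_tag_sites(seq):
            tag = seq[i : i + TAG_LEN]
            if "N" in tag:
                n_skipped_n += 1
                continue
            sense.append(ReferenceTag(tag, gene_id, i, "sense"))
        if sense:
            # re-create the 3'-most entry with its flag set (frozen dataclass)
            last = max(range(len(sense)), key=lambda k: sense[k].site_position)
            t = sense[last]
            sense[last] = ReferenceTag(
                t.tag_sequence, t.gene_id, t.site_position, "sense", True
            )
        tags.extend(sense)
        rc = reverse_complement(seq)
        for j in sense_tag_sites(rc):
            tag = rc[j : j + TAG_LEN]
            if "N" in tag:
                n_skipped_n += 1
                continue
            # CATG is palindromic: the site occupies sense [L-j-4, L-j)
            tags.append(ReferenceTag(tag, gene_id, length - j - 4, "antisense"))
    if n_skipped_n:
        logger.info("skipped %d tag sites containing N", n_skipped_n)
    return ReferenceTagDB(tags, n_genes=len(pairs))


def db_from_frame(frame: pd.DataFrame, n_genes: int | None = None) -> ReferenceTagDB:
    """Rebuild a ReferenceTagDB from its tabular serialisation."""
    tags = [
        ReferenceTag(
            str(r.tag_sequence),
            str(r.gene_id),
            int(r.position),
            str(r.strand),
            bool(r.is_3prime_most),
        )
        for r in frame.itertuples(index=False)
    ]
    if n_genes is None:
        n_genes = frame["gene_id"].nunique()
    return ReferenceTagDB(tags, n_genes=n_genes)
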