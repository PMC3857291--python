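"""Clean-tag to gene mapping with one-mismatch tolerance, and TPM.

Observed 21-nt clean tags are assigned to reference tags by best-hit
precedence: an exact match always beats a 1-mismatch match.  A tag whose
best-tier hits span two or more distinct genes is ambiguous and its
copies are discarded from every gene — only unambiguous tags contribute
to expression.  Tags whose only hits are antisense reference tags are
tabulated separately and excluded from gene expression totals by
default (they can be folded in with ``include_antisense=True``).

Expression is normalised to TPM, transcripts per million clean tags:
``count / library_size * 1e6`` where the denominator is the total
number of clean tags in the library, mapped or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._codec import ANCHOR, MISMATCH_MASKS, TAG_LEN, encode_tags
from .reference import ReferenceTagDB

__all__ = [
    "TagCountTable",
    "MappingReport",
    "MappingResult",
    "map_tags",
    "normalize_tpm",
    "quantify",
]


@dataclass
class TagCountTable:
    """Observed tag sequences and counts for one library.

    ``library_size`` is the total number of clean tags (the TPM
    denominator); it may exceed the sum of entry counts when unmappable
    tags were dropped upstream, and the entries of a raw (unfiltered)
    table may include tags without the CATG anchor.
    """

    library_id: str
    entries: dict[str, int]
    library_size: int

    def __post_init__(self) -> None:
        if self.library_size < 0:
            raise ValueError("library_size must be non-negative")
        for tag, count in self.entries.items():
            if count < 1:
                raise ValueError(f"count for tag {tag!r} must be >= 1")

    @property
    def n_distinct(self) -> int:
        return len(self.entries)

    @property
    def n_copies(self) -> int:
        return sum(self.entries.values())


@dataclass
class MappingReport:
    """Mapping outcome tallies, per distinct tag and copy-weighted.

    Mapped percentages of distinct tags are what SAGE-style studies
    usually print; copy-weighted fractions answer how much of the
    library's depth was usable.
    """

    library_id: str
    max_mismatch: int
    n_distinct: int = 0
    n_copies: int = 0
    distinct: dict[str, int] = field(default_factory=dict)
    copies: dict[str, int] = field(default_factory=dict)

    CATEGORIES = ("sense", "antisense", "ambiguous", "unmapped")

    def __post_init__(self) -> None:
        for c in self.CATEGORIES:
            self.distinct.setdefault(c, 0)
            self.copies.setdefault(c, 0)

    def fraction_distinct(self, category: str) -> float:
        return self.distinct[category] / self.n_distinct if self.n_distinct else 0.0

    def fraction_copies(self, category: str) -> float:
        return self.copies[category] / self.n_copies if self.n_copies else 0.0

    @property
    def mapped_fraction_distinct(self) -> float:
        """Fraction of distinct clean tags hitting the reference (sense or antisense)."""
        return self.fraction_distinct("sense") + self.fraction_distinct("antisense")

    @property
    def mapped_fraction_copies(self) -> float:
        return self.fraction_copies("sense") + self.fraction_copies("antisense")

    def to_dict(self) -> dict:
        return {
            "library_id": self.library_id,
            "max_mismatch": self.max_mismatch,
            "n_distinct": self.n_distinct,
            "n_copies": self.n_copies,
            "distinct": dict(self.distinct),
            "copies": dict(self.copies),
            "mapped_fraction_distinct": self.mapped_fraction_distinct,
            "mapped_fraction_copies": self.mapped_fraction_copies,
        }


@dataclass
class MappingResult:
    gene_counts: dict[str, int]
    antisense_counts: dict[str, int]
    report: MappingReport


def _validate_table(table: TagCountTable) -> list[tuple[str, int]]:
    items = sorted(table.entries.items())
    for row, (tag, _count) in enumerate(items, start=1):
        if len(tag) != TAG_LEN:
            raise ValueError(
                f"row {row}: tag {tag!r} has length {len(tag)}, expected {TAG_LEN}"
            )
        if not tag.startswith(ANCHOR):
            raise ValueError(f"row {row}: tag {tag!r} does not start with {ANCHOR}")
    return items


def map_tags(
    table: TagCountTable,
    db: ReferenceTagDB,
    max_mismatch: int = 1,
    include_antisense: bool = False,
) -> MappingResult:
    """Assign observed clean tags to genes with best-hit precedence.

    Parameters
    ----------
    max_mismatch:
        0 for exact-only, 1 to allow a single substitution when no exact
        hit exists.
    include_antisense:
        Fold counts whose only hits are antisense reference tags into
        the gene's expression count instead of tabulating them apart.

    Returns per-gene unambiguous counts, per-gene antisense counts and a
    :class:`MappingReport`.  Raises ``ValueError`` naming the offending
    row for malformed tags.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    items = _validate_table(table)
    report = MappingReport(table.library_id, max_mismatch)
    gene_counts: dict[str, int] = {}
    antisense_counts: dict[str, int] = {}
    if not items:
        return MappingResult(gene_counts, antisense_counts, report)

    tags = [t for t, _ in items]
    counts = np.array([c for _, c in items], dtype=np.int64)
    report.n_distinct = len(tags)
    report.n_copies = int(counts.sum())

    ref_seqs = sorted(db.gene_index)
    ref_codes = encode_tags(ref_seqs)
    order = np.argsort(ref_codes)
    ref_codes_sorted = ref_codes[order]
    ref_entries = [db.lookup(ref_seqs[i]) for i in order]

    obs_codes = encode_tags(tags)

    def _exact_hits(codes: np.ndarray) -> np.ndarray:
        """Index into ref_entries for each code, -1 when absent."""
        pos = np.searchsorted(ref_codes_sorted, codes)
        pos_clip = np.minimum(pos, len(ref_codes_sorted) - 1)
        hit = ref_codes_sorted[pos_clip] == codes
        return np.where(hit, pos_clip, -1)

    exact = _exact_hits(obs_codes) if len(ref_codes_sorted) else np.full(len(tags), -1)

    # hits[i]: list of reference-entry lists for observed tag i at its best tier
    best_hits: list[list] = [[] for _ in tags]
    for i, e in enumerate(exact):
        if e >= 0:
            best_hits[i] = [ref_entries[e]]

    if max_mismatch == 1 and len(ref_codes_sorted):
        unmatched = np.flatnonzero(exact < 0)
        chunk = 20000
        for start in range(0, len(unmatched), chunk):
            idx = unmatched[start : start + chunk]
            variants = obs_codes[idx][:, None] ^ MISMATCH_MASKS[None, :]
            vhits = _exact_hits(variants.ravel()).reshape(variants.shape)
            rows, cols = np.nonzero(vhits >= 0)
            for r, c in zip(rows.tolist(), cols.tolist()):
                best_hits[int(idx[r])].append(ref_entries[int(vhits[r, c])])

    for i, (tag, count) in enumerate(items):
        entry_lists = best_hits[i]
        if not entry_lists:
            category = "unmapped"
        else:
            entries = [t for lst in entry_lists for t in lst]
            genes = {t.gene_id for t in entries}
            if len(genes) >= 2:
                category = "ambiguous"
            else:
                (gene,) = genes
                if any(t.strand == "sense" for t in entries):
                    category = "sense"
                    gene_counts[gene] = gene_counts.get(gene, 0) + count
                else:
                    category = "antisense"
                    antisense_counts[gene] = antisense_counts.get(gene, 0) + count
                    if include_antisense:
                        gene_counts[gene] = gene_counts.get(gene, 0) + count
        report.distinct[category] += 1
        report.copies[category] += count

    return MappingResult(gene_counts, antisense_counts, report)


def normalize_tpm(
    counts: Mapping[str, int], library_size: int, genes: "list[str] | None" = None
) -> dict[str, float]:
    """counts / library_size * 1e6; genes absent from ``counts`` get 0."""
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    universe = list(genes) if genes is not None else list(counts)
    out = {}
    for g in universe:
        c = counts.get(g, 0)
        if c < 0:
            raise ValueError(f"negative count for gene {g!r}")
        out[g] = c / library_size * 1e6
    return out


def quantify(
    table: TagCountTable,
    db: ReferenceTagDB,
    max_mismatch: int = 1,
    include_antisense: bool = False,
) -> tuple[pd.DataFrame, MappingReport]:
    """Map a library and return per-gene (count, tpm) over all reference genes."""
    result = map_tags(table, db, max_mismatch, include_antisense)
    genes = db.gene_ids
    tpm = normalize_tpm(result.gene_counts, table.library_size, genes=genes)
    frame = pd.DataFrame(
        {
            "gene_id": genes,
            "count": [result.gene_counts.get(g, 0) for g in genes],
            "tpm": [tpm[g] for g in genes],
        }
    )
    return frame, result.report
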