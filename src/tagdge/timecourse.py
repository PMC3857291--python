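"""Time-course set algebra over per-comparison DE lists.

Combines the three treatment-vs-control DE lists of a time course into
three-set Venn partitions (per direction and overall), common/unique
tallies with printed-style percentages, and novel-gene detection —
genes silent in the control but expressed after treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

REGIONS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


def venn_partition(
    set_a: set, set_b: set, set_c: set
) -> dict[str, frozenset]:
    """Partition A∪B∪C into the 7 disjoint regions of a 3-set Venn diagram.

    Region keys name the sets an element belongs to *exactly*: ``"A"``
    is A-only, ``"AB"`` is (A∩B)−C, ``"ABC"`` is the triple overlap.
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    regions = {
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    out = {k: frozenset(v) for k, v in regions.items()}
    union = a | b | c
    covered = frozenset().union(*out.values())
    assert covered == union and sum(len(v) for v in out.values()) == len(union), (
        "venn regions must partition the union"
    )
    return out


def venn_counts(regions: Mapping[str, frozenset]) -> dict[str, int]:
    return {k: len(regions[k]) for k in REGIONS}


def shared_percentage(shared_count: int, total_count: int) -> float:
    """100 * shared/total, half-up rounded to one decimal place."""
    if total_count < 1:
        raise ValueError("total_count must be >= 1")
    if not 0 <= shared_count <= total_count:
        raise ValueError("shared_count must lie in [0, total_count]")
    pct = Decimal(100 * shared_count) / Decimal(total_count)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def detect_novel(
    control_counts: Mapping[str, int],
    treatment_counts: Mapping[str, int],
    min_count: int = 1,
) -> dict[str, int]:
    """Genes with zero unambiguous control count and >= min_count after treatment.

    Returns the novel genes with their raw treatment expression (tag
    count), for ranking.  This operationalises "novel, expressed gene"
    as induction from silence; it is a definition of this pipeline, not
    a universal one.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out = {}
    for gene, count in treatment_counts.items():
        if count >= min_count and control_counts.get(gene, 0) == 0:
            out[gene] = int(count)
    return out


@dataclass
class TimecoursePartition:
    """Venn partitions of a three-time-point DE analysis.

    ``condition_ids`` fixes the mapping of Venn labels A/B/C to the
    three treatment comparisons (in order).  A gene with inconsistent
    direction across time points appears once per direction in the
    per-direction totals, so up + down totals may exceed the number of
    distinct DE genes.
    """

    condition_ids: tuple[str, str, str]
    up_sets: dict[str, frozenset]
    down_sets: dict[str, frozenset]
    de_sets: dict[str, frozenset]
    up_regions: dict[str, frozenset]
    down_regions: dict[str, frozenset]
    all_regions: dict[str, frozenset]
    novel_sets: dict[str, dict[str, int]]
    novel_regions: dict[str, frozenset]

    @property
    def total_up(self) -> int:
        return len(frozenset().union(*self.up_sets.values()))

    @property
    def total_down(self) -> int:
        return len(frozenset().union(*self.down_sets.values()))

    @property
    def total_de(self) -> int:
        return len(frozenset().union(*self.de_sets.values()))

    def common_up_percentage(self) -> float:
        return shared_percentage(len(self.up_regions["ABC"]), max(self.total_up, 1))

    def common_down_percentage(self) -> float:
        return shared_percentage(len(self.down_regions["ABC"]), max(self.total_down, 1))

    def summary(self) -> dict:
        return {
            "condition_ids": list(self.condition_ids),
            "total_de": self.total_de,
            "total_up": self.total_up,
            "total_down": self.total_down,
            "per_condition": {
                cond: {
                    "up": len(self.up_sets[cond]),
                    "down": len(self.down_sets[cond]),
                    "de": len(self.de_sets[cond]),
                    "novel": len(self.novel_sets[cond]),
                }
                for cond in self.condition_ids
            },
            "venn_up": venn_counts(self.up_regions),
            "venn_down": venn_counts(self.down_regions),
            "venn_all": venn_counts(self.all_regions),
            "venn_novel": venn_counts(self.novel_regions),
            "common_up_percentage": self.common_up_percentage(),
            "common_down_percentage": self.common_down_percentage(),
        }

    def to_json_dict(self) -> dict:
        def _lists(regions: Mapping[str, frozenset]) -> dict:
            return {k: sorted(regions[k]) for k in REGIONS}

        return {
            "condition_ids": list(self.condition_ids),
            "up": _lists(self.up_regions),
            "down": _lists(self.down_regions),
            "all": _lists(self.all_regions),
            "novel": _lists(self.novel_regions),
            "summary": self.summary(),
        }


def build_timecourse(
    de_tables: Mapping[str, pd.DataFrame],
    control_counts: Mapping[str, int],
    treatment_counts: Mapping[str, Mapping[str, int]],
    condition_ids: Sequence[str],
    min_count: int = 1,
    tier: str = "significant",
) -> TimecoursePartition:
    """Assemble the Venn partitions and novel-gene sets of a time course.

    ``de_tables`` maps each treatment condition to its DE table (output
    of :func:`tagdge.diffexpr.compare_libraries`); only rows of the
    requested ``tier`` enter the up/down sets.
    """
    conds = tuple(condition_ids)
    if len(conds) != 3:
        raise ValueError("a three-set time course needs exactly 3 conditions")
    up_sets, down_sets, de_sets, novel_sets = {}, {}, {}, {}
    for cond in conds:
        de = de_tables[cond]
        picked = de[de["tier"] == tier]
        up = frozenset(picked.loc[picked["direction"] == "up", "gene_id"])
        down = frozenset(picked.loc[picked["direction"] == "down", "gene_id"])
        assert not (up & down), "up and down sets of one comparison must be disjoint"
        up_sets[cond], down_sets[cond] = up, down
        de_sets[cond] = up | down
        novel_sets[cond] = detect_novel(
            control_counts, treatment_counts[cond], min_count
        )
    a, b, c = conds
    return TimecoursePartition(
        condition_ids=conds,
        up_sets=up_sets,
        down_sets=down_sets,
        de_sets=de_sets,
        up_regions=venn_partition(up_sets[a], up_sets[b], up_sets[c]),
        down_regions=venn_partition(down_sets[a], down_sets[b], down_sets[c]),
        all_regions=venn_partition(de_sets[a], de_sets[b], de_sets[c]),
        novel_sets=novel_sets,
        novel_regions=venn_partition(
            set(novel_sets[a]), set(novel_sets[b]), set(novel_sets[c])
        ),
    )
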