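"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: the AC
oracle sums the conditional distribution in exact rational arithmetic,
the mapping oracle compares raw character arrays all-against-all, and
the Venn oracle tabulates membership bitmasks.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from tagdge.simulate import generate_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    return generate_transcriptome(n_genes=60, mean_length=400, catg_density=8.0, seed=123)


def ac_pvalue_exact(x: int, n1: int, y: int, n2: int) -> float:
    """Exact-rational two-sided AC p-value: 2*min(cdf, 1-cdf), capped at 1."""
    r = Fraction(n2, n1)
    cdf = sum(
        r**k * comb(x + k, k) / (1 + r) ** (x + k + 1) for k in range(y + 1)
    )
    return float(min(1, 2 * min(cdf, 1 - cdf)))


def hamming_map_oracle(tag_counts, ref_entries, max_mismatch=1):
    """All-pairs Hamming mapping with exact-over-1-mismatch precedence.

    ``ref_entries``: list of (tag_sequence, gene_id, strand).  Returns
    (gene_counts, antisense_counts, category per observed tag).
    """

    def hamming(a, b):
        return sum(ca != cb for ca, cb in zip(a, b))

    gene_counts, anti_counts, categories = {}, {}, {}
    for tag, count in tag_counts.items():
        best = None
        for dist_budget in range(max_mismatch + 1):
            hits = [e for e in ref_entries if hamming(tag, e[0]) == dist_budget]
            if hits:
                best = hits
                break
        if best is None:
            categories[tag] = "unmapped"
            continue
        genes = {g for _, g, _ in best}
        if len(genes) >= 2:
            categories[tag] = "ambiguous"
        else:
            (gene,) = genes
            if any(s == "sense" for _, _, s in best):
                categories[tag] = "sense"
                gene_counts[gene] = gene_counts.get(gene, 0) + count
            else:
                categories[tag] = "antisense"
                anti_counts[gene] = anti_counts.get(gene, 0) + count
    return gene_counts, anti_counts, categories


def venn_bitmask_oracle(a, b, c):
    """Region sizes via per-element membership bitmask tabulation."""
    names = {1: "A", 2: "B", 4: "C", 3: "AB", 5: "AC", 6: "BC", 7: "ABC"}
    sizes = {v: 0 for v in names.values()}
    for g in set(a) | set(b) | set(c):
        mask = (g in a) | ((g in b) << 1) | ((g in c) << 2)
        sizes[names[mask]] += 1
    return sizes


def random_tagset(rng: np.random.Generator, n: int) -> list:
    """n random CATG-anchored 21-mers."""
    bases = np.array(list("ACGT"))
    return [
        "CATG" + "".join(bases[rng.integers(0, 4, 17)]) for _ in range(n)
    ]
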