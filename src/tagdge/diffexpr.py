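"""Audic-Claverie differential testing between two tag libraries.

For a gene observed ``x`` times among ``N1`` clean tags in one library
and ``y`` times among ``N2`` in another, Audic & Claverie's model gives
the conditional probability of the second count given the first::

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

which is a negative-binomial distribution in ``y`` (size ``x+1``,
success probability ``N2/(N1+N2)``).  The two-sided p-value reported
here doubles the smaller of the two complementary tails ``P(Y <= y)``
and ``P(Y > y)``, capped at 1.  Splitting the point mass this way makes
the statistic exactly symmetric under exchanging the two libraries,
because the AC conditional tails obey
``P(Y <= y | x; N1, N2) = P(X > x | y; N2, N1)``.  Tails are
accumulated in log space with log-gamma factorials — library sizes in
the millions make naive factorials meaningless — and the shorter tail
is always the one summed directly, so the doubled (smaller) tail never
suffers cancellation.

Multiple testing is controlled per comparison with the
Benjamini-Hochberg step-up adjustment, and genes are classified into
two tiers: *significant* (FDR <= 0.001 and |log2 ratio| >= 1, i.e. at
least 2-fold) and the weaker *difference* tier (fold ratio strictly
between 1 and 2 with p <= 0.01 and FDR <= 0.001).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ac_pvalue",
    "ac_pvalues",
    "adjust_fdr",
    "classify_de",
    "compare_libraries",
    "volcano_table",
]

_TIER_SIGNIFICANT = "significant"
_TIER_DIFFERENCE = "difference"
_TIER_NOT_DE = "not_de"


def _log_pmf(x: int, ys: np.ndarray, log_r: float, log_1pr: float) -> np.ndarray:
    """log p(y | x) for an array of y values."""
    return (
        ys * log_r
        + gammaln(x + ys + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ys + 1.0)
        - (x + ys + 1.0) * log_1pr
    )


def ac_pvalue(x: int, n1: int, y: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (of N1) vs y (of N2).

    The returned value is ``min(1, 2 * min(P(Y <= y), P(Y > y)))``,
    which is exactly symmetric under swapping ``(x, N1)`` with
    ``(y, N2)``.  The shorter tail is summed directly in log space (the
    inclusive lower tail when y is at or below the conditional mean
    ``(x+1) * N2/N1``, the exclusive upper tail otherwise, chunked
    until the remaining mass is negligible); the other tail is its
    complement.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    if x != int(x) or y != int(y):
        raise ValueError("counts must be integers")
    x, y = int(x), int(y)
    log_r = np.log(n2) - np.log(n1)
    log_1pr = np.logaddexp(0.0, log_r)
    mean = (x + 1) * n2 / n1
    if y <= mean:
        terms = _log_pmf(x, np.arange(y + 1, dtype=float), log_r, log_1pr)
        lower = float(np.exp(logsumexp(terms)))
        upper = 1.0 - lower
    else:
        total = -np.inf
        start, chunk = y + 1, 1024
        while True:
            ys = np.arange(start, start + chunk, dtype=float)
            terms = _log_pmf(x, ys, log_r, log_1pr)
            total = np.logaddexp(total, logsumexp(terms))
            # past the mode the terms decay at least geometrically, so once
            # the last term is ~1e-22 of the running sum the rest is dust
            if terms[-1] < total - 50.0:
                break
            start += chunk
        upper = float(np.exp(total))
        lower = 1.0 - upper
    return min(1.0, 2.0 * min(lower, upper))


def ac_pvalues(
    xs: Sequence[int], n1: int, ys: Sequence[int], n2: int
) -> np.ndarray:
    """Vector of two-sided AC p-values for paired count arrays."""
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    if xs.shape != ys.shape:
        raise ValueError("count vectors must have equal length")
    return np.array([ac_pvalue(int(x), n1, int(y), n2) for x, y in zip(xs, ys)])


def adjust_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    results: pd.DataFrame,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    p_max: float = 0.01,
    floor_tpm: float = 0.001,
) -> pd.DataFrame:
    """Attach log2 ratio, tier and direction to a DE table.

    Expects columns ``tpm1``, ``tpm2``, ``p_value``, ``fdr``.  Zero TPMs
    are floored at ``floor_tpm`` before the ratio (the counts keep their
    true zeros for the test itself), so genes absent from one library
    still get a finite fold change.  Tiers:

    * ``significant`` — fdr <= ``fdr_max`` and |log2 ratio| >= ``min_abs_log2``
    * ``difference``  — fold ratio strictly between 1 and 2, with
      p <= ``p_max`` and fdr <= ``fdr_max`` (and not already significant)
    * ``not_de``      — everything else
    """
    if floor_tpm <= 0:
        raise ValueError("floor_tpm must be positive")
    out = results.copy()
    t1 = np.maximum(out["tpm1"].to_numpy(dtype=float), floor_tpm)
    t2 = np.maximum(out["tpm2"].to_numpy(dtype=float), floor_tpm)
    log2_ratio = np.log2(t2 / t1)
    out["log2_ratio"] = log2_ratio
    fold = 2.0 ** np.abs(log2_ratio)
    significant = (out["fdr"] <= fdr_max) & (np.abs(log2_ratio) >= min_abs_log2)
    difference = (
        ~significant
        & (fold > 1.0)
        & (fold < 2.0)
        & (out["p_value"] <= p_max)
        & (out["fdr"] <= fdr_max)
    )
    tier = np.where(
        significant, _TIER_SIGNIFICANT, np.where(difference, _TIER_DIFFERENCE, _TIER_NOT_DE)
    )
    out["tier"] = tier
    direction = np.where(
        tier == _TIER_NOT_DE, "none", np.where(log2_ratio > 0, "up", "down")
    )
    out["direction"] = direction
    return out


def compare_libraries(
    control_counts: Mapping[str, int],
    treatment_counts: Mapping[str, int],
    n1: int,
    n2: int,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    p_max: float = 0.01,
    floor_tpm: float = 0.001,
) -> pd.DataFrame:
    """Per-gene AC test of a treatment library against the control.

    The gene universe is the union of both count tables; absent genes
    count 0.  Returns one row per gene with counts, TPMs, log2 ratio,
    p-value, BH-adjusted FDR, tier and direction, sorted by fdr then
    |log2 ratio| descending.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("library sizes must be >= 1")
    genes = sorted(set(control_counts) | set(treatment_counts))
    if not genes:
        raise ValueError("no genes to compare")
    x = np.array([control_counts.get(g, 0) for g in genes], dtype=np.int64)
    y = np.array([treatment_counts.get(g, 0) for g in genes], dtype=np.int64)
    p = ac_pvalues(x, n1, y, n2)
    frame = pd.DataFrame(
        {
            "gene_id": genes,
            "x": x,
            "y": y,
            "tpm1": x / n1 * 1e6,
            "tpm2": y / n2 * 1e6,
            "p_value": p,
            "fdr": adjust_fdr(p),
        }
    )
    frame = classify_de(frame, fdr_max, min_abs_log2, p_max, floor_tpm)
    frame = frame.sort_values(
        ["fdr", "log2_ratio"],
        key=lambda s: np.abs(s) if s.name == "log2_ratio" else s,
        ascending=[True, False],
        kind="mergesort",
    ).reset_index(drop=True)
    return frame[
        [
            "gene_id",
            "x",
            "y",
            "tpm1",
            "tpm2",
            "log2_ratio",
            "p_value",
            "fdr",
            "tier",
            "direction",
        ]
    ]


def volcano_table(de: pd.DataFrame, floor_tpm: float = 0.001) -> pd.DataFrame:
    """log10-TPM axes of the classification scatter, one row per gene."""
    out = de[["gene_id", "tier", "direction"]].copy()
    out["log10_tpm_control"] = np.log10(np.maximum(de["tpm1"], floor_tpm))
    out["log10_tpm_treatment"] = np.log10(np.maximum(de["tpm2"], floor_tpm))
    return out
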