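"""Forward simulation of a transcriptome and DGE tag libraries.

The generator emulates the library-construction chemistry of an
NlaIII/MmeI tag assay: each sampled transcript contributes the 21-nt
tag (CATG + 17 nt) at its 3'-most usable CATG site — the fragment an
oligo(dT)-primed, bead-purified protocol retains — and per-base
substitution errors are applied to the emitted tags.  Per-gene sampling
weights carry a known differential-expression ground truth so that
recovery of fold changes and DE calls can be measured downstream.

Transcripts are i.i.d. uniform nucleotide sequences with
geometric-distributed lengths (heavy-tailed, like real unigene length
distributions) in which spontaneous CATG occurrences are scrubbed and
motifs re-injected at a controllable density.  All randomness flows
from the single seed of each call; no global state is touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._codec import TAG_LEN, decode_tag, encode_tag, starts_with_anchor
from .mapping import TagCountTable
from .reference import sense_tag_sites

logger = logging.getLogger(__name__)

_CATG_CODES = np.array([1, 0, 3, 2], dtype=np.uint8)  # A=0 C=1 G=2 T=3
_BASES = "ACGT"

DEFAULT_CONDITIONS = ("control", "12h", "24h", "48h")


@dataclass(frozen=True)
class SyntheticTranscript:
    """One simulated unigene (A/C/G/T alphabet, >= 60 nt)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 60:
            raise ValueError("transcript length must be >= 60 nt")
        if set(self.sequence) - set(_BASES):
            raise ValueError("sequence alphabet must be {A,C,G,T}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LibrarySpec:
    """Sequencing parameters of one simulated library."""

    condition_id: str
    depth: int
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")


class SimulationTruth:
    """Per-gene sampling weights and DE ground truth across conditions.

    ``weights`` holds the relative sampling weight of each gene in each
    condition (control weight = baseline abundance; treatment weight =
    baseline x fold change for ordinary genes).  ``direction`` labels
    each gene per treatment as up / down / null / novel.  Novel genes
    have zero weight in the control and a positive weight in at least
    one treatment, so a plain fold change is undefined for them.
    """

    def __init__(self, weights: pd.DataFrame, direction: pd.DataFrame, control: str):
        if control not in weights.columns:
            raise ValueError(f"control condition {control!r} missing from weights")
        if (weights.to_numpy() < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isfinite(weights.to_numpy()).all():
            raise ValueError("weights must be finite")
        self.weights = weights
        self.direction = direction
        self.control = control
        self.conditions = list(weights.columns)
        novel = (direction == "novel").any(axis=1)
        base = weights[control]
        if (base[novel] != 0).any():
            raise ValueError("novel genes must have zero control abundance")
        if ((weights.loc[novel].drop(columns=control) > 0).sum(axis=1) < 1).any():
            raise ValueError("novel genes must be expressed in >= 1 treatment")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def baseline(self) -> pd.Series:
        return self.weights[self.control]

    def fold_change(self, condition: str) -> pd.Series:
        """Treatment/control weight ratio; inf for novel genes, nan for 0/0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.weights[condition] / self.weights[self.control]

    def genes_with_direction(self, condition: str, label: str) -> set[str]:
        col = self.direction[condition]
        return set(col.index[col == label])

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gene_id": self.gene_ids})
        out["baseline"] = self.baseline.to_numpy()
        for cond in self.conditions:
            if cond == self.control:
                continue
            out[f"weight_{cond}"] = self.weights[cond].to_numpy()
            out[f"direction_{cond}"] = self.direction[cond].to_numpy()
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, control: str = "control") -> "SimulationTruth":
        frame = frame.set_index("gene_id")
        conds = [c[len("weight_"):] for c in frame.columns if c.startswith("weight_")]
        weights = pd.DataFrame({control: frame["baseline"]})
        direction = pd.DataFrame(index=frame.index)
        for cond in conds:
            weights[cond] = frame[f"weight_{cond}"]
            direction[cond] = frame[f"direction_{cond}"]
        return cls(weights, direction, control)


@dataclass
class LibraryStats:
    """Bookkeeping emitted alongside each simulated library."""

    condition_id: str
    n_raw: int
    n_clean: int
    n_dirty: int
    true_counts: dict[str, int] = field(default_factory=dict)
    unobservable_genes: list[str] = field(default_factory=list)


def _find_catg(codes: np.ndarray) -> np.ndarray:
    if codes.size < 4:
        return np.empty(0, dtype=np.intp)
    return np.flatnonzero(
        (codes[:-3] == _CATG_CODES[0])
        & (codes[1:-2] == _CATG_CODES[1])
        & (codes[2:-1] == _CATG_CODES[2])
        & (codes[3:] == _CATG_CODES[3])
    )


def _scrub_catg(codes: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every CATG occurrence by rerolling its final base."""
    while True:
        hits = _find_catg(codes)
        if hits.size == 0:
            return
        codes[hits + 3] = rng.integers(0, 4, hits.size, dtype=np.uint8)


def generate_transcriptome(
    n_genes: int,
    mean_length: int = 789,
    catg_density: float = 10.0,
    seed: int = 0,
) -> list[SyntheticTranscript]:
    """Simulate unigenes with a controllable CATG-site density.

    Lengths follow ``59 + Geometric(1/(mean_length-59))`` (mean
    ``mean_length``, minimum 60 nt).  Spontaneous CATG occurrences are
    removed before injecting ``Poisson(catg_density * length/1000)``
    motifs at random positions, so ``catg_density`` (expected sites per
    kb) is an approximate target: injections may overlap each other
    near saturation.  Deterministic given the seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if mean_length < 60:
        raise ValueError("mean_length must be >= 60")
    if catg_density < 0:
        raise ValueError("catg_density must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = 59 + rng.geometric(1.0 / (mean_length - 59), size=n_genes)
    width = len(str(n_genes))
    transcripts = []
    for i, length in enumerate(lengths):
        codes = rng.integers(0, 4, int(length), dtype=np.uint8)
        _scrub_catg(codes, rng)
        if catg_density > 0 and length >= 4:
            n_sites = min(int(rng.poisson(catg_density * length / 1000.0)), length - 3)
            if n_sites:
                starts = rng.choice(int(length) - 3, size=n_sites, replace=False)
                for s in np.sort(starts):
                    codes[s : s + 4] = _CATG_CODES
        seq = "".join(_BASES[c] for c in codes)
        transcripts.append(SyntheticTranscript(f"g{i + 1:0{width}d}", seq))
    return transcripts


def make_truth(
    gene_ids: Sequence[str],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    control: str = "control",
    frac_up: float = 0.06,
    frac_down: float = 0.03,
    frac_novel: float = 0.01,
    fold_change: float = 4.0,
    induce_prob: float = 0.6,
    baseline_sigma: float = 1.2,
    seed: int = 0,
) -> SimulationTruth:
    """Assign baseline abundances and per-condition fold changes.

    Baselines are log-normal (sigma ``baseline_sigma``), mimicking the
    heavy-tailed abundance spectrum of real libraries.  Disjoint random
    gene subsets are designated up-regulated (weight x ``fold_change``),
    down-regulated (weight / ``fold_change``) or novel (zero in control,
    switched on in treatments).  Each affected gene is perturbed in a
    random non-empty subset of the treatments (each included with
    probability ``induce_prob``), which produces the overlapping
    per-time-point DE sets a real time course shows.
    """
    if control not in conditions:
        raise ValueError("control must be one of conditions")
    if frac_up + frac_down + frac_novel > 1:
        raise ValueError("DE fractions must sum to <= 1")
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    rng = np.random.default_rng(seed)
    genes = list(gene_ids)
    n = len(genes)
    treatments = [c for c in conditions if c != control]
    base = rng.lognormal(mean=0.0, sigma=baseline_sigma, size=n)
    perm = rng.permutation(n)
    n_up = int(round(frac_up * n))
    n_down = int(round(frac_down * n))
    n_novel = int(round(frac_novel * n))
    up_idx = set(perm[:n_up].tolist())
    down_idx = set(perm[n_up : n_up + n_down].tolist())
    novel_idx = set(perm[n_up + n_down : n_up + n_down + n_novel].tolist())

    weights = pd.DataFrame(index=pd.Index(genes, name="gene_id"), dtype=float)
    weights[control] = base
    direction = pd.DataFrame(
        "null", index=weights.index, columns=treatments, dtype=object
    )
    for cond in treatments:
        weights[cond] = base.copy()

    def _induced_subset() -> list[str]:
        chosen = [t for t in treatments if rng.random() < induce_prob]
        if not chosen:
            chosen = [treatments[rng.integers(len(treatments))]]
        return chosen

    for i in sorted(up_idx):
        for cond in _induced_subset():
            weights.loc[genes[i], cond] = base[i] * fold_change
            direction.loc[genes[i], cond] = "up"
    for i in sorted(down_idx):
        for cond in _induced_subset():
            weights.loc[genes[i], cond] = base[i] / fold_change
            direction.loc[genes[i], cond] = "down"
    for i in sorted(novel_idx):
        weights.loc[genes[i], :] = 0.0
        for cond in _induced_subset():
            weights.loc[genes[i], cond] = base[i]
            direction.loc[genes[i], cond] = "novel"
    weights = weights[list(conditions)]
    return SimulationTruth(weights, direction, control)


def usable_tag_sites(sequence: str) -> list[int]:
    """CATG starts with a full 17-nt extension, ordered 3'-most first."""
    return sorted(sense_tag_sites(sequence), reverse=True)


def simulate_tag_library(
    transcripts: Iterable[SyntheticTranscript],
    truth: SimulationTruth,
    spec: LibrarySpec,
    partial_digest_prob: float = 0.0,
    keep_dirty: bool = False,
) -> tuple[TagCountTable, LibraryStats]:
    """Draw ``spec.depth`` tags from a transcriptome under known truth.

    Each tag is the 21-mer at the 3'-most usable CATG site of its source
    transcript (a site closer than 17 nt to the 3' end is skipped and
    the next-3'-most used; with ``partial_digest_prob`` > 0 a tag falls
    through to the next site with that probability, emulating partial
    NlaIII digestion).  Genes without a usable site are unobservable and
    logged.  Substitution errors hit each of the 21 positions
    independently at ``spec.error_rate``, uniformly over the three
    alternative bases.

    Tags whose anchor was destroyed by an error would be discarded as
    dirty by the upstream clean-tag filter, so the returned table keeps
    only anchor-bearing tags and sets ``library_size`` to their total;
    ``keep_dirty=True`` returns the raw table instead (all ``depth``
    emitted tags).  Error-free raw and clean tables are identical.
    """
    if not 0.0 <= partial_digest_prob < 1.0:
        raise ValueError("partial_digest_prob must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    transcripts = list(transcripts)
    cond = spec.condition_id
    if cond not in truth.conditions:
        raise ValueError(f"condition {cond!r} not present in truth")
    w = truth.weights[cond]

    observable: list[tuple[str, list[int]]] = []  # (gene_id, site tag codes)
    weights: list[float] = []
    unobservable: list[str] = []
    for t in transcripts:
        weight = float(w.get(t.gene_id, 0.0))
        if weight <= 0:
            continue
        sites = usable_tag_sites(t.sequence)
        if not sites:
            unobservable.append(t.gene_id)
            continue
        codes = [encode_tag(t.sequence[i : i + TAG_LEN]) for i in sites]
        observable.append((t.gene_id, codes))
        weights.append(weight)
    if unobservable:
        logger.info(
            "%s: %d expressed genes have no usable CATG site and are unobservable",
            cond,
            len(unobservable),
        )
    if not observable:
        raise ValueError(f"no observable expressed genes in condition {cond!r}")

    warr = np.asarray(weights)
    gene_counts = rng.multinomial(spec.depth, warr / warr.sum())

    emitted = np.empty(spec.depth, dtype=np.int64)
    true_counts: dict[str, int] = {}
    pos = 0
    for (gene_id, codes), count in zip(observable, gene_counts):
        if count == 0:
            continue
        true_counts[gene_id] = int(count)
        if partial_digest_prob == 0.0 or len(codes) == 1:
            emitted[pos : pos + count] = codes[0]
        else:
            p = partial_digest_prob
            probs = np.array(
                [(1 - p) * p**k for k in range(len(codes) - 1)] + [p ** (len(codes) - 1)]
            )
            site_counts = rng.multinomial(count, probs)
            offset = pos
            for code, sc in zip(codes, site_counts):
                emitted[offset : offset + sc] = code
                offset += sc
        pos += count

    if spec.error_rate > 0:
        for position in range(TAG_LEN):
            hit = np.flatnonzero(rng.random(spec.depth) < spec.error_rate)
            if hit.size:
                flips = rng.integers(1, 4, hit.size, dtype=np.int64)
                emitted[hit] ^= flips << np.int64(2 * (TAG_LEN - 1 - position))

    uniq, counts = np.unique(emitted, return_counts=True)
    clean_mask = starts_with_anchor(uniq)
    n_dirty = int(counts[~clean_mask].sum())
    if not keep_dirty:
        uniq, counts = uniq[clean_mask], counts[clean_mask]
    entries = {decode_tag(int(u)): int(c) for u, c in zip(uniq, counts)}
    library_size = int(counts.sum())
    stats = LibraryStats(
        condition_id=cond,
        n_raw=spec.depth,
        n_clean=spec.depth - n_dirty,
        n_dirty=n_dirty,
        true_counts=true_counts,
        unobservable_genes=unobservable,
    )
    return TagCountTable(cond, entries, library_size), stats


# ---------------------------------------------------------------------------
# Synthetic GO annotation (for exercising the enrichment stage end to end)
# ---------------------------------------------------------------------------

_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


def make_annotation(
    gene_ids: Sequence[str],
    n_slim_per_namespace: int = 4,
    n_leaves_per_slim: int = 5,
    max_terms_per_gene: int = 3,
    seed: int = 0,
) -> tuple[str, list[str], dict[str, set[str]]]:
    """Build a small synthetic ontology, slim list and gene annotation.

    The ontology has one root per namespace, ``n_slim_per_namespace``
    slim-level children and leaf terms under each slim term.  Genes are
    annotated to 1..``max_terms_per_gene`` random leaves.  Returns
    (OBO text, slim term ids, gene -> leaf-term-set).  This is a
    synthetic stand-in for a curated GO subset, sufficient to exercise
    slim mapping and enrichment with known structure.
    """
    rng = np.random.default_rng(seed)
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    slim_ids: list[str] = []
    leaves: list[str] = []
    counter = 1

    def _term(name: str, namespace: str, parent: str | None) -> str:
        nonlocal counter
        tid = f"GO:{counter:07d}"
        counter += 1
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {namespace}")
        if parent:
            lines.append(f"is_a: {parent}")
        lines.append("")
        return tid

    for ns in _NAMESPACES:
        root = _term(f"{ns} root", ns, None)
        for s in range(n_slim_per_namespace):
            slim = _term(f"{ns} slim {s + 1}", ns, root)
            slim_ids.append(slim)
            for leaf in range(n_leaves_per_slim):
                leaves.append(_term(f"{ns} leaf {s + 1}.{leaf + 1}", ns, slim))

    gene2go: dict[str, set[str]] = {}
    for g in gene_ids:
        k = int(rng.integers(1, max_terms_per_gene + 1))
        chosen = rng.choice(len(leaves), size=min(k, len(leaves)), replace=False)
        gene2go[g] = {leaves[int(i)] for i in chosen}
    return "\n".join(lines), slim_ids, gene2go
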