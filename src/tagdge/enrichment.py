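"""GO-slim mapping and hypergeometric over-representation.

Annotations are lifted onto a reduced (slim) vocabulary with map2slim
semantics: each annotated term contributes its *nearest* slim
ancestors-or-self — a slim term on an ancestor path counts only if no
other slim term lies strictly between it and the annotated term, and
ties across distinct paths are all kept.  Category over-representation
of a study set against a population is then scored with the one-sided
hypergeometric upper tail P(X >= k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class OntologyGraph:
    """A minimal is_a ontology: term metadata plus child -> parent edges."""

    terms: dict[str, dict]  # term_id -> {"name": ..., "namespace": ...}
    parents: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, ps in self.parents.items():
            if child not in self.terms:
                raise ValueError(f"edge from unknown term {child!r}")
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"edge to unknown term {p!r}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            g.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a edges must form a directed acyclic graph")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def name(self, term_id: str) -> str:
        return self.terms[term_id].get("name", term_id)

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].get("namespace", "")

    def parents_of(self, term_id: str) -> frozenset[str]:
        return self.parents.get(term_id, frozenset())

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable via is_a edges, excluding the term itself."""
        seen: set[str] = set()
        stack = list(self.parents_of(term_id))
        while stack:
            t = stack.pop()
            if t not in seen:
                seen.add(t)
                stack.extend(self.parents_of(t))
        return frozenset(seen)

    @classmethod
    def from_obo(cls, path) -> "OntologyGraph":
        """Read a (possibly minimal) OBO file, keeping id/name/namespace/is_a."""
        graph = obonet.read_obo(path)
        terms = {
            node: {
                "name": data.get("name", node),
                "namespace": data.get("namespace", ""),
            }
            for node, data in graph.nodes(data=True)
        }
        parents: dict[str, set[str]] = {}
        for child, parent, key in graph.edges(keys=True):
            if key == "is_a":
                parents.setdefault(child, set()).add(parent)
        return cls(terms, {c: frozenset(p) for c, p in parents.items()})


def read_slim_terms(path) -> list[str]:
    """One term id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.split()[0])
    return out


def read_gene2go(path) -> dict[str, set[str]]:
    """TSV of gene_id <tab> term_id (one pair per line, '#' comments ignored)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def nearest_slim_ancestors(
    term_id: str,
    graph: OntologyGraph,
    slim_terms: frozenset[str],
    _memo: dict | None = None,
) -> frozenset[str]:
    """Nearest slim ancestors-or-self of one term (map2slim semantics).

    A slim term itself maps to itself and shields everything above it;
    otherwise each parent path is followed until the first slim term,
    and the union over paths is returned (possibly empty).
    """
    memo = _memo if _memo is not None else {}
    if term_id in memo:
        return memo[term_id]
    memo[term_id] = frozenset()  # guards against pathological cycles
    if term_id in slim_terms:
        result = frozenset([term_id])
    else:
        result = frozenset().union(
            *(
                nearest_slim_ancestors(p, graph, slim_terms, memo)
                for p in graph.parents_of(term_id)
            )
        )
    memo[term_id] = result
    return result


def map_to_slim(
    gene2go: Mapping[str, Iterable[str]],
    graph: OntologyGraph,
    slim_terms: Iterable[str],
) -> dict[str, frozenset[str]]:
    """Lift each gene's annotations onto their nearest slim terms.

    Unknown annotated terms are skipped with a warning; genes whose
    terms have no slim ancestor map to nothing and are dropped (logged).
    """
    slim = frozenset(slim_terms)
    unknown_slim = slim - set(graph.terms)
    if unknown_slim:
        raise ValueError(f"slim terms not in ontology: {sorted(unknown_slim)}")
    memo: dict[str, frozenset[str]] = {}
    out: dict[str, frozenset[str]] = {}
    n_unknown = 0
    n_unmappable = 0
    for gene, terms in gene2go.items():
        mapped: set[str] = set()
        for t in terms:
            if t not in graph:
                n_unknown += 1
                logger.warning("unknown term %s annotated to gene %s; skipped", t, gene)
                continue
            mapped |= nearest_slim_ancestors(t, graph, slim, memo)
        if mapped:
            out[gene] = frozenset(mapped)
        else:
            n_unmappable += 1
    if n_unmappable:
        logger.info("%d genes had no slim-mappable annotation", n_unmappable)
    return out


def hypergeom_enrich(
    study: Iterable[str],
    population: Iterable[str],
    gene2slim: Mapping[str, frozenset[str]],
    graph: OntologyGraph | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of slim terms in a study set.

    With M = |population|, K = population genes carrying the term,
    n = |study| and k = study genes carrying it, the p-value is the
    upper tail P(X >= k) of Hypergeometric(M, K, n).  Returns one row
    per slim term observed in the population, sorted by p-value; the
    percentage column is 100*k/n, the bar length of the usual GO
    classification chart.
    """
    study = set(study)
    population = set(population)
    if not population:
        raise ValueError("population must be non-empty")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in gene2slim.get(gene, ()):  # genes without mapping contribute M only
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    m_total = len(population)
    n_study = len(study)
    rows = []
    for term in sorted(term_pop):
        big_k = term_pop[term]
        k = term_study.get(term, 0)
        p = float(hypergeom.sf(k - 1, m_total, big_k, n_study))
        rows.append(
            {
                "term_id": term,
                "term_name": graph.name(term) if graph else term,
                "namespace": graph.namespace(term) if graph else "",
                "study_hits": k,
                "study_size": n_study,
                "population_hits": big_k,
                "population_size": m_total,
                "percentage": 100.0 * k / n_study if n_study else 0.0,
                "p_value": p,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "namespace",
            "study_hits",
            "study_size",
            "population_hits",
            "population_size",
            "percentage",
            "p_value",
        ],
    )
    return frame.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
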