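"""Classic per-term Fisher GO enrichment with ancestor propagation.

Mirrors the "classic" algorithm of TopGO: every gene annotation is
propagated to all is_a ancestors, then each term is tested independently
with a one-sided (over-representation) Fisher exact test on the 2x2 table
of in-term vs not x in-test-set vs not, against a user-supplied gene
universe.  Raw p-values below alpha (default 0.01) are reported without
multiple-testing correction, with annotated/significant/expected counts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from scipy.stats import hypergeom


@dataclasses.dataclass
class GoTermResult:
    term_id: str
    namespace: str
    name: str
    annotated: int     # universe genes annotated to the term, after propagation
    significant: int   # test-set genes annotated
    expected: float    # annotated * |test| / |universe|
    p: float

    def __post_init__(self) -> None:
        if self.significant > self.annotated:
            raise ValueError("significant cannot exceed annotated")


def load_ontology(path: str | Path, include_part_of: bool = False) -> nx.DiGraph:
    """Load an OBO ontology as a child-to-parent DAG.

    Keeps is_a edges (plus part_of when requested), drops obsolete terms,
    and rejects cyclic inputs.
    """
    raw = obonet.read_obo(str(path))
    keep = {"is_a"} | ({"part_of"} if include_part_of else set())
    dag = nx.DiGraph()
    for node, data in raw.nodes(data=True):
        if data.get("is_obsolete") in ("true", True):
            continue
        dag.add_node(node, **data)
    for child, parent, key in raw.edges(keys=True):
        if key in keep and child in dag and parent in dag:
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError(f"{path}: ontology graph contains a cycle")
    return dag


def propagate_annotations(
    gene_to_terms: Mapping[str, Iterable[str]],
    dag: nx.DiGraph,
) -> dict[str, frozenset[str]]:
    """Close each gene's term set over is_a ancestors (idempotent)."""
    ancestor_cache: dict[str, frozenset[str]] = {}

    def ancestors(term: str) -> frozenset[str]:
        if term not in ancestor_cache:
            if term in dag:
                ancestor_cache[term] = frozenset(nx.descendants(dag, term)) | {term}
            else:
                ancestor_cache[term] = frozenset({term})
        return ancestor_cache[term]

    closure = {}
    for gene, terms in gene_to_terms.items():
        acc: set[str] = set()
        for term in terms:
            acc |= ancestors(term)
        closure[gene] = frozenset(acc)
    return closure


def fisher_enrichment(
    test_set: Iterable[str],
    universe: Iterable[str],
    closure: Mapping[str, frozenset[str]],
    dag: nx.DiGraph | None = None,
    alpha: float = 0.01,
) -> list[GoTermResult]:
    """One-sided over-representation Fisher test per term.

    For a term annotating K of the N universe genes, with k of the n
    test-set genes, p is the upper hypergeometric tail P(X >= k).  Results
    with p < alpha are returned sorted by p (ties by term id).
    """
    test = sorted(set(test_set))
    univ = sorted(set(universe))
    extra = set(test) - set(univ)
    if extra:
        raise ValueError(f"test genes not in universe: {sorted(extra)[:5]}")
    n_univ, n_test = len(univ), len(test)
    term_genes: dict[str, set[str]] = {}
    for gene in univ:
        for term in closure.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    test_as_set = set(test)
    results = []
    for term in sorted(term_genes):
        annotated = len(term_genes[term])
        significant = len(term_genes[term] & test_as_set)
        p = float(hypergeom.sf(significant - 1, n_univ, annotated, n_test))
        if p < alpha:
            data = dag.nodes.get(term, {}) if dag is not None else {}
            results.append(
                GoTermResult(
                    term_id=term,
                    namespace=_namespace_code(data.get("namespace", "")),
                    name=data.get("name", ""),
                    annotated=annotated,
                    significant=significant,
                    expected=annotated * n_test / n_univ if n_univ else 0.0,
                    p=p,
                )
            )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def _namespace_code(namespace: str) -> str:
    return {
        "biological_process": "BP",
        "cellular_component": "CC",
        "molecular_function": "MF",
    }.get(namespace, namespace or "NA")


def enrichment_table(results: Iterable[GoTermResult]) -> pd.DataFrame:
    """Table with the classic columns: Category/GO.ID/Term/Annotated/
    Significant/Expected/classicFisher."""
    rows = [
        {
            "Category": r.namespace,
            "GO.ID": r.term_id,
            "Term": r.name,
            "Annotated": r.annotated,
            "Significant": r.significant,
            "Expected": round(r.expected, 2),
            "classicFisher": r.p,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["Category", "GO.ID", "Term", "Annotated", "Significant",
                 "Expected", "classicFisher"],
    )


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping
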