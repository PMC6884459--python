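"""Gene-set overrepresentation analysis.

For each annotation term carried by at least one study gene, a one-sided
Fisher's exact test (hypergeometric upper tail) asks whether the term is
more frequent in the study set than expected from the background universe;
q-values come from the same Benjamini-Hochberg adjustment used by the
differential-expression stage. A descendant filter then reduces the
significant terms to the most specific ones — terms with no significant
descendant in a supplied parent->child hierarchy — approximating the
bottom-of-the-hierarchy term lists commonly reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy import stats as sps

from .stats import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    """Overrepresentation outcome for one term.

    k_study of the n_study study genes carry the term, K_background of the
    N_background universe genes do; fold_enrichment is the ratio of those
    frequencies.
    """

    term_id: str
    term_name: str
    k_study: int
    n_study: int
    K_background: int
    N_background: int
    fold_enrichment: float
    p_value: float
    q_value: float


def fisher_overrepresentation(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every term of the study set for overrepresentation.

    ``annotation`` maps gene -> term ids; only terms carried by at least
    one study gene are tested. The p-value is the hypergeometric upper
    tail P(X >= k) for k study genes with the term, and q-values are BH
    adjusted across the tested terms. Results are sorted by (q, p, term).
    """
    study = set(study_genes)
    background = set(background_genes)
    if not background:
        raise ValueError("background gene set is empty")
    stray = study - background
    if stray:
        raise ValueError(
            f"study genes absent from the background: {sorted(stray)[:5]}"
        )
    if not study:
        return []
    term_names = term_names or {}

    term_study: dict[str, int] = {}
    term_background: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    N, n = len(background), len(study)
    terms = sorted(term_study)
    p_values = []
    for term in terms:
        k, K = term_study[term], term_background[term]
        # upper tail P(X >= k) of Hypergeometric(N, K, n)
        p_values.append(float(sps.hypergeom.sf(k - 1, N, K, n)))
    q_values = bh_adjust(p_values)

    results = []
    for term, p, q in zip(terms, p_values, q_values):
        k, K = term_study[term], term_background[term]
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=term_names.get(term, ""),
                k_study=k,
                n_study=n,
                K_background=K,
                N_background=N,
                fold_enrichment=(k / n) / (K / N),
                p_value=min(p, 1.0),
                q_value=float(q),
            )
        )
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def most_specific_terms(
    results: Sequence[EnrichmentResult],
    term_edges: Iterable[tuple[str, str]] | None,
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], bool]:
    """Keep significant terms with no significant descendant.

    ``term_edges`` are (parent, child) pairs; the descendant relation is
    the transitive closure. With no edge table supplied, all significant
    terms are returned unchanged and the second element of the return
    value is True (a "no hierarchy" warning flag); otherwise it is False.
    Cycles in the edges raise ``ValueError``.
    """
    significant = [r for r in results if r.q_value < alpha]
    if term_edges is None:
        return significant, True

    graph = nx.DiGraph()
    graph.add_nodes_from(r.term_id for r in results)
    graph.add_edges_from(term_edges)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError("term hierarchy contains a cycle")

    significant_ids = {r.term_id for r in significant}
    kept = []
    for r in significant:
        descendants = nx.descendants(graph, r.term_id) if r.term_id in graph else set()
        if not descendants & (significant_ids - {r.term_id}):
            kept.append(r)
    return kept, False
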