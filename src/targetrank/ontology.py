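"""Disease ontology loading and evidence propagation.

The ontology is a DAG of ``is_a`` edges (child -> parent; a child may have
several parents).  Evidence asserted at a term is propagated to every ancestor
up to, and including, the designated therapeutic-area nodes; configured
generic root terms are excluded from propagation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .evidence import EvidenceString

logger = logging.getLogger(__name__)


class OntologyError(ValueError):
    pass


@dataclass
class OntologyGraph:
    """Disease DAG with designated therapeutic-area nodes.

    ``graph`` stores one directed edge child -> parent per ``is_a`` relation.
    """

    graph: nx.DiGraph
    therapeutic_areas: frozenset[str]
    root_ids: frozenset[str] = frozenset()
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str, include_self: bool = False) -> set[str]:
        """All terms reachable via parent edges, stopping at therapeutic areas.

        Therapeutic-area nodes are included but their own parents are not
        traversed; configured generic roots are excluded from the result.
        """
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")
        result: set[str] = set()
        if term not in self.therapeutic_areas:
            stack = list(self.parents(term))
            while stack:
                node = stack.pop()
                if node in result:
                    continue
                result.add(node)
                if node not in self.therapeutic_areas:
                    stack.extend(self.parents(node))
        result -= self.root_ids
        result.discard(term)
        if include_self:
            result.add(term)
        return result


def _parse_obo(text: str) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Parse ``[Term]`` stanzas from an OBO 1.2/1.4 document.

    Only ``id``, ``name`` and ``is_a`` tags are used; obsolete terms and all
    other relation types are ignored.
    """
    labels: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    current: str | None = None
    in_term = False
    for raw_line in text.splitlines():
        line = raw_line.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            in_term = line == "[Term]"
            current = None
            continue
        if not in_term or ":" not in line:
            continue
        tag, value = line.split(":", 1)
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            current = value
            labels.setdefault(current, current)
        elif tag == "name" and current:
            labels[current] = value
        elif tag == "is_a" and current:
            parent = value.split()[0]
            edges.append((current, parent))
        elif tag == "is_obsolete" and value == "true" and current:
            labels.pop(current, None)
            current = None
    return labels, edges


def _parse_edge_table(text: str) -> tuple[dict[str, str], list[tuple[str, str]]]:
    """Parse a 2-column ``child<TAB>parent`` table; '#' lines are comments."""
    labels: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise OntologyError(f"edge table line {lineno}: expected 2 columns, got {len(parts)}")
        child, parent = parts[0].strip(), parts[1].strip()
        edges.append((child, parent))
        labels.setdefault(child, child)
        labels.setdefault(parent, parent)
    return labels, edges


def load_ontology(
    doc: str | Path | io.TextIOBase,
    therapeutic_area_ids: Iterable[str],
    root_ids: Iterable[str] = (),
) -> OntologyGraph:
    """Build a validated :class:`OntologyGraph` from an OBO file or edge table.

    The format is sniffed from the content: documents containing a ``[Term]``
    stanza are treated as OBO, everything else as a tab-separated edge table.

    Raises :class:`OntologyError` on cycles (naming one) or when a listed
    therapeutic-area id is absent from the document.
    """
    if isinstance(doc, io.TextIOBase):
        text = doc.read()
    elif isinstance(doc, Path) or (isinstance(doc, str) and "\n" not in doc and Path(doc).exists()):
        text = Path(doc).read_text()
    else:
        text = str(doc)

    if "[Term]" in text:
        labels, edges = _parse_obo(text)
    else:
        labels, edges = _parse_edge_table(text)

    g = nx.DiGraph()
    g.add_nodes_from(labels)
    g.add_edges_from((c, p) for c, p in edges if c in labels and p in labels)

    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[0][0]}"
        raise OntologyError(f"ontology contains a cycle: {pretty}")

    ta = frozenset(therapeutic_area_ids)
    missing = ta - set(g.nodes)
    if missing:
        raise OntologyError(f"unknown therapeutic-area id(s): {sorted(missing)}")

    return OntologyGraph(
        graph=g,
        therapeutic_areas=ta,
        root_ids=frozenset(root_ids),
        labels=labels,
    )


def expand_evidence(
    graph: OntologyGraph,
    records: Iterable[EvidenceString],
    rejects: list[EvidenceString] | None = None,
) -> Iterator[tuple[str, EvidenceString, bool]]:
    """Propagate each evidence record to all ancestors of its disease term.

    Yields ``(disease_id, record, direct)`` tuples: one direct emission at the
    asserted term plus one indirect emission per ancestor, deduplicated across
    multiple paths.  Records whose disease id is not in the graph are diverted
    to ``rejects`` (when given) and logged.
    """
    n_rejected = 0
    for rec in records:
        if rec.disease_id not in graph:
            n_rejected += 1
            if rejects is not None:
                rejects.append(rec)
            continue
        yield rec.disease_id, rec, True
        for anc in sorted(graph.ancestors(rec.disease_id)):
            yield anc, rec, False
    if n_rejected:
        logger.warning("expand_evidence: %d record(s) with unresolvable disease ids", n_rejected)
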