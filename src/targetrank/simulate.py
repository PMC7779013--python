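"""Synthetic fixture generation: toy ontologies, evidence sets, report tables.

Everything is a pure function of its spec (seed included), so reruns are
byte-identical.  Generated artifacts are designed to exercise every filter
and error path of the consuming modules; the counts of planted structure are
returned as a coverage manifest.
"""

from __future__ import annotations

import json
from typing import Any

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .evidence import DATATYPES
from .scoring import DEFAULT_DATASOURCE_TO_DATATYPE

GENERIC_ROOT = "EFO_0000001"


class OntologyShape(BaseModel):
    n_nodes: int = 30  # excludes the generic root
    max_parents: int = 3
    n_therapeutic_areas: int = 2

    @field_validator("n_nodes", "max_parents", "n_therapeutic_areas")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("ontology shape counts must be positive")
        return v


class EvidenceShape(BaseModel):
    n_targets: int = 20
    n_evidence: int = 500
    datasource_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "ot_genetics_portal": 0.3,
            "chembl": 0.15,
            "project_score": 0.1,
            "europepmc": 0.25,
            "expression_atlas": 0.2,
        }
    )
    score_alpha: float = 2.0  # Beta(alpha, beta): most evidence weak
    score_beta: float = 5.0
    frac_gwas_above_cutoff: float = 0.2
    frac_priority_below_min: float = 0.3
    n_invalid: int = 0  # malformed records appended to exercise the validator


class PlantedAssociation(BaseModel):
    target_id: str
    disease_id: str
    n_evidence: int
    score: float
    datasource_id: str = "reactome"


class FaersShape(BaseModel):
    n_reports: int = 5000
    n_drugs: int = 10
    n_events: int = 50
    frac_bad_qualification: float = 0.0
    frac_bad_role: float = 0.0
    frac_duplicate_case: float = 0.0
    frac_blacklisted_event: float = 0.0


class PlantedSignal(BaseModel):
    drug: str
    event: str
    relative_risk: float

    @field_validator("relative_risk")
    @classmethod
    def _rr(cls, v: float) -> float:
        if v < 1:
            raise ValueError("relative_risk must be >= 1")
        return v


class FixtureSpec(BaseModel):
    seed: int = 0
    ontology: OntologyShape = Field(default_factory=OntologyShape)
    evidence: EvidenceShape = Field(default_factory=EvidenceShape)
    planted_associations: list[PlantedAssociation] = Field(default_factory=list)
    faers: FaersShape = Field(default_factory=FaersShape)
    planted_signals: list[PlantedSignal] = Field(default_factory=list)


def node_id(i: int) -> str:
    return f"EFO_{i:07d}"


def target_id(i: int) -> str:
    return f"ENSG{i:011d}"


# ---------------------------------------------------------------------------
# Ontology

def make_toy_ontology(shape: OntologyShape, seed: int) -> dict[str, Any]:
    """Random DAG serialised both as OBO text and an edge TSV.

    Node 1 is a generic root excluded from propagation; the next
    ``n_therapeutic_areas`` nodes are therapeutic areas (children of the
    root); every later node draws 1..max_parents parents among earlier
    non-root nodes, so the graph is acyclic by construction.
    """
    rng = np.random.default_rng([seed, 0xD15EA5E])
    n_ta = shape.n_therapeutic_areas
    total = shape.n_nodes + 1  # + generic root
    if shape.n_nodes < n_ta + 1:
        raise ValueError("need at least one non-therapeutic-area node")

    ids = [node_id(i + 1) for i in range(total)]
    root = ids[0]
    assert root == GENERIC_ROOT
    tas = ids[1 : 1 + n_ta]
    edges: list[tuple[str, str]] = [(ta, root) for ta in tas]
    for i in range(1 + n_ta, total):
        # parents drawn among earlier non-root nodes only
        pool = ids[1:i]
        k = int(rng.integers(1, min(shape.max_parents, len(pool)) + 1))
        parents = rng.choice(len(pool), size=k, replace=False)
        edges.extend((ids[i], pool[int(p)]) for p in sorted(parents))

    obo_lines = [
        "format-version: 1.2",
        f"! fixture seed: {seed}",
        "",
    ]
    parent_map: dict[str, list[str]] = {}
    for child, parent in edges:
        parent_map.setdefault(child, []).append(parent)
    for term in ids:
        obo_lines.append("[Term]")
        obo_lines.append(f"id: {term}")
        obo_lines.append(f"name: synthetic term {term}")
        for parent in parent_map.get(term, []):
            obo_lines.append(f"is_a: {parent}")
        obo_lines.append("")

    tsv_lines = [f"# seed: {seed}", "# child\tparent"]
    tsv_lines.extend(f"{c}\t{p}" for c, p in edges)

    return {
        "obo": "\n".join(obo_lines) + "\n",
        "tsv": "\n".join(tsv_lines) + "\n",
        "nodes": ids,
        "diseases": ids[1 + n_ta :],  # plain disease terms below the TAs
        "therapeutic_areas": tas,
        "root_id": root,
        "n_edges": len(edges),
    }


# ---------------------------------------------------------------------------
# Evidence

def _payload_for(source: str, score: float, rng: np.random.Generator,
                 shape: EvidenceShape) -> dict[str, Any]:
    if source == "ot_genetics_portal":
        above = rng.random() < shape.frac_gwas_above_cutoff
        pval = float(10 ** rng.uniform(-7.2, -5.5)) if above else float(10 ** rng.uniform(-30, -8))
        return {"resource_score": score, "gwas_pvalue": pval}
    if source == "project_score":
        below = rng.random() < shape.frac_priority_below_min
        priority = float(np.round(rng.uniform(5, 39) if below else rng.uniform(40, 100), 2))
        return {"priority_score": priority}
    if source == "chembl":
        return {"clinical_phase": int(rng.integers(0, 5))}
    return {"resource_score": score}


def make_evidence_set(
    shape: EvidenceShape,
    disease_ids: list[str],
    planted: list[PlantedAssociation],
    seed: int,
) -> dict[str, Any]:
    """JSON Lines evidence with planted pairs; returns text plus a manifest."""
    rng = np.random.default_rng([seed, 0xE71D])
    sources = sorted(shape.datasource_mix)
    probs = np.array([shape.datasource_mix[s] for s in sources], dtype=float)
    probs /= probs.sum()

    manifest = {
        "seed": seed,
        "n_background": shape.n_evidence,
        "n_planted": sum(p.n_evidence for p in planted),
        "n_invalid": shape.n_invalid,
        "n_gwas_above_cutoff": 0,
        "n_priority_below_min": 0,
    }
    lines: list[str] = []

    def emit(target: str, disease: str, source: str, payload: dict[str, Any]) -> None:
        if "gwas_pvalue" in payload and payload["gwas_pvalue"] > 5e-8:
            manifest["n_gwas_above_cutoff"] += 1
        if "priority_score" in payload and payload["priority_score"] < 40:
            manifest["n_priority_below_min"] += 1
        rec = {
            "target_id": target,
            "disease_id": disease,
            "datasource_id": source,
            "datatype_id": DEFAULT_DATASOURCE_TO_DATATYPE.get(source, "literature"),
            "score_payload": payload,
            "provenance": {"fixture_seed": seed},
        }
        lines.append(json.dumps(rec, sort_keys=True))

    for _ in range(shape.n_evidence):
        target = target_id(int(rng.integers(1, shape.n_targets + 1)))
        disease = disease_ids[int(rng.integers(0, len(disease_ids)))]
        source = sources[int(rng.choice(len(sources), p=probs))]
        score = float(np.round(rng.beta(shape.score_alpha, shape.score_beta), 6))
        emit(target, disease, source, _payload_for(source, score, rng, shape))

    for plant in planted:
        for _ in range(plant.n_evidence):
            emit(plant.target_id, plant.disease_id, plant.datasource_id,
                 {"resource_score": plant.score})

    for i in range(shape.n_invalid):
        bad = {
            "target_id": f"NOT_A_GENE_{i}",
            "disease_id": disease_ids[0],
            "datasource_id": "reactome",
            "datatype_id": "affected_pathway",
            "score_payload": {"resource_score": 0.5},
        }
        lines.append(json.dumps(bad, sort_keys=True))

    manifest["n_records"] = len(lines)
    manifest["n_valid"] = len(lines) - shape.n_invalid
    return {"jsonl": "\n".join(lines) + "\n", "manifest": manifest}


# ---------------------------------------------------------------------------
# Adverse-event reports

def drug_id(i: int) -> str:
    return f"CHEMBL{i:05d}"


def event_id(i: int) -> str:
    return f"event_{i:04d}"


def make_faers_reports(
    shape: FaersShape,
    planted: list[PlantedSignal],
    seed: int,
) -> dict[str, Any]:
    """Report TSV with planted drug-event signals and filter-rule violations.

    Each clean report carries one suspect drug and one event.  Planted
    (drug, event) pairs have the event's probability multiplied by the
    relative risk and renormalised within that drug, keeping report totals
    comparable across drugs.  Violation rows are appended on top of the clean
    table so they never perturb the planted structure.
    """
    rng = np.random.default_rng([seed, 0xFAE25])
    drugs = [drug_id(i + 1) for i in range(shape.n_drugs)]
    events = [event_id(i + 1) for i in range(shape.n_events)]

    drug_probs = rng.dirichlet(np.full(shape.n_drugs, 5.0))
    event_probs = rng.dirichlet(np.full(shape.n_events, 5.0))

    boosts: dict[str, dict[str, float]] = {}
    for plant in planted:
        boosts.setdefault(plant.drug, {})[plant.event] = plant.relative_risk

    drug_counts = rng.multinomial(shape.n_reports, drug_probs)
    rows: list[tuple[str, str, str, str, str, int]] = []
    quals = ("1", "2", "3")
    case_no = 0
    for d_idx, drug in enumerate(drugs):
        p = event_probs.copy()
        for event, rr in boosts.get(drug, {}).items():
            p[events.index(event)] *= rr
        p /= p.sum()
        ev_counts = rng.multinomial(int(drug_counts[d_idx]), p)
        for e_idx in np.repeat(np.arange(shape.n_events), ev_counts):
            case_no += 1
            qual = quals[int(rng.integers(0, 3))]
            rows.append((f"case{case_no:08d}", drug, events[int(e_idx)], qual, "PS", 1))

    manifest = {
        "seed": seed,
        "n_clean": len(rows),
        "n_bad_qualification": int(round(shape.frac_bad_qualification * shape.n_reports)),
        "n_bad_role": int(round(shape.frac_bad_role * shape.n_reports)),
        "n_duplicate_version": int(round(shape.frac_duplicate_case * shape.n_reports)),
        "n_blacklisted_event": int(round(shape.frac_blacklisted_event * shape.n_reports)),
    }

    def random_event() -> str:
        return events[int(rng.choice(shape.n_events, p=event_probs))]

    def random_drug() -> str:
        return drugs[int(rng.choice(shape.n_drugs, p=drug_probs))]

    for _ in range(manifest["n_bad_qualification"]):
        case_no += 1
        rows.append((f"case{case_no:08d}", random_drug(), random_event(), "5", "PS", 1))
    for _ in range(manifest["n_bad_role"]):
        case_no += 1
        rows.append((f"case{case_no:08d}", random_drug(), random_event(), "1", "C", 1))
    # stale lower-version rows for existing cases; the v1 row still wins
    n_clean = manifest["n_clean"]
    for _ in range(manifest["n_duplicate_version"]):
        victim = rows[int(rng.integers(0, n_clean))]
        rows.append((victim[0], victim[1], random_event(), victim[3], "PS", 0))
    for _ in range(manifest["n_blacklisted_event"]):
        case_no += 1
        rows.append((f"case{case_no:08d}", random_drug(), "drug_ineffective", "1", "PS", 1))

    manifest["n_rows"] = len(rows)
    lines = [f"# seed: {seed}", "case_id\tdrug\tevent\tqualification\tdrug_role\tversion"]
    lines.extend("\t".join(map(str, r)) for r in rows)
    return {"tsv": "\n".join(lines) + "\n", "manifest": manifest}


# ---------------------------------------------------------------------------
# Whole-fixture convenience

def generate_fixture(spec: FixtureSpec) -> dict[str, Any]:
    """Generate every artifact of a fixture spec (in-memory texts + manifest)."""
    onto = make_toy_ontology(spec.ontology, spec.seed)
    evid = make_evidence_set(spec.evidence, onto["diseases"], spec.planted_associations, spec.seed)
    faers = make_faers_reports(spec.faers, spec.planted_signals, spec.seed)
    return {
        "ontology": onto,
        "evidence": evid,
        "faers": faers,
        "manifest": {
            "seed": spec.seed,
            "ontology": {
                "n_nodes": len(onto["nodes"]),
                "n_edges": onto["n_edges"],
                "therapeutic_areas": onto["therapeutic_areas"],
                "root_id": onto["root_id"],
            },
            "evidence": evid["manifest"],
            "faers": faers["manifest"],
        },
    }
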