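"""Evidence scoring and harmonic-sum association aggregation.

Every piece of evidence gets a score in [0, 1] from a per-source scorer
(with hard filters that can reject it outright).  Scores for one
(target, disease, datasource) group are aggregated by a capped harmonic sum
``sum(s_(i) / i^2)`` over descending-sorted scores, normalised by the maximum
attainable sum so results stay in [0, 1].  Data-type and overall association
scores apply the same reduction to weight-multiplied datasource scores.
"""

from __future__ import annotations

import json
import logging
from typing import Any, Callable, Iterable, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .evidence import EvidenceString

logger = logging.getLogger(__name__)

#: Sentinel distinct from any score; evidence filtered out by its scorer.
REJECT = None

DEFAULT_DATATYPE_WEIGHTS = {
    "genetic_association": 1.0,
    "somatic_mutation": 1.0,
    "known_drug": 1.0,
    "affected_pathway": 1.0,
    "rna_expression": 0.2,
    "literature": 0.2,
    "animal_model": 0.2,
}

DEFAULT_DATASOURCE_TO_DATATYPE = {
    "ot_genetics_portal": "genetic_association",
    "eva": "genetic_association",
    "cancer_gene_census": "somatic_mutation",
    "intogen": "somatic_mutation",
    "chembl": "known_drug",
    "project_score": "affected_pathway",
    "reactome": "affected_pathway",
    "expression_atlas": "rna_expression",
    "europepmc": "literature",
    "phenodigm": "animal_model",
}


class ScoringError(ValueError):
    pass


class ScoringConfig(BaseModel):
    """Weights, caps and per-source thresholds driving association scoring."""

    cap: int = 100
    source_weights: dict[str, float] = Field(default_factory=dict)
    datasource_to_datatype: dict[str, str] = Field(
        default_factory=lambda: dict(DEFAULT_DATASOURCE_TO_DATATYPE)
    )
    datatype_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DATATYPE_WEIGHTS)
    )
    phase_scores: dict[int, float] = Field(
        default_factory=lambda: {4: 1.0, 3: 0.7, 2: 0.2, 1: 0.1, 0: 0.05}
    )
    gwas_pvalue_cutoff: float = 5e-8
    project_score_min: float = 40.0

    @field_validator("cap")
    @classmethod
    def _cap_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("cap must be >= 1")
        return v

    @model_validator(mode="after")
    def _ranges(self) -> "ScoringConfig":
        for name, mapping in (("source_weights", self.source_weights),
                              ("datatype_weights", self.datatype_weights)):
            for key, w in mapping.items():
                if not 0 < w <= 1:
                    raise ValueError(f"{name}[{key!r}] = {w} outside (0, 1]")
        for phase, s in self.phase_scores.items():
            if not 0 <= s <= 1:
                raise ValueError(f"phase_scores[{phase}] = {s} outside [0, 1]")
        return self

    @property
    def normalization_denominator(self) -> float:
        """Max attainable harmonic sum: sum_{i=1..cap} 1/i^2."""
        return sum(1.0 / (i * i) for i in range(1, self.cap + 1))

    def weight_for(self, datasource_id: str) -> float:
        """Per-source weight; falls back to the datatype weight, then 1.0."""
        if datasource_id in self.source_weights:
            return self.source_weights[datasource_id]
        dtype = self.datasource_to_datatype.get(datasource_id)
        return self.datatype_weights.get(dtype, 1.0) if dtype else 1.0

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "ScoringConfig":
        data = dict(raw)
        if "weights" in data:
            data["source_weights"] = data.pop("weights")
        if "datatypes" in data:
            data["datasource_to_datatype"] = data.pop("datatypes")
        if "phase_scores" in data:
            data["phase_scores"] = {int(k): v for k, v in data["phase_scores"].items()}
        return cls(**data)


# ---------------------------------------------------------------------------
# Per-source evidence scoring

Scorer = Callable[[EvidenceString, ScoringConfig], "float | None"]

def _clip01(x: float) -> float:
    return min(1.0, max(0.0, float(x)))


def _score_gwas(rec: EvidenceString, cfg: ScoringConfig) -> float | None:
    pval = rec.score_payload.get("gwas_pvalue")
    if pval is not None and pval > cfg.gwas_pvalue_cutoff:
        return REJECT
    return _clip01(rec.score_payload["resource_score"])


def _score_priority(rec: EvidenceString, cfg: ScoringConfig) -> float | None:
    priority = rec.score_payload["priority_score"]
    if priority < cfg.project_score_min:
        return REJECT
    return _clip01(priority / 100.0)


def _score_clinical_phase(rec: EvidenceString, cfg: ScoringConfig) -> float | None:
    phase = int(rec.score_payload["clinical_phase"])
    try:
        return cfg.phase_scores[phase]
    except KeyError:
        raise ScoringError(f"clinical_phase {phase} has no configured score") from None


def _score_default(rec: EvidenceString, cfg: ScoringConfig) -> float | None:
    if "resource_score" not in rec.score_payload:
        raise ScoringError(
            f"no scorer registered for datasource {rec.datasource_id!r} and no "
            f"resource_score in payload (target={rec.target_id}, disease={rec.disease_id})"
        )
    return _clip01(rec.score_payload["resource_score"])


SCORERS: dict[str, Scorer] = {
    "ot_genetics_portal": _score_gwas,
    "project_score": _score_priority,
    "chembl": _score_clinical_phase,
}


def register_scorer(datasource_id: str, scorer: Scorer) -> None:
    """Register (or replace) the scoring function for a datasource."""
    SCORERS[datasource_id] = scorer


def score_evidence(record: EvidenceString, config: ScoringConfig) -> float | None:
    """Score one evidence record in [0, 1], or :data:`REJECT` (None)."""
    scorer = SCORERS.get(record.datasource_id, _score_default)
    score = scorer(record, config)
    if score is not None and not 0.0 <= score <= 1.0:
        raise ScoringError(f"scorer for {record.datasource_id!r} returned {score} outside [0, 1]")
    return score


# ---------------------------------------------------------------------------
# Harmonic-sum aggregation

def harmonic_sum(scores: Sequence[float], cap: int) -> float:
    """Capped harmonic sum: sort descending, return sum of s_(i) / i^2."""
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ScoringError(f"score {s} outside [0, 1]")
    ordered = sorted(scores, reverse=True)[:cap]
    return sum(s / ((i + 1) ** 2) for i, s in enumerate(ordered))


def normalized_harmonic_sum(scores: Sequence[float], config: ScoringConfig) -> float:
    """Harmonic sum scaled into [0, 1] by the maximum attainable value."""
    return harmonic_sum(scores, config.cap) / config.normalization_denominator


def datasource_association(evidence_scores: Sequence[float], config: ScoringConfig) -> float:
    """Association score for one (target, disease, datasource) group."""
    return normalized_harmonic_sum(evidence_scores, config)


def _weighted_reduction(datasource_scores: Mapping[str, float], config: ScoringConfig) -> float:
    weighted = [config.weight_for(src) * s for src, s in datasource_scores.items()]
    return normalized_harmonic_sum(weighted, config)


def datatype_association(datasource_scores: Mapping[str, float], config: ScoringConfig) -> float:
    """Weighted reduction of the datasource scores belonging to one datatype."""
    for src in datasource_scores:
        if src not in config.datasource_to_datatype:
            raise ScoringError(f"datasource {src!r} has no datatype mapping")
    return _weighted_reduction(datasource_scores, config)


def overall_association(datasource_scores: Mapping[str, float], config: ScoringConfig) -> float:
    """Weighted reduction over all datasource scores of a target-disease pair."""
    return _weighted_reduction(datasource_scores, config)


# ---------------------------------------------------------------------------
# Association table construction

ASSOCIATION_COLUMNS = [
    "target_id",
    "disease_id",
    "direct",
    "overall_score",
    "evidence_count",
    "datasource_scores",
    "datatype_scores",
]


def build_associations(
    expanded: Iterable[tuple[str, EvidenceString, bool]],
    config: ScoringConfig,
    rejected_counter: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build the association table from ontology-expanded evidence.

    Produces one row per (target, disease) computed from direct evidence only
    (``direct=True``) and one over the union of direct and propagated evidence
    (``direct=False``).  Datasource/datatype score maps are serialised as JSON
    strings so the table round-trips through TSV.
    """
    # (target, disease, mode) -> datasource -> list of evidence scores
    groups: dict[tuple[str, str, bool], dict[str, list[float]]] = {}
    counts: dict[tuple[str, str, bool], int] = {}
    n_rejected = 0

    for disease_id, rec, direct in expanded:
        score = score_evidence(rec, config)
        if score is REJECT:
            if direct:
                n_rejected += 1
            continue
        modes = [(False,)] if not direct else [(False,), (True,)]
        for (mode_direct,) in modes:
            gkey = (rec.target_id, disease_id, mode_direct)
            groups.setdefault(gkey, {}).setdefault(rec.datasource_id, []).append(score)
            counts[gkey] = counts.get(gkey, 0) + 1

    if rejected_counter is not None:
        rejected_counter["n_rejected_by_scorer"] = n_rejected
    if n_rejected:
        logger.info("build_associations: %d evidence record(s) rejected by score filters", n_rejected)

    rows = []
    for (target, disease, direct), per_source in sorted(groups.items()):
        ds_scores = {
            src: datasource_association(scores, config)
            for src, scores in sorted(per_source.items())
        }
        dt_members: dict[str, dict[str, float]] = {}
        for src, s in ds_scores.items():
            dtype = config.datasource_to_datatype.get(src, "unknown")
            dt_members.setdefault(dtype, {})[src] = s
        dt_scores = {
            dtype: _weighted_reduction(members, config)
            for dtype, members in sorted(dt_members.items())
        }
        rows.append(
            {
                "target_id": target,
                "disease_id": disease,
                "direct": direct,
                "overall_score": overall_association(ds_scores, config),
                "evidence_count": counts[(target, disease, direct)],
                "datasource_scores": json.dumps(ds_scores, sort_keys=True),
                "datatype_scores": json.dumps(dt_scores, sort_keys=True),
            }
        )

    df = pd.DataFrame(rows, columns=ASSOCIATION_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            by=["overall_score", "evidence_count", "target_id", "disease_id", "direct"],
            ascending=[False, False, True, True, False],
            kind="mergesort",
        ).reset_index(drop=True)
    return df
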