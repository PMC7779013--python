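"""End-to-end pipeline: validate -> dedupe -> expand -> score -> associate,
with an optional adverse-event-report branch, run manifest and ranking."""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import evidence as ev
from . import pharmacovigilance as pv
from .evidence import TARGET_ID_RE
from .ontology import OntologyError, expand_evidence, load_ontology
from .scoring import ScoringConfig, build_associations

logger = logging.getLogger(__name__)


class MissingInputError(FileNotFoundError):
    """An input path named in the config does not exist (CLI exit code 2)."""


class PipelineInputError(ValueError):
    """Schema or ontology failed to load/validate (CLI exit code 3)."""


class PipelineInvariantError(RuntimeError):
    """An internal consistency check failed mid-run (CLI exit code 4)."""


def _sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _utc_now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds")


def load_config(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(config, Mapping):
        return dict(config)
    path = Path(config)
    if not path.exists():
        raise MissingInputError(f"config file not found: {path}")
    return yaml.safe_load(path.read_text()) or {}


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    """Execute the full pipeline described by a config mapping or YAML path.

    Returns the run manifest.  Outputs land in ``config['out_dir']``:
    validated evidence, validation report, association tables (TSV + JSON
    Lines), signal table when reports are provided, the resolved config, and
    ``manifest.json``.
    """
    cfg = load_config(config)
    out_dir = Path(cfg.get("out_dir", "targetrank_out"))
    started = _utc_now()

    evidence_path = cfg.get("evidence")
    ontology_path = cfg.get("ontology")
    if not evidence_path or not ontology_path:
        raise MissingInputError("config must name 'evidence' and 'ontology' inputs")
    inputs = {"evidence": Path(evidence_path), "ontology": Path(ontology_path)}
    if cfg.get("reports"):
        inputs["reports"] = Path(cfg["reports"])
    for name, path in inputs.items():
        if not path.exists():
            raise MissingInputError(f"{name} file not found: {path}")

    try:
        scoring_cfg = ScoringConfig.from_dict(cfg.get("scoring", {}))
    except (ValueError, TypeError) as exc:
        raise PipelineInputError(f"bad scoring config: {exc}") from exc

    try:
        ontology = load_ontology(
            inputs["ontology"],
            therapeutic_area_ids=cfg.get("therapeutic_areas", []),
            root_ids=cfg.get("root_ids", []),
        )
    except OntologyError as exc:
        raise PipelineInputError(str(exc)) from exc

    schema = ev.load_schema()
    raw_lines = [ln for ln in inputs["evidence"].read_text().splitlines() if ln.strip()]
    validated, report = ev.validate_evidence(raw_lines, schema)
    deduped = list(ev.deduplicate_evidence(validated))

    expansion_rejects: list[ev.EvidenceString] = []
    expanded = list(expand_evidence(ontology, deduped, rejects=expansion_rejects))
    rejected_counter: dict[str, int] = {}
    associations = build_associations(expanded, scoring_cfg, rejected_counter)

    if report.n_input != report.n_valid + report.n_invalid:
        raise PipelineInvariantError("validation counts do not add up")
    n_resolvable = len(deduped) - len(expansion_rejects)
    if len(expanded) < n_resolvable:
        raise PipelineInvariantError("expansion emitted fewer rows than resolvable records")

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "validated_evidence": out_dir / "validated_evidence.jsonl",
        "validation_report": out_dir / "validation_report.json",
        "associations_tsv": out_dir / "associations.tsv",
        "associations_jsonl": out_dir / "associations.jsonl",
        "resolved_config": out_dir / "resolved_config.yaml",
        "manifest": out_dir / "manifest.json",
    }
    paths["validated_evidence"].write_text(
        "".join(rec.to_json() + "\n" for rec in deduped)
    )
    paths["validation_report"].write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    associations.to_csv(paths["associations_tsv"], sep="\t", index=False)
    paths["associations_jsonl"].write_text(
        associations.to_json(orient="records", lines=True, double_precision=15)
        + ("\n" if len(associations) else "")
    )

    counts: dict[str, int] = {
        "n_input": report.n_input,
        "n_valid": report.n_valid,
        "n_invalid": report.n_invalid,
        "n_deduplicated": len(deduped),
        "n_unresolvable_disease": len(expansion_rejects),
        "n_expanded": len(expanded),
        "n_rejected_by_scorer": rejected_counter.get("n_rejected_by_scorer", 0),
        "n_associations": int(len(associations)),
    }

    if "reports" in inputs:
        reports_df = pd.read_csv(inputs["reports"], sep="\t", comment="#", dtype={"case_id": str})
        signals, removed = pv.run_faers_analysis(
            reports_df,
            alpha=float(cfg.get("alpha", 0.05)),
            n_sims=int(cfg.get("n_sims", 1000)),
            seed=int(cfg.get("seed", 0)),
        )
        paths["signals"] = out_dir / "signals.tsv"
        signals.to_csv(paths["signals"], sep="\t", index=False)
        counts["n_report_rows"] = int(len(reports_df))
        counts["n_reports_removed"] = int(sum(removed.values()))
        counts["n_signal_pairs"] = int(len(signals))
        counts["n_significant"] = int(signals["significant"].sum()) if len(signals) else 0

    resolved = dict(cfg)
    resolved["out_dir"] = str(out_dir)
    paths["resolved_config"].write_text(yaml.safe_dump(resolved, sort_keys=True))

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_digests": {name: _sha256_file(p) for name, p in inputs.items()},
        "seed": cfg.get("seed", 0),
        "counts": counts,
        "artifacts": {name: str(p) for name, p in paths.items() if name != "manifest"},
        "started": started,
        "finished": _utc_now(),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def rank_query(
    associations: pd.DataFrame,
    entity_id: str,
    mode: str = "indirect",
    top_k: int = 10,
) -> pd.DataFrame:
    """Top-k association rows for a disease (ranked targets) or a target
    (ranked diseases), in the requested direct/indirect mode."""
    if mode not in ("direct", "indirect"):
        raise ValueError("mode must be 'direct' or 'indirect'")
    df = associations[associations["direct"] == (mode == "direct")]
    column = "target_id" if TARGET_ID_RE.match(entity_id) else "disease_id"
    df = df[df[column] == entity_id]
    if df.empty:
        logger.warning("rank_query: no %s-mode associations for %s", mode, entity_id)
        return df.reset_index(drop=True)
    df = df.sort_values(
        by=["overall_score", "evidence_count", "target_id", "disease_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    return df.head(top_k).reset_index(drop=True)
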