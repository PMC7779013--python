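"""Reusable implementations of the release acceptance checks.

Each function recomputes its quantity from scratch by running the package on
synthetic inputs and returns a plain dict of measurements; the pytest
acceptance suite and ``scripts/acceptance.py`` both call these so the checks
cannot drift apart.
"""

from __future__ import annotations

import io
from typing import Any

import numpy as np
import pandas as pd

from . import pharmacovigilance as pv
from .simulate import FaersShape, PlantedSignal, make_faers_reports


def _counts_from_tsv(tsv: str) -> pv.ContingencyCounts:
    df = pd.read_csv(io.StringIO(tsv), sep="\t", comment="#", dtype={"case_id": str})
    return pv.aggregate_counts(df)


def null_calibration(
    n_seeds: int = 100,
    n_reports: int = 50_000,
    n_drugs: int = 20,
    n_events: int = 200,
    alpha: float = 0.05,
    n_sims: int = 250,
    seed: int = 0,
) -> dict[str, Any]:
    """Per-drug family-wise false-positive rate on null report tables."""
    shape = FaersShape(n_reports=n_reports, n_drugs=n_drugs, n_events=n_events)
    hits = 0
    runs = 0
    for k in range(n_seeds):
        out = make_faers_reports(shape, [], seed=seed * 100_003 + k)
        counts = _counts_from_tsv(out["tsv"])
        signals = pv.detect_signals(counts, alpha=alpha, n_sims=n_sims, seed=seed + k)
        per_drug = signals.groupby("drug")["significant"].any()
        hits += int(per_drug.sum())
        runs += len(per_drug)
    return {"false_positive_rate": hits / runs, "n_drug_runs": runs, "alpha": alpha}


def planted_signal_power(
    relative_risk: float,
    n_seeds: int = 50,
    n_reports: int = 20_000,
    n_drugs: int = 10,
    n_events: int = 50,
    alpha: float = 0.05,
    n_sims: int = 400,
    seed: int = 0,
) -> dict[str, Any]:
    """Fraction of seeds in which a planted (drug, event) pair is flagged."""
    drug, event = "CHEMBL00001", "event_0001"
    plant = [PlantedSignal(drug=drug, event=event, relative_risk=relative_risk)]
    flagged = 0
    min_nij = None
    for k in range(n_seeds):
        out = make_faers_reports(
            FaersShape(n_reports=n_reports, n_drugs=n_drugs, n_events=n_events),
            plant if relative_risk > 1 else [],
            seed=seed * 99_991 + k,
        )
        counts = _counts_from_tsv(out["tsv"])
        signals = pv.detect_signals(
            counts, alpha=alpha, n_sims=n_sims, seed=seed + k, drugs=[drug]
        )
        row = signals[(signals["drug"] == drug) & (signals["event"] == event)]
        if len(row) and bool(row.iloc[0]["significant"]):
            flagged += 1
        nij = counts.n_pair.get((drug, event), 0)
        min_nij = nij if min_nij is None else min(min_nij, nij)
    return {
        "power": flagged / n_seeds,
        "n_seeds": n_seeds,
        "min_pair_count": min_nij,
        "relative_risk": relative_risk,
    }


def harmonic_oracle_max_error(
    n_vectors: int = 1000, caps: tuple[int, ...] = (2, 10, 100), seed: int = 0
) -> dict[str, Any]:
    """Worst absolute deviation between the engine and a direct-summation oracle."""
    from .scoring import harmonic_sum

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        scores = rng.random(int(rng.integers(0, 201))).tolist()
        for cap in caps:
            oracle = 0.0
            for rank, s in enumerate(sorted(scores, reverse=True)[:cap], start=1):
                oracle += s / rank**2
            worst = max(worst, abs(harmonic_sum(scores, cap) - oracle))
    return {"max_abs_error": worst, "n_vectors": n_vectors}
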