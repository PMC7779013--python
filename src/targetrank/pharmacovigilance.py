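"""Drug adverse-event signal detection from spontaneous-report tables.

Pipeline: filter reports down to the reliable subset, count distinct reports
per drug, per event and per (drug, event) pair, score each pair with a
one-sided likelihood-ratio statistic, and call a pair significant when its
statistic exceeds a per-drug critical value obtained by Monte-Carlo
simulation of the null (events allocated to the drug's reports according to
their background frequencies).  The per-drug maximum statistic makes the
family-wise false-positive rate approximately the chosen alpha.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["case_id", "drug", "event", "qualification", "drug_role", "version"]

#: Reporter-qualification codes kept by default (health professionals).
DEFAULT_QUALIFICATION_WHITELIST = frozenset({"1", "2", "3"})
#: Drug-role codes kept by default (suspect drugs).
DEFAULT_ROLE_WHITELIST = frozenset({"PS", "SS"})


def default_event_blacklist() -> frozenset[str]:
    text = resources.files("targetrank").joinpath("data/event_blacklist.txt").read_text()
    terms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            terms.add(line.lower())
    return frozenset(terms)


@dataclass
class FilterConfig:
    qualification_whitelist: frozenset[str] = DEFAULT_QUALIFICATION_WHITELIST
    role_whitelist: frozenset[str] = DEFAULT_ROLE_WHITELIST
    event_blacklist: frozenset[str] = field(default_factory=default_event_blacklist)


@dataclass
class ContingencyCounts:
    """Distinct-report counts underlying the disproportionality analysis."""

    N: int
    n_drug: dict[str, int]
    n_event: dict[str, int]
    n_pair: dict[tuple[str, str], int]

    def validate(self) -> None:
        for (drug, event), nij in self.n_pair.items():
            bound = min(self.n_drug[drug], self.n_event[event])
            if not nij <= bound <= self.N:
                raise ValueError(f"inconsistent counts for ({drug}, {event})")


def filter_reports(
    rows: pd.DataFrame,
    filter_config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep the reliable subset of report rows; returns per-rule removal counts.

    Rules, in order: (1) reporter qualification in whitelist; (2) drug role in
    whitelist; (3) keep only the highest report version per case; (4) drop
    blacklisted uninformative event terms.
    """
    cfg = filter_config or FilterConfig()
    missing = [c for c in REQUIRED_COLUMNS if c not in rows.columns]
    if missing:
        raise KeyError(f"report table missing required column(s): {missing}")

    removed: dict[str, int] = {}
    df = rows

    kept = df["qualification"].astype(str).isin(cfg.qualification_whitelist)
    removed["qualification"] = int((~kept).sum())
    df = df[kept]

    kept = df["drug_role"].astype(str).isin(cfg.role_whitelist)
    removed["drug_role"] = int((~kept).sum())
    df = df[kept]

    max_version = df.groupby("case_id")["version"].transform("max")
    kept = df["version"] == max_version
    removed["version"] = int((~kept).sum())
    df = df[kept]

    normalized = df["event"].astype(str).str.lower().str.replace(" ", "_", regex=False)
    kept = ~normalized.isin(cfg.event_blacklist)
    removed["event_blacklist"] = int((~kept).sum())
    df = df[kept]

    logger.info("filter_reports: removed %s of %d rows", removed, len(rows))
    return df.reset_index(drop=True), removed


def aggregate_counts(rows: pd.DataFrame) -> ContingencyCounts:
    """Count distinct case ids overall, per drug, per event and per pair."""
    N = int(rows["case_id"].nunique())
    n_drug = rows.groupby("drug")["case_id"].nunique().to_dict()
    n_event = rows.groupby("event")["case_id"].nunique().to_dict()
    n_pair = rows.groupby(["drug", "event"])["case_id"].nunique().to_dict()
    counts = ContingencyCounts(
        N=N,
        n_drug={str(k): int(v) for k, v in n_drug.items()},
        n_event={str(k): int(v) for k, v in n_event.items()},
        n_pair={(str(d), str(e)): int(v) for (d, e), v in n_pair.items()},
    )
    counts.validate()
    return counts


def llr(nij: float, ni: float, nj: float, N: float) -> float:
    """One-sided log likelihood-ratio statistic for one (drug, event) pair.

    ``nij``: reports mentioning both; ``ni``: reports mentioning the event;
    ``nj``: reports mentioning the drug; ``N``: total reports.  Returns 0 when
    the pair is at or below its null expectation.
    """
    if not (0 <= nij <= min(ni, nj) <= N) or nj < 1:
        raise ValueError(f"invalid counts nij={nij}, ni={ni}, nj={nj}, N={N}")
    eij = nj * ni / N
    if nij <= eij:
        return 0.0
    out = nij * np.log(nij / eij)
    rest = nj - nij
    if rest > 0:
        out += rest * np.log(rest / (nj - eij))
    return float(out)


def _llr_vector(nij: np.ndarray, ni: np.ndarray, nj: float, N: float) -> np.ndarray:
    """Vectorised :func:`llr` over event axes; 0*log(0) treated as 0."""
    eij = nj * ni / N
    rest = nj - nij
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(nij > 0, nij * np.log(np.where(nij > 0, nij, 1) / eij), 0.0)
        term2 = np.where(rest > 0, rest * np.log(np.where(rest > 0, rest, 1) / (nj - eij)), 0.0)
    out = term1 + term2
    return np.where(nij > eij, out, 0.0)


def _drug_rng(seed: int, drug: str) -> np.random.Generator:
    """Per-drug generator independent of drug processing order."""
    digest = hashlib.sha256(drug.encode()).digest()
    return np.random.default_rng([seed, int.from_bytes(digest[:8], "little")])


def mc_critical_value(
    nj: int,
    event_marginals: np.ndarray,
    N: int,
    alpha: float = 0.05,
    n_sims: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Empirical (1 - alpha) quantile of the null per-drug maximum LLR.

    Null datasets allocate the drug's ``nj`` reports across events
    multinomially with probabilities proportional to the background event
    marginals; the statistic is the maximum LLR over events.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    ni = np.asarray(event_marginals, dtype=float)
    if ni.ndim != 1 or ni.size == 0:
        raise ValueError("event_marginals must be a non-empty 1-D array")
    if ni.size == 1:
        return 0.0  # a single event can never be disproportionate
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    probs = ni / ni.sum()
    sims = rng.multinomial(nj, probs, size=n_sims)
    max_llr = _llr_vector(sims, ni[None, :], float(nj), float(N)).max(axis=1)
    return float(np.quantile(max_llr, 1.0 - alpha))


SIGNAL_COLUMNS = [
    "drug", "event", "llr", "critical_value", "significant", "nij", "ni", "nj", "N",
]


def detect_signals(
    counts: ContingencyCounts,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    drugs: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Flag significant (drug, event) pairs; deterministic for a given seed.

    One row per observed pair, sorted by drug then LLR descending.  Per-drug
    random streams are derived from (seed, drug), so results do not depend on
    the order drugs are processed in.
    """
    events = sorted(counts.n_event)
    ni = np.array([counts.n_event[e] for e in events], dtype=float)
    pairs_by_drug: dict[str, list[str]] = {}
    for (drug, event), _ in counts.n_pair.items():
        pairs_by_drug.setdefault(drug, []).append(event)

    rows = []
    selected = sorted(pairs_by_drug) if drugs is None else sorted(set(drugs) & set(pairs_by_drug))
    for drug in selected:
        nj = counts.n_drug[drug]
        crit = mc_critical_value(
            nj, ni, counts.N, alpha=alpha, n_sims=n_sims, rng=_drug_rng(seed, drug)
        )
        for event in pairs_by_drug[drug]:
            nij = counts.n_pair[(drug, event)]
            stat = llr(nij, counts.n_event[event], nj, counts.N)
            rows.append(
                {
                    "drug": drug,
                    "event": event,
                    "llr": stat,
                    "critical_value": crit,
                    "significant": bool(stat > crit),
                    "nij": nij,
                    "ni": counts.n_event[event],
                    "nj": nj,
                    "N": counts.N,
                }
            )

    df = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            by=["drug", "llr", "event"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
    return df


def run_faers_analysis(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
    filter_config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, Mapping[str, int]]:
    """Filter -> aggregate -> detect, returning signals and removal counts."""
    filtered, removed = filter_reports(rows, filter_config)
    if filtered.empty:
        return pd.DataFrame(columns=SIGNAL_COLUMNS), removed
    counts = aggregate_counts(filtered)
    return detect_signals(counts, alpha=alpha, n_sims=n_sims, seed=seed), removed
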