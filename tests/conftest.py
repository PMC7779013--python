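import pandas as pd
import pytest

from targetrank.evidence import EvidenceString
from targetrank.ontology import load_ontology
from targetrank.scoring import ScoringConfig

# chain: C -> B -> A, with A a therapeutic area
CHAIN_TSV = "EFO_0000003\tEFO_0000002\nEFO_0000002\tEFO_0000001\n"
CHAIN = {"A": "EFO_0000001", "B": "EFO_0000002", "C": "EFO_0000003"}

# diamond: D -> B, D -> C, B -> A, C -> A
DIAMOND_TSV = (
    "EFO_0000014\tEFO_0000012\n"
    "EFO_0000014\tEFO_0000013\n"
    "EFO_0000012\tEFO_0000011\n"
    "EFO_0000013\tEFO_0000011\n"
)
DIAMOND = {"A": "EFO_0000011", "B": "EFO_0000012", "C": "EFO_0000013", "D": "EFO_0000014"}


@pytest.fixture
def chain_graph():
    return load_ontology(CHAIN_TSV, [CHAIN["A"]])


@pytest.fixture
def diamond_graph():
    return load_ontology(DIAMOND_TSV, [DIAMOND["A"]])


@pytest.fixture
def config():
    return ScoringConfig()


def make_record(
    target="ENSG00000157764",
    disease="EFO_0000270",
    source="reactome",
    datatype="affected_pathway",
    **payload,
):
    if not payload:
        payload = {"resource_score": 0.7}
    return EvidenceString(
        target_id=target,
        disease_id=disease,
        datasource_id=source,
        datatype_id=datatype,
        score_payload=payload,
    )


@pytest.fixture
def report_rows():
    """8 report rows violating one filter rule each (plus 4 clean)."""
    rows = [
        # case_id, drug, event, qualification, drug_role, version
        ("c1", "CHEMBL1", "nausea", "1", "PS", 1),
        ("c2", "CHEMBL1", "rash", "2", "PS", 1),
        ("c3", "CHEMBL2", "nausea", "3", "SS", 1),
        ("c4", "CHEMBL2", "headache", "1", "PS", 2),
        ("c5", "CHEMBL1", "rash", "5", "PS", 1),          # rule 1: consumer report
        ("c6", "CHEMBL2", "nausea", "1", "C", 1),          # rule 2: concomitant drug
        ("c4", "CHEMBL2", "rash", "1", "PS", 1),           # rule 3: stale version of c4
        ("c7", "CHEMBL1", "drug ineffective", "1", "PS", 1),  # rule 4: blacklisted event
    ]
    return pd.DataFrame(
        rows, columns=["case_id", "drug", "event", "qualification", "drug_role", "version"]
    )
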