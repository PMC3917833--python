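"""Shared fixtures: small hand-built databases and the planted-pair fixture."""

from __future__ import annotations

import pytest

from eukprimer.database_io import AlignedDatabase, Record
from eukprimer.fixtures import design_recovery_spec, generate


def make_db(rows, alignment_length=None, source="test"):
    """Build an AlignedDatabase from (id, seq, taxonomy-string) triples."""
    records = [
        Record(rid, seq, tuple(tax.split(";"))) for rid, seq, tax in rows
    ]
    n = alignment_length or len(records[0].seq)
    return AlignedDatabase(records, n, source)


@pytest.fixture(scope="session")
def recovery_fixture():
    """Planted-pair database + ground truth (seed 1), shared read-only."""
    spec = design_recovery_spec(seed=1)
    return generate(spec)


@pytest.fixture
def tiny_db():
    """Three eukaryotes, two bacteria; 12 aligned columns with gaps."""
    return make_db([
        ("e1", "ACGT-ACGTAC-", "Eukaryota;Annelida;C;O;F;Nereis"),
        ("e2", "ACGT-ACGTAC-", "Eukaryota;Annelida;C;O;F;Nereis"),
        ("e3", "ACTT-ACGAAC-", "Eukaryota;Arthropoda;C;O;F;Calanus"),
        ("b1", "AGGT-TCGTAC-", "Bacteria;Proteobacteria;C;O;F;Alteromonas"),
        ("b2", "AGGT-TCGTAC-", "Bacteria;Proteobacteria;C;O;F;Alteromonas"),
    ])
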