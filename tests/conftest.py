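import pytest

from termikit.kb import (
    CleavageEvent,
    InhibitionEvent,
    Knowledgebase,
    Protein,
    TerminusEvidence,
)
from termikit.synth import SynthParams, generate_kb

SEQ = "MKVLATTPRSQEWFDNGHIYCAKVLMNPERSTWQDFGHIKLYACDEFGHIK" \
      "LMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def tiny_kb():
    """Three proteins — a protease, an inhibitor and a substrate — with one
    cleavage and one inhibition."""
    proteins = [
        Protein("PROT1", "protease one", "human", SEQ),
        Protein("INHI1", "inhibitor one", "human", SEQ[::-1]),
        Protein("SUBS1", "substrate one", "human", SEQ[10:] + SEQ[:10]),
    ]
    termini = [
        TerminusEvidence("PROT1", "N", 1, "canonical", "curated"),
        TerminusEvidence("SUBS1", "N", 1, "canonical", "curated"),
        TerminusEvidence("SUBS1", "C", len(SEQ), "canonical", "curated"),
    ]
    return Knowledgebase(
        proteins=proteins,
        termini=termini,
        cleavages=[CleavageEvent("PROT1", "SUBS1", 50, "assay", "human")],
        inhibitions=[InhibitionEvent("INHI1", "PROT1", "assay")],
    )


@pytest.fixture(scope="session")
def synth_kb():
    return generate_kb(SynthParams(seed=42))
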