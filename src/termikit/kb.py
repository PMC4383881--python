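"""Flat-file knowledgebase of proteins, termini, cleavages and inhibitions.

The knowledgebase is a directory of six tab-separated tables plus one FASTA
file of protein sequences::

    proteins.tsv     accession  name  species  is_canonical  parent_accession
    features.tsv     protein_accession  kind  start  end  description
    termini.tsv      protein_accession  terminus_type  position  category
                     source_id  confidence
    cleavages.tsv    protease_accession  substrate_accession  p1_position
                     evidence_source  species
    inhibitions.tsv  inhibitor_accession  protease_accession  evidence_source
    orthologs.tsv    accession_a  species_a  accession_b  species_b  score
    sequences.fasta  one record per protein, id = accession

All residue positions are 1-based on the protein sequence.  A cleavage is
identified by the index of its P1 residue: the scissile bond lies between
``p1`` and ``p1 + 1``, so the neo-N-terminus created by the cleavage sits at
``p1 + 1`` and the neo-C-terminus at ``p1``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Protein",
    "Feature",
    "TerminusEvidence",
    "CleavageEvent",
    "InhibitionEvent",
    "OrthologPair",
    "Knowledgebase",
    "Violation",
    "KBError",
    "KBFormatError",
    "KBValidationError",
    "load_kb",
    "write_kb",
    "validate_kb",
    "TERMINUS_CATEGORIES",
    "FEATURE_KINDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

TERMINUS_CATEGORIES = (
    "canonical",
    "alt_splicing",
    "alt_translation",
    "cleavage",
    "experimental",
    "isoform_inferred",
)
FEATURE_KINDS = (
    "domain",
    "signal_peptide",
    "transit_peptide",
    "chain",
    "site",
    "modification",
)


class KBError(Exception):
    """Base class for knowledgebase errors."""


class KBFormatError(KBError):
    """A dialect file is missing or structurally malformed."""


class KBValidationError(KBError):
    """The loaded data violates referential-integrity rules."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        lines = "; ".join(str(v) for v in violations[:10])
        more = f" (+{len(violations) - 10} more)" if len(violations) > 10 else ""
        super().__init__(f"{len(violations)} violation(s): {lines}{more}")


@dataclass(frozen=True)
class Protein:
    accession: str
    name: str
    species: str
    sequence: str
    is_canonical: bool = True
    parent_accession: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Feature:
    protein_accession: str
    kind: str
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    description: str = ""


@dataclass(frozen=True)
class TerminusEvidence:
    protein_accession: str
    terminus_type: str  # "N" or "C"
    position: int  # 1-based index of the terminal residue
    category: str
    source_id: str = ""
    confidence: Optional[float] = None

    @property
    def key(self) -> str:
        """Stable identity used by isoform-inferred entries to reference
        their source (stored in the inferred entry's ``source_id``)."""
        return (
            f"{self.protein_accession}|{self.terminus_type}|"
            f"{self.position}|{self.category}|{self.source_id}"
        )


@dataclass(frozen=True)
class CleavageEvent:
    protease_accession: str
    substrate_accession: str
    p1_position: int
    evidence_source: str = ""
    species: str = "human"

    @property
    def site(self) -> tuple[str, int]:
        return (self.substrate_accession, self.p1_position)


@dataclass(frozen=True)
class InhibitionEvent:
    inhibitor_accession: str
    protease_accession: str
    evidence_source: str = ""


@dataclass(frozen=True)
class OrthologPair:
    accession_a: str
    species_a: str
    accession_b: str
    species_b: str
    score: Optional[float] = None


@dataclass(frozen=True)
class Violation:
    entity: str  # e.g. "cleavage[P1→P2@10]"
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.entity}.{self.field}: {self.rule}"


@dataclass
class Knowledgebase:
    proteins: list[Protein] = field(default_factory=list)
    features: list[Feature] = field(default_factory=list)
    termini: list[TerminusEvidence] = field(default_factory=list)
    cleavages: list[CleavageEvent] = field(default_factory=list)
    inhibitions: list[InhibitionEvent] = field(default_factory=list)
    orthologs: list[OrthologPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self._by_accession = {p.accession: p for p in self.proteins}
        self._evidence_by_key = {t.key: t for t in self.termini}

    def reindex(self) -> None:
        """Rebuild lookup indices after in-place mutation of the lists."""
        self._index()

    def protein(self, accession: str) -> Optional[Protein]:
        return self._by_accession.get(accession)

    def evidence(self, key: str) -> Optional[TerminusEvidence]:
        return self._evidence_by_key.get(key)

    def isoform_family(self, accession: str) -> list[Protein]:
        """All proteins sharing a canonical parent with ``accession``
        (the canonical entry plus every isoform), excluding itself."""
        prot = self.protein(accession)
        if prot is None:
            return []
        root = accession if prot.is_canonical else prot.parent_accession
        members = [
            p
            for p in self.proteins
            if p.accession == root or p.parent_accession == root
        ]
        return [p for p in members if p.accession != accession]

    def features_of(self, accession: str) -> list[Feature]:
        return [f for f in self.features if f.protein_accession == accession]

    def termini_of(self, accession: str) -> list[TerminusEvidence]:
        return [t for t in self.termini if t.protein_accession == accession]

    def cleavages_of_substrate(self, accession: str) -> list[CleavageEvent]:
        return [c for c in self.cleavages if c.substrate_accession == accession]


# ---------------------------------------------------------------------------
# validation

def _check_position(pos: int, lo: int, hi: int) -> bool:
    return lo <= pos <= hi


def validate_kb(kb: Knowledgebase) -> list[Violation]:
    """Check every referential-integrity rule; violations are returned as
    data, never raised.  An empty list means the knowledgebase is
    well-formed."""
    out: list[Violation] = []
    seen: set[str] = set()
    by_acc = {p.accession: p for p in kb.proteins}

    for p in kb.proteins:
        ent = f"protein[{p.accession}]"
        if p.accession in seen:
            out.append(Violation(ent, "accession", "duplicate accession"))
        seen.add(p.accession)
        if len(p.sequence) < 1:
            out.append(Violation(ent, "sequence", "sequence length must be >= 1"))
        bad = set(p.sequence) - _VALID_RESIDUES
        if bad:
            out.append(
                Violation(ent, "sequence", f"invalid residues {sorted(bad)}")
            )
        if not p.is_canonical:
            parent = by_acc.get(p.parent_accession or "")
            if parent is None:
                out.append(
                    Violation(ent, "parent_accession",
                              "isoform must name an existing canonical parent")
                )
            elif not parent.is_canonical:
                out.append(
                    Violation(ent, "parent_accession",
                              f"parent {parent.accession} is not canonical")
                )

    for f in kb.features:
        ent = f"feature[{f.protein_accession}:{f.kind}@{f.start}-{f.end}]"
        prot = by_acc.get(f.protein_accession)
        if prot is None:
            out.append(Violation(ent, "protein_accession", "unknown protein"))
            continue
        if not (1 <= f.start <= f.end <= prot.length):
            out.append(
                Violation(ent, "start/end",
                          f"must satisfy 1 <= start <= end <= {prot.length}")
            )

    keys = {t.key for t in kb.termini}
    for t in kb.termini:
        ent = f"terminus[{t.protein_accession}:{t.terminus_type}@{t.position}]"
        prot = by_acc.get(t.protein_accession)
        if prot is None:
            out.append(Violation(ent, "protein_accession", "unknown protein"))
            continue
        if t.terminus_type not in ("N", "C"):
            out.append(Violation(ent, "terminus_type", "must be N or C"))
        if not _check_position(t.position, 1, prot.length):
            out.append(
                Violation(ent, "position",
                          f"must satisfy 1 <= position <= {prot.length}")
            )
        if t.category not in TERMINUS_CATEGORIES:
            out.append(Violation(ent, "category", f"unknown category {t.category!r}"))
        if t.category == "isoform_inferred" and t.source_id not in keys:
            out.append(
                Violation(ent, "source_id",
                          "isoform_inferred evidence must reference a source evidence")
            )
        if t.confidence is not None and not (0.0 <= t.confidence <= 1.0):
            out.append(Violation(ent, "confidence", "must lie in [0, 1]"))

    for c in kb.cleavages:
        ent = (
            f"cleavage[{c.protease_accession}→{c.substrate_accession}"
            f"@{c.p1_position}]"
        )
        if c.protease_accession not in by_acc:
            out.append(Violation(ent, "protease_accession", "unknown protein"))
        sub = by_acc.get(c.substrate_accession)
        if sub is None:
            out.append(Violation(ent, "substrate_accession", "unknown protein"))
            continue
        if not _check_position(c.p1_position, 1, sub.length - 1):
            out.append(
                Violation(ent, "p1_position",
                          f"must satisfy 1 <= p1 <= {sub.length - 1} "
                          "(bond lies between p1 and p1+1)")
            )

    for i in kb.inhibitions:
        ent = f"inhibition[{i.inhibitor_accession}⊣{i.protease_accession}]"
        if i.inhibitor_accession not in by_acc:
            out.append(Violation(ent, "inhibitor_accession", "unknown protein"))
        if i.protease_accession not in by_acc:
            out.append(Violation(ent, "protease_accession", "unknown protein"))
        if i.inhibitor_accession == i.protease_accession:
            out.append(Violation(ent, "inhibitor_accession", "self-inhibition rejected"))

    for o in kb.orthologs:
        ent = f"ortholog[{o.accession_a}↔{o.accession_b}]"
        if o.species_a == o.species_b:
            out.append(Violation(ent, "species_b", "species must differ"))

    return out


# ---------------------------------------------------------------------------
# dialect I/O

_TABLES = {
    "proteins.tsv": ["accession", "name", "species", "is_canonical", "parent_accession"],
    "features.tsv": ["protein_accession", "kind", "start", "end", "description"],
    "termini.tsv": ["protein_accession", "terminus_type", "position", "category",
                    "source_id", "confidence"],
    "cleavages.tsv": ["protease_accession", "substrate_accession", "p1_position",
                      "evidence_source", "species"],
    "inhibitions.tsv": ["inhibitor_accession", "protease_accession", "evidence_source"],
    "orthologs.tsv": ["accession_a", "species_a", "accession_b", "species_b", "score"],
}


def _read_table(directory: Path, name: str) -> pd.DataFrame:
    path = directory / name
    if not path.is_file():
        raise KBFormatError(f"missing table: {name}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = _TABLES[name]
    if list(df.columns) != expected:
        raise KBFormatError(
            f"{name}: expected columns {expected}, found {list(df.columns)}"
        )
    return df


def _int_field(value: str, table: str, row: int, field_name: str) -> int:
    try:
        return int(value)
    except ValueError:
        # +2: header line plus 1-based numbering
        raise KBFormatError(
            f"{table} line {row + 2}: {field_name}={value!r} is not an integer"
        ) from None


def load_kb(directory_path: os.PathLike | str,
            min_confidence: Optional[float] = None) -> Knowledgebase:
    """Load and validate a knowledgebase directory.

    Duplicate (protease, substrate, p1) cleavage tuples are collapsed on
    load.  ``min_confidence`` drops terminus evidences whose confidence is
    recorded and falls below the threshold.  Raises
    :class:`KBValidationError` when referential integrity fails.
    """
    directory = Path(directory_path)
    fasta = directory / "sequences.fasta"
    if not fasta.is_file():
        raise KBFormatError("missing table: sequences.fasta")
    sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}

    dfp = _read_table(directory, "proteins.tsv")
    proteins = []
    for i, row in enumerate(dfp.itertuples(index=False)):
        seq = sequences.get(row.accession)
        if seq is None:
            raise KBFormatError(
                f"proteins.tsv line {i + 2}: accession {row.accession!r} "
                "has no record in sequences.fasta"
            )
        proteins.append(
            Protein(
                accession=row.accession,
                name=row.name,
                species=row.species,
                sequence=seq,
                is_canonical=row.is_canonical.lower() in ("true", "1", "yes"),
                parent_accession=row.parent_accession or None,
            )
        )

    dff = _read_table(directory, "features.tsv")
    features = [
        Feature(
            protein_accession=row.protein_accession,
            kind=row.kind,
            start=_int_field(row.start, "features.tsv", i, "start"),
            end=_int_field(row.end, "features.tsv", i, "end"),
            description=row.description,
        )
        for i, row in enumerate(dff.itertuples(index=False))
    ]

    dft = _read_table(directory, "termini.tsv")
    termini = []
    for i, row in enumerate(dft.itertuples(index=False)):
        conf = float(row.confidence) if row.confidence else None
        if min_confidence is not None and conf is not None and conf < min_confidence:
            continue
        termini.append(
            TerminusEvidence(
                protein_accession=row.protein_accession,
                terminus_type=row.terminus_type,
                position=_int_field(row.position, "termini.tsv", i, "position"),
                category=row.category,
                source_id=row.source_id,
                confidence=conf,
            )
        )

    dfc = _read_table(directory, "cleavages.tsv")
    cleavages: list[CleavageEvent] = []
    seen_cleavage: set[tuple[str, str, int]] = set()
    for i, row in enumerate(dfc.itertuples(index=False)):
        ev = CleavageEvent(
            protease_accession=row.protease_accession,
            substrate_accession=row.substrate_accession,
            p1_position=_int_field(row.p1_position, "cleavages.tsv", i, "p1_position"),
            evidence_source=row.evidence_source,
            species=row.species,
        )
        tup = (ev.protease_accession, ev.substrate_accession, ev.p1_position)
        if tup in seen_cleavage:
            continue
        seen_cleavage.add(tup)
        cleavages.append(ev)

    dfi = _read_table(directory, "inhibitions.tsv")
    inhibitions = [
        InhibitionEvent(
            inhibitor_accession=row.inhibitor_accession,
            protease_accession=row.protease_accession,
            evidence_source=row.evidence_source,
        )
        for row in dfi.itertuples(index=False)
    ]

    dfo = _read_table(directory, "orthologs.tsv")
    orthologs = [
        OrthologPair(
            accession_a=row.accession_a,
            species_a=row.species_a,
            accession_b=row.accession_b,
            species_b=row.species_b,
            score=float(row.score) if row.score else None,
        )
        for row in dfo.itertuples(index=False)
    ]

    kb = Knowledgebase(
        proteins=proteins,
        features=features,
        termini=termini,
        cleavages=cleavages,
        inhibitions=inhibitions,
        orthologs=orthologs,
    )
    violations = validate_kb(kb)
    if violations:
        raise KBValidationError(violations)
    return kb


def write_kb(kb: Knowledgebase, directory_path: os.PathLike | str) -> None:
    """Write a knowledgebase to a dialect directory.

    ``load_kb(write_kb(kb))`` is the identity up to row order; rows are
    emitted in a deterministic sorted order.
    """
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)

    def dump(name: str, rows: list[dict]) -> None:
        df = pd.DataFrame(rows, columns=_TABLES[name])
        df.to_csv(directory / name, sep="\t", index=False)

    dump("proteins.tsv", [
        {
            "accession": p.accession,
            "name": p.name,
            "species": p.species,
            "is_canonical": str(p.is_canonical).lower(),
            "parent_accession": p.parent_accession or "",
        }
        for p in sorted(kb.proteins, key=lambda p: p.accession)
    ])
    dump("features.tsv", [
        {
            "protein_accession": f.protein_accession,
            "kind": f.kind,
            "start": f.start,
            "end": f.end,
            "description": f.description,
        }
        for f in sorted(kb.features,
                        key=lambda f: (f.protein_accession, f.start, f.end, f.kind))
    ])
    dump("termini.tsv", [
        {
            "protein_accession": t.protein_accession,
            "terminus_type": t.terminus_type,
            "position": t.position,
            "category": t.category,
            "source_id": t.source_id,
            "confidence": "" if t.confidence is None else repr(t.confidence),
        }
        for t in sorted(kb.termini,
                        key=lambda t: (t.protein_accession, t.terminus_type,
                                       t.position, t.category, t.source_id))
    ])
    dump("cleavages.tsv", [
        {
            "protease_accession": c.protease_accession,
            "substrate_accession": c.substrate_accession,
            "p1_position": c.p1_position,
            "evidence_source": c.evidence_source,
            "species": c.species,
        }
        for c in sorted(kb.cleavages,
                        key=lambda c: (c.protease_accession,
                                       c.substrate_accession, c.p1_position))
    ])
    dump("inhibitions.tsv", [
        {
            "inhibitor_accession": i.inhibitor_accession,
            "protease_accession": i.protease_accession,
            "evidence_source": i.evidence_source,
        }
        for i in sorted(kb.inhibitions,
                        key=lambda i: (i.inhibitor_accession, i.protease_accession))
    ])
    dump("orthologs.tsv", [
        {
            "accession_a": o.accession_a,
            "species_a": o.species_a,
            "accession_b": o.accession_b,
            "species_b": o.species_b,
            "score": "" if o.score is None else repr(o.score),
        }
        for o in sorted(kb.orthologs,
                        key=lambda o: (o.accession_a, o.accession_b))
    ])

    records = [
        SeqRecord(Seq(p.sequence), id=p.accession, description="")
        for p in sorted(kb.proteins, key=lambda p: p.accession)
    ]
    SeqIO.write(records, str(directory / "sequences.fasta"), "fasta")
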