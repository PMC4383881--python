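"""Mapping termini and cleavages between protein sequences.

Entries are transferred between sequences (transcript products onto the
canonical entry, canonical entries onto isoforms and back) by exact
alignment of a local sequence context of up to 20 residues: the 20 residues
following an N-terminus, preceding a C-terminus, or surrounding a cleavage
site (10 on each side of the scissile bond), truncated at protein ends.
An entry maps only when its context occurs exactly once in the target
sequence; multiple matches are ambiguous and skipped, as is any context
shorter than ``MIN_WINDOW`` residues.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

from Bio.Seq import Seq

from .kb import CleavageEvent, Knowledgebase, Protein, TerminusEvidence

__all__ = [
    "ContextWindow",
    "MappingRecord",
    "PropagationResult",
    "match_context",
    "terminus_context",
    "cleavage_context",
    "map_transcript_termini",
    "map_tis_n_terminus",
    "propagate_across_isoforms",
    "translate_cds",
    "MIN_WINDOW",
    "CONTEXT_SPAN",
]

CONTEXT_SPAN = 20  # residues of context per entry
MIN_WINDOW = 8  # contexts shorter than this are too prone to spurious matches


@dataclass(frozen=True)
class ContextWindow:
    """A local sequence context and where its anchor sits inside it.

    ``anchor`` names what the window localizes; ``anchor_offset`` is the
    0-based index inside ``residues`` of the anchor residue (the terminal
    residue for termini, the P1 residue for cleavages).
    """

    residues: str
    anchor: str  # follows_N_terminus | precedes_C_terminus | surrounds_cleavage
    anchor_offset: int

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MappingRecord:
    """One line of the mapping report."""

    entry: str
    target_accession: str
    status: str  # mapped | ambiguous | unmapped | window_too_short
    position: Optional[int] = None


@dataclass(frozen=True)
class PropagationResult:
    kb: Knowledgebase
    report: list[MappingRecord]

    @property
    def mapped(self) -> list[MappingRecord]:
        return [r for r in self.report if r.status == "mapped"]


def match_context(window: Union[ContextWindow, str], target_sequence: str) -> list[int]:
    """Every 1-based start index at which the window occurs verbatim in the
    target, ascending; overlapping occurrences included.  Exact string
    matching — no mismatches, no gaps."""
    pattern = window.residues if isinstance(window, ContextWindow) else window
    if not pattern:
        raise ValueError("context window must be non-empty")
    hits = []
    start = target_sequence.find(pattern)
    while start != -1:
        hits.append(start + 1)
        start = target_sequence.find(pattern, start + 1)
    return hits


def terminus_context(sequence: str, terminus_type: str, position: int,
                     span: int = CONTEXT_SPAN) -> ContextWindow:
    """Context of a terminus: the ``span`` residues starting at an
    N-terminus or ending at a C-terminus (anchored on the terminal residue),
    truncated at the protein end."""
    i = position - 1
    if terminus_type == "N":
        return ContextWindow(sequence[i:i + span], "follows_N_terminus", 0)
    lo = max(0, i - span + 1)
    return ContextWindow(sequence[lo:i + 1], "precedes_C_terminus", i - lo)


def cleavage_context(sequence: str, p1_position: int,
                     half_span: int = CONTEXT_SPAN // 2) -> ContextWindow:
    """Context of a cleavage: ``half_span`` residues on each side of the
    scissile bond (P1 at the end of the left half), truncated at protein
    ends."""
    lo = max(0, p1_position - half_span)
    residues = sequence[lo:p1_position + half_span]
    return ContextWindow(residues, "surrounds_cleavage", p1_position - 1 - lo)


def _map_window(window: ContextWindow, target: str):
    """(status, anchor position on target or None)."""
    if len(window) < MIN_WINDOW:
        return "window_too_short", None
    hits = match_context(window, target)
    if not hits:
        return "unmapped", None
    if len(hits) > 1:
        return "ambiguous", None
    return "mapped", hits[0] + window.anchor_offset


# ---------------------------------------------------------------------------
# transcript- and translation-initiation-derived termini

def map_transcript_termini(
    transcript_protein_sequence: str,
    canonical_sequence: str,
    accession: str = "",
    source_id: str = "transcript",
) -> tuple[list[TerminusEvidence], list[MappingRecord]]:
    """Locate the termini of a transcript-encoded protein product on the
    canonical sequence.

    The first ``CONTEXT_SPAN`` residues of the product are matched to emit
    an N-terminus evidence (category ``alt_splicing``) at the unique match
    position; the last ``CONTEXT_SPAN`` residues likewise yield a C-terminus
    evidence at the position where the match ends.  Ambiguous or absent
    contexts produce diagnostics instead of evidences.
    """
    if not transcript_protein_sequence or not canonical_sequence:
        raise ValueError("sequences must be non-empty")
    evidences: list[TerminusEvidence] = []
    report: list[MappingRecord] = []

    n_window = terminus_context(transcript_protein_sequence, "N", 1)
    status, pos = _map_window(n_window, canonical_sequence)
    if status == "mapped":
        evidences.append(TerminusEvidence(accession, "N", pos,
                                          "alt_splicing", source_id))
    report.append(MappingRecord("transcript:N", accession, status, pos))

    c_window = terminus_context(transcript_protein_sequence, "C",
                                len(transcript_protein_sequence))
    status, pos = _map_window(c_window, canonical_sequence)
    if status == "mapped":
        evidences.append(TerminusEvidence(accession, "C", pos,
                                          "alt_splicing", source_id))
    report.append(MappingRecord("transcript:C", accession, status, pos))
    return evidences, report


def map_tis_n_terminus(
    translated_window: str,
    canonical_sequence: str,
    accession: str = "",
    source_id: str = "tis",
) -> Union[TerminusEvidence, MappingRecord]:
    """Locate an N-terminus implied by an alternative translation-initiation
    site.

    ``translated_window`` is the first ≤20 residues of the in-silico
    translation starting at the reported initiation codon.  A unique match
    yields an N-terminus evidence of category ``alt_translation``; otherwise
    a diagnostic record is returned.
    """
    if not translated_window:
        raise ValueError("translated window must be non-empty")
    window = ContextWindow(translated_window[:CONTEXT_SPAN], "follows_N_terminus", 0)
    status, pos = _map_window(window, canonical_sequence)
    if status == "mapped":
        return TerminusEvidence(accession, "N", pos, "alt_translation", source_id)
    return MappingRecord("tis:N", accession, status, pos)


def translate_cds(coding_sequence: str, span: int = CONTEXT_SPAN) -> str:
    """Translate a coding nucleotide sequence (standard genetic code) and
    return the first ``span`` residues, stopping at the first stop codon."""
    protein = str(Seq(coding_sequence).translate(to_stop=True))
    return protein[:span]


# ---------------------------------------------------------------------------
# isoform propagation

def propagate_across_isoforms(kb: Knowledgebase) -> PropagationResult:
    """Map every terminus evidence and cleavage onto the other members of
    its isoform family (canonical ↔ isoforms, in both directions).

    Each successfully mapped entry is added with category
    ``isoform_inferred`` and a ``source_id`` referencing the original
    evidence; cleavages carry the provenance in ``evidence_source``.
    Entries whose context is ambiguous, absent or too short on a target are
    skipped and counted in the report.  The operation is idempotent:
    inferred entries are never re-propagated and duplicates are never
    added.
    """
    new_termini = list(kb.termini)
    new_cleavages = list(kb.cleavages)
    existing_t = {(t.protein_accession, t.terminus_type, t.position,
                   t.category, t.source_id) for t in kb.termini}
    existing_c = {(c.protease_accession, c.substrate_accession, c.p1_position)
                  for c in kb.cleavages}
    report: list[MappingRecord] = []

    for t in kb.termini:
        if t.category == "isoform_inferred":
            continue
        source = kb.protein(t.protein_accession)
        if source is None:
            continue
        window = terminus_context(source.sequence, t.terminus_type, t.position)
        for target in kb.isoform_family(t.protein_accession):
            status, pos = _map_window(window, target.sequence)
            report.append(MappingRecord(t.key, target.accession, status, pos))
            if status != "mapped":
                continue
            entry = (target.accession, t.terminus_type, pos,
                     "isoform_inferred", t.key)
            if entry in existing_t:
                continue
            existing_t.add(entry)
            new_termini.append(TerminusEvidence(
                target.accession, t.terminus_type, pos,
                "isoform_inferred", t.key, t.confidence))

    for c in kb.cleavages:
        if c.evidence_source.startswith("isoform_inferred:"):
            continue
        source = kb.protein(c.substrate_accession)
        if source is None:
            continue
        window = cleavage_context(source.sequence, c.p1_position)
        origin = f"{c.protease_accession}|{c.substrate_accession}|{c.p1_position}"
        for target in kb.isoform_family(c.substrate_accession):
            status, pos = _map_window(window, target.sequence)
            report.append(MappingRecord(f"cleavage:{origin}",
                                        target.accession, status, pos))
            if status != "mapped":
                continue
            tup = (c.protease_accession, target.accession, pos)
            if tup in existing_c:
                continue
            existing_c.add(tup)
            new_cleavages.append(CleavageEvent(
                c.protease_accession, target.accession, pos,
                f"isoform_inferred:{origin}", c.species))

    new_kb = Knowledgebase(
        proteins=list(kb.proteins),
        features=list(kb.features),
        termini=new_termini,
        cleavages=new_cleavages,
        inhibitions=list(kb.inhibitions),
        orthologs=list(kb.orthologs),
    )
    return PropagationResult(new_kb, report)
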