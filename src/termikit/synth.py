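"""Synthetic knowledgebases and query lists with controlled structure.

The generator emulates the shape of a curated terminus/cleavage resource:
proteins (a subset of which act as proteases or protease inhibitors),
isoforms derived from canonical sequences by a single internal indel,
terminus evidences of every origin category, protease→substrate cleavage
events with some sites shared between two proteases (CASP3/CASP7-style
redundancy), and inhibitor→protease inhibition edges.  Query lists of
terminal peptides can then be drawn with a planted over-represented
protease, giving every downstream statistic a known ground truth.

All randomness flows through an integer seed via numpy's PCG64 generator,
so a fixed seed yields a byte-identical serialized knowledgebase on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kb import (
    AMINO_ACIDS,
    CleavageEvent,
    Feature,
    InhibitionEvent,
    Knowledgebase,
    Protein,
    TerminusEvidence,
)
from .analysis import QueryPeptide

__all__ = ["SynthParams", "PlantedSignal", "generate_kb", "generate_query_list"]


class SynthParameterError(ValueError):
    """Raised for infeasible generator parameter combinations."""


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic knowledgebase.

    Defaults describe a small but structurally complete resource: 100
    proteins of mean length 300 residues, 10 of them proteases each holding
    roughly an equal (~10%) share of the 200 cleavage events, 5 inhibitors,
    and isoforms for about a quarter of canonical entries.
    """

    n_proteins: int = 100
    n_proteases: int = 10
    n_inhibitors: int = 5
    mean_protein_length: int = 300
    n_cleavages: int = 200
    n_inhibitions: int = 10
    n_features_per_protein: int = 2
    isoform_rate: float = 0.25
    indel_length_range: tuple[int, int] = (1, 15)
    shared_site_rate: float = 0.1
    extra_evidence_rate: float = 0.1
    species: str = "mouse"
    residue_frequencies: Optional[Sequence[float]] = None
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_proteins, self.n_proteases, self.n_inhibitors,
               self.n_cleavages, self.n_inhibitions) < 0:
            raise SynthParameterError("counts must be non-negative")
        if self.n_proteases + self.n_inhibitors > self.n_proteins:
            raise SynthParameterError(
                "n_proteases + n_inhibitors must not exceed n_proteins")
        if not (0.0 <= self.isoform_rate <= 1.0):
            raise SynthParameterError("isoform_rate must lie in [0, 1]")
        if self.n_cleavages > 0 and self.n_proteases == 0:
            raise SynthParameterError("cleavages require at least one protease")
        if self.n_inhibitions > 0 and (self.n_inhibitors == 0 or self.n_proteases == 0):
            raise SynthParameterError("inhibitions require inhibitors and proteases")
        lo, hi = self.indel_length_range
        if not (1 <= lo <= hi):
            raise SynthParameterError("indel_length_range must satisfy 1 <= lo <= hi")
        if self.residue_frequencies is not None:
            freqs = np.asarray(self.residue_frequencies, dtype=float)
            if freqs.shape != (20,) or freqs.min() < 0 or not np.isclose(freqs.sum(), 1.0):
                raise SynthParameterError(
                    "residue_frequencies must be 20 non-negative values summing to 1")


@dataclass(frozen=True)
class PlantedSignal:
    """A query list with a known over-represented protease.

    ``fraction_from_protease`` of the peptides are 10-residue windows
    starting at P1+1 of randomly chosen cleavage sites of the planted
    protease; the rest are canonical protein starts or random internal
    positions.  ``ragging_jitter`` shifts planted starts by a uniform
    offset in [-j, +j], emulating exopeptidase trimming.
    """

    protease_accession: str
    list_size: int = 100
    fraction_from_protease: float = 0.5
    ragging_jitter: int = 0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.fraction_from_protease <= 1.0):
            raise SynthParameterError("fraction_from_protease must lie in [0, 1]")
        if self.list_size < 0:
            raise SynthParameterError("list_size must be non-negative")
        if self.ragging_jitter < 0:
            raise SynthParameterError("ragging_jitter must be non-negative")


def _random_sequence(rng: np.random.Generator, length: int,
                     freqs: Optional[np.ndarray]) -> str:
    residues = rng.choice(list(AMINO_ACIDS), size=length, p=freqs)
    return "".join(residues)


# isoform indels stay >= this many residues from both termini so that 20-aa
# terminal and cleavage context windows remain unambiguous
_INDEL_MARGIN = 25


def generate_kb(params: SynthParams) -> Knowledgebase:
    """Generate a validated knowledgebase from ``params``.

    Accession scheme: proteases ``PR0001``.., inhibitors ``IN0001``..,
    other substrates ``SB0001``..; isoforms append ``-2``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    freqs = (np.asarray(params.residue_frequencies, dtype=float)
             if params.residue_frequencies is not None else None)

    accessions: list[str] = []
    for i in range(params.n_proteases):
        accessions.append(f"PR{i + 1:04d}")
    for i in range(params.n_inhibitors):
        accessions.append(f"IN{i + 1:04d}")
    for i in range(params.n_proteins - params.n_proteases - params.n_inhibitors):
        accessions.append(f"SB{i + 1:04d}")

    min_len = max(60, 2 * _INDEL_MARGIN + params.indel_length_range[1] + 10)
    proteins: list[Protein] = []
    termini: list[TerminusEvidence] = []
    features: list[Feature] = []
    for acc in accessions:
        length = int(max(min_len, rng.normal(params.mean_protein_length,
                                             params.mean_protein_length * 0.2)))
        seq = _random_sequence(rng, length, freqs)
        proteins.append(Protein(accession=acc, name=f"protein {acc}",
                                species=params.species, sequence=seq))
        termini.append(TerminusEvidence(acc, "N", 1, "canonical", "synthetic"))
        termini.append(TerminusEvidence(acc, "C", length, "canonical", "synthetic"))
        for _ in range(params.n_features_per_protein):
            start = int(rng.integers(1, length))
            end = int(min(length, start + rng.integers(10, 60)))
            features.append(Feature(acc, "domain", start, end, "synthetic domain"))

    # isoforms: one internal indel per isoform, placed away from the termini
    lo, hi = params.indel_length_range
    isoforms: list[Protein] = []
    for prot in list(proteins):
        if rng.random() >= params.isoform_rate:
            continue
        indel_len = int(rng.integers(lo, hi + 1))
        deletion = bool(rng.random() < 0.5)
        max_pos = prot.length - _INDEL_MARGIN - (indel_len if deletion else 0)
        if max_pos <= _INDEL_MARGIN:
            continue
        pos = int(rng.integers(_INDEL_MARGIN, max_pos))  # 0-based offset
        if deletion:
            iso_seq = prot.sequence[:pos] + prot.sequence[pos + indel_len:]
        else:
            insert = _random_sequence(rng, indel_len, freqs)
            iso_seq = prot.sequence[:pos] + insert + prot.sequence[pos:]
        iso_acc = f"{prot.accession}-2"
        isoforms.append(Protein(accession=iso_acc, name=f"{prot.name} isoform 2",
                                species=params.species, sequence=iso_seq,
                                is_canonical=False, parent_accession=prot.accession))
        termini.append(TerminusEvidence(iso_acc, "N", 1, "canonical", "synthetic"))
        termini.append(TerminusEvidence(iso_acc, "C", len(iso_seq),
                                        "canonical", "synthetic"))
    proteins.extend(isoforms)

    protease_accs = accessions[:params.n_proteases]
    substrate_pool = [p for p in proteins
                      if p.is_canonical and p.accession not in protease_accs]
    if not substrate_pool and params.n_cleavages > 0:
        raise SynthParameterError("no substrates available for cleavages")

    # feasibility: distinct (protease, substrate, p1) tuples available
    if params.n_cleavages > 0:
        margin = _INDEL_MARGIN
        capacity = sum(max(0, p.length - 2 * margin) for p in substrate_pool)
        capacity *= max(1, params.n_proteases)
        if params.n_cleavages > capacity:
            raise SynthParameterError(
                f"n_cleavages={params.n_cleavages} exceeds the "
                f"{capacity} distinct sites available")

    cleavages: list[CleavageEvent] = []
    tuples: set[tuple[str, str, int]] = set()
    sites: list[tuple[str, int, str]] = []  # (substrate, p1, protease)
    attempts = 0
    while len(tuples) < params.n_cleavages:
        attempts += 1
        if attempts > 100 * params.n_cleavages + 1000:
            raise SynthParameterError("could not place the requested cleavages")
        if sites and rng.random() < params.shared_site_rate and params.n_proteases > 1:
            # attribute an existing site to a second protease
            sub_acc, p1, old_prot = sites[int(rng.integers(len(sites)))]
            protease = protease_accs[int(rng.integers(params.n_proteases))]
            if protease == old_prot:
                continue
        else:
            sub = substrate_pool[int(rng.integers(len(substrate_pool)))]
            sub_acc = sub.accession
            p1 = int(rng.integers(_INDEL_MARGIN, sub.length - _INDEL_MARGIN))
            protease = protease_accs[int(rng.integers(params.n_proteases))]
        tup = (protease, sub_acc, p1)
        if tup in tuples:
            continue
        tuples.add(tup)
        sites.append((sub_acc, p1, protease))
        cleavages.append(CleavageEvent(protease, sub_acc, p1,
                                       "synthetic", params.species))
        # evidence of the neo-N-terminus the cleavage creates
        if rng.random() < params.extra_evidence_rate:
            termini.append(TerminusEvidence(sub_acc, "N", p1 + 1,
                                            "cleavage", f"cleavage:{protease}"))

    # sprinkle non-canonical terminus evidences of the remaining categories
    for prot in proteins:
        if not prot.is_canonical:
            continue
        for category in ("experimental", "alt_splicing", "alt_translation"):
            if rng.random() < params.extra_evidence_rate:
                pos = int(rng.integers(2, prot.length))
                ttype = "N" if category == "alt_translation" else \
                    ("N" if rng.random() < 0.5 else "C")
                termini.append(TerminusEvidence(prot.accession, ttype, pos,
                                                category, "synthetic"))

    inhibitor_accs = accessions[params.n_proteases:
                                params.n_proteases + params.n_inhibitors]
    inhibitions: list[InhibitionEvent] = []
    pairs: set[tuple[str, str]] = set()
    attempts = 0
    while len(pairs) < params.n_inhibitions:
        attempts += 1
        if attempts > 100 * params.n_inhibitions + 1000:
            break  # fewer distinct pairs than requested; keep what exists
        inh = inhibitor_accs[int(rng.integers(len(inhibitor_accs)))]
        prot = protease_accs[int(rng.integers(len(protease_accs)))]
        if (inh, prot) in pairs:
            continue
        pairs.add((inh, prot))
        inhibitions.append(InhibitionEvent(inh, prot, "synthetic"))

    return Knowledgebase(proteins=proteins, features=features, termini=termini,
                         cleavages=cleavages, inhibitions=inhibitions)


_PEPTIDE_LEN = 10


def generate_query_list(kb: Knowledgebase, signal: PlantedSignal) -> list[QueryPeptide]:
    """Draw a terminal-peptide query list with a planted protease signal.

    Planted peptides are the 10-residue window starting at P1+1 of a
    randomly chosen cleavage of the planted protease (optionally offset by
    ragging jitter); background peptides are canonical N-terminal starts or
    random internal positions in equal proportion.  Every returned peptide
    occurs verbatim in its protein's sequence.
    """
    signal.validate()
    rng = np.random.default_rng(signal.seed)
    planted_cleavages = [c for c in kb.cleavages
                         if c.protease_accession == signal.protease_accession]
    if not planted_cleavages:
        raise SynthParameterError(
            f"planted protease {signal.protease_accession!r} has no cleavages")
    background_pool = [p for p in kb.proteins
                       if p.is_canonical and p.length > 3 * _PEPTIDE_LEN]

    n_planted = int(round(signal.list_size * signal.fraction_from_protease))
    peptides: list[QueryPeptide] = []
    for i in range(signal.list_size):
        if i < n_planted:
            c = planted_cleavages[int(rng.integers(len(planted_cleavages)))]
            prot = kb.protein(c.substrate_accession)
            start = c.p1_position  # 0-based index of P1+1
            if signal.ragging_jitter:
                start += int(rng.integers(-signal.ragging_jitter,
                                          signal.ragging_jitter + 1))
            start = max(0, min(prot.length - _PEPTIDE_LEN, start))
            label = "planted"
        else:
            prot = background_pool[int(rng.integers(len(background_pool)))]
            if rng.random() < 0.5:
                start = 0
                label = "background_canonical"
            else:
                start = int(rng.integers(1, prot.length - _PEPTIDE_LEN))
                label = "background_internal"
        peptides.append(QueryPeptide(
            protein_accession=prot.accession,
            peptide=prot.sequence[start:start + _PEPTIDE_LEN],
            terminus_type="N",
            quantity=None,
            label=label,
        ))
    return peptides
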