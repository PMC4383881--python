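"""Terminus-list annotation and protease-enrichment analysis.

Given a list of terminal peptides from an N- or C-terminomics experiment
(accession + peptide sequence + terminus type), each peptide is located on
its protein by exact substring search, classified by the origin of its
terminus (canonical start, alternative splicing, alternative translation,
proteolytic cleavage, prior experimental observation), annotated with the
protein features lost and retained in the truncated fragment, and the
responsible proteases are scored for over-representation.

Enrichment model
----------------
For each identified protease the 2×2 table ``[[k, n−k], [K, M−K]]`` is
formed, where

* ``k``  — list termini attributed to the protease,
* ``n``  — all cleavage-derived list termini (each counted once, however
  many proteases match it),
* ``K``  — distinct knowledgebase cleavage sites on the list's proteins
  attributed to the protease,
* ``M``  — distinct such sites attributed to any identified protease
  (a site shared by two proteases counts once in ``M`` but in each
  protease's ``K``).

The p-value is the one-sided (enrichment-tail) Fisher exact probability,
i.e. the hypergeometric upper tail P(X ≥ k) with population ``n+M``,
``k+K`` successes and ``n`` draws, computed in exact rational arithmetic.
q-values follow from Benjamini–Hochberg step-up across the identified
proteases.  Fold enrichment is ``(k/n)/(K/M)``; fold coverage ``k/K`` is
the fraction of the protease's known sites recovered in the experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kb import CleavageEvent, Feature, Knowledgebase, Protein, TerminusEvidence

__all__ = [
    "QueryPeptide",
    "TerminusAnnotation",
    "EnrichmentRow",
    "LogoMatrix",
    "TerminusAnalysisResult",
    "read_query_tsv",
    "write_query_tsv",
    "locate_terminus",
    "classify_terminus",
    "annotate_features",
    "fisher_enrichment_p",
    "bh_adjust",
    "protease_enrichment_table",
    "venn_counts",
    "substrate_protease_matrix",
    "ice_logo",
    "run_terminus_analysis",
    "CATEGORIES",
]

# the five origin categories a located terminus can carry
CATEGORIES = ("canonical", "alt_splicing", "alt_translation", "cleaved",
              "experimental")

# evidence category → annotation category (evidence category "cleavage"
# deliberately absent: the cleaved category is assigned from CleavageEvents,
# which carry the responsible protease)
_EVIDENCE_CATEGORY_MAP = {
    "canonical": "canonical",
    "alt_splicing": "alt_splicing",
    "alt_translation": "alt_translation",
    "experimental": "experimental",
}


@dataclass(frozen=True)
class QueryPeptide:
    """One submitted terminal peptide."""

    protein_accession: str
    peptide: str
    terminus_type: str  # "N" or "C"
    quantity: Optional[float] = None  # e.g. a log2 ratio
    label: Optional[str] = None


@dataclass
class TerminusAnnotation:
    query: QueryPeptide
    status: str  # located | not_found | ambiguous | unknown_protein
    position: Optional[int] = None
    ambiguous_positions: tuple[int, ...] = ()
    categories: frozenset[str] = frozenset()
    matched_evidence: tuple[TerminusEvidence, ...] = ()
    protease_matches: tuple[tuple[CleavageEvent, int], ...] = ()
    features_n_terminal: tuple[Feature, ...] = ()
    features_c_terminal: tuple[Feature, ...] = ()
    features_at_position: tuple[Feature, ...] = ()

    @property
    def located(self) -> bool:
        return self.status == "located"

    @property
    def matched_proteases(self) -> frozenset[str]:
        return frozenset(c.protease_accession for c, _ in self.protease_matches)


@dataclass(frozen=True)
class EnrichmentRow:
    protease_accession: str
    protease_name: str
    k: int  # list count
    n: int  # list count, total
    K: int  # DB count
    M: int  # DB count, total
    fold_enrichment: float
    fold_coverage: float
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# location, classification, feature annotation

def locate_terminus(query: QueryPeptide, protein: Optional[Protein]) -> TerminusAnnotation:
    """Locate the peptide on its protein by exact substring search.

    The reported position is that of the terminal residue: the first
    peptide residue for an N-terminus, the last for a C-terminus.  Zero
    hits → ``not_found``; two or more → ``ambiguous`` with every candidate
    position recorded.
    """
    if protein is None:
        return TerminusAnnotation(query, "unknown_protein")
    starts = []
    start = protein.sequence.find(query.peptide)
    while start != -1:
        starts.append(start + 1)
        start = protein.sequence.find(query.peptide, start + 1)

    def terminal(s: int) -> int:
        return s if query.terminus_type == "N" else s + len(query.peptide) - 1

    if not starts:
        return TerminusAnnotation(query, "not_found")
    if len(starts) > 1:
        return TerminusAnnotation(query, "ambiguous",
                                  ambiguous_positions=tuple(terminal(s) for s in starts))
    return TerminusAnnotation(query, "located", position=terminal(starts[0]))


def _resolved_category(ev: TerminusEvidence, kb: Knowledgebase) -> Optional[str]:
    if ev.category == "isoform_inferred":
        source = kb.evidence(ev.source_id)
        if source is None:
            return None
        return _EVIDENCE_CATEGORY_MAP.get(source.category)
    return _EVIDENCE_CATEGORY_MAP.get(ev.category)


def classify_terminus(annotation: TerminusAnnotation, kb: Knowledgebase,
                      window: int = 0) -> TerminusAnnotation:
    """Assign origin categories from knowledgebase evidence within
    ``±window`` residues of the located position (the ragging window,
    0..10).

    A cleavage event matches an N-terminus at ``t`` when ``|t − (P1+1)| ≤
    window`` (the neo-N-terminus of a cleavage at P1 sits at P1+1) and a
    C-terminus when ``|t − P1| ≤ window``; any match adds the ``cleaved``
    category and the protease.  Isoform-inferred evidences contribute the
    category of their source evidence.
    """
    if not annotation.located:
        return annotation
    if not (0 <= window <= 10):
        raise ValueError("window must lie in 0..10")
    acc = annotation.query.protein_accession
    ttype = annotation.query.terminus_type
    pos = annotation.position

    matched: list[TerminusEvidence] = []
    categories: set[str] = set()
    for ev in kb.termini:
        if ev.protein_accession != acc or ev.terminus_type != ttype:
            continue
        if abs(ev.position - pos) > window:
            continue
        matched.append(ev)
        cat = _resolved_category(ev, kb)
        if cat is not None:
            categories.add(cat)

    protease_matches: list[tuple[CleavageEvent, int]] = []
    for c in kb.cleavages:
        if c.substrate_accession != acc:
            continue
        neo = c.p1_position + 1 if ttype == "N" else c.p1_position
        offset = pos - neo
        if abs(offset) <= window:
            protease_matches.append((c, offset))
    if protease_matches:
        categories.add("cleaved")

    return replace(
        annotation,
        categories=frozenset(categories),
        matched_evidence=tuple(matched),
        protease_matches=tuple(protease_matches),
    )


def annotate_features(annotation: TerminusAnnotation,
                      kb: Knowledgebase) -> TerminusAnnotation:
    """Partition the protein's features relative to the located terminus.

    Features entirely N-terminal (``end < position``), entirely C-terminal
    (``start > position``) or spanning the position are listed separately;
    for an N-terminal peptide the N-terminal features are lost from the
    fragment and the C-terminal ones retained, and vice versa for a
    C-terminus.
    """
    if not annotation.located:
        return annotation
    pos = annotation.position
    n_term, c_term, at_pos = [], [], []
    for f in kb.features_of(annotation.query.protein_accession):
        if f.end < pos:
            n_term.append(f)
        elif f.start > pos:
            c_term.append(f)
        else:
            at_pos.append(f)
    return replace(annotation,
                   features_n_terminal=tuple(n_term),
                   features_c_terminal=tuple(c_term),
                   features_at_position=tuple(at_pos))


# ---------------------------------------------------------------------------
# statistics

def fisher_enrichment_p(k: int, n: int, K: int, M: int) -> float:
    """One-sided (enrichment-tail) Fisher exact probability for the table
    ``[[k, n−k], [K, M−K]]``.

    Equals the hypergeometric upper tail P(X ≥ k) for a population of
    ``n+M`` sites of which ``k+K`` are the protease's, drawing ``n``.
    Computed in exact rational arithmetic and rounded once to float.
    """
    if not (0 <= k <= n and 0 <= K <= M and n >= 1 and M >= 1):
        raise ValueError(
            f"invalid counts: need 0 <= k <= n, 0 <= K <= M, n,M >= 1; "
            f"got k={k}, n={n}, K={K}, M={M}")
    population = n + M
    successes = k + K
    num = sum(
        math.comb(successes, x) * math.comb(population - successes, n - x)
        for x in range(k, min(n, successes) + 1)
    )
    return float(Fraction(num, math.comb(population, n)))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j ≥ i} p_(j)·m/j over the ascending order, clipped to 1.
    """
    p = list(p_values)
    for v in p:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"p-value {v} outside [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        # q >= p holds mathematically; guard the last-ulp rounding of p*m/j
        q[i] = max(running, p[i])
    return q


def protease_enrichment_table(annotations: Iterable[TerminusAnnotation],
                              kb: Knowledgebase) -> list[EnrichmentRow]:
    """Per-protease enrichment statistics over classified annotations.

    Returns one row per identified protease (a protease matching at least
    one list terminus), sorted by descending list count ``k`` then
    accession.  Empty when no list terminus is cleavage-derived.
    """
    located = [a for a in annotations if a.located]
    cleaved = [a for a in located if "cleaved" in a.categories]
    n = len(cleaved)
    if n == 0:
        return []

    k_counts: dict[str, int] = {}
    for a in cleaved:
        for prot in a.matched_proteases:
            k_counts[prot] = k_counts.get(prot, 0) + 1
    identified = set(k_counts)

    list_proteins = {a.query.protein_accession for a in located}
    sites: set[tuple[str, int]] = set()
    site_proteases: dict[str, set[tuple[str, int]]] = {p: set() for p in identified}
    for c in kb.cleavages:
        if c.substrate_accession in list_proteins and c.protease_accession in identified:
            sites.add(c.site)
            site_proteases[c.protease_accession].add(c.site)
    M = len(sites)

    rows = []
    order = sorted(identified, key=lambda p: (-k_counts[p], p))
    p_values = []
    for prot in order:
        k = k_counts[prot]
        K = len(site_proteases[prot])
        p_values.append(fisher_enrichment_p(k, n, K, M))
    q_values = bh_adjust(p_values)
    for prot, p, q in zip(order, p_values, q_values):
        k = k_counts[prot]
        K = len(site_proteases[prot])
        protein = kb.protein(prot)
        rows.append(EnrichmentRow(
            protease_accession=prot,
            protease_name=protein.name if protein else prot,
            k=k, n=n, K=K, M=M,
            fold_enrichment=(k / n) / (K / M),
            fold_coverage=k / K,
            p_value=p,
            q_value=q,
        ))
    return rows


def venn_counts(annotations: Iterable[TerminusAnnotation]) -> dict[frozenset, int]:
    """Count located termini per exact subset of the origin categories.

    Subsets with zero count are omitted; the counts (including the empty
    set's) sum to the number of located termini.
    """
    counts: dict[frozenset, int] = {}
    for a in annotations:
        if not a.located:
            continue
        key = frozenset(a.categories)
        counts[key] = counts.get(key, 0) + 1
    return counts


def substrate_protease_matrix(annotations: Iterable[TerminusAnnotation]) -> pd.DataFrame:
    """Binary termini × proteases matrix of cleavage attribution.

    Rows are located termini with ≥1 protease match, labeled
    ``accession@position``; a cell is 1 iff the column protease matches the
    row terminus.  Rows and columns are ordered by descending marginal
    total, ties broken by label — a deterministic stand-in for a clustered
    display.
    """
    cells: dict[str, set[str]] = {}
    for a in annotations:
        if not a.located or not a.protease_matches:
            continue
        label = f"{a.query.protein_accession}@{a.position}"
        cells.setdefault(label, set()).update(a.matched_proteases)
    if not cells:
        return pd.DataFrame(dtype=int)
    rows = sorted(cells)
    cols = sorted({p for ps in cells.values() for p in ps})
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for label, proteases in cells.items():
        mat.loc[label, sorted(proteases)] = 1
    row_order = sorted(mat.index, key=lambda r: (-mat.loc[r].sum(), r))
    col_order = sorted(mat.columns, key=lambda c: (-mat[c].sum(), c))
    return mat.loc[row_order, col_order]


# ---------------------------------------------------------------------------
# sequence logo

@dataclass
class LogoMatrix:
    """Position × residue frequencies around the analyzed termini, with
    per-cell significance against a background composition (two-sided
    exact binomial test at the probability cutoff ``alpha``)."""

    offsets: list[int] = field(default_factory=list)
    counts: Optional[pd.DataFrame] = None  # offsets × residues, int
    totals: Optional[pd.Series] = None  # sequences contributing per offset
    frequencies: Optional[pd.DataFrame] = None
    background: dict[str, float] = field(default_factory=dict)
    p_values: Optional[pd.DataFrame] = None
    significant: Optional[pd.DataFrame] = None
    alpha: float = 0.05
    diagnostic: Optional[str] = None

    @property
    def empty(self) -> bool:
        return self.counts is None or self.counts.empty

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: offset, residue, count, total, frequency,
        background, p_value, significant, direction."""
        if self.empty:
            return pd.DataFrame(columns=["offset", "residue", "count", "total",
                                         "frequency", "background", "p_value",
                                         "significant", "direction"])
        records = []
        for off in self.offsets:
            total = int(self.totals.loc[off])
            for res in self.counts.columns:
                count = int(self.counts.loc[off, res])
                if count == 0:
                    continue
                freq = self.frequencies.loc[off, res]
                bg = self.background.get(res, 0.0)
                records.append({
                    "offset": off,
                    "residue": res,
                    "count": count,
                    "total": total,
                    "frequency": freq,
                    "background": bg,
                    "p_value": self.p_values.loc[off, res],
                    "significant": bool(self.significant.loc[off, res]),
                    "direction": "enriched" if freq > bg else
                                 ("depleted" if freq < bg else "equal"),
                })
        return pd.DataFrame.from_records(records)


def kb_residue_frequencies(kb: Knowledgebase) -> dict[str, float]:
    """Residue composition over every protein sequence in the
    knowledgebase — the default logo background."""
    counts: dict[str, int] = {}
    for p in kb.proteins:
        for res in p.sequence:
            counts[res] = counts.get(res, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {res: c / total for res, c in sorted(counts.items())}


def _logo_eligible(a: TerminusAnnotation) -> bool:
    # termini explained purely by translational events (canonical start,
    # alternative translation initiation) carry no cleavage-site signal
    if not a.located:
        return False
    return not (a.categories and
                a.categories <= {"canonical", "alt_translation"})


def ice_logo(annotations: Iterable[TerminusAnnotation], kb: Knowledgebase,
             span: int = 8, alpha: float = 0.05,
             background: Optional[dict[str, float]] = None) -> LogoMatrix:
    """Frequency sequence logo of the residues at offsets −span..+span
    around each eligible terminus (offset 0 = the terminal residue),
    with per-cell significance by a two-sided exact binomial test against
    the background composition.
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    if background is None:
        background = kb_residue_frequencies(kb)

    offsets = list(range(-span, span + 1))
    counts: dict[int, dict[str, int]] = {o: {} for o in offsets}
    totals: dict[int, int] = {o: 0 for o in offsets}
    n_sequences = 0
    for a in annotations:
        if not _logo_eligible(a):
            continue
        protein = kb.protein(a.query.protein_accession)
        if protein is None:
            continue
        n_sequences += 1
        for o in offsets:
            idx = a.position + o
            if 1 <= idx <= protein.length:
                res = protein.sequence[idx - 1]
                counts[o][res] = counts[o].get(res, 0) + 1
                totals[o] += 1
    if n_sequences == 0:
        return LogoMatrix(alpha=alpha, diagnostic="no eligible sequences")

    residues = sorted({r for by_res in counts.values() for r in by_res})
    count_df = pd.DataFrame(0, index=offsets, columns=residues, dtype=int)
    for o in offsets:
        for res, c in counts[o].items():
            count_df.loc[o, res] = c
    totals_s = pd.Series({o: totals[o] for o in offsets})
    freq_df = count_df.div(totals_s.replace(0, 1), axis=0)
    p_df = pd.DataFrame(1.0, index=offsets, columns=residues)
    sig_df = pd.DataFrame(False, index=offsets, columns=residues)
    for o in offsets:
        total = totals[o]
        if total == 0:
            continue
        for res in residues:
            c = int(count_df.loc[o, res])
            if c == 0:
                continue
            bg = background.get(res, 0.0)
            if bg <= 0.0:
                p = 0.0  # residue absent from the background yet observed
            elif bg >= 1.0:
                p = 1.0 if c == total else 0.0
            else:
                p = stats.binomtest(c, total, bg, alternative="two-sided").pvalue
            p_df.loc[o, res] = p
            # strict cutoff; at the boundary alpha=1 every present cell flags
            sig_df.loc[o, res] = bool(p < alpha or alpha >= 1.0)
    return LogoMatrix(offsets=offsets, counts=count_df, totals=totals_s,
                      frequencies=freq_df, background=dict(background),
                      p_values=p_df, significant=sig_df, alpha=alpha)


# ---------------------------------------------------------------------------
# query I/O and the full pipeline

def read_query_tsv(path) -> list[QueryPeptide]:
    """Read a query list TSV (columns: accession, peptide, terminus_type,
    optional quantity, optional label)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"accession", "peptide", "terminus_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"query file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        quantity = getattr(row, "quantity", "")
        out.append(QueryPeptide(
            protein_accession=row.accession,
            peptide=row.peptide,
            terminus_type=row.terminus_type,
            quantity=float(quantity) if quantity else None,
            label=getattr(row, "label", "") or None,
        ))
    return out


def write_query_tsv(queries: Sequence[QueryPeptide], path) -> None:
    pd.DataFrame([
        {
            "accession": q.protein_accession,
            "peptide": q.peptide,
            "terminus_type": q.terminus_type,
            "quantity": "" if q.quantity is None else repr(q.quantity),
            "label": q.label or "",
        }
        for q in queries
    ], columns=["accession", "peptide", "terminus_type", "quantity", "label"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class TerminusAnalysisResult:
    annotations: list[TerminusAnnotation]
    enrichment: list[EnrichmentRow]
    venn: dict[frozenset, int]
    matrix: pd.DataFrame
    logo: LogoMatrix
    diagnostics: list[str] = field(default_factory=list)

    @property
    def located(self) -> list[TerminusAnnotation]:
        return [a for a in self.annotations if a.located]


def _fmt_fold(x: float) -> str:
    # half-away-from-zero to 2 decimals (0.125 -> "0.13")
    return str(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _fmt_p(x: float) -> str:
    return f"{x:.2E}"


def annotation_frame(annotations: Sequence[TerminusAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append({
            "accession": a.query.protein_accession,
            "peptide": a.query.peptide,
            "terminus_type": a.query.terminus_type,
            "status": a.status,
            "position": "" if a.position is None else a.position,
            "ambiguous_positions": ";".join(map(str, a.ambiguous_positions)),
            "categories": ";".join(sorted(a.categories)),
            "evidences": ";".join(ev.key for ev in a.matched_evidence),
            "proteases": ";".join(sorted(a.matched_proteases)),
            "features_lost": ";".join(
                f.kind for f in (a.features_n_terminal
                                 if a.query.terminus_type == "N"
                                 else a.features_c_terminal)),
            "features_retained": ";".join(
                f.kind for f in (a.features_c_terminal
                                 if a.query.terminus_type == "N"
                                 else a.features_n_terminal)),
            "features_at_position": ";".join(f.kind for f in a.features_at_position),
            "quantity": "" if a.query.quantity is None else a.query.quantity,
            "label": a.query.label or "",
        })
    return pd.DataFrame(rows)


def enrichment_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "protease_name": r.protease_name,
            "protease_accession": r.protease_accession,
            "list_count": r.k,
            "list_count_total": r.n,
            "db_count": r.K,
            "db_count_total": r.M,
            "fold_enrichment": _fmt_fold(r.fold_enrichment),
            "fold_coverage": _fmt_fold(r.fold_coverage),
            "p_value": _fmt_p(r.p_value),
            "q_value": _fmt_p(r.q_value),
        }
        for r in rows
    ], columns=["protease_name", "protease_accession", "list_count",
                "list_count_total", "db_count", "db_count_total",
                "fold_enrichment", "fold_coverage", "p_value", "q_value"])


def run_terminus_analysis(query_list: Sequence[QueryPeptide], kb: Knowledgebase,
                  window: int = 0, span: int = 8, alpha: float = 0.05,
                  out_dir=None) -> TerminusAnalysisResult:
    """Execute the full locate → classify → annotate → statistics pipeline.

    Row-level problems (unknown accession, peptide not found, ambiguous
    placement) are recorded in the annotation's status and never abort the
    run.  With ``out_dir`` set, writes ``annotation.tsv``,
    ``enrichment.tsv``, ``venn.tsv``, ``matrix.tsv`` and ``logo.tsv``;
    outputs are deterministic given inputs and options.
    """
    diagnostics: list[str] = []
    annotations = []
    for q in query_list:
        ann = locate_terminus(q, kb.protein(q.protein_accession))
        if ann.located:
            ann = classify_terminus(ann, kb, window=window)
            ann = annotate_features(ann, kb)
        else:
            diagnostics.append(
                f"{q.protein_accession}:{q.peptide}: {ann.status}")
        annotations.append(ann)

    enrichment = protease_enrichment_table(annotations, kb)
    if not enrichment and annotations:
        diagnostics.append("no cleavage-derived termini; enrichment table empty")
    venn = venn_counts(annotations)
    matrix = substrate_protease_matrix(annotations)
    logo = ice_logo(annotations, kb, span=span, alpha=alpha)
    if logo.diagnostic:
        diagnostics.append(f"logo: {logo.diagnostic}")

    result = TerminusAnalysisResult(annotations, enrichment, venn, matrix, logo,
                             diagnostics)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annotation_frame(annotations).to_csv(out / "annotation.tsv",
                                             sep="\t", index=False)
        enrichment_frame(enrichment).to_csv(out / "enrichment.tsv",
                                            sep="\t", index=False)
        venn_rows = [
            {"categories": ";".join(sorted(key)) or "(none)", "count": count}
            for key, count in sorted(venn.items(),
                                     key=lambda kv: (-kv[1],
                                                     ";".join(sorted(kv[0]))))
        ]
        pd.DataFrame(venn_rows, columns=["categories", "count"]).to_csv(
            out / "venn.tsv", sep="\t", index=False)
        matrix.to_csv(out / "matrix.tsv", sep="\t",
                      index_label="terminus")
        logo.to_frame().to_csv(out / "logo.tsv", sep="\t", index=False)
    return result
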