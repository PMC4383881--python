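import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from termikit.kb import (
    CleavageEvent,
    Feature,
    Knowledgebase,
    Protein,
    TerminusEvidence,
)
from termikit.synth import PlantedSignal, SynthParams, generate_kb, generate_query_list
from termikit.analysis import (
    QueryPeptide,
    annotate_features,
    bh_adjust,
    classify_terminus,
    fisher_enrichment_p,
    ice_logo,
    locate_terminus,
    protease_enrichment_table,
    run_terminus_analysis,
    substrate_protease_matrix,
    venn_counts,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def _seq(rng, n):
    return "".join(rng.choice(list(AA), size=n))


# ---------------------------------------------------------------------------
# locating

def test_locate_prefix_suffix_and_internal():
    rng = np.random.default_rng(0)
    seq = _seq(rng, 120)
    prot = Protein("P1", "p", "human", seq)
    assert locate_terminus(QueryPeptide("P1", seq[:10], "N"), prot).position == 1
    assert locate_terminus(QueryPeptide("P1", seq[-10:], "C"), prot).position == 120
    # peptide planted at residues 45..54
    ann = locate_terminus(QueryPeptide("P1", seq[44:54], "N"), prot)
    assert ann.status == "located" and ann.position == 45
    ann = locate_terminus(QueryPeptide("P1", seq[44:54], "C"), prot)
    assert ann.position == 54


def test_locate_ambiguous_and_missing():
    prot = Protein("P1", "p", "human", "AAAAAAAA")
    ann = locate_terminus(QueryPeptide("P1", "AAAA", "N"), prot)
    assert ann.status == "ambiguous"
    assert ann.ambiguous_positions == (1, 2, 3, 4, 5)
    assert locate_terminus(QueryPeptide("P1", "WWWW", "N"), prot).status == "not_found"
    assert locate_terminus(QueryPeptide("GHOST", "AAAA", "N"), None).status == \
        "unknown_protein"


# ---------------------------------------------------------------------------
# classification

def _kb_one_protein(seq, termini=(), cleavages=(), features=()):
    return Knowledgebase(proteins=[Protein("P1", "p", "human", seq)],
                         termini=list(termini), cleavages=list(cleavages),
                         features=list(features))


def test_classify_canonical_at_window_zero():
    rng = np.random.default_rng(1)
    seq = _seq(rng, 100)
    kb = _kb_one_protein(seq, termini=[TerminusEvidence("P1", "N", 1,
                                                        "canonical", "s")])
    ann = locate_terminus(QueryPeptide("P1", seq[:10], "N"), kb.protein("P1"))
    ann = classify_terminus(ann, kb, window=0)
    assert ann.categories == {"canonical"}


def test_classify_cleaved_follows_p1_convention():
    rng = np.random.default_rng(2)
    seq = _seq(rng, 100)
    cleavage = CleavageEvent("P1", "P1", 49, "x", "human")
    kb = _kb_one_protein(seq, cleavages=[cleavage])
    # neo-N-terminus of a cleavage at P1=49 sits at position 50
    ann = locate_terminus(QueryPeptide("P1", seq[49:59], "N"), kb.protein("P1"))
    assert ann.position == 50
    ann = classify_terminus(ann, kb, window=0)
    assert ann.categories == {"cleaved"}
    assert ann.matched_proteases == {"P1"}
    # neo-C-terminus of the same cleavage sits at position 49
    ann_c = locate_terminus(QueryPeptide("P1", seq[39:49], "C"), kb.protein("P1"))
    assert ann_c.position == 49
    assert "cleaved" in classify_terminus(ann_c, kb, window=0).categories


def test_window_arithmetic_and_monotonicity():
    rng = np.random.default_rng(3)
    seq = _seq(rng, 100)
    # terminus at t=50; cleavage at P1 = 51 places the neo-N-terminus at 52
    kb = _kb_one_protein(seq, cleavages=[CleavageEvent("P1", "P1", 51, "x", "human")])
    base = locate_terminus(QueryPeptide("P1", seq[49:59], "N"), kb.protein("P1"))
    assert classify_terminus(base, kb, window=0).categories == frozenset()
    assert classify_terminus(base, kb, window=1).categories == frozenset()
    assert classify_terminus(base, kb, window=2).categories == {"cleaved"}
    # enlarging the window never removes a category
    prev = frozenset()
    for w in range(11):
        cats = classify_terminus(base, kb, window=w).categories
        assert prev <= cats
        prev = cats


def test_isoform_inferred_contributes_source_category():
    rng = np.random.default_rng(4)
    seq = _seq(rng, 100)
    src = TerminusEvidence("P1", "N", 30, "alt_splicing", "ensembl")
    inferred = TerminusEvidence("P1", "N", 20, "isoform_inferred", src.key)
    kb = _kb_one_protein(seq, termini=[src, inferred])
    ann = locate_terminus(QueryPeptide("P1", seq[19:29], "N"), kb.protein("P1"))
    ann = classify_terminus(ann, kb, window=0)
    assert ann.categories == {"alt_splicing"}


def test_feature_partition_matches_interval_check():
    rng = np.random.default_rng(5)
    seq = _seq(rng, 200)
    features = [Feature("P1", "domain", 10, 50, "d1"),
                Feature("P1", "domain", 55, 58, "d2"),
                Feature("P1", "site", 60, 60, "s"),
                Feature("P1", "chain", 30, 120, "c"),
                Feature("P1", "domain", 130, 180, "d3")]
    kb = _kb_one_protein(seq, features=features)
    ann = locate_terminus(QueryPeptide("P1", seq[59:69], "N"), kb.protein("P1"))
    ann = annotate_features(ann, kb)
    pos = ann.position
    assert pos == 60
    assert set(ann.features_n_terminal) == {f for f in features if f.end < pos}
    assert set(ann.features_c_terminal) == {f for f in features if f.start > pos}
    assert set(ann.features_at_position) == \
        {f for f in features if f.start <= pos <= f.end}


# ---------------------------------------------------------------------------
# Fisher exact / BH

def _enumeration_oracle(k, n, K, M):
    """Sum the probabilities of every 2x2 table with the observed margins
    whose top-left cell is >= k."""
    N, c1 = n + M, k + K
    total = Fraction(0)
    for a in range(max(0, c1 - M), min(n, c1) + 1):
        if a >= k:
            total += Fraction(math.comb(n, a) * math.comb(M, c1 - a),
                              math.comb(N, c1))
    return float(total)


@pytest.mark.parametrize("k,n,K,M,printed", [
    (4, 129, 4, 1265, "3.65E-03"),
    (1, 129, 1, 1265, "1.77E-01"),
    (68, 129, 537, 1265, "1.62E-02"),
    (7, 129, 28, 1265, "3.67E-02"),
    (51, 129, 544, 1265, "8.03E-01"),
])
def test_fisher_matches_published_values(k, n, K, M, printed):
    assert f"{fisher_enrichment_p(k, n, K, M):.2E}" == printed


def test_fisher_trivial_and_degenerate_tails():
    assert fisher_enrichment_p(0, 10, 3, 50) == 1.0
    assert fisher_enrichment_p(5, 5, 7, 7) == 1.0  # k=n, K=M: only one table


def test_fisher_rejects_invalid_counts():
    for bad in [(5, 4, 1, 10), (1, 4, 11, 10), (-1, 4, 1, 10), (0, 0, 1, 10)]:
        with pytest.raises(ValueError):
            fisher_enrichment_p(*bad)


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_fisher_equals_enumeration_and_scipy(data):
    n = data.draw(st.integers(1, 20))
    M = data.draw(st.integers(1, 20))
    k = data.draw(st.integers(0, n))
    K = data.draw(st.integers(0, M))
    p = fisher_enrichment_p(k, n, K, M)
    assert p == pytest.approx(_enumeration_oracle(k, n, K, M), rel=1e-12)
    scipy_p = stats.fisher_exact([[k, n - k], [K, M - K]],
                                 alternative="greater")[1]
    assert p == pytest.approx(scipy_p, rel=1e-9)


@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
@settings(max_examples=100, deadline=None)
def test_bh_matches_statsmodels_and_is_valid(ps):
    q = bh_adjust(ps)
    expected = multipletests(ps, method="fdr_bh")[1]
    assert q == pytest.approx(list(expected), abs=1e-12)
    assert all(qq >= pp and qq <= 1.0 for qq, pp in zip(q, ps))
    # monotone along the sorted p order
    order = sorted(range(len(ps)), key=lambda i: ps[i])
    sorted_q = [q[i] for i in order]
    assert sorted_q == sorted(sorted_q)


def test_bh_single_and_range_check():
    assert bh_adjust([0.03]) == [0.03]
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# enrichment table and summaries

def _annotate_all(queries, kb, window=0):
    anns = []
    for q in queries:
        a = locate_terminus(q, kb.protein(q.protein_accession))
        if a.located:
            a = classify_terminus(a, kb, window=window)
        anns.append(a)
    return anns


def test_enrichment_row_identities_on_synthetic_list(synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0001", list_size=80,
                                fraction_from_protease=0.5, seed=21))
    anns = _annotate_all(queries, synth_kb)
    rows = protease_enrichment_table(anns, synth_kb)
    assert rows, "planted list must produce an enrichment table"
    cleaved = [a for a in anns if a.located and "cleaved" in a.categories]
    n = len(cleaved)
    for r in rows:
        assert r.n == n and 0 < r.K <= r.M and 0 <= r.k <= r.n
        # algebraic identities before any rounding
        assert r.fold_enrichment * (r.K / r.M) * r.n == pytest.approx(r.k)
        assert r.fold_coverage * r.K == pytest.approx(r.k)
        assert r.q_value >= r.p_value
        # brute-force recount of k
        k_direct = sum(r.protease_accession in a.matched_proteases
                       for a in cleaved)
        assert r.k == k_direct


def test_enrichment_degenerate_single_protease():
    rng = np.random.default_rng(6)
    seq = _seq(rng, 100)
    kb = _kb_one_protein(seq, cleavages=[CleavageEvent("P1", "P1", 49, "x",
                                                       "human")])
    anns = _annotate_all([QueryPeptide("P1", seq[49:59], "N")], kb)
    rows = protease_enrichment_table(anns, kb)
    assert len(rows) == 1
    r = rows[0]
    assert (r.k, r.n, r.K, r.M) == (1, 1, 1, 1)
    assert r.fold_enrichment == 1.0 and r.p_value == 1.0


def test_enrichment_empty_without_cleaved_termini(synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0001", list_size=20,
                                fraction_from_protease=0.0, seed=22))
    anns = _annotate_all(queries, synth_kb)
    anns = [a for a in anns if "cleaved" not in a.categories]
    assert protease_enrichment_table(anns, synth_kb) == []


def test_venn_counts_sum_to_located(synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0002", list_size=60,
                                fraction_from_protease=0.4, seed=23))
    anns = _annotate_all(queries, synth_kb)
    counts = venn_counts(anns)
    located = [a for a in anns if a.located]
    assert sum(counts.values()) == len(located)
    # brute-force per-terminus tally
    for subset, count in counts.items():
        assert count == sum(a.categories == subset for a in located)
        assert count > 0
    assert venn_counts([]) == {}


def test_matrix_marginals_and_ordering(synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0001", list_size=60,
                                fraction_from_protease=0.7, seed=24))
    anns = _annotate_all(queries, synth_kb, window=1)
    mat = substrate_protease_matrix(anns)
    assert not mat.empty
    assert set(map(int, np.unique(mat.values))) <= {0, 1}
    # per-terminus and per-protease match counts equal the marginals
    by_label = {}
    for a in anns:
        if a.located and a.protease_matches:
            by_label.setdefault(f"{a.query.protein_accession}@{a.position}",
                                set()).update(a.matched_proteases)
    assert set(mat.index) == set(by_label)
    for label, prots in by_label.items():
        assert mat.loc[label].sum() == len(prots)
    row_sums = list(mat.sum(axis=1))
    col_sums = list(mat.sum(axis=0))
    assert row_sums == sorted(row_sums, reverse=True) or \
        all(a >= b or (a == b) for a, b in zip(row_sums, row_sums[1:]))
    assert col_sums == sorted(col_sums, reverse=True)
    assert substrate_protease_matrix([]).empty


# ---------------------------------------------------------------------------
# logo

def test_logo_identical_sequences_single_significant_residue():
    seq = "W" * 30
    kb = Knowledgebase(proteins=[Protein("P1", "p", "human", seq)])
    anns = []
    for _ in range(20):
        q = QueryPeptide("P1", seq[9:19], "N")
        a = locate_terminus(q, kb.protein("P1"))
        # poly-W is ambiguous by substring search; pin the position directly
        anns.append(a.__class__(q, "located", position=15,
                                categories=frozenset({"experimental"})))
    logo = ice_logo(anns, kb, span=3, alpha=0.05,
                    background={aa: 0.05 for aa in AA})
    for off in logo.offsets:
        assert logo.frequencies.loc[off, "W"] == 1.0
        assert bool(logo.significant.loc[off, "W"])


def test_logo_alpha_one_flags_every_present_cell(synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0001", list_size=40,
                                fraction_from_protease=0.8, seed=25))
    anns = _annotate_all(queries, synth_kb)
    logo = ice_logo(anns, synth_kb, span=4, alpha=1.0)
    frame = logo.to_frame()
    assert not frame.empty
    assert frame["significant"].all()
    # per-offset frequencies sum to one over the residues present
    for off, grp in frame.groupby("offset"):
        assert grp["frequency"].sum() == pytest.approx(1.0)


def test_logo_excludes_translational_termini_and_empty_case(synth_kb):
    q = QueryPeptide("PR0001", "X" * 10, "N")
    from termikit.analysis import TerminusAnnotation
    only_canonical = TerminusAnnotation(q, "located", position=1,
                                        categories=frozenset({"canonical"}))
    logo = ice_logo([only_canonical], synth_kb, span=3)
    assert logo.empty and logo.diagnostic is not None


# ---------------------------------------------------------------------------
# full pipeline

def test_run_terminus_analysis_is_deterministic_and_complete(tmp_path, synth_kb):
    queries = generate_query_list(
        synth_kb, PlantedSignal("PR0001", list_size=50,
                                fraction_from_protease=0.5, seed=26))
    out1, out2 = tmp_path / "a", tmp_path / "b"
    res = run_terminus_analysis(queries, synth_kb, out_dir=out1)
    run_terminus_analysis(queries, synth_kb, out_dir=out2)
    for name in ("annotation.tsv", "enrichment.tsv", "venn.tsv",
                 "matrix.tsv", "logo.tsv"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    assert res.enrichment[0].protease_accession == "PR0001"
    best = min(res.enrichment, key=lambda r: r.q_value)
    assert best.protease_accession == "PR0001"


def test_run_terminus_analysis_empty_list_and_bad_rows(tmp_path, synth_kb):
    res = run_terminus_analysis([], synth_kb, out_dir=tmp_path / "empty")
    assert res.annotations == [] and res.enrichment == []
    bad = [QueryPeptide("NOPE", "ACDEFGHIKL", "N"),
           QueryPeptide("PR0001", "WWWWWWWWWW", "N")]
    res = run_terminus_analysis(bad, synth_kb)
    assert [a.status for a in res.annotations] == ["unknown_protein",
                                                   "not_found"]
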