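# termikit

Analysis toolkit for **protein termini and proteolytic processing**.
Terminomics experiments (e.g. TAILS N-terminomics) produce lists of
thousands of terminal peptides; the hard questions are *where each
terminus comes from* — a canonical start, alternative splicing,
alternative translation initiation, or a proteolytic cleavage — and *which
protease is responsible*, directly or through the protease web of
cleavage and inhibition dependencies.

termikit answers both over a flat-file knowledgebase (TSV tables + FASTA)
of proteins, terminus evidences, protease→substrate cleavage events and
inhibitor→protease inhibitions:

* **Terminus annotation & protease enrichment** — locate each submitted
  peptide on its protein, classify the terminus origin within a
  configurable "ragging" window (±0–10 residues), partition protein
  features into lost/retained for the truncated fragment, and score each
  protease for over-representation.  For a protease with *k* matched list
  termini out of *n* cleavage-derived termini, against *K* of *M* known
  database sites on the list's proteins, the p-value is the one-sided
  Fisher exact probability of the table [[k, n−k], [K, M−K]] — the
  hypergeometric upper tail P(X ≥ k) — with Benjamini–Hochberg q-values
  across proteases, fold enrichment (k/n)/(K/M) and fold coverage k/K.
  Summaries include origin-category Venn counts, a substrate × protease
  matrix, and a frequency sequence logo with per-cell exact-binomial
  significance against a background composition.
* **Protease-web path finding** — build the directed cleavage/inhibition
  network, extend it with hypothesized edges from a candidate protease to
  the observed substrates, and exhaustively enumerate node-simple paths
  obeying the web's grammar (a cleavage may be followed by a cleavage or
  by the cleaved inhibitor's inhibition; an inhibition must be followed by
  the inhibited protease acting; the final cleavage must match the
  observed position under the P1 convention).  Output as a table and
  Graphviz DOT.
* **Sequence-context mapping** — transfer termini and cleavage sites
  between isoforms (and from transcript products / translation-initiation
  windows onto canonical sequences) by exact matching of a 20-residue
  local context; ambiguous or interrupted contexts are skipped and
  reported.
* **Synthetic knowledgebases** — a seeded generator of proteins, isoforms
  with internal indels, shared cleavage sites and planted query-list
  signals, so every statistic can be tested against known ground truth.

Positions are 1-based; a cleavage is identified by its P1 residue, with
the scissile bond between P1 and P1+1, so a cleavage at P1 creates a
neo-N-terminus at P1+1 and a neo-C-terminus at P1.

## Worked example

```bash
python examples/enrichment_from_counts.py
```

```
protease     k     K  fold_enr  coverage           p           q
MMP2        68   537      1.24      0.13    1.62E-02    2.70E-02
GRAB        16    58      2.71      0.28    7.28E-04    3.64E-03
CASP3        7    28      2.45      0.25    3.67E-02    4.59E-02
MPPB         4     4      9.81      1.00    3.65E-03    9.13E-03
THRB         1     1      9.81      1.00    1.77E-01    1.77E-01
```

Reading the MPPB row: all 4 of its known database sites on the list's
proteins were observed among the 129 cleavage-derived termini (fold
coverage 1.00), nearly ten-fold more than its share of database sites
predicts (fold enrichment 9.81), and that excess is unlikely by chance
(p = 3.65E-03).  MMP2's large count (k = 68) reflects its large known
substrate repertoire (K = 537) rather than specific enrichment
(fold enrichment 1.24).

The other scripts in `examples/` each demonstrate one capability:
`terminus_analysis_synthetic.py` (full pipeline on a planted synthetic list,
recovering the planted protease at q ≈ 4E-19), `pathfinder_relay.py`
(the MMP2 → SERPING1 ⊣ C1S → C4 cleave–inhibit–cleave relay with DOT
output), `isoform_propagation.py` (a cleavage at P1=100 transferred to
P1=95 across a 5-residue deletion, while a site inside the deletion stays
unmapped).

## Command line

```bash
termikit synth   --out kb/ --seed 7                 # synthetic KB + query.tsv
termikit validate kb/
termikit analyze  --input kb/query.tsv --kb kb/ --window 0 --out report/
termikit pathfind --input kb/query.tsv --kb kb/ --protease PR0001 --out paths/
```

Each run writes its reports plus a `manifest.json` with the tool version,
effective options and input digests.

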