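# Methods

## The knowledgebase model

The unit of reference is a protein sequence with a UniProt-style
accession.  Isoforms are first-class entries pointing at a canonical
parent.  Five entity types hang off proteins: sequence features
(domains, chains, sites…), terminus evidences, cleavage events,
inhibition events and ortholog pairs.  All positions are 1-based residue
indices on the carrying protein.  A cleavage is identified by its P1
residue: the scissile bond lies between P1 and P1+1, hence the
neo-N-terminus it creates is at P1+1 and the neo-C-terminus at P1.  This
single-integer convention is what edge labels, window arithmetic and
position matching all use.

The on-disk form is a directory of six TSV tables plus one FASTA file —
chosen over a relational backend so that knowledgebases are diffable,
round-trippable (`load ∘ write` is the identity up to row order) and easy
to construct in tests.  Loading collapses duplicate cleavage tuples and
enforces referential integrity (dangling accessions, out-of-range
positions, self-inhibitions); violations are reported as data with
entity, field and rule, and `load_kb` refuses malformed input.
Evidence-confidence values are carried and can gate loading
(`min_confidence`) but do not enter any statistic.

## Terminus classification

Each query peptide is located on its protein by exact substring search;
only a unique hit yields a position (the first residue for N-termini,
the last for C-termini).  Ambiguous placements — common for short or
low-complexity peptides — are reported, not guessed; the minimum peptide
length is 4, and 10-residue peptides are the generator's default.

A located terminus collects origin categories from knowledgebase
evidence within ±`window` residues: canonical, alternative splicing,
alternative translation, prior experimental observation, and
cleavage-derived.  The window (default 0, maximum 10) absorbs "ragging"
— processive exopeptidase trimming that scatters termini around the true
cleavage position.  Cleavage matching follows the P1 convention: a
cleavage at P1 matches an N-terminus at *t* when |t − (P1+1)| ≤ window,
a C-terminus when |t − P1| ≤ window.  Category assignment is monotone in
the window: enlarging it can only add categories.  Isoform-inferred
evidences contribute the category of their source evidence, which they
reference by a stable key.  Evidences of category `cleavage` are
recorded among the matched evidences but do not by themselves assign the
cleavage-derived category — that category is reserved for matches to
cleavage events, which carry the responsible protease.

Features are partitioned into strictly N-terminal, strictly C-terminal
and spanning the terminus; for an N-terminal peptide the N-terminal
features are lost from the observed fragment and the C-terminal ones
retained (reversed for C-termini).

## Enrichment statistics

Identified proteases are those matching at least one list terminus.  The
2×2 table per protease is [[k, n−k], [K, M−K]]:

* *n* counts cleavage-derived list termini, each once however many
  proteases match it; *k* counts those matched by the given protease, so
  Σk may exceed *n* when proteases share sites.
* *M* counts distinct (substrate, P1) database sites on the list's
  proteins attributed to any identified protease, each site once; *K*
  counts the sites attributed to the given protease, so ΣK may exceed
  *M*.

The p-value is the one-sided enrichment tail of the Fisher exact test —
the hypergeometric upper tail P(X ≥ k) with population n+M, k+K
successes and n draws — computed in exact rational arithmetic
(`math.comb` + `Fraction`) and converted to float once.  Exactness
matters: tail sums of large binomial coefficients lose digits in naive
floating point, and the test suite holds the implementation to
12-significant-digit agreement with a fixed-margin enumeration oracle
over every table with n+M ≤ 40.  q-values are Benjamini–Hochberg
step-up, implemented directly and cross-checked against
`statsmodels.multipletests` in tests.  Fold enrichment is (k/n)/(K/M)
and fold coverage k/K; the algebraic identities
fold_enrichment·(K/M)·n = k and fold_coverage·K = k hold before
rounding.

Report files round folds to 2 decimals and p/q to 3 significant figures
in scientific notation.  Fold rounding is half-away-from-zero (0.125 →
0.13), matching how such tables are conventionally printed; full
precision is retained internally.

The "clustered" substrate × protease matrix is replaced by a
deterministic ordering — rows and columns sorted by descending marginal
totals, ties by label — so outputs are byte-reproducible; hierarchical
clustering would add a cosmetic permutation without changing any count.

## Sequence logo

The logo summarizes residues at offsets −span..+span (default span 8,
offset 0 = terminal residue) around every located terminus not explained
purely by translational events (canonical start and/or alternative
translation initiation), since those carry no cleavage-site signal.
Offsets falling outside the protein are skipped per sequence.  Per
offset and residue the observed fraction is compared to a background
composition — by default the residue frequencies over all knowledgebase
sequences, overridable — with a two-sided exact binomial test; a cell is
flagged at p < alpha (default 0.05; at the boundary alpha = 1 every
present cell flags).  The exact test is slightly conservative for small
counts; calibration is verified in the test suite on null lists of 1000
termini over uniform-composition proteomes, where the significant-cell
fraction stays within 3 binomial standard errors of alpha.

## Context mapping and isoform propagation

Entries transfer between sequences by exact alignment of a local context
of up to 20 residues: the 20 following an N-terminus, the 20 preceding a
C-terminus, or 10 on each side of a cleavage's scissile bond (the
symmetric split of 20), truncated at protein ends.  An entry maps only
when the context occurs exactly once in the target; zero matches
(typically a context interrupted by an indel) and multiple matches are
skipped and tallied in a mapping report, because silently picking among
multiple exact hits would corrupt positions.  Contexts shorter than 8
residues are refused as too prone to spurious matches.  Propagation runs
canonical ↔ isoform in both directions, marks transferred entries
`isoform_inferred` with a reference to their source, never re-propagates
inferred entries, and is therefore idempotent.  Correctness is defined
by re-extraction: the context at the mapped position of the target
equals the source context, verified exhaustively in tests.

Transcript-derived termini and translation-initiation N-termini reduce
to the same primitive: the first/last 20 residues of the product (or the
≤20-residue translated window) are matched against the canonical
sequence; a helper translates a supplied coding sequence with the
standard genetic code, but no transcript database access is involved.

## Path finding in the protease web

The web has typed directed edges: cleavages (protease → substrate,
labeled with P1) and inhibitions (inhibitor → protease).  Given a
candidate protease and observed substrates, the web is extended with
hypothesized cleavage edges from the candidate to each listed protein at
the observed position (never between list proteins, and an existing
identical knowledgebase edge takes precedence).

A meaningful path is node-simple, starts with a cleavage by the
candidate, and follows the grammar C (C | I C)*: after cleaving a
protein, either that protein (a protease) acts next, or the cleaved
protein is an inhibitor and its inhibition edge leads to a protease that
must act next.  Inhibition-first or inhibition-terminated sequences are
mechanistically meaningless and excluded.  The final cleavage enters the
target and must match the position implied by the observed terminus (P1
convention) within the position window; an `--any-position` escape hatch
accepts any knowledgebase cleavage of the target.  The single
hypothesized candidate→target edge is reported separately as
"hypothesized direct" — an explanation proper contains at least one
knowledgebase edge.

Enumeration is exhaustive depth-first with no heuristic pruning, bounded
by `max_length` (default 4 edges, which covers cleave–inhibit–cleave
relays plus one step while keeping enumeration tractable) and a
10 000-path-per-target cap with an explicit truncation flag.  The test
suite holds the search to exact set equality with a brute-force
enumerator (plain recursion plus an independent grammar predicate) on
100 random webs for every max_length in 1..5, plus monotonicity checks
(removing an edge never adds a path; raising max_length never removes
one).

Cross-species mapping replaces the candidate and each target by its
ortholog, reducing one-to-many clusters to the highest-score pair (ties
broken lexicographically) for determinism; observed positions are
carried over unchanged but flagged approximate, since residue numbering
differs between orthologs.  Targets without orthologs are dropped and
reported; a candidate without an ortholog is an error.

## Synthetic data

The generator emulates a curated terminus/cleavage resource, not any
particular proteome: i.i.d. sequences (uniform over the 20 amino acids
by default, with an optional frequency table so logo nulls are
controllable), protein lengths normal around a 300-residue mean
(floored), canonical terminus evidences at positions 1 and length,
sparse extra evidences of the other origin categories, cleavage sites
placed ≥25 residues from protein ends, a configurable fraction of sites
shared by a second protease (emulating CASP3/CASP7-style redundancy),
and inhibitor→protease pairs.  Isoforms differ from their parent by one
internal indel of 1–15 residues at least 25 residues from both termini,
guaranteeing that terminal and cleavage contexts near the ends remain
unambiguous — which is what makes propagation tests deterministic.
Query lists plant a signal: a chosen fraction of peptides are 10-residue
windows starting at P1+1 of one protease's cleavages (optionally
jittered to emulate ragging), the rest canonical starts or random
internal positions.

Defaults describe the benchmark condition used throughout the tests: 100
proteins, 10 proteases each holding ~10% of 200 cleavages, lists of 100
termini with half planted.  All randomness flows through numpy's PCG64
with an explicit integer seed; a fixed seed yields byte-identical
serialized knowledgebases across platforms, and the command-line
generator refuses to run without a seed.

What the generator does **not** emulate: real cleavage-site specificity
(no PSSMs), homology between proteins, non-uniform substrate abundance,
or peptide-level noise such as missed identifications.  Passing the
planted-signal and calibration tests therefore shows the statistics and
bookkeeping are correct under their stated model, not that real
terminomics lists will be as clean; on real data, ambiguity rates and
the evidence mix depend on the knowledgebase snapshot.

## Numerical and degenerate-input choices

* Fisher p-values: exact rational, no log-space approximation; k = 0
  gives p = 1 by construction, and k=n with K=M is the single-table
  degenerate case with p = 1.
* BH: the running minimum is clamped to q ≥ p to guard the last-ulp
  rounding of p·m/j; otherwise the textbook step-up.
* Empty inputs return empty results with diagnostics (empty query list,
  no cleavage-derived termini, no logo-eligible sequences), never
  exceptions; row-level problems (unknown accession, unplaceable
  peptide) are carried in the annotation status.
* All emitted tables are deterministically sorted; reruns are
  byte-identical.

## Known limitations

* The enrichment background is conditioned on the proteins of the
  submitted list and the proteases identified in it; it is not a
  proteome-wide null, and a query experiment already represented in the
  knowledgebase is not deduplicated from the background.
* Exact context matching cannot transfer entries across point mutations
  or near indels; the skip-on-ambiguity rule is conservative by design.
* Path finding is qualitative: it enumerates mechanistic possibilities
  and neither ranks them by likelihood nor models abundance or kinetics.
* Ortholog mapping does not remap residue positions between species;
  carried-over positions are approximate by construction.
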