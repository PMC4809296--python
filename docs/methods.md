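# Methods

This note documents the models and procedures implemented in `ugtfam`,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the package's known limitations.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Gapped-motif mining

Family discovery rests on two gapped patterns over the ~44-residue PSPG
box, written as dash-separated tokens that are either literal residue
runs or fixed-length wildcard gaps `<n>x`:

```
pspg-1: W-2x-Q-11x-F-2x-H-1x-GW-1x-S-9x-P-9x-Q     (15 tokens, span 44)
pspg-2: W-2x-Q-3x-L-10x-H-1x-G-5x-E-17x            (12 tokens, span 44)
```

`pspg-1` anchors nine literals including the terminal Gln and therefore
selects the Q-terminal (glucosylating) form; `pspg-2` constrains only
the N-terminal half of the box (six literals) and tolerates the
divergent C-terminal half, including His-terminal (galactosylating)
members.  Patterns compile to overlap-reporting regular expressions; a
position-by-position brute-force matcher serves as the oracle in tests
and in the acceptance script, and the two must agree exactly.

Conventions and edge cases:

* `X` in a scanned sequence matches any literal by default
  (`allow_x=True`) because translated transcriptome assemblies contain
  ambiguous residues; the flag disables this for curated input.
* All overlapping hits are reported in ascending start order.
  For PSPG extraction the "best" hit is the left-most 44-residue hit,
  with ties between patterns broken by the order the patterns were
  supplied.  Coordinates are 0-based half-open internally and 1-based
  in reports.
* The partial-sequence filter removes records *fewer than* 250 residues
  long, so a 250-residue record is kept.  The filter is applied to
  mined candidates, reflecting a discovery workflow in which fragments
  are recognised only after the motif pulls them in.
* Identification routes other than motif scanning (homology search,
  keyword search) are out of scope; externally identified records can
  simply be merged into the input FASTA.

One numbering caveat: the consensus position list used for profiling
places P at position 39, while `pspg-1` anchors its P literal at window
position 34.  The two constraints come from different summaries of the
same motif family and cannot be reconciled from first principles, so
the pattern is kept as written and the consensus list is treated as an
independent specification; the root synthetic box satisfies both.

## Distances, neighbour joining, bootstrap

Distances are **p-distances** — the proportion of compared sites that
differ — with pairwise deletion: sites where either row carries `-` or
`X` are excluded, and a pair with zero comparable sites is an error
rather than a guess.  By default distances are computed on the
motif-anchored 44-column PSPG boxes, which makes a multiple-sequence
aligner unnecessary and keeps the procedure reproducible; a pre-aligned
FASTA can be supplied instead when full-length alignments are wanted.

**Neighbour joining** follows Saitou & Nei: repeatedly join the pair
(i, j) minimising Q(i, j) = (n−2)·d(i, j) − r_i − r_j, with branch
lengths ℓ_i = d(i, j)/2 + (r_i − r_j)/(2(n−2)).  Two numerical
policies make the output deterministic and well-formed:

* Q-ties break on the lowest (row, column) index pair of the current
  matrix, so permuting input labels yields an isomorphic tree.
* Negative branch-length estimates are clamped to zero with the
  deficit moved to the sibling branch, preserving the joined pair's
  summed path length (the standard remedy; on additive matrices no
  negative estimates arise and NJ is exact — tests require RF = 0 and
  path lengths to 1e-9 against random generating trees).

Trees are unrooted; the returned object is a scikit-bio `TreeNode`
with a trifurcating root used for presentation only.

**Bootstrap supports** resample alignment columns with replacement
(default 1000 replicates, seeded), rebuild the NJ tree per replicate,
and count each of the full tree's non-trivial bipartitions, treating
the tree as unrooted.  Support = 100 × count / replicates is stored on
the internal node (`node.support`), which serialises as an internal
Newick label.  A replicate whose resampled columns leave some pair
with no comparable site counts as supporting nothing — a conservative
choice that only matters for gap- or X-rich alignments.

## Group assignment and novel-group detection

Published UGT groups are carried by labelled reference sequences
included in the analysis.  Each query receives the group of its
nearest reference by patristic (path-length) distance, ties broken on
the reference label.  That call is overridden by `novel-candidate` for
every member of a *maximal* bipartition side that (i) has bootstrap
support ≥ `support_min` (default 60, the conventional display cutoff
for "supported" nodes), (ii) contains at least `novel_min_size`
queries (default 3, the size at which a clade plausibly constitutes a
group rather than a stray pair), and (iii) contains no reference.
References self-assign, and exactly one assignment is produced per
tip.

This nearest-reference + supported-clade rule is an operationalisation
of the visual clade inspection practised in the field; it is
deterministic and auditable, but it is not a claim about what any
particular published analysis did by hand.

## PSPG profiling and donor prediction

`build_profile` computes exact per-position residue counts over a box
collection, normalised to frequencies.  `check_consensus` passes a
position iff the summed frequency of its allowed residues reaches
`min_freq` (default 0.9 — "highly conserved" is not a number anywhere
in the literature, so the threshold is explicit and configurable).
The default conserved-position set is W1, Q4, L8, H10, H19, C20, G21,
W22, N23, S24, E27, P39, E/D43, Q44.

`predict_donor` reads position 44 only: Q → UDP-glucose-preferring,
H → UDP-galactose-preferring, anything else → unknown.  The call is
deliberately labelled `rule-of-thumb`: the terminal residue correlates
with donor preference across characterised plant UGTs, but swapping it
by mutagenesis does not reliably flip specificity, so the prediction
is a screening aid, not a mechanism.  Pairwise motif identity is
reported as mean and minimum over unordered pairs (an "identity of a
group" is otherwise ambiguous).

## Kinetics

`fit_mm` fits v = V_max·S/(K_m + S).  The default **hyperbolic**
method is nonlinear least squares (`scipy.optimize.curve_fit`)
initialised at V_max⁰ = max(v), K_m⁰ = median(S), both constrained
positive; the **double-reciprocal** method is the classical ordinary
least squares on 1/v vs 1/S with K_m = slope/intercept and
V_max = 1/intercept.  The line fit is provided for comparability with
published plots but is statistically inferior (it amplifies noise at
low S and is undefined at v = 0, which raises an error); both methods
agree to 1e-6 relative on noise-free data, and the residual sum of
squares is always reported on the original scale so they are
comparable.  Fitting requires ≥ 4 distinct concentrations; replicates
are fitted pooled rather than averaged.

Unit conventions: concentrations in μM, rates in pKat·mg⁻¹.  The
turnover number is k_cat = V_max × 10⁻¹² × 10³ × M (V_max in
pKat·mg⁻¹, enzyme molar mass M in g·mol⁻¹, k_cat in s⁻¹), and the
specificity constant k_cat/K_m is reported in s⁻¹·μM⁻¹.  Because
fusion-protein preparations often lack a meaningful molar mass, k_cat
may be supplied directly (`attach_kcat`), and the package never
derives one published table column from another: printed V_max and
k_cat columns in the literature are not always mutually consistent
under any realistic mass, so each is treated as an independent input.

The UDP calibration inverts an ordinary-least-squares line
area = a·conc + b fitted to ≥ 2 standards; back-calculated
concentrations outside the standards' range (20–500 μM in the
motivating assay design) are flagged as extrapolated rather than
rejected.

## Product identity

Nominal integer masses (C 12, H 1, N 14, O 16, P 31, S 32) are the
default because unit-resolution negative-mode spectra are the use
case; monoisotopic masses are available as an option.  The
deprotonated ion is [M−H]⁻ = nominal mass − 1 (monoisotopic: − 1.00728)
and requires at least one hydrogen.  Neutral losses are annotated from
a small built-in table — 162 anhydrohexose, 146 anhydrodeoxyhexose,
132 anhydropentose, 152 galloyl, 60 hexose cross-ring cleavage —
and anything else is reported `unassigned` rather than guessed (the
211 fragment of β-glucogallin, a 120 Da difference, stays unassigned).
Isotope patterns, adducts and spectrum simulation are out of scope.

## Synthetic-data generator

`make_family` emulates the *structure* of a translated transcriptome
set containing a glycosyltransferase family.  Each member is
`random flank + mutated group-ancestor box + random flank`; group
ancestors derive from a root box that satisfies the consensus spec and
both mining patterns.  Divergence has three independent axes:

* `within_divergence` (default 0.05) — per-position substitution
  probability, member vs its group ancestor, at non-anchor box
  positions: roughly the within-group divergence of recent paralogs.
* `between_divergence` (default 0.15 = 3 × within) — same, group
  ancestor vs root, so groups form clean clades.
* `motif_conservation` (default 1.0) — probability each
  pattern-literal (anchor) position is left intact per member; at 1.0
  mining recall is 100% by construction, and lowering it degrades
  recall monotonically in expectation.

The terminal residue (position 44) is assigned per group (alternating
Q/H by default) and held fixed in every member: it is the ground-truth
label that donor predictions are checked against.  Mutations are
uniform exchanges to a different residue; flanks are uniform over the
20 amino acids; flank lengths default to 110–160 so full-length
members exceed 250 residues.  Partials (a chosen fraction, count
rounded) are generated with short flanks so the whole record stays
below 250 residues while the box survives — mirroring fragments that
still cover the conserved C-terminal region, and making stage counts
exactly predictable.  Decoys are uniform random sequences of 250–400
residues with no planted box (a chance motif match in a decoy has
probability ≪ 10⁻⁶ per sequence).

What this does **not** emulate: real amino-acid composition and
substitution biases, indels (none are generated, in or out of the
box), correlated sites, alignment error, or chimeric/misassembled
transcripts.  Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under controlled divergence — not
recall/precision on real transcriptomes, which depend on assembly
quality and true family divergence.

`simulate_assay` draws v = V_max·S/(K_m+S) × (1+ε) with
ε ~ N(0, cv) truncated at −0.99 (multiplicative noise is the standard
error model for rate assays; truncation keeps rates positive).

## Pipeline

`run_pipeline` executes read → mine → filter partials → extract boxes
→ profile/predict → NJ + bootstrap → assign, writing one artifact per
stage plus `summary.json` and a timestamp-free `run.log`.  A single
seed governs the bootstrap; counts satisfy mined = kept + removed, and
re-running a config reproduces every artifact byte for byte.  The tree
and classification stages are skipped (with a note) below 3 boxes or
without usable references.  Default parameters: min_length 250,
bootstrap replicates 1000, support_min 60, novel_min_size 3.

## Problem sizes used in the shipped checks

The test suite and acceptance script use desk-scale problem sizes
chosen to exercise every code path with tight statistics: 1000 random
sequences per pattern for scanner/oracle agreement, 100 random
additive matrices (5–12 taxa) for NJ, 1000 bootstrap replicates on
4–10-taxon alignments, 200 replicates for the noisy Michaelis–Menten
recovery study, and an end-to-end family of six groups (33 members
plus 8 decoys).  The end-to-end scenario plants a 3-member
reference-free group with very high internal conservation
(within 0.02) and deep between-group divergence (0.25), the regime of
a genuinely novel group.  The planted clade is always flagged as a
novel candidate; its bootstrap support sits at or within a few percent
of 100 depending on the realisation, because the binding quantity is
the *minimum* distance between the six independently drawn group
ancestors, whose lower tail a column resample can occasionally thin.
With the looser generator defaults (0.05/0.15) the support fluctuates
a few percent more, as resampling theory predicts.

## Known limitations

* Group assignment quality degrades when reference coverage is sparse
  or a query's true group has no reference — such queries are silently
  absorbed by the nearest represented group unless they form a
  supported clade of ≥ novel_min_size.
* p-distances saturate for deep divergence; no correction
  (Poisson/JTT) is applied because the motif-anchored boxes are short
  and the groups of interest are recent.
* The donor rule covers only the Q/H dimorphism; other terminal
  residues return `unknown` by design.
* The double-reciprocal fit weights errors poorly and is retained only
  for comparability; confidence intervals on kinetic parameters are
  not computed.
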