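# Methods

## Diagnostic characters

Given an alignment of one marker and a partition of its sequences into
species, fix a query species `Q`; the reference group `R` is every other
assigned sequence (optionally restricted to a subset of species via
`AnalysisConfig.reference_scope`). All coordinates are 1-based alignment
columns, the convention in which molecular diagnoses are printed.

A column `i` is a **single diagnostic character** with state `s` when

1. every sequence of `Q` carries the same unambiguous base
   `s ∈ {A,C,G,T}` at `i`, and
2. `s` is not in the set of states the reference can realise at `i`.

An adjacent duo `(i, i+1)` is a **combined diagnostic character** with
states `ss'` when the query is uniform and unambiguous at both columns,
no reference sequence can realise the dinucleotide `ss'`, and neither
`i` nor `i+1` is single-diagnostic for `Q`. Only adjacent duos
(k-window = 2) are computed: they read as a two-base motif, keep
diagnosis lists manageable, and avoid the combinatorial explosion of
arbitrary-span pairs (which is a documented non-goal).

### Ambiguity and gap policy

Input alignments carry gaps and IUPAC ambiguity codes, and the
definitions above need a stance on them. Two modes are provided:

* **conservative** (default): a query column containing any gap or
  ambiguity code is ineligible; the reference's realisable set is the
  union of IUPAC expansions of its observed codes (`N → {A,C,G,T}`,
  `Y → {C,T}`, …), and for duos a reference row whose expansions at `i`
  and `i+1` jointly admit `ss'` disqualifies the pair. A character
  reported under this mode can never be falsified by resolving an
  ambiguity in the reference data.
* **strict**: every code is its own literal symbol; an `N` in the
  reference blocks nothing unless it equals the query state verbatim.

In both modes the gap `-` is a distinct symbol that never equals a base,
and reported states are always plain A/C/G/T. The published analyses
this package mirrors do not state which behaviour their tool used, so
exact reproduction of printed positions may depend on the toggle; both
modes are first-class and the reproduction checker can be run under
either.

### Ordering and determinism

Singles are listed ascending by position, then duos ascending by first
position. Printed diagnoses in the literature are not consistently
sorted; a canonical sorted order was chosen so that identical inputs
yield byte-identical output (the text renderer is presentation over the
sorted canonical set).

### Monotonicity

Enlarging the reference (or query) group can only make condition 1–2
harder, so the set of single characters is antitone in both groups.
Combined characters are *not* literally antitone: a duo is excluded
while a member column is single-diagnostic, and that single may vanish
when the group grows, letting the duo surface. The property that does
hold — and the one the test suite asserts — is subsumption: any duo
found with the larger group is, with the smaller group, either the same
duo or covered by a single at one of its member positions. No
diagnostic information is ever created by adding sequences; it only
degrades from single to combined or disappears.

## Classification

An aligned unknown sequence is scored against each species' diagnosis
for a marker as the fraction of its characters matched; species with no
characters are excluded with a warning. Under the conservative policy
an ambiguity code in the query counts as a possible match (its expansion
must contain the diagnostic state); under strict only literal equality
matches; gaps never match. The verdict is `unique` iff exactly one
species attains fraction 1.0, `ambiguous` for more than one, `no_call`
otherwise. This is deliberate plumbing, not a probabilistic assigner:
it operationalises "identifiable through DNA" for sequences already
aligned to the reference coordinates.

## Distances

`p_distance` is the uncorrected proportion of differing sites over the
sites compared. Under **pairwise deletion** (default) a site is compared
when both sequences carry an unambiguous base — gaps *and* ambiguity
codes are excluded per pair, matching the literal "number of base
differences per site" counting; a **complete deletion** option drops a
column for all pairs when any sequence is not an unambiguous base there,
for sensitivity checks. A pair with zero comparable sites is undefined
and is excluded from group means with a warning rather than propagating
NaN (robustness to short fragments). Within-group means over all
unordered pairs (undefined for n < 2 — the output distinguishes a true
0.0000 from NA), between-group means over all cross pairs; the matrix is
symmetric with within means on the diagonal, rows in first-appearance
order of the partition. Tables are rendered at 4 decimals with `NA` for
undefined; prose-style summaries use the truncated integer percent
(`floor(100·d)`), the convention observed in published remark sections
(0.0889 → 8%). Model-corrected distances (JC, K2P) and tree building
are out of scope.

## Synthetic data

The generator emulates the structure of a real multi-species barcode
alignment, not a realistic phylogeny: a **star phylogeny** is exactly
what makes pairwise expectations controllable, and the analyses being
tested consume distances, not trees. From a uniform random root, each
species ancestor substitutes each site with probability δ
(`between_rate`), each individual substitutes each site with probability
ε (`within_rate`); a substitution always moves to one of the three other
bases uniformly. Gaps and ambiguity codes are injected per site at
given rates.

Planted characters are constructed directly and their columns **locked**
against mutation, gaps and ambiguity everywhere, which makes
planted-character recovery an exact (recall = 1) test instead of a
probabilistic one:

* planted single for species `k`: the column is fixed to `s` in `k` and
  forced to bases ≠ `s` in every other species;
* planted duo: each member base is placed in some reference row (so
  neither column is single-diagnostic) while no reference row carries
  the dinucleotide — this needs at least two reference species, hence
  at least three species overall.

A post-generation audit re-verifies every planted character against the
emitted alignment before the dataset is returned.

### Closed-form expectations

With per-edge substitution probability `p` "to a different base,
uniform over 3", the per-site transition matrix is
`M(p) = (1−4p/3)·I + (p/3)·J`. These matrices commute, so along a path
with edge probabilities `p₁…p_k` the probability that the endpoints
differ is `(3/4)·(1 − Π(1−4pᵢ/3))`. Hence

* `expected_within(ε) = (3/4)(1−(1−4ε/3)²) = 2ε(1−ε) + (2/3)ε²`
  (two ε edges through the species ancestor);
* `expected_between(ε, δ) = (3/4)(1 − (1−4ε/3)²(1−4δ/3)²)`
  (tip–ancestor–root–ancestor–tip).

Both are checked against Monte-Carlo realisations at large L (3
binomial standard errors) in the test suite. Locked columns do not
follow the model, so convergence tests use plant-free, noise-free specs.

### Default conditions

`default_spec()` mirrors a real COI dataset of Norwegian *Chaetozone*
(bi-tentaculate cirratulid polychaetes): 13 species with per-species
sequence counts (10, 8, 13, 10, 2, 45, 36, 2, 9, 3, 17, 2, 5) echoing
the published per-species sample sizes, 658 columns, ε = 0.002 (expected
within ≈ 0.004, inside the observed 0.001–0.011 band), δ = 0.11
(expected between ≈ 0.207, mid-range of the observed 0.09–0.28), 1%
gaps, 0.2% ambiguity codes, and 2 planted singles + 1 planted duo per
species. What the generator does **not** emulate: nested phylogenetic
structure (all between-species expectations are equal), indel evolution
(gaps are i.i.d. noise, not homologous events), rate heterogeneity
across sites, and codon structure. Passing tests therefore demonstrate
correctness of the definitions and the machinery, not robustness to
those real-data features.

## Reproduction of published values

`diagchar.reproduce` stores the published mean COI distance table, six
prose divergence percentages, and the printed diagnostic positions for
three species of the *Chaetozone* study, and recomputes them with this
package when the study's supplementary alignments and specimen list are
staged under `data/supplementary/` (they are not redistributable here).
The floor-percent consistency between the stored table and the quoted
percentages needs no external data and is always checked. One published
species diagnosis contains a typographic anomaly in the original listing
and is excluded from position-level checks rather than second-guessed.
Printed within-group values of exactly "0" are compared as 0.0000, the
package's own output distinguishing that from NA (undefined, n < 2).

## Numerical and design choices

* One canonical alphabet (uppercase, `U → T`, only `-` as gap, `.`
  rejected) simplifies all downstream set logic.
* Sequences present in an alignment but absent from the partition are
  dropped with a warning by default (outgroups and unassigned specimens
  are common in real supplementary files); `--strict` makes this an
  error.
* COI and 28S diagnoses are computed independently per marker; a species
  missing from a marker yields an empty entry, not an error.
* Nearest-neighbour ties are broken by matrix (first-appearance) order.
* JSON is the canonical output format; the text diagnosis is derived
  from it, uses an ASCII hyphen for duos (`--unicode` restores the
  typographic en dash), and parses back losslessly (characters and
  sequence counts; alignment lengths travel only in JSON).
* Problem sizes in the test and acceptance runs (desk-scale instances of
  ≤ 10 sequences × ≤ 50 columns for oracle sweeps; L = 5000–20000 for
  convergence checks; the 13-species default spec elsewhere) were chosen
  as the smallest sizes at which each property is informative.

## Known limitations

* Only k-window = 2 (adjacent duos); arbitrary-span combined characters
  and character ranking are not computed.
* The classifier assumes the query is already aligned to the reference
  coordinates; no alignment is performed.
* Group means weight every sequence pair equally, so large species
  dominate between-group means exactly as in the emulated analyses.
* The generator's star phylogeny cannot produce the nested divergence
  structure (e.g. pairs of sister species at 0.09 among background at
  0.25) seen in real tables.
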