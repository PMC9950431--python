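# Methods

This note documents the models, conventions and design choices behind
each stage of the pipeline, the defaults and why they were chosen, and
what the synthetic benchmark does and does not establish about real
data.

## Sequence handling and ORF translation

Protein records are uppercase strings over the 20 standard residues
plus `X`; coordinates are 1-based inclusive throughout, matching the
"Cys14" convention used for knottin scaffolds. ORF enumeration scans
all six reading frames and emits every maximal stop-free stretch of at
least 40 amino acids (configurable). No initiator methionine is
required and sequence ends count as open boundaries: the goal is the
complete set of *potential* reading frames for downstream domain
scanning, not gene prediction. Codons containing `N` translate to `X`,
and `X` never matches a cysteine pattern downstream, so ambiguity can
only suppress, never create, a domain call. The standard genetic code
(translation table 1) is used.

## ICK domain recognition

An ICK pattern is a cysteine count (6 for the three-disulfide form,
8 for the four-disulfide form) plus per-loop length bounds. A window of
consecutive cysteines is a hit iff every inter-cysteine spacing lies
within bounds; overlapping candidates are resolved greedily
leftmost-first, which is deterministic and matches how tandem domains
tile along a sequence. The default 3-DS bounds — (3,9), (3,9), (0,7),
(1,17), (3,19) residues for the five loops — admit the fixture
scaffold's loops (6,6,0,4,10 and 6,6,0,4,9) and typical calcin-like
knottins while rejecting most spurious cysteine runs; no reference
pattern is printed anywhere authoritative, so the bounds are package
defaults and fully configurable. The 4-DS default is the same knot core
with a generous loop four, where the extra disulfide sits.

Connectivity follows the knottin rule on sorted cysteine ranks: C1–C4,
C2–C5, C3–C6 for 3-DS; for 4-DS the core C1–C4, C2–C5, C3–C8 plus the
extra loop-four pair C6–C7. The 4-DS extra-pair placement is a declared
convention (the form is usually described only as carrying one
additional loop-four disulfide), kept separate from the rule so it can
be swapped.

Quality control removes the classic defect classes seen when mining
translated transcripts: any inter-cysteine loop longer than 25 residues
(`LONG_LOOP`), more than 60 residues upstream of the first domain
cysteine (`LONG_NTERM`, the "unusual propeptide / frameshift tail"
signature), or fewer cysteines than the scaffold requires
(`MISSING_CYS`). The bounds are deliberately generous: they retain
every well-formed domain the generator produces while excluding the
described defect classes. Every removal is logged with its reason code.

## Internal repeat mining

Tandem (double-knot) candidates are found by aligning a sequence
against itself with the optimal-local-alignment recurrence, excluding
all cells within `min_unit_len` of the main diagonal so the trivial
self-match cannot score. Scoring is BLOSUM62 with affine gaps (open 11,
extend 1, a gap of length L costing 11 + (L−1)). This replaces the
iterative segment-vs-sequence BLAST approach with an exact,
deterministic equivalent that needs no external binary and has a
directly testable optimum. The optimal alignment can run a few residues
past the true repeat junction, making the two projected intervals
overlap; because aligned pairs are monotonic in both coordinates, the
call is trimmed to the larger of the two non-overlapping pieces (prefix
capped below the second interval's start, or suffix raised above the
first's end). A call is emitted when both intervals are at least
`min_unit_len` (default 20) residues and the column identity of the
alignment is at least `min_identity` (default 40%); both intervals are
then masked and the search iterates up to `max_rounds` (default 3)
times. Repeat units shorter than `min_unit_len` are by construction
undetectable; that floor is the resolution limit of the method, not a
tuning artifact.

## Redundancy removal

Clustering mirrors the CD-HIT convention without wrapping the tool:
records are processed longest-first (ties by id), each joining the
first cluster whose representative is at least 99% identical, where
identity is identical aligned positions divided by the shorter
sequence's length under a global BLOSUM62 alignment (open 11, extend
1). The deterministic processing order makes the partition independent
of input order, and representatives are never shorter than their
members. No k-mer prefilter is used: the exact all-vs-representative
scheme is O(n²) and intended for desk scale (below a few thousand
records).

## Cysteine-anchored regional alignment

Because the cysteine scaffold is the one absolutely conserved feature
of an ICK family, the k cysteines are fixed as single-residue anchor
columns and the k+1 pre-/inter-/post-cysteine regions are aligned
independently. Each region uses progressive profile alignment: guide
order from pairwise 2-mer cosine distances (closest pair first, then
nearest remaining, ties by id), sequences added to the growing profile
by global affine-gap alignment against mean-BLOSUM62 column scores.
Regions whose longest member is 0 or 1 residues are copied verbatim.
Anchor columns are therefore gap-free and cysteine-only *by
construction*, and degapping any row reproduces its input exactly —
both properties are fuzz-tested. Sequences whose cysteine count
deviates from the family's modal count are rejected with a reason (or
raise, in strict mode); there is no attempt to rescue shifted
scaffolds inside regions. For highly diverged loops of equal length the
optimal profile alignment may stagger residues with gap columns; this
is the correct optimum under the scoring, not an error. This in-repo
aligner stands in for external regional-alignment tooling (MAFFT
L-INS-i per region) so the pipeline is self-contained and exactly
reproducible; the scoring is configurable.

## Distances, tree and bootstrap

Pairwise distances are p-distances over mutually ungapped columns with
Kimura's protein correction d = −ln(1 − p − 0.2p²), capped at −ln(0.01)
≈ 4.6 when the argument falls to 0.01 (saturation). The tree is
Saitou–Nei neighbour joining with negative branch lengths clamped to
zero and Q-matrix ties broken by the lexicographically smallest leaf
name under each candidate, so output is independent of input order; on
additive matrices the reconstruction is exact (property-tested on
random trees up to 12 taxa, and cross-checked against an independent
NJ implementation). Distance NJ + nonparametric bootstrap is the
package's declared stand-in for maximum-likelihood tree search with
ultrafast bootstrap: columns are resampled with replacement (one
generator stream per replicate index, so runs are reproducible and
parallelisable), support is the percentage of replicate trees
containing each bipartition of the point-estimate tree, and internal
edges below the collapse threshold (default 50) are collapsed into
multifurcations. The default replicate count is 1,000.

## Site-specific substitution rates

Per-column likelihoods are computed by Felsenstein pruning under a
Poisson amino-acid model — uniform exchangeabilities and uniform
frequencies — whose transition probability has the closed form
P(same) = (1 + 19·e^(−20/19·rt))/20. The closed form makes every
likelihood unit-testable against direct enumeration (the two-taxon case
is asserted to 1e-10). Rate heterogeneity uses discrete-gamma
categories (default 4) with equal-probability bins represented by their
bin means; the gamma shape α is optimised by bounded one-dimensional
maximisation of the total log-likelihood (0.05 ≤ α ≤ 50) unless
supplied. The reported column rate is the posterior-mean category rate
under a uniform category prior, normalised to mean 1 over scored
columns; all-gap columns are flagged unscored and excluded. Gaps are
treated as missing data (partial likelihood 1 in every state). The
Poisson model is a deliberate simplification of empirical matrices
(VT, WAG …): relative rates across columns — the quantity of interest
for the "which domain evolves faster" question — are robust to the
exchangeability matrix, and the model is pluggable.

## Sequence space

Each aligned position contributes six descriptors: average residue mass
(monomer minus water, Da), integer net charge at pH 7 (K,R = +1;
D,E = −1; H = 0 — a declared convention, the scale being configurable),
Kyte–Doolittle hydropathy, TOP-IDP disorder propensity, disulfide
potential (1 for Cys) and occupancy (1 for a residue, 0 for a gap).
Gaps are all-zero except occupancy 0; `X` is zero-filled with occupancy
1 by default. The values ship in a versioned table
(`knotminer/data/properties.tsv`). Columns are centred and scaled to
unit variance (constant columns dropped and recorded), and scores come
from the SVD of the scaled matrix with the sign of each component fixed
so its largest-magnitude loading is positive. Neighbour ranking uses
Euclidean distance in the first three components by default (matching
a three-dimensional sequence-space projection); the full retained score
space is available because "physicochemically most similar" admits
either reading.

## Synthetic data and what the tests show

The generator emulates the data regime the pipeline assumes: families
evolved down random bifurcating trees from a scaffold ancestor under
the same Poisson process the inference uses (so parameter recovery is a
fair test), with slow/fast site classes (defaults 0.3 / 1.7, half the
sites slow); tandem records built as tail + domain copy + linker +
domain copy + tail with independent per-copy divergence (defaults 0.1
and 0.3, making the second domain faster — the double-knot evolution
signature); and decoys drawn i.i.d. with 3% cysteine frequency,
rejection-sampled to never match the scaffold pattern. Loop and tail
residues are uniform over the 19 non-cysteine letters, and mutation
redraws from the same 19-letter alphabet by default, so the cysteine
ground truth stays unambiguous; the model-exact 20-state redraw is
available and exercised by the closed-form tests. Every manifest claim
(intervals, cysteine positions, labels) is verified against the emitted
records at generation time.

The default benchmark is 3 families × 12 members + 5 tandems + 200
decoys. Deliberate simplifications: no indels inside regions beyond
what divergence produces, no signal peptides or propeptides, no
composition bias, absolute cysteine conservation. Passing tests
therefore demonstrate algorithmic correctness and recovery under the
stated model — not robustness to frameshifts, shifted scaffolds or
compositionally skewed real transcriptomes, which is exactly the gap
the QC stage's reason codes are designed to surface on real input.

Problem sizes used by the test battery (chosen as desk-scale
benchmarks): 500 fuzzed sequences for scanner/oracle equivalence, 200
simulated duplications for repeat mining, 1,000 fuzzed families for
alignment integrity, 100 random additive matrices (≤12 taxa) for NJ
exactness, a seeded 10-taxon/60-column benchmark for rate recovery
(Spearman ≥ 0.6), 20 seeded replicates for the domain-2-faster
direction, and 100 seeded replicates for planted-cluster neighbour
recovery.

## Numerical and determinism notes

All stochastic steps take explicit integer seeds; the bootstrap derives
one `numpy` generator per replicate index from the run seed. Pipeline
reruns with identical config and seed are byte-identical (asserted via
sha256 checksums in the run manifest; the config hash excludes the
output directory). Alignment and NJ ties are broken lexicographically
by id. Likelihoods are floored at 1e-300 before logs; degenerate inputs
(empty FASTA, fewer than 3 taxa, all-gap columns, pairs with no shared
ungapped columns) either produce clean empty results or raise errors
naming the offending records, as documented per function.
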