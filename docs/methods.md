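# Methods

This note documents the models, parameter choices and numerical conventions
behind `tetrarab`, and what the synthetic-data studies do and do not show
about real data.

## Motif-based Rab annotation

A candidate protein is annotated in three steps.

**Motif scan.** Each of the five Rab-diagnostic motifs (IGVDF, KLQIW,
RFRSIT, YYRGA, LVYDIT; 27 residues total) is located by exhaustive
ungapped-window search: the best-scoring window (matched residues, leftmost
on ties) is a hit when its mismatch count is at most `max_mismatch`
(default 2 per motif). Because the motifs correspond to ordered structural
elements of the G domain, hits must occur at strictly increasing positions;
motif *i* is searched only downstream of the reported motif *i−1*
(`ordered=False` disables this). Positions are reported 1-based; internal
computation is 0-based half-open.

**Family discrimination.** Every family's score is the sum over its motifs
of best-window matched-residue counts. The call goes to the arg-max family
provided its score reaches 40% of that family's maximum possible score and
strictly beats the runner-up (tie tolerance 0); otherwise the call is
`unknown`. The 40% floor and the 2-mismatch default were chosen so that
exact consensus sequences always pass while random sequences essentially
never do; both are configurable, as real divergent Rabs blur any fixed
cutoff. Consensus motifs for Ras, Rho, Arf/Sar and Ran were transcribed
from canonical human members (HRAS effector and switch-II segments, RHOA
P-loop and post-DTAGQ segment, ARF1 P-loop and interswitch, RAN P-loop and
post-DTAGQ segment); the whole library can be replaced via a
family-sectioned plain-text file.

**Prenylation.** Geranylgeranylation requires specific C-terminal
cysteines. The last four residues are tested against the anchored pattern
set CC, CXC, CCX, CCXX, CXXX, in that order, first match wins. The window
and pattern set are a fixed operationalization: the biological literature
does not enumerate a closed pattern list, and four residues cover every
pattern above.

**Verdict.** `Rab` = Rab family call, ≥ `min_motifs` (default 3) motif hits,
prenylatable; `Rab-like` = same but not prenylatable; everything else
`non-Rab`. How many of the five motifs, and how degenerate, should suffice
is a judgment call; the defaults are recorded in the configuration and can
be tightened to `min_motifs=5, max_mismatch=0` for strict consensus calls.

## Ciliate-code gene calling

The ciliate nuclear code (NCBI table 6) reassigns TAA and TAG to glutamine,
leaving TGA as the sole stop. `translate_ciliate` implements the full
64-codon table natively (the test suite compares it codon-by-codon against
an independently transcribed reference table). ORF prediction translates
the mRNA in all three forward frames, picks the frame with the most ordered
Rab-motif hits (lowest frame on ties), then:

- start = nearest in-frame ATG at or upstream of the first motif hit. This
  is the most conservative reading of "start sites shortly upstream of the
  first conserved motif"; an optional `max_start_distance` (default
  unlimited) caps the search.
- stop = first in-frame TGA downstream of the last motif hit.
- an in-frame TGA *between* motifs raises an error by default
  (`on_internal_stop="truncate"` instead ends the model there).

Transcripts are treated as intronless mRNAs; the reverse strand is not
searched. Both match how ciliate Rab gene models are curated against
EST-confirmed mRNAs rather than raw genome sequence.

## Pairwise alignment and reciprocal best hits

`align_pair` is an affine-gap optimal alignment (global or local) computed
with Biopython's `PairwiseAligner`; defaults are BLOSUM62 with gap open 11
and extend 1, i.e. a gap of length *L* costs 11 + *L* (BLAST-style). A
brute-force enumeration oracle in the test suite verifies optimality on
all small inputs. `percent_identity` counts identical aligned positions
over all aligned columns; whether gapped columns enter the denominator is
a flag (`count_gaps`, default on), because published identity figures
rarely state their convention. Reciprocal best hits require each partner
to be the *unique* top-scoring hit of the other; ties are dropped rather
than broken arbitrarily, for determinism. No heuristic seeding or E-value
model is provided — at family scale, exact scoring is affordable and
simpler to reason about.

## Phylogenetics

**Trimming.** The Rab C terminus (the hypervariable region, typically
30–80 residues) carries targeting information but no phylogenetic signal at
deep divergences. In `auto` mode, every alignment column beyond the column
of the last Rab-motif residue (maximized over rows, so no sequence loses
motif columns) is removed; a numeric trim instead gaps out a fixed number
of C-terminal residues per sequence. All gap-bearing columns are then
dropped, and trimming leaving fewer than 10 columns is an error. The
operation is idempotent. Trimming precedes bootstrap resampling.

**Distances.** p-distance (mismatches over compared sites, pairwise
deletion of gaps — after gap-column removal, pairwise and complete deletion
coincide) or Poisson correction −ln(1 − p), which errors on saturated
pairs rather than returning infinity.

**Neighbor joining.** Standard Saitou–Nei agglomeration on the Q
criterion. Determinism: Q values are rounded to 12 decimals and ties are
broken by the lexicographically smallest pair of cluster labels (a cluster
is labeled by its smallest leaf id). Negative branch lengths are clamped
to zero. The result is an unrooted tree stored with a trifurcating seed
node; NJ is exact on additive matrices, which the test suite exercises
with randomized additive-tree oracles up to 12 taxa, and cross-checks
against dendropy's independent NJ implementation.

**Bootstrap.** Columns are resampled with replacement per replicate
(100 replicates by default), the NJ tree is rebuilt, and bipartition
frequencies (percentages) are written onto the full-data tree — supports
map to the full-data tree, not the consensus, following Phylip/PhyML
convention. All resampling uses a single seeded generator, so output
Newick strings are byte-identical across runs at a fixed seed.

**Consensus.** Majority rule: bipartitions in strictly more than half of
the input trees (such a set is always pairwise compatible), supports =
occurrence percentages, no branch lengths.

**Conservation classification.** For each query and each method tree, the
*smallest supported clade* is the smallest subtree, under the tree's
displayed rooting, with support ≥ 50 (the usual display threshold for
bootstrap values) that contains the query plus at least one other leaf;
trees supplied without support annotations are treated as fully supported.
A query is `conserved` when that clade contains a non-ciliate reference in
at least 2 method trees, `lineage-restricted` when the clade exists and is
all-ciliate in *every* method tree, and `divergent` otherwise. The quorum
of 2 mirrors the practice of accepting topological conclusions supported
by two of three inference methods; the smallest-supported-clade rule
replaces by-eye clade reading with a reproducible criterion. Maximum
likelihood and Bayesian inference are not implemented; such trees enter as
Newick.

## Expression analysis

The stage grid is fixed: growth at three densities (Ll, Lm, Lh), seven
starvation time points (S0, S3, S6, S9, S12, S15, S24) and ten conjugation
time points (C0–C18 in 2 h steps). A gene is `expressed` in a condition
when any in-condition stage exceeds the background threshold (strict >;
the threshold is an absolute intensity with no universal default —
microarray background depends on the platform, so it is a required,
explicit parameter with a default of 100 AU).

A *discrete peak* is a stage whose value strictly exceeds
`fold_threshold` (default 2) times the maximum over the other
non-excluded stages of its condition block — the strongest reading of a
">2-fold peak at a distinct time point", and scale-free by construction.
S0 is excluded by default because it coincides with transfer to starvation
medium and is hard to interpret; the exclusion set is configurable. The
growth block participates in peak calling like any other block. Missing
stages flag the profile but do not drop it.

## Colocalization

Thresholds per channel: `fraction_of_max` (default 0.5) takes the given
fraction of the dynamic range above the image minimum — so a constant
image yields an empty mask under the strict-> rule, and a zero-background
image reduces to fraction × max; `absolute` and `quantile` are also
available. Manual per-image thresholding is not reproducible, so
a deterministic rule replaces it. A channel's overlap is the sum of its
intensity over the AND mask divided by the sum over its own mask (0 for an
empty mask). This intensity-sum fraction is the primary statistic because
it is guaranteed to lie in [0, 1] and registers 1.0 for complete overlap;
the mean-intensity-ratio variant (AND-mask mean over channel-mask mean) is
available behind `use_mean_ratio` but is not bounded by 1. Cell batches
with fewer than 4 analyzable cells get no summary unless forced, matching
the minimum sampling of the imaging protocol; per-cell failures are
isolated and reported.

## Synthetic data

The generators are pure functions of (seed, parameters).

- `simulate_rab_gene` plants the five Rab motifs (or Ras motifs for
  non-Rab) on random linkers, appends a class-appropriate C terminus, and
  back-translates under the ciliate code with uniform codon choice, random
  UTRs and a planted TGA stop. Linkers exclude Met and Cys so the planted
  start and prenylation signal are unambiguous — real genes offer no such
  guarantee, so perfect recovery on simulations bounds, but does not
  measure, performance on curated mRNAs.
- `simulate_family` evolves a root sequence along a tree under
  independent-site uniform replacement (each site on a branch of length
  *b* substitutes with probability 1 − e^(−rate·b) to a uniformly chosen
  different residue). This Jukes–Cantor-like model keeps an analytic
  handle for tests; it does not reproduce empirical exchangeabilities
  (WAG), site-rate variation, or indels, so bootstrap values on simulated
  families are optimistic relative to real Rab alignments. Optional iid
  per-leaf tails emulate the hypervariable C terminus.
- `simulate_expression` multiplies a flat baseline (peak stages scaled by
  the planted fold) by iid log-normal noise with mean 1 and the stated
  coefficient of variation (σ² = ln(1 + CV²)). Real microarray noise is
  neither iid nor purely multiplicative; no probe-level or normalization
  artifacts are modeled. Under this model the strict >2-fold rule detects
  fold-3 peaks with ≈0.99 sensitivity at CV 0.1 but only ≈0.73 at CV 0.2
  (the extreme value of the comparator block eats most of the 3/2 margin)
  — an intrinsic property of peak-over-maximum detection, reported
  honestly by the acceptance script.
- `simulate_coloc_image` renders equal-amplitude isotropic Gaussian puncta
  at well-separated integer pixel centers, with a chosen fraction of green
  puncta sharing centers with red ones. Equal footprints make the planted
  fraction recoverable to numerical precision at zero noise; real images
  add background, uneven amplitudes and chromatic offsets that this does
  not emulate.

## Problem sizes

The test suite and acceptance script use desk-scale studies chosen to make
each property measurable with comfortable margins: 500 random pairs for
the alignment oracle (lengths ≤ 9), 1000 sequences for the motif-scan
oracle, 200 random additive matrices (≤ 12 taxa) for NJ exactness, 100
seeded simulations each for ORF and topology recovery (8 taxa, 300 sites,
rate 1.0), 500 planted peaks and 300 flat genes for the expression study,
and 15 image pairs across five planted fractions for colocalization.

## Known limitations

- No profile (HMM/PSSM) models: motif scanning is consensus-based, which
  underestimates sensitivity on deeply divergent family members.
- No alignment construction: multiple alignments are consumed, not built.
- Conservation calls depend on the displayed rooting of input trees and on
  the support threshold; both are explicit parameters.
- The packaged localization table covers primary localizations only;
  secondary localizations were never machine-readable in the source.
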