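# Methods

## The problem and the model

Given a multiple sequence alignment that contains one *reference* protein
(typically dysfunctional) and a large family of functional homologs, plus a
3D structure of one functional family member, `mu8` quantifies where and how
the reference deviates from its family in terms of amino-acid biophysical
properties, and places those deviations in conservation and spatial context.

The central statistic is the per-position, per-characteristic **c-score**

    cs(p, r) = ( is_ref(p, r) − mean_fam(p, r) ) / sigma_fam(p, r)

where `p` is a biophysical characteristic (an amino-acid index scale, or a
PC1 representative of a class of such scales), `is_ref(p, r)` is the value
of `p` for the reference residue at cropped position `r`, and the mean and
standard deviation are taken over the family's residues in the same
alignment column. The score is a conservation-weighted z-like deviation: a
substitution in a variable column scores low even if its property value is
unusual in absolute terms, while the same substitution in a conserved column
(small sigma) scores high. The method's working assumption is that
large |c| in conserved regions flags substitutions likely to disturb
function.

### Family statistics

* The family **excludes the reference** by default. The statistic contrasts
  reference against family; including the reference shrinks its own
  deviation. `include_reference_in_family=True` restores inclusion.
* The standard deviation is the **population** form (divisor *n*): the
  column's residues are treated as the complete comparison population, not a
  sample from a larger one. The same convention standardizes index scales,
  whose 20 residue values are likewise a complete population.
* Gaps, `X`, and residues whose scale value is missing are excluded from a
  column before computing mean/sigma. A column with one contributor keeps
  its mean but has no sigma; its c-score is undefined (NaN).
* Columns whose contributing values are exactly identical are snapped to
  sigma = 0 exactly; the naive two-pass formula otherwise leaves
  ~1e-16-level noise that the sigma floor (below) would incorrectly rescue
  into O(1) spurious scores.

### The sigma floor

The c-score divides by sigma, which is exactly 0 in perfectly conserved
columns. Rather than produce infinities or drop those columns — the most
interesting ones — the denominator is floored:

    sigma_eff = max(sigma, f · median{ sigma > 0 })      f = 0.01 by default

A deviation in a perfectly conserved column therefore scores ~100× the
typical column's score, preserving the ranking intent ("huge deviation where
the family never varies") with a finite number. Every floored cell is
flagged (`sigma_floored`) and logged, so the edit is auditable. `f` is
exposed as `sigma_floor_frac`.

### PC1 representative scales

With hundreds of published index scales, users either pick specific
accessions (`indices` mode) or use one representative per characteristic
class (`pc1` mode, default). The six classes follow the conventional
grouping: alpha/turn propensity, beta propensity, hydrophobicity,
composition, physicochemical, and a catch-all *other*. Class membership
comes from a user-editable TSV; a best-effort default map of well-known
accessions ships with the package, and unmapped accessions fall into
*other* so arbitrary AAindex snapshots load.

Each class member is standardized (mean 0, population sd 1 over its 20
residue values; scales with missing values are dropped with a warning), and
the class's scales are treated as points in 20-dimensional residue space.
PC1 is the leading eigenvector of the **uncentered** second-moment matrix
`XᵀX/n`. Uncentered is deliberate: the scales are already centered
individually, and centering across as few as two observations would always
produce a rank-1 matrix and a meaningless variance share of 1.0; the
uncentered form gives the natural answers in the degenerate cases (k
identical scales → share 1.0; two orthogonal equal-norm scales → 0.5).
`variance_explained = λ₁/Σλ` is reported per class so users can judge how
representative the single scale is. Sign is fixed by orienting PC1 to
correlate positively with the elementwise mean of the inputs (tie: largest
loading positive), making runs and permutations reproducible.

### Conservation rows

The heat-map statistic is the per-position family sigma of the
characteristic's index values — the denominator the c-score already
computes. (A per-family "variation of c-scores" is not well defined, since
c-scores exist only for the reference; sigma is the quantity that captures
the intended "variation of the characteristic in the family".) Each row is
min-max normalized to [0, 1] for display; an all-equal row renders as fully
conserved (all 0). Raw sigmas are exported alongside so no information is
lost to normalization.

### Histograms, filters, stacks

Score histograms use 40 equal bins on [−3, +3] sigma. Scores beyond the cap
are counted in the edge bins *and* tallied separately
(`n_clamped_low/high`): the display is outlier-robust but no observation is
silently dropped. Filters are closed intervals `[lo, hi]` over finite
scores. The stacked-bar layout partitions characteristics at each position
by score sign (zeros omitted), with segment magnitude |c| clamped at 3 to
match the histogram cap and the raw value preserved alongside. The
characteristic order is fixed (alpha/turn, beta, hydrophobicity,
composition, physicochemical, other) across histograms, stacks, and
conservation rows, so the left-to-right histogram order equals the
top-to-bottom heat-map order.

## Structure handling

Cα coordinates are read from PDB `ATOM` records (first model; HETATM
ignored; altlocs resolved by highest occupancy, first on ties; residues
without a Cα are skipped with a warning; the first chain is the default —
for homodimeric enzymes any protomer serves, and `--chain` overrides).

The chain is linked to the cropped reference by sliding its residue string
ungapped along the reference and taking the identity-maximizing offset,
accepted at ≥ 95% identity over the overlap; to prevent a trivially short
perfect overlap from winning, only offsets covering at least half of the
shorter sequence are considered. An explicit offset bypasses the check
(needed e.g. for Cα-only traces with uninformative residue names).

Proximity is the Euclidean Cα–Cα distance in Å. For a focus region (a
contiguous window of ≤ 15 reference positions), each outside residue gets
its **minimum** distance to any focus residue — the min, not the mean,
matches the "sphere of influence" reading of within-distance membership.
Residues qualifying for a user-chosen band `d_lo ≤ d ≤ d_hi` (default
0–8 Å, a conventional Cα contact cutoff; fully brushable) are merged into
maximal runs of consecutive positions; each run becomes one chord with the
run's minimum distance and a brightness rank (0 = closest = darkest).
Sequence neighbors of the focus are *not* excluded by default (trivially
close residues are real neighbors); `min_seq_separation` provides
contact-map-style exclusion for users who want it. The proximity histogram
uses fixed 2 Å bins from 0.

## Synthetic data generator

The `fixtures` module emulates the statistical structure of a real study at
the scale of a triose-phosphate isomerase family — defaults: L = 248
residues, N = 200 family members, a 7-residue implanted anomaly at positions
150–156 — without any external downloads.

* **Scales**: within each class, scale = √ρ·prototype + √(1−ρ)·noise with
  ρ = 0.7, giving realistic within-class correlation and a dominant PC1
  (the generated classes come out at roughly 50–80% variance explained).
* **Family**: a uniform-random consensus; each family sequence substitutes
  each position independently with a per-position probability (default 0.15
  everywhere — of the order of the residue variability seen in large enzyme
  families; configurable per position), uniformly over the other 19
  letters.
* **Anomaly**: the reference equals the consensus except inside the anomaly
  window, where each residue is greedily chosen to maximize the summed
  |standardized index deviation| from the family column mean over one
  designated scale per class. Greedy maximization guarantees a detectable
  multi-characteristic signal; the `strength_sigma` field records the
  intended magnitude but does not constrain the greedy choice.
* **Gap columns**: ~2% extra columns are inserted in which the reference
  row is `-` (family rows get random residues or gaps). Cropping removes
  exactly these, exercising the crop path while keeping reference numbering
  1..L stable; the reference's own residues are never gapped.
* **Structure**: a self-avoiding random walk with exact 3.8 Å steps
  (consecutive-Cα convention) and ≥ 3.0 Å pairwise separation enforced by
  rejection with back-off; optionally labeled with the reference sequence so
  automatic structure mapping works.

All generators are pure functions of spec + seed (byte-identical reruns).

What the generator does **not** emulate: phylogenetic correlation between
family members (sequences are i.i.d. given the consensus — real families
have tree structure, which inflates the effective conservation of clades),
insertions in the family relative to the reference, realistic secondary
structure in the Cα trace, and correlated substitution processes
(substitutions are uniform over the 19 alternatives rather than
BLOSUM-like). Passing tests therefore demonstrate the pipeline's
correctness and the statistic's ability to localize implanted
multi-characteristic deviations, not calibrated power on real evolutionary
data.

## Numerical choices

* Missing values are NaN internally and `null` in JSON; all reductions are
  NaN-aware. JSON numbers carry 6 significant digits.
* PC1 eigenvalues below 1e-12 of the largest are treated as exact zeros, so
  degenerate (rank-1) classes report variance_explained exactly 1.0.
* Histogram bins are half-open with a closed last bin (numpy convention),
  so the cap value itself is always counted.
* Alignment letters outside the 20 standard residues plus `X`/`-` map to
  `X` with a logged warning; `.` is accepted as a gap alias.
* Positions are 1-based everywhere a user sees them (files, JSON, CLI);
  column indices in `colmap` are 0-based into the original alignment.

## Problem sizes used in the test suite

The shipped tests run the full study design (L = 248, N = 200, 30 scales)
for the recovery check — it completes in well under a second — and smaller
alignments (5–8 sequences, 10–15 columns) for oracle-equivalence checks
against straight-line loop reimplementations. Property-based tests use
derandomized hypothesis profiles for reproducibility.

## Known limitations

* One reference, one chain, one model: no ensembles, no mmCIF, no
  family-wide structural variation.
* Family insertions relative to the reference are cropped away, not
  analyzed.
* No multiple-testing control over c-scores; the score is a screening
  statistic, and index relevance remains a user decision.
* The default class map is a best-effort reconstruction of the conventional
  six-class grouping and will classify unlisted accessions as `other`.
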