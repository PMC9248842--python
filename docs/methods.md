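# Methods

## Problem and model

A protein model built into a cryo-EM map carries a sequence-assignment
hypothesis: residue *i* of chain *c* is amino acid *m*ᵢ. A register shift is
a systematic violation of that hypothesis over a contiguous stretch — the
backbone is traced through the right density but the identities are displaced
by a fixed offset *k* along the sequence. `registercheck` treats validation as
hypothesis testing: the map (through a residue-type classifier) supplies, for
each modelled residue, a probability distribution over the 20 standard types;
the most plausible ungapped placement of a fragment's profile on the reference
sequence either confirms the model's register or proposes a better one, and an
assignment p-value decides whether the evidence is sufficient.

Working assumptions: fragments are continuous (no gapped alignment — the
backbone trace fixes the spatial order of residues); modified residues are
excluded from windows; the reference sequences supplied by the user contain
the true sequence of every chain; profile rows are treated as independent
across positions when scoring (the classifier sees overlapping density, so
this is an approximation — the shuffle-based null absorbs most of its effect).

## Placement score and p-value

A profile of length *L* placed at offset *o* of reference *R* scores
`S(o) = Σ_i log p_i(R[o+i])`; the best placement is the argmax with ties
broken towards the smallest offset. Significance is calibrated per fragment
against a null of `n_null` composition-preserving shuffles of the *same*
reference, which controls for both reference length and composition bias in
one construction. Because the null statistic is a maximum over all placements,
its distribution is extreme-value-like; the estimator is a hybrid:

* while at least 5 of the null best-scores reach the observed score the
  empirical rank `(1 + #null ≥ obs)/(n_null + 1)` is returned — under the
  null the observed score is exchangeable with the shuffled ones, so this is
  calibrated by construction (measured: fraction of null p-values < 0.05 is
  0.03–0.05 across seeds);
* deeper in the tail a right-tail Gumbel fit (MLE) to the null best-scores
  extrapolates the probability, floored at 10⁻³⁰⁰ so no p-value is exactly
  zero. A zero-variance null (uniform profile) returns p = 1.

A pure Gumbel fit was measurably conservative near p = 0.05 and inaccurate in
the bulk (checked against exact enumeration on a two-letter reference); the
hybrid keeps the extreme-value extrapolation exactly where the empirical rank
runs out of resolution.

The decision threshold defaults to p ≤ 10⁻³. The original construction — the
lower bound of a 99.5% one-sided confidence interval over mismatched-fragment
p-values from a PDB-scale survey — is available as
`calibrate_threshold` / `registercheck calibrate-threshold`, which fits the
same quantile from user-supplied or synthetic mismatch p-values (synthetic
mismatches at the default conditions give a threshold of order 10⁻²–10⁻³,
consistent with the shipped default).

## Windowing and adaptive extension

Chains are segmented at residue-numbering gaps, intervening non-standard
residues, missing Cα atoms and Cα–Cα distances above `max_ca_gap` (default
4.5 Å — chosen above any plausible bonded Cα–Cα distance, including cis
peptides, and below the ~5.5 Å of a broken trace; configurable because only
the continuity requirement itself, not its metric form, is intrinsic to the
method). Insertion codes order after the bare number and do not break
continuity. Windows of length 20 advance in steps of 5; a final end-anchored
window guarantees full coverage, and segments of 10–19 residues form a single
full-segment window. Windows whose p-value exceeds the threshold are
re-scored at lengths 40 then 60, grown symmetrically about the window centre
and clipped at segment ends, stopping early once conclusive. Longer windows
trade localization for power, which compensates for low local resolution and
coordinate error; both directions are verified in the acceptance tests.

## Verdicts and issue regions

Each final window receives exactly one of four verdicts: `NO_REFERENCE`
(chain-level identification failed), `INCONCLUSIVE` (p above threshold),
`CONFIRMED` (confident, assigned sequence equals the model) or
`REGISTER_ERROR` (confident, differs). The suggested shift of a flagged
window is the assignment offset minus the offset implied by the chain's
global ungapped alignment to the reference. Overlapping or adjacent flagged
windows with a common shift merge into one region reported in author residue
numbers with the corrected assignment of its most confident window;
differing shifts stay separate regions.

Confident windows assigned at the model's own register but differing at a few
letters are routed to the sequence-mismatch check: differing positions are
pooled across windows, contiguous runs longer than `mismatch_max` (default 2)
are left to the shift logic, the rest are reported as point substitutions
(model vs reference letter). Pooling before the cutoff matters: a window that
clips two letters of a three-letter run would otherwise misreport them as
point mismatches. Finally, where confident model-agreeing assignments flank a
coordinate break, the difference of their reference offsets is compared with
the author residue-number difference; a discrepancy (e.g. continuous
numbering across a five-residue physical gap) is reported as a numbering
problem with its size.

## Residue-type scorers

The scorer contract is deliberately narrow: backbone coordinates and map in,
one normalized probability row per residue out, deterministic, and blind to
the model's recorded identities. Three sources satisfy it:

* **Baseline density scorer.** For each residue a local frame is built from
  N–CA–C; each of the 20 types gets an idealized side chain (CB from
  tetrahedral geometry; chain atoms in a trans zig-zag approximating the most
  common rotamer; branches and planar rings for the aromatics; electron-count
  weights, so sulfur and aromatic types are heavy and bulky). Gaussian-atom
  template density (σ = 0.25 × working resolution) is rendered on the map
  voxels within 2 Å of any template atom, and the Pearson correlation between
  template and map over that union footprint ranks the types. Correlations
  map to probabilities by softmax at temperature 0.04, chosen so per-residue
  entropy on the self-consistency fixture sits mid-range between one-hot and
  uniform (≈1.6 nats of a 3.0-nat maximum). Degenerate frames (collinear
  backbone) and featureless map regions yield uniform rows with a warning.
  Self-consistency at 2.5 Å: 85–90% top-1 on a 40-residue fixture.
* **External profile table.** A TSV keyed by chain and residue number carries
  rows from any upstream classifier; chains validate map-free.
* **Synthetic generator** (below).

The neural-network classifier of the tool this package models itself on is
deliberately out of scope — its trained weights are not reproducible in a
clean-room build — and the baseline is a genuine, if simpler, density scorer,
not a numerical stand-in for the network's outputs. Everything downstream of
the profile is the method proper.

## Reference identification

The profile of the chain's longest continuous segment is placed on every
database sequence; the per-sequence placement tail probability times the
database size gives the E-value (a Bonferroni-style expected count of chance
hits, matching the standard definition). Matches above the cutoff (default
10⁻³) are discarded; an empty list is the "reference cannot be identified"
verdict. Uniform profiles produce degenerate nulls (p = 1) and therefore
never match.

## Map operations

Volumes are read and written as MRC/CCP4 2014 via gemmi, with the axis
permutation undone from the MAPC/MAPR/MAPS header directly so the grid start
is preserved (the periodic wrap that a library-side "setup" applies would
silently move the map relative to the model for nonzero NXSTART). Grids are
float64 in memory: B-factor sharpening amplifies high-frequency quantization
noise, and single precision would break the exact inverse
blur(+B)∘sharpen(−B) = identity on band-limited maps. Resolution truncation
zeroes Fourier coefficients with d < d_min (default 2.5 Å) on the full-map
FFT without resampling; |s|² is computed from the reciprocal metric tensor,
so non-orthogonal cells are handled. Local-resolution values are averaged
over voxels whose centres lie within 2 Å of any fragment atom; non-positive
or non-finite voxels count as undefined, and a fragment with no defined voxel
in range proceeds without resolution annotation.

## Synthetic data: what it emulates and what it does not

The generator produces reference sequences (uniform composition by default),
profiles, register-shifted stretches, jittered coordinates and Gaussian-atom
maps. Profile quality is set by `top1_accuracy`, interpreted as the
*expected probability mass on the true type*: each row gives the truth a
Beta-distributed probability with that mean (strength 30) and spreads the
rest over the other 19 types with a symmetric Dirichlet. The limits behave
correctly (one-hot at 1.0; indistinguishable from uniform at 1/20), and the
default 0.6 produces assignment behaviour comparable to a good classifier at
moderate resolution. A fixed logistic curve maps a pseudo-local-resolution in
Å to accuracy (0.9 at 2.5 Å, 0.1 at 8 Å, midpoint 5.25 Å) — a declared
emulation of classifier-confidence decay, not a measured curve. Register
shifts replace span letters with reference letters *k* positions away;
coordinate jitter applies independent isotropic Gaussian displacements
rescaled so the realized all-atom r.m.s.d. equals the target exactly.

What the synthetic fixtures do **not** model: real cryo-EM noise (CTF,
B-factor heterogeneity, anisotropy), solvent and ligand density, rotamer
diversity, crystallographic/point-group symmetry, and classifier error
correlations along the chain. Passing tests therefore demonstrate the
statistical machinery — calibration, recovery, specificity, directionality —
under controlled conditions, not end-to-end performance on experimental
reconstructions, for which profile quality is the dominant unknown.

## Problem sizes and numerical choices

Test and acceptance computations use chains of 120–200 residues, null
ensembles of 100–200 shuffles, 500 calibration simulations, 100 + 100
recovery/control runs and 20 identification trials against 50-sequence
databases; these sizes give binomial standard errors comfortably inside the
asserted bands while keeping the default suite around a minute. Probability
floors: profile log-probabilities are clipped at 10⁻¹⁰; p-values at 10⁻³⁰⁰.
Ties in placement scores break to the smallest offset for determinism. All
randomness flows through explicit `numpy.random.Generator` objects; two runs
with the same inputs and seed produce byte-identical reports.

## Known limitations

Short register shifts (span ≲ 10 residues) are diluted inside 20-residue
windows and may not reach significance — suspect regions shorter than that
are still reported, never suppressed. Fragments are ungapped, so
insertion/deletion-type tracing errors appear indirectly (as flanking shift
or numbering issues) rather than as first-class verdicts. The baseline scorer
uses a single rotamer per type and no B-factor model; at resolutions worse
than ~4 Å its profiles approach uniform and chains become inconclusive rather
than wrong. E-values assume database sequences are exchangeable with
composition-preserving shuffles, which underestimates significance for highly
biased compositions.
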