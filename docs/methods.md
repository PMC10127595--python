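# Methods

## Scope and data model

The package analyses the read-coverage signature left on a lysogen's
genome by its spontaneously produced phages. The central intermediate is
the per-base `CoverageTrack` of the induced-phage sequencing fraction;
everything upstream (read simulation, k-mer mapping) exists to produce
such tracks with known ground truth, and everything downstream
(segmentation, classification, comparison) consumes them. Coordinates are
0-based half-open internally and converted to 1-based inclusive only at
reporting and serialization boundaries, keeping interval arithmetic
unambiguous and BED-compatible.

## Synthetic-data generator

`simulate_genome` draws i.i.d. bases at a requested GC content (default
0.635, typical of rhizobial chromosomes) and plants features with full
ground-truth records:

* **Prophages** carry an expected core coverage rate λ_c and an optional
  one-sided flank: a `flank_extent`-bp interval abutting exactly one core
  boundary at rate λ_f, either flat or decaying geometrically with
  distance (parameter per kb). The flat default reflects that only a
  coverage *range* is observed for flanks, not a shape; the physical
  extent of over-packaged flanks is unknown, so `flank_extent` is a free
  parameter. Flank over-packaging is modeled phenomenologically — no
  terminase/packaging mechanics are simulated.
* **IS elements** are planted as identical copies per family (one random
  sequence per family, spliced at every copy site). Identity across
  copies is exactly what produces multi-mapping downstream.

`simulate_phage_reads` samples read start positions with per-base
intensity rate/L (L = read length), so the expected per-base coverage
equals the analytic profile returned by `expected_coverage_profile`, up to
ramps of width L at rate steps. Replicons are circular by default — reads
wrap the origin — while the caller treats tracks as linear; planted
features are kept away from the origin, so wrap handling only affects the
simulator and mapper. Errors are substitutions only (sufficient for a
coverage-level analysis; keeps the built-in mapper gap-free). Contaminant
reads, emulating sequencing-kit taxa that map nowhere, are drawn from a
fixed-seed 50-kb random sequence disjoint from the genome. A configurable
expected-read-count cap (default 5 million) refuses accidental
larger-than-desk-scale runs. All outputs are deterministic for a fixed
seed.

The reference fold profile is background 35×, flank 1,000×, core
70,000×. Because every decision downstream is fold-based, tests that need
read-level simulation use scaled-down absolute depths with the same fold
ratios (e.g. background 1×, core 1,000× on ≤ 300-kb replicons) to stay
fast; tests that operate at the track level use the full profile via
`sample_coverage_track`, which Poisson-samples the analytic profile
per-position — equivalent in per-base distribution to simulate-and-map,
minus edge ramps and mapping noise.

What the generator does **not** emulate: real genomes' compositional
structure (GC skew, repeats beyond the planted IS), mappability variation,
GC-dependent library bias, indels, polymorphic prophage subpopulations,
and coverage autocorrelation from fragment-size distributions. Passing
tests therefore demonstrate that the caller recovers the *designed*
statistical structure (Poisson noise around a step-like fold profile with
repeat artifacts), not that it is robust to every artifact of real
libraries.

## Mapper

`build_index`/`map_reads` implement seed-and-verify placement: exact
k-mer anchors (k = 21 default, both strands, circular wrap indexed) at a
stride of k across the read, full-read verification with ≤ 2 substitutions
(for L ≈ 100 and error rates ≤ 1%, the expected number of errors per read
is < 1, and ≤ 2 errors can never cover all anchors, so every read within
the budget is found). All equally best loci are collected; the multi-map
policy then resolves them: `random_best` (seeded; the default, and the
semantics under which IS artifact peaks arise), `all_weighted` (1/n_best
at every best locus; variance-reduced and exactly conservative —
Σ track = Σ placed bases), or `unique` (discard ties). The aligner used in
the original experiments does not document its multi-map settings;
`random_best` is this package's explicit assumption, surfaced as a flag.
Paired mates are mapped as independent singletons — pairing adds nothing
at coverage level. The mapper exists so the pipeline is self-contained
and testable against a brute-force substring oracle; externally produced
BedGraph coverage enters through `read_bedgraph` on equal terms.

## Caller

* **Background**: global median of the track (zeros included), optionally
  excluding masked intervals. Enriched features occupy ≪ 50% of
  positions, so the median is insensitive to them.
* **Smoothing**: running median, window 201 bp (odd), edges truncated.
  A median preserves step edges (the crossing stays at the step for an
  ideal step) while removing isolated spikes narrower than half the
  window.
* **Segmentation**: per-position fold thresholds (defaults 500 / 10, set
  with wide margins between the observed core folds of ~1,700–4,300 and
  flank folds of ~15–60), maximal constant-level runs, same-level merging
  across ≤ 2 kb of strictly lower level. The 2-kb default bridges an
  IS-length in-core dip without risking fusion of distinct prophages
  (planted pairs are > 10 kb apart). Bridged gaps are recorded as
  `internal_dips`, reported but never interpreted. Segments shorter than
  200 bp are dropped.
* **Refinement**: applied to enriched segments only. Plateau = median of
  the segment interior; boundary threshold max(core_fold · background,
  plateau/2); boundaries move on the smoothed track, never extending a
  segment by more than one smoothing window. No single boundary rule for
  fixing exact prophage coordinates from a coverage track is in general
  use; this rule is the package's own, validated by ±200-bp recovery on
  Poisson-sampled tracks. A degenerate segment (plateau ≤ background) is flagged and passed
  through unchanged, never silently dropped.
* **Classification**: enriched ≥ 5 kb → core; elevated within 2 kb of a
  core → flank, attached but reported separately (flanks never extend the
  core's reported coordinates, since prophage coordinates conventionally
  exclude the over-packaged flanks); remaining
  segments overlapping an IS annotation and ≤ 2× its length → artifact
  with the IS named; anything left → artifact with an "unexplained" note.
  A genome whose phage fraction maps evenly except at IS elements (the
  gene-transfer-agent-like pattern) therefore reports 0 cores plus
  elevated IS artifacts rather than a distinct verdict.

No significance model is attached: the decision rule is magnitude-based
by design, and a Poisson/FDR-based caller is future work. Scale invariance
(all thresholds are folds) is tested as an invariant.

## Prediction comparison

Predictions (BED or GFF3; GFF3 starts decremented on load) are matched
many-to-one to the core with greatest base overlap, ties broken by
smaller summed absolute boundary offset, then leftmost — a deterministic
stand-in for the visual matching one would otherwise do. Reported per
match: Jaccard, base precision and recall of the prediction against the
core, signed boundary offsets; unmatched predictions are counted per
tool. The prediction tools themselves are never run here.

## Mobilome profiling

IS density is count / (length / 10⁶); rounding (none or nearest) is a
reporting convention recorded in output metadata. IS densities quoted in
the literature rarely state their length basis (chromosome only vs.
including plasmids) or their rounding, so no single convention is
forced. Windowed densities use the
midpoint rule (an element straddling a window edge is counted once —
window counts always partition the total). Family abundances are
log10(1 + count per Mb) with catalytic classes from a built-in table
(IS110 → DEDD, IS91 → HUH, ISCNY → unclassified, all other families DDE).
"Consecutive duplicates" counts adjacent same-family pairs with a gap ≤
`max_gap` (default 500 bp — there is no canonical gap, so
the value is exposed and reported alongside results); a run of n
contributes n − 1 pairs. The plasmid screen matches gene-name/product
word tokens case-insensitively: repABC requires all of repA/repB/repC,
tra and par require an operon gene token (`tra`/`traX`, `par`/`parX`), so
"transferase" is not a tra hit.

## Growth and virion statistics

Doubling time is g = t / (3.3 · log10(b/B)). A common microbiological
shorthand writes this formula without the logarithm; read literally that
form is dimensionally and numerically nonsensical (growth would drive
g → 0), and 3.3 ≈ 1/log10 2 only makes sense applied to the log of the
ratio, so the logarithmic form is implemented and noted in output
metadata. PLP:bacterium ratios are
computed per replicate and then averaged at matching timepoints (missing
timepoints skipped, not imputed). Capsid volume is the sphere formula
(4/3)π(d/2)³, reported to 2 significant figures; capsid volumes quoted
alongside TEM measurements are not always consistent with the sphere
formula, so the worked example anchors on a 70-nm capsid, where it is.
Genome size from capsid diameter uses a
packing density ρ ∈ [0.40, 0.53] bp/nm³, calibrated so a 60-nm capsid
implies 45–60 kb. The growth simulator integrates dP/dt = y·B(t) − δ·P
(`solve_ivp`) over exponential (optionally capped) cell growth, with
lognormal or Poisson observation noise; no induction-rate model is fitted
to data — only the descriptive statistics above are computed.

## Problem sizes and numerical choices

Test and acceptance runs use 120–300-kb replicons, 44,597-bp planted
prophages (a representative spontaneously produced prophage size), 50-seed
repetitions for stochastic recovery claims, and ~200k-read mapping runs —
sizes chosen so the full suite runs on a laptop-class single core in
minutes while keeping every fold ratio at the reference values. Ties
and degenerate inputs: all-zero tracks error ("no background signal"), even smoothing
windows and non-monotone timepoints are rejected at construction, the
mapper counts rather than errors on unplaceable reads, and an empty read
set makes `mapped_fraction` an error rather than NaN.

## Known limitations

The caller assumes a single dominant background level per replicon; a
plasmid-rich sample with very different per-replicon depths should be
called per replicon (as the API does). Boundary refinement inherits a
read-length-scale ramp (~L/2) when coverage comes from mapped reads
rather than direct per-base sampling. The monotonicity of call counts in
`core_fold`/`merge_gap` is verified empirically on planted profiles, not
proven for adversarial tracks.
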