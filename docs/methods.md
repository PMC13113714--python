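# Methods

## Acoustic model

Each airway is idealized as a straight cylindrical tube of acoustic length
*L* carrying standing waves at speed of sound *v*. Two boundary conditions
are used:

- **open–open** (air enters at the internal naris and leaves at an anterior
  opening or the external naris): resonances at *f_k = k·v / 2L*,
  *k = 1, 2, …*;
- **open–closed** (a diverticulum or median chamber that dead-ends inside a
  crest): resonances at *f_k = (2k−1)·v / 4L* — only odd partials exist, and
  the fundamental is an octave below the open tube of the same length.

Conventions and caveats:

- *Harmonic rank.* "k-th harmonic" is a rank in the resonance series, not a
  frequency multiplier. The 2nd harmonic of a closed tube is 3× its
  fundamental. This uniform counting is used everywhere (types, tables,
  tests).
- *Speed of sound* defaults to 343 m/s (dry air, 20 °C) and is configurable.
  Because every modeled frequency is proportional to *v*, group contrasts
  and overlap fractions are invariant to its exact value; only absolute Hz
  change.
- *End corrections.* The idealized model treats tube mouths as exact
  pressure nodes. A classical unflanged-pipe correction (0.6 × radius per
  open end) is available through `end_correction_m` but off by default; at
  the length-to-radius ratios of these airways the correction is a few
  percent, well below the uncertainty of measuring a convoluted cavity with
  a single path length.
- *What the model is for.* Tube resonance ranks taxa and clades by relative
  resonant regime. It does not reconstruct actual vocalizations: no vocal
  source, wall impedance, radiation or soft-tissue geometry is modeled.

Measurement enters only as a calibrated path length: landmark chains in
pixel units, summed segment-by-segment and scaled by a meters-per-pixel
factor from a scale bar. Lengths start at the internal naris; open routes
end at the anterior opening of the passage (or the posterior extremity of
the external naris), closed routes at the closed extremity. Whether a
curved diverticulum is traced as a midline curve or chorded is the
measurer's choice; both are accepted, neither is enforced.

## Group comparison

The unit of observation is one airway pathway: at harmonic rank *k* each
airway contributes its *f_k*, and groups are compared per rank with a
two-sided two-sample t-test (pooled-variance Student by default, Welch by
flag). For pairs of open-airway groups the t statistic is identical across
ranks (every *f_k* is a common multiple of *f_1*); between closed- and
open-airway groups it drifts with rank because the odd-multiple and
integer-multiple ladders diverge — which is why significance can sharpen
"with increasing harmonic level" in mixed comparisons.

Group-level contrasts use adult specimens only by default: immature crests
house shorter airways and would mix ontogenetic with taxonomic variation.
Raw p-values are reported; Holm/Bonferroni adjustment is available but off,
since the per-rank tests on a shared fundamental are strongly dependent and
a blanket correction would be misleadingly conservative.

Range overlap is plain interval arithmetic on per-group min/max envelopes:
overlap length `max(0, min(hi) − max(lo))` and the fraction of the first
range covered (asymmetric by design: "how much of A lies inside B").
Beat frequencies are |f_k^A − f_k^B| per rank for a co-excited airway pair.

## Parsimony

Tree length is computed by generalized (Sankoff) dynamic programming with a
per-character cost matrix — unit costs for unordered characters (equivalent
to Fitch counting) and |i−j| state distances for ordered (additive)
characters. This one algorithm exactly handles polytomies (scored as-is,
soft-polytomy semantics), polymorphic cells (zero leaf cost for every
admissible state) and missing data (`?`/`-` cost zero everywhere, so a
missing cell can never add steps).

Ensemble indices follow the conventions of standard parsimony software:
per character, *m* is the exact minimum steps attainable on any tree
(smallest state subset hitting every cell, minus one, for unordered; the
unavoidable interval span for ordered — both account for polymorphism,
where a naive "observed states − 1" count can exceed the tree score) and
*g* is the score on the completely unresolved bush, computed with the same
DP. Sums over active characters (×weight) give M and G, then CI = M/S and
RI = (G−S)/(G−M); RI is undefined (reported as missing) when G = M. All
variable characters are included by default, uninformative ones too;
`informative_only` excludes them. CI/RI are carried at full precision and
rounded half-up to three decimals only in reports.

Ancestral mapping returns, per node, the set of states realized in at least
one most-parsimonious reconstruction (leaf nodes report their observed
cells). Minimum independent origins of a binary trait is the smallest
number of ancestral→derived transitions among reconstructions of minimal
total change, computed by a lexicographic (changes, gains) DP with the root
held at the ancestral state — the natural convention when the tree is
rooted on an outgroup lacking the trait; if no reconstruction permits an
ancestral root the constraint is dropped.

Search is deliberately modest: exhaustive enumeration to ~8 taxa (the
oracle for everything else) and a seeded random-addition + NNI hill-climber
for desk-scale matrices. Replicating any particular program's heuristic
trajectory is a non-goal; deposited trees are scored, not rediscovered.

## Synthetic cohort

The generator emulates the comparative study design so every stage runs
offline: 14 species / 17 individuals in three groups —

- 5 lambeosaurine species, each with a closed median-chamber airway and a
  slightly shorter (×0.9) closed lateral diverticulum, so the diverticulum
  fundamental is slightly higher; the first two species add ontogenetic
  series (juvenile + subadult; juvenile), with airway lengths scaled by
  0.5 / 0.8;
- 4 saurolophine and 4 plain non-hadrosaurid species with one open primary
  airway each;
- 1 focal early-branching taxon (subadult) with three fixed open pathways:
  primary 0.2549 m, anterodorsal 0.6305 m, anteroventral 0.4135 m —
  lengths back-calculated from its reported ~672 / ~272 / ~415 Hz
  fundamentals.

Lengths are log-normal (positive, right-skewed across taxa). Medians and
log-sds are set so the ±2σ band matches the reference ranges: closed
lambeosaurine airways ≈0.56–1.48 m (fundamentals ≈58–154 Hz; median 0.91 m,
log-sd 0.25) and open airways ≈0.19–0.43 m (fundamentals ≈400–900 Hz;
median 0.286 m, log-sd 0.18). All randomness flows from one integer seed;
identical seeds give byte-identical tables.

What the generator does **not** emulate: within-airway shape variation,
measurement error, phylogenetic autocorrelation of lengths, or any
correlation between routes beyond the fixed diverticulum ratio. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline recovers
a planted between-group separation — not that real airway data satisfy the
tube idealization.

One statistical consequence worth stating: the saurolophine and
non-hadrosaurid groups are drawn from the same length distribution, so
"their difference is non-significant at α = 0.05" fails in ≈5% of seeds by
construction — that is the nominal false-positive rate of the test itself,
not a pipeline defect. Checks of that pattern across seed batches should
expect ~5 failing seeds per 100.

The matrix simulator evolves binary characters by a single origin on a
random edge of a random true tree, flipping one extra random clade with the
configured homoplasy probability. At homoplasy 0 the matrix is perfectly
congruent (score on the true tree = M, CI = 1), giving a sharp correctness
anchor.

## Numerical conventions

- Frequencies, lengths and indices are carried at full double precision;
  rounding (whole Hz, 3-decimal CI/RI) happens only at report time.
- Degenerate inputs raise typed errors (`paleophony.errors`): non-positive
  lengths or calibrations, <2-point polylines, unknown route/group labels,
  groups of fewer than two observations, ragged or empty matrices,
  tree/matrix label mismatches.
- Equal-length spectra compare exactly; the t-test of two identical
  constant groups reports t = 0, p = 1 (no evidence of difference) rather
  than NaN.
- Problem sizes in the test suite: exhaustive parsimony oracles run on ≤6
  (occasionally 8) taxa; cohort-recovery checks use 100 seeded replicates
  of the 17-individual default cohort.
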