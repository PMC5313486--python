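# Methods

This note documents the models, parameter choices and numerical conventions
behind `methanotype`, and what the synthetic-data generators do and do not
emulate.

## Sniffer model and quantification

A milking-robot sniffer logs CH₄ concentration (mg/kg) at 1 Hz near the
feed trough. The signal model is

    c(t) = baseline(t) + Σ_i A_i · s(t − t_i) / φ + ε(t)

where `baseline` is ambient barn air (a level plus a bounded AR(1) drift),
`s` is a unit pulse with a linear rise (default 3 s) and exponential decay
(time constant 6 s), events `t_i` follow a Poisson process (default
1.5/min during milking), `φ ≥ 1` is the ambient-air dilution factor and `ε`
is white noise. The pulse shape is a free modelling choice — the sharp
rise/slow decay morphology is what a height-threshold peak filter presumes.
Ambient-air dynamics in a milking station are not characterised anywhere we
know of; the AR(1) drift (SD 10 mg/kg, coefficient 0.99, clipped at ±3 SD)
is a declared choice that produces realistic slow variation without trend
explosions.

**Baseline estimation** is a rolling 10th percentile over a centred 60 s
window. The low percentile is robust to pulses, which only occupy the upper
tail of a window; the cost is a small negative bias (≈1.3 noise SDs on
clean Gaussian segments) that inflates peak areas by a few percent. The
bias is common to all cows and sessions, so rankings and tertile
classifications are unaffected; the calibration gain absorbs it to first
order.

**Peak calling**: candidate summits are local maxima of the
baseline-corrected signal of height ≥ 200 mg/kg (lower peaks are
discarded). Peak boundaries extend while the corrected signal exceeds 5 %
of the summit height, plus the flanking crossing sample on each side so
that the trapezoidal integral covers the full rise and fall;
super-threshold runs closer than 3 s merge into one peak. Height is the
maximum above baseline; area is the trapezoidal integral of the corrected
signal over the interval. Overlapping eructations that merge into one
called peak do not bias the CH₄ index, because frequency × mean area
reduces to (total area)/duration.

**Index and calibration.** Each milking with ≥ 3 peaks yields an index
= frequency × mean area ((mg/kg·s)/min); milkings with fewer peaks are
invalid and carry no index. The index is converted to g CH₄/day as
`rate = index × φ × G`, where `φ` is the mean released:sampled
concentration ratio over the gas-release records (two sites × five
replicates in the reference design) and `G` (the *station gain*, default
0.022 g/day per undiluted index unit) is an installation constant relating
undiluted index units to mass flow. How a per-milking index was
extrapolated to a daily rate is not specified by the measurement protocol
this follows; the single multiplicative gain is this package's declared
convention, and the same constant is shared by the simulator so the
calibration chain is identifiable and round-trips the truth. Session rates
are averaged per cow over 14-day period windows; a cow-period with no
valid session is missing (never zero) and later excludes the cow from
classification.

## Emitter classification

Cows with complete period data are split, within each period, into
tertiles of period emission (ties broken by overall mean). Persistently
bottom-tertile cows are L, persistently top-tertile cows are H, everything
else M. Only the qualitative criterion (persistence across all periods) is
standard; the within-period-tertile operationalization is this package's
choice. The rule is rank-based, hence invariant to any strictly monotone
transform of the rates.

## ECM, digestibility, VFA

ECM uses the 3140 kJ reference-energy formula
`ECM = milk·(38.3·fat + 24.2·protein + 16.54·lactose + 20.7)/3140` with
composition in g/kg; coefficients are exposed as a parameter. Marker
digestibility uses acid-insoluble ash as an indigestible internal marker:
fecal DM = AIA intake / fecal AIA concentration, and each nutrient's
apparent digestibility is (intake − fecal output)/intake, reported ×1000 as
g/kg. Negative values are flagged rather than clamped so that
marker-recovery failures surface. VFA profiles are renormalized to
100 mol/100 mol before the (acetate+butyrate)/propionate ratio is taken;
note that a group mean of per-animal ratios generally differs from the
ratio of group means, so only the definitional formula is provided.

## qPCR

Standard curves are OLS fits of Cq on log₁₀(copies) over the nine-decade
plasmid series (10⁰–10⁸ copies); efficiency is (10^(1/|slope|) − 1)·100.
Replicate Cq values are averaged before back-transformation (equivalently a
geometric mean of copy estimates), and the 1:50 and 1:100 pre-dilutions are
treated as independent measurements whose copies/mL estimates are averaged
on the log scale — the aggregation conventions are this package's choices.
Copies/mL = copies-per-reaction × dilution / template volume (µL) × 1000.
Cq values outside the calibrated range trigger an extrapolation warning,
not an error, matching plate practice.

## Community analysis

- **Replicate consistency**: an OTU is retained if all three replicate
  libraries of at least one (cow, period) sample contain it. The strictest
  global reading (every sample) would erase nearly everything and is
  available as a switch.
- **Read threshold**: threshold = floor(fraction × grand total); OTUs must
  strictly exceed it. The same rule with fraction 10⁻⁵ reproduces a
  57-read detection cut on a ~5.7M-read study and with 10⁻³ a 5786-read
  univariate cut on 62 libraries of 93,323 reads.
- **Rarefaction** draws exactly `depth` reads per library without
  replacement (multivariate hypergeometric). Each library's stream is a
  child of (seed, library id), so dropping one library never changes the
  others. Libraries below an explicit depth are dropped with a logged
  warning.
- **Bray–Curtis** D = Σ|x−y| / Σ(x+y) on pooled-replicate relative
  abundances; **PCoA** by Gower double-centering and eigendecomposition.
  Negative eigenvalues (non-Euclidean distances) are reported but their
  axes dropped, and explained variance is computed over the positive
  spectrum only; no Cailliez correction is applied.
- **PERMANOVA** uses the among/within sums-of-squared-distances pseudo-F
  with p = (1 + #{F* ≥ F})/(1 + n_perm). Because each cow contributes one
  sample per period, permutations can be restricted to shuffle whole cows,
  keeping repeated measures together; this is the pipeline default.
- **Differential abundance**: periods are averaged to one value per cow
  (removing the repeated-measures dependence a mixed model would
  otherwise handle), clusters are compared per OTU with Welch's t on
  logit-transformed proportions (half-minimum pseudo-count), and p-values
  are BH-adjusted over exactly the set of OTUs above the 0.1 % abundance
  threshold. Outlier-sample removal before cluster definition is manual
  (an explicit label list), never automatic.

## Synthetic-data generators

The generators define the study conditions everything is tested under:

- **Herd**: 21 cows in three emitter tertiles with true rates around
  280/315/350 g CH₄/day (within-group SD 8), emulating a cohort of
  persistent low/medium/high emitters selected from a larger herd; three
  14-day periods at 2.5 milkings/day, 8-minute sessions. Low/high emitters
  carry community state L/H respectively; medium emitters carry either
  state, mirroring their occurrence in both observed community clusters.
- **Community**: state-L composition places ~26 differential OTUs at their
  reported cluster-L percentages (e.g. a Succinivibrionaceae OTU at
  1.99 %), applies the observed H:L fold-changes for state H, plants
  archaeal OTUs (~0.5 % of reads) whose ruminantium:gottschalkii clade
  split flips between states (61.8/25.4 % of archaea in L vs 40.7/44.0 %
  in H), and spreads the remaining mass over 90 filler OTUs. Per
  cow-period compositions are Dirichlet with concentration 2000 — chosen
  to reproduce the between-cow dispersion the reported standard errors of
  difference imply (CV ≈ 10–30 % for most differential OTUs) — and
  libraries are multinomial draws of 40,000 reads, three replicates per
  sample.
- **qPCR**: Cq from the log-linear curve with 0.2 Cq noise; RO truth
  declines from low to high emitters (2.2×10⁷ → 6.8×10⁶ copies/mL) while
  SGMT does not.
- **Phenotype tables**: fecal nutrient masses follow from intake and the
  planted digestibilities (OM 0.71, NDF 0.64, CP 0.70, DM 0.69) with exact
  AIA conservation, so the marker computation round-trips the truth at
  zero noise. The default fecal-concentration measurement noise (relative
  SD 0.001) represents the analytical precision of a pooled multi-day
  composite sample and keeps digestibility recovery within 2 g/kg. VFA
  state means follow the reported cluster profiles (butyrate 14.7 vs
  17.3 mol/100 mol, propionate 19.6 vs 17.1).

What the generators do **not** emulate: diurnal and feeding-related
emission rhythms, cow-specific eructation frequency or baseline behaviour,
taxon-specific overdispersion (one concentration parameter governs all
OTUs), compositional correlations beyond the simplex constraint, period
(time) effects and breed effects on any phenotype, and sequence-level
artefacts (chimeras, misclassification) — the OTU count table is the entry
point. Passing tests therefore demonstrate the correctness and calibration
of the analysis chain under these idealised conditions, not the field
performance of sniffer phenotyping on real herds.

## Problem sizes and numerics

The test suite's Monte-Carlo checks use 100 seeded herds for emission
recovery (full three-period design), 500 exchangeable-null simulations for
PERMANOVA type-I error (199 permutations each, 12 samples), 200 null
communities for FDR control, and 30 herds for differential-power
estimation; `scripts/acceptance.py` uses 20/200/15 for the same quantities.
Floating-point conventions: peak areas are trapezoidal to machine
precision against an independent oracle; PCoA eigenvalues below
10⁻¹⁰·max|λ| are treated as zero; permutation p-values are never zero by
construction. The emitter classifier breaks within-period ties by overall
mean emission, making the partition deterministic.

## Known limitations

- The CH₄ index→rate gain is calibration-dependent; absolute rates are
  only as good as the release-experiment constant, though rankings and
  group contrasts are insensitive to it.
- Cluster discovery in the pipeline (2-means on the first two PCo axes,
  lower-emission cluster labelled L) is a simple stand-in for the manual
  cluster definition practised with ordination plots; the PERMANOVA then
  tests clusters derived from the same distances, which inflates its
  nominal significance and is reported as descriptive confirmation, not
  inference.
- Welch's t on cow-averaged logit proportions ignores period effects and
  breed structure; with strong period trends a mixed model would be
  preferable.
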