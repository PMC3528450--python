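# Methods

This note documents the models, algorithms and design choices behind the
`crabtree` package: a reusable re-implementation of the comparative
systems-biology workflow for a Crabtree-negative yeast (*Scheffersomyces
stipitis*-like) versus a Crabtree-positive yeast (*Saccharomyces
cerevisiae*-like) growing aerobically on glucose.

## Atom-transition network (`crabtree.network`)

The central-carbon network covers glycolysis, the oxidative and
non-oxidative pentose phosphate pathway (PPP), the PDH bypass (pyruvate
decarboxylase, acetaldehyde dehydrogenase, acetyl-CoA synthase), pyruvate
dehydrogenase (PDH), pyruvate carboxylase (PYC), malic enzyme (MAE),
mitochondrial transport of pyruvate / oxaloacetate / acetyl-CoA, the TCA
cycle, the glyoxylate shunt (ICL, MLS), nine biomass precursor drains and
four secretion reactions (ethanol, glycerol, acetate, pyruvate).  Both
Crabtree variants share this topology; in the Crabtree-negative organism
the secretion fluxes are simply expected to fit to ~0.

Conventions and simplifications:

* Carbon positions are 1-based biochemical numbering (glucose C1 =
  aldehyde carbon).  Every reaction's atom map is a bijection between
  substrate and product carbons, enforced by `validate_network`.
* Linear glycolysis segments without branch points are lumped
  (G6P→F6P→GAP→PEP pool→pyruvate are the explicit branch-point pools),
  matching the resolution at which labeling data can distinguish fluxes.
* Rotationally symmetric intermediates (succinate, fumarate) are flagged
  and orientation-averaged with weight 0.5 at the point of production;
  reactions are not duplicated.
* TCA atom transitions follow first-turn biochemistry: the CO2 released by
  isocitrate dehydrogenase and 2-oxoglutarate dehydrogenase comes from the
  oxaloacetate carboxyls; the acetyl carbons enter glutamate C4/C5.
* CO2 is modeled as an unlabeled external pool.  Carboxylation (PYC) draws
  unlabeled CO2; the small re-fixation of labeled CO2 is neglected.  This
  is a common approximation, and because the synthetic data generator and
  the fitter share the same simulator the workflow stays self-consistent.
* Mitochondrial and cytosolic pyruvate, acetyl-CoA and oxaloacetate are
  separate pools connected by irreversible transport reactions, so
  compartment-specific routes (PDH vs the PDH bypass) are represented.
* The stoichiometric matrix of the built network has 23 balanced
  metabolites, 41 reactions and 18 degrees of freedom.

Networks serialize to a small JSON dialect (metabolites, reactions with
atom maps as `[substrate_instance, position]` arrays per product carbon,
substrate labeling patterns, biomass demand weights) plus a human-readable
TSV summary with atom-map strings such as `PYRm>CO2[PYRm:1]+AcCoAm[PYRm:2,PYRm:3]`.

## Label simulation (`crabtree.labeling`)

Steady-state 13C propagation uses the elementary-metabolite-unit (EMU)
decomposition: the mass-isotopomer distribution (MID) of any carbon
fragment of size *s* satisfies a linear flux-weighted balance in which
condensation reactions contribute convolutions of strictly smaller
fragments.  Systems are therefore solved size-ascending by dense direct
solves; the networks here generate a few hundred EMUs at most (195 for the
default amino-acid fragment set), so one simulation costs ~1 ms.

* Reversible reactions contribute a reverse direction with the inverse
  atom map.  Bidirectional exchange is parameterized by an extent
  e ∈ [0,1): exchange flux = e/(1−e), capped at 1e3 on the glucose = 100
  scale.  The default extent is 0 everywhere (net-flux model), and the
  synthetic data are generated with extents 0 so the fitter is estimating
  under the same model.
* Summed fractional labeling: SFL = 100 × Σ_j j·MID_j, i.e. the expected
  number of labeled carbons per fragment in percent.
* The amino-acid → precursor fragment map ships as editable JSON data, not
  code (Ala←pyruvate, Ser←3PG pool, Gly←Ser C1–C2, Asp/Thr←OAA,
  Glu/Pro←AKG, His←R5P, Phe/Tyr←2×PEP+E4P, Val←2×pyruvate(mito),
  Ile←OAA+pyruvate, Leu←AcCoA(mito)+2×pyruvate).  The condensation
  structure of each entry is the list of precursor EMUs whose MIDs are
  convolved.  Measured fragment sets differ between labs; edit the JSON to
  match.
* Natural 13C abundance is off by default; `natural_abundance_convolve`
  applies (or inverts) the binomial correction when real measurements need
  it.  Synthetic data are simulated without natural abundance so that the
  generator and the fitter agree exactly.
* Correctness is established against an independent oracle: exhaustive
  positional-isotopomer enumeration (fixed-point iteration over all 2^n
  labeling states per pool).  EMU and enumeration agree elementwise to
  <1e-9 on the toy networks and to ~1e-12 on the full yeast network.

Numerical details: MIDs are clipped at 0 and renormalized (guarding
~1e-16 negatives from the linear solve); inside the fitter the solver runs
in a tolerant mode where pools that lose all inflow at an interior search
point are regularized toward the unlabeled distribution instead of raising.

## Flux estimation (`crabtree.fluxfit`)

Weighted least squares over steady-state flux distributions:

SSR = Σ_i ((SFL_sim,i − SFL_obs,i)/sd_i)² + Σ_r ((v_r − r_obs,r)/sd_r)²

with the glucose uptake fixed to 100 (the scale on which yeast flux maps
are reported) and all irreversible fluxes ≥ 0.

* Steady state is structural: a null-space basis of the stoichiometric
  matrix is chosen once by Gaussian elimination with a fixed column order
  (deterministic pivoting; scenario-relevant fluxes such as PDH, MAE, ICL,
  the PPP entry and the drains are kept in the free set), and the
  optimizer works in free-flux coordinates, so S·v = 0 holds to machine
  precision for every candidate.
* Bounds: free fluxes carry box bounds (irreversible ≥ 0, default upper
  300); dependent irreversible fluxes are clipped inside the simulator and
  penalized with weight 1e3 per unit of violation; the returned solution
  is verified against the bounds.
* Multistart: start 0 anchors the measured rates — a ridge-regularized
  quadratic program fits the (linear) rate measurements subject to the
  irreversibility inequalities — and the remaining starts are a seeded
  hit-and-run walk from it along rate-consistent directions (the null
  space of the rate map).  This keeps every start inside the flux polytope
  and consistent with the measured secretions and drains, which is what
  makes the global search reliable.  Ties within 1e-9 go to the lowest
  start index; everything is deterministic given the seed.
* Two optimization stages per start: a bounded trust-region-reflective
  pass (forward differences, Jacobian-scaled), then a Levenberg–Marquardt
  polish with central differences on the best few candidates.  The polish
  matters: several flux directions (notably the PDH vs PDH-bypass split)
  are shallow curved valleys whose gradients are at the edge of
  forward-difference accuracy.
* Measured rates of absent products are included as 0 ± sd rather than
  omitted (the Crabtree-negative case secretes nothing).
* Uncertainty: `monte_carlo_intervals` resamples the measurements with
  their stated sds and refits from the point estimate (2.5–97.5
  percentiles); fluxes whose interval spans more than 50 units are flagged
  poorly determined rather than silently reported.
  `linearized_flux_sd` gives the cheaper first-order screen.

Identifiability of the demonstration scenarios: with noise-free SFLs the
fit recovers every planted flux of both S. cerevisiae scenarios to <0.01
units.  At 1% SFL noise the PDH/bypass split, the anaplerotic loop
(PYC/OAT/MDH) and the glyoxylate fluxes become poorly determined — their
95% Monte-Carlo intervals span 10–67 units — while glycolysis, the PPP
split, the drains, secretions and the TCA input stay determined to ±2.
The noisy-recovery test therefore scores exactly the fluxes whose interval
width is at most twice the recovery tolerance, which is what
"identifiable at this noise level" means operationally.

## Ground-truth flux scenarios (`crabtree.synth`)

Four steady-state flux maps on the glucose = 100 scale, built by exact
linear solve in null-space coordinates from 18 target fluxes each:

* `positive_batch` — respiro-fermentative: PDC 153, ethanol secretion 129,
  PDH 4.3, low TCA (~15), biomass drains scaled to Ysx ≈ 0.17.
* `positive_chemostat` — respiratory: PDH 61.7, high TCA (~64–69), no
  secretion, drains scaled to the higher respiratory biomass yield.
* `negative_batch` / `negative_chemostat` — both respiratory, no
  secretion, PDH 65–67 (slightly above the positive chemostat), PPP entry
  45 in batch vs 40 in chemostat, lower anaplerosis (MAE 3, PYC ~22).

The PDH values of the two positive scenarios (4.3 and 61.7) are the
anchored worked-example values; the remaining targets are chosen once as
physiologically plausible values consistent with the reported yields and
with the qualitative flux statements (batch fermentation dominated by the
PDC route, respiratory growth dominated by PDH; MAE active in all
conditions, which is also what makes the mitochondrial pyruvate pool
isotopically distinct and the PDH/bypass split identifiable at all).

## Physiology (`crabtree.physiology`)

* µ_max: least-squares slope of ln(biomass) vs time.  Window
  auto-selection takes the longest contiguous window with R² ≥ 0.999, ties
  toward the earlier window (reproducible, and consistent with sampling in
  mid-exponential phase).  Constant biomass returns µ = 0 with a warning
  flag rather than an error.
* q_s: batch = µ·|dS/dX| (glucose regressed on biomass over the
  exponential window); chemostat = D(S_in − S)/X.  Conversion constant
  30.026 mg per C-mmol of glucose (180.156/6).
* Yields: batch = regression slopes over the exponential window; chemostat
  = X/(S_in − S) and P/(S_in − S).
* Off-gas: outlet flow corrected by the inert-gas balance
  F_out = F_in(1−yO2,in−yCO2,in)/(1−yO2,out−yCO2,out);
  OTR = (F_in·yO2,in − F_out·yO2,out)/(V·Vm), CTR with signs reversed;
  molar volume default 24.055 L/mol (25 °C, 1 atm), configurable because
  off-gas normalization conventions differ between setups.  RQ = CTR/OTR
  (molar); undefined (flagged) when the gas composition does not change.
* Carbon balance: recovery = (C in biomass + CO2 + secreted products)/(C
  from glucose) on a specific-rate basis; biomass carbon via the standard
  C-mol formula CH1.8O0.5N0.2 (24.63 g/C-mol, configurable).  For a fully
  respiratory profile with that formula the computed RQ lies in
  [0.95, 1.15]; an RQ below 1 for respiratory growth (as sometimes
  reported from fermentor data) is reported as computed, never forced.
* Chemostat steady state: biomass drift < 2% over at least five residence
  times.

The batch generator plants µ, X0, S0 and yields; glucose and products
track the yields exactly, and the off-gas block is constructed by
inverting the OTR/CTR formulas, so gas rates round-trip to machine
precision.  CO2 evolution closes the planted carbon balance and O2 uptake
follows the planted RQ (default 1).

## Metabolome and expression statistics (`crabtree.omics`)

* Welch's unequal-variance t-test in closed form with the
  Welch–Satterthwaite df; degenerate zero-variance groups return p = 1
  (equal means) or p → 0 flagged by an infinite t.  The type-I error on
  null lognormal data is calibrated in the tests.
* Fold change = ratio of group means on the protein-normalized abundances
  as provided; no multiple-testing correction by default (raw p-values
  with the two thresholds 0.05 and 0.1 are the reported quantity); an
  optional Benjamini–Hochberg column is available.  Whether to
  log-transform before testing is a flag, off by default.
* Decimal-comma table cells ("38,76") are handled by a documented reader
  flag, not by locale guessing.
* FPKM = count × 10^9 / (length × total mapped fragments); log2 display
  tables use a pseudocount of 1, raw FPKM stays unshifted.
* The metabolome generator rescales each sampled group to hit the planted
  mean ratio exactly, so worked-example fold changes (e.g. adenine 38.76)
  are deterministic, while within-group variability (lognormal, CV 0.3 by
  default, n = 6 per group) still exercises the test.

## Reporter features (`crabtree.reporter`)

Gene p-values are transformed to z = Φ⁻¹(1−p) (clipped to 1e-15); a
feature with k neighbor genes scores Z = Σz/√k.  The background corrects
for k: for each distinct k (ascending, one seeded stream) the mean µ_k and
sd σ_k of the statistic over `n_background` random k-subsets of the
scored-gene universe give Z' = (Z−µ_k)/σ_k and reporter p = 1−Φ(Z').
Subsets are sampled without replacement (chunked arg-partition of random
keys), which matters on small universes where with-replacement sampling
would be biased; the tests verify 1% agreement with exhaustive k-subset
enumeration.  Directional scores run the procedure on the two directional
p-value sets and keep the more significant side, signed +(−log10 p) for
condition-A-up and negative for B-up; exact ties keep the A sign and are
flagged.  Cutoffs default to 0.01 for GO terms and 0.05 for metabolites.
The universe is the set of scored genes (the available-data null), and a
constant z-field (σ_k below 1e-9 relative) yields corrected Z = 0 rather
than numerical noise.

## Ortholog families and TF comparison (`crabtree.orthotf`)

Groups files use the OrthoMCL dialect `FAMID: tag|gene tag|gene ...`;
parsing is strict (line numbers on malformed members, duplicate genes
across families rejected).  TF genes absent from every family become
singleton families, so species-specific TFs without orthologs still count
as unique families.  A family is shared when it contains at least one TF
from each species; the looser "any gene from both species" definition is
behind a flag.  shared + unique_A + unique_B always equals the number of
TF-containing families.  Unique families join the catalog annotations and
a user watchlist (e.g. INO2, INO4, SGC1, RGT1, MIG2, MIG3, VID22, RMD5,
GSM1); watchlist entries found in no family are listed separately instead
of being dropped.  Reproducing proteome-scale Venn counts requires both
proteomes and the external TF database and is out of scope here; the
module consumes clustering output, it does not re-implement the Markov
clustering.

## Pipeline (`crabtree.pipeline`, `crabtree.cli`)

One YAML config drives the stages (synth, physiology, fluxes, metabolome,
fpkm, reporter, tf_venn) in dependency order; every threshold is surfaced
in the config with the study defaults.  Reports are plain TSVs mirroring
the study's tables; the manifest records the config hash, seed, stage
timings and SHA-256 checksums of all inputs and outputs.  Re-running an
identical config is byte-identical; missing inputs fail pre-flight before
any stage runs.  Figure rendering is intentionally out of scope — the
TSV matrices are the artifact.

## What the synthetic data do and do not show

The generators emulate: exponential batch and steady chemostat kinetics
with exact planted parameters, off-gas consistent with the carbon balance,
SFL datasets from planted flux maps under 100% [1-13C]glucose with
additive Gaussian noise, two-group lognormal metabolome tables with exact
planted fold changes, negative-binomial count matrices (Gamma–Poisson,
variance = µ + φµ²), and random bipartite reporter graphs with planted hot
features (neighbor p-values Beta(0.05, 1)).

They do not emulate: deviations from exponential balanced growth, GC-MS
fragment-specific measurement artifacts or natural-abundance effects,
peak-picking and normalization of real metabolome platforms, positional
biases of RNA-seq, or annotation noise in gene–feature graphs.  Passing
the recovery tests therefore demonstrates correctness of the estimators
under their stated models — not robustness to real-data artifacts outside
those models.

## Problem sizes and runtimes

The bundled demonstrations use the study-scale dimensions where they are
cheap (13 SFL fragments, 13 measured rates, 200-gene/40-feature reporter
graphs, 6 + 6 metabolome samples) and reduced replicate counts where full
fits repeat (20 noisy-replicate fits with chained warm starts, 20-sample
Monte-Carlo intervals).  A single flux fit with the default 20 starts
takes one to two minutes; the full acceptance recomputation runs in a few
minutes on one core.

## Known limitations

* Exchange-flux extents are simulated but not fitted by default; flux maps
  are net-flux maps under extents 0.
* CO2 labeling is not tracked (unlabeled-pool approximation).
* The PDH/bypass split is intrinsically weakly identifiable from
  proteinogenic SFLs when the mitochondrial and cytosolic pyruvate pools
  are isotopically similar (MAE ≈ 0); noise-free data recover it, 1%
  noise does not — the uncertainty machinery reports this instead of
  hiding it.
* The fragment map approximates some amino-acid carbon skeletons (Phe/Tyr)
  at the level needed for self-consistent synthetic studies; users fitting
  real GC-MS data should replace it with their measured fragment set.
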