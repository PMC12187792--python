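# Methods

## Data model

Concentrations are held long-form per compartment (frond, humus, topsoil,
subsoil) as `(site_id, element, replicate, value_mg_kg)` with explicit NaN
for missing values; zero is a measurement, never a placeholder. Carbon and
nitrogen, often reported in g/kg, are converted to mg/kg on read when a
`units` column says so. Values below a detection limit may be written
`"<x"`; the policy substitutes x/2 (default), x, or NaN. Analytical
replicates are collapsed by their median by default (robust to a single bad
digestion; the mean is available), and collapsing a single replicate is the
identity.

Site factors carry the evaporation class as a closed interval in mm/y; rank
correlations use its midpoint, which is invariant to how the interval string
is dashed. Bedrock enters screens as 0/1 indicators per class.

## Summary battery

Per element across sites: min, max, mean, SD with the n−1 denominator,
RSD% = 100·SD/mean (undefined, reported NaN, when the mean is 0), quartiles,
median, and the **unscaled** MAD (median of |x−median|, no 1.4826 factor —
chosen so MAD sits inside the interquartile range as robust surveys
tabulate it). The robust CV is 100·MAD/median. Quartiles default to the
linear-interpolation convention (numpy/type 7); legacy statistics packages
differ by at most one representable step, so the convention is an argument,
not a constant. A consistency checker flags (never repairs) batteries whose
printed order statistics are impossible, e.g. a mean above the maximum —
transcribed tables do contain such rows.

Matrices destined for clustering are log10 of the replicate median per
(site, element) — median first, then log. The alternative reading (median of
logs) is behind `log_mode="median_of_logs"`; for three near-identical
analytical replicates the two differ negligibly, but the default is the
stated convention.

## Accumulation indices

BcF = c_frond/c_substrate and EF = (E/Al)_frond/(E/Al)_substrate are
computed per site–element–horizon on replicate-aggregated values, then
aggregated across sites by the median with the contributing count always
reported; NaN propagates rather than being dropped silently, and a zero
denominator yields NaN with a warning, never infinity. Both indices are
invariant to a common rescaling of all concentrations, and EF(Al) ≡ 1 is an
exact identity used as a pipeline self-check.

The six enrichment classes are implemented as half-open intervals
[0,1.5), [1.5,2), [2,5), [5,20), [20,40), [40,∞): the conventional printed
limits share endpoints, and assigning each shared endpoint to the upper
class makes a true partition whose top class is anchored by "≥ 40".

Verdicts: an element is an *excluder* when its median BcF is below 0.1 in
every horizon with data, and *accumulated* when its median EF reaches 10 in
any horizon (the 10–100 and 100–500 EF bands mark strong accumulation in
this literature).

Stoichiometric limitation flags follow the widely used N:P mass-ratio
cut-offs of 14 (N-limited below) and 16 (P-limited above); the source
convention for these thresholds is a wetland fertilization synthesis, so
both are arguments.

## REE normalization and Ce anomalies

Two named PAAS compositions ship as versioned CSV resources:
`PAAS-TM1985` (Taylor & McLennan 1985; default) and `PAAS-P2012`
(Pourmand et al. 2012). Every output row records the reference name —
swapping references is a visible config change, never a silent default
change. Ce\* is the geometric extrapolation Pr²_N/Nd_N, so
Ce/Ce\* = Ce_N·Nd_N/Pr²_N. The ratio is invariant to dilution of the raw
REE vector and to rescaling of the whole reference table, and is homogeneous
of degree 1 in Ce — properties the test suite asserts. "Significantly"
different from 1 is operationalized as a symmetric band, default ±0.10;
published per-sample anomaly cohorts cannot be reproduced without the
original per-sample supplement, so cohort-level constants are not asserted
anywhere.

## Association

Spearman's rank correlation is used throughout (concentrations stay skewed
after transformation); pairs require ≥ 3 complete cases, constant variables
report NaN, and the screen-wide Benjamini–Hochberg adjustment is reported
next to raw p-values with conventional star flags (* <0.05, ** <0.01,
*** <0.001).

Clustering uses d = 1 − Pearson r and Ward's amalgamation rule applied by
the Lance–Williams update **directly to the supplied dissimilarities**
("ward.D" style). This is mathematically impure — Ward's variance argument
assumes squared Euclidean distances — but it is what legacy clustering
software computes on a correlation distance, and reproducing that procedure
is the point; scipy's `linkage(method="ward")`, which squares its input, is
deliberately not used. Ties in candidate merge distance are broken by the
lexicographically smallest pair of leaf-label sets, making the merge history
deterministic and independent of input row order. The tests verify the
implementation against an independent closed form: the Ward cluster distance
equals S(A∪B) − S(A) − S(B) with S(C) = (2/|C|)·Σ_{i<j∈C} d_ij, re-evaluated
from the original matrix at every step. Trees serialize to Newick (branch
lengths are merge-height differences, clipped at 0) and to a JSON merge
list.

## Synthetic generator

The generator states a world and sticks to it:

* 35 sites; bedrock drawn from the empirical five-class mixture
  (7 SAND : 6 PHYL : 9 GRA : 10 PAR : 3 BAS); elevation uniform on
  275–925 m; potential evaporation = 750 − 0.3·elevation + N(0, 25) mm/y,
  binned into 50 mm/y classes (reproducing the 500–700 mm/y class range and
  the negative elevation–evaporation rank correlation); humus pH
  4.0 + bedrock offset (+0.8 basic rocks, −0.3 sandstone, −0.2 granite)
  + N(0, 0.2).
* Subsoil concentrations are log-normal per element with GSD 2.0 around
  illustrative geometric means (back-solved from published frond medians of
  a comparable survey through the default BcFs — realistic scales, not
  ground truth). Granite-affine elements (Rb, Cs, Be, Tl, U) are shifted ×5
  on granitic bedrock.
* Topsoil and humus apply per-element horizon multipliers to the same
  realization; the humus layer is enriched ×3 in deposition-affected
  elements (Cd, Hg, Bi, Cu, Mo, Pb, Sb, Sn) and depleted in Al (×0.3).
* Fronds couple to a single reference horizon (default topsoil, reflecting
  uptake from the mineral soil rather than the litter layer):
  frond = BcF_true × c_ref × lognormal(GSD 1.3). Default true BcFs: 0.05
  for the excluded set (Na, As, Bi, Pb, Sb, Sn, Th, Tl, W, Al, Fe, Cr, Li,
  Ag, U, V), 1.5 for mobile nutrients (K, Mg, Cd, Cu, Hg, Mn, Rb, Zn), 0.8
  for REEs, 0.5 otherwise.
* REEs (La, Ce, Pr, Nd, Y) share a per-site latent factor with loading
  ρ = 0.9 at both the substrate and the uptake stage, giving pairwise
  log-correlations ≈ ρ². A Ce multiplier (default 1) scales the frond Ce
  and therefore scales every recovered Ce/Ce\* exactly — the anomaly
  injection is a closed loop.
* Three analytical replicates with GSD 1.02.

All randomness flows through `numpy.random.default_rng` (PCG64) seeded per
generation stage from the single config seed, so output is bit-reproducible
across platforms. With all GSDs at 1 the world is noise-free and every
downstream index is analytically exact.

What the generator does **not** emulate — so a green test does not
establish it: homeostatic control of tightly regulated elements (real C
varies ~1%, synthetic C gets the generic GSD), inter-element correlations
beyond the REE block, spatial autocorrelation, pH–mobility feedbacks, and
any real substrate chemistry. Recovery tests certify the pipeline's
arithmetic and its statistical calibration, not environmental realism.

## Numerical and degenerate-input choices

* Division guards: zero substrate or normalizer → NaN + warning, never ±inf.
* Negative concentrations and duplicate (site, element, replicate) keys are
  hard errors naming the offender; unknown element symbols are warned about
  but retained (novel analytes are not the reader's business to censor).
* Zero or missing values reaching the log10 step are a hard error: censoring
  policy must be applied upstream, silently imputing there would hide it.
* Newick branch lengths are clipped at 0 (ward.D on a correlation distance
  is monotone in practice but the writer does not assume it).

## Limitations

* The EF/BcF cut-offs (0.1, 10) are conventions of this literature, not
  estimated quantities.
* ward.D on 1−Pearson r has no variance-minimization interpretation; it is
  provided for procedural fidelity. For a purist analysis, feed Euclidean
  distances to another tool or use the exported merge list.
* The shipped PAAS tables cover only La, Ce, Pr, Nd, Y — the elements this
  kind of survey measures; no full 14-REE pattern modelling, no tetrad
  effect, no Eu anomaly.
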