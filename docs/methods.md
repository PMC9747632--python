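# Methods

## Isotopologue correction

A metabolite with *n* carbons, *j* of which came from tracer material, is
measured at mass shift `Binomial(j, purity) + Binomial(n−j, a)`, with
`a = 0.0107` the natural ¹³C abundance and `purity = 0.99` a standard
vendor lot purity (both configurable; the correction is exactly the
identity when purity → 1 and a → 0). The correction matrix stacks these
column distributions; because correction is carbon-only, no mass shift can
exceed m+n and every column is a probability vector. Measured vectors are
inverted by nonnegative least squares (`scipy.optimize.nnls`) and
renormalized, so noisy inputs can never yield negative fractions; on
noise-free forward-convolved data the inverse is exact to well below 1e-8.
Correction ignores N/H/O isotopes: the experiments this package targets
use carbon tracers quantified on a high-resolution Orbitrap where those
isotopologues are resolved away. The assumption is recorded as a settings
flag (`resolution_assumption="carbon-only"`) so an elemental extension
would not change call sites.

## MIDA dimer model

GAP and DHAP are treated as one fully equilibrated 3-carbon monomer pool;
glucose is two independent draws from it, so the hexose MID is the
monomer MID's self-convolution. No positional isotopomers are tracked
within the triose, and no substrate channeling is modeled — deviations of
observed from predicted hexose MIDs surface as fit residuals, not model
terms. The inverse problem (monomer labeled fraction from an observed
hexose MID under a single-labeled-species scheme) is solved by bounded
scalar least squares on [0, 1] with `xatol = 1e-10`; it round-trips the
forward model to 1e-6 and returns 0 for a degenerate all-m+0 input. The
diagnostic ratio 2(1−p)/p is strictly decreasing in p, so a rising glucose
m+1/m+2 (2-¹³C) or m+3/m+6 (U-¹³C) ratio reads directly as dilution of the
monomer pool by unlabeled carbon.

## In vitro flux attribution

The triose-phosphate pool is the single mixing node: each labeling scheme
measures its substrate's fractional contribution as the labeled fraction
of the triose MID (measured GAP, or GAP+DHAP — either is accepted; when no
triose measurement exists the fraction is inferred from glucose through
the dimer model). Total carbon flux is 6 × the media glucose accumulation
rate (glycogen release is ignored: these cultures produce >95% of media
glucose by gluconeogenesis), and substrate fluxes are the shares of that
total. The full elementary-metabolite-unit network that originally
validated this attribution is deliberately not reproduced; the single-node
model is exactly the level at which the fluxes are reported and
interpreted here. TCA carbon loss does not enter the attribution; it is
reported separately per TCA substrate as λ = 1 − (mean heavy carbons per
labeled molecule)/3, estimated from the m+1/m+2/m+3 composition.

Bookkeeping conventions: the three labeled fractions may oversum slightly
by measurement noise — up to 5 percentage points they are renormalized
with a warning (unlabeled share 0), beyond that the schemes are rejected
as inconsistent. Reported ratios and fold changes are rounded to one
decimal and percentages to integers.

## In vivo turnover and network model

F_circ = infusion_rate × (1/fraction − 1), in the units of the infusion
rate, with optional per-gram normalization (both per-mouse and per-gram
reporting occur in practice; the choice is a flag, not a model change).

The circulatory network fixes three nodes (glycerol, glucose, lactate) and
seven nonnegative carbon fluxes; glycerol appears only from lipolysis
(there is no lactate→glycerol or glucose→glycerol edge, consistent with
circulating glycerol acquiring essentially no label from the other nodes),
glycerol→glucose is lossless (a ¹³C₃-glycerol tracer produces only m+3 and
m+6 glucose in hepatocytes), and lactate→glucose carries a scalar TCA loss
factor. Sink fluxes are derived from node carbon balance, leaving five
free parameters. Steady-state enrichments are linear in the fluxes and
solved in closed form per infusion.

Fitting minimizes log-scale enrichment residuals (the declared measurement
noise is multiplicative, so relative misfit is the matching objective; a
structurally-zero observation instead penalizes any predicted label)
plus a relative residual between measured F_circ and the turnover implied
by the predicted infused-node enrichment, with a heavy penalty on negative
derived sinks. The global stage is `scipy.optimize.differential_evolution`
(seeded; default popsize 20, 250 iterations, bounds = 10× the largest
measured carbon turnover — data-derived, so the fit is invariant to unit
rescaling) followed by a bounded trust-region least-squares polish. The
procedure is deterministic given the seed, invariant to experiment
ordering, and recovers a noise-free synthetic network to machine
precision.

95% confidence intervals are a parametric bootstrap (default
`n_boot = 200`; below 40 a warning is emitted): observed enrichments are
resampled with multiplicative lognormal noise at the measurement scale
(supplied, or estimated from the residuals with a degrees-of-freedom
correction and floored at 1e-8 so noise-free fits give degenerate
intervals), each resample is refitted locally from the best fit, and
2.5/97.5 percentiles are taken per edge and for the TCA loss factor,
expanded if necessary to bracket the point estimate. Perturbing the
measured data rather than the fitted predictions keeps interval width
proportional to the local flux scale, which matters because estimator
spread scales with flux magnitude under multiplicative noise. With only
~7 informative observations for 5 parameters the intervals are still
slightly liberal (per-edge coverage ≈ 0.90–0.95 at 5% noise in the
package's own simulations) — an honest small-sample property of the
percentile bootstrap, not corrected by reweighting.

## Synthetic data

The in vitro generator emulates 8-h hepatocyte incubations with the
four-substrate mix at fasting concentrations (0.5 mM glutamine, 0.33 mM
glycerol, 0.25 mM pyruvate, 2.5 mM lactate, replenished every 2 h — hence
linear glucose accumulation), under either the U-¹³C or the 2-¹³C scheme
set (glutamine stays U-¹³C in the latter, as in the experiments). Default
ground truth is the basal operating point: triose shares 0.756/0.133/0.111
and 75 nmol glucose/h. Glycerol-derived triose keeps its label intact; PL-
and glutamine-derived triose loses each tracer carbon independently with
probability λ (default 0.2, which makes m+3 > m+2 > m+1 for U-¹³C TCA
substrates as observed; the analyzer's λ estimator conditions on labeled
molecules and therefore differs from the generator's unconditional
thinning by O(λ³) — negligible at the default). Measurement noise is
multinomial ion counting at depth 10⁴ per spectrum per timepoint plus a 2%
CV on glucose totals; `ion_depth=None` gives the noise-free limit.

The in vivo generator solves the network's steady-state enrichments under
the standard infusates (0.1 μl/g/min of 150 mM glycerol, 40 + 360 mM
pyruvate/lactate, or 200 mM glucose; 25 g body mass) and applies lognormal
noise at CV 0.05. The default network (μmol C/min: lipolysis→Gro 6.4,
Gro→Glc 5.4, Gro→sink 1.0, Lac→Glc 8.0, Glc→Lac 12.0, Glc→sink 1.4,
Lac→sink 4.0, λ = 0.45) puts the infused glycerol node at 15% enrichment
and glycerol's contribution to glucose carbon at 60%, with carbon flowing
predominantly glycerol→glucose→lactate. One structural consequence of the
fixed topology: lactate has no unlabeled peripheral source, so its
turnover is bounded by glucose production and the lactate/glucose nodes
sit near 25% enrichment rather than the ~15% a real mouse shows — the
model trades that realism for identifiability of the seven edges.

## What passing tests do and do not show

The generators share the label-routing assumptions of the analyzers
(single mixing node, i.i.d. dimerization, fixed network topology,
independent per-carbon loss), so round-trip recovery demonstrates
correctness and calibration of the estimation chain under those
assumptions — not their validity for real hepatocytes or mice. Real data
add positional isotopomer effects, metabolite-specific ionization noise,
incomplete steady state, and exchange fluxes the 7-edge topology omits.
Simulation sizes (200 in vitro replicates at depth 10⁴; 100 in vivo
replicates with 200 bootstrap refits) were chosen to bound Monte Carlo
error on the reported recovery rates while keeping a single-CPU run of the
whole suite in a few minutes.
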