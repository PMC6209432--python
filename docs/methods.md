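# Methods

`memstab` models one experimental program: engineering kinetically
thermostable variants of an oligomeric membrane transporter by consensus
mutagenesis, and quantifying how those variants resist irreversible thermal
denaturation. This note describes the models, the estimation procedures,
the synthetic-data generators used to validate them, and the design choices
made where the underlying methodology leaves room.

## Consensus and covariance design

**Column profiles.** An input alignment (FASTA) is reduced to per-column
residue frequencies in the coordinates of a chosen target sequence; columns
where the target carries a gap are dropped, because the design space is
substitutions only — insertions relative to the target cannot be encoded in
a variant of fixed length. Frequencies are computed with the *total* row
count as denominator by default, so gap-rich columns depress every residue
frequency (the convention of common alignment viewers); a non-gap
denominator is available (`denominator="nongap"`).

**Frequency rule.** A consensus substitution is called at a position when
the modal non-gap residue (i) differs from the target residue, (ii) has
frequency strictly above `f_min` (default 0.20), and (iii) exceeds the
target residue's frequency by at least `delta` (default 0.10, percentage
points, inclusive). Both thresholds are explicit, configurable arguments
because the underlying cutoffs are approximate in origin; a modal tie
suppresses the call, since "the most frequent residue" is undefined under a
tie. Calls are then intersected with declared structured regions (a
1-based, inclusive interval table with ScaD/TranD domain tags); secondary
structure prediction itself is out of scope — regions are inputs.

**Percent similarity** of a design uses a fixed conservative partition
{ILVM, FWY, KRH, DE, ST, NQ, AG, C, P}, recorded in the variant metadata;
other partitions exist and would shift the number by a point or two.

**Covariance.** The covariance-restricted design keeps exactly the
consensus calls whose positions occur in the top-k (default 100) covarying
column pairs, optionally after removal of pairs that fail a structural
contact check. The default scorer is mutual information with
average-product correction on sequence-reweighted counts (weights
1/n_neighbors at 80% identity, the standard guard against phylogenetic
bias); a mean-field DCA scorer (one-hot covariance inversion with ridge
regularization, Frobenius-norm couplings, APC) and an importer for
externally computed score tables are provided. Full pseudo-likelihood
maximization is deliberately not reimplemented: at the alignment sizes this
package targets, MI-APC reproduces the *ranking* behavior that the design
step consumes, and production users can import scores from a dedicated
server. Scored pairs require a minimum target-sequence separation of 5
residues (configurable) to strip trivial neighbor signal.

**Contacts.** Contact maps are minimum inter-atomic distances per residue
pair, over all heavy atoms (Calpha-only mode available) and over *all*
chain pairs of the structure, so inter-subunit contacts of a trimer are
captured. Structure-to-target mapping is an explicit per-chain
residue-number offset table, with a global pairwise-alignment fallback
(match +1 / mismatch −1 / gap −2); unmappable residues are reported, never
silently dropped. Pairs farther than a storage cap (default 12 Å) read +inf.
Whether false-negative pairs are removed before or after the top-k cut is
exposed as a flag (`remove_before_cut`, default True — removal first, so
the cut is taken over validated pairs); the original workflow's order is
not documented, and both orders are tested.

## Thermal melting: the Hill law

All three folded-population proxies — SEC trimer area fraction, slow
HDX-component fraction, low-m/z bimodal fraction — are fitted with the same
empirical melting law

    f(T) = 1 / (1 + (T50 / T)^H)

with **T in degrees Celsius**. This is deliberate and load-bearing: the
law is empirical, not thermodynamic, and the magnitudes of published Hill
coefficients (−4 to −21) only arise on the Celsius scale; refitting in
Kelvin would change H drastically. f(T50) = 0.5 exactly for any H. The
quantities are *kinetic* stability readouts (irreversible unfolding after a
20-minute temperature pre-pulse), not equilibrium stabilities.

Fits are bounded trust-region least squares from neutral deterministic
starts (T50 at the grid midpoint, H = −10). The HDX flavors bound H to
(−20, 0]; the SEC flavor is unbounded below, since SEC melts are steeper
than −20. A `bound_hit` flag reports when H lands on its bound, and series
that do not bracket f = 0.5 are fitted but flagged `unbracketed`. Fewer
than 4 temperatures, or an all-equal series, is an error.

**SEC processing.** Trimer fraction = trapezoid area of the chromatogram
inside a fixed elution window (default 2.7–3.25 ml for trimers eluting at
~3.0 ml vs monomers at ~3.5 ml) over total area. The window boundary is a
config choice; with 0.08-ml-wide Gaussian peaks the >3-sigma tail exchange
across the boundary biases recovered midpoints by ~0.01 °C — negligible
against the reported uncertainties but visible at machine precision.
Fractions are normalized to the 4 °C reference run before fitting, and the
total-area ratio against that reference is carried as the
aggregation/loss control.

## HDX-MS kinetics

**Model.** Deuterium uptake of a peptide is
`D(t) = A0 + A1(1−e^(−k1 t)) + A2(1−e^(−k2 t))`: a burst already complete
at the first (10 s) time point, an intermediate component, and a slow
component. Rates are positive by the decay convention. Identifiability of
the two exponentials is enforced by disjoint default bounds, k1 ∈ [10⁻³, 1]
s⁻¹ and k2 ∈ [10⁻⁶, 10⁻³] s⁻¹, matching the observed regimes (k1 ~
10⁻¹–10⁻² s⁻¹, k2 < 10⁻³ s⁻¹) and preventing label swapping. Starts are
fixed (k1 = 10⁻², k2 = 10⁻⁴ s⁻¹; A0 at the 10 s uptake).

**Amplitude constraint.** A0+A1+A2 is constrained to a caller-supplied
ceiling — the saturating uptake observed for the peptide under the harshest
condition — as an exact *equality* via a simplex reparameterization: two
free fractions on [0,1] determine all three amplitudes, so the constraint
can never be violated by the optimizer. A0 is fitted (initialized at the
10 s point) rather than pinned there, because pinning propagates
single-point noise; a strict mode (`fix_a0=True`) pins it.

**Global fits.** For a pre-pulse temperature series of one peptide, k1 and
k2 are shared across all temperatures while each temperature keeps its own
amplitude triple (lmfit, bounded least squares). The slow-component
fraction A2/(A0+A1+A2), normalized to its 20 °C reference value, is the
unimodal melting observable; its Hill fit gives T50-HDX-Uni. A zero
reference fraction makes the peptide unanalyzable (flagged, not fudged).
Constraining rates to be shared can only increase the residual sum of
squares relative to free per-condition fits; this ordering is asserted in
the tests. Uptake values are relative throughout — no back-exchange
correction is applied, matching the acquisition convention of the data
this models.

**Intrinsic rates.** The unprotected-exchange reference is the standard
empirical poly-DL-alanine scheme: per-amide acid/base/water-catalyzed rates
with log-additive side-chain factors of the residue and its predecessor,
charged-terminus corrections, pD via [D⁺] = 10^(−pD) and [OD⁻] =
10^(pD−15.05), and Arrhenius temperature factors (Ea = 14/17/19 kcal/mol
for acid/base/water). Side-chain ionization is fixed at the near-neutral
state (Asp⁻/Glu⁻, neutral His, reduced Cys) — the scheme as implemented is
not valid at strongly acidic pD. The first amide of each peptide is always
excluded (it back-exchanges during analysis), as are prolines. The
unprotected uptake curve defaults to the sum of per-amide exponentials
Σᵢ(1−e^(−kᵢt)); a single-exponential mode using the summed overall rate is
available (`mode="single"`), since either convention is defensible for the
dotted "fully exposed" reference curves.

## Bimodal envelopes (EX1-like analysis)

Bimodal m/z envelopes — two coexisting mass populations of one peptide —
are detected by a deterministic AIC criterion replacing manual inspection:
an envelope is bimodal iff the 2-Gaussian fit beats the 1-Gaussian fit by
ΔAIC > 10 *and* the centers are separated by > 2·max(sigma) *and* the minor
component carries > 10% of the area (all three thresholds configurable and
reported). This replaces the isotope-resolved binomial-fit approach of the
published external tool with a self-contained, reproducible criterion on
profile data.

Deconvolution fits the 2-Gaussian mixture in m/z space on
replicate-averaged envelopes, initialized at the two highest local maxima
with sigma from the dominant peak's FWHM. Fitted centers are bounded to
the observed grid — an off-grid Gaussian could otherwise carry arbitrary
invisible area at zero residual cost. For temperature series, the low- and
high-m/z component positions are anchored by the coldest and hottest
envelopes of the series and each fit's centers are bounded to ±1 m/z around
those anchors; this keeps the deconvolution identifiable at the extremes
where one component's area vanishes (the fraction then correctly goes to 0
or 1 instead of splitting arbitrarily). The per-temperature mean low-m/z
fraction over ≥4 labeling times is the bimodal melting observable
(T50-HDX-Bi after Hill fitting). Charge enters only when converting
centroid shifts to Daltons: uptake = Δcentroid × z, with intensity-weighted
(trapezoid) centroids.

## Transport

Counts are background-subtracted (clamped at zero with a warning if
background exceeds signal), converted to pmol through a per-concentration
specific-activity table — the tracer fraction of the titration mix differs
across concentrations (1, 5, 5, 5 μM tracer at 0, 5, 50, 200 μM substrate)
so the conversion cannot be a single constant — and normalized to protein
(GFP fluorescence estimate). Initial rates use the origin-constrained
least-squares slope b = Σtᵢyᵢ/Σtᵢ² over the 120 s and 180 s points,
reported per minute. Km and Vmax come from a bounded nonlinear
Michaelis–Menten fit (Km > 0) started at the observed plateau and the
interpolated half-saturation concentration.

## Synthetic data: what it does and does not emulate

Every generator draws from the analytic model of its observable with
additive Gaussian noise on the observable (matching the replicate-scatter
style of the source data) and emits a ground-truth sidecar. Defaults are
the study conditions: labeling times {10, 60, 300, 1800, 3600} s, pre-pulse
temperatures 20–65 °C, trimer/monomer elution at 3.0/3.5 ml, titration at
{0, 5, 50, 200} μM, k1 = 0.05 s⁻¹ and k2 = 5×10⁻⁴ s⁻¹ in the published
regime, envelope grids at 0.02 m/z (≥10 points per isotopic-width
Gaussian). MSA columns are independent except declared coupled pairs — the
minimal model that exercises the consensus and covariance stages
separately. The uptake melt generator allocates the slow amplitude as
A2(T) = M·s_ref·f(T;T50,H) with A0+A1+A2 = M at every temperature
(s_ref = 0.85 by default: reference kinetics dominated by the slow
component, burst near zero).

Not emulated: isotope fine structure, retention-time drift, back-exchange,
peak tailing (EMG shapes), phylogenetic tree structure in MSAs, or
correlated noise. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated models, not robustness to
every artifact of real LC-MS or SEC data.

Problem sizes used by the test suite and the acceptance script — 62-point
SEC grids, 19-temperature envelope series, 10-temperature × 5-time uptake
series, alignments of 10³–10⁴ rows × ≤40 columns — were chosen as the
smallest sizes at which the recovery properties are comfortably
demonstrated; everything runs in seconds on one core.

## Numerical and degenerate-input conventions

* All fits use deterministic starts; no stochastic restarts in the default
  path (non-convergence warns and flags rather than silently retrying).
* Chromatogram/envelope grids must be strictly increasing; degenerate
  inputs (zero total area or intensity, all-equal melting fractions, empty
  component lists, single-row alignments) raise errors rather than
  returning NaN.
* Replicate envelope averaging is a pointwise mean on the common grid;
  s.e.m. is carried for reporting only, not as fit weights (weights are
  available via the `sem` argument of `fit_hill`).
* CLI reports are JSON with sorted keys plus TSV tables; reruns with the
  same config and seed are byte-identical, and every report embeds the
  config hash and package version.

## Known limitations

* MI-APC is a ranking-grade covariance score, not a coupling-strength
  estimate; at very shallow alignments (< ~500 effective sequences) its
  ranking degrades before DCA's would.
* The intrinsic-rate table is transcribed from the published empirical
  scheme at near-neutral ionization only; pD far from 7 or unusual termini
  chemistry (amidated C-terminus, acetylated N-terminus) are not modeled.
* The Hill law is descriptive; T50 values are operational midpoints tied to
  the 20-minute pre-pulse protocol and do not transfer to other heating
  protocols.
* Michaelis–Menten parameters from a 4-point titration carry large
  sampling variance (the per-seed Km scatter at 5% noise exceeds 10%);
  the estimator is unbiased, and the tests check the mean over seeds.
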