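# Methods

## The positional labeling model

`citrace.model` tracks the expected fractional ¹³C excess at the six carbon
positions of citrate — first moments of the positional isotopomer
distribution, not full bond-pattern isotopomer vectors. This is sufficient
because both diagnostic ratios, R1 = ((C2+C4)−C3)/(C2+C4) and
R2 = (C1+C5)/C3, are linear in positional integrals. Multiplet fine
structure (which reflects pairwise co-labeling) is needed only to render
realistic synthetic spectra and is parameterized separately (see below).

Assumptions, in the order they enter:

1. **Entry.** Per citrate formed, labeled carbons arrive via PDC/acetyl-CoA
   with probability 1−p onto a single position (C2 for [1,6-¹³C₂]glucose,
   which glycolysis converts to [3-¹³C]pyruvate; C1 for [2-¹³C]pyruvate),
   and via PC/oxaloacetate with probability p onto C3 and C4 at ½ each.
   PDC entries are weighted by the acetyl-CoA pool enrichment f_a, PC
   entries by the pyruvate pool enrichment f_p.
2. **Complete scrambling.** Fast exchange through the symmetric
   fumarate/succinate stage makes the oxaloacetate pool positionally
   symmetric; the 50/50 split is exact and no partial-scrambling parameter
   exists.
3. **Unlabeled CO₂.** The bicarbonate pool is large, so carbon refixed by
   PC is unlabeled; PC introduces label only through pyruvate C2/C3.
4. **Per-turn divergence.** A fraction d of the citrate pool leaves the
   cycle each turn. All cataplerotic routes are absorbed into d, so d is an
   upper bound on the true citrate secretion fraction c.
5. **Turn transition.** Citrate processed onward re-forms with the carbon
   fate map C1→(C5,C6)/2, C2→(C3,C4)/2, C3→(C3,C4)/2, C4→(C5,C6)/2; C5 and
   C6 leave as CO₂. The map is linear and sub-stochastic (columns 1–4 sum
   to 1, columns 5–6 to 0).
6. **Steady state.** The accumulated 48-h secretion is identified with the
   geometric mixture s = Σ_k d(1−d)^k T^k L₀; no kinetics are modeled.

The sum is evaluated iteratively and truncated when the largest entry of
the increment drops below `tol` (default 1e−12) or after `max_turns`
(default 200) turns; the label content of a generation decays at least as
fast as ((1−d)/2)^k, so truncation error is negligible at these defaults.
d = 0 is rejected rather than special-cased (no secretion means no
secreted distribution; small-d limits are evaluated explicitly). The test
suite checks the iterative evaluation against independently derived
closed-form geometric sums to 1e−10 over a (d, p) grid.

The mean number of turns before secretion is the mean of the geometric
exit-time distribution, (1−d)/d. A label-weighted variant would differ;
the plain geometric mean is adopted because it is the natural reading of
"turns completed before a label is secreted" and reproduces the printed
headline value.

[5-¹³C]glutamine is represented only by its direct citrate entry positions
(C1 reductive, C5/C6 oxidative) for the glutamine module; it is not run
through the turn-transition engine, and the engine rejects it, because no
R1/R2 analysis is defined for that tracer.

## Enrichment conventions

For the glucose experiment the defaults are f_p = 0.80 (from lactate ¹³C
satellites, taking lactate as a fast-exchanging proxy of pyruvate) and
f_a = 0.56 (from the labeling pattern of secreted glutamate C4). For the
pyruvate experiment the measured pyruvate enrichment is 0.83 but no
acetyl-CoA value is available; the package carries over the
acetyl/pyruvate enrichment *ratio* of the glucose experiment
(0.56/0.80 = 0.70), giving f_a = 0.581. Because R2 is homogeneous of
degree 0 in (f_a, f_p) — the PDC lineage scales with f_a and the PC lineage
with f_p — only this ratio matters, and the absolute 0.83 drops out of the
inversion. Both tracers accept explicit enrichments for other conventions;
this is the single most consequential convention in the package and is
therefore surfaced in the CLI (`--fp`, `--fa`, config key `fp_pyruvate`).

## Inversion

R1 is strictly increasing in d at fixed p, and R2 strictly decreasing in p
at fixed d, over the admissible region (asserted numerically in the test
suite). `invert_ratios` therefore solves the two constraint curves
p(d | R1_obs) and p(d | R2_obs) by bisection at each grid point
(d step 0.01), locates their intersection by sign change, refines d by
Brent's method on the curve gap, and polishes the 2-vector residual with a
Newton-type root solve to 1e−8. Shallow, near-tangent intersections can
produce two adjacent sign changes on the grid; candidates are refined and
deduplicated by proximity before ambiguity is declared, and genuinely
distinct multiple roots raise an error listing them. Out-of-range ratios
fail loudly with the attainable envelope in the message; nothing is
clamped. Observed R1 is accepted anywhere in (0, 1] — the joint
feasibility check, not a fixed floor, decides whether a pair is invertible,
since R1 below 0.5 is attainable when the PC route is strong.

`solve_p_at_fixed_d` is exposed separately so a PC fraction can be explored
for a sample whose R1 (hence d) was not measured — e.g. a VCaP-like
R2 ≈ 13.8 maps to p ≈ 0.1 over the plausible d range; no single value is
asserted because d is unidentified there.

## NMR quantification

Fitting follows the prior-knowledge (AMARES-style) paradigm in the
frequency domain: Lorentzian lines with positions pinned in Hz by the known
¹J(C2,C3) = 38 Hz coupling, a single shared phase (fixed at 0 by default),
linewidths constrained to 4–20 Hz (FWHM), and symmetric satellite lines
tied to equal amplitude. The C2/4 region (46.5 ppm) is a singlet plus a
±19 Hz doublet — the C2–C4 coupling is below the linewidth and neglected;
the C3 region (76.2 ppm) is a central line plus four outer lines at ±19
and ±38 Hz. Integrals are analytic component areas (height × π × HWHM),
not trapezoidal sums. Because C2/4 and C3 belong to the same molecules in
the same spectrum, `fit_citrate_regions` fixes the C3 linewidth at the
value fitted on the much stronger C2/4 multiplet, which markedly reduces
the variance of the weak C3 integral.

Numerical choices: the fit window is ±140 Hz around the anchor; the anchor
shift is fitted within ±15 Hz; amplitudes are bounded below by 0; noise σ
is estimated as the 0.2-quantile of |intensity| in the window divided by
0.2533 (the Gaussian 0.2-quantile of |X|/σ), which is robust to peaks;
goodness of fit is residual RMS over σ. The baseline is assumed flat and
zero; a linear-baseline option (`baseline="linear"`) exists for windows
contaminated by tails of distant strong lines and is off by default.
Linewidths converging onto a bound are flagged (`at_bound`).

Quantification: concentration = (I_met/n_protons)/(I_TSP/9) × 0.2 mM
against the TSP internal standard; rate = mM × mL × 1000 / (h × cells/10⁶)
in nmol/h per 10⁶ cells. `medium_volume_mL` deliberately has no default —
it must be supplied, preventing silent unit errors. Fractional enrichment
is satellite/(satellite+unlabeled); the acetyl-CoA variant takes
caller-supplied glutamate C4 labeled/unlabeled integrals rather than
hard-coding a glutamate multiplet model. The glucose-remaining formula
divides the glucose ¹³C integral by 2 labeled carbons per molecule (each
[1,6-¹³C₂]glucose yields two trioses carrying one label apiece) and by the
tracer's isotopic purity (default 0.99); the multiplicity correction is a
configurable argument. ¹³C integral comparisons assume equal per-carbon
response (no NOE/T1 correction) — a documented limitation consistent with
ratio-based use.

## Glutamine split

HMBC cross-peak intensities are not proportional to carbon amounts (J(C,H)
and relaxation differ per pair), so a reference HMBC on unlabeled citrate,
whose true C1/5:C6 ratio is 2:1, calibrates a single multiplicative
correction factor = 2/observed. With reductive label y on C1 and oxidative
label x on C5 and λx on C6 (λ ∈ (0,1] models label loss from C6 by
exchange with CO₂; default 1), the corrected ratio ρ = (y+x)/(λx) gives
y/x = λρ − 1 and a reductive fraction f_red = (λρ−1)/(λρ+λ), which reduces
to (ρ−1)/(ρ+1) at λ = 1. Ratios below the oxidative-only floor 1/λ are
rejected as inconsistent. The percent contribution to the citrate C1,5,6
pool extends the measured labeled C1/5 concentration by the inferred C6
(= C1/5·(1/ρ)) and divides by 3 × citrate concentration. Note that once ρ
is *measured*, λ cancels exactly in this total — λ affects the
reductive/oxidative attribution, not the amount of observed label; this is
a property of the inference route, not a bug. Cytosolic and mitochondrial
reductive carboxylation are not distinguished (the measurement cannot).

## Synthetic data

The generator (`citrace.synthetic`) emulates 1D media spectra: ¹³C citrate
multiplets whose per-position areas follow the forward model at the chosen
(d, p, f_p, f_a) ground truth; a ¹³C TSP line at −2.0 ppm; remaining
[1,6-¹³C₂]glucose and [3-¹³C]lactate lines; and a ¹H spectrum with the
citrate AB quartet (2.54–2.72 ppm), lactate and alanine methyl doublets
(³J(H,H) = 6.9 Hz) with ¹³C satellites at ±¹J(C,H)/2 = ±63.5 Hz scaled by
f_p, and the 0.2 mM TSP reference at 0 ppm. Axes are −5–200 ppm at 32k
points (¹³C, 125.76 MHz) and ~0–10 ppm at 16k points (¹H, 500 MHz);
linewidths are 8 Hz (¹³C) and 1.2 Hz (¹H). Noise is i.i.d. Gaussian per
point with σ = (tallest citrate line height)/SNR, seeded; identical ground
truths produce bit-identical spectra.

Default study conditions emulate an LNCaP-like incubation: d = 0.79,
p = 0.21, citrate 0.27 mM (≈5.6 nmol/h per 10⁶ cells for 10⁷ cells in
10 mL over 48 h), lactate 5 mM, alanine 0.5 mM, glucose 11 → 5 mM,
SNR 100. The C2 doublet fraction (0.30) and the C3 five-line pattern
(0.6/0.15/0.05 center/±19/±38) are free generator parameters chosen to
look like realistic partially co-labeled citrate; they are *not* derived
from the positional model, which carries no co-labeling information — so
synthetic multiplet structure must not be over-interpreted, and passing
tests say nothing about real doublet fractions.

What the generator does not emulate: phase errors, baseline roll and
shimming artifacts, T1/NOE response differences between carbons,
J-modulation, peak overlap from the full media background (only the tails
of the lines it renders), or time-resolved labeling kinetics. Recovery
results on synthetic data therefore bound what the pipeline can do on real
spectra from above.

A note on attainable precision: with σ defined against the tallest citrate
line, the weak five-line C3 multiplet carries an irreducible integral
standard deviation of ≈3.7% at SNR 50 — the exact linear least-squares
estimator with true anchor and linewidth does no better — so occasional
per-spectrum C3 errors above 5% at the low end of the 50–200 SNR range are
a property of the measurement, not of the fitter. The linear-baseline
option removes the ~1% systematic from far-line tails but adds variance
and does not change this floor.

## End-to-end recovery

`end_to_end_recovery` simulates a glucose run and a paired [2-¹³C]pyruvate
run at the same (d, p), fits the citrate regions (C1/5 as a singlet in the
pyruvate run), forms R1 and R2, and inverts. The C3 fits are not
signal-gated because C3 legitimately vanishes as p → 0 (the d = 1, p = 0
limit must yield R1 ≈ 1, not an error); if the measured ratios fall
outside the model envelope (degenerate truths), the report carries NaN
parameter estimates rather than failing. At the default conditions
(SNR 100) the chain recovers d within 0.05 and p within 0.03.

## Known limitations

* d aggregates all cataplerotic effluxes; only an upper bound on the true
  citrate secretion fraction is identified without extending the model
  with glutamate (or other) pool exchange.
* The pyruvate-experiment acetyl-CoA enrichment is a convention (ratio
  carried over from the glucose experiment), not a measurement.
* First-moment tracking cannot predict multiplet fine structure; a full
  isotopomer simulation would be required for that.
* Equal per-carbon ¹³C response is assumed across resonances.
* The model assumes isotopic steady state over the incubation; early
  transients are not represented.
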