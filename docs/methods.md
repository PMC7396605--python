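# Methods

## Model

The pipeline analyses closed-system kinetic isotope fractionation of a
single substrate (no daughter-compound mass balance). Isotope
compositions are stored in δ-notation (‰) and converted to ratio
multipliers `R = 1 + δ/1000` at exactly one boundary (`dualcsia.core`),
which eliminates the ×1000 error class. δ values must exceed −1000‰;
the chlorine reference is treated as an opaque SMOC-anchored laboratory
scale because every downstream quantity is a ratio of ratios.

**Rayleigh regression.** The enrichment factor ε (‰) is the OLS slope
of `1000·ln(R_t/R_0)` on `ln f` with a free intercept. The free
intercept absorbs mis-specification of the starting composition δ₀;
on exact data the slope is unbiased either way, and the intercept is a
useful diagnostic (it should be ~0 when δ₀ is right). The 95%
confidence interval is the two-tailed t interval with n − 2 degrees of
freedom. Replicate measurements enter as individual points rather than
vial means: averaging first would discard the degrees of freedom the
t interval relies on. Fits go through `statsmodels.OLS`.

**Dual-element slope.** Λ is the OLS slope of δ¹³C (response) on
δ³⁷Cl (predictor), carbon on the ordinate, fitted in δ-space — the
convention of published dual-element plots. Two consequences are worth
stating explicitly:

1. *Curvature.* Exact Rayleigh data are linear in ln-ratio space, not
   δ-space, so the noiseless δ-space slope deviates from ε_C/ε_Cl; over
   the design f = 0.9 … 0.1 the deviation grows with |ε_C − ε_Cl| and
   reaches ~4% at ε_C = −35‰, ε_Cl = −0.4‰ (2.6% at the
   1,2-dichloroethane pair −27.5/−5.3, where the δ-space value 5.33 is
   in fact the one that matches published Λ tables). The property suite
   asserts a ≤5% envelope plus exact agreement with an independent
   closed-form OLS oracle.
2. *Attenuation.* Analytical noise on the predictor (δ³⁷Cl) biases the
   OLS slope slightly toward zero (classical errors-in-variables); at
   the default design and 0.5‰ noise the attenuation is ~2%. OLS is
   kept as the default because the plain slope + t-based CI is the
   published evaluation procedure; an errors-in-variables (York-type)
   regression is a documented extension point, deliberately off by
   default.

`compare_lambdas` uses a Welch-type t statistic on two slopes with
Welch–Satterthwaite degrees of freedom (each slope carrying n − 2).
Published "±" half-widths can be converted back to standard errors via
`dual_fit_from_summary`, which assumes they are 95% t half-widths — the
only uncertainty procedure the source tables state.

**AKIE.** `AKIE = 1/(1 + z·(n/x)·ε/1000)` with the (n, x, z) registry
shipped as a human-editable CSV (`dualcsia/data/position_params.csv`),
each entry carrying a provenance note. The concerted-chlorine entry for
1,2-DCA (n = 2, x = 2, z = 2) is tagged `reconstructed`: the printed
source line is garbled, and this is the unique small-integer triple
whose factor (z·n/x = 2) reproduces the published concerted chlorine
AKIE from its ε. The PCE entries are stored exactly as printed even
though their published AKIEs are not arithmetically consistent with
them; `compute_akie(..., factor_override=...)` is the escape hatch for
such cases, and PCE AKIE reproduction is not asserted anywhere.
CI propagation maps the ε interval endpoint-wise through the monotone
decreasing AKIE function (endpoints swap). Display rounding is 3
decimals; full precision is retained internally and in JSON reports.

**Mechanism discrimination.** An individual AKIE is flagged as
exceeding its element's Streitwieser limit (C: 1.057, Cl: 1.013) by a
plain point comparison. A mechanism *scenario* (concerted vs stepwise
parameterization of 1,2-DCA) is rejected only when **all** of its
AKIEs exceed their limits: concordant exceedance across both elements
is the decisive physical signal, whereas a single marginal exceedance
(e.g. carbon 1.0582 vs 1.057, well inside its own CI) does not rule a
mechanism out on its own. The Λ-pattern boundary Λ* = 6 used by
`classify_dual_pattern` is operational configuration placed between the
empirically observed clusters (~2–5 vs ~8–15), not theory; the label is
`ambiguous` whenever the 95% CI straddles the boundary, and the
boundary is a keyword argument.

## Synthetic data

`simulate_rayleigh_series` emulates the sacrificial-vial assay the
analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `f_grid` | 0.9 … 0.1, step 0.1 | nine vials sacrificed across the degradation window |
| `n_replicates` | 3 | triplicate isotope measurements per vial |
| `noise_sd` | 0.5‰ | analytical uncertainty, independent Gaussian per element per measurement |
| `delta0_c` / `delta0_cl` | −30‰ / 0‰ | starting compositions, typical for industrial solvents; slopes are invariant to them (asserted by test) |
| `seed` | 0 | `numpy.random.default_rng` seed; same seed ⇒ bit-identical series |

Deltas follow the exact distillation law
`δ_t = (1 + δ₀/1000)·f^(ε/1000) − 1` before noise.
`make_study_fixture` selects published (ε_C, ε_Cl) pairs per assay
compound × cultivation history as generating truth (two combinations
are recorded as not determined and raise accordingly).

What the generator does **not** emulate: correlated replicate errors
(shared headspace injections), drift within a measurement sequence,
concentration-measurement error in f, substrate carryover between
vials, or daughter-product isotope mass balance. Passing recovery tests
therefore show that the estimator is correct and well-calibrated for
independent Gaussian analytical noise under the stated design — not
that field or instrument data meet those assumptions.

## Isotopologue oracle

`simulate_isotopologues` is a forward simulator independent of the
Rayleigh/AKIE algebra, used to validate it. Molecules are partitioned
into isotopologue classes (sets of heavy positions, per element); each
class is consumed with first-order kinetics at a rate set by a channel
rule:

* `competing_channels` — every reactive position is a channel of rate
  k/z, slowed by its position KIE when heavy (intramolecular
  competition);
* `single_concerted_channel` — one channel of rate k divided by the
  product of the KIEs of heavy atoms at reactive positions. This
  product rule is one defensible reading of "concerted"; no molecular
  rate model is canonical, so the rule is configurable, and
  oracle-vs-algebra equivalence is asserted only for geometries where
  the mapping is unambiguous (single reactive position, or identical
  KIEs in the dilute limit).

Because the classes are uncoupled, each decays as an exact exponential;
the trajectory is evaluated in closed form with the time for each
target f located by Brent root-finding (xtol 1e−14). This replaces a
numerical ODE integration with something strictly more accurate at
lower cost. A per-molecule stochastic mode (multinomial class
assignment + exponential lifetimes, survivors selected by order
statistics) exists for small-N validation.

The default is the dilute single-label approximation (`max_heavy = 1`);
full multinomial classes are available via `max_heavy = n_positions`
and matter for chlorine, whose ~24% heavy abundance is not dilute in
polychlorinated species. The bulk-δ trajectory carries a genuine
O(abundance) dependence — heavy classes contribute light atoms to the
pool and shift f itself — measured at ~0.01‰ for natural ¹³C abundance
(1.1%) and ~0.05‰ at 5%; tests assert those bounds rather than exact
abundance invariance.

## Numerical and interface choices

* All randomness flows through `numpy.random.default_rng(seed)`;
  reports echo the seed and serialize with sorted keys and fixed float
  display (ε/Λ to 1 decimal, AKIE to 3), so regeneration is
  byte-identical. Floats in JSON are rounded at 1e−12 to cut
  representation noise.
* Degenerate designs (zero predictor variance), n < 3, missing δ₀,
  f ≤ 0, and out-of-domain ε (1 + z·(n/x)·ε/1000 ≤ 0) raise typed
  errors; f > 1 is accepted with a warning (noise around the starting
  concentration is common in real assays).
* The measurement CSV schema is versioned by a leading comment line;
  the f = 1 reference row carries the starting composition so files are
  self-contained.
* Test and validation problem sizes: recovery ensembles use 100 seeds
  (Λ) and 200 seeds (ε) of the 27-observation default design; the
  stochastic-vs-deterministic check uses 2×10⁵ molecules in a
  strong-KIE regime where sampling noise is small relative to signal.

## Known limitations

* Substrate-only: no sequential daughter chains (PCE→TCE→…→ethene) and
  no product isotope mass balance.
* No enzyme-level corrections (commitment to catalysis, binding
  masking, transport limitation): AKIEs are *apparent* by construction
  and are lower bounds on intrinsic KIEs when masking is present.
* OLS Λ inherits the curvature and attenuation effects quantified
  above; for very asymmetric ε pairs (|ε_C/ε_Cl| ≳ 50) interpret Λ
  against the fitted value, not the ε ratio.
* The registry covers the chlorinated ethenes and 1,2-DCA; TCE is a
  valid compound label for data handling but has no AKIE
  parameterization entry.
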