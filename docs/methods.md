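# Methods

`encortex` is a steady-state rate model of cat primary visual cortex built
to study one question: how can a *single, spatially uniform* cortical
computation produce systematically different response properties in
iso-orientation domains and at pinwheel centres of the orientation
preference map?  This note documents the model, its parameters, the
synthetic data that stands in for recordings and optical-imaging maps, the
numerical choices, and the limits of what the simulations show.

## Feedforward pathway

A stimulus is a luminance image `S(x, y)` in `[0, 1]` on a square grid
(default 64 x 64 pixels at 0.1 deg/px).  Gratings are
`0.5 + 0.5 c sin(2 pi f (x cos(theta) + y sin(theta)) + phi)`; plaids add
components around mid-grey, with the plaid's *total contrast* defined as
the sum of component Michelson contrasts (so an n-component plaid at total
contrast 1 carries `1/n` per component).  Multi-component plaids stagger
the component phases uniformly around the phase circle
(`phi_k = 2 pi k / n`); a common phase would superpose all components
coherently at one point and the response to an octotropic (eight-grating)
plaid would collapse to a cancellation artifact.  Spatial frequency is
never a fitted quantity; the default 0.5 cyc/deg is a typical area-17
optimum and must simply be resolvable by the thalamic kernels.

Four stages follow.

1. **Photoreceptor.** Pointwise Naka-Rushton compression
   `P = S^e / (S^e + L50^e)` with `L50 = 0.5` (the mid-grey adaptation
   point) and exponent `e = 10`.  The steep sigmoid centred on the
   operating point means high incremental gain in a narrow luminance band:
   grating modulations compress early, giving the thalamic drive a
   saturating contrast response (half-saturation near 20 % contrast at the
   cortical stage) and, through it, feedforward cross-orientation
   suppression.  A hyperbolic unit (exponent 1) cannot play this role
   here: it is steepest at zero luminance, so the dark half-cycle of a
   grating is *expanded* rather than compressed, the OFF-channel drive
   grows supralinearly with contrast, and masking turns into facilitation.
2. **Thalamus.** `P` is convolved (reflective boundary) with a
   difference-of-Gaussians receptive field; the surround s.d. is 0.9 deg
   and the centre s.d. is fixed at one third of it.  Both Gaussians are
   normalised to unit volume so the kernel integrates to zero and a blank
   screen evokes exactly nothing.  The OFF field is the negated ON field.
3. **Push-pull cortical input.** `n` thalamic subunits are sampled along
   two vertical columns half a grating period apart (ON column left, OFF
   column right), spaced by the DoG centre s.d.  In each subregion the
   rectified input of one polarity excites and the rectified opposite
   polarity inhibits: the ON column contributes
   `[t_on]+ - g [t_off]+` per subunit, mirrored at the OFF column, with
   pull gain `g = 0.8`.  At `g = 1` the antagonistic pair recombines into
   the signed thalamic drive exactly and the receptive field is blind to
   patterns that modulate only along the columns (orthogonal gratings);
   the slight excess of excitation at `g = 0.8` leaves a ~2 % rectified
   floor, a realistic multi-unit baseline.  Narrowly tuned units use 8
   subunits (tuning half-width ~21 deg), broadly tuned units 2 (~45 deg).
   Preferred orientations other than vertical are realised by rotating
   the stimulus, not the receptive field (analytically for grating
   components, by resampling for arbitrary images).
4. **Spiking.** `C = A max(T, 0)^m` with `m = 2`.  The global gain `A` is
   the model's only free scale; it is calibrated once so that the
   phase-averaged response of a narrow unit to its preferred
   full-contrast grating is 1.  The same `A` applies to every neuron, so
   broad units are absolutely weaker — regional differences must never be
   produced by regional parameters.

Flashed presentation at four spatial phases is modelled by evaluating the
static pipeline at each phase and averaging the spiking outputs, exactly
as recorded response magnitudes are averaged.  Pair plaids average over
all 16 phase combinations.

## Cortical circuit

Each neuron interacts with six neighbours at 100-300 um on either side
along the electrode axis, weighted by a Gaussian of sigma 180 um
(normalised to sum 1, self excluded).  The lateral terms couple
*phase-averaged mean rates*: coupling raw per-phase responses would make
the interaction depend on accidental phase alignment between differently
tuned neighbours, an artifact of the four-phase flash protocol rather
than a circuit property.

Reference neighbourhoods: an **iso-orientation** site has co-tuned
neighbours (preference jitter within +-10 deg); a **pinwheel** site's
neighbours span the full 180 deg with the most dissimilar
(near-orthogonal) preferences nearest, as in polar-plot examples of
tracks crossing a pinwheel.  Population simulations read neighbourhoods
directly off a synthetic map.

* **Surround excitation** `C_E = C * sum_j w_j C_j`.
* **Un-oriented inhibition** `C_U = gain * p / (p + s50)` where `p` is the
  rectified ON+OFF thalamic drive pooled over an isotropic Gaussian
  window (a quarter of the grid extent; a hard-edged window would pick up
  partial grating periods anisotropically).  `s50` is 5 % of the pooled
  drive at full contrast, so `C_U` is "severely compressed": within 20 %
  of its ceiling from 25 % contrast upward, and orientation-blind to
  within ~1 %.
* **EN model** `C_EN = r_max C_E / (b1 C_E + b2 C_U + b0)` with
  `r_max = 2`, `b0 = 0.01`, `b1 = b2 = 1`.
* **DN comparison model** `C_N = C / (sum_j w_j C_j + b0)` — the same
  pre-cortical stages, with the excitation pool moved into a divisive
  denominator.

The `C_U` gain is calibrated so that `b2 C_U` at full contrast sits a
factor 1.5 above `b1 C_E` of an iso-domain reference neuron driven by its
preferred full-contrast grating.  This is the operating point at which
(i) the normalization visibly bends the iso-domain contrast-response
curve, (ii) the co-tuned excitation still narrows iso-domain tuning (the
denominator must not be dominated by `C_E` itself, which would re-broaden
the curve), and (iii) the octotropic-plaid ordering between pinwheel and
iso sites keeps the sign of the excitation pool rather than being
inverted by compression of the reference response.  The calibration uses
the model's own reference circuit, happens once at construction, and the
resulting constants are identical at every site; a uniform-parameter
contract the population code never violates.

## Synthetic data

* **Orientation maps.** Complex Gaussian noise band-pass filtered at
  1/wavelength (wavelength 1000 um, pixel pitch 20 um, Gaussian bandwidth
  25 % of the pass frequency); orientation is half the argument of the
  filtered field.  Such fields have uniformly distributed preferences,
  smooth iso-orientation domains and pinwheels (phase singularities of
  charge +-1/2, located by plaquette winding numbers) at a density of a
  few per square millimetre — the qualitative statistics of
  optical-imaging maps, which is all the downstream analyses use.  No fit
  to real imaging data is attempted.
* **Electrode tracks.** Straight lines of up to 32 sites at exactly
  100 um spacing; site orientations are bilinearly interpolated on the
  doubled-angle complex field, which respects circular topology.
* **Recordings.** Per-site mean responses are
  `R_max c^n/(c^n + c50^n) * exp(kappa (cos 2(theta - pref) - 1)) + b`
  with independent Poisson spike counts over 20 trials.  The response
  magnitude is the trial-mean count; no peri-stimulus smoothing is
  re-implemented because every downstream statistic consumes one
  magnitude per stimulus.  Default truth ranges used in tests
  (`R_max` 20-50 counts, `c50` 0.1-0.5, `n` 1.5-4, `kappa` 1-4) are
  typical of cat area-17 multi-unit data.  Site screening follows the
  recording convention: signal-to-noise ratio above 5 (preferred-stimulus
  mean over the across-trial s.d. of the least effective stimulus), and a
  local homogeneity index only where three screened sites flank the
  reference on each side.

## Analysis battery

* **Contrast response.** Bounded least-squares Naka-Rushton fits with
  five log-spaced `c50` starts and exponent limits [0.5, 6] (the
  hyperbolic ratio has shallow local minima at extreme exponents).  The
  *effective* maximum is the fitted value at 100 % contrast and the
  *effective* semi-saturation solves `f(c) = f(1)/2`, which has the
  closed form `c50 (1 + 2 c50^n)^(-1/n)`.  Fit quality is the Pearson
  correlation between fit and data; fits below 0.95 are flagged.
* **Orientation tuning.** Von Mises over doubled angles with an explicit
  baseline, `b + a exp(kappa (cos 2(theta - pref) - 1))`; half-width at
  half height above the baseline is `arccos(1 - ln 2 / kappa)/2`; flat
  curves (kappa below ln 2 / 2) are flagged with a 90 deg width.
  Circular variance is computed from the measured responses.  Fits below
  0.7 are flagged.
* **Suppression index** `SI = 1 - R(plaid)/R(preferred at 0.5 contrast)`;
  the mean SI averages over the eight plaids pairing the preferred
  battery orientation with every battery orientation (the
  preferred+preferred pair included by default, switchable).
* **Local homogeneity index.** Gaussian-weighted (sigma 180 um) resultant
  of doubled orientations over all neighbouring sites, normalised by the
  sum of the weights so a homogeneous neighbourhood scores exactly 1.
  The 2D version uses all map pixels within 3 sigma.  The 1D-vs-2D
  validation samples random interior points, averages the 1D index over
  eight penetration angles (15-site tracks, spanning well beyond the
  Gaussian window) and summarises the scatter with a quadratic fit,
  Spearman correlation and the worst-case 1D overestimate.
* **Nonlinearity index.** Signed area between the fitted curve and the
  chord from the half-maximum point to the maximum point, normalised by
  the area between the chord and the maximal-saturation path (the
  triangle `(1 - c_s) M / 4`), evaluated by trapezoidal quadrature at
  1001 contrast samples: +1 maximal saturation, 0 linear, -1 maximal
  expansion.  A semi-saturation at 1 makes the triangle degenerate and is
  flagged.
* **Correlations.** Pearson r with two-sided p and the least-squares
  line; Spearman rank correlations accompany the octotropic analyses.  No
  multiple-testing correction is applied; p-values are reported raw.

## Population simulation

120 model neurons are placed at map locations stratified into three 2D-LHI
bands (40 each), guaranteeing dynamic range.  A site takes its preferred
orientation from the map, its six lateral neighbours from a random-angle
track through its position, and its tuning class from the local
homogeneity (narrow where 2D LHI >= 0.5, broad otherwise — matching the
observation that thalamic afferents are less orientation-balanced near
pinwheels).  Each site is probed with the grating battery, the
preferred-orientation pair plaids and the octotropic plaid under the EN
model, then fitted with the full battery.  For speed, the feedforward
pathway is tabulated once per tuning class on a 2.5 deg grid of
stimulus-relative orientations (5 deg for pair plaids) and interpolated
periodically; interpolation agrees with direct evaluation to better than
3 % and the approximation is itself under test.

## Known limitations

* The model is static: flash timing, response dynamics, adaptation and
  thalamic contrast-gain control are outside its scope.
* The photoreceptor steepness, push-pull pull gain, column geometry and
  the `C_U` calibration level are operating-point choices documented
  above, not quantities estimated from data; the simulations establish
  *directions* (orderings, correlation signs), and the package's checks
  treat them that way.
* Equal-contrast facilitation ("summation") by a mask that does not
  itself drive the neuron is not reproduced: in this architecture — and in
  a divisive-normalization account evaluated on the same single-unit
  configuration — an orthogonal equal-contrast mask suppresses.  The
  winner-take-all regime at disparate contrasts, and its completion by
  the iso-domain cortical suppression, are reproduced.
* In the image-processing demonstration the pinwheel pool's lateral term
  is the orientation-average of the iso pools' terms, so its summed
  response cannot exceed the iso pool's in absolute units; the
  contour/pattern dissociation is therefore expressed as each pool's
  response relative to its own grating-driven maximum (iso pools prefer
  isolated contours outright; pinwheel pools show the stronger relative
  preference for the multi-orientation rosette).
* Synthetic maps reproduce pinwheel topology and uniform orientation
  coverage but none of the higher-order statistics of measured maps;
  passing tests show the analysis pipeline behaves correctly on fields
  with that topology, not that the generator is a model of cortex.
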