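# Methods

Model formulation, parameter defaults, numerical choices and known
limitations of the `beltsim` pipeline.

## 1. Fabric and belt stiffness

A textile panel tested in uniaxial tension shows a hysteretic
loading/unloading loop. Because a belt is stretched, locked, and then
relaxes against the body, the mechanically relevant stiffness is the
tangent at the *start of unloading*: `unloading_stiffness` fits a straight
line to tension-per-unit-width vs. strain over the first 2% of the
unloading strain range (at least 5 samples). Units are N/m: tension per
unit belt width per unit strain.

Panels combine as a spring network (`Leaf` / `Series` / `Parallel`):
parallel stiffnesses add, series compliances add. The catalog contains the
five measured fabrics and the two commercial belts built from them:

| belt | network | k_eq |
| --- | --- | --- |
| A | series(fabric1, fabric3, fabric3) | 13.55 kN/m |
| B | series(fabric2, fabric4, fabric5) | 11.17 kN/m |

Belt B's published network expression reduces algebraically to the plain
series chain of its three panel stiffnesses; evaluating it from the
rounded per-fabric values gives 11.17 kN/m against the published
11.4 kN/m (computed from unrounded lab data), a 2% discrepancy.

The belt anchor tension per unit width is `T0 = k_eq * stretch` with the
nominal closure stretch 0.20. `k_eq` is a per-width quantity, so no
division by the belt height is involved; the belt height (default 0.26 m)
only sets the contact band.

## 2. Trunk surface

Torsos are radius maps `r(theta, z)` on a regular cylindrical grid
(default 360 x 80 over 0.40 m). Frame convention: the belt closure sits
on the abdomen at `theta = 90 deg`, the back midline at `270 deg`; `+y`
is anterior, `+x` the patient's left-right axis.

* **Scan ingestion** (`cylindrical_resample`): the vertical axis passes
  through the cloud centroid; cell radii are per-cell medians; holes are
  filled by periodic angular interpolation. `despike_and_smooth` replaces
  outliers beyond 3 robust standard deviations (1.4826 x MAD) of the local
  5x5 median and applies a separable Gaussian (sigma 2 cells), periodic
  across the theta seam. When the MAD degenerates to zero (exact grids),
  any deviation from the local median counts as an outlier.
* **Synthetic generator** (`synthetic_trunk`): superellipse cross-section
  (exponent 2.4) plus anatomical perturbations — an anterior Gaussian
  protrusion whose amplitude is the BMI proxy and whose apex sags below
  the lumbar level as it grows, a posterior lordosis hollow (depth
  0.025 m at z = 0.18 m), a narrow concave spinal furrow (8 mm deep,
  7 deg sigma), gluteal and chest flares, optional left/right asymmetry
  and seeded low-order Fourier noise. Defaults are study conditions, not
  tuned values.
* **Curvature** (`angular_curvature`): per node, the cross-section
  polyline within a +/-8 deg window is expressed in the local tangent
  frame and a quadratic is least-squares fitted;
  `gamma = y'' / (1 + y'^2)^{3/2}` signed positive where convex. The
  window bias grows with the square of the window width; +/-8 deg keeps
  the bias on a 0.15 m cylinder below 0.5% (a +/-15 deg window would give
  1.2%). The axial curvature `gamma2` uses fixed second-difference
  filters over +/-3 cells.
* **Lumbar center** (`lumbar_center`): deepest point of the posterior
  midline radius profile; falls back to mid-height (with a warning) when
  the profile has no interior minimum.

## 3. Belt placement and adhesion

The belt band is centred vertically on the lumbar center. The per-row
rest length is fixed at placement: `L0 = circumference / (1 + stretch)`,
so body compression during equilibration slackens the belt and lowers its
tension. Along each row the tension per unit width satisfies

```
dT/ds = -xi * a * gamma(s) * T,     gamma clipped at 0 (lift-off)
```

integrated with the exact per-segment exponential (midpoint curvature),
which reproduces the capstan closed form on circular sections. Locking
modes set the boundary layout:

* `frictionless` — no shear transfer; T uniform at the anchor value;
* `symmetric` — both hands pull to the front; decay both ways from the
  closure, branches meeting at the back midline;
* `asymmetric` — one hand holds, the other pulls the strap a full wrap;
  one-way decay producing left/right asymmetry and a parasitic
  anterior-posterior moment.

Transverse (axial) tension follows the Poisson coupling
`T2 = max(k_t * (-nu_belt * eps1), 0)`; for a belt with positive Poisson
ratio the axial strain is contractile and T2 is zero.

## 4. Pressure and elastic remodeling

Interface pressure is the extended Law of Laplace
`p = T1*gamma1 + T2*gamma2` with both curvature terms clipped at zero and
`p = 0` wherever `gamma1 <= 0` (belt lift-off). Conversion: 1 mmHg =
133.322 Pa.

The trunk is a homogeneous linear-elastic half-space (default E = 15 kPa,
nu = 0.48). The surface deflection under a uniform rectangular pressure
patch is Love's closed-form kernel; the total deflection of a gridded
pressure field is its convolution with that kernel, evaluated with FFTs —
circular along theta (shorter-way distance across the seam, uniform mean
arc spacing) and zero-padded along z.

### Fixed-point equilibrium

Compression slackens the belt and flattens the surface, lowering the
pressure, so pressure and geometry are coupled. The loop gain of the
naive explicit iteration is roughly
`G = C * (k_eq * gamma * 2*pi/L0 + T*gamma^2)` with `C` the band
compliance; at E = 15 kPa it reaches ~15, far beyond the explicit
stability limit. `equilibrate` therefore:

* ramps the tension in `n_steps` (default 10) increments;
* starts from the a-priori relaxation factor `lambda = 1/(1+G)`;
* adapts `lambda` by Aitken's Delta-squared rule, clamped to [0.02, 1],
  skipping the update and halving `lambda` whenever the residual grows
  (breaks shallow limit cycles);
* caps any single step at 5 mm of radial motion;
* aborts with a diagnostic after 4 significant (>20%) consecutive
  residual growths, and warns when the final deflection exceeds 10% of
  the local radius (the half-space assumption is then strained).

Convergence is declared when the maximum relative pressure residual drops
below `tol` (default 1e-3).

## 5. Wrench reduction

Cell forces act along the inward radial normal with area
`r * dtheta * dz`. The field reduces to a force screw at the lumbar point
(on the body surface, configurable); `M_t` is the moment component about
the left-right (`x`) axis, positive when it tends to reduce the lumbar
lordosis. Per-slice resultants and pressure-weighted centers of force are
reported, with unloaded slices excluded (NaN centers) rather than shown
as 0/0.

## 6. Trials and statistics

`make_cohort` draws subjects with alternating sexes, uniform BMI
(21-38), age and height; BMI maps linearly to the protrusion amplitude
(5 mm at BMI 21, +5 mm per BMI unit) and weakly to the base radii. Each
subject carries seeded smooth surface noise. `run_cohort` runs the fully
crossed design and applies paired tests within subject (belt, locking),
unpaired tests for sex, and OLS regressions of mean pressure and `M_t`
on BMI and the coefficient of adhesion. Each sample is screened with an
Anderson-Darling normality test at the 5% level; normal samples use
Student's t, otherwise Wilcoxon / Mann-Whitney. All tests use
alpha = 0.05.

## Known limitations

* **Large deflections.** At E = 15 kPa the equilibrium deflection under a
  20%-stretched stiff belt reaches 20-30 mm, 15-25% of the local radius;
  the linear half-space assumption is strained there (a warning is
  emitted). Results at such moduli are trend-level, not quantitative.
* **Mean pressure vs. BMI.** On the synthetic cohort the area-weighted
  mean pressure *rises* weakly with BMI, whereas clinical measurements
  tend to show the opposite; the generator's larger obese radii increase
  belt tension faster than the local curvature drops. The delordosing
  moment trend (decreasing in BMI, changing sign) is reproduced.
* **Half-space geometry.** Love superposition unrolls the surface into a
  tangent plane with a uniform mean arc spacing per band; azimuthal
  spacing variation within a row is ignored.
* **No whalebones/stays, no dynamic effects, no through-thickness soft
  tissue structure.** The trunk is homogeneous and the belt massless and
  inextensible in bending.
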