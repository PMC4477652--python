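# Methods

## The exchange model

An imino proton (G, U) exchanges with water only from the open state of its
base pair. In the EX2 limit — opening/closing fast compared to proton
transfer — the apparent exchange rate measured by selective inversion
recovery is

    k_ex(c_cat, T) = (k_Tr,int(T) + k_Tr,ext(c_cat, T)) · K_Diss/(1 + K_Diss) + d

with

* `K_Diss(T) = exp(−(ΔH_diss − T·ΔS_diss)/RT)` — the opening equilibrium,
  under the assumption that ΔH_diss and ΔS_diss are temperature-independent
  (no ΔCp term; the van't Hoff diagnostic exposes curvature if the
  assumption fails);
* `k_Tr,int(T) = (k_B·T/h)·exp(−(ΔH‡_int − T·ΔS‡_int)/RT)` — Eyring-form
  transfer via internal catalytic groups of neighbouring bases;
* `k_Tr,ext(c, T) = d_dif · k_NTP(T) · c/c_ref` — transfer via the dissolved
  catalyst HPO₄²⁻, modelled from the free-mononucleotide (UTP/GTP) exchange
  rate in Eyring form, scaled by a dimensionless diffusion correction
  `d_dif` and linearly by catalyst concentration relative to the reference
  concentration `c_ref` at which the NTP parameters apply;
* `d` — a dipolar cross-relaxation contribution, visible as a
  low-temperature plateau of k_ex.

The composition is evaluated as `(k_int + k_ext)·σ(ln K) + d` with
`σ` the logistic function, which is exact and immune to overflow of
`1 + 1/K` for very stable pairs. Energies are kJ/mol, entropies J/(mol K),
temperatures kelvin internally (°C at all file interfaces, offset 273.15);
all exponents are evaluated in joules.

The shipped NTP transfer-state defaults (ΔH‡ = 35 kJ/mol,
ΔS‡ = −35 J/(mol K), d_dif = 0.3, c_ref = 1 mM) are placeholders chosen to
give realistic transfer-rate magnitudes (k_Tr,ext ≈ 3·10⁴ s⁻¹ at 2 mM,
20 °C, about an order of magnitude above k_Tr,int, so that the
two-concentration design is informative). They must be replaced by
literature values before analysing real measurements; every correctness
test injects known values, so no result here depends on them. Whether
hydroxide catalysis contributes at pH 6.8 is deliberately out of scope: the
external term models HPO₄²⁻ only.

## Inversion-recovery fitting

The transfer profile `I(t_m)/I(0) − 1 = −2k_ex(e^(−R₁ᴴt_m) −
e^(−R₁ᵂt_m))/(R₁ᵂ − R₁ᴴ)` assumes perfectly inverted water magnetization.
It is symmetric in (R₁ᴴ, R₁ᵂ), so the two relaxation rates are not
identifiable from shape; results are reported under the convention
R₁ᵂ ≤ R₁ᴴ (water relaxes more slowly than exchange-broadened imino protons
in this regime), and R₁ᵂ can be pinned from an independent measurement.
Within 10⁻⁶ relative of the degenerate line the analytic limit
`−2k_ex·t_m·e^(−R₁t_m)` is used, keeping the model continuous.

Fits are unweighted least squares (the weighting of the original profile
fits is not specified anywhere; unweighted is the neutral choice) in
log-parameters, with five log-spaced k_ex starts and lowest-RSS tie-break.
Standard errors come from the Jacobian covariance; because profiles carry
~12–16 points for 3 parameters, ±2σ intervals have slightly sub-Gaussian
coverage (t-distributed errors), which the test suite accounts for.
Profiles with no dip above twice a robust noise floor are returned with
k_ex = 0 and an `upper_bound` flag. Summed profiles of overlapped
resonances (e.g. U7/U37) are fitted to the same model and yield one
averaged rate under a joint label.

## Global stability fitting

One series = rates over a temperature grid at two catalyst concentrations.
The five parameters (ΔH_diss, ΔS_diss, ΔH‡_int, ΔS‡_int, d) are fitted by
bounded trust-region least squares weighted 1/σ², jointly over both
concentrations; two concentrations are required because the
concentration dependence of k_Tr,ext is what separates K_Diss from k_Tr.
Bounds (ΔH_diss ∈ [0, 600] kJ/mol, ΔS_diss ∈ [0, 1600] J/(mol K),
ΔH‡ ∈ [0, 300], ΔS‡ ∈ [−1000, 1000], d ∈ [0, 20] s⁻¹) span the observed
parameter ranges with margin. Initialization is data-driven: d from the
cold plateau; (ΔH, ΔS) from a van't Hoff line through the
between-concentration rate differences (which isolate the open-state
fraction); the internal Eyring pair from the residual internal rate.
Seven seeded multi-starts perturb this guess; optimizer tolerances 10⁻¹²
make noiseless round trips exact to well below 10⁻⁴ relative.

Series whose rates a constant explains (reduced χ² of the weighted mean
< 2) are flagged `not_determinable` — their opening free energy is
unbounded above, mirroring the treatment of terminal base pairs whose
stability can only be bounded by the weakest measurable pair. Temperature
spans under 15 K are flagged `weak_span`.

Monte Carlo errors: each iteration Gaussian-noises every rate by its
standard error and every catalysis input by its configured uncertainty
(all declared uncertainties are noised; the original choice of which inputs
to noise is not recorded), refits from the best fit, and collects the
parameter vector. The MC error is the sample standard deviation (a central
68% interval is also reported); the (ΔH, ΔS) sample covariance gives the
1σ confidence ellipse. Default 200 iterations (minimum 100 for reported
errors); >20% refit failures abort. ΔH and ΔS errors are almost perfectly
correlated within a fit (|r| > 0.95: narrow tilted ellipses) — which is
precisely why compensation claims need the validity test below.

The EX2 diagnostic checks, report-only: (1) rates actually depend on
catalyst concentration (paired z > 5 at matched temperatures — under
EX1-like opening-limited exchange they saturate and do not); (2) no
systematic per-concentration offset of weighted residuals; (3) no
temperature-ordered runs-test trend. Shared-stability fits of overlapped
neighbours average the two series point-wise and flag reduced χ² > 3 as
`inconsistent_pair`.

## Enthalpy–entropy compensation

ΔH (kJ/mol) is regressed on ΔS (kJ/(mol K)) by unweighted OLS: slope = T_c
(K), intercept = y₀ (kJ/mol). Unweighted regression on the reported tables
reproduces the published compensation parameters; an error-weighted
variant would require the unpublished weighting scheme and is not
provided. Fewer than 3 members, or a ΔS range under 3× the mean MC error
of ΔS, yields "insufficient spread".

A fitted line is only called *genuine* if two checks pass:

1. **Ellipse separation** — projected onto the line direction in the
   (ΔS, ΔH) plane, the members' 1σ MC ellipses must be pairwise disjoint.
   Within-fit error correlation produces narrow tilted ellipses; if they
   overlap, the apparent line may be one error ellipse in disguise.
2. **Krug-style harmonic-mean test** — the 95% CI of T_c must exclude the
   harmonic mean of the experimental temperatures, the slope that pure
   fit-error covariance generates. This is a documented stand-in for the
   original (supplementary, unreprinted) statistical tests and is flagged
   as such in reports.

Calibration on constructed controls: members on a line with separated
ellipses are called genuine; pure-noise member sets (one true point,
scatter along the harmonic-mean slope) are rejected with type-I rate
well under 5%.

Construct comparisons (ΔΔH, ΔΔS, ΔΔG at 20 °C, T·ΔΔS) match labels by
name and report unmatched labels. ΔΔG differences recorded Gibbs energies
when both constructs carry them — fitted ΔG values are reported at higher
precision than the rounded ΔH/ΔS pairs, so re-deriving ΔΔG from rounded
differences can deviate by a few tenths of kJ/mol — and falls back to
ΔΔH − T·ΔΔS/1000 otherwise (where the identity is exact).

## Two-state melting

CD signal = B_f(T)·f_f + B_u(T)·(1 − f_f) with linear baselines per state
and `f_f = 1/(1 + exp(−(ΔH_unf − TΔS_unf)/RT))`; T_m = 1000·ΔH_unf/ΔS_unf
is always the derived quantity. One linear baseline per state fitted
simultaneously with the transition is the standard reading of a
"linear temperature dependence of the CD baseline"; the hairpin is
monomolecular, so no concentration term appears. Internally the transition
is parameterized as (T_m, ΔH) for conditioning; fits are unweighted
multi-start over T_m guesses. Transition amplitudes below 3× the residual
rmse are flagged (`broad_transition` / `no_transition`), and a warning is
issued when the data do not extend ≥10 K beyond the transition on both
sides. The fit is exactly invariant under affine rescaling of the signal
axis.

## Synthetic data: what it does and does not emulate

Generators copy the experimental design: T ∈ {−5, −2, …, 55} °C,
c ∈ {2, 29} mM HPO₄²⁻, log-spaced mixing times 2 ms–2 s. Noise is
multiplicative Gaussian on rates (default 5% — matching how rate errors
are reported; recorded σ is truthful) and additive Gaussian on CD signal
(default 1% of the transition amplitude). IR profiles above a detectability
ceiling (k_ex > 150 s⁻¹, severe exchange broadening) are dropped, mimicking
the loss of fast-exchanging resonances. Compensation-line constructs draw
ΔS uniformly over the observed range and set ΔH = T_c·ΔS/1000 + y₀ +
N(0, scatter) with scatter 2 kJ/mol, about the size of the residuals of the
published stem-II line. All generators are bit-reproducible under a seed.

Not emulated: raw FIDs/spectra and peak integration, radiation damping,
temperature-calibration error, baseline drifts, non-Gaussian outliers,
EX1 kinetics beyond the one saturation-type negative control, and
multi-transition melting. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the model's own
assumptions — not robustness to every artifact of real spectra.

## Problem sizes and numerical choices

The recovery experiment in the acceptance script uses 5 compensation-line
members × 50 replicates × 100 MC iterations — around 25 000 five-parameter
refits, a few minutes on one CPU, chosen so the 2σ-coverage estimate has
~1% Monte Carlo error. The validity calibration uses 100 negative-control
replicates. Degenerate inputs are handled explicitly: zero catalyst gives
zero external transfer; K → ∞ and K → 0 limits of the exchange model are
exact; the IR model's equal-relaxation-rate line uses the analytic limit;
ties in multi-start selection go to the lowest residual sum.

## Known limitations

* The diffusion correction `d_dif` and the concentration scaling of the
  NTP rate are modelled linearly from configuration inputs; the original
  derivation is not public.
* The compensation validity test is a Krug-style surrogate, not the
  original (unpublished) test; verdicts are labelled accordingly.
* "Not determinable" base pairs are detected from the data alone (no
  temperature dependence beyond noise); the alternative definition via a
  lower confidence bound against the weakest measurable pair requires a
  reference construct and is left to the caller.
* MC errors assume the recorded per-rate σ is trustworthy; no robust-loss
  option is provided.
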