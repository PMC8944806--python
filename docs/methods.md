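# Methods

## Model

A CTPR array of N repeats is a one-dimensional lattice of 2N helix units
(17 residues each), indexed from the C terminus (index 0 = C-terminal B
helix). Folded helices contribute intrinsic free energies g_A/g_B and
adjacent folded pairs interfacial energies g_AB (within a repeat) or
g_BA (between repeats); unfolded units contribute exactly zero. An
optional next-nearest-neighbour variant adds g_AA/g_BB couplings. All
energies are folding free energies in kT (negative = stable;
kT = 4.114 pN·nm at 25 °C by default).

Repeat-level energies follow the convention ΔG_unit = g_A + g_B + g_AB
and ΔG_nn = g_BA, so ΔG_tot = N·ΔG_unit + (N−1)·ΔG_nn. The reverse
mapping (repeat → helix) is underdetermined; the package's default
("uniform-interface split") assigns every interface ΔG_nn and splits the
remainder evenly between the helices, with two documented refinements:

- `helix_bias` (presets: 0.5 kT) makes the B helix less stable than the
  A helix by 2×bias without changing ΔG_unit. The exposed C-terminal B
  helix packs against a single neighbour; without some A/B asymmetry the
  helix chain is exactly palindromic and the unfolding pathway would be
  artificially symmetric. The bias is small enough to leave the
  minimal-stable-unit counts (3 helices for rv, 2 for a) and the plateau
  force unchanged, while reproducing the observed C-to-N directionality.
- `interface_split` (default 0) weakens the intra-repeat interface
  relative to the inter-repeat one, compensated in the intrinsic terms.
  With a zero split and g_A = g_B the equilibrium FDC of the
  heteropolymer chain is observationally identical to a homopolymer
  chain; the parameter-recovery studies therefore generate from
  `interface_split = 1 kT`, which makes the heteropolymer character
  detectable (alternating even/odd unzipping costs), mirroring the
  physically distinct packing of the two interfaces.

### Mechanics

At trap separation d the configuration c stores
E(c,d) = G_fold(c)·kT + G_mech(c,d). The serial network comprises two
harmonic traps (0.30 pN/nm each), an eWLC handle (Lc = 350 nm,
Lp = 40 nm, K = 1200 pN), and the unfolded chain as a Marko–Siggia WLC
(Lp = 0.9 nm, 0.365 nm/residue; contour set by the number of unfolded
helices, 17 residues each, plus an optional constant flank for tags —
zero by default, since a constant contour only translates the curve).
The balanced tension solves Σ extensions(F) + ξ_folded(c) = d; the
public root finder brackets on [0, 200] pN to 10⁻⁶ pN, while the
ensemble engine inverts a dense pre-tabulated monotone extension sum
(40 001 grid points to 200 pN, interpolation error ≪ 10⁻³ pN).
Tensions below 10⁻³ pN are treated as slack. Configurations sharing
unfolded contour and folded extension are mechanically identical, so all
Boltzmann sums run over those groups; log-space accumulation keeps
fold-energy ranges of hundreds of kT stable.

### Superhelix geometry

The folded remainder contributes the chord of a circular helix,
sqrt((m·rise)² + (2R·sin(m·φ/2))²) + offset, with helices counted as
half repeats and disjoint folded segments adding independently. Defaults
describe the helix traced by the repeat centroids — the path the pulled
termini sit on: adjacent repeat centroids in a TPR stack are ~1.0–1.1 nm
apart and the array turns over every ~8 repeats, which fixes
rise ≈ 0.9 nm and R ≈ 1 nm (a-type preset: R = 1.0 nm, rise = 0.90 nm,
φ = 45°, offset = 1.0 nm; rv-type: R = 1.3 nm, rise = 0.80 nm, wider and
shorter). Note the centroid radius is much smaller than the solenoid's
outer envelope (several nm): using the envelope radius would imply
~3 nm centroid spacing and produce plateau oscillations an order of
magnitude larger than observed. With the centroid geometry the 20- and
26-repeat model plateaus show 2 and 3 oscillation periods of a few
tenths of pN. The beads-on-a-string law ξ = (n/N)·ξ_max is retained as
the rejected alternative; it reproduces the terminal dip but flattens
the plateau.

### State spaces

`full` enumerates all 2^n helix states (capped at 24 helices), `zipper`
keeps the empty state plus every contiguous folded block
(n(n+1)/2 + 1 states), and `skip` removes every state containing a
folded run of length 1–2 that touches neither end of the array.
Isolated short internal islands are transient nuclei with strongly
positive energy; pruning them cuts the state space from 2^n to ~1.62^n
while keeping the multi-segment intermediates that matter near the dip.
Two consequences are documented rather than hidden: short *internal*
contiguous blocks are zipper states but are pruned by skip (so zipper is
not a strict subset of skip), and exhaustive skip enumeration at 40
helices (~3.5·10⁸ states) is beyond desk scale — the zipper/skip
agreement check runs at 10 repeats (20 helices, 23 184 states, exact).

A repeat-level lattice (one two-state unit per repeat, 34 residues and
one whole repeat of arc per unit) is selected by passing `RepeatParams`
to the engine; it implements the homopolymer-repeat variant and is used
for the stiff-apparatus simulation and the chemical-denaturation model.

## Observables

- **Equilibrium FDC**: Boltzmann average of per-configuration balanced
  forces on a separation grid (default 0.25 nm). The derivative of
  −kT·ln Z w.r.t. separation is implemented as a cross-check; the two
  routes agree to < 0.05 pN, and ∫F dd equals the free-energy difference
  to 10⁻³ relative (thermodynamic identity).
- **Plateau window**: for model curves, the region where unfolding is in
  progress (mean folded helices ≤ 2N−1) but the terminal dip has not
  been reached; the dip's landmark is P(fully unfolded) = 50 %, the same
  point that defines the seed statistic. Oscillation counting uses the
  tighter P < 5 % bound so the dip does not distort the detrend. For
  measured curves, the window is the longest run with smoothed local
  slope < 0.02 pN/nm (15 nm smoothing, threshold relaxed stepwise if no
  ≥ 25 nm run exists, points below 2 pN excluded as tether slack).
- **Plateau force**: centre of a single Gaussian fitted to the 0.1 pN
  force histogram of the plateau window.
- **Seed size**: bisection (0.01 nm) for the separation where the fully
  unfolded state reaches 50 % population, then the expectation of the
  folded-helix count over all other configurations.
- **Unfolding work W_F**: −∫(F_data − F_always-unfolded-model) dd over
  the curve's span; the handle/trap contribution cancels and the
  protein's folding work (negative when stable) remains. The baseline
  choice is validated against a partition-function free-energy-difference
  oracle to 5 %.
- **Contour-length gain**: composite branch fits (handle fixed; chain
  contour + rigid offset free before the transition, contour free after
  it). Pre-branch points above 4 pN are excluded because the terminal
  helices already unzip gradually below the plateau and would leak
  protein contour into the folded-branch fit.

## Synthetic data

The generator emulates equilibrium stretch/relax cycles: the model mean
force plus Gaussian noise whose variance is the instrument floor
(default 0.3 pN) plus, optionally, the equilibrium force variance of the
configuration mixture — large on plateau and dip where states of
different extension exchange, near zero on the WLC branches — plus
per-cycle rigid force/distance offsets (0.2 pN, 1 nm) that mimic
calibration drift and exist to exercise the alignment stage. All
randomness flows from one seeded generator. Denaturation curves come
from the repeat-level homopolymer chain with ΔG_unit(D) = ΔG_unit(water)
+ m·D (m ≥ 0: denaturant destabilises) through per-curve linear
baselines.

What the generator does **not** emulate: time-resolved hopping, drift,
bead dynamics, tether rupture, loading-rate-dependent hysteresis, or any
deviation of the real instrument from the model family being fitted.
Passing round-trip tests therefore demonstrates estimator correctness
and identifiability under the stated noise, not robustness to
model misspecification in real data.

## Fitting

FDC fits are bounded trust-region least squares over the cached forward
model (the state geometry and the mechanical tables do not depend on the
energies, so each iteration only re-weights configurations). Residuals
are weighted by the per-bin standard errors that cycle averaging
records; the noise is strongly heteroscedastic and unweighted fits let
flexible variants harvest the dip. Standard errors come from the
residual-scaled curvature at the optimum; a 200-draw seeded residual
bootstrap is available. The helix-level objective has the well-known
compensation ridge (destabilising one term while stabilising another
changes the curve little), so the variant-comparison suite uses nested
warm starts (repeat-level fit → homopolymer → heteropolymer → nnn) and a
back-projection refit whenever a sub-model fits worse than its
super-model's restriction; models are ranked by AIC = n·ln(RSS/n) + 2k.
Geometry stays fixed during energy fits (identifiability). Both free and
symmetry-constrained (repeat-level) parameterisations are exposed.

The denaturation fit is global across array lengths (≥ 2 required —
with one length ΔG_unit and ΔG_nn are degenerate), sharing
ΔG_unit(water), m and ΔG_nn with per-curve baselines.

## Problem sizes and calibration studies

The replicate studies use 5-repeat arrays, 30 cycles per replicate at
0.5 nm grid spacing and 20 seeded replicates; parameter recovery is
checked as 2σ coverage (≥ 90 %) and model selection as the AIC rank of
the generating variant. These sizes keep the default test suite around a
minute on one CPU. The recovery grid spans ΔG_unit ∈ [−3, 2] and
ΔG_nn ∈ [−14, −9] kT. The stiff-apparatus simulation uses a 5-repeat
homopolymer test protein (ΔG_unit = −10, ΔG_nn = −6 kT, straight-rod
geometry) whose rips are individually resolvable; stiffening all
compliant elements ×100 converts the flat plateau into five sawtooth
peaks, reproducing the AFM-like phenomenology.

## Known limitations

- The folded remainder is a rigid chord along the pulling axis; no
  orientational averaging or elastic deformation of the superhelix.
- Equilibrium only: no kinetics, no hysteresis at high pulling speed.
- The helix-level decomposition parameters (bias, interface split) are
  plausibility choices, not fitted structural quantities; repeat-level
  energies are invariant to them by construction.
- Plateau-force absolute values depend on the handle/linker stand-in
  constants at the few-percent level.
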