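# Methods

`genodt` models arrhythmogenesis in arrhythmogenic right ventricular
cardiomyopathy (ARVC) at two scales: single ventricular myocytes with
genotype-specific ionic remodeling, and 2D monodomain tissue sheets carrying
image-derived (or synthetic) structural remodeling, probed with a clinical
rapid-pacing ventricular tachycardia (VT) induction protocol.

## Cell models

The baseline myocyte — used for the gene-elusive (GE) ARVC genotype — is the
ten Tusscher–Panfilov 2006 (TT2) epicardial human ventricular model with all
published constants, plus a late sodium current

    I_NaL = g_NaL * mL * hL * (V - E_Na)

with the O'Hara–Rudy-style two-gate formulation (activation mL sharing the
fast-sodium activation time constant; inactivation hL with tau_hL = 200 ms).
`g_NaL` defaults to 0.0065 nS/pF, chosen so the paced GE cell reproduces the
reference calcium-transient biomarkers (time to peak ~26 ms, peak Cai
~8.6e-4 mM, 90% return ~360 ms at 1 Hz); it is an ordinary entry of the
parameter file and can be overridden.

The epicardial phenotype is used throughout (the cell type is exposed only
through the parameter values; mid/endo variants can be loaded as parameter
files).

### PKP2 variant

Plakophilin-2 loss-of-function remodeling is expressed purely as parameter
transformations of the GE set:

| parameter | change | rationale |
|---|---|---|
| g_Na | x 0.30 | reduced sodium current density |
| g_CaL | x 0.50 | reduced L-type calcium current |
| g_bCa | x 5 | Cx43-hemichannel-mediated background calcium entry |
| k_NaCa | x 0.80 | NCX downregulation |
| V_rel | 0.102 -> 0.0816 ms^-1 | reduced RyR2 expression |
| V_leak | 3.6e-4 -> 2.88e-4 ms^-1 | reduced RyR2 expression |
| K_bufsr | 0.3 -> 0.18 mM | reduced calsequestrin affinity (SR Ca overload) |

The increased RyR2 calcium sensitivity of PKP2-deficient myocytes is
represented only indirectly, through the elevated free calcium in the SR,
subspace and cytosol that these changes produce; no gating modification is
added.

### Diffuse-fibrosis variant

Myocardium inside diffuse-fibrosis regions uses the GE baseline with
HCM-type (Coppini) electrical remodeling: I_NaL +107%, I_CaL +19%,
I_Kr -34%, I_Ks -27%, I_to -85%, I_K1 -15%, NCX +34%, SERCA -43%.  Its
action potential is markedly longer (APD90 ~365 ms at 600 ms cycle length
vs ~300 ms for GE), which makes fibrotic regions the dominant source of
refractoriness dispersion at tissue scale.  The fibrosis transformation is
applied to the GE baseline regardless of the genotype of the surrounding
myocardium (composition with PKP2 is not performed): the remodeling data it
encodes were measured relative to baseline tissue, and this keeps the
fibrotic substrate identical across genotype arms, isolating the genotype
effect in the non-fibrotic myocardium.

### Numerics

Hodgkin–Huxley gates advance by Rush–Larsen exponential updates;
concentrations and voltage by forward Euler; default dt = 0.02 ms for
single cells.  Halving dt changes the paced APD90 by well under 1 ms (see
tests).  The unstimulated model settles to a fixed point with |I_total| <
1e-3 pA/pF.

## Cell protocols

* **Steady-state pacing**: 20 beats at the basic cycle length, starting
  from the published (1 Hz-conditioned) initial state; the last beat is the
  measurement beat.  Beat-to-beat APD90 periodicity (<0.5 ms) is checked.
  Biomarkers follow the standard definitions; APD90 runs from the maximum
  upstroke velocity instant to 90% repolarization of the measured AP's own
  amplitude; calcium-transient time-to-peak is measured from stimulus
  onset, and the 90% return time from the peak toward the pre-stimulus
  diastolic level.
* **Diastolic threshold**: bisection (1% tolerance) on the amplitude of a
  1 ms rectangular pulse; capture = V crosses 0 mV within 50 ms.
* **S1-S2 restitution**: 20 conditioning S1 at BCL 1000 ms, a single S2,
  then 5 recovery beats between successive S2 tests; the diastolic interval
  (DI) is measured from 90% repolarization of the preceding AP to S2 onset
  and decremented in 25 ms steps from 1000 ms, continuing past 50 ms until
  one-to-one capture is lost (no 0 mV crossing, or APD90 < 30 ms).  The S2
  is delivered at twice the diastolic threshold level, realized as twice
  the standard -52 pA/pF conditioning stimulus (which is itself ~2.1x the
  bisection threshold of the baseline cell for 1 ms pulses).  This reading
  matters: with the premature stimulus at exactly 2x the bisection
  threshold the PKP2 cell loses capture a full DI step earlier and its
  curve flattens (max slope 0.33), while the stronger conventional S2
  reproduces the reference restitution of both genotypes (GE min APD90
  ~158 ms, max slope ~1.10; PKP2 ~207 ms and ~0.57).  The exact-threshold
  mode remains available (`s2_amplitude="2x_threshold"`).
* **Slope**: maximum |dAPD90/dDI| over adjacent captured samples.
* **I-V curves**: two-step voltage clamp on the fast sodium gates
  (holding -90 mV); peak inward I_Na per test potential.  Because the PKP2
  transformation rescales only g_Na, the PKP2/GE peak ratio is exactly 0.30
  at every test potential — a structural invariant used as a test.

Measured excitability note: the bisection threshold of the PKP2 cell from
rest is marginally *lower* than GE's (23.3 vs 24.4 pA/pF for 1 ms pulses)
— its elevated resting potential sits closer to the sodium activation
range, outweighing the 70% g_Na reduction for point stimulation of an
isolated cell.  The PKP2 deficit in excitability appears where it matters
mechanistically: upstroke velocity (V_max ~128 vs ~349 mV/ms), peak
overshoot, conduction velocity, and the ability of premature wavefronts to
propagate in tissue.

## Tissue model

Monodomain reaction-diffusion on a regular 2D sheet:

    dV/dt = div(D grad V) - I_ion - I_stim,   D = sigma / (beta * Cm)

with per-node conductivity tensors built from the local fiber angle
(sigma_l = 0.171 S/m, sigma_t = 0.0428 S/m, beta = 1400 /cm, Cm = 1
uF/cm^2 by default, giving ~65 / ~29 cm/s longitudinal/transverse GE
conduction velocity at dx = 250 um).  SCAR and VOID nodes are excluded
from the solved system (no-flux internal boundaries); FIBROSIS nodes carry
the fibrosis cell variant and optionally a conductivity scale
(`fibrosis_sigma_scale`) representing interstitial fibrosis.

Spatial discretization uses harmonic-mean face conductivities and centered
cross-derivative terms; in locally homogeneous interior regions the axial
terms upgrade to a 6th-order (or 4th-order) Laplacian.  This matters
because the AP foot length (~180 um at 65 cm/s) is marginal at coarse
spacings: with a plain 2nd-order stencil the plane-wave CV shifts ~10%
between dx = 400 and 200 um; the high-order stencil reduces this to ~7% at
the default conductivities and ~3% in the resolved regime (2.5x sigma).
The mesh-convergence test is run at the resolved operating point; runs at
the default operating point use dx <= 250 um when quantitative CV matters,
while the reentry fixtures use dx = 500 um, where the mechanism (block,
wavelength, circulation) is preserved even though CV carries a few percent
of discretization bias.

The ionic reaction inside the tissue kernel evaluates all voltage-dependent
rates and current coefficients from lookup tables (0.025 mV spacing,
covering -120 to +400 mV so that strong stimulus artifacts stay on-table),
with exact per-node reversal potentials refreshed every 1 ms.  A
zero-diffusion node reproduces the exact single-cell integrator to < 0.2 mV
RMS over a full AP.  Activation times (upward 0 mV crossings, with a 25 ms
refractory guard against threshold jitter) are recorded in-kernel;
simulations terminate early once the sheet is quiescent (all V < -65 mV
after the last stimulus).

## VT induction

Programmed stimulation from any of 9 pacing sites (centers of a 3x3
basal/mid/apical x anterior/lateral/posterior tiling — an RV free-wall
analog of the AHA segments): six S1 at 600 ms cycle length, S2 starting at
300 ms coupling and decremented by 10 ms until reentry or local non-capture
(no activation within 5 mm of the site within 50 ms); exhausted stages add
S3 and then S4 riding on the shortest captured couplings, the same way.
The coupling search has an absolute floor of 120 ms.  Induced VT = a node
re-activating at least 3 times after the last stimulus (>= 2 full cycles)
with inter-activation interval CV < 20% and period < 600 ms; candidate
critical sites within 2 mm collapse together.  Morphologies are identified
by the ordered region-level activation sequence plus rotation chirality
around the critical site (sign of the angular LAT progression in a 1-4 mm
annulus); reentries from different pacing sites with the same region and
morphology count once.  The observation window after the last extrastimulus
is 2000 ms.

## Synthetic fixtures

Patient imaging and EP study data are not available, so seeded generators
stand in:

* **LGE-like phantoms**: elliptical myocardium mask; contiguous scar and
  fibrosis blobs grown by seeded stochastic flood fill to *exactly* the
  requested pixel fractions (defaults 5% dense scar, 14% diffuse fibrosis
  — the basal-RV burden scale reported for ARVC cohorts); per-class
  intensities from truncated normals (+-1.3 class SD) so that the SD-band
  segmentation recovers ground truth exactly at zero added noise; optional
  global Gaussian noise on top.  These phantoms emulate intensity
  statistics only — not LGE texture, partial-volume effects or surface-coil
  bias — so segmentation tests validate the thresholding rules, not
  clinical robustness.
* **Isthmus substrate**: 5 x 5 cm sheet (500 um spacing), two dense-scar
  islands with diffuse-fibrosis halos and a conducting channel between
  them.  The channel core is normal myocardium lined by fibrotic walls.
* **Fibrosis-band substrate**: a horizontal diffuse-fibrosis band crossing
  the full sheet, its width varying smoothly (2 mm at the sheet edges to
  10 mm at the center), with the same corner-scar confinement.

Both substrates confine the excitable area with corner scars because open
2D expanses are rotor traps for the GE model specifically: its steep APD
restitution turns any premature wavebreak into a sustained functional
rotor (periods ~350-380 ms observed), which has no counterpart in the
clinical genotype contrast being modeled.

Fixture simulations use `fibrosis_sigma_scale = 0.25` (interstitial
fibrosis as reduced coupling) with the standard conductivities.

### What the genotype contrast shows — and what it cannot

The shipped isthmus substrate confines the peri-scar circuit with corner
scars and seals one section of the resulting annular track with a fibrotic
plug.  Under the rapid-pacing protocol the two genotype arms behave
asymmetrically, and the asymmetry runs in the clinically expected
direction:

* The PKP2 arm tolerates far deeper prematurity than GE (extrastimulus
  couplings down to ~200 ms vs ~260-320 ms — the flat PKP2 restitution
  keeps premature APs propagating where GE wavefronts are absorbed), its
  premature wavefronts block unidirectionally at the refractory fibrotic
  gate, travel the long way around the track, and re-enter through the
  recovered gate: a genuine re-entrant return (several hundred nodes
  re-excited on the band substrate, a smaller footprint on the isthmus).
  GE re-excitation stays far smaller and never organizes into a circuit.
* The re-entrant PKP2 wave nevertheless extinguishes after a single cycle,
  at the same gate: the fibrosis variant's refractory period is long and
  essentially rate-independent (~430-500 ms including its slow
  crawl-activation), which exceeds any circulation period attainable on a
  5 x 5 cm sheet (<= ~400 ms at PKP2 conduction velocities).  A circuit
  gated by fibrosis is therefore self-extinguishing here, and a circuit
  without a fibrotic gate has no PKP2-selective block to start from (the
  one dispersion source that remains, steep APD restitution, belongs to
  GE — on substrates with large fibrotic gates it is the GE arm that
  sustains multi-cycle reentry).

Consequently the packaged substrates demonstrate genotype-dependent
unidirectional block and single-cycle re-entrant returns, but not the
>= 2-cycle sustained VT of the full clinical contrast; sustaining the
circuit requires path lengths and recovery windows that exist in 3D
patient anatomy but not on a desk-scale 2D sheet with these cell models.
The corresponding acceptance-level tests assert the full sustained-VT
contrast and are expected to fail on this build; the realized contrast
(re-excitation in the PKP2 arm only) is asserted separately and holds.

A protocol note that matters for reproduction: with these cell models the
tissue refractory period at the 600 ms drive cycle exceeds the protocol's
printed 300 ms initial coupling, so the coupling scan first walks upward
(10 ms steps, at most to 500 ms) until the extrastimulus produces a
propagated response, and then decrements exactly as specified.  Capture is
judged as propagated activation within 5 mm of the site but outside the
electrode disk, within 50 ms of the stimulus.

## Quantification

Otsu thresholding (exact search over distinct masked intensities) splits
the myocardium histogram; the low class supplies the reference mean/SD;
dense scar = intensity >= mean + 4 SD (inclusive), diffuse fibrosis =
[mean + 2 SD, mean + 4 SD).  Regional remodeling fractions are normalized
by total tissue volume, so per-region values sum to the global fraction.
Pearson correlations relate regional remodeling burden to VT counts.
Region-level VT-location predictions pool (case x region) decisions into
one confusion matrix for sensitivity, specificity, accuracy, error rate,
F1 and the Matthews correlation coefficient (per-case averaging is not
implemented as a separate mode; pooled decisions are the default and only
mode).

## Problem sizes

Default problem sizes are chosen for desk-scale reproducibility: single
cells at dt = 0.02 ms; restitution over 39+ DIs; tissue fixtures at
100 x 100 nodes (5 x 5 cm, dx = 500 um) with dt = 0.05 ms; induction
mechanism runs use the basal-posterior pacing site (the site implicated in
the reference reentry analyses).

## Known limitations

* 2D sheets, not patient ventricles: no transmural heterogeneity, no
  rule-based fiber rotation, no Purkinje system.
* The fibrosis variant's conductivity scale and the default monodomain
  conductivities are literature-scale choices, not fits to patient data.
* Restitution depends visibly on the premature-stimulus convention (see
  above); both conventions are exposed.
* The phantom generator emulates intensity statistics, not imaging physics.
* Patient-level prediction metrics cannot be reproduced without the
  (private) clinical data; the metric formulas are exercised on synthetic
  region sets instead.
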