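# Methods

## Model and assumptions

The package treats the coronary circulation as a lumped-parameter
(Windkessel) electrical analog under the standard hydraulic/electrical
equivalences: pressure drop (dyn/cm²) ↔ voltage, flow (cm³/s) ↔ current,
viscous resistance (dyn·s/cm⁵) ↔ resistance, compliance ↔ capacitance.
Each vessel segment is a rigid Poiseuille tube, R = 8µl/(πr⁴), with its wall
compliance folded in through the cyclic-impedance magnitude
Z = 1/√((1/R)² + (2πC/T_c)²). A stenosis is not a separate object: the
segment's mean lumen radius, averaged along the lesion, carries the whole
effect through the r⁻⁴ dependence.

The analysis is **steady mean-flow over impedance magnitudes**, not
time-domain integration: element values are cyclic impedances, the network
is solved as a resistive circuit, and Kirchhoff's laws therefore hold
exactly for the reported mean flows. This matches a single-number-per-state
flow table; it does not resolve waveforms, and the literal alternative of
driving Eq.-style flow with an absolute pressure rather than a pressure
drop is rejected because it would predict nonzero flow at FFR = 1.
Poiseuille resistance assumes laminar flow in rigid, circular tubes; no
Womersley/pulsatile correction and no flow-dependent (nonlinear) stenosis
resistance are applied. Venous/ground pressure is 0.

Each artery's subtree terminates in a collection chamber: its inherent
resistance (LAD/LCX/RCA = 1671/1820/591 dyn·s/cm⁵) in parallel with a
trapped-air compliance derived from Boyle's law,
C = P₀V₀(1/P_d − 1/P_s)/(P_s − P_d) with P₀ = 760 mmHg and V₀ = 4.4·10⁴ mm³,
followed in series by the activity-state distal resistance to ground. The
chamber pair sits between the artery outlet and the distal resistor because
the physical chamber collects outflow before the adjustable catheter
resistance. Arteries with several root segments attach all roots directly
at the aortic node, in parallel.

## Compliance units

Two compliance quantities coexist and are deliberately distinct:

* **Chamber compliance** is a true volume compliance (mm³/mmHg, converted
  to cm⁵/dyn), dimensionally commensurate with 1/R in the impedance
  magnitude.
* **Vessel-wall compliance** entering a segment's impedance is the
  material's *area* compliance expressed in CGS (cm⁴/dyn; numerically the
  volume compliance of 1 cm of vessel), one quantum per segment,
  independent of segment length. This is the units convention in which the
  impedance relation is stated, and it is the only reading consistent with
  the flow magnitudes the model is meant to reproduce: summing
  area × length volume compliance along a 20–30 cm ostium-to-site path
  caps the path impedance at T_c/(2πC) ≈ 9·10³ dyn·s/cm⁵ regardless of
  stenosis severity, which would render severe lesions hydraulically
  invisible and inflate invasive-derived flows several-fold. Severe-lesion
  flows (≈0.4 cc/s at FFR 0.8 under 100 mmHg) correspond to path
  impedances of order 5·10⁴ dyn·s/cm⁵, which the area-compliance reading
  yields and the volume reading cannot.

The dimensionally consistent volume form (area compliance × length) remains
available: config `compliance_mode = "per_artery"` makes segments purely
resistive and lumps each artery's total wall volume compliance as a single
shunt across its chamber block. The default is `per_segment`.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| viscosity µ | 0.037 | poise | 3.7 cP, 40% glycerol blood analogue |
| mean aortic pressure | 133322 (=100 mmHg) | dyn/cm² | physiologic input head |
| cardiac period T_c | 0.8 | s | 75 bpm typical resting rate |
| total input flow | 8.33 | cm³/s | standard total coronary + aortic throughput |
| material area compliance | 0.0975 | mm²/mmHg | midpoint of the flexible-material range 0.075–0.120 |
| chamber inherent R | 1671/1820/591 | dyn·s/cm⁵ | measured chamber properties (LAD/LCX/RCA) |
| chamber P₀, V₀ | 760 mmHg, 4.4·10⁴ mm³ | | trapped-air reference state |
| chamber P_s, P_d | 120, 80 | mmHg | standard systole/diastole (chamber pressures not separately specified) |
| distal resistance R/E1/E2 | 250k/120k/60k | dyn·s/cm⁵ | inside the achievable 50–300k catheter range, strictly decreasing with activity; per-state values are rig-specific, so round representative values are shipped and fully overridable |

1 mmHg = 1333.22 dyn/cm² throughout.

## Solution routes and numerics

Two independent solvers cover every network. `reduce_network` performs
exact series/parallel graph reduction (merge parallel edges as harmonic
sums, eliminate internal degree-2 nodes as series sums); tree-built
networks always collapse, and a non-reducible topology falls back to the
nodal route. `nodal_solve` assembles the node-conductance system with the
source node held at the aortic pressure and ground at zero and solves it
densely (networks have tens of nodes). The two routes agree to ≤1e-9
relative on randomized trees — this is a standing test, not an assumption.
Conductance matrices are well-conditioned for physiologic element values;
degenerate user inputs (zero radius, non-positive period, systole ≤
diastole) are rejected at the element level rather than surfacing as
numerical failures.

Outlet calibration is closed-form: 1/R_out = I_target/P − 1/Z_coronary,
so the post-calibration source flow equals the target exactly (to
round-off); if the coronary tree alone would draw ≥ I_target the
calibration reports the excess instead of producing a non-physical
negative resistance.

## Flow at a measurement site

`I_W` is the solved flow through the site's own segment element. The
invasive and benchtop estimates convert a distal pressure into flow through
the **cumulative path impedance** Z_path: the summed Poiseuille resistance
of the ostium-to-site chain with the chain's accumulated wall compliance
(one material-compliance quantum per segment; zero in per-artery mode). By
construction I_B at distal pressure FFR·P_a is identically I_I at that FFR.
FFR readings ≥ 1 (possible with sensor noise) are clamped to zero flow with
a warning, since they imply no measurable gradient. The model's own FFR is
the site's downstream node pressure over the source pressure.

Note that Z_path applied to the cumulative (R, C) differs from the sum of
per-segment impedances whenever C > 0, and flow leaks into side branches
along the path; the path-impedance convention is therefore a *definition*
of the pressure-derived methods, not an identity of the network. The
synthetic ground truth (below) adopts the same convention, which is what
makes the three methods exactly consistent in the noiseless limit. The
ratio of rest to exercise site flows is *not* the FFR — both quantities
are reported so the discrepancy, which stems from the Poiseuille
resistances, stays observable.

## Synthetic cohort

`synth` generates five-patient cohorts. Per artery: a proximal trunk whose
root radius is drawn from the 3–5 mm main-vessel diameter range; for LAD
and LCX a lesion segment (radius reduced by the severity fraction, default
0.65 ± 0.04 jitter, length from the upper half of the 2–12 cm segment
range) followed by the measurement-site segment; then 2–5 bifurcations
where a daughter leaf branches off and the trunk continues, both children
tapering by the symmetric Murray factor 2^(−1/3). The RCA is generated
healthy with no site. Placing the lesion proximal to all branching mirrors
the common clinically significant phenotype and makes the site flow the
artery inflow; with severity 0.65 the ostium-to-site impedances span
roughly 1–5·10⁴ dyn·s/cm⁵ and model FFR crosses the 0.8 threshold between
rest and exercise, emulating a cohort in which most lesions are
hemodynamically significant.

Synthetic sensors are generated from the solved network: the ground-truth
distal pressure is the path-impedance-consistent P_d = P_a − I_W·Z_path
(identical to the node pressure for rigid single-path arteries), the
invasive FFR is P_d/P_a plus Gaussian noise (sd 0.03, clamped to (0, 1.2])
and the benchtop reading is P_d in mmHg plus Gaussian noise (sd 2 mmHg).
All draws come from `numpy.random.default_rng` seeded by
(seed, model index, stream), so every artifact is bit-reproducible.

What the generator does **not** emulate: real anatomy (tortuosity, lesion
eccentricity, diffuse disease), pulsatile waveforms, autoregulation,
hyperemia pharmacology, or measurement error structure beyond additive
Gaussian noise. Passing tests therefore demonstrate internal consistency of
the modelling chain and statistical machinery under controlled conditions —
not clinical accuracy on real patients.

## Design choices made where the design was open

* Pruned daughter branches: the data model keeps every listed segment;
  pruning is the user's choice upstream.
* Whether material compliance is applied per segment or lumped per artery
  is configurable (`compliance_mode`), default per segment.
* Bland-Altman grouping (all site × state points pooled vs per-model
  means) is a flag, default pooled; limits use the sample (n−1) SD.
* Per-model Pearson uses that model's six site × state flows; the cohort
  average is the arithmetic mean of per-model coefficients.
* Source flow normalization: the aortic outlet absorbs whatever share of
  the 8.33 cc/s the coronary tree does not draw; at low distal resistance
  most of the source flow is coronary. The calibration reproduces this
  normalization without asserting it is physiological.

## Problem sizes

The shipped analyses and checks use five-model cohorts (27–35 segments per
model, networks of ~40 elements), 1000 random trees of up to 30 segments
for the dual-solver cross-check, and 100 cohort seeds for the
noise-recovery statistics; each network solve is a dense linear system of a
few tens of unknowns, so the full pipeline runs in seconds.

## Known limitations

Steady magnitude analysis conflates mean and pulsatile quantities — the
compliance terms damp effective impedances but no phase information exists;
chamber compliance is constant across activity states; Poiseuille
resistance underestimates losses at severe, turbulent stenoses; the
common-chamber boundary gives all of an artery's branches a shared distal
bed, so flow splits among branches by epicardial resistance only.
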