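# Methods

## Scope and model overview

`mlrgait` simulates sagittal-plane human locomotion with the smallest
neural circuit that can start and stop gait: a two-neuron brainstem
model of the midbrain locomotor region (MLR) — pedunculopontine
nucleus (PPN) and cuneiform nucleus (CnF) — driving a 12-unit spinal
central pattern generator (CPG) and a reflexive posture controller,
coupled to a 7-link, 18-muscle musculoskeletal model. The purpose is to
study how abnormal brainstem drive during gait initiation produces
freezing of gait (FOG) and its subtypes; the package therefore also
contains a wearable-sensor-style FOG detector, a (s_PPN, s_CnF)
parameter sweep, and Ward-linkage cluster analysis with nonparametric
group statistics.

## Musculoskeletal model

Seven rigid segments (HAT = head-arms-torso, two thighs, two shanks,
two feet) form a tree rooted at the hip with 9 generalized coordinates:
hip position (x, y) and seven absolute segment angles
(counterclockwise-positive; HAT/thigh/shank from the vertical, feet
from the horizontal). Joint angles follow from segment angles: hip =
thigh − HAT (flexion positive), knee = shank − thigh (flexion negative,
range −2.8..−0.1 rad), ankle = foot − shank (dorsiflexion positive,
range −1.0..0.54 rad). Dynamics are assembled as M(q) q̈ = Q with
segment-Jacobian mass-matrix accumulation and solved by a dense 9×9
Cholesky factorization; tests verify the formulation against ballistic
center-of-mass motion, energy conservation in passive flight
(drift < 1e-6 of the initial energy per second at dt = 0.1 ms), and
vertical-impulse balance over whole strides of the walking model.

All joints are pin joints with linear viscosity (hip/knee/ankle:
1.09 / 3.17 / 0.943 N·m·s/rad). Outside their ranges the knee and ankle
receive linear elastic-damping limit torques (2.0e3 N·m/rad with
3.0e2 and 3.0e1 N·m·s/rad respectively), zero at the boundary.

Ground contact acts at a heel and a toe point per foot through
unilateral spring-dampers: vertical 2.5e4 N/m and 1.0e3 N·s/m with the
force clamped at ≥ 0 (no adhesion), horizontal 5.0e3 N/m and
1.0e2 N·s/m with the spring anchored at the touchdown x-position and
released when the vertical force vanishes (stick model). Anchors are
discrete states held fixed across the four Runge-Kutta stages of a step
and updated once per step.

Segment masses/lengths/inertias are a surrogate anthropometry for a
~70 kg, 1.7 m adult (total mass 71.4 kg) from the classic planar-gait
modelling lineage; every value is exposed in the configuration and
flagged `surrogate`.

## Muscle model

Nine muscles per leg (GM, IL, BFL, RF, BFS, VA, GC, SO, TA) follow a
three-element Hill model:

F = F_CE · k(ξ) · h(η) · α + c_PD · L̇ + k_PE (exp(15 (L − L̄)) − 1)

with k(ξ) = 0.32 + 0.71 exp(−1.112(ξ−1)) sin(3.722(ξ−0.656)) and
h(η) = 1 + tanh(3 η), ξ = L/L̄, η = L̇/V̄. The sign convention is η > 0
while lengthening, so h > 1 eccentric and the damping term resists
stretch. The raw tension can be marginally negative through the damping
term; the tendon force applied to the skeleton is clamped at ≥ 0
(muscles pull, never push).

Muscle-joint geometry uses constant moment arms:
L = L̄ − Σ_j ρ_j (θ_j − θ_ref,j), torque ρ_j F at each spanned joint
(virtual-work consistent by construction; verified numerically). The
biarticular muscles (BFL, RF, GC) span two joints. Moment arms, optimal
lengths, maximum tensions, c_PD and k_PE are surrogates from the cited
anatomical-model lineage. V̄ is set to 10 optimum lengths per second.

Activation is the motoneuron output directly; no additional
excitation-activation filter is applied because none is part of the
model definition.

The metabolic rate is a surrogate activation/shortening-heat model,
Ė = F_CE·V̄·(c_act·α + c_short·α·max(0,−η) + c_basal): nonnegative,
nondecreasing in activation, and linear in F_CE. It only enters the
gross cost of transport C = (1/TMV) ∫ Σ Ė dt used by the fitness
function, so only its scale and monotonicity matter.

## Nervous system

MLR: two leaky rate neurons with mutual rectified coupling
(w_PPN←CnF = 0.10, w_CnF←PPN = 0.01, as published) and piecewise-
constant higher-center input HC(t) = s for t ≤ 3 s and 1 afterwards.
The unprinted coefficients are calibrated so the unit-input fixed point
is exactly (1.0, 1.0): with β_CnF = 0.10 this forces β_PPN = 0.19 and
w_HC = 1.09 (two free choices removed by the calibration constraint and
one scale choice). Time constants τ_PPN = 0.5 s > τ_CnF = 0.05 s
reproduce the long-lasting PPN vs short-lasting CnF pulse response.

The MLR states are initialized at their fixed point under HC(0): the
nuclei are taken to be equilibrated to their drive before gait
initiation. This choice matters: with a rest start the 1/u_PPN posture
gain transiently saturates every muscle regardless of condition,
masking the brainstem manipulation; with the equilibrated start the
abnormal drive shapes the whole 0-3 s window (e.g. s_PPN = 0 keeps the
posture gain at its floored maximum — rigidity — for the entire
initiation phase).

CPG: 12 Matsuoka units (flexor/extensor half-center pairs for hip,
knee, ankle of each leg), τ = 0.04 s rise and τ' = 0.30 s adaptation
time constants, β = 2.5. These values put the autonomous stride period
near human cadence (~1.0 s under unit drive; roughly two steps per
second). Slower constants cap the attainable walking speed well below
normal because the body outruns the rhythm. The connection skeleton
has 9 free inhibitory magnitudes (within-pair ×3, contralateral
hip-flexor and hip-extensor coupling ×2, ipsilateral hip→knee and
knee→ankle phase couplings ×4) expanded symmetrically into the 12×12
matrix; the diagonal is zero. Tonic drive is u0 · u_CnF to every unit.
Under zero drive the network is quiescent; under constant drive every
unit shows a limit cycle whose period is independent of the starting
phase.

Motoneurons: α_m = 2/(1 + exp(0.25 (Σ_i w^α_mi y_i + P_m/u_PPN))) − 1,
clamped to [0, 1] (the muscle model declares 0 ≤ α ≤ 1 while the raw
sigmoid range is (−1, 1)). The sum over CPG outputs runs over the 12
units, routed to 18 muscles by a fixed w^α matrix (negative =
excitatory through the decreasing sigmoid; biarticular muscles receive
reduced secondary routes). Each primary route is paired with reciprocal
inhibition from the antagonist half-center unit (positive weight):
without it the rhythm can only add excitation on top of the posture
tone and can never unload a muscle the posture controller holds active
— in particular the stance plantarflexor release that initiates gait
and the swing-phase relaxation that permits long steps. u_PPN is floored at 1e-3 inside the division
only, preserving "low PPN → high muscle tone" while keeping the system
integrable at zero brainstem drive.

Sensory feedback (16 weights) and posture control (23 weights) are
mirror-symmetric linear forms over segment angles, joint angles and
body-weight-normalized vertical ground-reaction forces. Their
structural signs implement standard locomotor reflexes (load → stance
extensors, contralateral load → swing initiation, thigh position →
phase switching) and upright balance strategies (trunk-pitch error →
stance-gated antigravity muscles, joint-angle errors → restoring
muscles). The exact published forms are unavailable; these surrogates
are isolated behind two single functions so they can be replaced
without touching anything else. Both operators are exactly left/right
mirror-symmetric (verified bitwise by swap tests) and linear in their
inputs.

## Simulation

The coupled 44-state system (9 + 9 body, 2 MLR, 24 CPG) is integrated
with fixed-step classical Runge-Kutta at dt = 0.1 ms for 15 s,
recording at 100 Hz (the wearable-sensor rate the FOG detector
targets). The model falls when hip height drops below 60% of standing
or trunk pitch exceeds ±1 rad; integration stops at the fall. A run is
a pure function of its inputs (bitwise-reproducible).

Initial condition: a gait-initiation stance — upright double support
with both feet slightly behind the hip (thigh angles −0.06 and
−0.16 rad) and the trunk leaned forward (−0.08 rad), zero velocities,
CPG at rest with a 0.05 bias on the left hip-flexor unit to break
left/right symmetry, and contacts pre-loaded at their static
penetration so the model starts settled. The asymmetric stance plays
the role of the anticipatory weight shift that precedes human gait
initiation: the center of mass starts slightly ahead of the ankles, so
the backward reaction of the first leg swing does not topple the body.

"Lower-leg acceleration" is the second central difference of the shank
midpoint anteroposterior position on the 100 Hz series; "lower-leg
angular velocity" is the shank segment angular velocity.

Step events are vertical-GRF onsets: a limb must be unloaded for
≥ 50 ms and then stay loaded ≥ 50 ms (debouncing transients). Gait
metrics: D (hip AP displacement until fall or end), S (step count),
T (duration), V = D/T, C as above; C is reported missing when T or D
is zero rather than infinite.

## Optimization

49 free parameters (u0, 16 feedback, 9 CPG, 23 posture weights) are
nonnegative magnitudes — all structural signs live in the network
skeletons — with generous per-group upper bounds. They are optimized
against

J = 1.5D + 0.5S + 0.1T + P + 5 (D < 10 m);
J = 1.0D + 0.2S + P + 25/C + 20 (D ≥ 10 m), P = −2.5 on a fall

by a real-coded generational GA: tournament-2 selection, per-gene
BLX-0.5 crossover (rate 0.9), Gaussian mutation (rate 0.15-0.3, σ = 5%
of range), elitism 2, population 64. Simulation crashes score −inf and
never abort a run. The packaged normal controller was produced by this
GA in stages: posture weights first against a standing objective, then
the full 49-vector through a curriculum of walking objectives
(distance-shaped selection among non-falling gaits, with evaluations
from several initial-push conditions to select for catching steps) — a
desk-scale schedule of a few hundred generations in total rather than
the cluster-scale run this model family typically uses; the staged
seeding and curriculum substitute for the larger budget. One coupling
weight of the final vector (the hip half-center mutual inhibition) was
raised from the GA value of 0 to 0.5 so the packaged network is also
rhythmic without sensory feedback, matching the intended autonomous
behaviour of the oscillator; the walk is preserved (20.0 m in 15 s,
33 steps, 1.34 m/s, cost of transport 5.4 J kg⁻¹ m⁻¹).

The abnormal sweep evaluates 200×200 (s_PPN, s_CnF) pairs, 0.00 to 2.00
in 0.01 steps, half-open per axis so the grid has exactly 40,000 pairs
(the closed interval would give 40,401, contradicting the published
count). Each pair modifies HC only during the first 3 s. The sweep is
resumable and order-independent; per-pair failures are recorded as
falls.

## FOG detection

Freeze ratio: per 2-s window (hop 0.5 s) of mean-detrended lower-leg
AP acceleration, the one-sided periodogram power in the freeze band
(3-10 Hz) divided by the power in the locomotor band (0-3 Hz). Bands
are half-open [low, high), so the 3 Hz bin belongs to the freeze band
and the DC bin (removed by detrending anyway) to the locomotor band.
If the locomotor power is below 1e-12 the ratio is reported at the cap
(1e6) when freeze-band power exists, else 0 — an all-zero signal is
degenerate, not freezing. The per-leg ratios are combined by max
(configurable). A window is FOG-positive when the freeze ratio exceeds
1.5 AND the left/right shank angular-velocity correlation magnitude is
below 0.5; healthy alternating gait is strongly anticorrelated, so
|r| is thresholded. Consecutive positive windows (gaps ≤ 1 s bridged)
form episodes; episodes shorter than 1 s are dropped. Thresholds are
configuration values in the spirit of the open-source clinical
detector this follows, which publishes the two statistics but whose
constants are sensor- and cohort-specific.

## Cluster analysis and statistics

FOG-positive (s_PPN, s_CnF) pairs are clustered with Euclidean Ward
linkage. The agglomeration coefficient at k clusters is the Ward merge
height of the fusion producing k clusters; the stopping rule examines
the percentage increase of the coefficient when merging k → k−1: the
chosen k has the largest increase among candidates whose subsequent
increases stay below 0.7× that jump (the plateau). A profile whose
largest change is below 20% is featureless and returns k = 1 with a
warning. Ties in Ward merges are broken by lowest index (scipy's
deterministic ordering), making assignments platform-reproducible.

Group comparisons (walking distance and freeze ratio over the first
3 s) use Shapiro-Wilk normality and Levene variance gates: the
parametric path (one-way ANOVA + t-tests) only when all groups pass,
otherwise Kruskal-Wallis + Mann-Whitney U. Pairwise p-values are
Bonferroni-adjusted (min(1, p·m)); clusters with fewer than 3 members
are excluded from testing with a warning.

## Synthetic fixtures

`fixtures.synthetic_gait_signals` emulates only the features the FOG
detector consumes: anti-phase locomotor sinusoids with planted
trembling intervals built from three independent band-limited
multi-sine components, mixed so the left/right correlation equals the
requested value, plus seeded Gaussian noise. It does not emulate
gait-cycle asymmetries, harmonics, or sensor artifacts of real
accelerometry — detector tests on these fixtures demonstrate the
statistic and episode logic, not clinical performance.
`fixtures.synthetic_cluster_points` plants seeded Gaussian blobs
clipped to the [0, 2]² parameter domain. All fixtures are pure
functions of spec + seed.

## Numerical choices and limitations

- dt = 0.1 ms is required by the vertical contact damping (foot mass
  ~1 kg, c = 1e3 N·s/m gives a ~1 ms time scale); RK4 at this step
  conserves energy to ~1e-9 per second in passive flight.
- The motoneuron sigmoid argument is clamped at ±60 before
  exponentiation to avoid overflow at extreme posture gains.
- The 18-index upper bound sometimes quoted for the motoneuron sum is
  treated as a typographical artifact: the CPG has 12 outputs and the
  sum runs over them.
- Performance-critical code is compiled with numba; compiled and
  interpreted paths share one implementation (module-level njit
  functions), so unit tests exercise the same code the simulator runs.
- The model is 2-D, armless, and brainstem+spinal only; conclusions
  about balance recovery, arm swing, or cortical contributions are out
  of reach by construction.
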