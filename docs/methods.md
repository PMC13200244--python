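# Methods

`gctetra` couples a surface-hopping simulator on a model Hamiltonian of a
stacked guanine–cytosine tetramer with the trajectory-ensemble analysis used
to characterize DNA photorelaxation. The simulator is not an electronic
structure method: it is a synthetic-data generator whose trajectories carry
ground-truth logs, so every analysis stage (descriptors, classification,
proton-transfer detection, pattern statistics, kinetics) can be verified
against known conditions. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The vibronic model

The electronic basis is a set of diabatic configurations over four
nucleobase fragments (two strands × one G·C Watson–Crick pair each):

* the closed-shell ground state;
* one local excitation LE(A) per fragment A;
* charge-transfer configurations CT(A→B) for topologically allowed G→C
  pairs — Watson–Crick (interstrand), π-stacked (intrastrand), or diagonal.

Nuclear coordinates are mass-weighted harmonic modes shared by all
configurations (linear vibronic coupling, LVC):

    V_d(x) = ε_d + Σ_k κ_dk x_k + ½ Σ_k ω_k² x_k²

with a constant symmetric diabatic coupling matrix. Because the harmonic
part is shared, energy gaps are affine in the coordinates, adiabatic
gradients are exact Hellmann–Feynman sums, and the model has no
electronic-structure cost. Units are eV / fs / Å with ħ = 0.6582 eV·fs;
mass-weighted coordinates absorb the mass, so the kinetic energy is p²/2.

The mode set of the default models: one "driver" mode per strand
(ω = 0.15 rad/fs; the LE minima are displaced by 4 units along the
own-strand driver, so the bright band breathes), one bath mode
(ω = 0.15), and one proton coordinate per Watson–Crick hydrogen bond
(ω ≈ 0.30–0.34; six bonds: the central N–N, the amino→carbonyl N–O and the
reverse C→G bond for each pair). Proton coordinates are effective
reaction coordinates, not literal N–H stretches: their frequencies are
chosen so the transfer sweep takes a few fs and the Wigner spread stays
well below the declared crossing points.

### Geometry emission

Each hydrogen bond is emitted as a collinear donor/H/acceptor atom triplet
with donor–acceptor distance 2.9 Å and the donor–H distance an affine
function of the bond's proton coordinate. The affine gain is fixed so the
H–acceptor distance reaches 1.1 Å exactly when the coordinate passes the
bond's declared crossing point `r_star`. Detection in the analysis layer
therefore operates on plain geometric distances (the X–H ≤ 1.1 Å
criterion), while the generator logs the coordinate-space crossings as
ground truth; the two views agree by construction, which is what the
permanence-recovery tests check.

## The surface-hopping engine

Decoherence-corrected fewest-switches surface hopping:

* nuclei: velocity-Verlet on the active adiabatic surface, classical step
  0.5 fs (the study protocol);
* electronic amplitudes (excited states only): fixed-step RK4 at the
  0.025 fs quantum substep with linearly interpolated energies and
  couplings;
* nonadiabatic couplings: the gap-curvature (Baeck–An) estimate
  σ = ½·√(Δ̈/Δ) from the three most recent classical steps, clamped to 0
  when the curvature-to-gap ratio is nonpositive. The sign gauge takes the
  upper triangle nonnegative; the convention is validated against the
  Landau–Zener closed form (2000-trajectory single-passage test);
* hops: fewest-switches probabilities accumulated over the substeps of one
  classical step, one decision per classical step; accepted hops rescale
  the momentum along the unit vector of the adiabatic gradient difference
  so total energy is conserved exactly (checked to 1e-10 eV); frustrated
  hops keep the momentum by default (reject-and-invert is a config
  option);
* decoherence: energy-based damping exp(−dt/τ) with
  τ = ħ/|ΔE|·(1 + α/E_kin), α = 0.1 hartree, applied once per classical
  step, followed by an exact renormalization of the active amplitude;
* termination: when the active–ground gap falls below 0.2 eV, or when the
  active surface has dived through the (uncoupled) ground crossing within
  a single step and is majority ground-configuration. The termination time
  is taken as the ground-state arrival time;
* back-hopping among excited states is allowed; hops into the ground state
  never occur (the quantum subsystem spans the excited states only).

Two implementation details matter for robustness. First, when the
excited-block diabatic coupling matrix is identically zero, the Baeck–An
estimate is suppressed: the true nonadiabatic coupling vanishes by
symmetry, while the gap-curvature formula would fabricate couplings from
any oscillating gap. This makes the zero-coupling limit exact (zero hops,
total-energy drift below 1e-6 eV). Second, excited states are tracked by
eigenvector overlap between consecutive steps: at unresolved (trivial)
crossings the energy-ordered index would switch surfaces and kick the
integrator, so amplitudes, gap histories and the active index follow the
overlap assignment instead, and index reassignments are logged separately
from hops.

Numerical tolerances: quantum norm is conserved to 1e-8 per step (exact
after the decoherence rescale); total energy between hops is conserved to
the sub-µeV level on smooth stretches, but individual passages through
sharp avoided crossings at the 0.5 fs step leave kicks of up to ~0.1 eV —
an integrator guard aborts a trajectory only if the accumulated drift
between hops exceeds 1.5 eV.

## Initial conditions

Ground-state harmonic Wigner sampling: x ~ N(0, √(ħ/2ω)),
p ~ N(0, √(ħω/2)) per mode. At each sampled geometry the model is
diagonalized; each excited state's oscillator-strength proxy is the
strength-weighted composition of its eigenvector (LE configurations are
bright, CT configurations dark). Initial states are assigned within the
excitation window (4.9 ± 0.5 eV by default) with probability proportional
to the strength proxy; samples with no in-window bright state are dropped.

## The default study-condition ensembles

`gc_tetramer_model(tag)` emulates one sequence each at the study scale
(104 nonalternating / 100 alternating trajectories in the acceptance run):

* a bright band of four coupled LEs (couplings 0.045 eV, offsets
  4.82–5.00 eV) that is delocalized at excitation (PR ≈ 2–3: local
  excitation / exciton / excimer character early);
* inert CT precursor states, one per WC pair, 0.7 eV below the band:
  charge-separated but without proton stabilization. Their strongly
  contrasting driver slope makes the band cross them often, so the
  populated state acquires CT > 0.8 and PR < 1.5 within a few tens of fs
  and stays there — the early-localization regime;
* a manifold of reactive CT channels at a common deeper offset Δ0, each
  stabilized along the proton coordinates of a designated WC pair
  (strong slope 0.35 eV/unit on the primary bond, 0.15 on the secondary
  N–O bond, 0.02 on the spectator). Stochastic capture into a reactive
  channel is the rate-limiting step; the captured channel then slides down
  the proton coordinate, crosses the 1.1 Å criterion, and closes the gap
  to the ground state within a few fs, so proton transfer and decay stay
  tightly correlated (the PT-vs-final-time diagonal).

The decay constant is controlled by the common reactive offset through a
frozen design table (offset → measured mean arrival time, log-linear
interpolation), calibrated per sequence on 800-trajectory design runs:
Δ0 = 1.49 eV (nonalternating, 64 fs) and 2.81 eV (alternating, 141 fs).
Arrival-time distributions are approximately exponential (mean/median
≈ 1.2–1.4 versus 1.44 for an exact exponential).

The joint proton/electron-transfer pattern mixture is set by channel
multiplicity: nonalternating 6 WC : 1 diagonal acceptor-shared : 1
diagonal donor-shared; alternating 5 WC : 3 intrastrand acceptor-shared :
1 intrastrand donor-shared. Capture rates are close to uniform per
channel, but the event-time electron/hole localization is read off the
populated state at the moment of the proton crossing, and the captured
channel can exchange identity with neighbouring CT surfaces during the
final dive — so the *measured* pattern fractions are a smeared version of
the multiplicities (paired hydrogen-atom transfer remains dominant in the
nonalternating stack and the acceptor-shared channel is strongest among
the intrastrand routes of the alternating one, but with 10–20-point
shifts). The clean mixture-recovery tests therefore use
`run_mixture_ensemble`, which draws one single-route model per trajectory
from configured multinomial weights; the recovered fractions match the
configuration within binomial error.

Two secondary dials are fixed per sequence: the N–O bond crossing point
(3.7 / 3.6 units), which sets the share of trajectories with a secondary
N–O transfer, and the primary-bond crossing fraction (0.70 / 0.62 of the
gap-closure coordinate), which sets the small share of trajectories that
reach the ground state without any permanent proton transfer.

## What the generator does and does not emulate

Emulated: the excitation-window selection over a bright ππ* band;
delocalized early character drifting to localized CT; exponential
population decay with sequence-dependent time constants; dominant central
N–N transfer with secondary N–O transfer and (configurably rare) reverse
C→G transfer; back-transfers through the custody state machine; the three
joint proton/electron-transfer patterns with their strand characters; a
small share of decays without permanent transfer.

Not emulated: real tetramer energetics and geometry (atom positions are
schematic bond triplets), anharmonicity and intramolecular vibrational
redistribution, ring-puckering and other monomer-like decay channels,
solvent and backbone effects, double tautomerization after return to the
ground state. Passing tests demonstrate that the analysis stack measures
what the generator did — not that the generator reproduces the real
photochemistry.

## Analysis conventions

* Descriptors: CT is the total off-diagonal weight of the normalized
  fragment Ω matrix; PR is the mean of hole and electron participation
  ratios; POS uses 1-based declared topology order; PR_NTO = (Σλ)²/Σλ²;
  Z_HE = 2^S with S the Shannon entropy (bits) of the normalized weights.
  All are invariant under positive rescaling of Ω. Note the ordering
  PR_NTO ≤ Z_HE (Rényi monotonicity).
* Classification thresholds: CT 0.2/0.8, PR 1.25/1.75, PR_NTO 1.25;
  boundary points resolve by the ≤/< structure of the rule; missing
  PR_NTO falls back on PR alone with a warning.
* Timelines sample every 10 fs up to 50 fs, every 50 fs after, plus the
  final step, using the nearest recorded step.
* PT events: first-crossing times (no dwell requirement); hydrogen custody
  alternates sides, so back-transfers are explicit reverse events; an
  event is permanent iff its target side still satisfies the 1.1 Å
  criterion at the final frame, and a trajectory has a permanent PT iff a
  *forward* event is permanent. Percentages are per trajectory for bond
  types and per event for patterns (binomial standard errors,
  100·√(p(1−p)/n)).
* Decay constants: censored maximum likelihood by default
  (τ̂ = Σ all observed times / number of uncensored arrivals, standard
  error τ̂/√n), with a least-squares fit of the S0 occupation against
  1 − exp(−(t−t0)/τ) as the cross-check (t0 opt-in, default 0).

## Problem sizes

The test suite runs two-state Landau–Zener ensembles of 2000 trajectories,
a 500-trajectory constant-hazard recovery at τ = 100 fs, a 250-trajectory
configured-mixture ensemble and assorted small ensembles; the acceptance
script propagates 104 + 100 trajectories at the default conditions. All
together a few minutes on one CPU.
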