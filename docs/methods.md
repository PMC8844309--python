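# Methods

## Probe-sphere pathway profiling

The profiler treats the channel as a set of hard spheres (atom centers
plus van der Waals radii) and reports, at each station *s* along a path
direction, the radius of the largest probe sphere whose center lies in the
plane through *s* normal to the path:

    f(p) = min_i ( |p − x_i| − r_i ),      radius(s) = max_p f(p),

subject to |p − center(s−1)| ≤ tether in-plane (default: one step). The
tether is the continuity constraint that keeps the walk a pathway rather
than a set of independent largest-empty-circle problems; it also bounds
|center(i+1) − center(i)| by √2·step.

The maximisation is a multi-start Nelder–Mead search in the 2-D plane
(k = 8 starts: the previous center plus Gaussian jitter of scale tether/2,
drawn from a `numpy` Generator seeded by `rng_seed`). Published
pathway-finding tools use simulated annealing here; a seeded multi-start
local search makes profiles bit-reproducible, which matters more for a
tested pipeline than annealing's asymptotic guarantees. Clearance
evaluations use a KD-tree to restrict the atom set per station. The walk
proceeds outward from the seed station in both directions and stops in a
direction when the probe exceeds the escape radius (default 12 Å); that
station is flagged `open` (open to bulk) and excluded from minima.

Conventions. For pore profiles, *s* is the signed axial coordinate along
`ChannelAxis.direction` (+ = extracellular) from the axis origin; the seed
is the caller's probe start, conventionally the pore-gate ring center
(computed with `residue_center`). For portals, the seed is the centroid of
the portal-lining residues and the direction is the horizontal unit vector
from the seed toward the axis, so *s* > 0 runs inward and *s* < 0 outward.
Defaults: step 0.25 Å, escape radius 12 Å.

The symmetry axis is estimated from a ring selection as the eigenvector of
smallest dispersion of the ring-point covariance (the ring normal); the
sign is fixed by an extracellular reference selection, since nothing else
in a coordinate file says which way is out.

Accuracy. On stacked-ring solids the profiler matches the analytic
clearance to machine precision at the stations of exact rings and to
better than h²/8R between rings spaced h apart (verified against a dense
3-D grid-search oracle on hourglass solids, tolerance 0.1 Å). A useful
fact exploited by the tests: on the axis of an azimuthally uniform ring,
clearance is independent of how many atoms discretise the ring, so
profiler error against the ring analytic is zero at any azimuthal density;
discretisation error enters only through ring spacing (and through rim
granularity for portal holes).

## Hydrophobic-gating heuristic

Full channel-annotation machinery estimates a water free-energy profile;
here the published heuristic is deliberately simplified to a two-threshold
rule. Per station, hydrophobicity is the mean Kyte–Doolittle hydropathy
(hydrophobic > 0) over residues with any atom within `contact_cutoff`
(default 6 Å) of the probe center; stations with no lining residue are
marked undefined, not interpolated. The profile's `barrier_flag` is set
iff some station is simultaneously narrow (radius < r_wet, default 3.5 Å —
about the radius below which an apolar pore may dewet) and apolar
(hydrophobicity > h_crit, default 0). Narrow-but-polar and
wide-but-apolar pores both pass, which is the behaviour the wetting
simulations of MscS-like channels show. This flag is a screen, not an
energy: it cannot quantify barrier heights and ignores conformational
response.

## Compartments and crossing events

The channel geometry is distance-based: a cylinder of radius
`cylinder_radius` about the axis split at z boundaries (cage bottom, pore
bottom, pore top), portal annuli (radial × axial windows), and an
extracellular half-space. Boundary ties resolve PORE > CAGE > PORTAL >
bulk, so labels are deterministic. A crossing event is a maximal run in
which an ion visits PORTAL, later PORE, and then reaches the extracellular
bulk with no intervening return to the cytoplasmic bulk; the cytoplasmic
bulk resets the state machine, partial passages produce nothing. Transit
time is portal entry to bulk exit. The detector is closed in tests against
a regular-expression oracle on label strings and against the Brownian
generator's own passage log, exactly.

Conductance follows G = Q/(t·V) with Q = n_events × charge; the result is
reported as a magnitude in pS. The estimator is exact arithmetic — all
sampling error lives in the event count.

z-tracks unwrap periodic boxes by minimal-image per-step displacement
before projecting on the axis, preventing spurious crossings. Contact
ladders record the first frame at which any side-chain nitrogen of each
selected basic residue (NZ/NH1/NH2/NE by default) comes within `cutoff`
(default 4 Å — a typical Cl⁻–amine contact distance) of the ion;
`unidirectional` is true iff after first contact with the acceptor residue
of the handover pair the donor is never re-contacted within the event. χ1
is the N–CA–CB–CG dihedral in (−180°, 180°] with bins trans
[120°, 180°] ∪ (−180°, −120°), gauche− [−120°, 0°), gauche+ [0°, 120°);
the dihedral convention is verified against an independent implementation.

## GHK permeability

With P_Na ≡ 1 and r = P_Cl/P_Na,

    Erev = (RT/F) · ln[(Na_o + r·Cl_i)/(Na_i + r·Cl_o)],

and the inverse r = (Na_o − e^x·Na_i)/(e^x·Cl_o − Cl_i), x = Erev·F/RT,
which round-trips to 1e-9 relative. Feasible Erev lies strictly between
the Na⁺ and Cl⁻ Nernst potentials (open interval — the limits correspond
to r → 0 and r → ∞); symmetric ionic products make the inversion
degenerate and raise. Temperature defaults to 298.15 K (RT/F = 25.693 mV)
because recordings were at room temperature; sucrose and HEPES are treated
as impermeant and do not enter the equation. Liquid-junction potentials
are not modelled; callers doing selectivity work can offset Erev before
inversion.

## Sweep analysis

Leak subtraction removes the pre-stimulus baseline mean (or a fitted line
in `linear` mode) and is idempotent. Amplitude histograms are fitted by
least squares on binned counts (bin width 0.2 pA) with a Gaussian
mixture — mirroring trace-histogram practice rather than per-sample EM —
with component means initialised at smoothed histogram peaks ranked by
prominence; discrete traces whose mass occupies at most n_components bins
short-circuit to exact per-bin means. The single-channel amplitude is the
separation of the two heaviest components. Degenerate fits (single level,
missing peaks, non-convergence) are flagged, not silently returned.

Slope conductance is ordinary least squares of amplitude (pA) on holding
potential (mV), scaled ×1000 to pS, with the zero-current intercept
reported as Erev; it is checked against the normal-equations closed form.
Deactivation fits I(t) = A·exp(−(t − t_stim_end)/τ) + baseline by
nonlinear least squares with τ initialised at the 1/e crossing.
Single-exponential is the default model; the reported biological contrast
(fast wild-type vs ~40-fold slower salt-bridge mutants) is a ratio of
single-exponential τ values. Currents follow the amplifier convention
that inward current at negative potential is negative.

## Synthetic generators — what they emulate and what they do not

Toy solids are jitter-free pseudo-atom rings (one residue per ring, so
hydropathy profiling sees a chosen lining), with portal holes cut by atom
omission. They provide analytic clearance ground truth; they have no side
chains, no thermal disorder, and axisymmetric geometry, so passing
profiler tests demonstrates geometric correctness, not robustness to real
protein surface roughness.

Brownian ions follow overdamped Langevin steps Δx = v·dt·ẑ + N(0, 2D·dt),
with drift v = μqV/L from a uniform potential drop V across the channel
span L, μ = D/kT (Einstein), inside the channel span only (a
`drift_everywhere` switch exists for ballistic checks). Defaults are the
driven-permeation regime the analyses target: V = −425 mV, monovalent
anions, D = 203 Å²/ns
(bulk chloride, 2.03e-9 m²/s), dt = 2 ps, 100 ns, and 85 ions ≈ 0.5 M in
the box volume. Walls are an analytic solid (membrane slab pierced by the
pore; cytoplasmic cage with either side-wall portal windows or, in
`axial` mode, a central floor aperture for which strong-drift flux has a
closed form); moves ending inside the solid are rejected (approximate
reflection), and ions leaving the top are reinjected into the bottom
reservoir so the ion count is constant. The passage log is computed by the
generator's own labelling code, independent of the analysis module. Not
emulated: electrostatics of the cage and portal lysines (so transit-time
distributions and absolute conductances of the toy differ freely from any
real channel), explicit water, ion–ion interactions, and membrane
fluctuations. Closure tests therefore certify the event-detection
pipeline, not channel physics.

Patch sweeps are N independent two-state channels: closed→open at
`open_rate` and open→closed at `close_rate_during` while the pressure step
is on; after stimulus end reopening stops and channels close at 1/τ,
giving an ensemble-mean exponential decay. I(t) = N_open·γ·(V − E_rev)/1000
+ Gaussian noise. Defaults emulate a wild-type-like single channel:
γ = 270 pS, symmetric 150 mM NaCl (E_rev = 0), −80 mV holding, a 1 s
−70 mmHg pulse at 20 kHz, τ = 0.477 s, σ = 1 pA. No subconductance
levels, flicker block, or stretch-dependent inactivation (the modelled
channel family shows none).

## Numerical choices and problem sizes

Tolerances: profiler vs analytic ≤ 0.05 Å on toy solids; grid-search
oracle agreement ≤ 0.1 Å; C7 symmetry of portal profiles ≤ 1e-3 Å; GHK
round-trip ≤ 1e-9 relative; OLS vs normal equations ≤ 1e-10. Parameter
recovery at SNR 10 is assessed as bias of the mean over 100 seeded
replicates (γ and amplitude within 2%, τ within 5%) — a single
macroscopic sweep estimates τ with spread ≈ τ/√N_channels, so per-sweep
checks would conflate bias with sampling noise. Test simulations use
scaled-down sizes chosen for comfortable laptop runtimes (e.g. 4–30 ns of
Brownian dynamics with 25–85 ions, 20 closure seeds, 100 fit replicates);
the statistics they check are size-independent closures and biases, so the
scale-down does not weaken the claims being made.

Degenerate inputs raise typed errors rather than returning NaN: collinear
axis selections, empty profile windows, non-decaying deactivation
segments, unbracketed I–V data, symmetric-solution GHK inversion, and
unstable Brownian timesteps (rms step > aperture/4).

## Known limitations

The profiler's lateral tether can clip a pathway that genuinely jinks
faster than one step per station; widen `lateral_tether` for strongly
kinked portals. The wetting flag is a heuristic screen (see above). The
Brownian generator's rejection walls slightly under-diffuse within one
step of the solid. Deposited-structure checks (pore-gate constriction
≈ 3.5 Å, mean portal minimum ≈ 2.1 Å on the FLYC1 heptamer) run only when
the public coordinate file is present locally; the repository does not
bundle it.
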