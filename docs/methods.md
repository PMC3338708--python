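# Methods

## Model

Proteins are chains of N beads on the simple cubic lattice: consecutive
beads occupy neighboring sites (bond length = lattice spacing), all beads
occupy distinct sites, and a *non-bonded contact* is any chain-nonadjacent
pair of beads at unit distance.  Sublattice parity forces every contact to
have odd sequence separation ≥ 3.

Energetics are native-centric (Gō-type): a conformation's energy is

    E(Γ) = −ε · #(formed native contacts),

with ε = 1 in reduced units and kB = 1 throughout, so E is an integer in
[−ε·n_native, 0] and is proportional to the fraction of native contacts Q.
Non-native adjacencies carry zero energy — the potential contains only the
native-contact sum, which isolates the effect of native topology from any
sequence signal.  Chains with all native contacts formed are treated as
native; under this potential energy E = −ε·n_native is equivalent to Q = 1.

## Native structures and circular permutants

Native structures are *maximally compact* conformations: Hamiltonian paths
of an a×b×c cuboid with volume N.  Any such path has exactly
(a−1)bc + a(b−1)c + ab(c−1) − (N−1) non-bonded contacts (lattice edges
minus bonds); for 48-mers on 3×4×4 this is 57, independent of the path.

Parents are produced by simulated annealing of homopolymer collapse: from
a random coil, every non-bonded adjacency is worth −1 and the temperature
is annealed geometrically (defaults 2.0 → 0.30 over 60 stages of 2×10⁵
attempted moves) until the maximal contact count is reached; runs that
fail, or whose termini are not lattice neighbors, are retried with fresh
sub-seeds.  Termini adjacency is required so the chain closes into a
cycle: circular permutant k re-indexes the beads as (j + k) mod N, turning
the cut bond into a contact and the old terminus–terminus contact into a
bond — contact count is conserved exactly, which the family builder also
asserts by recomputation.  A box with all dimensions odd can never yield
adjacent termini (the endpoints of a Hamiltonian path on an odd-site
bipartite graph share a sublattice color), so 3×3×3 systems are supported
only as contact-counting fixtures, not as permutant families.

Contact order is reported in absolute form, CO = mean |i − j| over the
native contacts; at fixed N the relative CO differs only by the factor
1/N.  High-/low-CO parents are chosen as the CO extremes of a seeded
candidate pool (pool size is a caller choice; ties broken by lexicographic
coordinate order).

## Monte Carlo engine

Move set: end moves (a terminal bead relocated to one of the 5 other
neighbor sites of its anchor), corner flips (the diagonal bead of a right
angle moved to the opposite square corner) and crankshafts (beads i, i+1
rotated 90°/180°/270° about the axis through beads i−1 and i+2 whenever
those are lattice neighbors; any rotation about that axis preserves all
four bond lengths).  One attempted elementary move is one MC time unit;
null proposals (a bead with no geometric move) and rejections advance time
too.  Proposals pick a bead uniformly and then one *geometric* candidate
uniformly, with collisions handled as rejections: the geometric candidate
count at the chosen bead is invariant under the move itself, so the
proposal density is symmetric and Metropolis acceptance min(1, e^(−ΔE/T))
satisfies detailed balance.  (Filtering occupied candidates *before* the
uniform choice — a tempting reading of "legal moves" — would bias the
chain; the implemented scheme is validated against exact Boltzmann
enumeration of the 8-mer cube within three standard errors per energy
level.)

Implementation: numba kernels over int64 coordinates with an occupancy
grid on a 64³ torus (coordinates hashed by their low 6 bits; since any two
beads of an N ≤ 48 chain differ by < 64 per coordinate, wrapped overlap
and adjacency tests are exact).  Energy is tracked incrementally and
re-verified from scratch in the debug validator.  Randomness is an
explicit xorshift64* stream seeded via splitmix64; every run is
bit-reproducible given its seed, and a master seed spawns per-stage,
per-trajectory streams through `numpy.random.SeedSequence`.  Throughput is
roughly 10⁷ attempted moves per second per core for 48-mers.

Random coils are grown as non-reversal walks with restart on collision,
which makes every self-avoiding walk of the target length equally likely.

## Thermodynamics

Parallel tempering runs one replica per ladder temperature (default: 50
geometric temperatures on [0.45, 1.6] for 48-mers), advancing each replica
between swap attempts and swapping adjacent temperatures with the standard
replica-exchange acceptance, alternating pair parity sweep by sweep.  The
colder half of the ladder starts from the native conformation and the
hotter half from random coils, which gives WHAM the histogram overlap it
needs with short burn-in.

Because Gō energies are integers, histograms use bin width 1 with no
binning ambiguity.  WHAM iterates the standard self-consistency equations
in log space until the per-temperature shifts change by < 10⁻⁷ (cap 10⁵
iterations), after checking that neighboring temperatures share at least
one populated bin.  From the density of states: free-energy profiles
F(E; T) = E − T ln Ω̂(E) (additive constant fixed at min F = 0), reweighted
mean energy, and the fluctuation heat capacity Cv(T) = Var(E)/T².  Tm is
the Cv peak; the pipeline evaluates Cv from the density of states on a
fine grid with parabolic refinement, and the direct per-temperature
fluctuation estimator with parabolic peak interpolation is available (and
tested) as well.

Barrier analysis on F(E; Tm): the folded minimum is the lowest-energy
local minimum (E = −57 for 48-mers), the barrier is the highest maximum
between the basins, and the unfolded minimum is the global minimum of F on
the high-energy side of the barrier.  Isolated unsampled interior levels
(up to 3 bins wide — e.g. the one-broken-contact level of a compact
native state is essentially unreachable) are tolerated; wider gaps raise
an error.  A profile is classified non-two-state when an extra local
minimum between the barrier and the folded minimum is protected by its own
local barrier of ≥ 0.5 reduced units (config-exposed; the default sits in the measured gap between profile-roughness dips, which stay below ~0.4, and pronounced intermediate minima above ~0.55); such permutants
stay in the table but are excluded from every regression.  ΔG‡ =
F(barrier) − F(unfolded) is reported both in reduced units and in units of
Tm, which is what makes the ln k vs ΔG‡/Tm slope dimensionally comparable
to −1.  All study results are computed at each permutant's own Tm, where
the barrier is largest and best conditioned.

## Kinetics

For each permutant, independent trajectories start from fresh random
coils at Tm and stop at Q = 1; the first passage time (FPT) is the MC step
of first full nativeness (default 500 trajectories, cap 10⁹ steps with
explicit censoring).  The survival curve Pu(t) — the fraction of
uncensored trajectories with FPT > t — is evaluated on a logarithmic grid
(plus t = 0), and ln Pu is fitted by weighted least squares over the
window Pu ∈ [0.05, 0.95] (trimming the short-time transient and the noisy
tail), with delta-method binomial weights nPu/(1−Pu).  k = −slope, in
inverse MC steps; only within-study comparisons are meaningful.  The
weighted RMS residual is reported and values above 0.10 flag visibly
non-exponential decay; censoring above 5% flags the rate unreliable.
Simulation at the study scale (n = 500) shows < 1% relative bias and < 5%
relative RMSE on exponential data.

## Transition-state ensemble and network

Candidates are trajectory snapshots (with run/step provenance,
deduplicated) whose energy lies within ±1 reduced unit of the barrier
peak.  Each candidate's commitment probability Pfold is measured by M =
100 trial runs at Tm that end on folding (Q = 1) or unfolding (Q ≤ 0.2);
trials hitting the step cap count as indeterminate and flag the estimate
beyond a 10% share.  M = 100 bounds the binomial standard error at 0.05
for p ≈ 1/2.  TSE members satisfy |Pfold − 1/2| ≤ 0.1 with SE ≤ 0.05; the
target ensemble size is ≥ 100 (warned below).  The unfold threshold 0.2
cleanly separates the basins (the unfolded basin sits near E = 0) and is
config-exposed for sensitivity analysis, as are the band, window and M.

CO_TSE averages, member by member, the contact order of *formed native*
contacts (non-native adjacencies are energetically silent and the analysis
concerns native topology).  RMSD_TSE is the mean optimal-superposition
RMSD to the native structure in lattice units, computed by the Kabsch
least-squares rotation with reflections excluded; note the continuous
optimum can be strictly below the best of the 24 lattice rotations, which
is why the brute-force lattice-rotation scan serves as an upper-bound
oracle in the tests rather than an equality check.  The transition-state
network (TSN) is the set of native contacts formed in at least p* = 0.5 of
TSE members (config-exposed; monotonically shrinking in p*), reported with
its size n, mean separation CO_TSN and contact-range spectrum.

## Family-level statistics

The per-permutant table joins CO, Tm, ΔG_fold, ΔG‡ (both unit systems),
ln k, CO_TSE, RMSD_TSE, n_TSN, CO_TSN and the two-state flag; stage
failures leave explicit NaN gaps with a status note.  The correlation
battery fits, by ordinary least squares over two-state permutants only:
ln k–ΔG‡/Tm, ln k–CO, ln k–CO_TSE, CO–CO_TSE, CO–CO_TSN and n_TSN–CO,
each also on the CO ≤ 18.5 subset (the high-CO regime removed; threshold
config-exposed).

## Problem sizes and what the tests show

The full study — two 48-mer families, all 48 permutants, 500 trajectories
each — takes CPU-hours to CPU-days end to end, dominated by kinetics at
Tm (per-permutant mean first passage times reach ~10⁸ MC steps, and slow,
high-CO permutants are one to two orders of magnitude costlier than fast
ones).  The test suite exercises the same code paths at sizes chosen to
finish in minutes: exhaustive enumeration oracles and detailed-balance
checks on the 8-mer cube (2×2×2, 5 contacts), full pipeline runs
(including the Pfold/TSE stage) on 18-mers (3×3×2, 16 contacts), reduced
high/low-CO family studies on 36-mers (3×3×4, 40 contacts; 10 evenly
spaced permutants, 100 trajectories, 22 PT temperatures at 6.4×10⁶ steps
per replica), and a thermodynamics-only 48-mer family (12 permutants)
for the Tm-homogeneity and folded-basin checks.

The small-size limits are worth knowing, because they bound what reduced
runs can show.  The 8-mer cube folds downhill: at its heat-capacity peak
the folded minimum is the global minimum of F and there is no activation
barrier, so barrier-dependent quantities are undefined there and the
family pipeline reports the failed thermo stage explicitly.  At N = 18
and N = 24 barriers are ~1 kT and the ln k–ΔG‡/Tm correlation degrades to
|r| ≈ 0.2–0.7.  At N = 36 the transition-state-theory slope is recovered
(≈ −0.87, within the −1 ± 0.25 band) but the correlation tops out near
|r| ≈ 0.89: the residual ln k scatter at fixed ΔG‡ (~0.35, permutant-
to-permutant prefactor variability rather than measurement noise) is
sizable against the ~1.6 Tm-unit barrier range of the two-state subset.
The |r| ≥ 0.9 regime needs the ~3-unit barrier range of 48-mer families,
i.e. the full-scale study.  Thermodynamic precision matters equally: at
four-fold lower PT sampling the Tm estimator noise (σ ≈ 2.5% per
permutant) both inflates the apparent family Tm spread (7% vs a
noise-adjusted ~4%) and injects a spurious positive ΔG‡–ln k coupling,
since an overestimated Tm simultaneously raises the measured barrier and
speeds the measured kinetics.

## What the generator emulates — and does not

The synthetic structures reproduce the defining properties of the study's
parents: maximally compact 48-mers on 3×4×4 with adjacent termini,
selected for high/low contact order from a seeded pool.  The original
parent conformations themselves are not published, so family-level
numbers (CO ranges, specific correlation coefficients) are
pipeline-specific; only the structural laws (57 contacts, E_native = −57),
the thermodynamic/kinetic consistency relations and the qualitative
family contrasts are transferable.  The model has no side chains, no
sequence heterogeneity, no non-native attraction and lattice-discretized
geometry; conclusions about real proteins inherit all the usual caveats
of native-centric lattice models.
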