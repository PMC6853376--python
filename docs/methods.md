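# Methods

## Model and assumptions

The package models `N` RNA species and `M` miRNA species interacting
through a bipartite network under deterministic mass-action kinetics.
miRNA availability is the only inhibition-limiting resource: every free
miRNA is assumed bound to its effector complex and ready to act, and
unbinding of formed miRNA–RNA complexes is neglected (`k⁻ = 0`), in line
with the observation that mature miRNAs are predominantly
Argonaute-loaded.  Complexes decay through a stoichiometric channel
(rate `σ`, miRNA consumed with the target) and a catalytic channel
(rate `κ`, miRNA recycled); only their ratio `λ = σ/(σ+κ)` matters for
free-species steady states.

Per-edge kinetics are reduced to two thresholds: `μ⁰_ia`, the free-miRNA
level at which repression of RNA `i` by miRNA `a` crosses over, and
`m⁰_ia`, the free-RNA level at which sequestration of `a` by `i` crosses
over.  With shared degradation rates they obey `μ⁰/m⁰ = λ·d/δ` on every
edge, so a single per-edge scalar (set by the binding mode, below)
fixes both.

The analysis is strictly steady-state and linear-response: transient
amplification phenomena, recycling-round-dependent miRNA decay, and
stochastic (master-equation) effects are out of scope.  Responses to
*large* perturbations, where the system leaves the linear regime, are
likewise not described by χ.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `d` | 0.08 | 1/h | RNA degradation rate (shared) |
| `delta` | 0.027 | 1/h | miRNA degradation rate (shared) |
| `lam` | 0.2 | – | stoichiometricity ratio σ/(σ+κ) |
| `mu0_base` | 4 | molecules | reference repression threshold μ₀ |
| `b_mean` | 8 | molecules/h | mean RNA transcription rate (held fixed) |
| `beta_mean` | swept | molecules/h | mean miRNA transcription rate (control parameter) |
| `cv_tr` | 0.1–2 | – | CV of lognormal transcription rates (same for both sides) |
| `complex_decay_total` | 1 | 1/h | σ+κ; nuisance scale |

The defaults correspond to mammalian half-life scales (RNA ≈ 9 h, miRNA
≈ 26 h) and a mostly catalytic decay pathway.  With these values
`μ⁰/m⁰ ≈ 0.59` and the implied association rate for the strongest
(k-mer) class is `k⁺ = d/μ₀ = 0.02` /molecule/h.
`complex_decay_total` affects only complex abundances and ODE
transients, never free-species steady states (verified by a dedicated
invariance test).

Binding-heterogeneity (BH) scenarios map the four CLASH edge classes to
multipliers of `mu0_base`:

- **low** — all modes ×2 (homogeneous network, μ⁰ = 8);
- **medium** — k-mer ×1 (stronger), all others ×2;
- **high** — a two-fold geometric ladder (×1, ×2, ×4, ×8).

The high-BH ladder ordering strongest→weakest is taken as
k-mer < seed-nc < noseed-9nt < noseed, consistent with the medium
scenario singling out k-mer as the strong class; whether the two
no-seed classes should swap places is not empirically settled, so the
ordering is configurable (`BHScenario.high(order=...)`).  All k-mer
lengths (6–9 nt) share one strength.

## Steady-state solver

The titration fixed point is solved by alternating the two update maps
(μ from m, then m from μ).  Both maps are antitone, so their
composition is monotone; starting from the unrepressed RNA profile the
iterates decrease monotonically onto the unique fixed point, and no
damping or line search is needed.  Convergence is linear with an
unknown rate that approaches 1 near the crossover regime, so the
stopping rule extrapolates the remaining distance geometrically from
the observed contraction of successive updates (`res·q/(1−q) < tol`,
default `tol = 1e-12` relative) rather than trusting the raw update
size; iteration also stops if updates stall at ~64 machine epsilons.
Non-convergence within `max_iter` raises, never returns silently.
An earlier damped variant (fixed damping halved on residual increase)
was abandoned: adaptive damping can collapse the step size and make an
update-based residual pass spuriously, while the monotone structure
makes damping unnecessary in the first place.

Complex levels do not feed back on the free-species fixed point and are
computed afterwards as `c_ia = k⁺_ia m_i μ_a/(σ+κ)`.

The independent oracle integrates the full kinetics (free species plus
one complex variable per edge) with SciPy's BDF at `rtol = 1e-10` to
`t_end = 50/δ ≈ 1850 h`, well past the slowest relaxation scale.
Fixed-point and ODE free levels agree within 1e-6 relative on all
fixture motifs and random networks up to N = 50.

## Susceptibility

`W` is assembled sparsely as `diag(m²/m*)·A·diag(μ²/μ*)·Bᵀ` with
`A_ia = 1/μ⁰_ia`, `B_ja = 1/m⁰_ja` supported on the edges; its support
is exactly the co-regulated RNA pairs.  χ is obtained from a sparse LU
factorization of `I − W` applied to the dense right-hand side
`diag(m/m*)` — no explicit inverse.  Stability (`ρ(W) < 1`) is
guaranteed at a stable steady state; it is monitored operationally
(the solve must succeed and yield non-negative entries, with tiny
negative round-off clipped at `1e-10` of the maximum) and, in
validation mode, by a 200-step power-iteration estimate of ρ(W).

The finite-difference oracle evaluates `χ_ij = d_j (m_i(b_j(1+ε)) −
m_i(b_j(1−ε)))/(2 b_j ε)` with relative step `ε = 1e-4` and solver
tolerance 1e-14, keeping truncation error well above round-off.  The
resulting noise floor on χ entries is ≈1e-10 absolute, so
oracle-equivalence tests compare with `rtol = 1e-4` and a small
absolute floor (`atol = 1e-11`): entries large enough to be numerically
resolvable are held to the relative tolerance, entries below the noise
floor (long-chain pairs can reach 1e-12) are compared absolutely.

## Synthetic interactome generator

The generator emulates three gross features of CLASH-style interactome
reconstructions: heavy-tailed degree distributions on both sides,
a binding-mode composition dominated by non-canonical seed pairings
(default frequencies 0.08/0.77/0.05/0.10 for kmer/seed-nc/noseed-9nt/
noseed — only the 77% seed-nc share is empirically pinned; the split of
the remainder is a package choice), and i.i.d. lognormal transcription
rates with exact population mean and CV (log-scale parameters
`s² = ln(1+cv²)`, `loc = ln(mean) − s²/2`).

Node weights are drawn from a truncated discrete power law (exponent
2.2, cutoff at the edge count) and edges sampled proportionally to
weight products with duplicate rejection — a configuration-style model
chosen because only the heavy-tail property, not a specific degree
law, is empirically constrained.  Degree-0 nodes are retained by the
generator (they decouple in the model), but edge-list I/O can never
represent them, so loaded interactomes contain only connected nodes.
The generator does **not** reproduce the exact CLASH degree sequence,
degree–degree correlations, or mode–degree associations; conclusions
drawn from synthetic ensembles are therefore about the modelled
feature set, and the degree-preserving null model is the right tool
when an empirical degree sequence must be held fixed.  Every generator
is a pure function of its seed; ensembles derive per-replicate
generators from a base seed with counter-based spawn keys
(condition index, replicate index), recorded in the output tables.

## Metrics conventions

- Pair averages run over *ordered* distinct pairs (χ is directional).
- `max_chi` is the per-realization maximum, then averaged across
  replicates.
- Selectivity rows/columns with zero off-diagonal sum are undefined
  (NaN) and excluded from the S_in/S_out averages; an all-zero χ raises
  an undefined-metric signal rather than returning a number.
- The locality correlation returns the true Pearson value in [−1, 1]
  (the kernel construction makes it positive in practice, but negative
  values are not clipped).
- The asymmetry index averages `|χ_ij − χ_ji|/(χ_ij + χ_ji)` over
  unordered pairs whose sum exceeds a floor of `1e-8·max χ`, excluding
  numerically-zero pairs.  This is the package's declared default; the
  floor and the statistic are configurable.
- Sextile persistence ranks pairs by realization-averaged χ, splits
  into six equal bins (stable tie-break by pair index), and reports
  per-bin conserved fractions plus a chance baseline from 1000 seeded
  rank permutations (≈1/6); both the naive and permutation baselines
  are reported because no canonical construction exists.
- The susceptible region is operationalized as the grid interval where
  mean χ is at least 5% of its peak.

## Null models

Uniform rewiring places each edge uniformly among unoccupied (RNA,
miRNA) pairs — duplicate pairs are forbidden because the model admits
one interaction channel per pair — preserving node sets, edge count and
the mode multiset while destroying degree sequences.  Degree-preserving
randomization performs double edge swaps (default 10× the edge count
accepted swaps, attempt budget 10× that), rejecting swaps that would
duplicate a pair; each edge keeps the binding mode of its miRNA
endpoint, so per-miRNA mode multisets are also invariant.  Whether
modes should instead be shuffled relative to pairs is undetermined;
the inheritance rule is the declared choice.

## Desk-scale study conditions

System-level analyses run on a synthetic network of 300 RNAs × 60
miRNAs × 1200 edges (isolated nodes pruned on load), a 25-point
log-spaced β̄ grid from 0.1 to 1e4 molecules/h, high BH, and 10–40
replicates per condition depending on the statistic.  These sizes were
chosen so the full qualitative battery — interior peak of mean χ,
earlier peak of max χ at low TH, ρ decreasing and selectivity
increasing with TH, late CV-of-expression maximum — is stable and
reproducible in minutes.  At this scale the mean self-susceptibility
exceeds the mean cross-susceptibility by ~2.5 orders of magnitude
(the gap grows with network size), and one desk-scale caveat is worth
recording: at high transcriptional heterogeneity (CV_tr = 2) the
max-χ peak moves to *larger* β̄ than the mean-χ peak — the
earlier-peak ordering is a low-TH feature at this size, so the
acceptance battery evaluates it on the CV_tr = 0.1 sweep.

## Known limitations

- Shared `d` and `δ` across species; per-edge σ/κ heterogeneity is not
  modelled.
- Transcription rates are uncorrelated quenched draws; correlated
  heterogeneity (which can qualitatively change fluctuation
  processing) is not covered.
- Susceptibilities with respect to miRNA transcription rates
  (∂m/∂β) are not implemented; no main-line analysis uses them.
- The ODE integrator carries one state variable per edge and is an
  oracle for small systems, not a production path for CLASH-scale
  networks.
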