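# Methods

## The mass-action model

The cell is treated as a well-mixed equilibrium system. Protein *i* has a
fixed total concentration C_i (nM) partitioned between the free folded
monomer F_i, a collective pool U_i of biologically unusable states
(unfolded, misfolded, oligomerised), and heterodimers D_ij with its
interaction partners. Complexes are restricted to dimers: binary
interaction data carry no stoichiometry, and the dimer restriction keeps
the equilibrium system closed. Only folded monomers interact; the unfolded
pool of one protein is assumed not to interact with any state of any other
protein, and chaperone-mediated turnover of the unfolded pool is neglected.

Mass conservation plus the law of mass action (D_ij = F_i F_j / K_ij) and
the two-state folding balance (U_i = e^(-dG_f,i) F_i, dG_f in units of
k_BT, positive = folded favoured) give the fixed point

    F_i = C_i / (1 + e^(-dG_f,i) + sum_j F_j / K_ij).

The interaction constant K_int,i = sum_j F_j / K_ij measures the effective
binding strength a protein experiences at self-consistency; the
interaction-induced stability is dG_int,i = ln(1 + K_int,i), because
(1 + K_int) is exactly the factor by which the unfolded fraction

    U_i / C_i = 1 / (1 + e^(dG_f,i) (1 + K_int,i))

is suppressed relative to the same protein with no partners. dG_int >= 0
always, with equality iff the protein has no partners with nonzero free
concentration.

### Stability modes

* `infinite` (default): every protein treated as infinitely stable
  (U = 0). This yields the upper limit of interaction-induced stability
  and requires no per-protein stability data; dG_total and the unfolded
  fraction are reported as absent rather than inventing a dG_f.
* `explicit`: per-protein dG_fold from the input table.
* `chain_length`: dG_f,i = a + b * length_i, a linear stand-in for
  length-dependent stability models (defaults a = 0, b = 0.05 k_BT per
  residue, giving ~15 k_BT for a 300-residue protein).
* `minimal`: all dG_f at a configurable floor (default 0, i.e. marginal
  stability) — a worst-case variant.

### Numerics

The solver iterates the fixed point with a simultaneous (Jacobi) update so
results are independent of protein ordering; Gauss–Seidel sweeps are an
opt-in speedup. Convergence requires both the per-protein relative change
between consecutive sweeps and the relative mass-balance residual
|F_i + U_i + sum_j D_ij - C_i| / C_i to fall below `rel_tol` (default
1e-8); the residual condition guarantees that conservation holds at the
advertised accuracy even when the contraction is slow. Very tight binders
at matched abundances (K_d orders of magnitude below the concentrations)
make the undamped iteration oscillate between near-0 and near-C; when the
residual stalls for 100 sweeps the mixing weight is halved (floor 1/64),
which restores convergence on all such cases we construct. An independent
oracle (`brute_force_equilibrium`) solves the same system by Powell's
hybrid method in log-concentration space — nonnegativity built in — and is
used to cross-check the fixed point on small networks.

Dissociation constants can be supplied per edge or assigned by rule:
`abundance_recipe` sets K_ij = alpha * min(C_i, C_j) (default alpha = 0.1)
on the argument that tightening a bond beyond the point where the scarcer
partner is fully sequestered buys nothing; `lognormal` draws i.i.d. values
(default median 50 nM, log-sd 1.0); `fixed` sets a single value (default
5 nM, a typical strong specific interaction). Concentrations are nM
throughout; a converter from molecules/cell uses a configurable cell
volume (default 42 fL, haploid budding yeast). Energies are k_BT
internally, with an optional kcal/mol display column (x 0.593 at 298 K).

## Evolutionary capacitance

Knocking protein *i* out (removing it and its edges) and re-solving the
network changes every other protein's dG_int. The capacitance

    Cap_i = sum_{j != i} max(0, dG_int,j(full) - dG_int,j(without i))

counts only destabilised proteins: indirect effects can have either sign,
since removing a competitor frees a shared partner and can stabilise third
parties. Losses below 1e-12 k_BT are treated as solver noise. The sum runs
network-wide by default (a `partners_only` switch restricts it to direct
partners), capacitance defaults to the infinite-stability mode to match
the upper-limit dG_int estimates, and a `dosage` option scales the
protein's concentration instead of removing it. Ranking ties are broken by
protein id so reports are reproducible.

Two genuine physical effects keep the capacitance–degree rank correlation
moderate rather than overwhelming on random networks: a protein cannot
lend more total stabilisation than its own abundance supports (sum_j D_ij
<= C_i), and after a knockout the equilibrium re-binds, compensating part
of the partners' loss wherever they have alternative partners. Hubs still
dominate star-like neighbourhoods, and the degree association is positive
and highly significant on scale-free networks, but a pure degree reading
of capacitance would be wrong — sufficient abundance matters as much.

## The evolutionary model

A toy organism (default 15 proteins, seed-fixed connected random topology
with mean degree 3, lognormal abundances with median 300 nM and log-sd
0.3) evolves under the fitness

    Phi = exp(-c * sum_i U_i),

i.e. misfolding toxicity proportional to the total unfolded concentration.
Each generation one mutation is proposed: with probability `p_stability`
(default 0.5) one protein's dG_f takes a Gaussian step (destabilising on
average), otherwise one edge's K_d is redrawn from its lognormal prior.
Abundances and topology never change. The proposal is accepted with the
canonical-ensemble probability min(1, (Phi'/Phi)^nu); the stationary
distribution is proportional to Phi^nu, so the selection exponent nu plays
the role of (twice) the effective population size and 1/nu acts as an
evolutionary temperature. nu = 0 is pure drift; a `kimura` option replaces
the rule with the diffusion fixation probability as a robustness check.

By default the unfolded load uses a two-level scheme: the network free
concentrations are solved with every protein treated as highly stable, and
each protein's unfolded fraction then follows from its own two-state
balance U/C = 1/(1 + e^dG (1 + K_int)). The optional fully coupled variant
(`unfolded_feedback=True`) feeds the unfolded pool back into the network
solve. The distinction matters qualitatively: under full coupling a
destabilised protein also withdraws the free monomer it offers its
partners, so in the drift regime the whole network loses interaction
stabilisation at once and the compensation phenomenon largely disappears.
The two-level scheme preserves it and is the default.

### Parameter calibration

Everything here is a documented configuration parameter; the defaults
place the studied range of population sizes (nu in {2, 20, 200}) across
the drift-to-selection transition, which is where the model's interesting
behaviour lives:

* **Stability window** [dG_min, dG_max] = [-4, 15] k_BT. The ceiling
  models the bounded stability of real sequences; the floor models the
  bounded *instability* of a still-foldable sequence (at -4 k_BT a protein
  is ~98% unfolded without partners). A floor is necessary for a finite
  drift regime at all: the selection gradient against unfolding vanishes
  exponentially once a protein is mostly unfolded, so an unbounded walk
  with destabilising bias escapes irreversibly and the low-nu organism
  collapses into complete proteome unfolding.
* **Mutation kernel** Gaussian(-0.5, 1.0) k_BT, reflected at the window
  boundaries: random missense mutations are destabilising on average, on
  the lower end of the ~1 k_BT scale seen in mutational scanning
  compilations (the toy model's "generation" granularity is arbitrary, so
  only the bias-to-variance ratio matters for the dynamics).
* **K_d prior** lognormal(median 500 nM, log-sd 2.5): measured binary PPI
  affinities span roughly six decades, from sub-nM obligate complexes to
  high-uM transient contacts; the heavy tight tail is what gives selection
  at small population sizes something to retain.
* **Toxicity scale** c = 0.002 per nM. Because the acceptance rule sees
  fitness only through nu * c * (unfolded-load change), c is a pure gauge
  for the units of nu; the default places the studied range nu in
  {2, 20, 200} across the drift-to-selection transition of the stability
  walk, so that the smallest population is genuinely drift-dominated
  (mean dG_f below zero, proteome held together by interactions), the
  middle sits in the transition, and the largest is selection-dominated
  with intrinsic stabilities of a few k_BT.
* **Run length** 2x10^4 generations with the second half analysed
  (burn-in 50%), 3 replicate mutation streams per nu, one shared organism
  per sweep. These sizes keep a full sweep to a few minutes while the
  post-burn-in means are stable to a few percent.

Two structural properties of the model are worth knowing when
interpreting sweeps. First, once a population size is large enough that
stabilities sit in mutation–selection balance, the selection pressure on
dissociation constants becomes independent of nu: the balance condition
pins nu * c * U at the mutational-supply scale, and the per-redraw
selection tilt reduces to dK_int/(1+K_int), with nu, c and the abundances
cancelling. Mean dG_int therefore rises from its weak-selection level to
a peak near the transition and is then flat (to slight decline) across
further decades of nu — it does not fall monotonically over a wide nu
range, although its share of the total stability falls steeply. Second,
the dG_int–dG_f rank correlation switches from near zero in the drift
regime (stabilities pinned near the floor carry no ranking information)
to strongly negative in the selection regime, where the balance relation
dG_f ~ ln(nu c C) - ln(1 + K_int) ties the two quantities: stabilisation
concentrates on the proteins that remain least stable. The correlation
therefore strengthens in magnitude with population size — the need-basis
picture — and its negative sign at large populations is the same
orientation the synthetic-proteome pipeline recovers between aggregation
scores (an inverse stability proxy) and induced stability.

## Rank statistics

Spearman's rho is the Pearson correlation of average-ranked data (average
ranks for ties — abundance tables are tie-rich). Partial rank correlations
use the recursion formula for one control and the inverse of the rank
correlation matrix for several; the two routes agree exactly for one
control. Controls that are constant are dropped with a warning; rows with
missing values are dropped listwise; a control perfectly rank-correlated
with either variable raises a degeneracy error. Significance, when
requested, is a seeded two-sided permutation test (default 10^4
permutations) rather than an asymptotic approximation, since sample sizes
in these analyses are sometimes small and tie-heavy.

## Synthetic proteomes

The generator draws abundances lognormally (default median 50 nM, log-sd
1.5 — spanning the range where nM-scale binding goes from saturating to
weak), realises a Poisson or power-law degree sequence as a simple graph
via configuration-model simplification, assigns K_d by any of the
mass-action rules, and optionally draws intrinsic stabilities
Normal(10, 3) k_BT. Two couplings can be planted:

* `kd_stability_coupling` (gamma, default 0.5) multiplies each edge's K_d
  by exp(gamma * (min(dG_a, dG_b) - mean dG)): interactions whose least
  stable member is below average become tighter. This emulates, as a
  generative fact, the compensatory coupling that evolution produces —
  unstable proteins with tight interactions — so that pipeline-level
  correlation analyses have a planted truth to recover. Without it a
  protein's own stability would be independent of its K_int by
  construction, since dG_f,i does not enter K_int,i.
* Aggregation scores agg_i = beta_s * dG_f,i + beta_C * ln C_i + noise
  (defaults beta_s = -1, beta_C = -0.5, noise sd 1), a linear-plus-noise
  stand-in for sequence-based aggregation predictors: scores fall with
  stability and with abundance. It makes no claim to model any particular
  predictor.

What passing tests on these proteomes do and do not show: they demonstrate
that the pipeline recovers planted orderings with the correct sign at
realistic sample sizes, not that real interactomes have the planted
effect sizes. Real data differ in ways the generator deliberately ignores:
duplicate genes, complex membership (many-body binding), correlated
evidence errors, assortativity between abundance and degree, and the
non-additive sequence determinants of aggregation.

## Known limitations

* Heterodimers only: homodimers and higher-order complexes are out of
  scope (self-edges are rejected at parse time).
* Equilibrium only: no chaperone kinetics, no synthesis/degradation
  fluxes, no explicit aggregation dynamics.
* The evolutionary model's fitness sees only the total unfolded
  concentration; expression levels and network topology do not evolve.
* The toy-proteome results are qualitative regime statements; absolute
  values depend on the calibration choices documented above.
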