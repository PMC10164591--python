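# Methods

## The model

`tailkin` simulates the removal of 3′ poly(A) tails from a population of
RNA substrates by a multi-subunit deadenylase (two catalytic subunits, CCR4
and CAF1, on a non-catalytic scaffold carrying the NOT module) under the
control of three effector proteins: Smaug, which binds sequence elements
(SREs) in the RNA body and tethers the complex via the NOT module; Cup,
which binds RNA without sequence specificity and promotes recruitment; and
the cytoplasmic poly(A)-binding protein PABPC, which coats the tail.

The simulation is an exact continuous-time Markov process (Gillespie direct
method) over explicit molecules and explicit enzyme agents, with four event
types:

| event | propensity | notes |
|---|---|---|
| bind | `k_on · [E_free] · m` per unbound molecule | `m` is the molecule's association multiplier (below) |
| remove one nt | `k_cat_ccr4 + k_cat_caf1` per engaged complex | active subunits only; × `(1−theta_dead)` if exactly one subunit is catalytically dead; × `pabpc_stim` on a PABPC-covered tail |
| dissociate | `k_off` per engaged complex | × `tether_off_scale` for a tethered engagement |
| handoff | `handoff_rate` per complex sitting on a finished tail | followed by instantaneous rebinding to a uniformly chosen free substrate |

Tails are integers, never increase, and stop at zero; the RNA body is never
degraded. Molecule count is conserved. A single seeded PCG64 generator
drives each `simulate` call; identical inputs and seed give bit-identical
output.

**Effector occupancy** is a fast pre-equilibrium: per-molecule Bernoulli
flags drawn once at t = 0 from `C/(C+Kd)`, mirroring assays that
pre-incubate RNA with effectors before enzyme addition. Smaug occupancy of
a two-SRE substrate is collapsed to one bound/unbound flag; a substrate
with mutated or absent SREs has occupancy exactly zero. PABPC copies are
drawn per molecule as Binomial(⌊tail/footprint⌋, occupancy) and are shed
as the shrinking tail can no longer accommodate them.

**Association multiplier.** Relative to basal binding (`m = 1`):
Cup-occupied molecules bind at `cup_on_scale`; a PABPC-covered 3′ end
multiplies by `pabpc_end_block`; each PABPC copy beyond the first
multiplies effector-mediated association by `pabpc_recruit_block`. An
engagement is *tethered* (dissociation scaled by `tether_off_scale`) when
the molecule is Smaug-occupied and the complex carries the NOT module;
complexes without it (CORE, the CCR4–CAF1 heterodimer) never tether, which
reproduces their insensitivity to Smaug.

**Agent counts.** Concentrations in nM are mapped to agent counts at a
fixed scale (default 100 molecules per nM of substrate); the enzyme count
is derived from the enzyme:substrate concentration ratio, rounding half
up. Fully deadenylated molecules are no longer binding targets.

## Default parameters

No rate constants are reported for this system, so the defaults are the
declared model configuration, chosen once to reproduce the observed
reaction behaviour and then used everywhere:

| parameter | default | unit | rationale |
|---|---|---|---|
| `k_cat_ccr4`, `k_cat_caf1` | 25 each | nt/s | 50 nt/s total: a 70-nt tail is stripped in ~1.4 s, consistent with complete products inside the 5-s burst window |
| `handoff_rate` | 0.1 | /s | sets the slow second phase of the burst: ~12% of 50 nM substrate finished at 5 s by 5 nM enzyme |
| `k_on` | 0.010 | /nM/s | calibrated so the basal (untethered) reaction gives the observed ~50-fold lower end-product rate for the SRE-mutant substrate |
| `k_off` | 200 | /s | distributive basal behaviour: 0.25 nt removed per engagement on average, giving tight, synchronously shortening tail distributions |
| `tether_off_scale` | 2.5e-5 | – | tethered engagements essentially never dissociate mid-tail (k_off,eff = 0.005/s) |
| `theta_dead` | 0.6 | – | a dead subunit occludes the 3′ end 60% of engaged time; with equal subunit rates a single-dead complex runs at (1−0.6)·0.5 = 20% of wild type, the observed ~80% reduction |
| `cup_on_scale` | 10 | – | Cup-occupied RNA completes a 70-nt tail distributively within tens of minutes at 2 nM enzyme |
| `pabpc_footprint` | 17 | nt | the largest integer placing 4 copies on a 70-nt tail |
| `pabpc_end_block` / `pabpc_stim` / `pabpc_recruit_block` | 0.2 / 1.5 / 0.5 | – | initial 3′-end sequestration, later stimulation of catalysis through covered poly(A), and inhibition of effector-mediated recruitment by excess copies |
| Kd (Smaug / Cup / PABPC) | 1 / 20 / 10 | nM | high-affinity SRE binding; weaker, sequence-independent Cup binding; roughly one PABPC copy bound at low-nM concentrations |

Crowding (PEG), ATP and ionic conditions are absorbed into the rate
constants. The sensitized crowding-agent-free condition used for the
cooperativity experiment is emulated by `k_on × 0.2` and
`tether_off_scale = 0.005` (association and tether stability both suffer
without crowding), so that neither effector alone saturates the reaction.

## Gel readout

A population snapshot is rendered as a densitometry trace: each molecule
of total length L contributes a Gaussian band at `pos(L) = a − b·log10(L)`
(defaults a = 100, b = 40) with width `sigma(L) = 1.5 + 0.03·L` nt,
converted to position units through the local slope of the length map.
Bands are normalized so total intensity equals molecule count × gain
before noise; noise is an optional constant background plus Gaussian
multiplicative term. The modal tail length is the argmax of the trace
mapped back to length minus the body, ties resolved to the longest length
(a deterministic convention that biases rates downward uniformly).
"Fully deadenylated" intensity is integrated within 2 nt of the body-only
position; because bands are broad at small lengths this undercounts by a
few percent relative to the exact molecule count, which is available from
raw states.

## Estimators and classification

* **Deadenylation rate (nt/min):** negated least-squares slope of modal
  tail length over time, fitted from t = 0 up to (excluding) the first
  point where the mode falls below 5 nt — beyond that the mode jumps to
  the accumulating end-product band and no longer reports the substrate
  band. Exactly-flat series return 0.
* **End-product rate (nM/min):** least-squares slope of fraction × total
  concentration between the last point below the 2% detection threshold
  and the first point at ≥98% (lag and plateau excluded).
* **Burst fit:** `P(t) = A(1−e^{−kt}) + v t` by bounded nonlinear least
  squares. Note the fitted amplitude measures the first catalytic round
  (≈1 RNA per enzyme); the gel-lane reading "product at the first
  time point / enzyme" also counts early handoff completions and is
  slightly larger (≈1.2).
* **First appearance time:** linear interpolation of the first upward
  crossing of the 2% detection threshold (`alpha`, a quantification of an
  unquantified visual criterion).
* **Processivity:** coexistence index = min(fraction finished, fraction
  within 5 nt of the initial tail), evaluated at the first sampled state
  with ≥10% product — a threshold high enough that the index is read from
  an established product band rather than pinned at the detection limit.
  The titration-invariance ratio is max/min of first-appearance times
  over an enzyme titration. Verdicts: processive iff index ≥ 0.05 and
  (when measurable) ratio ≤ 1.5 — a missing ratio is non-blocking because
  a fast processive burst cannot be titrated; distributive iff index <
  0.05 and ratio ≥ 2; otherwise indeterminate. The thresholds separate
  the two simulated regimes by an order of magnitude.
* **Cooperativity:** score = mean over the time grid of
  `P_both − clip(P_smaug + P_cup − P_none, 0, 1)`. The no-interaction
  null is simulated by letting co-occupied molecules respond only to the
  stronger single effect (Smaug tethering at basal association): there is
  then literally no term in which the two effects combine, and the score
  is centred at zero up to Monte-Carlo noise. With the interaction
  enabled, co-occupancy gives Cup-speed recruitment *and* tethering
  simultaneously, and the score is strongly positive.

## Parameter recovery

`fit_kinetic_params` minimizes squared residuals between observed and
simulated summary curves (modal tail, normalized by the initial tail
length, and product fraction). Every candidate is simulated with the same
inner seed (common random numbers), making the objective deterministic
and exactly zero at the truth for self-generated data. Optimization is
Nelder–Mead in log10 space from the best point of a coarse log grid;
parameters whose whole bounded range leaves the loss bit-identical are
reported as non-identifiable before fitting (e.g. `theta_dead` from
wild-type-only data).

## What the synthetic data do and do not emulate

Scenarios reproduce the reported assay conditions — substrate identity,
enzyme variant, and the quoted nM concentrations per experiment — with
time grids reconstructed at each assay's sampling resolution (seconds for
the burst, minutes elsewhere; exact sampling times are not printed and are
plausible reconstructions). The generator does not emulate label
chemistry differences, gel-image artifacts beyond band broadening and the
stated noise model, enzyme active-fraction uncertainty, partial effector
preparations, or competition by carrier tRNA. Passing tests therefore
demonstrate internal consistency of the kinetic reasoning with the
reported observations, not agreement with unpublished raw data.

## Numerical choices and problem sizes

Event selection uses exact integer class counts recomputed every
iteration, with float weight aggregates refreshed every 2^16 events to
cancel drift. Default test problem sizes are 300–4000 molecules per
simulation; the burst-magnitude check uses 10^5 molecules and the
recovery check 10^4, at which Monte-Carlo error is well below the stated
tolerances. The 1.2-RNA-per-enzyme burst reading carries the same caveat
as the original quantification: it divides by a nominal enzyme
concentration and does not model active-fraction uncertainty.

## Known limitations

* The single-exponential handoff is one reading of the slow burst phase;
  the data equally admit substrate-rebinding kinetics as the slow step.
* The reported ~16-min lag of the SRE-mutant reaction and its ~50-fold
  lower end-product rate cannot both hold in a synchronous distributive
  model (the lag implied by the rate is longer); the defaults reproduce
  the quantified 50-fold ratio and let the lag follow from it.
* PABPC site filling is independent-site; at its Kd this predicts two
  copies on a 70-nt tail rather than the reported one, while the packing
  limit (four copies) and the inhibition pattern are reproduced.
* Effector binding kinetics, mRNA body decay, decapping, translation and
  spatial effects are out of scope.
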