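# Methods

## Model and assumptions

The method predicts the flux-difference vector `Δv = v_P − v_C` between a
perturbed (P) and a control (C) condition of the same genome-scale metabolic
network. Two assumptions carry all the weight:

1. **Balanced differences.** Each condition is at metabolic steady state, so
   `S v_C = S v_P = 0` and hence `S Δv = 0`. No cellular objective is
   assumed for either condition.
2. **Expression-consistent signs.** Where expression of a reaction's enzymes
   rose (fell), the flux difference is *encouraged* — not forced — to be
   positive (negative). Inconsistencies are admitted but minimized, which
   matters because transcript changes only weakly control flux.

All reactions that admit negative flux in either condition are split into
irreversible forward/backward halves (the backward column is the negated
forward column); the optimization runs in this split space, and net
per-reaction differences are recovered as forward − backward.

## The two-step optimization

**Step 1 (consistency MILP).** Binary indicators per split reaction:
`zU_i = 1` iff `Δv_i ≥ μ_i`, `zD_i = 1` iff `Δv_i ≤ −η_i`, and `z0_i = 1`
forces `Δv_i = 0`. The objective maximizes
`Φ = Σ_{R_up} w_i (zU_i − zD_i) + Σ_{R_down} w_j (zD_j − zU_j)` subject to
the balance, box bounds on `Δv`, the indicator linking constraints (big-M),
`zU + zD ≤ 1`, and pair couplings `z0_k + zU_k ≥ zD_k'`,
`z0_k + zD_k ≥ zU_k'` for each forward/backward pair.

**Step 2 (parsimony).** Among all solutions with `Φ = Φ*`, return the one
minimizing `‖Δv‖₂²` (default) or `‖Δv‖₁`. L2 gives a unique `Δv` for a
fixed indicator assignment; L1 is a single LP/MILP and is the practical
choice for large models.

### Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `epsilon_frac` | 0.001 | — | thresholds `μ = η = ε` = this fraction of the largest flux bound magnitude over both conditions |
| `M` | 1e5 | flux | big-M constant; validated to exceed every bound/threshold magnitude, auto-raised with a warning if the default is too small |
| `bound_cap` | 1e4 | flux | replaces infinite flux-difference bounds before building |
| weights `w` | 1 | — | per-reaction priority in `Φ`; knockouts enter `R_down` with weight 10 |
| `norm` | L2 | — | step-2 norm (L1 recommended for genome-scale models) |
| `binaries` | free | — | step 2 re-optimizes the binaries ("free") or freezes the step-1 incumbent ("fixed") |
| regulation mode | fc_cutoff, param 1 | — | `R_up = {fc > param}`, `R_down = {fc < 1/param}`; "percentile" takes the top/bottom tails of log2 fold change instead |

### Design choices where the formulation was open

- **Pair couplings are applied symmetrically** (both orders of each
  forward/backward pair). Applied only forward-to-backward, a regulated
  reversible reaction can cancel its forced forward change with a
  sub-threshold backward change sitting exactly at `μ`, producing a net zero
  — defeating the couplings' stated purpose of preventing simultaneous
  two-sided changes. The one-sided variant remains available
  (`pair_coupling="printed"`), and both are exercised against the
  enumeration oracle in the tests.
- **`z0` is free by default** for non-forced reactions (the solver may use
  it to satisfy pair couplings); a strict mode fixes `z0 = 0` outside the
  forced set. Strict mode can only lower `Φ*`, which the tests assert.
- **Percentile selection** ranks covered reactions by log2 fold change so
  the two tails are symmetric; boundary ties are all included, and a
  reaction enters `R_up` only with fold change > 1 (resp. < 1 for `R_down`),
  guarding the degenerate case of a tail crossing unity.
- **Genes without data evaluate to fold change 1** inside a rule; dropping
  them would distort AND/OR semantics asymmetrically. Reactions with no rule
  or no covered gene are never regulated.
- **Bound overrides on reversible reactions** constrain the *net* difference
  via an extra constraint row, since a net interval is not expressible as
  split box bounds. Overrides on irreversible reactions replace the box
  interval directly. Whether an override is an equality or an interval is
  the caller's choice (an equality is a degenerate interval).

## Numerical choices

- All LPs and MILPs are solved with HiGHS through scipy
  (`scipy.optimize.milp` / `linprog`), relative MIP gap 0.
- **Row-wise tightened big-M.** Each indicator row uses the smallest valid
  constant for that row (e.g. `μ_i − Δv_min,i` on the release side of the
  up-indicator) rather than the global `M`. The integer-feasible set is
  identical, but the LP relaxation is tighter and — decisive in practice —
  the solver's integrality tolerance is not amplified by an oversized
  constant into violations of the indicator semantics.
- **Binary repair.** After any mixed-integer solve, the binaries are rounded
  and the continuous problem is re-solved with the binaries pinned, so the
  returned `Δv` satisfies the indicator semantics exactly; `Φ*` is computed
  from the rounded binaries in exact binary arithmetic.
- **L2 with fixed binaries** reduces to projecting the origin onto
  `{S Δv = 0} ∩ box ∩ override slabs`, computed by Dykstra's alternating
  projections followed by an active-set KKT polish (pin active bounds, solve
  the reduced least-norm problem by pseudoinverse, accept only if feasible).
  Deterministic; repeated solves agree exactly.
- **L2 with free binaries** runs a best-first branch-and-bound over the
  binaries. Node bounds come from a valid inequality (an asserted indicator
  implies `Δv_i² ≥ μ_i²`, so the LP minimum of `Σ μ² zU + η² zD` under the
  node's constraints bounds the achievable squared norm); integral nodes are
  evaluated exactly by the fixed-binaries projection. The search starts from
  the fixed-binaries solution, so it can only improve on it; if the node
  limit (default 2000) is reached the best incumbent is returned and flagged
  `node_limit`.
- Step-2 consistency is enforced as the equality `Φ = Φ*`; if numerically
  infeasible, it is retried as `Φ ≥ Φ* − 1e−9`.
- Degenerate inputs: all-zero bounds give `ε = 0` with a warning; a reaction
  in both regulation sets is rejected at build time; contradictory overrides
  surface as an infeasibility report naming the constraint groups.

## Synthetic data generator

The generator emulates the statistical structure the method assumes, with
known ground truth. Networks are a source → chain → sink backbone with
branches, mixed GPR rule shapes (single gene, complex, isozymes, nested),
cycling subsystem labels, and a configurable reversible fraction (default
bounds ±10 mmol gDW⁻¹ h⁻¹). Control fluxes are sampled from the null space
and scaled strictly inside the bounds; the perturbation shifts the
null-space direction with most weight on the chosen target reactions so that
the largest target change equals `magnitude` exactly — both condition
fluxes satisfy `S v = 0` to machine precision by construction. Gene fold
changes are generated from the true `Δv`: sign-matching log2 fold changes
(magnitude growing with `|Δv|`, baseline 0.5), log-normal noise of standard
deviation `noise_sd`, and a fraction `inconsistency_frac` of regulated
reactions deliberately sign-flipped. Flips are the prefix of a
seed-determined permutation, so flip sets are nested as the fraction grows —
degradation curves over a fixed seed are directly comparable. Reactions
with `|Δv|` above 0.02 (twice the default `ε` under the default bounds) and
a GPR rule form the regulated truth set.

What the generator does **not** emulate: promiscuous enzymes (each toy
reaction has its own genes, so the Min/Max inverse mapping is exact),
realistic kinetics or thermodynamics, measurement error on fluxes, lumped
measured reactions, and genome-scale dimensionality. Passing the recovery
tests therefore shows the optimization recovers directions when expression
is informative — not that real transcriptomes are this informative.

## Problem sizes used in the checks

The test-suite and the acceptance script run at desk scale by choice:
enumeration-oracle comparisons on 50 random networks of ≤ 8 split reactions;
recovery studies on 20 scenario seeds of 10–30 reactions at inconsistency
fractions {0, 0.1, 0.3, 0.5} (L1 norm, free binaries); evaluation batches
of 12 scenarios with one measured-rate constraint injected. Mean clean-data
sign recovery is 1.0; recovery at 30 % inconsistency stays above 0.7 and
degrades monotonically. All reported numbers are recomputed at run time by
`scripts/acceptance.py`.

## Known limitations

- Sign accuracy against a dense ground truth is inherently limited by
  parsimony: step 2 zeroes every change not needed for `Φ*`, so small true
  changes are predicted as 0 unless a measured rate anchors the scale.
- The free-binaries L2 mode is exact only up to its node limit; on larger
  models use L1 (exact single MILP) or the fixed-binaries L2 mode.
- Metabolite throughput differences are computed from direction-resolved
  split differences, i.e. the change in directional production attributable
  to `Δv` — not the difference of absolute production fluxes between
  conditions, which would require `v_C` itself.
- Reactions reversible in only one condition are split with the disallowed
  direction's bounds zeroed in the other condition, keeping one index space.
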