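# Methods

## Model

Every node of a directed, signed network is an ODE for a non-negative
activity. A node Y with activating inputs {Aᵢ} and inhibiting inputs {Iⱼ}
evolves as

    dY/dt = −δ_Y·Y + (β_Y + Σᵢ Act(Aᵢ; α, γ, η)) · Πⱼ Inh(Iⱼ; α, γ, η)

with Hill-type transfer functions Act(x) = α·x^η/(x^η + γ^η) and
Inh(x) = α·γ^η/(x^η + γ^η). Activations are summed on top of the
independent zero-order activity β; inhibitions multiply the entire
production term; a node with no inputs is the linear source–decay system
with fixed point β/δ. This is a coarse-grained, semi-quantitative model: it
assumes continuous, saturating regulation and needs no kinetic constants,
which is exactly the regime of poorly characterised systems measured only
by bulk OMICs.

### Parameters

| parameter | meaning                         | default | unit            |
|-----------|---------------------------------|---------|-----------------|
| β         | independent (zero-order) activity | 0.01  | activity / time |
| δ         | first-order decay rate          | 1       | 1 / time        |
| α         | link amplitude                  | 1       | activity / time |
| γ         | half-activation threshold       | 1       | activity        |
| η         | Hill exponent                   | 1       | –               |

The standard parametrization (all unity except β = 0.01) keeps the system
non-stiff and strictly positive. The perturbation scheme raises β of the
perturbed nodes tenfold (0.01 → 0.1), the order of magnitude of expression
changes seen in two-condition designs. η = 1 everywhere by default; it is
exposed per link for users who want cooperative (η > 1) regulation.

## Steady-state computation

Acyclic networks are solved exactly by substitution in topological order:
each node's fixed point is (β + Σ activations)·Π inhibitions / δ, with all
upstream activities already settled. Cyclic networks are integrated with
fixed-step explicit RK4 (step 0.01 time units) from the no-interaction
fixed point β/δ until max|dX/dt| < 1e−9, with a horizon of t_max = 1e4;
hitting the horizon raises a convergence error carrying the last state and
residual — non-convergence is surfaced, never silently truncated. Both
paths agree to ≤ 1e−6 on acyclic fixtures (tested). Activities that
undershoot zero numerically are clipped at 0. The steady state reported for
a cyclic network is the one reached from this fixed initial condition; no
basin exploration is attempted (multiple fixed points are possible in
principle under non-default parameters), which keeps runs reproducible.

## Summary statistics and distance

A candidate is one (orientation, perturbation condition) pair. Its summary
is the per-node sensitivity ε = ln(SS_high/SS_low)/ln(β_high/β_low), the
discrete log-log response of each node to the β switch. When several nodes
are perturbed together they switch in concert and the denominator is the
single shared log-ratio. Simulated and observed vectors are each scaled by
their own maximum absolute component before the Euclidean comparison. This
max-abs scaling is sign- and ratio-preserving and makes the comparison
invariant to the logarithm base of the observed data: a log₂FC vector and a
natural-log sensitivity vector are proportional to the same underlying
log-ratios, so after independent scaling the base constant cancels.
Observed fold changes are scaled per comparison, not globally across
comparisons.

## ABC over orientations

The inferred parameter is the direction of every link; the prior is
uniform (every orientation simulated under every condition, exactly once —
no sampling, hence no randomness anywhere in the inference path). The
rejection step ranks pooled candidates by distance and keeps the smallest
⌈total·fraction/100⌉, extended to include every candidate tied with the
cut distance (default fraction 0.1 %; the ceiling guarantees at least one
acceptance on small candidate sets). Posterior link probabilities count
pooled accepted candidates — an orientation accepted under k conditions
contributes k — mirroring a scheme that thresholds the pooled simulated
dataset; the unique-orientation tally is also reported in diagnostics. A
link's forward and reverse posteriors sum to 1 exactly.

Candidates whose integration fails to converge (possible only for cyclic
orientations) are excluded from the ranking and counted in diagnostics: no
defensible distance exists for them. By default all 2^L orientations are
enumerated, honouring the exhaustive design; an `acyclic_only` switch
restricts to DAG orientations, which is both the method's stated domain of
validity and orders of magnitude faster (substitution instead of
integration). The perturbation design defaults to single-node conditions
and is configurable up to all non-empty subsets; the realized candidate
count is always reported so any scheme can be compared like-for-like.

## Undirected inference

Pearson correlations are computed gene-by-gene across samples on
unthresholded abundance values; constant genes are excluded with a warning.
Partial correlations come from the inverse of the correlation matrix,
pcor_ij = −Ω_ij/√(Ω_ii·Ω_jj). When the matrix is rank-deficient or
numerically singular (fewer samples than genes, exact collinearity) the
correlation matrix is first shrunk toward the identity with the analytic
data-driven intensity λ* = Σ_{i≠j} Var(r_ij) / Σ_{i≠j} r_ij² (clipped to
[0, 1], logged); a pseudo-inverse is the fallback of last resort. A link is
called where |r| and |pcor| both pass the threshold (default 0.99): the AND
rule implements partial correlation's purpose of pruning indirect links.
The threshold is applied to absolute values and the plain correlation's
sign becomes the link sign (positive → activation, negative → inhibition).
Lowering the threshold can only add links (tested property). Fold changes
use log2((mean_b + c)/(mean_a + c)) with pseudocount c = 0 by default and a
hard error on zero means — silent distortion is impossible; differential
-expression prefiltering is accepted as a precomputed gene list or p-value
map, since DE testing happens upstream.

## Synthetic benchmark generator

The generator emulates the two-condition design the inference assumes. A
ground-truth network is a random connected DAG (fixed topological order,
each node wired to a random earlier parent, extra forward links added
uniformly), with a configurable fraction of inhibitory links (default
0.25). Observed data are the model's own steady states: "axenic" at
baseline β, "mixed" with the perturbed subset (default: the most upstream
node) at high β, each replicated (default 4, matching typical quadruplicate
cultures) with multiplicative log-normal noise (default sd 0.05 on the log
scale, a realistic between-replicate spread for abundance data).

Because the generating model and the inference model coincide, zero-noise
recovery is a closed-loop correctness check, not evidence about real data.
What passing benchmarks do show: the pipeline's plumbing is lossless, the
summary statistic discriminates orientations, and recovery degrades
gracefully with noise. What they do not show: robustness to model
misspecification (real regulation is not Hill-η=1), to hidden confounders,
or to the information loss of averaging heterogeneous populations. The
generator also does not simulate sequencing counts (negative binomial) or
proteomics missingness.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale: networks of
3–6 nodes, up to 2^12 orientations in counting checks, 20 seeded noisy
benchmarks (5 nodes, 5 links, 5 % noise, quadruplicates) for the recovery
rate. The noisy benchmark restricts enumeration to acyclic orientations —
the method's stated domain — where the exact substitution solver applies.
Distances are compared as plain float64; ties at the acceptance cut are
included by construction, so results are independent of sort stability and
worker partitioning. Orientation enumeration refuses L > 24 edges unless
the cap is raised explicitly.

## Known limitations

- The exhaustive 2^L design is exponential; published-scale runs need HPC.
  Monte Carlo orientation sampling is deliberately not implemented.
- Inference is over link directions only; β, δ, α, γ, η are fixed, not
  inferred.
- Cyclic candidate networks are simulated but the posterior's meaning is
  cleanest on DAGs; feedback loops may not admit a unique steady state.
- With near-symmetric observed data (e.g. an all-zero vector) directions
  are genuinely unidentifiable and posteriors sit at 0.5 — this is the
  correct answer, not a failure mode.
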