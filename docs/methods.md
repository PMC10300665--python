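# Methods

## Model structure

One replicate simulates N agents of two fixed types choosing among R roles
over T discrete timesteps. Defaults (N = 1000, 500 per type; R = 60;
T = 400; 5% death per agent-step; abilities ~ N(100, 20)) are the headline
study conditions and are used for all reported numbers. Each timestep draws
a fresh uniform permutation of the population; agents act in that order, and
all social counts and prices update live within the step, so later actors
see the consequences of earlier actions. A dying agent is replaced in place
by a naive agent of the same type, created this step and acting from the
next; its contributions to occupancy and to the social counts are removed at
death, so all public information refers to living agents only.

## Economy

Each performing agent supplies goods in proportion to its ability. The price
of role r is

    price_r = (N/R) / (S_r/μ + 1),

with S_r the summed ability of the role's current performers and μ the mean
ability: prices are strictly positive, strictly decreasing in supply, ~1
when average agents spread uniformly, and finite for empty roles. An agent
evaluating or performing a role is first removed from its own production
slot, so the price it faces reflects the other N−1 agents (the +1 stands in
for one average entrant). Payoff is credited at the price in force at the
moment the agent acts.

Pricing by supplied quantity rather than by performer headcount is a
deliberate design choice. Headcount prices take only R discrete values, so
untried roles of equal occupancy tie *exactly* and an arbitrarily small
belief difference decides every such choice; prior strength then cannot
grade outcomes, because only the sign of the belief matters. Continuous
supply makes role values a continuum, so the size of a believed advantage
competes with real price dispersion — small expected differences tip few
decisions, large ones tip many.

## Beliefs

Shared priors state that a proportion q of roles favours each type (prior
mass q per favouring hypothesis, 1−2q on neutrality) and that a favoured
type's ability is shifted by s standard deviations relative to neutral
(between-type gap 2sσ). Presets: none (q = 0), few-small (0.1, 0.2),
few-large (0.1, 0.5), many-small (0.4, 0.2), many-large (0.4, 0.5).

For each role the public counts (continuing_t, abandoned_t) per type are
treated as Bernoulli continue/abandon trials with continue-probability 0.5
under neutrality and 0.5 ± δ, δ = s/2, under a favouring hypothesis (δ is
capped at 0.45 to keep probabilities interior for any future s). The
three-hypothesis posterior (A0, A1, An) is computed in log space; binomial
coefficients cancel. An egalitarian prior (q = 0) returns (0, 0, 1)
identically — such agents ignore type-labelled social information. The
expected ability of an untried role for an agent is then
A_own·(μ+sσ) + A_other·(μ−sσ) + An·μ, so the prior effect size enters twice:
in inference (through δ) and in valuation (through sσ). Tried roles use the
agent's true ability, which it learns exactly on first performance. In the
perfect-knowledge condition agents skip inference entirely and value every
role at own ability × price.

## Decisions

Role choice is argmax of expected payoff over candidate roles; payoffs equal
within a relative 1e-9 count as ties and are broken uniformly at random.
Under forced exploration (minimum E distinct roles; E = 4 or 10 in the two
extended-exploration models) candidates are restricted to untried roles
until the quota is met.

The search value V is the maximum expected payoff over untried roles (best
known alternative excluding the current role once everything is tried, so
"further search" stays defined). A single satisficing reservation θ·V
governs both transitions: a just-performed role is adopted as occupation
when its realized payoff strictly exceeds θ·V (and the exploration quota is
met), and an occupation is abandoned when its payoff falls strictly below
θ·V. Payoff exactly at the reservation is kept. Using one reservation for
both decisions, rather than adoption at V and abandonment at θ·V, is the
second substantive design choice: with the asymmetric rule, lowering θ
widens a hysteresis band without making early adoption easier, and in
simulation this *reversed* the intended inertia effect (θ = 0.75 produced
slightly less segregation than θ = 1.0 under strong priors) while
compressing differences between prior regimes. With the single reservation,
low θ lets agents settle early — necessarily on heavily social information —
and holds them there; high θ forces continuous re-justification against the
market. This reproduces both orderings: segregation rises strictly across
prior regimes, and θ = 0.75 segregates far more than θ = 1.0.

## States of reality

Models 1–3 fix the favoured-role structure once per replicate: ⌊0.2R⌋ roles
per type, drawn uniformly without replacement, with offset Δ = 15 (model 1;
d = 2Δ/σ = 1.5), Δ = 4 (model 2; d = 0.4) or none (model 3). Models 4–6 use
the model-1 structure but agents created after timestep 40 receive no
offsets; models 5 and 6 add forced exploration (E = 4, 10). `cohens_d_audit`
verifies the realised effect sizes empirically through the same generator
used by the simulation.

## Segregation index

S = 2 × the occupancy-weighted mean absolute deviation of each role's type
share from 50:50, over occupied roles; an entirely empty table has no value.
Every living agent that performed a role this step counts toward that role
(explorers included); agents replaced during the step have produced nothing
and are excluded, so the end-of-step occupancy sums to N minus that step's
deaths (~5%). Even unsegregated worlds floor near S ≈ 0.2 because ~17
agents per role cannot split evenly — the perfect-knowledge model-3 baseline
(≈0.21) quantifies this floor.

## Randomness and reproducibility

One `numpy.random.Generator` per replicate drives ability draws, death,
acting order and tie-breaks. Replicate streams are derived by hashing
(base_seed, model, priors, perfect-flag, θ, replicate) through
`SeedSequence`, truncated below 2^31, so conditions are independent and
adding conditions never perturbs existing ones. Runs are exactly
reproducible given a seed; two runs differing only in a global price rescale
are bit-identical in behaviour.

## Numerical and implementation notes

The per-step loop is compiled with numba; the public module functions wrap
the same kernels, and tests compare compiled against interpreted execution
on identical RNG streams. Posterior computation is log-space with max
subtraction; role supply is maintained incrementally in float64 (drift is
far below decision tolerances over 4×10^5 agent-steps). The belief table is
cached and refreshed only when the social counts change version.

Reported numbers use 10 replicates per condition (the full design in the
source study used 100); at 10 replicates the standard error of a condition
mean is ~0.01 on the segregation scale, sufficient for every ordering and
baseline comparison made here, and one replicate runs in well under a second
once compiled.

## What the generator does and does not emulate

The synthetic worlds realise the stated study conditions exactly: balanced
types, iid Gaussian abilities, static (or vanishing) favoured-role
structure, global social information, uniform shared priors. They do not
model individual variation in priors or social-learning propensity,
networks restricting who observes whom, historical/media transmission
beyond living agents, wealth accumulation, or more than two types — so
passing tests show the mechanism is sufficient to generate and maintain
segregation under these idealised conditions, not that it is calibrated to
any empirical labour market.

## Known limitations

The likelihood treats population counts as independent Bernoulli trials,
although agents' outcomes are correlated through the shared signal; with
large counts posteriors saturate, so the graded effect of prior strength
operates mainly through valuation (sσ) and the reservation dynamics rather
than through posterior uncertainty. The exact functional forms of the price
and of the favour-probability calculation in the original implementation are
not published in the main text; the forms above are this package's own
documented reconstruction, validated at the level of reproduced aggregate
behaviour (baselines and orderings).
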