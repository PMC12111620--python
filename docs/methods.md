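# Methods

## Models

A user's behavior is modelled as a conditionally stationary binary
stochastic process.  The **self-driven** model is the process's
ε-machine: a unifilar edge-emitting hidden Markov model whose states are
the causal states — equivalence classes of past suffixes with identical
conditional futures.  Unifilarity (state + emitted symbol determine the
next state) makes the state sequence recoverable from the observations,
which is what permits exact filtering and log-loss scoring.

The **social-induced** model is an ε-transducer: the emission
distribution over the next output conditions on the hidden state *and*
the current input symbol (the label of the parent comment being replied
to), and the state updates unifilarly on the (input, output) pair.  The
input process itself is deliberately not modelled: the transducer is a
conditional model, and all population comparisons concern predictive
power over the output only.

Timing convention: the emission at step *t* conditions on the input at
step *t*, i.e. the parent comment, which exists before the reply is
written.  The alternative convention (strictly previous input) is
available behind `estimate_transducer(..., input_shift=1)`; on data
generated under either convention the other sees the same structure
shifted by one step, so the choice is a labelling of alignment rather
than substance.

## Reconstruction (CSSR)

Estimation follows causal-state splitting reconstruction with two
phases.

*Phase 1 — splitting.*  Sliding-window counts of all subsequences up to
length L<sub>max</sub>+1 are collected.  Starting from a single state
holding the empty history, histories are extended one symbol into the
past, level by level.  An extension with at least `min_count` (= 5)
observations is tested against its parent state's pooled next-symbol
distribution with a two-sample Pearson chi-square (no continuity
correction); when rejected at level α it is reassigned to the
non-rejecting state with the largest p-value, or founds a new state.  A
level is swept repeatedly until assignments stop changing.  Untestable
extensions inherit the parent state.  For transducers the same logic
runs over joint (input, output) histories; two histories are equivalent
only if their conditional output distributions agree for *every* input
value with sufficient support, tested at α/2 per input (Bonferroni over
the two input symbols).

*Phase 2 — determinization and transient removal.*  States whose member
histories lead, on the same symbol, to different successor states are
split (members with unobserved extensions follow the heaviest group)
until a fixed point.  Transition probabilities are pooled maximum
likelihood estimates over *leaf* members — members not subsumed by a
longer member of the same state — so each sequence position is counted
exactly once.  The machine is then restricted to the terminal strongly
connected component of the transition graph (the unique component a long
realization cannot leave; if several are terminal the one carrying the
most count mass is kept).  Every estimated model is validated
(row-stochastic within 1e−9, unifilar, strongly connected recurrent
part) before being returned.

The significance level α = 0.001 throughout; it controls the rate of
spurious state splits, and with the default grid each fit runs on the
order of a few dozen tests, so occasional extra states appear at the
percent level — visible in cohort histograms as a thin tail of
larger-than-true state counts, as in the observed population.

*Choosing L<sub>max</sub>.*  The sequence is halved; a machine is fit on
the first half at each candidate L<sub>max</sub> and scored by mean
per-symbol log loss (base 2, probability floor 1e−6) on the second half.
The smallest candidate within 1e−4 bits of the minimum wins: on
memoryless data all candidates produce the same one-state machine and
tie exactly, while half-sample boundary effects perturb otherwise
identical models' losses at the 1e−5 level and must not buy extra model
size.  Real structure differences in the fixtures exceed 0.04 bits.
The default candidate grid is 1–6; cohort runs use 1–3, which suffices
for every archetype the generator produces (the deepest, the three-state
machine, is order 2).

## Information measures

All quantities are in bits.  For a machine, predictive complexity
C = H[π] is the Shannon entropy of the stationary distribution π over
recurrent states, obtained by direct linear solve of πP = π.  The
machine entropy rate is Σ<sub>s</sub> π(s) H(X | s); it is exposed
alongside the block-entropy estimate of h, and the two agree on fixture
data within 0.02 bits at n = 4×10⁵.

Sequence-level estimates use plug-in block entropies H(L) of
overlapping windows, with no bias correction (test sample sizes are
large relative to 4^L):

* E = 2H(L) − H(2L), h = (H(2L) − H(L))/L, with L the model's
  L<sub>max</sub>.  Tiny negative plug-in artifacts are clipped to 0.

For transducers the output-only definitions would be blind to the
social channel by construction (the current input is not part of the
output past), so the social-induced summary uses the joint process:
E = 2H₄(L) − H₄(2L) over 4-letter (input, output) blocks, and h is the
joint block-entropy rate minus the input block-entropy rate — the
remaining output uncertainty given the joint past and the current input
— clipped to [0, 1].  C for a transducer is the entropy of the
empirical post-synchronization state-visit distribution, since the
transducer's stationary law depends on the input process it does not
model.  One-state models carry C = 0 exactly.

## Filtering and scoring

Filtering tracks the set of states consistent with the observed suffix;
the first position at which the set is a singleton is the
synchronization index.  An observation with no outgoing edge from any
candidate state flags the position desynchronized and restarts from the
full recurrent set — estimated machines need not support every held-out
subsequence, and aborting would bias model selection against larger
machines.  Desynchronized and pre-synchronization positions are
excluded from scoring; probabilities are floored at 1e−6 so unseen
events cost a finite penalty.

## Synthetic cohorts

The generator emulates the structure of the observed population: one
binary output stream per user, an aligned binary parent stream, per-user
lengths drawn uniformly from the observed range (9,642–89,763 comments;
analysis and test cohorts use shorter ranges, noted below), and a mix of
archetypes:

* `coin` — memoryless Bernoulli(0.5) users (the dominant self-driven
  class);
* `two_state` / `three_state` — users driven by the built-in average
  machines with the published transition probabilities;
* `transducer_coupled` — users driven by the built-in two-state
  transducer (published input-conditional responses) under i.i.d.
  Bernoulli(0.5) parent labels, a memoryless input that isolates the
  transducer's structure;
* `balanced_coupled` — an additional archetype whose trolling
  probability is 0.6 or 0.2 according to whether the parent's label
  disagrees with the user's own last label.  The two responses cancel
  in the input marginal, so the output process alone is i.i.d.
  Bernoulli(0.4) (one causal state) while the input-conditional model
  has two.  This archetype exists because the published transducer's
  input-marginal output chain is itself first-order Markov — a
  self-driven fit legitimately finds its two states — so a population
  in which most users look memoryless self-driven yet multi-state
  social-induced, the observed population's signature, cannot be
  produced from the published fixtures alone.

Per-user individuality comes from jittering fixture probabilities on
the logit scale (s.d. `jitter`, default 0.02, clipped to [0.01, 0.99]);
the logit scale avoids boundary pile-up and keeps rows stochastic by
construction.  For `balanced_coupled` the jitter perturbs the (low,
high) response pair while preserving the marginal balance.  All
randomness derives from a single master seed via spawned generator
streams; the same configuration reproduces the cohort byte-for-byte.

What the generator does *not* emulate: real trolling labels come from a
noisy classifier, comment timing is ignored (as in the modelling it
feeds), parent labels are not i.i.d. in reality, and real users are not
drawn from four clean archetypes.  Passing recovery tests therefore
shows that the estimators recover the models they assume when those
models are true — not that the assumed models describe any particular
platform.

## Averaging across users

Hidden states are unlabeled, so models are aligned before averaging:
one model is the reference (the first by default, exposed as a
parameter), and each other model's states are matched to it by
minimizing the total Euclidean distance between next-symbol probability
vectors (machines) or concatenated input-conditional emission vectors
(transducers), via the Hungarian algorithm; among cost ties the
lexicographically smallest permutation is taken (resolved by
enumeration up to 7 states).  Destination structure is excluded from
the cost.  The aligned transition/emission probabilities are averaged
element-wise; destinations are set by majority vote with a per-edge
agreement fraction reported, and the result is labelled a structural
summary rather than a generative model whenever agreement is below 1 —
with near-equal feature vectors (e.g. a user whose non-troll and
transition states happen to jitter together) role swaps do occur.

## Cohort statistics

Correlations between C and E/h are computed after dropping users with
C = 0 (one-state models share no information between past and future)
and then users with any measure beyond 3 standard deviations of the
cohort mean; the 3-s.d. rule is a parameter (`outlier_sd`).  Group
contrasts use Welch's unequal-variance t-test with Welch–Satterthwaite
degrees of freedom; measure-by-state-count structure uses one-way
fixed-effects ANOVA.  Per-user L<sub>max</sub> is selected
independently for the machine and the transducer.  Per-user fitting
failures are recorded and skipped, never fatal.

## Problem sizes

Recovery experiments use 2×10⁵ symbols per run (the published
probabilities are recovered within ±0.005 at this size; the acceptance
tolerance is ±0.02) and 20 seeds.  Cohort-level tests use 200 users of
2×10⁴ symbols with the L<sub>max</sub> grid 1–3; the analysis drivers
use 60 users of 1–3×10⁴ symbols.  These sizes are the package's own
balance between estimator variance and turnaround; all of them are
parameters of the respective functions.

## Known limitations

* The published three-state machine's figure does not print every edge
  label; the fixture follows the stated topology constraints (troll
  entered only from transition, transition only from non-troll, all
  remaining mass returning to non-troll).  The source also reports two
  mutually inconsistent values for the troll-state benign-parent
  response (a 0.45/0.28 pair alongside 71%); the fixture adopts the
  percentage reading and the 0.45/0.28 pair remains unused.
* Plug-in block entropies are biased downward at window lengths close
  to log₂ of the sequence length; no correction is applied, so E/h
  values at large L<sub>max</sub> on short sequences are indicative
  only (a warning is attached).
* Averaging across models with differing topologies produces a
  structural summary, not a generative model; the code flags this
  rather than renormalizing it away.
* Alphabets are binary end to end; the containers would admit larger
  alphabets structurally, but no estimator here is tested beyond {0,1}.
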