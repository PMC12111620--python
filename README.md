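# causalstates

Minimal maximally predictive hidden-state models of binary behavior
sequences, built for studying **behavioral contagion** — here, online
trolling — as a dynamical process.

A user's comment history is reduced to a binary stream
X<sub>t</sub> ∈ {0, 1} (1 = trolling).  Two questions are asked of every
user:

* **Self-driven** — how much of the behavior is predictable from the
  user's own past, P(X<sub>t</sub> | X<sub>t−1</sub>, X<sub>t−2</sub>, …)?
* **Social-induced** — how much more is predictable once the label
  Y<sub>t</sub> of the parent comment being replied to is added,
  P(X<sub>t</sub> | past, Y<sub>t</sub>)?

The answers come from computational mechanics: the **ε-machine** (for
the self-driven view) and the **ε-transducer** (for the social-induced
view) are the unique minimal unifilar hidden-state models whose states
are equivalence classes of pasts with identical conditional futures.
They are estimated from data with the **CSSR** algorithm (Causal-State
Splitting Reconstruction): history suffixes up to length L<sub>max</sub>
are split into states whenever their empirical next-symbol distributions
differ by a two-sample chi-square test at level α (default 0.001), the
partition is determinized, and transient states are removed.
L<sub>max</sub> is chosen by train/test predictive log loss.

Each fitted model is summarized by the field's standard information
measures (all in bits):

* statistical (predictive) complexity **C = H[π]**, the entropy of the
  stationary distribution over causal states — the stored information an
  optimal predictor needs;
* predictable information (excess entropy) **E = 2H(L) − H(2L)**, from
  block entropies — what the past communicates to the future;
* entropy rate (remaining uncertainty) **h = (H(2L) − H(L))/L** — the
  irreducible per-symbol unpredictability.

Population stages mirror a cohort study: per-user fits, state-count and
L<sub>max</sub> histograms, C–E and C–h correlations (after dropping
C = 0 users and outliers), Welch tests contrasting the two model
families, and population-average machines built by aligning hidden
states across users with the Hungarian algorithm and averaging the
aligned transition matrices element-wise.

Because the original comment corpus is not redistributable, the package
ships a first-class synthetic-data module: the two- and three-state
average machines and the two-state transducer with their published
transition probabilities are built in as fixtures, and cohorts mixing
memoryless users with hidden-pattern and input-coupled users can be
generated reproducibly.

## Worked example

Simulate the printed three-state average machine and recover it:

```python
from causalstates import (
    fixture_machine_3state, simulate_machine, estimate_machine,
    statistical_complexity, machine_entropy_rate, empirical_E_h,
)
from causalstates.models import CSSRConfig, state_after_context

truth = fixture_machine_3state()
seq = simulate_machine(truth, 200_000, seed=1)

machine = estimate_machine(seq, CSSRConfig(alpha=0.001, lmax=3))
print("states:", machine.n_states)

troll = state_after_context(machine, seq, [1, 1])        # state after "11"
transition = state_after_context(machine, seq, [0, 1])   # state after "01"
print(f"troll self-stay:      {machine.next_symbol_dist(troll)[1]:.3f}")
print(f"transition -> troll:  {machine.next_symbol_dist(transition)[1]:.3f}")

E, h = empirical_E_h(seq, 3)
print(f"C = {statistical_complexity(machine):.3f} bits")
print(f"E = {E:.3f} bits, h = {h:.3f} bits/symbol")
```

Output:

```
states: 3
troll self-stay:      0.761
transition -> troll:  0.391
C = 1.435 bits
E = 0.156 bits, h = 0.884 bits/symbol
```

The reconstruction recovers the generator's three hidden states and its
transition probabilities (0.76 troll self-stay, 0.39 transition→troll)
to within sampling error; C is the entropy of the recovered stationary
state distribution, h matches the generator's entropy rate, and E stays
within C, as it must for a maximally predictive model.

## Analysis scripts

The `analysis/` drivers run the full study on synthetic cohorts and
write their tables under `results/`:

1. `01_simulate_cohort.py` — generate the cohort CSV + ground truth;
2. `02_recover_printed_machines.py` — parameter recovery of the printed
   average models across seeds;
3. `03_cohort_analysis.py` — per-user machine/transducer fits and the
   population comparisons (histograms, correlations, Welch tests);
4. `04_average_models.py` — Hungarian-aligned average of 35 re-estimated
   three-state machines, exported as JSON and DOT.

A `causalstates` command-line interface wraps the same library
(`generate`, `fit-machine`, `fit-transducer`, `measures`, `average`,
`cohort`, `report`).

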