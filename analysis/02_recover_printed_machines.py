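#!/usr/bin/env python
"""Recover the printed average models from their own simulations.

For each printed model — the two-state machine (troll self-stay 67%),
the three-state machine (troll self-stay 76%, transition-to-troll 39%)
and the two-state transducer (48 / 72 / 71% input-conditional responses)
— simulate 200,000 symbols and re-estimate with CSSR, over several
seeds.  Writes per-seed estimates and prints how tightly the printed
probabilities are recovered.
"""

from pathlib import Path

import pandas as pd

from causalstates.recovery import (
    three_state_recovery,
    transducer_recovery,
    two_state_recovery,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(n_seeds: int = 5) -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for seed in range(n_seeds):
        r3 = three_state_recovery(10_000 + seed)
        r2 = two_state_recovery(20_000 + seed)
        rt = transducer_recovery(30_000 + 2 * seed)
        rows.append(
            {
                "seed": seed,
                "m3_states": r3["n_states"],
                "m3_troll_stay": r3["troll_stay"],
                "m3_transition_to_troll": r3["transition_to_troll"],
                "m2_states": r2["n_states"],
                "m2_troll_stay": r2["troll_stay"],
                "t_states": rt["n_states"],
                "t_switch_1given1": rt["switch_on_troll_input"],
                "t_stay_1given1": rt["stay_troll_on_troll_input"],
                "t_stay_0given0": rt["stay_nontroll_on_benign_input"],
            }
        )
    df = pd.DataFrame(rows)
    out = RESULTS / "recovery.csv"
    df.to_csv(out, index=False)

    printed = {
        "m3_troll_stay": 0.76,
        "m3_transition_to_troll": 0.39,
        "m2_troll_stay": 0.67,
        "t_switch_1given1": 0.48,
        "t_stay_1given1": 0.72,
    }
    print(f"wrote per-seed estimates to {out}\n")
    for col, target in printed.items():
        worst = (df[col] - target).abs().max()
        print(
            f"{col}: printed {target:.2f}, recovered "
            f"{df[col].mean():.4f} +/- {df[col].std():.4f} "
            f"(worst deviation {worst:.4f})"
        )
    print(
        f"state counts recovered exactly in "
        f"{(df.m3_states == 3).sum()}/{len(df)} (3-state), "
        f"{(df.m2_states == 2).sum()}/{len(df)} (2-state), "
        f"{(df.t_states == 2).sum()}/{len(df)} (transducer) runs"
    )


if __name__ == "__main__":
    main()
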