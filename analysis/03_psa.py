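#!/usr/bin/env python
"""Probabilistic sensitivity analysis: 10,000 Monte-Carlo draws and the CEAC.

Every uncertain input is sampled from its published distribution family
(gamma costs, beta probabilities/utilities, lognormal hazard ratios,
uniform discount rate); both strategies are re-evaluated per draw.
Writes the paired incremental samples, the acceptability curve and a
summary under results/.
"""

import json
from pathlib import Path

import pandas as pd

from hcc_cea.analysis import run_psa
from hcc_cea.parameters import load_baseline

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2021
N_ITER = 10_000


def main() -> None:
    OUT.mkdir(exist_ok=True)
    ps = load_baseline()
    res = run_psa(ps, n_iter=N_ITER, seed=SEED)

    pd.DataFrame(
        {"delta_cost": res.delta_cost, "delta_qalys": res.delta_qalys}
    ).to_csv(OUT / "psa_samples.csv", index=False)
    res.ceac.to_csv(OUT / "ceac.csv", index=False)
    (OUT / "psa_summary.json").write_text(json.dumps(res.summary(), indent=2))

    s = res.summary()
    print(f"PSA over {N_ITER:,} draws (seed {SEED}):")
    print(
        f"  mean incremental cost  ${s['mean_delta_cost']:,.0f}, "
        f"mean incremental QALYs {s['mean_delta_qalys']:.3f}"
    )
    print(
        f"  P(FOLFOX-HAIC cost-effective at ${res.wtp:,.0f}/QALY) "
        f"= {res.prob_cost_effective:.2%}"
    )


if __name__ == "__main__":
    main()
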