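"""Generate the synthetic study cohorts.

Two training batches (10 normal + 10 disease; 5 normal + 10 disease) with a
per-gene batch offset on the second, plus an independent validation cohort
(8 normal + 9 disease), all from the same Gaussian log2-intensity model with
5 planted markers (3 up, 2 down) at effect size 1.5 log2 units.

Writes tab-separated expression matrices and sample sheets under
results/analysis/sim/.
"""

import json
import sys
from pathlib import Path

from avcdiag.synthetic import simulate, simulate_validation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/analysis/sim")
OUT.mkdir(parents=True, exist_ok=True)

mats, sheet, truth = simulate(g_total=2000, n_up=3, n_down=2, effect=1.5, seed=SEED)
for i, m in enumerate(mats, start=1):
    m.data.to_csv(OUT / f"batch{i}_expression.tsv", sep="\t", index_label="gene")
sheet.table.to_csv(OUT / "samples.csv", index=False)

vm, vs = simulate_validation(truth, seed=SEED + 10_000)
vm.data.to_csv(OUT / "validation_expression.tsv", sep="\t", index_label="gene")
vs.table.to_csv(OUT / "validation_samples.csv", index=False)

(OUT / "truth.json").write_text(
    json.dumps(
        {
            "planted_up": truth.planted_up,
            "planted_down": truth.planted_down,
            "effect": truth.effect,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
        },
        indent=1,
    )
)

print(f"seed {SEED}: wrote 2 training batches (20 + 15 samples), "
      f"validation cohort (17 samples), planted markers "
      f"{truth.planted_up + truth.planted_down} -> {OUT}")
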