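"""Generate the default synthetic caged-biomonitoring study.

Writes the raw study artifacts (contaminant panel with detection limits,
per-site temperature readings, metabolite matrix, planted ground truth)
under results/study/.
"""

import argparse
from pathlib import Path

from cecselect import SimulationConfig, simulate_study
from cecselect import io as cio

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out", type=Path, default=Path("results/study"))
args = parser.parse_args()

cfg = SimulationConfig(seed=args.seed)
panel, matrix, truth = simulate_study(cfg)
args.out.mkdir(parents=True, exist_ok=True)
cio.write_contaminant_table(panel, args.out / "panel.csv",
                            temperature_path=args.out / "temperatures.csv")
cio.write_metabolite_matrix(matrix, args.out / "metabolites.csv")
cio.write_json(truth.to_dict(), args.out / "truth.json")

print(f"{cfg.n_sites} sites x {cfg.n_events_per_site} events x "
      f"{cfg.n_analytes} analytes; {panel.n_censored} records below the "
      f"detection limit")
print(f"{matrix.values.shape[0]} animals x {matrix.values.shape[1]} "
      f"metabolites; planted: {len(truth.active_contaminants)} active "
      f"contaminants, {len(truth.responsive_metabolites)} responsive "
      f"metabolites")
print(f"wrote {args.out}/panel.csv, temperatures.csv, metabolites.csv, truth.json")
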