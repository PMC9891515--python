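"""Select the contaminants that significantly covary with metabolites.

Backward elimination: responses with CV-ANOVA p > alpha are removed
simultaneously each iteration until none qualifies (temperature is kept by
force).  Every excluded contaminant is then offered back one at a time and
re-admitted only if p < alpha AND the pooled Q2Cum strictly increases.  The
ranked table lists the retained responses by Q2Y, strongest first.
"""

import argparse
from pathlib import Path

import pandas as pd

from cecselect import select_contaminants, TEMPERATURE_RESPONSE
from cecselect import io as cio

parser = argparse.ArgumentParser()
parser.add_argument("--screen", type=Path, default=Path("results/screen"))
parser.add_argument("--pre", type=Path, default=Path("results/preprocess"))
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--folds", type=int, default=7)
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out", type=Path, default=Path("results/selection"))
args = parser.parse_args()

xm = cio.read_metabolite_matrix(args.screen / "X_screened.csv")
y = pd.read_csv(args.pre / "Y.csv", index_col=0)

trace = select_contaminants(xm.values, y, alpha=args.alpha,
                            components="auto", folds=args.folds,
                            seed=args.seed, site_of=xm.site_of.to_numpy(),
                            force_keep=(TEMPERATURE_RESPONSE,))

args.out.mkdir(parents=True, exist_ok=True)
cio.write_json(trace.to_dict(), args.out / "trace.json")
trace.ranked.to_csv(args.out / "ranked.tsv", sep="\t")

n_removed = sum(len(s.removed) for s in trace.iterations)
n_back = sum(s.accepted for s in trace.reintroduction)
final = [r for r in trace.final["responses"] if r != TEMPERATURE_RESPONSE]
print(f"elimination removed {n_removed} of {y.shape[1] - 1} contaminants "
      f"over {len(trace.iterations)} iteration(s); re-introduction "
      f"re-admitted {n_back}")
print(f"final model: water temperature and {len(final)} contaminants; "
      f"Q2Cum {trace.final['q2cum']:.3f} "
      f"(vs {trace.global_q2cum:.3f} for the global model)")
top = trace.ranked.head(5)
print("strongest relationships (Q2Y): "
      + ", ".join(f"{r} ({v:.3f})" for r, v in top["Q2Y"].items()))
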