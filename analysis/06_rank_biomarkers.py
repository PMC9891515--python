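"""Rank metabolite biomarkers of the final model by VIP.

Variable importance in projection summarizes each metabolite's contribution
to the explained response variance across components (mean squared VIP is 1
by construction).  Metabolites with VIP statistically greater than 1
(delete-one-fold jackknife, one-sided p < 0.05) are the biomarker
candidates; their loading signs on components 1 and 2 give the direction of
association.
"""

import argparse
from pathlib import Path

import pandas as pd

from cecselect import vip_significance
from cecselect import io as cio

parser = argparse.ArgumentParser()
parser.add_argument("--screen", type=Path, default=Path("results/screen"))
parser.add_argument("--pre", type=Path, default=Path("results/preprocess"))
parser.add_argument("--selection", type=Path, default=Path("results/selection"))
parser.add_argument("--folds", type=int, default=7)
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out", type=Path, default=Path("results/biomarkers"))
args = parser.parse_args()

xm = cio.read_metabolite_matrix(args.screen / "X_screened.csv")
y = pd.read_csv(args.pre / "Y.csv", index_col=0)
trace = cio.read_json(args.selection / "trace.json")
final = trace["final"]["responses"]
a = trace["final"]["n_components"]

res = vip_significance(xm.values, y[final], a, folds=args.folds,
                       seed=args.seed, site_of=xm.site_of.to_numpy())

table = pd.DataFrame({"VIP": res.vip, "jackknife_se": res.jackknife_se,
                      "p": res.p}).join(res.loading_sign)
table = table.sort_values("VIP", ascending=False)
args.out.mkdir(parents=True, exist_ok=True)
table.to_csv(args.out / "vip.tsv", sep="\t")

marker = table[(table["VIP"] >= 1.0) & (table["p"] < 0.05)]
print(f"{len(marker)} of {len(table)} screened metabolites have VIP >= 1 "
      f"with VIP significantly greater than 1 (p < 0.05)")
for name, row in marker.head(10).iterrows():
    print(f"  {name}: VIP {row['VIP']:.2f}, p {row['p']:.4f}, "
          f"component-1 loading {row.get('component1', '?')}")
print(f"full table in {args.out}/vip.tsv")
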