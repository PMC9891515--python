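"""Fit and cross-validate the global multi-response PLS model.

The screened metabolites are the explanatory block X; per-site contaminant
maxima plus water temperature are the responses Y.  The number of latent
components is chosen by cross-validated Q2Cum gain; the fitted model's
per-component variance shares and the cross-validated Q2 are reported.
"""

import argparse
from pathlib import Path

import pandas as pd

from cecselect import choose_components, cross_validate, fit_pls
from cecselect import io as cio

parser = argparse.ArgumentParser()
parser.add_argument("--screen", type=Path, default=Path("results/screen"))
parser.add_argument("--pre", type=Path, default=Path("results/preprocess"))
parser.add_argument("--folds", type=int, default=7)
parser.add_argument("--seed", type=int, default=17)
parser.add_argument("--out", type=Path, default=Path("results/model"))
args = parser.parse_args()

xm = cio.read_metabolite_matrix(args.screen / "X_screened.csv")
y = pd.read_csv(args.pre / "Y.csv", index_col=0)
sites = xm.site_of.to_numpy()

a = choose_components(xm.values, y, folds=args.folds, seed=args.seed,
                      site_of=sites)
model = fit_pls(xm.values, y, a)
cv = cross_validate(xm.values, y, a, folds=args.folds, seed=args.seed,
                    site_of=sites)

args.out.mkdir(parents=True, exist_ok=True)
cio.write_json(model.to_dict(), args.out / "model.json")
cio.write_json({"n_components": a, "q2cum": cv.q2cum,
                "q2y": dict(zip(cv.y_names, cv.q2y.tolist())),
                "r2x_per_component": model.r2x,
                "r2y_per_component": model.r2y}, args.out / "cv_global.json")

pct = lambda v: f"{100 * v:.1f}%"
print(f"global model: {a} components over {xm.values.shape[1]} metabolites "
      f"and {y.shape[1]} responses")
print("variance explained in X per component: "
      + ", ".join(pct(v) for v in model.r2x))
print("variance explained in Y per component: "
      + ", ".join(pct(v) for v in model.r2y))
print(f"cross-validated Q2Cum of the global model: {cv.q2cum:.3f}")
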