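"""Screen metabolites for site differences.

One-way ANOVA per metabolite across the four deployment sites; metabolites
with omnibus p < 0.05 form the explanatory block of the PLS model.  The
letter-pair table renders the significant Tukey-Kramer site pairs: sites
sharing a lowercase letter differ significantly.
"""

import argparse
from pathlib import Path

from cecselect import anova_screen, site_difference_table
from cecselect import io as cio

parser = argparse.ArgumentParser()
parser.add_argument("--pre", type=Path, default=Path("results/preprocess"))
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--out", type=Path, default=Path("results/screen"))
args = parser.parse_args()

matrix = cio.read_metabolite_matrix(args.pre / "X_full.csv")
matrix.normalized = True   # written post-normalization by 02_preprocess

result = anova_screen(matrix, alpha=args.alpha)
args.out.mkdir(parents=True, exist_ok=True)
cio.write_json({"alpha": args.alpha, "selected": result.selected,
                "p": result.table["p"].to_dict()}, args.out / "screen.json")
site_difference_table(result).to_csv(args.out / "site_differences.tsv",
                                     sep="\t", index=False)
cio.write_metabolite_matrix(
    matrix.copy(values=matrix.values[result.selected]),
    args.out / "X_screened.csv")

n = len(result.table)
print(f"of {n} metabolites, {n - len(result.selected)} were not "
      f"significantly different across sites (p >= {args.alpha}); "
      f"{len(result.selected)} screened in")
print(f"letter-pair table written to {args.out}/site_differences.tsv")
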