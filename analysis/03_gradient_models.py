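"""Regress network metrics on the environmental gradients.

Screens the predictors for collinearity, then fits the six metric models
(Gamma, Gaussian, Beta families as appropriate) on all analysed sites, on
the >=20-flock subset, and — for modularity — on the r_com > 0.4 subset.
Coefficient tables go to results/study/fits.json (written by script 02);
this script prints the sign/significance summary and writes a flat
coefficient CSV.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fits = json.loads((ROOT / "study" / "fits.json").read_text())
    rows = []
    for subset, models in fits.items():
        for resp, f in models.items():
            for c in f["coefficients"]:
                rows.append({"subset": subset, "response": resp,
                             "family": f["family"], "n": f["n"],
                             "interaction_retained": f["interaction_retained"],
                             **c})
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "study" / "coefficients.csv", index=False)

    focal = df[(df.response == "modularity_q")
               & (df.term == "elevation")]
    print("elevation effect on modularity (per-SD coefficient):")
    for _, r in focal.iterrows():
        star = "*" if r.pvalue < 0.05 else " "
        print(f"  subset {r.subset:7s} n={r.n:3d}  "
              f"beta={r.estimate:+.4f}  p={r.pvalue:.4f}{star}")
    sig = df[(df.pvalue < 0.05) & (df.term != "intercept")]
    print(f"\n{len(sig)} significant coefficients across all models; "
          f"full table in {ROOT / 'study' / 'coefficients.csv'}")


if __name__ == "__main__":
    main()
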