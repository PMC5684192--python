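"""Fit the constant-fraction TEMRA composition model.

Reads the simulated donor composition table and fits the single constant
c — the absolute frequency of GPR56-Perforin- TEMRA cells among CD4
T cells — by least squares on the within-TEMRA proportion scale.  The
model predicts p_dn = min(1, c / f_temra): donors with few TEMRA cells
have mostly double-negative TEMRA, donors with an expanded compartment
mostly GPR56+/Perforin+ cells.  Writes the fit JSON, the per-donor
observed-vs-predicted table and the sampled model curve.
"""

import json
from pathlib import Path

from temra_repertoire import (
    composition_report,
    fit_constant_fraction,
    read_composition_table,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    obs = read_composition_table(ROOT / "cohort" / "composition.tsv")
    fit = fit_constant_fraction(obs, fit_scale="proportion")
    donors, curve = composition_report(obs, fit)

    with open(ROOT / "composition_fit.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
    donors.to_csv(ROOT / "composition_donors.tsv", sep="\t", index=False)
    curve.to_csv(ROOT / "composition_curve.tsv", sep="\t", index=False)

    print(f"fitted constant double-negative fraction "
          f"c = {fit.c_hat:.4%} over {fit.n_donors} donors "
          f"(generator truth 0.8%; RSS {fit.residual_sum_of_squares:.4g})")
    print(donors[["donor_id", "f_temra", "p_dn_within",
                  "p_dn_predicted"]].to_string(index=False))


if __name__ == "__main__":
    main()
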