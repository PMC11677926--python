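#!/usr/bin/env python
"""Generate the synthetic study systems used by the downstream analyses.

Writes the stylised OD-stretch bands (bulk HDO plus diglycine-, NAGMA- and
DMSO-affected water), a binary molality series for each solute, and the
ternary mixtures for both peptide–DMSO regimes, all as two-column CSV with
a ground-truth JSON next to them.
"""

import argparse
import json
from pathlib import Path

from hdospec.bands import band_parameters
from hdospec.spectra import write_spectrum
from hdospec.synth import make_band, make_binary_series, make_grid, \
    make_ternary_series, reference_bands

MOLALITIES = [0.1, 0.2, 0.3, 0.4, 0.5]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path,
                    default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    grid = make_grid()
    bands = reference_bands(grid)
    truth = {"seed": args.seed, "molalities": MOLALITIES, "bands": {}}
    for name, s in bands.items():
        write_spectrum(s, out / f"band_{name}.csv")
        p = band_parameters(s, (2200.0, 2750.0))
        truth["bands"][name] = {"nu_max": round(p.nu_max, 2),
                                "nu_gravity": round(p.nu_gravity, 2)}
        print(f"band {name:22s} max {p.nu_max:7.1f}  gravity {p.nu_gravity:7.1f} cm-1")

    # binary molality series per solute (0.3% additive noise default)
    for solute, n_true in (("diglycine", 9.0), ("nagma", 6.0), ("dmso", 6.0)):
        series = make_binary_series(bands["bulk"], bands[solute], n_true,
                                    MOLALITIES, seed=args.seed)
        for p in series:
            write_spectrum(p.spectrum,
                           out / f"series_{solute}_m{p.molality:.1f}.csv")
        truth[f"N_{solute}"] = n_true

    # ternary regimes: excess perturbation (diglycine-like, +2 changed
    # waters) and shell overlap (NAGMA-like, 0.7 shared waters)
    changed = make_band(2350.0, 60.0, 0.0, 1.0, grid)
    write_spectrum(changed, out / "band_changed_injected.csv")
    for rho_fix in make_ternary_series(bands["diglycine"], bands["dmso"],
                                       changed, 2.0, 3.0, 2.0,
                                       (1.0, 2.0, 3.0, 4.0, 5.0),
                                       seed=args.seed):
        write_spectrum(rho_fix.eps_exp,
                       out / f"ternary_excess_rho{rho_fix.molar_ratio:.0f}.csv")
    truth["ternary_excess"] = {"N_A": 2.0, "N_B_per_ratio": 3.0,
                               "N_changed": 2.0}
    for rho_fix in make_ternary_series(bands["nagma"], bands["dmso"], None,
                                       4.0 - 0.7, 6.0, 0.0, (1.0,),
                                       seed=args.seed):
        write_spectrum(rho_fix.eps_exp, out / "ternary_overlap_rho1.csv")
    truth["ternary_overlap"] = {"N_A_effective": 3.3, "N_B": 6.0,
                                "N_theor": 10.0}

    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    print(f"\nwrote synthetic systems + ground truth to {out}")


if __name__ == "__main__":
    main()
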