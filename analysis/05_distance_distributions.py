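#!/usr/bin/env python
"""Band parameters and O⋯O distance distributions of the study bands.

For every stylised affected-water band: band maximum, gravity center, and
the moments of the distance distribution P(R_OO) obtained through the
empirical ν_OD ↔ R_OO correlation.  Also writes the ΔP(R_OO) curve of the
injected changed-affected component against the peptide-affected water —
the strengthening/weakening diagnostic.
"""

import argparse
import csv
from pathlib import Path

import numpy as np

from hdospec.bands import band_parameters, distance_distribution, \
    distribution_difference
from hdospec.synth import make_band, make_grid, reference_bands

WINDOW = (2200.0, 2750.0)
R_RANGE = (2.58, 3.20)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1,
                    help="accepted for interface symmetry; this stage is "
                         "deterministic")
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    grid = make_grid()
    bands = reference_bands(grid)
    bands["changed_injected"] = make_band(2350.0, 60.0, 0.0, 1.0, grid)

    rows, dists = [], {}
    for name, s in bands.items():
        p = band_parameters(s, WINDOW)
        d = distance_distribution(s, R_RANGE)
        dists[name] = d
        rows.append({
            "band": name,
            "nu_max_cm1": round(p.nu_max, 1),
            "nu_gravity_cm1": round(p.nu_gravity, 1),
            "r_oo_max_A": round(d.r_max, 3),
            "r_oo_gravity_A": round(d.r_gravity, 3),
        })
        print(f"{name:22s} nu_max {p.nu_max:7.1f}  nu_g {p.nu_gravity:7.1f}  "
              f"R_OOo {d.r_max:.3f}  R_OOg {d.r_gravity:.3f}")

    path = args.out_dir / "table_band_parameters.csv"
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)

    r, dp = distribution_difference(dists["changed_injected"],
                                    dists["diglycine"])
    with (args.out_dir / "delta_p_changed_vs_peptide.csv").open("w") as fh:
        fh.write("# R_OO/A,delta_P\n")
        for ri, di in zip(r, dp):
            fh.write(f"{ri:.4f},{di:.6g}\n")
    # the crossing between the positive (short-R) and negative (long-R) lobes
    lo, hi = sorted((int(np.argmax(dp)), int(np.argmin(dp))))
    crossing = r[lo + int(np.argmin(np.abs(dp[lo:hi + 1])))]
    print(f"\nΔP(changed − peptide): positive below {crossing:.2f} Å, negative "
          "above -> the changed-affected water sits at shorter O...O "
          "distances (stronger hydrogen bonds) than the peptide hydration "
          "shell")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
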