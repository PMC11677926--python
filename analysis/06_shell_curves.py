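#!/usr/bin/env python
"""Hydration-cluster O⋯O interaction curves.

Builds toy hydration shells with known distance multisets: a uniform
single-population shell, the same shell rigidly compressed by 0.05 Å
(emulating the strengthening seen around a peptide in the presence of a
co-solute), and a bimodal shell with tight and loose hydrogen-bond
populations.  Writes the normalised interaction curves and reports the
downward shift and the inflection diagnostic.
"""

import argparse
import csv
from pathlib import Path

import numpy as np

from hdospec.shells import curve_inflection, first_shell_oxygens, \
    normalized_interaction_curve, oo_distances
from hdospec.synth import make_toy_shell


def curve_from_targets(targets, seed):
    model = make_toy_shell(2 * len(targets), oo_target_distances=targets,
                           seed=seed)
    oxy = first_shell_oxygens(model)
    return normalized_interaction_curve(oo_distances(model, oxy, (2.40, 3.05)))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    uniform = list(np.round(np.linspace(2.67, 2.97, 12), 3))
    compressed = [round(d - 0.05, 3) for d in uniform]
    bimodal = (list(np.round(np.linspace(2.70, 2.80, 8), 3))
               + list(np.round(np.linspace(2.85, 3.00, 4), 3)))

    curves = {
        "uniform": curve_from_targets(uniform, args.seed),
        "compressed": curve_from_targets(compressed, args.seed + 1),
        "bimodal": curve_from_targets(bimodal, args.seed + 2),
    }

    path = args.out_dir / "interaction_curves.csv"
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["shell", "r_oo_A", "normalized_index"])
        for name, c in curves.items():
            for d, x in zip(c.sorted_distances, c.normalized_index):
                writer.writerow([name, f"{d:.4f}", f"{x:.4f}"])

    below = np.all(curves["compressed"].sorted_distances
                   < curves["uniform"].sorted_distances)
    print(f"compressed shell lies everywhere below the reference curve: "
          f"{bool(below)} (shorter O...O -> stronger hydrogen bonds)")
    pos, mag = curve_inflection(curves["bimodal"])
    print(f"bimodal shell: inflection at normalised index {pos:.2f} "
          f"(second-difference peak {mag:.3f} Å) separating tight "
          "2.70–2.80 Å and loose 2.85–3.00 Å populations")
    pos_u, mag_u = curve_inflection(curves["uniform"])
    print(f"uniform shell second-difference peak {mag_u:.3f} Å -> no break")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
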