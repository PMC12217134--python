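"""Ligament CSA profiles on the phantom specimen.

Aligns each phantom ligament to its longitudinal axis, slices it at the
rat increment (0.1 mm), and compares the recovered midsubstance CSA to
the generator's analytic value. Writes per-tissue slice profiles and a
summary table under results/ligaments/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

import rodentmorph as rm
from rodentmorph.types import MorphometryConfig


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--phantoms", type=Path, default=Path("scratch/phantoms"))
    parser.add_argument("--out", type=Path, default=Path("results/ligaments"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    cfg = MorphometryConfig(species="rat")

    rows = []
    for stl in sorted(args.phantoms.glob("*.stl")):
        if "meniscus" in stl.name:
            continue
        tissue = stl.stem
        mesh = rm.read_stl(stl, name=tissue)
        cloud = rm.mesh_to_pointcloud(mesh)
        aligned, _ = rm.align_longitudinal(cloud)
        profile = rm.slice_profile(aligned, cfg)
        pd.DataFrame(
            {
                "z_lo": [s.z_lo for s in profile.sections],
                "z_hi": [s.z_hi for s in profile.sections],
                "area_mm2": profile.areas,
            }
        ).to_csv(args.out / f"{tissue}_profile.csv", index=False)
        truth = json.loads((args.phantoms / f"{tissue}_truth.json").read_text())
        target = truth["values"]["midsubstance_csa_mm2"]
        err = 100 * abs(profile.midsubstance_csa - target) / target
        rows.append(
            {
                "tissue": tissue,
                "n_sections": profile.n_sections,
                "midsubstance_csa_mm2": profile.midsubstance_csa,
                "analytic_csa_mm2": target,
                "error_pct": err,
            }
        )
        print(f"{tissue}: measured {profile.midsubstance_csa:.4f} mm^2, "
              f"analytic {target:.4f} mm^2 ({err:.2f}% off)")

    pd.DataFrame(rows).to_csv(args.out / "summary.csv", index=False)
    print(f"\nwrote {args.out}/summary.csv; midsubstance CSA recovered within "
          f"{max(r['error_pct'] for r in rows):.2f}% despite the flared insertions")


if __name__ == "__main__":
    main()
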