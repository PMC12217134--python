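"""Generate the synthetic specimen set used by the downstream analyses.

Writes four tube ligaments (rat-scale radii), medial/lateral C-shaped
menisci with 1.2x horns, and an elliptical tibial footprint mask, each
with its analytic ground-truth manifest, under results/phantoms/.
"""

import argparse
from pathlib import Path

import numpy as np

import rodentmorph as rm

LIGAMENT_RADII = {"ACL": 0.29, "PCL": 0.33, "MCL": 0.23, "LCL": 0.28}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("scratch/phantoms"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for tissue, r in LIGAMENT_RADII.items():
        spec = rm.LigamentPhantomSpec(
            length=2.0,
            radius_profile={"kind": "flared", "r_mid": r, "r_end": 1.3 * r,
                            "flare_fraction": 0.2},
            cross_section={"kind": "circle", "r": r},
            seed=args.seed,
        )
        mesh, manifest = rm.make_ligament_phantom(spec)
        rm.write_stl(mesh, args.out / f"{tissue}.stl")
        manifest.to_json(args.out / f"{tissue}_truth.json")
        print(f"{tissue}: tube r={r} mm, analytic midsubstance CSA "
              f"{manifest.values['midsubstance_csa_mm2']:.4f} mm^2")

    for side in ("medial", "lateral"):
        spec = rm.MeniscusPhantomSpec(side=side, horn_scale=1.2, seed=args.seed)
        mesh, manifest = rm.make_meniscus_phantom(spec)
        rm.write_stl(mesh, args.out / f"{side}_meniscus.stl")
        manifest.to_json(args.out / f"{side}_meniscus_truth.json")
        print(f"{side} meniscus: central {manifest.values['central_width_mm']:.2f} x "
              f"{manifest.values['central_height_mm']:.2f} mm, horn width "
              f"{manifest.values['horn_width_mm']:.2f} mm")

    vol, manifest = rm.make_footprint_mask(
        {"kind": "ellipse", "a": 3.0, "b": 2.0}, voxel_size=0.1, seed=args.seed
    )
    rm.geometry_io.write_label_volume(vol, args.out / "footprint.nii.gz")
    manifest.to_json(args.out / "footprint_truth.json")
    print(f"footprint: {manifest.values['area_mm2']:.2f} mm^2 "
          f"(analytic {np.pi * 6:.2f})")


if __name__ == "__main__":
    main()
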