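"""Cohort statistics on a synthetic cohort drawn at the published effect
sizes.

Simulates 10 knees per species with ligament CSA and meniscal widths/
heights drawn around the published means and SDs, then runs the full
rank-based analysis stage: Kruskal-Wallis + Tukey-on-ranks for ligament
CSA, ART two-way tests for normalized CSA (species x ligament) and
meniscal geometry (side x region), Bonferroni-corrected post hocs.
Writes the report CSVs under results/cohort/.
"""

import argparse
from pathlib import Path

import rodentmorph as rm
from rodentmorph import reference_values as ref
from rodentmorph.pipeline import run_cohort
from rodentmorph.synthetic import make_cohort_table


def _tables(seed):
    tables = []
    for sp in ("rat", "mouse"):
        csa, _ = make_cohort_table(ref.ligament_cohort_effects(sp), 0.05, 10, seed=seed)
        csa["measure"] = "midsubstance_csa"
        csa["units"] = "mm^2"
        tables.append(csa)
        norm = csa.copy()
        norm["value"] = 100 * norm["value"] / ref.FOOTPRINT[sp][0]
        norm["measure"] = "normalized_csa"
        norm["units"] = "%"
        tables.append(norm)
        for dim in ("width", "height"):
            t, _ = make_cohort_table(
                ref.meniscus_cohort_effects(sp, dim), 0.1, 10, seed=seed + 1
            )
            t["tissue"] = t["side"] + "_meniscus"
            t["measure"] = t["region"] + "_" + dim
            t["units"] = "mm"
            tables.append(t.drop(columns=["side", "region"]))
    return tables


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    report = run_cohort(_tables(args.seed))
    for name, frame in report.items():
        frame.to_csv(args.out / f"{name}.csv", index=False)

    omnibus = report["omnibus"]
    print(omnibus.to_string(index=False))
    kw = omnibus[omnibus["test"] == "kruskal_wallis"]
    print(f"\nligament-type effect detected in {int((kw['p'] < 0.05).sum())}/2 "
          "species at the published effect sizes")
    region = omnibus[omnibus["comparison"].str.contains("width: region")]
    print(f"meniscal width region effect: p = "
          f"{', '.join(f'{p:.2g}' for p in region['p'])} (regionally dependent "
          "width, as the generator encodes)")


if __name__ == "__main__":
    main()
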