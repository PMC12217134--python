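"""Published reference cohort statistics for rodent knee morphometry.

Mean +/- SD ligament CSA, normalized CSA, regional meniscal widths and
heights, and tibial plateau footprints reported for 20-week female Long
Evans rats (n = 10 knees) and 12-week female C57BL/6 mice (n = 10 knees)
imaged at 9.4T. These printed summary statistics serve two roles: inputs
for the worked normalization/averaging arithmetic, and realistic effect
sizes for the synthetic cohort generator.
"""

from __future__ import annotations

LIGAMENTS = ("ACL", "PCL", "MCL", "LCL")
MENISCUS_REGIONS = ("anterior_horn", "central", "posterior_horn")

N_KNEES = {"rat": 10, "mouse": 10}

#: ligament CSA, mm^2 (mean, sd)
LIGAMENT_CSA = {
    "rat": {
        "ACL": (0.26, 0.04),
        "PCL": (0.35, 0.08),
        "MCL": (0.17, 0.03),
        "LCL": (0.24, 0.09),
    },
    "mouse": {
        "ACL": (0.029, 0.007),
        "PCL": (0.041, 0.015),
        "MCL": (0.031, 0.007),
        "LCL": (0.054, 0.017),
    },
}

#: normalized ligament CSA, % of tibial plateau footprint (mean, sd)
NORMALIZED_CSA = {
    "rat": {
        "ACL": (0.78, 0.11),
        "PCL": (1.10, 0.20),
        "MCL": (0.50, 0.10),
        "LCL": (0.71, 0.30),
    },
    "mouse": {
        "ACL": (0.52, 0.15),
        "PCL": (0.71, 0.30),
        "MCL": (0.54, 0.14),
        "LCL": (0.95, 0.30),
    },
}

#: tibial plateau footprint, mm^2 (mean, sd)
FOOTPRINT = {"rat": (33.35, 2.80), "mouse": (5.67, 0.50)}

#: meniscal widths, mm, keyed [species][side][region] -> (mean, sd)
MENISCAL_WIDTH = {
    "rat": {
        "medial": {
            "anterior_horn": (1.35, 0.2),
            "central": (0.62, 0.11),
            "posterior_horn": (0.97, 0.15),
        },
        "lateral": {
            "anterior_horn": (1.00, 0.2),
            "central": (0.79, 0.16),
            "posterior_horn": (0.97, 0.15),
        },
    },
    "mouse": {
        "medial": {
            "anterior_horn": (0.57, 0.17),
            "central": (0.36, 0.07),
            "posterior_horn": (0.48, 0.11),
        },
        "lateral": {
            "anterior_horn": (0.42, 0.11),
            "central": (0.35, 0.06),
            "posterior_horn": (0.33, 0.18),
        },
    },
}

#: meniscal heights, mm, keyed [species][side][region] -> (mean, sd)
MENISCAL_HEIGHT = {
    "rat": {
        "medial": {
            "anterior_horn": (0.89, 0.15),
            "central": (0.81, 0.12),
            "posterior_horn": (0.88, 0.17),
        },
        "lateral": {
            "anterior_horn": (0.75, 0.18),
            "central": (0.83, 0.15),
            "posterior_horn": (0.73, 0.14),
        },
    },
    "mouse": {
        "medial": {
            "anterior_horn": (0.31, 0.07),
            "central": (0.29, 0.06),
            "posterior_horn": (0.32, 0.06),
        },
        "lateral": {
            "anterior_horn": (0.27, 0.09),
            "central": (0.33, 0.06),
            "posterior_horn": (0.29, 0.05),
        },
    },
}

#: inter-rater intraclass correlation reported for the segmentation step
REPORTED_ICC = 0.79

#: scan voxel size, mm isotropic (also the default slab increment)
VOXEL_SIZE = {"rat": 0.1, "mouse": 0.05}


def ligament_cohort_effects(species: str):
    """Cohort-generator effect list for one species' ligament CSAs."""
    return [
        {"species": species, "tissue": lig, "mean": m, "sd": s}
        for lig, (m, s) in LIGAMENT_CSA[species].items()
    ]


def meniscus_cohort_effects(species: str, measure: str = "width"):
    """Cohort-generator effect list for one species' meniscal geometry."""
    table = MENISCAL_WIDTH if measure == "width" else MENISCAL_HEIGHT
    return [
        {
            "species": species,
            "side": side,
            "region": region,
            "mean": m,
            "sd": s,
        }
        for side, regions in table[species].items()
        for region, (m, s) in regions.items()
    ]
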