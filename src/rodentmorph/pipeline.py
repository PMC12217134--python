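"""End-to-end orchestration: per-specimen morphometry tables and cohort
statistics reports.

``run_specimen`` takes one knee's tissue files (STL per ligament and
meniscus, a footprint mask or area) and produces a tidy morphometry
table; ``run_cohort`` pools such tables and runs the rank-based analysis
stage (Kruskal-Wallis per species with post hoc comparisons for ligament
CSA, ART two-way tests for normalized CSA and meniscal geometry, and
agreement analyses when paired data are supplied).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import geometry_io, ligament, meniscus, stats
from .footprint import plateau_footprint
from .ligament import round_half_away
from .types import AnatomicFrame, MorphometryConfig, StatResult

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_specimen", "run_cohort", "stats_to_frame"]

LIGAMENT_TISSUES = ("ACL", "PCL", "MCL", "LCL")
MENISCUS_TISSUES = ("medial_meniscus", "lateral_meniscus")


@dataclass
class RunConfig:
    """One specimen's inputs and analysis settings.

    ``ligaments`` maps tissue name -> STL path; ``menisci`` maps tissue
    name -> (STL path, side, 3x3 anatomic rotation); ``footprint`` is a
    label-volume path or a pre-measured area in mm^2. Species presets fix
    the slab increment (rat 0.1 mm, mouse 0.05 mm) unless overridden.
    """

    specimen: str
    species: str = "rat"
    ligaments: Dict[str, str] = field(default_factory=dict)
    menisci: Dict[str, tuple] = field(default_factory=dict)
    footprint: Optional[object] = None
    increment: Optional[float] = None
    midsubstance_fraction: float = 0.50
    csa_method: str = "hull"
    meniscus_mode: str = "max"
    n_stations: int = 10
    slice_thickness: Optional[float] = None
    seed: int = 0

    def morph_config(self) -> MorphometryConfig:
        return MorphometryConfig(
            species=self.species,
            increment=self.increment,
            midsubstance_fraction=self.midsubstance_fraction,
            csa_method=self.csa_method,
        )

    def provenance(self) -> dict:
        payload = {
            "specimen": self.specimen,
            "species": self.species,
            "increment": self.increment,
            "midsubstance_fraction": self.midsubstance_fraction,
            "csa_method": self.csa_method,
            "meniscus_mode": self.meniscus_mode,
            "n_stations": self.n_stations,
            "seed": self.seed,
        }
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]
        return {**payload, "config_hash": digest}


def _footprint_area(cfg: RunConfig) -> Optional[float]:
    if cfg.footprint is None:
        return None
    if isinstance(cfg.footprint, (int, float)):
        return float(cfg.footprint)
    vol = geometry_io.read_label_volume(cfg.footprint)
    return plateau_footprint(vol).area


def run_specimen(cfg: RunConfig) -> pd.DataFrame:
    """Morphometry table for one specimen.

    Rows are (specimen, species, tissue, measure, value, units): one
    midsubstance-CSA row per ligament (plus a normalized-CSA row when a
    footprint is available) and width/height rows per meniscal region.
    Per-tissue failures are logged and skipped; the run fails only when
    every tissue fails.
    """
    mcfg = cfg.morph_config()
    footprint_area = _footprint_area(cfg)
    rows: List[dict] = []
    failures: List[str] = []

    for tissue, path in cfg.ligaments.items():
        try:
            mesh = geometry_io.read_stl(path, name=tissue)
            cloud = geometry_io.mesh_to_pointcloud(mesh)
            aligned, frame = ligament.align_longitudinal(cloud)
            aligned_mesh = None
            if mcfg.csa_method == "plane_intersection":
                from .types import TriangleMesh

                aligned_mesh = TriangleMesh(
                    vertices=frame.apply(mesh.vertices), faces=mesh.faces, name=tissue
                )
            profile = ligament.slice_profile(aligned, mcfg, mesh=aligned_mesh)
            rows.append(
                _row(cfg, tissue, "midsubstance_csa", profile.midsubstance_csa, "mm^2")
            )
            if footprint_area is not None:
                rows.append(
                    _row(
                        cfg,
                        tissue,
                        "normalized_csa",
                        ligament.normalize_csa(profile.midsubstance_csa, footprint_area),
                        "%",
                    )
                )
        except Exception as exc:  # noqa: BLE001 - per-tissue degradation
            logger.warning("ligament %s failed: %s", tissue, exc)
            failures.append(tissue)

    for tissue, (path, side, rotation) in cfg.menisci.items():
        try:
            mesh = geometry_io.read_stl(path, name=tissue)
            frame = AnatomicFrame(rotation=np.asarray(rotation, dtype=float), side=side)
            cloud = meniscus.orient_meniscus(mesh, frame)
            thickness = cfg.slice_thickness or MorphometryConfig.SPECIES_INCREMENT[
                cfg.species
            ]
            for region_measure in meniscus.measure_regions(
                cloud,
                side=side,
                slice_thickness=thickness,
                n_stations=cfg.n_stations,
                mode=cfg.meniscus_mode,
            ):
                rows.append(
                    _row(
                        cfg,
                        tissue,
                        f"{region_measure.region}_width",
                        region_measure.width,
                        "mm",
                    )
                )
                rows.append(
                    _row(
                        cfg,
                        tissue,
                        f"{region_measure.region}_height",
                        region_measure.height,
                        "mm",
                    )
                )
        except Exception as exc:  # noqa: BLE001
            logger.warning("meniscus %s failed: %s", tissue, exc)
            failures.append(tissue)

    if footprint_area is not None:
        rows.append(_row(cfg, "tibia", "footprint_area", footprint_area, "mm^2"))

    n_tissues = len(cfg.ligaments) + len(cfg.menisci)
    if n_tissues > 0 and len(failures) == n_tissues:
        raise RuntimeError(f"all tissues failed: {failures}")
    table = pd.DataFrame(rows)
    table.attrs["provenance"] = cfg.provenance()
    return table


def _row(cfg: RunConfig, tissue: str, measure: str, value: float, units: str) -> dict:
    return {
        "specimen": cfg.specimen,
        "species": cfg.species,
        "tissue": tissue,
        "measure": measure,
        "value": float(value),
        "units": units,
    }


def stats_to_frame(results: Sequence[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into the report CSV layout."""
    rows = []
    for r in results:
        df = r.df
        if isinstance(df, (tuple, list)):
            df = ",".join(f"{d:g}" for d in df)
        rows.append(
            {
                "test": r.test_name,
                "comparison": r.label,
                "statistic": r.statistic,
                "df": df,
                "p": r.p_value,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)


def _summary_table(tidy: pd.DataFrame, by: List[str]) -> pd.DataFrame:
    grouped = tidy.groupby(by, observed=True)["value"]
    out = grouped.agg(["mean", "std", "count"]).reset_index()
    out["mean_2dp"] = out["mean"].map(lambda v: round_half_away(v, 2))
    out["sd_2dp"] = out["std"].map(lambda v: round_half_away(v, 2) if np.isfinite(v) else v)
    return out


def run_cohort(
    tables: Sequence[pd.DataFrame],
    alpha: float = 0.05,
) -> Dict[str, pd.DataFrame]:
    """Cohort statistics over pooled per-specimen morphometry tables.

    Per species: Kruskal-Wallis across ligaments on midsubstance CSA with
    Tukey-on-ranks post hocs (Bonferroni corrected). Across species:
    ART two-way (species x ligament) on normalized CSA with pairwise
    rank-sum post hocs per ligament. Menisci: ART two-way (side x region)
    per species for width and height with rank-sum post hocs. Also
    returns mean +/- SD summary tables (2 decimals, half away from zero).
    """
    tidy = pd.concat(list(tables), ignore_index=True)
    report: Dict[str, pd.DataFrame] = {}
    omnibus: List[StatResult] = []
    posthoc: List[StatResult] = []

    csa = tidy[tidy["measure"] == "midsubstance_csa"]
    for species, sub in csa.groupby("species", observed=True):
        tissues = [t for t in LIGAMENT_TISSUES if t in set(sub["tissue"])]
        groups = [sub.loc[sub["tissue"] == t, "value"].to_numpy() for t in tissues]
        if len(groups) < 2 or any(len(g) < 2 for g in groups):
            continue
        kw = stats.kruskal_wallis(groups, alpha=alpha)
        kw.label = f"{species}: CSA ~ ligament"
        omnibus.append(kw)
        if kw.p_value < alpha:
            posthoc.extend(
                stats.posthoc_pairwise(
                    groups, method="tukey_on_ranks", labels=tissues, alpha=alpha
                )
            )

    norm = tidy[tidy["measure"] == "normalized_csa"]
    if norm["species"].nunique() == 2:
        counts = norm.groupby(["species", "tissue"], observed=True).size()
        if (counts >= 2).all() and len(counts) == 2 * norm["tissue"].nunique():
            art = stats.art_anova_2way(
                norm["value"].to_numpy(),
                norm["species"].to_numpy(),
                norm["tissue"].to_numpy(),
                alpha=alpha,
                names=("species", "ligament"),
            )
            for r in art.values():
                r.label = f"normalized CSA: {r.label}"
                omnibus.append(r)
            species_names = sorted(norm["species"].unique())
            per_tissue = []
            for tissue, sub in norm.groupby("tissue", observed=True):
                x = sub.loc[sub["species"] == species_names[0], "value"].to_numpy()
                y = sub.loc[sub["species"] == species_names[1], "value"].to_numpy()
                r = stats.rank_sum(x, y, alpha=alpha)
                r.label = f"normalized CSA {tissue}: {species_names[0]} vs {species_names[1]}"
                per_tissue.append(r)
            adj = stats.adjust_bonferroni([r.p_value for r in per_tissue])
            for r, pa in zip(per_tissue, adj):
                r.p_adjusted = pa
            posthoc.extend(per_tissue)

    men = tidy[tidy["tissue"].isin(MENISCUS_TISSUES)].copy()
    if len(men):
        men["side"] = men["tissue"].str.replace("_meniscus", "", regex=False)
        men["region"] = men["measure"].str.rsplit("_", n=1).str[0]
        men["dimension"] = men["measure"].str.rsplit("_", n=1).str[1]
        for (species, dim), sub in men.groupby(["species", "dimension"], observed=True):
            counts = sub.groupby(["side", "region"], observed=True).size()
            if len(counts) != sub["side"].nunique() * sub["region"].nunique() or (
                counts < 2
            ).any():
                continue
            art = stats.art_anova_2way(
                sub["value"].to_numpy(),
                sub["side"].to_numpy(),
                sub["region"].to_numpy(),
                alpha=alpha,
                names=("side", "region"),
            )
            for r in art.values():
                r.label = f"{species} meniscal {dim}: {r.label}"
                omnibus.append(r)
            if any(r.p_value < alpha for r in art.values()):
                regions = sorted(sub["region"].unique())
                groups = [
                    sub.loc[sub["region"] == reg, "value"].to_numpy() for reg in regions
                ]
                ph = stats.posthoc_pairwise(
                    groups, method="rank_sum", labels=regions, alpha=alpha
                )
                for r in ph:
                    r.label = f"{species} meniscal {dim}: {r.label}"
                posthoc.extend(ph)

    report["omnibus"] = stats_to_frame(omnibus)
    report["posthoc"] = stats_to_frame(posthoc)
    report["summary_ligaments"] = _summary_table(
        tidy[tidy["measure"].isin(["midsubstance_csa", "normalized_csa"])],
        ["species", "tissue", "measure"],
    )
    if len(men):
        report["summary_menisci"] = _summary_table(
            men, ["species", "side", "region", "dimension"]
        )
    return report
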