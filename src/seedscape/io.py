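"""Reading and writing the pipeline's on-disk formats.

Rasters travel as ESRI ASCII grids (plain text, integer codes) or as
single-band TIFFs whose cell size and origin are stored as JSON in the
ImageDescription tag. Tabular data are CSV: community blocks in long format
(patch_id, plot, species, abundance, dispersal), patch centres, diversity
records, landscape-metric records, scale profiles and model summaries.
Simulation configs round-trip through YAML mirroring the
:class:`~seedscape.synthetic.SimulationConfig` field names.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SimulationConfig
from .types import (
    CommunityBlock,
    ConfigError,
    CoverageRecord,
    DiversityRecord,
    LandCoverRaster,
    MetricRecord,
    ScaleProfile,
)

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_raster_tiff",
    "read_raster_tiff",
    "write_communities_csv",
    "read_communities_csv",
    "write_centres_csv",
    "read_centres_csv",
    "diversity_frame",
    "coverage_frame",
    "metric_frame",
    "profiles_frame",
    "write_config_yaml",
    "read_config_yaml",
]


def write_ascii_grid(raster: LandCoverRaster, path: str | Path) -> None:
    """ESRI ASCII grid: 6-line header then rows north to south."""
    path = Path(path)
    nrows, ncols = raster.grid.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\n"
        f"cellsize {raster.cell_size}\n"
        f"NODATA_value -9999\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(path: str | Path) -> LandCoverRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh, dtype=np.int16)
    grid = np.atleast_2d(grid)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ConfigError(f"{path}: grid shape does not match header")
    return LandCoverRaster(
        grid=grid,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )


def write_raster_tiff(raster: LandCoverRaster, path: str | Path) -> None:
    """Single-band TIFF; cell size and origin go into ImageDescription."""
    import tifffile

    meta = {"cell_size": raster.cell_size, "origin": list(raster.origin)}
    tifffile.imwrite(
        str(path), raster.grid.astype(np.int16), description=json.dumps(meta)
    )


def read_raster_tiff(path: str | Path) -> LandCoverRaster:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        grid = tif.asarray()
        desc = tif.pages[0].tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    return LandCoverRaster(
        grid=grid,
        cell_size=float(meta.get("cell_size", 1.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )


def write_communities_csv(blocks: list[CommunityBlock], path: str | Path) -> None:
    """Long format: one row per (patch, plot, species) with abundance > 0."""
    rows = []
    for b in blocks:
        for j in range(b.n_plots):
            for i in range(b.n_species):
                a = int(b.abundance[j, i])
                if a > 0:
                    rows.append(
                        {
                            "patch_id": b.patch_id,
                            "plot": j,
                            "species": b.species_labels[i],
                            "abundance": a,
                            "dispersal": "animal" if b.dispersal[i] else "other",
                            "x": b.centre[0],
                            "y": b.centre[1],
                            "n_plots": b.n_plots,
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_communities_csv(path: str | Path) -> list[CommunityBlock]:
    df = pd.read_csv(path)
    required = {"patch_id", "plot", "species", "abundance", "dispersal"}
    if not required <= set(df.columns):
        raise ConfigError(f"{path}: missing columns {required - set(df.columns)}")
    blocks = []
    for patch_id, sub in df.groupby("patch_id", sort=True):
        species = sorted(sub["species"].unique())
        sp_index = {s: i for i, s in enumerate(species)}
        n_plots = (
            int(sub["n_plots"].iloc[0])
            if "n_plots" in sub.columns
            else int(sub["plot"].max()) + 1
        )
        ab = np.zeros((n_plots, len(species)), dtype=np.int64)
        for _, row in sub.iterrows():
            ab[int(row["plot"]), sp_index[row["species"]]] += int(row["abundance"])
        disp = np.zeros(len(species), dtype=bool)
        for s, grp in sub.groupby("species"):
            disp[sp_index[s]] = (grp["dispersal"] == "animal").all()
        centre = (
            (float(sub["x"].iloc[0]), float(sub["y"].iloc[0]))
            if "x" in sub.columns
            else (0.0, 0.0)
        )
        blocks.append(
            CommunityBlock(
                patch_id=str(patch_id),
                abundance=ab,
                species_labels=tuple(species),
                dispersal=disp,
                centre=centre,
            )
        )
    return blocks


def write_centres_csv(
    centres: dict[str, tuple[float, float]], path: str | Path
) -> None:
    pd.DataFrame(
        [{"patch_id": k, "x": v[0], "y": v[1]} for k, v in centres.items()]
    ).to_csv(path, index=False)


def read_centres_csv(path: str | Path) -> dict[str, tuple[float, float]]:
    df = pd.read_csv(path)
    return {
        str(r["patch_id"]): (float(r["x"]), float(r["y"])) for _, r in df.iterrows()
    }


def diversity_frame(records: list[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "q": r.q,
                "alpha": r.alpha,
                "beta": r.beta,
                "gamma": r.gamma,
                "n_plots": r.n_plots,
            }
            for r in records
        ]
    )


def coverage_frame(records: list[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "coverage": r.coverage,
                "n": r.n,
                "f1": r.f1,
                "f2": r.f2,
            }
            for r in records
        ]
    )


def metric_frame(records: list[MetricRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patch_id": r.patch_id,
                "radius_m": r.radius_m,
                "metric": r.metric,
                "value": r.value,
            }
            for r in records
        ]
    )


def profiles_frame(profiles: list[ScaleProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for radius, r2 in p.r2cv.items():
            rows.append(
                {
                    "response": p.response,
                    "predictor": p.predictor,
                    "radius_m": radius,
                    "r2cv": r2,
                    "n_effective": p.n_effective[radius],
                    "selected": radius == p.selected_radius,
                }
            )
    return pd.DataFrame(rows)


def write_config_yaml(config: SimulationConfig, path: str | Path) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in config.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_config_yaml(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    if "sad_shape" in data:
        data["sad_shape"] = tuple(data["sad_shape"])
    if "class_proportions" in data:
        data["class_proportions"] = {
            int(k): float(v) for k, v in data["class_proportions"].items()
        }
    try:
        return SimulationConfig(**data)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
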