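"""End-to-end orchestration: simulate/load -> diversity -> metrics ->
scale selection -> multimodel inference -> diagnostics.

Every stage writes its table to the output directory so intermediate
results can be inspected or re-consumed, and a ``run.json`` log records
seeds, configuration and the headline results. A fixed configuration
reproduces every output exactly.

The six response variables are the alpha and beta diversities at orders
0, 1 and 2, named after the species group each order emphasizes:
``alpha_all``/``beta_all`` (q = 0, richness), ``alpha_typical``/
``beta_typical`` (q = 1, exponential Shannon) and ``alpha_dominant``/
``beta_dominant`` (q = 2, inverse Simpson).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import io as sio
from .diagnostics import clark_evans, distance_screen, pairwise_distances, shapiro_screen
from .inference import run_inference, vif_screen, VIF_THRESHOLD
from .landscape import metric_table
from .scale import bootstrap_scale, sweep_profiles
from .synthetic import SimulationConfig, make_study
from .types import (
    CommunityBlock,
    ConfigError,
    DEFAULT_QUALITY_RANKING,
    DEFAULT_RADII,
    GlobalModelSpec,
    LandCoverRaster,
    METRIC_NAMES,
)

__all__ = ["RunConfig", "run_pipeline", "response_table", "build_global_specs"]

RESPONSE_NAMES = {
    ("alpha", 0): "alpha_all",
    ("alpha", 1): "alpha_typical",
    ("alpha", 2): "alpha_dominant",
    ("beta", 0): "beta_all",
    ("beta", 1): "beta_typical",
    ("beta", 2): "beta_dominant",
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulation`` is given (synthetic study) or all three of
    ``raster_path``/``communities_path``/``centres_path`` point at inputs.
    """

    out_dir: str | Path = "seedscape_run"
    simulation: SimulationConfig | None = None
    raster_path: str | Path | None = None
    communities_path: str | Path | None = None
    centres_path: str | Path | None = None
    radii: tuple[float, ...] = DEFAULT_RADII
    ranking: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_QUALITY_RANKING)
    )
    predictors: tuple[str, ...] = METRIC_NAMES
    bootstrap_B: int = 1000
    bootstrap_predictors: tuple[str, ...] | None = None  # None = selected terms
    top_k_terms: int = 3
    global_models: dict[str, list[tuple[str, float]]] | None = None
    permutations: int = 999
    seed: int = 0
    animal_dispersed_only: bool = True

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ConfigError("radii must be strictly increasing")
        self.radii = radii
        has_paths = all(
            p is not None
            for p in (self.raster_path, self.communities_path, self.centres_path)
        )
        if self.simulation is None and not has_paths:
            raise ConfigError(
                "either a simulation config or raster/communities/centres paths"
            )
        if self.simulation is None:
            for p in (self.raster_path, self.communities_path, self.centres_path):
                if not Path(p).exists():
                    raise ConfigError(f"missing input path: {p}")


def response_table(div_frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long diversity table to one column per named response."""
    out = {}
    for (level, q), name in RESPONSE_NAMES.items():
        sub = div_frame[div_frame["q"] == q].set_index("patch_id")
        out[name] = sub[level]
    return pd.DataFrame(out)


def build_global_specs(
    profiles_df: pd.DataFrame,
    responses: pd.DataFrame,
    metrics_df: pd.DataFrame,
    top_k: int = 3,
    vif_threshold: float = VIF_THRESHOLD,
) -> list[GlobalModelSpec]:
    """Global model per response from the scale-selection profiles.

    Takes each response's ``top_k`` predictors by best R2_CV at their
    selected scale, then iteratively drops the highest-VIF term until the
    remaining terms pass the collinearity screen.
    """
    specs = []
    for response in responses.columns:
        sub = profiles_df[
            (profiles_df["response"] == response) & profiles_df["selected"]
        ].dropna(subset=["r2cv"])
        sub = sub.sort_values("r2cv", ascending=False).head(top_k)
        terms = [(row["predictor"], float(row["radius_m"])) for _, row in sub.iterrows()]
        while len(terms) >= 2:
            design = pd.DataFrame(
                {
                    f"{m}_{int(r)}": metrics_df[
                        (metrics_df["metric"] == m)
                        & (metrics_df["radius_m"] == r)
                    ].set_index("patch_id")["value"]
                    for m, r in terms
                }
            ).dropna()
            vifs = vif_screen(design)
            if (vifs < vif_threshold).all():
                break
            worst = vifs.idxmax()
            terms = [t for t in terms if f"{t[0]}_{int(t[1])}" != worst]
        specs.append(GlobalModelSpec(response=response, terms=tuple(terms)))
    return specs


def _load_inputs(
    config: RunConfig,
) -> tuple[LandCoverRaster, list[CommunityBlock]]:
    if config.simulation is not None:
        return make_study(config.simulation)
    raster = (
        sio.read_raster_tiff(config.raster_path)
        if str(config.raster_path).endswith((".tif", ".tiff"))
        else sio.read_ascii_grid(config.raster_path)
    )
    blocks = sio.read_communities_csv(config.communities_path)
    centres = sio.read_centres_csv(config.centres_path)
    blocks = [
        CommunityBlock(
            patch_id=b.patch_id,
            abundance=b.abundance,
            species_labels=b.species_labels,
            dispersal=b.dispersal,
            centre=centres.get(b.patch_id, b.centre),
        )
        for b in blocks
    ]
    return raster, blocks


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write all outputs, return a result bundle."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    raster, blocks = _load_inputs(config)
    centres = {b.patch_id: b.centre for b in blocks}
    sio.write_ascii_grid(raster, out / "raster.asc")
    sio.write_communities_csv(blocks, out / "communities.csv")
    sio.write_centres_csv(centres, out / "centres.csv")

    # diversity stage (animal-dispersed species only, as the analyses require)
    analysed = (
        [dv.filter_animal_dispersed(b) for b in blocks]
        if config.animal_dispersed_only
        else blocks
    )
    div_records = dv.diversity_table(analysed)
    div_frame = sio.diversity_frame(div_records)
    div_frame.to_csv(out / "diversity.csv", index=False)
    cov_frame = sio.coverage_frame(dv.coverage_table(analysed))
    cov_frame.to_csv(out / "coverage.csv", index=False)
    responses = response_table(div_frame)
    responses.to_csv(out / "responses.csv")

    # landscape metrics stage
    metrics = metric_table(
        raster, centres, radii=config.radii, ranking=config.ranking
    )
    metrics_df = sio.metric_frame(metrics)
    metrics_df.to_csv(out / "metrics.csv", index=False)

    # scale-of-effect stage
    resp_series = {c: responses[c] for c in responses.columns}
    profiles = sweep_profiles(
        resp_series, metrics_df, config.predictors, radii=config.radii
    )
    profiles_df = sio.profiles_frame(profiles)
    profiles_df.to_csv(out / "profiles.csv", index=False)

    # global models, then bootstrap uncertainty for the terms actually used
    if config.global_models is not None:
        specs = [
            GlobalModelSpec(response=r, terms=tuple((m, float(rad)) for m, rad in t))
            for r, t in config.global_models.items()
        ]
    else:
        specs = build_global_specs(
            profiles_df, responses, metrics_df, top_k=config.top_k_terms
        )

    boot_rows = []
    boot_results = {}
    for spec in specs:
        predictors = (
            config.bootstrap_predictors
            if config.bootstrap_predictors is not None
            else tuple(m for m, _ in spec.terms)
        )
        for predictor in predictors:
            res = bootstrap_scale(
                responses[spec.response],
                metrics_df,
                predictor,
                B=config.bootstrap_B,
                seed=rng,
                radii=config.radii,
                response_name=spec.response,
            )
            boot_results[(spec.response, predictor)] = res
            for radius, count in res.counts.items():
                boot_rows.append(
                    {
                        "response": spec.response,
                        "predictor": predictor,
                        "radius_m": radius,
                        "count": count,
                        "B": res.B,
                        "mean_radius": res.mean_radius,
                        "sd_radius": res.sd_radius,
                    }
                )
    pd.DataFrame(boot_rows).to_csv(out / "bootstrap.csv", index=False)

    # multimodel inference stage
    reports = run_inference(specs, responses.reset_index(), metrics_df)
    rank_rows, avg_rows = [], []
    for rep in reports:
        for c in rep.ranking:
            rank_rows.append(
                {
                    "response": rep.response,
                    "terms": "+".join(c.terms) or "(null)",
                    "k": c.k,
                    "loglik": c.loglik,
                    "aicc": c.aicc,
                    "delta": c.delta,
                    "weight": c.weight,
                    "best_supported": c.best_supported,
                    "in_confidence_set": c in rep.confidence,
                }
            )
        for a in rep.averaged:
            avg_rows.append(
                {
                    "response": rep.response,
                    "term": a.term,
                    "coefficient": a.coefficient,
                    "use": a.use,
                    "importance": a.importance,
                    "influential": a.influential,
                }
            )
    pd.DataFrame(rank_rows).to_csv(out / "ranking.csv", index=False)
    pd.DataFrame(avg_rows).to_csv(out / "averaged.csv", index=False)

    # diagnostics stage (reported, never gating)
    pts = list(centres.values())
    area = raster.width_m * raster.height_m
    ce_r, ce_p = clark_evans(pts, area)
    dmat = pairwise_distances(pts)
    diag = {"clark_evans": {"R": ce_r, "p": ce_p}, "responses": {}}
    for name in responses.columns:
        vals = responses[name].to_numpy()
        w, p_sw, ok = shapiro_screen(vals)
        r_m, p_m = distance_screen(
            dmat, vals, permutations=config.permutations, seed=rng
        )
        diag["responses"][name] = {
            "shapiro_W": w,
            "shapiro_p": p_sw,
            "normal": ok,
            "mantel_r": r_m,
            "mantel_p": p_m,
        }
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=2))

    log = {
        "seed": config.seed,
        "n_patches": len(blocks),
        "radii": list(config.radii),
        "predictors": list(config.predictors),
        "bootstrap_B": config.bootstrap_B,
        "global_models": {
            s.response: [f"{m}_{int(r)}" for m, r in s.terms] for s in specs
        },
        "selected_scales": {
            f"{p.response}~{p.predictor}": p.selected_radius for p in profiles
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    (out / "run.json").write_text(json.dumps(log, indent=2))

    return {
        "raster": raster,
        "blocks": blocks,
        "diversity": div_frame,
        "coverage": cov_frame,
        "responses": responses,
        "metrics": metrics_df,
        "profiles": profiles,
        "profiles_df": profiles_df,
        "bootstrap": boot_results,
        "global_specs": specs,
        "reports": reports,
        "diagnostics": diag,
        "log": log,
    }
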