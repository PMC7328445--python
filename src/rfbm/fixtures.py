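"""Built-in study domains, config-driven runs, and run manifests.

Three fixture domains cover the study geometries:

* ``ring`` -- the lobed neural-tube cross-section: outer contour
  ``R_outer(phi) = 100 (1 + 0.5 cos^2(4 phi))``, inner circle radius 50;
* ``crowded_disk`` -- disk of radius 100 packed with 1013 obstacles of
  radius 2, all inside radius 90 so an outer rim of width 10 stays free
  (an abstracted neocortical patch with a soma-free layer I);
* ``brainlike`` -- a smoothed random-harmonic, bilaterally symmetric blob
  with a midline slit obstacle emulating a ventricle, digitized to a
  row-interval matrix.

``run_from_config`` executes a full simulate / accumulate / (optionally)
optical-transform / analyze pipeline from a TOML file and writes plain-text
outputs plus a manifest sufficient to re-run the job bit-identically.
"""

from __future__ import annotations

import json
import time
import tomllib
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .density import fit_attenuation, optical_transform, write_pgm
from .domains import (
    CrowdedDiskDomain,
    Domain,
    PolarRingDomain,
    RowIntervalDomain,
    digitize_contour,
    place_obstacles,
    read_contour_csv,
    smooth_and_symmetrize,
)
from .stats import boundary_accumulation_index
from .walker import SimulationConfig, default_step_size, run_ensemble

__all__ = [
    "make_fixture",
    "make_brainlike_contour",
    "RunConfig",
    "load_config",
    "run_from_config",
    "ConfigError",
]

FIXTURE_NAMES = ("ring", "crowded_disk", "brainlike")


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


# ---------------------------------------------------------------------------
# Fixture domains
# ---------------------------------------------------------------------------


def make_brainlike_contour(
    seed: int = 0,
    mean_radius: float = 80.0,
    aspect: float = 1.25,
    roughness: float = 0.12,
    n_vertices: int = 512,
    smoothing_window: int = 9,
) -> np.ndarray:
    """Toy coronal-section outline: a smoothed, mirror-symmetric blob.

    A radial profile with a few random low-order harmonics perturbs an
    ellipse; the right half is smoothed with a moving average and reflected
    across the midline, so the result is exactly bilaterally symmetric like
    a digitized section contour.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for k in range(2, 6):
        amp = roughness / k
        r += amp * rng.normal() * np.cos(k * theta)
        r += amp * rng.normal() * np.sin(k * theta)
    r = mean_radius * np.clip(r, 0.3, None)
    contour = np.column_stack([aspect * r * np.cos(theta), r * np.sin(theta)])
    return smooth_and_symmetrize(contour, window=smoothing_window, axis_x=0.0)


def make_fixture(name: str, seed: int = 0, **params) -> Domain:
    """Build one of the named study domains with its standard parameters.

    ``ring`` and ``crowded_disk`` default to the reference geometry above;
    keyword ``params`` override individual fields (e.g. ``n_obstacles``).
    ``seed`` matters only for the stochastic fixtures (obstacle packing,
    brain-like harmonics).
    """
    if name == "ring":
        return PolarRingDomain(
            base_radius=params.get("base_radius", 100.0),
            modulation=params.get("modulation", 0.5),
            lobe_count=params.get("lobe_count", 4),
            inner_radius=params.get("inner_radius", 50.0),
        )
    if name == "crowded_disk":
        radius = params.get("radius", 100.0)
        r_obs = params.get("r_obs", 2.0)
        placement = params.get("placement_radius", 90.0)
        n_obs = params.get("n_obstacles", 1013)
        obstacles = place_obstacles(n_obs, r_obs, placement, seed=seed)
        return CrowdedDiskDomain(radius=radius, obstacles=tuple(obstacles))
    if name == "brainlike":
        contour = make_brainlike_contour(
            seed=seed,
            mean_radius=params.get("mean_radius", 80.0),
            aspect=params.get("aspect", 1.25),
            roughness=params.get("roughness", 0.12),
        )
        factor = params.get("reduction_factor", 2)
        outer = digitize_contour(contour, reduction_factor=factor)
        # Midline ventricular slit: a thin open box on the symmetry axis.
        height = int(params.get("ventricle_half_height", 25))
        half_width = float(params.get("ventricle_half_width", 3.0))
        slit = RowIntervalDomain(
            y_min=-height,
            x_left=np.full(2 * height + 1, -half_width, dtype=np.int64),
            x_right=np.full(2 * height + 1, half_width, dtype=np.int64),
            scale=1.0,
        )
        return RowIntervalDomain(
            y_min=outer.y_min,
            x_left=outer.x_left,
            x_right=outer.x_right,
            scale=outer.scale,
            inner_regions=(slit,),
        )
    raise ValueError(
        f"unknown fixture {name!r}; available fixtures: {', '.join(FIXTURE_NAMES)}"
    )


# ---------------------------------------------------------------------------
# Config schema
# ---------------------------------------------------------------------------


class DomainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fixture: str | None = None
    fixture_seed: int = 0
    contour_file: str | None = None
    inner_contour_files: list[str] = Field(default_factory=list)
    reduction_factor: int = Field(default=1, ge=1)
    n_obstacles: int | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _one_source(self):
        if (self.fixture is None) == (self.contour_file is None):
            raise ValueError("specify exactly one of 'fixture' or 'contour_file'")
        if self.fixture is not None and self.fixture not in FIXTURE_NAMES:
            raise ValueError(
                f"unknown fixture {self.fixture!r}; choose from {FIXTURE_NAMES}"
            )
        return self


class NoiseSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    hurst: float = Field(gt=0.0, lt=1.0)
    sigma: float | None = Field(default=None, gt=0.0)
    method: str = "circulant"


class RunSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_steps: int = Field(ge=1)
    n_fibers: int = Field(ge=1)
    seed: int
    paper_scale: bool = False


class GridSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cell_size: float = Field(gt=0.0)


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    directory: str = "rfbm_out"
    optical_target_mean: float | None = Field(default=None, ge=0.0, lt=1.0)
    boundary_band_width: float | None = Field(default=None, gt=0.0)
    write_pgm: bool = False


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    domain: DomainSection
    noise: NoiseSection
    run: RunSection
    grid: GridSection
    outputs: OutputSection = OutputSection()


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration.

    Schema violations raise :class:`ConfigError` whose message names the
    offending field path (e.g. ``noise.hurst``).
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            "invalid run configuration:\n  " + "\n  ".join(lines)
        ) from exc


def _build_domain(section: DomainSection, base_dir: Path) -> Domain:
    if section.fixture is not None:
        params = {}
        if section.n_obstacles is not None:
            params["n_obstacles"] = section.n_obstacles
        if section.fixture == "brainlike":
            params["reduction_factor"] = section.reduction_factor
        return make_fixture(section.fixture, seed=section.fixture_seed, **params)
    contour = read_contour_csv(base_dir / section.contour_file)
    outer = digitize_contour(contour, reduction_factor=section.reduction_factor)
    inners = []
    for f in section.inner_contour_files:
        inner = digitize_contour(
            read_contour_csv(base_dir / f),
            reduction_factor=section.reduction_factor,
        )
        inners.append(inner)
    if inners:
        outer = RowIntervalDomain(
            y_min=outer.y_min,
            x_left=outer.x_left,
            x_right=outer.x_right,
            scale=outer.scale,
            inner_regions=tuple(inners),
        )
    return outer


def run_from_config(config_path, execute: bool = True) -> dict:
    """Execute (or just validate and echo) a config-driven simulation run.

    Writes, under ``outputs.directory``: the density grid as TSV + JSON
    sidecar, an analysis report (boundary index, rejection rates), the
    optional optical grid, and ``manifest.json`` echoing the full
    configuration, package version, master seed and timing.  On mid-run
    failure, partial outputs are removed and the exception propagates.
    ``execute=False`` validates and writes only the manifest (useful for
    reference-scale configs meant for larger machines).
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    base_dir = config_path.parent
    out_dir = base_dir / cfg.outputs.directory
    out_dir.mkdir(parents=True, exist_ok=True)
    domain = _build_domain(cfg.domain, base_dir)
    sigma = cfg.noise.sigma
    if sigma is None:
        sigma = default_step_size(cfg.noise.hurst)
    sim = SimulationConfig(
        domain=domain,
        hurst=cfg.noise.hurst,
        sigma=sigma,
        n_steps=cfg.run.n_steps,
        n_fibers=cfg.run.n_fibers,
        seed=cfg.run.seed,
        cell_size=cfg.grid.cell_size,
        noise_method=cfg.noise.method,
    )
    manifest = {
        "version": __version__,
        "config": cfg.model_dump(),
        "resolved_sigma": sigma,
        "master_seed": cfg.run.seed,
        "seed_scheme": "SeedSequence(master).spawn(n_fibers); fiber i spawns "
        "(noise_x, noise_y, start) sub-streams",
        "executed": bool(execute),
        "outputs": [],
    }
    if not execute:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest

    written: list[Path] = []
    try:
        t0 = time.perf_counter()
        result = run_ensemble(sim)
        elapsed = time.perf_counter() - t0
        grid = result.density

        p_tsv, p_meta = out_dir / "density.tsv", out_dir / "density_meta.json"
        grid.write_tsv(p_tsv, p_meta, extra_meta={"seed": cfg.run.seed})
        written += [p_tsv, p_meta]

        # band default: two step standard deviations, but never thinner than
        # one grid cell (the band must contain at least one cell layer)
        band = cfg.outputs.boundary_band_width or max(2.0 * sigma, cfg.grid.cell_size)
        report = {
            "boundary_index": boundary_accumulation_index(
                grid, domain, band
            ).as_dict(),
            "rejection_rate_mean": float(result.rejection_rates.mean()),
            "rejection_rate_per_fiber": result.rejection_rates.tolist(),
        }
        if cfg.outputs.optical_target_mean is not None:
            cx, cy = grid.center_mesh()
            mask = domain.contains_many(cx, cy)
            k = fit_attenuation(grid, cfg.outputs.optical_target_mean, mask=mask)
            optical = optical_transform(grid, k)
            p_opt = out_dir / "optical.tsv"
            p_opt_meta = out_dir / "optical_meta.json"
            optical.write_tsv(p_opt, p_opt_meta)
            written += [p_opt, p_opt_meta]
            report["attenuation_k"] = k
        p_report = out_dir / "report.json"
        with open(p_report, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p_report)

        if cfg.outputs.write_pgm:
            p_pgm = out_dir / "density.pgm"
            write_pgm(p_pgm, grid.counts)
            written.append(p_pgm)

        manifest["outputs"] = [p.name for p in written]
        manifest["elapsed_seconds"] = elapsed
        manifest["rejection_rate_mean"] = report["rejection_rate_mean"]
        p_manifest = out_dir / "manifest.json"
        with open(p_manifest, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
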