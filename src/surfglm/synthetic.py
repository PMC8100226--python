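"""Synthetic meshes, surface maps, and phenotype tables.

Nothing in this package requires real MRI data: this module fabricates the
three inputs the pipeline consumes — a template triangle mesh (an icosphere
standing in for a hemisphere template), per-subject smooth per-vertex maps
with a planted covariate effect on a geodesic patch, and phenotype tables,
optionally with missing values and simple regression-based imputations.

The generated maps emulate smoothed cortical-thickness data: a constant
baseline (default 2.5 mm, a plausible mean thickness), plus spatially
smooth Gaussian noise (default SD 0.3 mm), plus a linear age/sex effect
confined to a patch around a chosen vertex.  The age distribution is
uniform over 47–80 years with effects parameterized per year around the
mean of 63.9, and sex is balanced — the covariate structure of a typical
aging-cohort sample.  Everything is driven by a single seed and written in
the same subjects-directory layout the real pipeline reads, so the
generated trees are valid inputs with zero special-casing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from scipy.sparse.csgraph import dijkstra

from . import fsio
from .fsio import MghImage, SurfaceMesh, VertexMapStack
from .pooling import ImputedPhenotypes
from .randomfield import smooth_on_mesh, smoothing_operator

__all__ = ["SimulationConfig", "make_icosphere", "simulate_arrays", "simulate_dataset", "inject_missing_and_impute"]

AGE_MIN, AGE_MAX, AGE_CENTER = 47.0, 80.0, 63.9


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    ``beta_age`` is in map units per year, ``beta_sex`` in map units for
    male vs. female; both act only on the patch.  ``patch_radius_mm`` is a
    geodesic radius (approximated by graph distance × mean edge length); the
    effect profile is 1 inside the radius and tapers linearly to 0 over an
    additional half radius.
    """

    subdivisions: int = 2  # icosphere level: V = 10·4^s + 2
    radius_mm: float = 100.0  # hemisphere-scale sphere
    n_subjects: int = 100
    beta_age: float = 0.0
    beta_sex: float = 0.0
    patch_center: int = 0
    patch_radius_mm: float = 60.0
    noise_sd: float = 0.3
    noise_smooth_iters: int = 2
    baseline: float = 2.5
    seed: int = 0
    hemi: str = "lh"
    measure: str = "thickness"
    fwhm: int = 10
    target: str = "fsaverage"


def make_icosphere(subdivisions: int, radius_mm: float = 100.0) -> SurfaceMesh:
    """Subdivided icosahedron projected onto a sphere: V = 10·4^s + 2."""
    if subdivisions < 0 or subdivisions > 7:
        raise ValueError("subdivisions must be in [0, 7]")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(coords=np.asarray(m.vertices), faces=np.asarray(m.faces))


def patch_profile(mesh: SurfaceMesh, center: int, radius_mm: float) -> np.ndarray:
    """Effect weight in [0, 1]: 1 within the patch, linear taper beyond.

    Geodesic distance is approximated by unweighted graph distance times the
    mean edge length — adequate on near-regular icospheres.
    """
    op = smoothing_operator(mesh)  # reuse sparsity pattern for the graph
    hops = dijkstra(op, directed=False, indices=center, unweighted=True)
    dist = hops * mesh.edge_mean
    taper = radius_mm / 2.0
    return np.clip(1.0 - np.maximum(dist - radius_mm, 0.0) / taper, 0.0, 1.0)


def simulate_phenotypes(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(AGE_MIN, AGE_MAX, size=n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    ids = [f"sub{i + 1:04d}" for i in range(n)]
    return pd.DataFrame({"id": ids, "age": age, "sex": sex})


def simulate_arrays(cfg: SimulationConfig) -> tuple[SurfaceMesh, np.ndarray, pd.DataFrame]:
    """Generate the mesh, an n × V map matrix, and the phenotype table.

    The in-memory core of :func:`simulate_dataset`; useful when the files
    on disk are not needed (e.g., large replicate studies).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5EED]))
    mesh = make_icosphere(cfg.subdivisions, cfg.radius_mm)
    pheno = simulate_phenotypes(cfg.n_subjects, rng)
    patch = patch_profile(mesh, cfg.patch_center, cfg.patch_radius_mm)
    if cfg.patch_radius_mm * 2.0 > np.pi * cfg.radius_mm and (cfg.beta_age or cfg.beta_sex):
        import warnings

        warnings.warn("patch radius exceeds the hemisphere; effect covers everything")
    effect = cfg.beta_age * (pheno["age"].to_numpy() - AGE_CENTER) + cfg.beta_sex * (
        pheno["sex"].to_numpy() == "M"
    )
    maps = cfg.baseline + np.outer(effect, patch)
    if cfg.noise_sd > 0:
        noise = rng.standard_normal((cfg.n_subjects, mesh.n_vertices))
        if cfg.noise_smooth_iters > 0:
            noise = smooth_on_mesh(noise, mesh, cfg.noise_smooth_iters)
            noise *= 1.0 / noise.std()  # keep the marginal SD at noise_sd
        maps = maps + cfg.noise_sd * noise
    return mesh, maps, pheno


def simulate_dataset(cfg: SimulationConfig, dir_subj: Path | str) -> tuple[SurfaceMesh, pd.DataFrame]:
    """Write a complete synthetic subjects directory.

    Produces ``<dir_subj>/<id>/surf/<hemi>.<measure>.fwhm<k>.<target>.mgh``
    for every subject, the template surface at
    ``<dir_subj>/<target>/surf/<hemi>.white``, and ``phenotypes.csv``.
    Byte-identical across runs for a fixed config.
    """
    dir_subj = Path(dir_subj)
    mesh, maps, pheno = simulate_arrays(cfg)
    surf_dir = dir_subj / cfg.target / "surf"
    surf_dir.mkdir(parents=True, exist_ok=True)
    fsio.write_surface(mesh, surf_dir / f"{cfg.hemi}.white")
    fname = fsio.map_filename(cfg.hemi, cfg.measure, cfg.fwhm, cfg.target)
    for i, sid in enumerate(pheno["id"]):
        d = dir_subj / sid / "surf"
        d.mkdir(parents=True, exist_ok=True)
        fsio.write_mgh(MghImage.from_map(maps[i]), d / fname)
    pheno.to_csv(dir_subj / "phenotypes.csv", index=False)
    return mesh, pheno


def inject_missing_and_impute(
    table: pd.DataFrame,
    miss_rate: float,
    m: int,
    seed: int = 0,
    id_column: str = "id",
) -> ImputedPhenotypes:
    """MCAR-mask ``age`` and fill it back by regression imputation.

    Exactly ``round(miss_rate · n)`` ages are deleted completely at random.
    Each of the M imputations replaces them with the prediction from an
    age-on-sex regression fitted to the observed rows plus Gaussian noise at
    the residual SD, so the imputations carry proper between-imputation
    variability.  This is a deliberately simple reference imputer for
    testing the pooling machinery, not a production imputer.
    """
    if not (0.0 <= miss_rate < 1.0):
        raise ValueError("miss_rate must be in [0, 1)")
    if m < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1337]))
    n = len(table)
    n_miss = int(round(miss_rate * n))
    miss_idx = rng.choice(n, size=n_miss, replace=False)
    observed = np.ones(n, dtype=bool)
    observed[miss_idx] = False
    if n_miss == 0:
        return ImputedPhenotypes(tables=[table.copy() for _ in range(m)], id_column=id_column)
    x = np.column_stack([np.ones(n), (table["sex"].to_numpy() == "M").astype(float)])
    if observed.sum() < x.shape[1]:
        raise ValueError(
            f"only {int(observed.sum())} complete rows remain; need at least {x.shape[1]}"
        )
    y_obs = table["age"].to_numpy(dtype=float)[observed]
    coefs, _, _, _ = np.linalg.lstsq(x[observed], y_obs, rcond=None)
    resid = y_obs - x[observed] @ coefs
    dof = max(int(observed.sum()) - x.shape[1], 1)
    sd = float(np.sqrt((resid**2).sum() / dof))
    pred_miss = x[miss_idx] @ coefs
    tables = []
    for _ in range(m):
        t = table.copy()
        ages = t["age"].to_numpy(dtype=float)
        ages[miss_idx] = pred_miss + rng.normal(0.0, sd, size=n_miss)
        t["age"] = ages
        tables.append(t)
    return ImputedPhenotypes(tables=tables, id_column=id_column)
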