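"""End-to-end orchestration: validate inputs, fit, correct, write outputs.

A project runs in six stages — input checking, model preparation, stack
loading, vertex-wise analysis, multiple-testing correction, and output
generation — and leaves a self-describing directory behind:

========================================  =======================================
``<project>.manifest.json``               full record of the run (config, stack
                                          names, cluster tables, file list)
``finalMask.mgh``                         the vertex mask actually analyzed
``fwhm.dat``                              estimated residual smoothness (mm)
``stack_names.txt``                       stack number ↔ design column name
``significant_clusters.txt``              all significant clusters, one per row
``stackN.{coef,se,t,p}.mgh``              per-stack result maps
``stackN.cache.thT.abs.sig.cluster.mgh``  −log10 cluster-wise p per vertex
``stackN.cache.thT.abs.sig.masked.mgh``   coefficients, non-significant-cluster
                                          vertices zeroed
``stackN.cache.thT.abs.sig.ocn.mgh``      significant-cluster id per vertex
``stackN.cache.thT.abs.sig.cluster.summary``  text table of all clusters
``<project>.log``                         the run log
========================================  =======================================

Stack numbering follows design-matrix column order, so ``stack1`` is always
the intercept.  ``T`` in the cache file names encodes the cluster-forming
threshold as round(−10·log10(mcz_thr)) — 0.001 becomes ``th30``.  Cluster
inference is performed for every stack except the intercept (whose
whole-cortex "effect" is not a hypothesis of interest); corrected p-values
are computed within the analyzed hemisphere and compared against
``cwp_thr``, whose default 0.025 is 0.05 Bonferroni-corrected for analyzing
both hemispheres.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fsio
from .design import DesignMatrix, FormulaSpec, build_design, parse_formula
from .fsio import MghImage, SurfaceMesh, VertexMapStack
from .massglm import DEFAULT_CHUNK_SIZE, make_mask, residuals, run_massglm
from .pooling import ImputedPhenotypes, PooledResult, pool_rubin, read_phenotypes
from .randomfield import (
    DEFAULT_CWP_THR,
    DEFAULT_MCZ_THR,
    DEFAULT_N_SIM,
    Cluster,
    ClusterTable,
    SmoothnessEstimate,
    clusterwise_correct,
    estimate_fwhm,
    find_clusters,
    simulate_null_max_areas,
)

__all__ = ["ProjectConfig", "SessionResult", "check_inputs", "run_project", "summarize", "load_manifest"]


@dataclass
class ProjectConfig:
    """Everything a run needs; defaults mirror the standard analysis recipe."""

    formula: str
    data: object  # path | glob | DataFrame | list | ImputedPhenotypes
    id: str
    hemi: str
    project: str
    dir_subj: str
    dir_out: str | None = None  # default: <dir_subj>/<project>
    target: str = "fsaverage"
    fwhm: int = 10
    measure: str | None = None  # default: from the formula response
    custom_measure: str | None = None
    mcz_thr: float = DEFAULT_MCZ_THR
    cwp_thr: float = DEFAULT_CWP_THR
    chunk_size: int = DEFAULT_CHUNK_SIZE
    n_sim: int = DEFAULT_N_SIM
    n_cores: int = 1
    seed: int = 0
    mask_path: str | None = None
    sep: str = ","
    imputation_column: str | None = None
    df_method: str = "barnard-rubin"


@dataclass
class SessionResult:
    config: ProjectConfig
    mesh: SurfaceMesh
    mask: np.ndarray
    pooled: PooledResult
    smoothness: SmoothnessEstimate
    cluster_tables: dict[str, ClusterTable]
    null_areas: np.ndarray
    paths: list[str]
    out_dir: str
    log: list[str] = field(default_factory=list)

    @property
    def stack_names(self) -> list[str]:
        return self.pooled.stack_names

    def significant_clusters(self) -> list[tuple[str, Cluster]]:
        rows = []
        for name, table in self.cluster_tables.items():
            for c in table.significant(self.config.cwp_thr):
                rows.append((name, c))
        return rows


class SessionError(RuntimeError):
    pass


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except SessionError:
                raise
            except Exception as exc:
                raise SessionError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _resolve_measure(cfg: ProjectConfig, spec: FormulaSpec) -> str:
    if cfg.custom_measure:
        name = cfg.custom_measure
        return name[len("qdecr_"):] if name.startswith("qdecr_") else name
    if cfg.measure:
        return cfg.measure
    return spec.response


def check_inputs(cfg: ProjectConfig, tables: ImputedPhenotypes, spec: FormulaSpec) -> list[str]:
    """Integrity checks; returns the info lines to log.

    All failures are collected and reported together rather than
    fail-fast on the first.
    """
    errors: list[str] = []
    dir_subj = Path(cfg.dir_subj)
    if cfg.hemi not in {"lh", "rh"}:
        errors.append(f"hemi must be 'lh' or 'rh', got {cfg.hemi!r}")
    for nm, val in (("mcz_thr", cfg.mcz_thr), ("cwp_thr", cfg.cwp_thr)):
        if not (0.0 < val < 1.0):
            errors.append(f"{nm} must be in (0, 1), got {val}")
    if any(ch in cfg.project for ch in "/\\\0"):
        errors.append(f"project name {cfg.project!r} is not filesystem-safe")
    if not dir_subj.is_dir():
        errors.append(f"subjects directory does not exist: {dir_subj}")
    measure = _resolve_measure(cfg, spec)
    template = dir_subj / cfg.target / "surf" / f"{cfg.hemi}.white"
    if not template.exists():
        errors.append(f"template surface not found: {template}")
    for i, t in enumerate(tables.tables):
        missing_vars = [v for v in spec.variables if v not in t.columns]
        if missing_vars:
            errors.append(f"imputation {i + 1}: variable(s) missing from data: {', '.join(missing_vars)}")
    ids = tables.ids
    if len(set(map(str, ids))) != len(ids):
        errors.append("duplicate subject identifiers in the phenotype table")
    if dir_subj.is_dir():
        missing_ids = [
            str(sid)
            for sid in ids
            if fsio._subject_map_path(dir_subj, str(sid), cfg.hemi, measure, cfg.fwhm, cfg.target) is None
        ]
        if missing_ids:
            errors.append(
                f"no {cfg.hemi}.{measure} map on disk for {len(missing_ids)} subject(s): "
                + ", ".join(missing_ids)
            )
    if errors:
        raise SessionError("input checking failed:\n  - " + "\n  - ".join(errors))
    return [f"n = {len(ids)} subjects, M = {tables.m} imputation(s), measure = {measure}"]


def _th_code(mcz_thr: float) -> int:
    return int(round(-10.0 * math.log10(mcz_thr)))


def analyze(
    designs: list[DesignMatrix],
    stack: VertexMapStack,
    mesh: SurfaceMesh,
    mask: np.ndarray,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    mcz_thr: float = DEFAULT_MCZ_THR,
    cwp_thr: float = DEFAULT_CWP_THR,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    df_method: str = "barnard-rubin",
) -> tuple[PooledResult, SmoothnessEstimate, dict[str, ClusterTable], np.ndarray]:
    """The in-memory analysis core: fit, pool, estimate smoothness, correct.

    Used by :func:`run_project` and directly by simulation studies that do
    not need files on disk.  Cluster inference covers every non-intercept
    stack; the simulated null is shared across stacks (it depends only on
    the mesh, mask, smoothness and threshold).
    """
    ref = designs[0]
    for d in designs[1:]:
        if d.colnames != ref.colnames or d.n != ref.n:
            raise ValueError("design matrices differ across imputations")
    fits = [run_massglm(d, stack, mask, chunk_size) for d in designs]
    pooled = pool_rubin(fits, n=ref.n, p=ref.p, df_method=df_method)
    res = residuals(designs[0], stack, fits[0])
    smoothness = estimate_fwhm(res[:, :], mesh, mask)
    null_areas = simulate_null_max_areas(
        mesh, mask, smoothness.fwhm_mm, mcz_thr=mcz_thr, n_sim=n_sim, seed=seed
    )
    tables: dict[str, ClusterTable] = {}
    for j, name in enumerate(pooled.stack_names):
        if name == "(Intercept)":
            continue
        table = find_clusters(pooled.pval[j], pooled.tval[j], mesh, mask, mcz_thr)
        clusterwise_correct(table, null_areas, cwp_thr)
        tables[name] = table
    return pooled, smoothness, tables, null_areas


CLUSTER_COLUMNS = ["cluster_id", "stack", "stack_name", "area_mm2", "n_vertices", "peak_vertex", "peak_t", "sign", "cwp"]


def _cluster_rows(result: SessionResult) -> list[dict]:
    rows = []
    names = result.stack_names
    for name, c in result.significant_clusters():
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "stack": names.index(name) + 1,
                "stack_name": name,
                "area_mm2": repr(c.area_mm2),
                "n_vertices": c.n_vertices,
                "peak_vertex": c.peak_vertex,
                "peak_t": repr(c.peak_t),
                "sign": c.sign,
                "cwp": repr(c.cwp),
            }
        )
    return rows


def run_project(cfg: ProjectConfig) -> SessionResult:
    """Execute the full six-stage pipeline and write all output files.

    Any stage failure aborts with the stage name in the message and removes
    files written so far.
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    say(f"project {cfg.project!r}: formula {cfg.formula!r}, hemi {cfg.hemi}, target {cfg.target}")

    # Stage 1: input checking
    spec = _stage("input checking")(parse_formula)(cfg.formula)
    if isinstance(cfg.data, ImputedPhenotypes):
        tables = cfg.data
    else:
        tables = _stage("input checking")(read_phenotypes)(
            cfg.data, cfg.id, sep=cfg.sep, imputation_column=cfg.imputation_column
        )
    log.extend(_stage("input checking")(check_inputs)(cfg, tables, spec))
    measure = _resolve_measure(cfg, spec)

    # Stage 2: model preparation (one design per imputation; shared columns)
    designs = _stage("model preparation")(
        lambda: [build_design(spec, t) for t in tables.tables]
    )()
    say(f"design matrix: n = {designs[0].n}, p = {designs[0].p}, columns = {designs[0].colnames}")

    # Stage 3: stack loading (shared across imputations, loaded once)
    mesh = _stage("stack loading")(fsio.read_surface)(
        Path(cfg.dir_subj) / cfg.target / "surf" / f"{cfg.hemi}.white"
    )
    stack = _stage("stack loading")(fsio.load_stack)(
        cfg.dir_subj, [str(s) for s in tables.ids], cfg.hemi, measure, cfg.fwhm, cfg.target
    )
    if stack.n_vertices != mesh.n_vertices:
        raise SessionError(
            f"stage 'stack loading' failed: maps have {stack.n_vertices} vertices "
            f"but the template surface has {mesh.n_vertices}"
        )
    cortex = None
    if cfg.mask_path:
        cortex = np.flatnonzero(fsio.read_mgh(cfg.mask_path).vertex_values != 0)
    mask = _stage("stack loading")(make_mask)(stack, cortex)
    say(f"V = {stack.n_vertices} vertices, {int(mask.sum())} in the final mask")

    # Stages 4 + 5: vertex-wise analysis and multiple-testing correction
    pooled, smoothness, cluster_tables, null_areas = _stage("vertex-wise analysis")(analyze)(
        designs,
        stack,
        mesh,
        mask,
        chunk_size=cfg.chunk_size,
        mcz_thr=cfg.mcz_thr,
        cwp_thr=cfg.cwp_thr,
        n_sim=cfg.n_sim,
        seed=cfg.seed,
        df_method=cfg.df_method,
    )
    say(
        f"residual smoothness: fwhm = {smoothness.fwhm_mm:.3f} mm "
        f"(rho = {smoothness.rho_edge:.4f}); null: {cfg.n_sim} simulations, "
        f"mcz_thr = {cfg.mcz_thr}, cwp_thr = {cfg.cwp_thr}"
    )

    # Stage 6: output generation
    out_dir = Path(cfg.dir_out) if cfg.dir_out else Path(cfg.dir_subj) / cfg.project
    written: list[Path] = []
    result = SessionResult(
        config=cfg,
        mesh=mesh,
        mask=mask,
        pooled=pooled,
        smoothness=smoothness,
        cluster_tables=cluster_tables,
        null_areas=null_areas,
        paths=[],
        out_dir=str(out_dir),
        log=log,
    )
    try:
        _write_outputs(result, out_dir, written)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise SessionError(f"stage 'output generation' failed: {exc}") from exc
    result.paths = [str(p) for p in written]
    return result


def _write_map(values: np.ndarray, path: Path, written: list[Path]) -> None:
    fsio.write_mgh(MghImage.from_map(np.asarray(values, dtype=np.float32)), path)
    written.append(path)


def _write_outputs(result: SessionResult, out_dir: Path, written: list[Path]) -> None:
    cfg = result.config
    out_dir.mkdir(parents=True, exist_ok=True)
    pooled = result.pooled
    th = _th_code(cfg.mcz_thr)
    _write_map(result.mask.astype(np.float32), out_dir / "finalMask.mgh", written)
    p_fwhm = out_dir / "fwhm.dat"
    p_fwhm.write_text(f"{result.smoothness.fwhm_mm:.6f}\n")
    written.append(p_fwhm)
    p_names = out_dir / "stack_names.txt"
    p_names.write_text(
        "".join(f"stack{i + 1}\t{nm}\n" for i, nm in enumerate(pooled.stack_names))
    )
    written.append(p_names)
    for j, name in enumerate(pooled.stack_names):
        sn = f"stack{j + 1}"
        _write_map(pooled.qbar[j], out_dir / f"{sn}.coef.mgh", written)
        _write_map(pooled.se[j], out_dir / f"{sn}.se.mgh", written)
        _write_map(pooled.tval[j], out_dir / f"{sn}.t.mgh", written)
        _write_map(pooled.pval[j], out_dir / f"{sn}.p.mgh", written)
        if name not in result.cluster_tables:
            continue
        table = result.cluster_tables[name]
        _, logp_map, _sig = clusterwise_correct(table, result.null_areas, cfg.cwp_thr, result.mesh.n_vertices)
        base = f"{sn}.cache.th{th}.abs.sig"
        _write_map(logp_map, out_dir / f"{base}.cluster.mgh", written)
        masked = np.zeros(result.mesh.n_vertices)
        ocn = np.zeros(result.mesh.n_vertices)
        for c in table.significant(cfg.cwp_thr):
            masked[c.vertices] = pooled.qbar[j][c.vertices]
            ocn[c.vertices] = c.cluster_id
        _write_map(masked, out_dir / f"{base}.masked.mgh", written)
        _write_map(ocn, out_dir / f"{base}.ocn.mgh", written)
        p_sum = out_dir / f"{base}.cluster.summary"
        lines = ["# all clusters for " + name + f" (mcz_thr={cfg.mcz_thr}, n_sim={len(result.null_areas)})"]
        lines.append("\t".join(["cluster_id", "area_mm2", "n_vertices", "peak_vertex", "peak_t", "sign", "cwp"]))
        for c in table:
            lines.append(
                f"{c.cluster_id}\t{c.area_mm2!r}\t{c.n_vertices}\t{c.peak_vertex}\t{c.peak_t!r}\t{c.sign}\t{c.cwp!r}"
            )
        p_sum.write_text("\n".join(lines) + "\n")
        written.append(p_sum)
    p_sig = out_dir / "significant_clusters.txt"
    rows = _cluster_rows(result)
    lines = ["\t".join(CLUSTER_COLUMNS)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in CLUSTER_COLUMNS))
    p_sig.write_text("\n".join(lines) + "\n")
    written.append(p_sig)
    p_log = out_dir / f"{cfg.project}.log"
    p_log.write_text("".join(ln + "\n" for ln in result.log))
    written.append(p_log)
    manifest = {
        "project": cfg.project,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {
            k: (v if isinstance(v, (str, int, float, bool, type(None))) else str(type(v).__name__))
            for k, v in dataclasses.asdict(cfg).items()
        },
        "n": int(pooled.df_resid + pooled.p),
        "m": pooled.m,
        "p": pooled.p,
        "df_resid": pooled.df_resid,
        "n_vertices": int(result.mesh.n_vertices),
        "n_masked": int(result.mask.sum()),
        "fwhm_mm": result.smoothness.fwhm_mm,
        "rho_edge": result.smoothness.rho_edge,
        "n_sim": int(len(result.null_areas)),
        "stack_names": pooled.stack_names,
        "clusters": {
            name: [
                {
                    "cluster_id": c.cluster_id,
                    "area_mm2": c.area_mm2,
                    "n_vertices": c.n_vertices,
                    "peak_vertex": c.peak_vertex,
                    "peak_t": c.peak_t,
                    "sign": c.sign,
                    "cwp": c.cwp,
                }
                for c in table
            ]
            for name, table in result.cluster_tables.items()
        },
        "files": [str(p.name) for p in written],
    }
    p_man = out_dir / f"{cfg.project}.manifest.json"
    p_man.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(p_man)


def load_manifest(path: Path | str) -> dict:
    """Load a project manifest (``<project>.manifest.json`` or its directory)."""
    path = Path(path)
    if path.is_dir():
        hits = sorted(path.glob("*.manifest.json"))
        if not hits:
            raise FileNotFoundError(f"no manifest in {path}")
        path = hits[0]
    return json.loads(path.read_text())


def summarize(source: SessionResult | dict | Path | str) -> str:
    """Human-readable report: run parameters plus the significant clusters.

    Accepts a live :class:`SessionResult`, a loaded manifest dict, or a
    path to a manifest / project directory — the manifest alone is enough
    to re-render the report without recomputation.
    """
    if isinstance(source, (str, Path)):
        source = load_manifest(source)
    if isinstance(source, SessionResult):
        man = {
            "project": source.config.project,
            "config": dataclasses.asdict(source.config),
            "m": source.pooled.m,
            "p": source.pooled.p,
            "df_resid": source.pooled.df_resid,
            "n_vertices": int(source.mesh.n_vertices),
            "n_masked": int(source.mask.sum()),
            "fwhm_mm": source.smoothness.fwhm_mm,
            "n_sim": int(len(source.null_areas)),
            "stack_names": source.stack_names,
            "clusters": {
                name: [
                    {
                        "cluster_id": c.cluster_id,
                        "area_mm2": c.area_mm2,
                        "n_vertices": c.n_vertices,
                        "peak_vertex": c.peak_vertex,
                        "peak_t": c.peak_t,
                        "sign": c.sign,
                        "cwp": c.cwp,
                    }
                    for c in table
                ]
                for name, table in source.cluster_tables.items()
            },
        }
    else:
        man = source
    cfg = man["config"]
    lines = [
        f"surfglm project: {man['project']}",
        f"  formula:    {cfg.get('formula')}",
        f"  hemisphere: {cfg.get('hemi')}   target: {cfg.get('target')}   fwhm-in: {cfg.get('fwhm')}",
        f"  subjects:   n = {man['df_resid'] + man['p']}, M = {man['m']} imputation(s)",
        f"  vertices:   {man['n_masked']} analyzed of {man['n_vertices']} (mask)",
        f"  smoothness: {man['fwhm_mm']:.3f} mm FWHM (estimated)",
        f"  correction: mcz_thr = {cfg.get('mcz_thr')}, cwp_thr = {cfg.get('cwp_thr')}, "
        f"n_sim = {man['n_sim']}, seed = {cfg.get('seed')}, chunk_size = {cfg.get('chunk_size')}",
        "",
    ]
    names = man["stack_names"]
    sig = []
    for name, clist in man["clusters"].items():
        for c in clist:
            if c["cwp"] is not None and c["cwp"] <= cfg.get("cwp_thr", DEFAULT_CWP_THR):
                sig.append((name, c))
    if not sig:
        lines.append("zero significant clusters.")
    else:
        lines.append(f"{len(sig)} significant cluster(s):")
        lines.append("\t".join(CLUSTER_COLUMNS))
        for name, c in sig:
            lines.append(
                "\t".join(
                    str(x)
                    for x in [
                        c["cluster_id"],
                        names.index(name) + 1,
                        name,
                        repr(c["area_mm2"]),
                        c["n_vertices"],
                        c["peak_vertex"],
                        repr(c["peak_t"]),
                        c["sign"],
                        repr(c["cwp"]),
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def read_significant_clusters(path: Path | str) -> pd.DataFrame:
    """Parse ``significant_clusters.txt`` back into a typed DataFrame."""
    df = pd.read_csv(path, sep="\t")
    return df
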