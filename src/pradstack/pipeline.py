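"""File formats, run configuration and the end-to-end pipeline.

Canonical interchange formats:

* phase space: CSV with header ``t0,v0,st0,sv0,t1,v1,st1,sv1,e_in,e_out,wepl``
  (mm, slopes, MeV) preceded by a ``#`` comment line carrying the tracker
  span, or an equivalent columnar HDF5 layout (one dataset per column,
  ``u_front``/``u_rear`` as root attributes);
* images and stacks: MetaImage (MHD/RAW) with a TOML sidecar carrying the
  depth axis, grid metadata and provenance (config hash, seed, version);
* reports: JSON.

``run_pipeline`` chains simulate -> filter -> DDB stack -> focus stack ->
depth map -> QA report; each stage is resumable from its cached output and
the whole chain is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import SimpleITK as sitk

from . import __version__
from .ddb import DdbStack, ImageGrid, filter_events, reconstruct_stack
from .depth import Roi, cube_bottom_edge_roi, roi_depth_estimate
from .focus import FocusConfig, FocusResult, focus_stack
from .montecarlo import BeamConfig, PhaseSpace, TransportConfig, \
    build_cube_phantom, cube_specs, transport
from .paths import fit_spline
from .quality import cube_mtf, roi_noise

__all__ = ["RunConfig", "read_phase_space", "write_phase_space",
           "write_image", "read_image", "dump_toml", "run_pipeline"]

log = logging.getLogger(__name__)

SCHEMA = PhaseSpace.COLUMNS


# -- TOML emission (nested tables of scalars; stdlib tomllib reads) ---------


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dump_toml(data: dict, path: str | Path | None = None) -> str:
    """Serialize a {section: {key: scalar-or-list}} dict (plus top-level
    scalars) to TOML text; round-trips through ``tomllib.loads``."""
    lines = []
    for k, v in data.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_toml_value(v)}")
    for k, v in data.items():
        if isinstance(v, dict):
            lines.append(f"\n[{k}]")
            for kk, vv in v.items():
                lines.append(f"{kk} = {_toml_value(vv)}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# -- run configuration -------------------------------------------------------


@dataclass
class PathConfig:
    lambda0: float = 1.0
    lambda1: float = 1.0


@dataclass
class ReconstructionConfig:
    pixel_size: float = 0.5  # mm
    extent: tuple[float, float] = (110.0, 110.0)  # mm
    depth_step: float = 1.0  # mm
    sigma_mult: float = 3.0


@dataclass
class QaConfig:
    noise_roi_center: tuple[float, float] = (30.0, -30.0)  # mm (t, v)
    noise_roi_size: float = 25.0  # mm
    phantom: str = "cubes"


@dataclass
class RunConfig:
    """Full pipeline configuration, mirroring the TOML file layout."""

    seed: int = 0
    beam: BeamConfig = field(default_factory=BeamConfig)
    transport: TransportConfig = field(default_factory=TransportConfig)
    path: PathConfig = field(default_factory=PathConfig)
    reconstruction: ReconstructionConfig = field(
        default_factory=ReconstructionConfig)
    fs: FocusConfig = field(default_factory=FocusConfig)
    qa: QaConfig = field(default_factory=QaConfig)

    _SECTIONS = {
        "beam": BeamConfig,
        "transport": TransportConfig,
        "path": PathConfig,
        "reconstruction": ReconstructionConfig,
        "fs": FocusConfig,
        "qa": QaConfig,
    }

    def to_dict(self) -> dict:
        out: dict = {"seed": self.seed}
        for name in self._SECTIONS:
            section = asdict(getattr(self, name))
            section.pop("laplacian_kernel", None)  # API-configurable only
            section = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in section.items()}
            out[name] = section
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        cfg = cls(seed=int(data.pop("seed", 0)))
        for name, section in data.items():
            if name not in cls._SECTIONS:
                raise ValueError(f"unknown config section [{name}]")
            klass = cls._SECTIONS[name]
            allowed = {f.name for f in fields(klass)} - {"laplacian_kernel"}
            unknown = set(section) - allowed
            if unknown:
                raise ValueError(
                    f"unknown keys in [{name}]: {sorted(unknown)}")
            current = getattr(cfg, name)
            for k, v in section.items():
                if isinstance(getattr(current, k), tuple):
                    v = tuple(v)
                setattr(current, k, v)
            if hasattr(current, "__post_init__"):
                current.__post_init__()  # re-validate after mutation
        return cfg

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_toml(self, path: str | Path | None = None) -> str:
        return dump_toml(self.to_dict(), path)

    def digest(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:16]


# -- phase-space I/O ---------------------------------------------------------


def write_phase_space(ps: PhaseSpace, path: str | Path) -> None:
    """Write list-mode records to CSV (``.csv``) or columnar HDF5 (``.h5``)."""
    path = Path(path)
    if path.suffix == ".h5":
        with h5py.File(path, "w") as fh:
            fh.attrs["u_front"] = ps.u_front
            fh.attrs["u_rear"] = ps.u_rear
            fh.attrs["version"] = __version__
            for c in SCHEMA:
                fh.create_dataset(c, data=getattr(ps, c))
        return
    df = pd.DataFrame({c: getattr(ps, c) for c in SCHEMA})
    with open(path, "w") as fh:
        fh.write(f"# u_front={ps.u_front!r} u_rear={ps.u_rear!r} "
                 f"version={__version__}\n")
        df.to_csv(fh, index=False)


def read_phase_space(path: str | Path) -> PhaseSpace:
    """Read and validate list-mode records; rows violating the record
    invariants (e_out > e_in, non-finite, negative WEPL) are dropped with a
    logged count."""
    path = Path(path)
    if path.suffix == ".h5":
        with h5py.File(path, "r") as fh:
            missing = [c for c in SCHEMA if c not in fh]
            if missing:
                raise ValueError(f"phase-space file missing columns {missing}")
            cols = {c: fh[c][:] for c in SCHEMA}
            u_front = float(fh.attrs["u_front"])
            u_rear = float(fh.attrs["u_rear"])
    else:
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("#"):
                for tok in first[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                header_line = None
            else:
                header_line = first
            try:
                df = pd.read_csv(fh, header=None if header_line else 0,
                                 names=(header_line.strip().split(",")
                                        if header_line else None),
                                 float_precision="round_trip")
            except pd.errors.EmptyDataError as exc:
                raise ValueError(f"empty phase-space file {path}") from exc
        missing = [c for c in SCHEMA if c not in df.columns]
        if missing:
            raise ValueError(f"phase-space file missing columns {missing}")
        cols = {c: df[c].to_numpy(dtype=np.float64) for c in SCHEMA}
        u_front = float(meta.get("u_front", 0.0))
        u_rear = float(meta.get("u_rear", 200.0))
    ok = np.ones(cols["t0"].shape, dtype=bool)
    for c in SCHEMA:
        ok &= np.isfinite(cols[c])
    ok &= cols["e_out"] <= cols["e_in"]
    ok &= cols["wepl"] >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropped %d invalid phase-space rows", n_bad)
        cols = {c: arr[ok] for c, arr in cols.items()}
    return PhaseSpace(u_front=u_front, u_rear=u_rear, **cols)


# -- image I/O ---------------------------------------------------------------


def write_image(array: np.ndarray, path: str | Path,
                spacing: tuple | None = None, origin: tuple | None = None,
                sidecar: dict | None = None) -> None:
    """Write a 2D image or 3D stack as MetaImage (MHD/RAW); optional TOML
    sidecar (``<name>.toml``) for depth axis / grid / provenance metadata."""
    path = Path(path)
    arr = np.asarray(array, dtype=np.float32)
    img = sitk.GetImageFromArray(arr)
    if spacing is not None:
        img.SetSpacing(tuple(float(s) for s in spacing))
    if origin is not None:
        img.SetOrigin(tuple(float(o) for o in origin))
    sitk.WriteImage(img, str(path))
    if sidecar is not None:
        dump_toml(sidecar, path.with_suffix(".toml"))


def read_image(path: str | Path):
    """Read a MetaImage file; returns (array, spacing, origin)."""
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img), img.GetSpacing(), img.GetOrigin()


# -- pipeline ----------------------------------------------------------------


def _provenance(cfg: RunConfig) -> dict:
    return {"config_sha256": cfg.digest(), "seed": cfg.seed,
            "version": __version__}


def run_pipeline(cfg: RunConfig, outdir: str | Path,
                 resume: bool = True) -> dict:
    """Run simulate -> filter -> DDB stack -> focus stack -> depth map -> QA.

    Produces ``ps.csv``, ``stack.mha``, ``fs.mha``, ``depth.mha`` and
    ``qa.json`` (with TOML sidecars) in ``outdir``. With ``resume`` a stage
    whose output file already exists is loaded instead of recomputed.
    Returns the QA report as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)

    def stage(name):
        def deco(fn):
            def run(*a):
                try:
                    return fn(*a)
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage '{name}' failed: "
                                       f"{exc}") from exc
            return run
        return deco

    beam = BeamConfig(**{**asdict(cfg.beam), "rng_seed": cfg.seed})
    tcfg = TransportConfig(**{**asdict(cfg.transport), "rng_seed": cfg.seed})

    ps_path = outdir / "ps.csv"

    @stage("simulate")
    def _simulate() -> PhaseSpace:
        if resume and ps_path.exists():
            log.info("simulate: reusing cached %s", ps_path)
            return read_phase_space(ps_path)
        phantom = build_cube_phantom(cfg.reconstruction.pixel_size)
        ps = transport(phantom, beam, tcfg)
        write_phase_space(ps, ps_path)
        log.info("simulate: %d events scored (seed %d)", len(ps), cfg.seed)
        return ps

    ps = _simulate()

    @stage("reconstruct")
    def _reconstruct(ps: PhaseSpace) -> DdbStack:
        grid = ImageGrid(cfg.reconstruction.pixel_size,
                         cfg.reconstruction.extent)
        kept = filter_events(ps, cfg.reconstruction.sigma_mult)
        paths = fit_spline(kept, cfg.path.lambda0, cfg.path.lambda1)
        stack = reconstruct_stack(kept, paths, grid,
                                  cfg.reconstruction.depth_step,
                                  cfg.reconstruction.sigma_mult)
        write_image(stack.images, outdir / "stack.mha",
                    spacing=(grid.pixel_size, grid.pixel_size,
                             cfg.reconstruction.depth_step),
                    sidecar={**prov,
                             "depths_mm": [float(d) for d in stack.depths],
                             "grid": {"pixel_size": grid.pixel_size,
                                      "extent": list(grid.extent)}})
        return stack

    stack = _reconstruct(ps)

    @stage("focus-stack")
    def _focus(stack: DdbStack) -> FocusResult:
        res = focus_stack(stack, cfg.fs)
        meta = {**prov, "units": "mm WET"}
        write_image(res.fs_image, outdir / "fs.mha",
                    spacing=(stack.grid.pixel_size, stack.grid.pixel_size),
                    sidecar=meta)
        write_image(res.focal_depth_map, outdir / "depth.mha",
                    spacing=(stack.grid.pixel_size, stack.grid.pixel_size),
                    sidecar={**prov, "units": "mm depth"})
        return res

    res = _focus(stack)

    @stage("qa")
    def _qa() -> dict:
        grid = stack.grid
        report: dict = {"provenance": prov,
                        "n_planes": int(stack.n_planes),
                        "n_events": int(len(ps))}
        half = cfg.qa.noise_roi_size / 2.0
        ct, cv = cfg.qa.noise_roi_center
        rs, cs = grid.roi_slices((ct - half, ct + half), (cv - half, cv + half))
        noise_roi = Roi(rs.start, cs.start, rs.stop, cs.stop)
        report["fs_noise_mm"] = roi_noise(res.fs_image, noise_roi)
        if cfg.qa.phantom == "cubes":
            cubes = {}
            for cube in cube_specs():
                mtf = cube_mtf(res.fs_image, grid, cube)
                ddb_plane = int(np.argmin(np.abs(stack.depths
                                                 - cube.u_proximal)))
                mtf_ddb = cube_mtf(stack.images[ddb_plane], grid, cube)
                roi = cube_bottom_edge_roi(grid, cube)
                est = roi_depth_estimate(res, roi)
                cubes[f"{cube.u_proximal:g}mm"] = {
                    "mtf10_fs": mtf.mtf10,
                    "mtf10_ddb_at_depth": mtf_ddb.mtf10,
                    "edge_sigma_fs_mm": mtf.sigma,
                    "depth_median_mm": est.median_depth,
                    "depth_iqr_mm": est.iqr,
                }
            report["cubes"] = cubes
        (outdir / "qa.json").write_text(json.dumps(report, indent=2,
                                                   sort_keys=True))
        return report

    return _qa()
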