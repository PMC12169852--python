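"""Readers, writers, configuration and the end-to-end pipeline.

Mesh frames arrive as PLY/OBJ (via trimesh) or legacy ASCII VTK polydata;
a JSON manifest lists the frames in time order with their timestamps.  An
optional axis map applied once at read time brings the embryo's
animal-vegetal axis onto +z, the convention all downstream math assumes.
Fitted surfaces and strain fields are stored as HDF5, spectral products as
CSV, and every run writes a provenance manifest with the exact
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .harmonics import HarmonicSeries, VarianceTable, sh_forward, variance_ratios
from .kinematics import StrainField, compute_strain_field
from .registration import EvolvingSurface, FitParams, propagate_markers
from .scalogram import Scalogram, default_scales, find_events, normalize_series, ricker_cwt
from .sphere import SphereMesh, build_icosphere, vertex_area_weights

logger = logging.getLogger(__name__)

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_frames",
    "apply_axis_map",
    "write_surface_h5",
    "read_surface_h5",
    "write_strain_h5",
    "write_scalogram_h5",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# mesh formats


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal legacy ASCII VTK POLYDATA reader (triangles only)."""
    tokens: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "ASCII" not in lines[2].upper():
        raise ValueError(f"{path}: only legacy ASCII VTK is supported")
    for line in lines[3:]:
        tokens.extend(line.split())
    it = iter(range(len(tokens)))
    i = 0
    verts = faces = None
    while i < len(tokens):
        tok = tokens[i].upper()
        if tok == "POINTS":
            n = int(tokens[i + 1])
            data = np.array(tokens[i + 3 : i + 3 + 3 * n], dtype=float)
            verts = data.reshape(n, 3)
            i += 3 + 3 * n
        elif tok == "POLYGONS":
            n = int(tokens[i + 1])
            size = int(tokens[i + 2])
            data = np.array(tokens[i + 3 : i + 3 + size], dtype=np.int64)
            faces = []
            j = 0
            for _ in range(n):
                k = data[j]
                if k != 3:
                    raise ValueError(f"{path}: non-triangular polygon")
                faces.append(data[j + 1 : j + 4])
                j += k + 1
            faces = np.asarray(faces)
            i += 3 + size
        else:
            i += 1
    if verts is None or faces is None:
        raise ValueError(f"{path}: POINTS/POLYGONS sections not found")
    return verts, faces


def _write_vtk_polydata(path: Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmorphomap surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} float\n")
        for v in vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a triangle mesh (PLY/OBJ/VTK) as (vertices, faces)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return _read_vtk_polydata(path)
    import trimesh

    m = trimesh.load(path, process=False, force="mesh")
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64)


def write_mesh(path: str | Path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write a triangle mesh; format chosen by extension (PLY/OBJ/VTK)."""
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        _write_vtk_polydata(path, vertices, faces)
        return
    import trimesh

    trimesh.Trimesh(vertices, faces, process=False).export(path)


def _check_closed(vertices: np.ndarray, faces: np.ndarray, name: str) -> None:
    """Raise if the mesh has boundary edges (with the boundary-loop count)."""
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]), axis=1
    )
    _, counts = np.unique(e, axis=0, return_counts=True)
    n_boundary = int(np.sum(counts == 1))
    if n_boundary:
        raise ValueError(f"{name}: open mesh with {n_boundary} boundary edge(s)")


_AXES = {"x": 0, "y": 1, "z": 2}


def apply_axis_map(vertices: np.ndarray, axis_map: str) -> np.ndarray:
    """Permute/flip coordinate axes, e.g. ``"x,z,-y"`` sends +y data to +z.

    The i-th entry names the source axis (with optional sign) that becomes
    output axis i.  Used once at read time to put the animal-vegetal axis
    on +z.
    """
    parts = [p.strip() for p in axis_map.split(",")]
    if len(parts) != 3:
        raise ValueError("axis_map needs 3 comma-separated entries")
    out = np.empty_like(vertices)
    for i, p in enumerate(parts):
        sign = -1.0 if p.startswith("-") else 1.0
        out[:, i] = sign * vertices[:, _AXES[p.lstrip("+-")]]
    return out


def read_frames(
    manifest_path: str | Path, axis_map: str = "x,y,z"
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray, list[dict] | None]:
    """Read a frame sequence from a JSON manifest.

    The manifest holds ``{"time_unit": "hours"|"minutes", "frames":
    [{"time": t, "path": mesh-or-directory}, ...]}``; paths are resolved
    relative to the manifest.  A directory entry is a per-cell frame whose
    files are named ``<cell_id>.<ext>``; the whole-embryo surface for such
    frames must be provided separately (cells feed junction validation).
    Returns (frames, times in hours, per-frame cell dicts or None).
    """
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    unit = spec.get("time_unit", "hours")
    scale = {"hours": 1.0, "minutes": 1.0 / 60.0}[unit]
    frames = []
    cells_per_frame: list[dict] = []
    times = []
    any_cells = False
    for k, entry in enumerate(spec["frames"]):
        if "time" not in entry:
            raise ValueError(f"frame {k}: missing timestamp")
        times.append(float(entry["time"]) * scale)
        p = manifest_path.parent / entry["path"]
        if p.is_dir():
            any_cells = True
            cells = {}
            for f in sorted(p.iterdir()):
                if f.suffix.lower() in (".ply", ".obj", ".vtk"):
                    v, fa = read_mesh(f)
                    _check_closed(v, fa, f.name)
                    cells[f.stem] = (apply_axis_map(v, axis_map), fa)
            cells_per_frame.append(cells)
            allv = np.concatenate([v for v, _ in cells.values()])
            frames.append((allv, None))  # no merged surface; cells only
        else:
            v, fa = read_mesh(p)
            _check_closed(v, fa, p.name)
            frames.append((apply_axis_map(v, axis_map), fa))
            cells_per_frame.append({})
    times = np.asarray(times)
    if np.any(np.diff(times) <= 0):
        raise ValueError("manifest timestamps must be strictly increasing")
    return frames, times, (cells_per_frame if any_cells else None)


# ---------------------------------------------------------------------------
# HDF5 products


def write_surface_h5(path: str | Path, surface: EvolvingSurface) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=surface.times)
        f.create_dataset("faces", data=surface.faces)
        f.create_dataset("positions", data=surface.positions)
        f.attrs["provenance"] = surface.provenance


def read_surface_h5(path: str | Path) -> EvolvingSurface:
    import h5py

    with h5py.File(path, "r") as f:
        return EvolvingSurface(
            f["times"][:], f["positions"][:], f["faces"][:], f.attrs.get("provenance", "raw_input")
        )


def write_strain_h5(path: str | Path, strain: StrainField) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=strain.times)
        f.create_dataset("D", data=strain.tensors)
        f.create_dataset("eigvals", data=strain.eigvals)
        f.create_dataset("scalar", data=strain.scalar)


def write_scalogram_h5(path: str | Path, scalogram: Scalogram) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=scalogram.times)
        f.create_dataset("scales", data=scalogram.scales)
        f.create_dataset("C", data=scalogram.coefficients)
        if scalogram.series_id is not None:
            f.attrs["l"], f.attrs["m"] = scalogram.series_id


def write_scalar_ply(
    path: str | Path, vertices: np.ndarray, faces: np.ndarray, scalar: np.ndarray
) -> None:
    """ASCII PLY with a per-vertex ``quality`` channel for external viewers."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    scalar = np.asarray(scalar, float)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(vertices)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property float quality\n"
            f"element face {len(faces)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v, q in zip(vertices, scalar):
            fh.write(f"{v[0]:.7g} {v[1]:.7g} {v[2]:.7g} {q:.7g}\n")
        for f in faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def write_coefficients_h5(path: str | Path, series: HarmonicSeries) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=series.times)
        f.create_dataset("coeffs", data=series.coeffs)
        f.attrs["lmax"] = series.lmax


def export_scalogram_png(path: str | Path, scalogram: Scalogram) -> None:
    """Optional heatmap export of |C| (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.pcolormesh(scalogram.times, scalogram.scales, scalogram.magnitude, shading="auto")
    ax.set_xlabel("time [h]")
    ax.set_ylabel("scale [frames]")
    ax.set_yscale("log")
    if scalogram.series_id is not None:
        ax.set_title(f"|C| of f_{scalogram.series_id[0]}{scalogram.series_id[1]}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# configuration and the end-to-end pipeline


@dataclass
class PipelineConfig:
    """Everything a run needs; round-trips losslessly through TOML/JSON."""

    input_manifest: str | None = None
    output_dir: str = "morphomap_out"
    axis_map: str = "x,y,z"
    subdivision_level: int = 4
    fit: FitParams = field(default_factory=FitParams)
    spatial_sigma: float = 1.0
    temporal_sigma: float = 1.0
    lmax: int = 12
    windows: list[tuple[float, float]] | None = None  # None: full range
    n_scales: int = 32
    series: list[tuple[int, int]] = field(default_factory=lambda: [(0, 0), (1, 0)])
    min_separation: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "fit" in d and isinstance(d["fit"], dict):
            d["fit"] = FitParams(**d["fit"])
        if d.get("windows"):
            d["windows"] = [tuple(w) for w in d["windows"]]
        if d.get("series"):
            d["series"] = [tuple(s) for s in d["series"]]
        return cls(**d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as f:
            return cls.from_dict(tomllib.load(f))

    def to_toml(self, path: str | Path) -> None:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            if isinstance(v, (int, float)):
                return repr(v)
            if isinstance(v, str):
                return json.dumps(v)
            if isinstance(v, (list, tuple)):
                return "[" + ", ".join(fmt(x) for x in v) + "]"
            raise TypeError(type(v))

        d = self.to_dict()
        fit = d.pop("fit")
        lines = []
        for k, v in d.items():
            if v is None:
                continue
            lines.append(f"{k} = {fmt(v)}")
        lines.append("\n[fit]")
        for k, v in fit.items():
            if v is None:
                continue
            lines.append(f"{k} = {fmt(v)}")
        Path(path).write_text("\n".join(lines) + "\n")


def run_pipeline(
    config: PipelineConfig,
    frames: list[tuple[np.ndarray, np.ndarray]] | None = None,
    times: np.ndarray | None = None,
) -> dict:
    """Markers -> strain -> harmonics -> scalograms, with full provenance.

    ``frames``/``times`` may be passed directly (e.g. from the simulator);
    otherwise they are read from ``config.input_manifest``.  Every product
    is written under ``config.output_dir``; on a stage failure the partial
    outputs are kept and the failing stage is recorded in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "products": {}, "failed_stage": None}
    result: dict = {"manifest": manifest}

    def finish():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        return result

    stage = "read_frames"
    try:
        if frames is None:
            frames, times, _cells = read_frames(config.input_manifest, config.axis_map)
        times = np.asarray(times, float)

        stage = "fit"
        base = build_icosphere(config.subdivision_level)
        fitted, fit_results = propagate_markers(frames, times, base, config.fit)
        write_surface_h5(out / "fitted_surface.h5", fitted)
        manifest["products"]["fitted_surface"] = "fitted_surface.h5"
        manifest["fit_residuals"] = [
            {"frame": k, "max": r.residual_max, "mean": r.residual_mean, "rms": r.residual_rms}
            for k, r in enumerate(fit_results)
        ]
        result["fitted"] = fitted

        stage = "strain"
        strain = compute_strain_field(fitted, config.spatial_sigma, config.temporal_sigma)
        write_strain_h5(out / "strain.h5", strain)
        manifest["products"]["strain"] = "strain.h5"
        result["strain"] = strain

        stage = "harmonics"
        weights = vertex_area_weights(base.vertices, base.faces)
        coeffs = sh_forward(strain.scalar, weights, base.theta, base.phi, config.lmax)
        series = HarmonicSeries(strain.times, config.lmax, coeffs)
        series.to_dataframe().to_csv(out / "coefficients.csv", index=False)
        vr = variance_ratios(series)
        vr.to_dataframe().to_csv(out / "variance_ratios.csv", index=False)
        manifest["products"]["coefficients"] = "coefficients.csv"
        manifest["products"]["variance_ratios"] = "variance_ratios.csv"
        result["series"] = series
        result["variance"] = vr

        stage = "scalogram"
        windows = config.windows or [(float(times[0]), float(times[-1]))]
        events_rows = []
        result["scalograms"] = []
        for l, m in config.series:
            for wi, window in enumerate(windows):
                ts = np.real(series.series(l, m))
                z, wt = normalize_series(ts, strain.times, window)
                scales = default_scales(len(z), config.n_scales)
                scal = ricker_cwt(z, scales, wt, series_id=(l, m))
                name = f"scalogram_l{l}m{m}_w{wi}"
                write_scalogram_h5(out / f"{name}.h5", scal)
                long = pd.DataFrame(
                    {
                        "time": np.tile(scal.times, len(scal.scales)),
                        "scale": np.repeat(scal.scales, len(scal.times)),
                        "value": scal.coefficients.ravel(),
                    }
                )
                long.to_csv(out / f"{name}.csv", index=False)
                manifest["products"][name] = f"{name}.h5"
                result["scalograms"].append(scal)
                for t, s, c in find_events(scal, config.min_separation):
                    events_rows.append((l, m, wi, t, s, c))
        pd.DataFrame(
            events_rows, columns=["l", "m", "window", "time", "scale", "coefficient"]
        ).to_csv(out / "events.csv", index=False)
        manifest["products"]["events"] = "events.csv"
    except Exception as exc:  # partial outputs are kept
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        finish()
        raise
    return finish()
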