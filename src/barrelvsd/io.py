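"""File interchange: multi-page TIFF per trial, HDF5 containers, PNG maps.

The canonical on-disk form of a synthetic cohort is a single HDF5 file:

    /animals/<animal_id>/evoked        (trial, frame, row, col) float32
    /animals/<animal_id>/blank         idem
    /animals/<animal_id>/spontaneous   idem
    /animals/<animal_id>/vessel_mask   (row, col) bool

Each movie dataset carries the acquisition geometry and labels as HDF5
attributes; the file root records the master seed.  Ground truth travels
as a JSON sidecar.  ΔF/F movies are stored as ``/dff`` + ``/vessel_mask``
with provenance attributes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import tifffile

from .core import AcquisitionGeometry, DffMovie, FluorescenceMovie
from .synthetic import AnimalRecord, Cohort, GenotypeParams

__all__ = [
    "write_trials_tiff",
    "read_trials_tiff",
    "write_cohort_hdf5",
    "read_cohort_hdf5",
    "write_dff_hdf5",
    "read_dff_hdf5",
    "save_map_png",
]


def _geometry_attrs(geometry: AcquisitionGeometry) -> dict:
    return {
        "n_rows": geometry.n_rows,
        "n_cols": geometry.n_cols,
        "pixel_size_um": geometry.pixel_size_um,
        "frame_rate_hz": geometry.frame_rate_hz,
        "n_frames": geometry.n_frames,
        "stim_onset_frame": -1 if geometry.stim_onset_frame is None else geometry.stim_onset_frame,
    }


def _geometry_from_attrs(attrs) -> AcquisitionGeometry:
    onset = int(attrs["stim_onset_frame"])
    return AcquisitionGeometry(
        n_rows=int(attrs["n_rows"]),
        n_cols=int(attrs["n_cols"]),
        pixel_size_um=float(attrs["pixel_size_um"]),
        frame_rate_hz=float(attrs["frame_rate_hz"]),
        n_frames=int(attrs["n_frames"]),
        stim_onset_frame=None if onset < 0 else onset,
    )


def write_trials_tiff(movie: FluorescenceMovie, out_dir: Path, stem: str = "trial") -> list[Path]:
    """One multi-page TIFF per trial (page = frame), float32."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(movie.n_trials):
        p = out_dir / f"{stem}_{i:03d}.tif"
        tifffile.imwrite(p, movie.data[i].astype(np.float32))
        paths.append(p)
    return paths


def read_trials_tiff(
    paths: list[Path], geometry: AcquisitionGeometry, condition: str = "evoked", **labels
) -> FluorescenceMovie:
    data = np.stack([tifffile.imread(p) for p in sorted(paths)])
    return FluorescenceMovie(data, geometry, condition, **labels)


def _write_movie(group: h5py.Group, name: str, movie: FluorescenceMovie) -> None:
    ds = group.create_dataset(name, data=movie.data.astype(np.float32), compression="gzip")
    for k, v in _geometry_attrs(movie.geometry).items():
        ds.attrs[k] = v
    ds.attrs["condition"] = movie.condition
    ds.attrs["group"] = movie.group
    ds.attrs["animal_id"] = movie.animal_id


def _read_movie(ds: h5py.Dataset) -> FluorescenceMovie:
    return FluorescenceMovie(
        ds[()].astype(np.float64),
        _geometry_from_attrs(ds.attrs),
        condition=str(ds.attrs["condition"]),
        group=str(ds.attrs["group"]),
        animal_id=str(ds.attrs["animal_id"]),
    )


def write_cohort_hdf5(cohort: Cohort, path: Path, ground_truth_sidecar: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = cohort.seed
        root = f.create_group("animals")
        for a in cohort.animals:
            g = root.create_group(a.animal_id)
            g.attrs["group"] = a.group
            g.attrs["seed"] = a.seed
            g.attrs["center"] = list(a.center)
            g.create_dataset("vessel_mask", data=a.vessel_mask)
            for name in ("evoked", "blank", "spontaneous"):
                movie = getattr(a, name)
                if movie is not None:
                    _write_movie(g, name, movie)
    if ground_truth_sidecar:
        Path(str(path) + ".truth.json").write_text(cohort.ground_truth_json())
    return path


def read_cohort_hdf5(path: Path) -> Cohort:
    """Reload a cohort container.  Per-animal generative params are restored
    from the ground-truth sidecar when present, else left at defaults."""
    truth_path = Path(str(path) + ".truth.json")
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    params_by_id = {}
    if truth:
        for rec in truth["animals"]:
            params_by_id[rec["animal_id"]] = GenotypeParams(**rec["params"])
    animals = []
    evoked_geometry = spont_geometry = None
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        for animal_id in sorted(f["animals"]):
            g = f["animals"][animal_id]
            movies = {}
            for name in ("evoked", "blank", "spontaneous"):
                movies[name] = _read_movie(g[name]) if name in g else None
            if movies["evoked"] is not None:
                evoked_geometry = movies["evoked"].geometry
            if movies["spontaneous"] is not None:
                spont_geometry = movies["spontaneous"].geometry
            animals.append(
                AnimalRecord(
                    animal_id=animal_id,
                    group=str(g.attrs["group"]),
                    params=params_by_id.get(animal_id, GenotypeParams()),
                    center=tuple(int(v) for v in g.attrs["center"]),
                    vessel_mask=g["vessel_mask"][()].astype(bool),
                    evoked=movies["evoked"],
                    blank=movies["blank"],
                    spontaneous=movies["spontaneous"],
                    seed=int(g.attrs["seed"]),
                )
            )
    return Cohort(animals, evoked_geometry, spont_geometry, seed)


def write_dff_hdf5(dff: DffMovie, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("dff", data=dff.data.astype(np.float32), compression="gzip")
        for k, v in _geometry_attrs(dff.geometry).items():
            ds.attrs[k] = v
        ds.attrs["condition"] = dff.condition
        ds.attrs["group"] = dff.group
        ds.attrs["animal_id"] = dff.animal_id
        mask = dff.vessel_mask
        f.create_dataset(
            "vessel_mask",
            data=np.zeros(dff.geometry.shape, bool) if mask is None else mask,
        )
        f.attrs["provenance"] = json.dumps(dff.provenance)
    return path


def read_dff_hdf5(path: Path) -> DffMovie:
    with h5py.File(path, "r") as f:
        ds = f["dff"]
        mask = f["vessel_mask"][()].astype(bool)
        return DffMovie(
            ds[()].astype(np.float64),
            _geometry_from_attrs(ds.attrs),
            condition=str(ds.attrs["condition"]),
            group=str(ds.attrs["group"]),
            animal_id=str(ds.attrs["animal_id"]),
            vessel_mask=mask if mask.any() else None,
            provenance=json.loads(f.attrs["provenance"]),
        )


def save_map_png(
    values: np.ndarray,
    path: Path,
    title: str = "",
    symmetric: bool = True,
    pixel_size_um: Optional[float] = None,
) -> Path:
    """Render a 2-D map to PNG; missing (vessel) pixels are gray, and the
    color scale is symmetric about zero for correlation maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = np.asarray(values, dtype=float)
    vmax = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    vmin = -vmax if symmetric else float(np.nanmin(values))
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("RdBu_r" if symmetric else "viridis").copy()
    cmap.set_bad("0.5")
    im = ax.imshow(values, cmap=cmap, vmin=vmin, vmax=vmax)
    if pixel_size_um is not None:
        ax.set_xlabel(f"pixels ({pixel_size_um:g} μm each)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
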