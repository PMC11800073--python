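"""Reading and writing volumes, sinograms and phantoms.

HDF5 carries arrays plus their metadata; NPY holds bare arrays; TIFF stacks
hold 32-bit image data.  Round trips are lossless for 32-bit data.
"""
from __future__ import annotations

import pathlib

import h5py
import numpy as np
import tifffile

from .materials import MaterialSpec
from .phantom import SpectralPhantom
from .recon import ReconVolume
from .sinogram import SpectralSinogram


class FormatError(ValueError):
    pass


def write_volume(data: np.ndarray, path, fmt: str | None = None, **metadata) -> None:
    """Write an array as .h5 (with metadata attrs), .npy, or .tif stack."""
    path = pathlib.Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("h5", "hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("data", data=data)
            for key, val in metadata.items():
                ds.attrs[key] = val
    elif fmt == "npy":
        np.save(path, data)
    elif fmt in ("tif", "tiff"):
        tifffile.imwrite(path, np.asarray(data, dtype=np.float32))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")


def read_volume(path):
    """Read a volume; returns (array, metadata dict)."""
    path = pathlib.Path(path)
    suffix = path.suffix.lstrip(".").lower()
    if suffix in ("h5", "hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["data"]
            return ds[()], dict(ds.attrs)
    if suffix == "npy":
        return np.load(path), {}
    if suffix in ("tif", "tiff"):
        return tifffile.imread(path), {}
    raise FormatError(f"unknown volume format {suffix!r}")


def write_sinogram(sino: SpectralSinogram, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=sino.data)
        fh.create_dataset("channel_edges", data=sino.channel_edges)
        fh.attrs["channel_kind"] = sino.channel_kind
        if sino.angles_deg is not None:
            fh.create_dataset("angles_deg", data=sino.angles_deg)


def read_sinogram(path) -> SpectralSinogram:
    with h5py.File(path, "r") as fh:
        angles = fh["angles_deg"][()] if "angles_deg" in fh else None
        return SpectralSinogram(
            data=fh["data"][()],
            channel_kind=str(fh.attrs["channel_kind"]),
            channel_edges=fh["channel_edges"][()],
            angles_deg=angles,
        )


def write_phantom(phantom: SpectralPhantom, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mixture", data=phantom.mixture_volume)
        fh.attrs["voxel_size_mm"] = phantom.voxel_size_mm
        fh.attrs["sphere_radius_mm"] = phantom.containment_sphere_radius_mm
        grp = fh.create_group("materials")
        for i, m in enumerate(phantom.material_list):
            sub = grp.create_group(f"{i:02d}_{m.name}")
            sub.attrs["name"] = str(m.name)
            sub.attrs["density"] = m.density
            sub.create_dataset("energy_grid", data=m.energy_grid)
            sub.create_dataset("mass_attenuation", data=m.mass_attenuation)


def read_phantom(path) -> SpectralPhantom:
    with h5py.File(path, "r") as fh:
        materials = []
        for key in sorted(fh["materials"].keys()):
            sub = fh["materials"][key]
            materials.append(
                MaterialSpec(
                    name=str(sub.attrs["name"]),
                    density=float(sub.attrs["density"]),
                    energy_grid=sub["energy_grid"][()],
                    mass_attenuation=sub["mass_attenuation"][()],
                )
            )
        return SpectralPhantom(
            mixture_volume=fh["mixture"][()],
            voxel_size_mm=float(fh.attrs["voxel_size_mm"]),
            material_list=materials,
            containment_sphere_radius_mm=float(fh.attrs["sphere_radius_mm"]),
        )


def write_detector(model, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("response", data=model.response)
        fh.create_dataset("energy_grid", data=model.energy_grid)
        fh.attrs["crosstalk"] = model.crosstalk_fraction
        fh.attrs["dead_time_s"] = model.dead_time_s
        fh.attrs["exposure_s"] = model.exposure_s


def read_detector(path):
    from .detector import DetectorModel

    with h5py.File(path, "r") as fh:
        return DetectorModel(
            energy_grid=fh["energy_grid"][()],
            response=fh["response"][()],
            crosstalk_fraction=float(fh.attrs["crosstalk"]),
            dead_time_s=float(fh.attrs["dead_time_s"]),
            exposure_s=float(fh.attrs["exposure_s"]),
        )


def write_history_csv(history: dict, path) -> None:
    """Per-epoch training metrics as CSV (one column per logged series)."""
    keys = list(history.keys())
    n = max((len(v) for v in history.values()), default=0)
    lines = [",".join(["epoch"] + keys)]
    for i in range(n):
        row = [str(i)] + [
            f"{history[k][i]:.8g}" if i < len(history[k]) else "" for k in keys
        ]
        lines.append(",".join(row))
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


def write_recon(volume: ReconVolume, path, fmt: str = "h5") -> None:
    path = pathlib.Path(path)
    if fmt == "h5":
        with h5py.File(path, "w") as fh:
            fh.create_dataset("data", data=volume.data)
            fh.create_dataset("bin_edges", data=volume.bin_edges)
            fh.attrs["voxel_size_mm"] = volume.voxel_size_mm
    elif fmt in ("tif", "tiff"):
        # one multi-page stack per energy bin next to each other
        tifffile.imwrite(path, np.asarray(volume.data, dtype=np.float32))
    else:
        raise FormatError(f"unknown reconstruction format {fmt!r}")


def read_recon(path) -> ReconVolume:
    with h5py.File(path, "r") as fh:
        return ReconVolume(
            data=fh["data"][()],
            voxel_size_mm=float(fh.attrs["voxel_size_mm"]),
            bin_edges=fh["bin_edges"][()],
        )
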