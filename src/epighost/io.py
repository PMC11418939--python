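"""File formats: HDF5 containers for waveforms/scenes/k-space, NIfTI images,
and TOML experiment configuration.

HDF5 layouts (all complex arrays stored natively):

waveform:  /grad/samples_mTm, /grad/raster_s, /adc/windows (raster index
           ranges), /adc/time_windows, /adc/dwell_s, /lines/boundaries,
           /lines/flat_top_ranges, /lines/polarity
scene:     /image, /coil_maps, /b0_map_hz, /t2star_map_s + attrs
k-space:   /samples, /navigator, /traj/{nominal,actual}_kx_{plus,minus},
           /traj/sample_times_s, /lines/*, attrs for protocol and GIRF,
           optional /acs subgroup with the same layout
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .girf import GirfModel, KTrajectory, girf_preset
from .phantom import PhantomScene
from .forward import KSpaceData
from .waveforms import EpiProtocol, GradientWaveform

__all__ = [
    "save_waveform",
    "load_waveform",
    "save_scene",
    "load_scene",
    "save_kspace",
    "load_kspace",
    "write_nifti",
    "read_nifti_complex",
    "load_config_file",
    "protocol_from_dict",
    "girf_from_dict",
]


def save_waveform(path, waveform: GradientWaveform) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grad")
        g.create_dataset("samples_mTm", data=waveform.samples_mTm)
        g.attrs["raster_s"] = waveform.raster_s
        a = f.create_group("adc")
        a.create_dataset("windows", data=np.asarray(waveform.adc_windows))
        a.create_dataset("time_windows", data=np.asarray(waveform.adc_time_windows))
        a.attrs["dwell_s"] = waveform.dwell_s
        a.attrs["n_samples_per_line"] = waveform.n_samples_per_line
        g.attrs["t_excitation_s"] = waveform.t_excitation_s
        li = f.create_group("lines")
        li.create_dataset("boundaries", data=np.asarray(waveform.line_boundaries))
        li.create_dataset(
            "flat_top_ranges", data=np.asarray(waveform.flat_top_ranges)
        )
        li.create_dataset("polarity", data=waveform.line_polarity)


def load_waveform(path) -> GradientWaveform:
    with h5py.File(path, "r") as f:
        return GradientWaveform(
            samples_mTm=f["grad/samples_mTm"][()],
            raster_s=float(f["grad"].attrs["raster_s"]),
            line_boundaries=tuple(map(tuple, f["lines/boundaries"][()].tolist())),
            adc_windows=tuple(map(tuple, f["adc/windows"][()].tolist())),
            flat_top_ranges=tuple(
                map(tuple, f["lines/flat_top_ranges"][()].tolist())
            ),
            adc_time_windows=tuple(
                map(tuple, f["adc/time_windows"][()].tolist())
            ),
            dwell_s=float(f["adc"].attrs["dwell_s"]),
            n_samples_per_line=int(f["adc"].attrs["n_samples_per_line"]),
            line_polarity=f["lines/polarity"][()],
            t_excitation_s=float(f["grad"].attrs["t_excitation_s"]),
        )


def save_scene(path, scene: PhantomScene) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=scene.image)
        f.create_dataset("coil_maps", data=scene.coil_maps)
        f.create_dataset("b0_map_hz", data=scene.b0_map_hz)
        f.create_dataset("t2star_map_s", data=scene.t2star_map_s)
        f.attrs["pixel_size_m"] = scene.pixel_size_m
        f.attrs["seed"] = scene.seed


def load_scene(path) -> PhantomScene:
    with h5py.File(path, "r") as f:
        return PhantomScene(
            image=f["image"][()],
            coil_maps=f["coil_maps"][()],
            b0_map_hz=f["b0_map_hz"][()],
            t2star_map_s=f["t2star_map_s"][()],
            pixel_size_m=float(f.attrs["pixel_size_m"]),
            seed=int(f.attrs["seed"]),
        )


def _write_traj(group, traj: KTrajectory, tag: str) -> None:
    group.create_dataset(f"nominal_kx_{tag}", data=traj.nominal_kx)
    group.create_dataset(f"actual_kx_{tag}", data=traj.actual_kx)
    group.create_dataset(f"line_polarity_{tag}", data=traj.line_polarity)
    group.create_dataset(f"sample_times_s_{tag}", data=traj.sample_times_s)


def _read_traj(group, tag: str) -> KTrajectory:
    return KTrajectory(
        nominal_kx=group[f"nominal_kx_{tag}"][()],
        actual_kx=group[f"actual_kx_{tag}"][()],
        line_polarity=group[f"line_polarity_{tag}"][()],
        sample_times_s=group[f"sample_times_s_{tag}"][()],
    )


def _protocol_attrs(protocol: EpiProtocol) -> dict:
    d = dataclasses.asdict(protocol)
    return {k: ("" if v is None else v) for k, v in d.items()}


def _protocol_from_attrs(attrs) -> EpiProtocol:
    kw = {}
    for f in dataclasses.fields(EpiProtocol):
        v = attrs[f.name]
        if isinstance(v, bytes):
            v = v.decode()
        if isinstance(v, str) and v == "":
            v = None
        kw[f.name] = v
    for key in (
        "matrix_read", "matrix_phase", "grappa_factor", "acs_lines",
        "readout_oversampling",
    ):
        kw[key] = int(kw[key])
    kw["ramp_sampling"] = bool(kw["ramp_sampling"])
    for key in ("fov_m", "gmax_mTm", "slew_Tms", "raster_s"):
        kw[key] = float(kw[key])
    for key in ("echo_spacing_s", "bandwidth_per_pixel_hz", "te_s"):
        if kw[key] is not None:
            kw[key] = float(kw[key])
    kw["polarity_scheme"] = str(kw["polarity_scheme"])
    return EpiProtocol(**kw)


def _girf_attrs(girf: GirfModel) -> dict:
    return {
        "girf_delay_s": girf.delay_s,
        "girf_eddy": np.asarray(girf.eddy_terms, dtype=float).reshape(-1, 2)
        if girf.eddy_terms
        else np.zeros((0, 2)),
        "girf_resonance": np.asarray(girf.resonance_terms, dtype=float).reshape(-1, 3)
        if girf.resonance_terms
        else np.zeros((0, 3)),
        "girf_shim_connected": girf.third_order_shim_connected,
    }


def _girf_from_attrs(attrs) -> GirfModel:
    return GirfModel(
        delay_s=float(attrs["girf_delay_s"]),
        eddy_terms=tuple(map(tuple, np.asarray(attrs["girf_eddy"]).tolist())),
        resonance_terms=tuple(
            map(tuple, np.asarray(attrs["girf_resonance"]).tolist())
        ),
        third_order_shim_connected=bool(attrs["girf_shim_connected"]),
    )


def _save_kspace_group(f, data: KSpaceData) -> None:
    f.create_dataset("samples", data=data.samples)
    f.create_dataset("navigator", data=data.navigator)
    tr = f.create_group("traj")
    _write_traj(tr, data.trajectories[1], "plus")
    _write_traj(tr, data.trajectories[-1], "minus")
    li = f.create_group("lines")
    li.create_dataset("ky_per_line", data=data.ky_per_line)
    li.create_dataset("indices", data=data.line_indices)
    li.create_dataset("acquired_mask", data=data.acquired_line_mask)
    li.create_dataset("polarity", data=data.line_polarity)
    li.create_dataset("frame_polarity", data=data.frame_polarity)
    f.attrs["echo_spacing_s"] = data.echo_spacing_s
    f.attrs["te_s"] = data.te_s
    f.attrs["noise_sd"] = data.noise_sd
    for k, v in _protocol_attrs(data.protocol).items():
        f.attrs[f"protocol_{k}"] = v
    for k, v in _girf_attrs(data.girf).items():
        f.attrs[k] = v
    if data.acs is not None:
        _save_kspace_group(f.create_group("acs"), data.acs)


def _load_kspace_group(f) -> KSpaceData:
    proto_attrs = {
        k[len("protocol_") :]: v
        for k, v in f.attrs.items()
        if k.startswith("protocol_")
    }
    return KSpaceData(
        samples=f["samples"][()],
        trajectories={1: _read_traj(f["traj"], "plus"), -1: _read_traj(f["traj"], "minus")},
        ky_per_line=f["lines/ky_per_line"][()],
        line_indices=f["lines/indices"][()],
        acquired_line_mask=f["lines/acquired_mask"][()].astype(bool),
        line_polarity=f["lines/polarity"][()],
        frame_polarity=f["lines/frame_polarity"][()],
        echo_spacing_s=float(f.attrs["echo_spacing_s"]),
        te_s=float(f.attrs["te_s"]),
        protocol=_protocol_from_attrs(proto_attrs),
        girf=_girf_from_attrs(f.attrs),
        navigator=f["navigator"][()],
        acs=_load_kspace_group(f["acs"]) if "acs" in f else None,
        noise_sd=float(f.attrs["noise_sd"]),
    )


def save_kspace(path, data: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        _save_kspace_group(f, data)


def load_kspace(path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        return _load_kspace_group(f)


def write_nifti(path, image: np.ndarray, pixel_size_m: float) -> None:
    """Write a 2-D (or stacked 3-D) image as NIfTI-1.

    Complex images are written as a 2-volume magnitude/phase stack; pixel
    size is recorded in the header in mm.
    """
    img = np.asarray(image)
    if np.iscomplexobj(img):
        vols = np.stack([np.abs(img), np.angle(img)], axis=-1)
    else:
        vols = img.astype(np.float64)
    affine = np.diag([pixel_size_m * 1e3, pixel_size_m * 1e3, 1.0, 1.0])
    nib.save(nib.Nifti1Image(vols, affine), str(path))


def read_nifti_complex(path) -> np.ndarray:
    """Read a magnitude/phase NIfTI pair written by :func:`write_nifti`."""
    vols = np.asarray(nib.load(str(path)).dataobj)
    if vols.ndim == 3 and vols.shape[-1] == 2:
        return vols[..., 0] * np.exp(1j * vols[..., 1])
    return vols


def protocol_from_dict(d: dict) -> EpiProtocol:
    known = {f.name for f in dataclasses.fields(EpiProtocol)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    return EpiProtocol(**d)


def girf_from_dict(d) -> GirfModel:
    if isinstance(d, str):
        return girf_preset(d)
    if "preset" in d:
        return girf_preset(d["preset"])
    return GirfModel(
        delay_s=d.get("delay_s", 0.0),
        eddy_terms=tuple(map(tuple, d.get("eddy_terms", []))),
        resonance_terms=tuple(map(tuple, d.get("resonance_terms", []))),
        third_order_shim_connected=d.get("third_order_shim_connected", True),
    )


def load_config_file(path) -> dict:
    with open(Path(path), "rb") as fh:
        return tomllib.load(fh)
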