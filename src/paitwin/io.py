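"""HDF5 / YAML persistence for phantoms, channel data and images."""

from __future__ import annotations

import h5py
import numpy as np
import yaml

from .forward import ChannelData
from .phantoms import (CLASS_NAMES, LabelMap, NodeGroundTruth, TissuePhantom)
from .recon import MultispectralImage

__all__ = [
    "save_phantom", "load_phantom",
    "save_channels", "load_channels",
    "save_msi", "load_msi",
]

_GRIDS = ("mua", "mus_reduced", "gruneisen", "sos", "density", "attenuation",
          "so2_truth", "bvf_truth")


def save_phantom(path, phantom: TissuePhantom) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=phantom.label_map.labels)
        f.attrs["spacing"] = phantom.spacing
        f.attrs["class_table"] = yaml.safe_dump(
            {int(k): v for k, v in phantom.label_map.class_table.items()})
        f.create_dataset("wavelengths", data=phantom.wavelengths)
        for name in _GRIDS:
            f.create_dataset(name, data=getattr(phantom, name))
        if phantom.node_truth is not None:
            g = f.create_group("node_truth")
            g.attrs["bvf"] = phantom.node_truth.bvf
            g.attrs["so2"] = phantom.node_truth.so2
            g.attrs["state_name"] = phantom.node_truth.state_name


def load_phantom(path) -> TissuePhantom:
    with h5py.File(path, "r") as f:
        class_table = {int(k): v for k, v in
                       yaml.safe_load(f.attrs["class_table"]).items()}
        label_map = LabelMap(labels=f["labels"][()],
                             spacing=float(f.attrs["spacing"]),
                             class_table=class_table)
        node_truth = None
        if "node_truth" in f:
            g = f["node_truth"]
            node_truth = NodeGroundTruth(bvf=float(g.attrs["bvf"]),
                                         so2=float(g.attrs["so2"]),
                                         state_name=str(g.attrs["state_name"]))
        grids = {name: f[name][()] for name in _GRIDS}
        return TissuePhantom(label_map=label_map,
                             wavelengths=f["wavelengths"][()],
                             node_truth=node_truth, **grids)


def save_channels(path, cd: ChannelData, metadata: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=cd.samples)
        f.create_dataset("wavelengths", data=cd.wavelengths)
        f.attrs["time_step"] = cd.time_step
        for k, v in (metadata or {}).items():
            f.attrs[k] = v


def load_channels(path) -> tuple[ChannelData, dict]:
    with h5py.File(path, "r") as f:
        cd = ChannelData(samples=f["samples"][()],
                         time_step=float(f.attrs["time_step"]),
                         wavelengths=f["wavelengths"][()])
        meta = {k: v for k, v in f.attrs.items() if k != "time_step"}
    return cd, meta


def save_msi(path, msi: MultispectralImage) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("pixels", data=msi.pixels)
        f.create_dataset("wavelengths", data=msi.wavelengths)
        f.attrs["spacing"] = msi.spacing


def load_msi(path) -> MultispectralImage:
    with h5py.File(path, "r") as f:
        return MultispectralImage(pixels=f["pixels"][()],
                                  spacing=float(f.attrs["spacing"]),
                                  wavelengths=f["wavelengths"][()])
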