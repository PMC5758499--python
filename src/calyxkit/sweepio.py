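"""HDF5 sweep bundles and TIFF stacks.

Sweep bundles: one group per sweep (``/sweeps/<i>/samples``) with
``sample_rate``, ``mode`` and a JSON protocol descriptor as attributes;
injected ground truth, when present, under ``/sweeps/<i>/ground_truth``.
Stacks are multi-page TIFFs with the voxel spacing recorded in the image
description tag (JSON).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .protocol import StimulusProtocol
from .synth import EventGroundTruth, ImageStack, SweepRecording

__all__ = ["write_sweeps", "read_sweeps", "write_stack", "read_stack"]

_GT_FIELDS = ("event_times", "true_eepsp_slope", "true_eap_dvdt",
              "true_prespike_amp", "is_failure")


def _protocol_to_json(proto) -> str:
    if proto is None:
        return "null"
    if isinstance(proto, StimulusProtocol):
        return json.dumps({"kind": "two_burst", **proto.to_dict()})
    return json.dumps(proto)


def _protocol_from_json(s: str):
    d = json.loads(s)
    if d is None:
        return None
    if isinstance(d, dict) and d.get("kind") == "two_burst":
        d = dict(d)
        d.pop("kind")
        return StimulusProtocol.from_dict(d)
    return d


def write_sweeps(path, sweeps: list[SweepRecording], meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("sweeps")
        for i, sw in enumerate(sweeps):
            g = root.create_group(str(i))
            g.create_dataset("samples", data=sw.samples, compression="gzip")
            g.attrs["sample_rate"] = sw.sample_rate
            g.attrs["mode"] = sw.mode
            g.attrs["protocol"] = _protocol_to_json(sw.protocol)
            if sw.meta:
                g.attrs["meta"] = json.dumps(sw.meta)
            if sw.ground_truth is not None:
                gt = g.create_group("ground_truth")
                for name in _GT_FIELDS:
                    gt.create_dataset(name, data=getattr(sw.ground_truth, name))
        if meta:
            for k, v in meta.items():
                f.attrs[k] = v


def read_sweeps(path) -> list[SweepRecording]:
    out: list[SweepRecording] = []
    with h5py.File(path, "r") as f:
        root = f["sweeps"]
        for key in sorted(root, key=int):
            g = root[key]
            gt = None
            if "ground_truth" in g:
                gt = EventGroundTruth(**{
                    name: g["ground_truth"][name][()] for name in _GT_FIELDS
                })
            out.append(SweepRecording(
                samples=g["samples"][()],
                sample_rate=float(g.attrs["sample_rate"]),
                mode=str(g.attrs["mode"]),
                protocol=_protocol_from_json(g.attrs["protocol"]),
                ground_truth=gt,
                meta=json.loads(g.attrs["meta"]) if "meta" in g.attrs else {},
            ))
    return out


def write_stack(path, stack: ImageStack) -> None:
    desc = json.dumps({"spacing_um_zyx": list(stack.spacing), **stack.meta})
    tifffile.imwrite(path, stack.voxels.astype(np.float32), description=desc)


def read_stack(path) -> ImageStack:
    with tifffile.TiffFile(path) as tf:
        vox = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc) if desc else {}
    spacing = tuple(meta.pop("spacing_um_zyx", (0.5, 0.1, 0.1)))
    return ImageStack(vox.astype(float), spacing, meta=meta)
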