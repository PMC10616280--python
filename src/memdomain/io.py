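"""Reading and writing the pipeline's exchange formats.

ACF curves and diffusion-time grids travel as tidy CSV with a header;
ground truth rides in JSON sidecars; image stacks are multi-page TIFF
(ZYX, 16-bit) with voxel calibration in a JSON sidecar; mesh snapshots
export to PLY with the vertex type encoded as colour.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd

from .fcs import ACFCurve, ZScanSeries
from .synthetic import ImageStack

__all__ = [
    "write_acf_csv", "read_acf_csv",
    "write_zscan_csv", "read_zscan_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_json", "read_json",
]


def write_acf_csv(curves: Sequence[ACFCurve], path) -> None:
    rows = []
    for c in curves:
        for lag, g in zip(c.lags, c.g):
            rows.append((c.vesicle_id, c.waist, c.z_offset, lag, g))
    df = pd.DataFrame(rows, columns=["vesicle_id", "waist_um", "z_um",
                                     "lag_s", "value"])
    df.to_csv(path, index=False)


def read_acf_csv(path) -> List[ACFCurve]:
    df = pd.read_csv(path)
    curves = []
    for (vid, waist, z), grp in df.groupby(
            ["vesicle_id", "waist_um", "z_um"], sort=False):
        grp = grp.sort_values("lag_s")
        curves.append(ACFCurve(lags=grp["lag_s"].to_numpy(),
                               g=grp["value"].to_numpy(),
                               vesicle_id=str(vid), waist=float(waist),
                               z_offset=float(z)))
    return curves


def write_zscan_csv(series: Sequence[ZScanSeries], path) -> None:
    rows = []
    for s in series:
        for z, tau in zip(s.z, s.tau_d):
            rows.append((s.vesicle_id, s.waist, z, tau))
    df = pd.DataFrame(rows, columns=["vesicle_id", "waist_um", "z_um",
                                     "tau_d_ms"])
    df.to_csv(path, index=False)


def read_zscan_csv(path) -> List[ZScanSeries]:
    df = pd.read_csv(path)
    out = []
    for (vid, waist), grp in df.groupby(["vesicle_id", "waist_um"], sort=False):
        out.append(ZScanSeries(z=grp["z_um"].to_numpy(),
                               tau_d=grp["tau_d_ms"].to_numpy(),
                               waist=float(waist), vesicle_id=str(vid)))
    return out


def write_stack_tiff(stack: ImageStack, path) -> None:
    import tifffile
    path = Path(path)
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.rint(data), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = {"voxel_size_um": list(stack.voxel_size),
               "origin_um": list(stack.origin), "axes": "ZYX"}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack_tiff(path) -> ImageStack:
    import tifffile
    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageStack(data=data, voxel_size=tuple(meta["voxel_size_um"]),
                      origin=tuple(meta.get("origin_um", (0, 0, 0))))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     cls=_NumpyEncoder) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
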