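"""Reading and writing of scene artifacts.

Images: 16-bit grayscale TIFF for scan/phase/nuclei/IVM, 8-bit PNG for masks
and region maps.  Tables: CSV via pandas.  Parameters: YAML.  All writers are
deterministic (no timestamps) so fixed-seed pipeline runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SceneParams, SyntheticScene


def write_image16(path, img: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit grayscale TIFF."""
    data = np.clip(np.asarray(img, float), 0.0, 1.0)
    tifffile.imwrite(str(path), (data * 65535.0 + 0.5).astype(np.uint16))


def read_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG and rescale integer types to [0, 1]."""
    arr = np.asarray(
        tifffile.imread(str(path))
        if str(path).lower().endswith((".tif", ".tiff"))
        else iio.imread(str(path))
    )
    if arr.ndim == 3:  # drop any color axis
        arr = arr[..., 0]
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(str(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def _params_to_dict(params: SceneParams) -> dict:
    d = dataclasses.asdict(params)
    if d.get("pattern") is None:
        d["pattern"] = dataclasses.asdict(params.resolved_pattern())
    d["cell_diameter_um"] = list(d["cell_diameter_um"])
    return d


def write_scene(scene: SyntheticScene, out_dir) -> None:
    """Write scan/phase/nuclei TIFFs, truth CSV, dark-zone PNG and params YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image16(out / "scan.tif", scene.scan)
    write_image16(out / "phase.tif", scene.phase)
    write_image16(out / "nuclei.tif", scene.nuclei)
    write_mask_png(out / "dark_zone.png", scene.truth.dark_zone_mask)

    t = scene.truth
    rows = [
        {"kind": "cell", "row_px": r, "col_px": c, "diameter_um": d}
        for (r, c), d in zip(t.cell_centroids, t.cell_diameters_um)
    ] + [
        {"kind": "debris", "row_px": r, "col_px": c, "diameter_um": float("nan")}
        for r, c in t.debris_centroids
    ]
    pd.DataFrame(rows, columns=["kind", "row_px", "col_px", "diameter_um"]).to_csv(
        out / "truth.csv", index=False, float_format="%.4f"
    )
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(_params_to_dict(scene.params), fh, sort_keys=True)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_detections_csv(path, det) -> None:
    pd.DataFrame(
        {
            "row_px": det.centroids[:, 0],
            "col_px": det.centroids[:, 1],
            "area_px": det.areas_px,
        }
    ).to_csv(path, index=False, float_format="%.4f")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
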