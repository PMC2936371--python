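"""Image and result I/O.

Readers accept 8/16-bit grayscale PNG/TIFF (and single-frame DICOM) and
normalize to floats in [0, 1]; writers serialize tracked trees, centerline
tables, metrics and the run configuration in stable, diff-friendly form
(JSON values rounded to 4 decimals, keys sorted).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .config import RunConfig
from .pto import ArteryElement
from .tracker import ArteryTree, MetricsReport, TrackedBranch, TreeNode


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

def read_image(path: str | Path, invert: bool = False) -> np.ndarray:
    """Read a grayscale image as floats in [0, 1].

    PNG/TIFF via imageio; ``.dcm`` via pydicom (first frame of multi-frame
    files).  RGB inputs are converted by luminance with a warning.  With
    ``invert`` the gray scale is flipped (dark-vessel angiograms).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = np.asarray(ds.pixel_array, float)
        if arr.ndim == 3:
            arr = arr[0]
    else:
        import imageio.v3 as iio

        try:
            raw = np.asarray(iio.imread(path))
        except Exception as exc:  # pragma: no cover - format specific
            raise ValueError(f"cannot read {path.name} as PNG/TIFF: {exc}") from exc
        arr = raw
        if arr.ndim == 3:
            if arr.shape[-1] in (3, 4):
                warnings.warn(f"{path.name}: RGB input converted by luminance")
                arr = arr[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
            else:
                raise ValueError(f"{path.name}: ambiguous multichannel layout "
                                 f"{arr.shape}")
        arr = np.asarray(arr, float)
        if np.issubdtype(raw.dtype, np.integer):
            arr = arr / float(np.iinfo(raw.dtype).max)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image")
    lo, hi = float(arr.min()), float(arr.max())
    if hi > 1.0 or lo < 0.0:
        arr = (arr - lo) / max(hi - lo, 1e-12)
    if invert:
        arr = arr.max() - arr
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as 16-bit PNG/TIFF (clipped to [0, 1])."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(image, float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 65535).astype(np.uint16))


def write_float_map(path: str | Path, data: np.ndarray) -> None:
    """Write a float map (vesselness, best scale) as 32-bit TIFF."""
    import tifffile

    tifffile.imwrite(Path(path), np.asarray(data, np.float32))


# ---------------------------------------------------------------------------
# trees and results
# ---------------------------------------------------------------------------

def _round(x, nd=4):
    return round(float(x), nd)


def tree_to_dict(tree: ArteryTree) -> dict:
    return {
        "seed": None if tree.seed is None else [_round(v) for v in tree.seed],
        "branches": [
            {
                "level": b.level,
                "spawn_node": b.spawn_node,
                "end_node": b.end_node,
                "end_reason": b.end_reason,
                "elements": [
                    {
                        "x": _round(e.position[0]),
                        "y": _round(e.position[1]),
                        "zhat": _round(e.zhat),
                        "dx": _round(e.direction[0]),
                        "dy": _round(e.direction[1]),
                        "diameter": _round(e.diameter),
                    }
                    for e in b.elements
                ],
            }
            for b in tree.branches
        ],
        "nodes": [
            {
                "x": _round(n.position[0]),
                "y": _round(n.position[1]),
                "kind": n.kind,
                "membership": _round(n.membership),
                "id": n.node_id,
                "radius": _round(n.radius),
            }
            for n in tree.nodes
        ],
        "config": tree.config,
    }


def tree_from_dict(d: dict) -> ArteryTree:
    branches = []
    for bd in d.get("branches", []):
        els = [ArteryElement(position=np.array([ed["x"], ed["y"]]),
                             zhat=ed["zhat"],
                             direction=np.array([ed["dx"], ed["dy"]]),
                             diameter=ed["diameter"])
               for ed in bd["elements"]]
        branches.append(TrackedBranch(elements=els, level=bd.get("level", 1),
                                      spawn_node=bd.get("spawn_node"),
                                      end_node=bd.get("end_node"),
                                      end_reason=bd.get("end_reason", "")))
    nodes = [TreeNode(position=np.array([nd["x"], nd["y"]]), kind=nd["kind"],
                      membership=nd.get("membership", 1.0),
                      node_id=nd.get("id", -1), radius=nd.get("radius", 10.0))
             for nd in d.get("nodes", [])]
    seed = d.get("seed")
    return ArteryTree(branches=branches, nodes=nodes,
                      seed=None if seed is None else tuple(seed),
                      config=d.get("config", {}))


def write_tree(path: str | Path, tree: ArteryTree) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=1, sort_keys=True))


def read_tree(path: str | Path) -> ArteryTree:
    return tree_from_dict(json.loads(Path(path).read_text()))


def write_centerlines_csv(path: str | Path, tree: ArteryTree) -> None:
    """One row per artery element: branch id, x, y, diameter, vesselness."""
    import pandas as pd

    rows = []
    for bi, b in enumerate(tree.branches):
        for e in b.elements:
            rows.append({"branch": bi, "x": _round(e.position[0]),
                         "y": _round(e.position[1]),
                         "diameter": _round(e.diameter),
                         "zhat": _round(e.zhat)})
    pd.DataFrame(rows, columns=["branch", "x", "y", "diameter", "zhat"]).to_csv(
        Path(path), index=False)


def write_metrics(path: str | Path, metrics: MetricsReport) -> None:
    d = {k: (v if isinstance(v, (dict, bool)) else _round(v))
         for k, v in vars(metrics).items()}
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def write_overlay(path: str | Path, image: np.ndarray, tree: ArteryTree) -> None:
    """RGB overlay: image in gray, centerlines in red, nodes marked."""
    g = np.clip(np.asarray(image, float), 0, 1)
    rgb = np.stack([g, g, g], axis=-1)
    H, W = g.shape
    pts = tree.dense_points(0.5)
    for x, y in pts:
        xi, yi = int(round(x)), int(round(y))
        if 0 <= xi < W and 0 <= yi < H:
            rgb[yi, xi] = (1.0, 0.1, 0.1)
    colors = {"termination": (0.2, 0.4, 1.0), "bifurcation": (0.1, 1.0, 0.1),
              "crossing": (1.0, 1.0, 0.1)}
    for n in tree.nodes:
        c = colors.get(n.kind, (1, 1, 1))
        xi, yi = int(round(n.position[0])), int(round(n.position[1]))
        for dy in range(-2, 3):
            for dx in range(-2, 3):
                if 0 <= xi + dx < W and 0 <= yi + dy < H and abs(dx) + abs(dy) <= 2:
                    rgb[yi + dy, xi + dx] = c
    import imageio.v3 as iio

    iio.imwrite(Path(path), (rgb * 255).astype(np.uint8))


def write_results(out_dir: str | Path, tree: ArteryTree, cfg: RunConfig,
                  image: np.ndarray | None = None,
                  metrics: MetricsReport | None = None) -> dict[str, Path]:
    """Write tree.json, centerlines.csv, config.json (+ overlay.png and
    metrics.json when available) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    files["tree"] = out / "tree.json"
    write_tree(files["tree"], tree)
    files["centerlines"] = out / "centerlines.csv"
    write_centerlines_csv(files["centerlines"], tree)
    files["config"] = out / "config.json"
    cfg.dump(files["config"])
    if image is not None:
        files["overlay"] = out / "overlay.png"
        write_overlay(files["overlay"], image, tree)
    if metrics is not None:
        files["metrics"] = out / "metrics.json"
        write_metrics(files["metrics"], metrics)
    return files
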