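"""Readers/writers: multi-page TIFF stacks, PNG masks, CEE CSVs, regression
spec JSON and the cohort manifest. Every writer/reader pair round-trips
bit-identically; schema errors name the offending field."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cee_features import FACTOR_ORDER
from .segmentation import SliceStack


class SchemaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stacks


def write_stack(stack: SliceStack, path) -> None:
    """Multi-page TIFF, slices bottom -> top, float64 pages; geometry and
    provenance go into the ImageDescription tag as JSON."""
    desc = json.dumps({
        "embryo_id": stack.embryo_id,
        "pixel_size_um": stack.pixel_size_um,
        "slice_pitch_um": stack.slice_pitch_um,
        "meta": {k: v for k, v in stack.meta.items()
                 if isinstance(v, (str, int, float, bool, dict))},
    })
    tifffile.imwrite(str(path), stack.slices.astype(np.float64),
                     description=desc)


def read_stack(path, expected_n_slices: int | None = None) -> SliceStack:
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description or "{}"
    if pages.ndim == 2:
        pages = pages[None]
    if expected_n_slices is not None and pages.shape[0] != expected_n_slices:
        raise SchemaError(
            f"{path}: expected {expected_n_slices} pages, found {pages.shape[0]}")
    try:
        info = json.loads(desc)
    except json.JSONDecodeError:
        info = {}
    return SliceStack(
        embryo_id=info.get("embryo_id", Path(path).stem),
        slices=pages.astype(np.float64),
        pixel_size_um=float(info.get("pixel_size_um", 1.0)),
        slice_pitch_um=float(info.get("slice_pitch_um", 10.0)),
        meta=info.get("meta", {}),
    )


def write_masks(masks: np.ndarray, directory) -> list[Path]:
    """One 8-bit PNG per slice (0/255), named mask_<index>.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, m in enumerate(np.asarray(masks)):
        p = directory / f"mask_{i:02d}.png"
        iio.imwrite(p, (m.astype(np.uint8) * 255))
        paths.append(p)
    return paths


def read_masks(directory) -> np.ndarray:
    directory = Path(directory)
    files = sorted(directory.glob("mask_*.png"))
    if not files:
        raise FileNotFoundError(f"no mask PNGs under {directory}")
    return np.stack([iio.imread(f) > 127 for f in files])


# ---------------------------------------------------------------------------
# tables


def write_cee(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cee(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in FACTOR_ORDER if c not in table.columns]
    if missing:
        raise SchemaError(f"CEE table missing column: {missing[0]}")
    return table


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    for col in ("embryo_id", "stack_path", "outcome"):
        if col not in manifest.columns:
            raise SchemaError(f"manifest missing column: {col}")
    return manifest


def join_manifest_cee(manifest: pd.DataFrame, cee: pd.DataFrame) -> pd.DataFrame:
    """Inner join on embryo_id; any orphan id on either side is a hard error."""
    if "embryo_id" not in cee.columns:
        raise SchemaError("CEE table missing column: embryo_id")
    m_ids = set(manifest["embryo_id"])
    c_ids = set(cee["embryo_id"])
    orphans = sorted(m_ids ^ c_ids)
    if orphans:
        raise SchemaError(f"unmatched embryo_id between manifest and CEE table: "
                          f"{orphans[:10]}")
    return manifest.merge(cee, on="embryo_id", validate="one_to_one")


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(embryos, outdir) -> pd.DataFrame:
    """Write stacks (TIFF), ground-truth masks (PNG), the CEE CSV and a
    manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "stacks").mkdir(parents=True, exist_ok=True)
    rows = []
    cee_rows = []
    for e in embryos:
        stack_path = outdir / "stacks" / f"{e.embryo_id}.tiff"
        write_stack(e.stack, stack_path)
        mask_dir = outdir / "masks" / e.embryo_id
        write_masks(e.masks, mask_dir)
        rows.append({"embryo_id": e.embryo_id,
                     "stack_path": str(stack_path.relative_to(outdir)),
                     "mask_dir": str(mask_dir.relative_to(outdir)),
                     "outcome": e.outcome})
        cee_rows.append({"embryo_id": e.embryo_id, **e.cee})
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, outdir / "manifest.csv")
    write_cee(pd.DataFrame(cee_rows), outdir / "cee.csv")
    return manifest


def save_volume(volume, path) -> None:
    """Compressed array file with a JSON header of provenance."""
    np.savez_compressed(path, voxels=volume.voxels.astype(np.float32))
    with open(str(path) + ".json", "w") as fh:
        json.dump({"embryo_id": volume.embryo_id,
                   "shape": list(volume.voxels.shape),
                   "intensity_scale": volume.intensity_scale,
                   "degenerate": volume.degenerate}, fh)


def load_volume(path):
    from .reconstruction import Volume3D

    with open(str(path) + ".json") as fh:
        info = json.load(fh)
    with np.load(path) as data:
        vox = data["voxels"].astype(np.float64)
    return Volume3D(embryo_id=info["embryo_id"], voxels=vox,
                    intensity_scale=info["intensity_scale"],
                    degenerate=info["degenerate"])
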