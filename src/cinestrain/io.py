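"""Readers and writers for the package's on-disk formats.

Masks travel either as a PNG/TIFF series with a ``manifest.csv``
(columns ``slice,frame,path`` plus a ``stack_meta.json`` holding the
physical spacing) or as NIfTI volumes laid out (x, y, frame), one file
per slice.  Contours, strain curves, slope metrics, point tracks and
thickening tables are plain CSV with the headers documented on each
function; scalar reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .strain import SlopeMetrics, StrainCurve
from .tagged import PointTrack, TaggedSequence
from .ventriculo import SegmentationStack

_META_NAME = "stack_meta.json"


# ---------------------------------------------------------------------------
# segmentation stacks
# ---------------------------------------------------------------------------

def write_mask_stack(stack: SegmentationStack, outdir, fmt: str = "png") -> Path:
    """Write one image per (slice, frame) plus manifest and spacing metadata.

    Returns the manifest path.  ``fmt`` is "png" or "tif".
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(stack.n_slices):
        for t in range(stack.n_frames):
            name = f"mask_s{s:02d}_f{t:03d}.{fmt}"
            iio.imwrite(outdir / name, stack.masks[s, t])
            rows.append({"slice": s, "frame": t, "path": name})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    (outdir / _META_NAME).write_text(json.dumps({
        "pixel_area": stack.pixel_area,
        "slice_spacing": stack.slice_spacing,
    }))
    return manifest


def write_mask_stack_nifti(stack: SegmentationStack, outdir) -> list[Path]:
    """One (x, y, frame) NIfTI per slice; zooms carry pixel size and
    slice spacing."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = float(np.sqrt(stack.pixel_area))
    paths = []
    for s in range(stack.n_slices):
        vol = np.transpose(stack.masks[s], (2, 1, 0))  # (W, H, T) -> x, y, frame
        img = nib.Nifti1Image(vol.astype(np.uint8), affine=np.eye(4))
        img.header.set_zooms((px, px, stack.slice_spacing))
        p = outdir / f"mask_slice{s:02d}.nii.gz"
        nib.save(img, p)
        paths.append(p)
    return paths


def read_mask_stack(
    path,
    pixel_area: float | None = None,
    slice_spacing: float | None = None,
) -> SegmentationStack:
    """Load a stack from a manifest CSV, a NIfTI file, or a directory of
    per-slice NIfTI files.  Explicit spacing arguments override metadata."""
    path = Path(path)
    if path.suffix == ".csv":
        return _read_manifest(path, pixel_area, slice_spacing)
    if path.is_dir():
        files = sorted(path.glob("*.nii*"))
        if not files:
            manifest = path / "manifest.csv"
            if manifest.exists():
                return _read_manifest(manifest, pixel_area, slice_spacing)
            raise FileNotFoundError(f"no NIfTI files or manifest.csv in {path}")
        return _read_nifti_slices(files, pixel_area, slice_spacing)
    return _read_nifti_slices([path], pixel_area, slice_spacing)


def _read_manifest(manifest: Path, pixel_area, slice_spacing) -> SegmentationStack:
    df = pd.read_csv(manifest)
    base = manifest.parent
    meta = {}
    meta_path = base / _META_NAME
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    pixel_area = pixel_area if pixel_area is not None else meta.get("pixel_area", 1.0)
    slice_spacing = (
        slice_spacing if slice_spacing is not None else meta.get("slice_spacing", 1.0)
    )
    slices = sorted(df["slice"].unique())
    frames = sorted(df["frame"].unique())
    first = None
    data = {}
    for row in df.itertuples():
        p = base / row.path
        if not p.exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
        img = np.asarray(iio.imread(p))
        data[(row.slice, row.frame)] = img
        first = img if first is None else first
    masks = np.zeros((len(slices), len(frames)) + first.shape, dtype=np.uint8)
    for (s, t), img in data.items():
        masks[slices.index(s), frames.index(t)] = img
    return SegmentationStack(masks, pixel_area=pixel_area, slice_spacing=slice_spacing)


def _read_nifti_slices(files, pixel_area, slice_spacing) -> SegmentationStack:
    vols, zooms = [], None
    for f in files:
        img = nib.load(str(f))
        zooms = img.header.get_zooms()
        vols.append(np.transpose(np.asarray(img.dataobj), (2, 1, 0)))  # -> (T, H, W)
    if pixel_area is None:
        pixel_area = float(zooms[0]) * float(zooms[1])
    if slice_spacing is None:
        slice_spacing = float(zooms[2])
    return SegmentationStack(
        np.stack(vols), pixel_area=pixel_area, slice_spacing=slice_spacing
    )


# ---------------------------------------------------------------------------
# contours
# ---------------------------------------------------------------------------

def write_contours(records: dict, path) -> None:
    """``records[(slice, frame, layer)]`` is an (N, 2) point array; written
    with header ``slice,frame,layer,point_index,x,y``."""
    rows = []
    for (s, f, layer), pts in records.items():
        for k, (x, y) in enumerate(np.asarray(pts, float)):
            rows.append({"slice": s, "frame": f, "layer": layer,
                         "point_index": k, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours(path) -> dict:
    df = pd.read_csv(path)
    out = {}
    for (s, f, layer), grp in df.groupby(["slice", "frame", "layer"]):
        grp = grp.sort_values("point_index")
        out[(s, f, layer)] = grp[["x", "y"]].to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# strain curves and metrics
# ---------------------------------------------------------------------------

def write_strain_curves(
    curves: list[StrainCurve], path, slice_id: int = 0, level: str = "mid-cavity"
) -> None:
    """Header ``slice,level,direction,layer,sector,frame,strain``."""
    rows = []
    for c in curves:
        for t, v in enumerate(c.values, start=1):
            rows.append({
                "slice": slice_id, "level": level, "direction": c.direction,
                "layer": c.layer, "sector": c.sector_id, "frame": t, "strain": v,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_slope_metrics(
    entries: list[tuple[StrainCurve, SlopeMetrics]], path,
    slice_id: int = 0, level: str = "mid-cavity",
) -> None:
    """Header ``slice,level,direction,layer,sector,S1,S2,peak,peak_frame``."""
    rows = []
    for curve, m in entries:
        rows.append({
            "slice": slice_id, "level": level, "direction": curve.direction,
            "layer": curve.layer, "sector": curve.sector_id,
            "S1": m.s1, "S2": m.s2 if m.s2_defined else np.nan,
            "peak": m.peak, "peak_frame": m.peak_frame,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_thickening_table(tables: dict[str, dict[int, float]], path) -> None:
    """Header ``subject,sector_1..sector_16`` (segment 17 never reported)."""
    rows = []
    for subject, sectors in tables.items():
        row = {"subject": subject}
        row.update({f"sector_{i}": sectors.get(i, np.nan) for i in range(1, 17)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tagged sequences, seeds and tracks
# ---------------------------------------------------------------------------

def read_tagged_stack(path, spacing: float = 1.0) -> TaggedSequence:
    """Multi-page TIFF or NIfTI (x, y, frame) tagged stack."""
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        frames = tifffile.imread(path)
    else:
        vol = np.asarray(nib.load(str(path)).dataobj)
        frames = np.transpose(vol, (2, 1, 0))
    return TaggedSequence(frames=np.asarray(frames, float), spacing=spacing)


def write_tagged_stack(seq: TaggedSequence, path) -> None:
    tifffile.imwrite(path, seq.frames.astype(np.float32))


def read_seeds(path) -> list[tuple[float, float]]:
    """Seed CSV with header ``point_id,x,y``."""
    df = pd.read_csv(path).sort_values("point_id")
    return list(zip(df["x"].to_numpy(float), df["y"].to_numpy(float)))


def write_tracks(tracks: list[PointTrack], path) -> None:
    """Header ``point_id,frame,x,y,corr`` (corr is nan for frame 1)."""
    rows = []
    for pid, tr in enumerate(tracks):
        for t, (x, y) in enumerate(tr.positions):
            corr = tr.scores[t - 1] if t > 0 else np.nan
            rows.append({"point_id": pid, "frame": t + 1, "x": x, "y": y,
                         "corr": corr})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json_report(report: dict, path) -> None:
    def _coerce(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    Path(path).write_text(
        json.dumps({k: _coerce(v) for k, v in report.items()}, indent=2)
    )
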