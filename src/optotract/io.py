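"""Readers and writers for the standard formats the pipeline touches.

All on-disk conventions are normalized at this boundary: streamline
coordinates are always returned in scanner/world millimetre (RAS) space no
matter the voxel convention of the file, surfaces come back with normals
and vertex areas populated, and spike CSVs are validated against their
period sidecars.  No science lives here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .histology import HistologyBlock
from .spikes import Periods, SpikeRecord
from .surface import LabeledSurface
from .tracts import SurfaceMap, TerminalGeometry, Tractogram

log = logging.getLogger("optotract")


class FormatError(ValueError):
    """Malformed or unsupported on-disk data."""


class EmptyTractogramError(FormatError):
    pass


# ---------------------------------------------------------------------------
# Streamlines (TRK / TCK)
# ---------------------------------------------------------------------------


def write_tractogram(tractogram: Tractogram, path: str | Path) -> None:
    """Write streamlines (world mm, RAS) as TRK or TCK by extension."""
    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise FormatError(f"unsupported tractogram extension: {path.suffix}")
    nib_tg = nib.streamlines.Tractogram(
        [s.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nib_tg, str(path))
    log.info("write_tractogram: %d streamlines -> %s", len(tractogram), path)


def read_tractogram(path: str | Path, space_check: bool = True) -> Tractogram:
    """Load a TRK/TCK tractogram in world millimetre (RAS) coordinates.

    nibabel applies the on-disk voxel-to-world transform, so a TRK stored
    with a non-RAS voxel order yields the same coordinates as the
    equivalent TCK.  ``space_check`` additionally requires all coordinates
    finite.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises several header error types
        raise FormatError(f"cannot parse tractogram {path.name}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    if not streamlines:
        raise EmptyTractogramError(f"{path.name} contains no streamlines")
    if space_check:
        for s in streamlines:
            if not np.isfinite(s).all():
                raise FormatError(f"{path.name}: non-finite coordinates")
    log.info("read_tractogram: %d streamlines <- %s", len(streamlines), path)
    return Tractogram(streamlines)


# ---------------------------------------------------------------------------
# Surfaces and surface maps (GIfTI)
# ---------------------------------------------------------------------------


def write_surface(surface: LabeledSurface, path: str | Path) -> None:
    """Write mesh + labels (+ normals) to a GIfTI file."""
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            surface.vertices.astype(np.float32),
            intent="NIFTI_INTENT_POINTSET", datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            surface.triangles.astype(np.int32),
            intent="NIFTI_INTENT_TRIANGLE", datatype="NIFTI_TYPE_INT32",
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            surface.vertex_labels.astype(np.int32),
            intent="NIFTI_INTENT_LABEL", datatype="NIFTI_TYPE_INT32",
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            surface.vertex_normals.astype(np.float32),
            intent="NIFTI_INTENT_VECTOR", datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    nib.save(img, str(path))


def read_surface(path: str | Path) -> LabeledSurface:
    """Read a labeled surface from GIfTI; recompute anything absent.

    Raises :class:`FormatError` on missing mesh arrays and a consistency
    error when the label array length disagrees with the vertex count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    by_intent: dict[int, list[np.ndarray]] = {}
    for da in img.darrays:
        by_intent.setdefault(da.intent, []).append(da.data)
    codes = nib.nifti1.intent_codes.code
    try:
        vertices = by_intent[codes["NIFTI_INTENT_POINTSET"]][0]
        triangles = by_intent[codes["NIFTI_INTENT_TRIANGLE"]][0]
    except KeyError as exc:
        raise FormatError(f"{path.name}: missing mesh array ({exc})") from exc
    labels = by_intent.get(codes["NIFTI_INTENT_LABEL"], [None])[0]
    if labels is None:
        labels = np.zeros(len(vertices), dtype=np.int64)
    normals = by_intent.get(codes["NIFTI_INTENT_VECTOR"], [None])[0]
    return LabeledSurface(
        vertices=np.asarray(vertices, dtype=float),
        triangles=np.asarray(triangles, dtype=np.int64),
        vertex_labels=np.asarray(labels, dtype=np.int64),
        vertex_normals=None if normals is None else np.asarray(normals, float),
    )


def write_surface_map(map_: SurfaceMap, path: str | Path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            np.asarray(map_.values, dtype=np.float32),
            intent="NIFTI_INTENT_ESTIMATE", datatype="NIFTI_TYPE_FLOAT32",
        )
    )
    img.meta["kind"] = map_.kind
    nib.save(img, str(path))


def read_surface_map(path: str | Path) -> SurfaceMap:
    img = nib.load(str(path))
    if not img.darrays:
        raise FormatError(f"{Path(path).name}: no data arrays")
    kind = img.meta.get("kind", "density")
    return SurfaceMap(values=np.asarray(img.darrays[0].data, float), kind=kind)


# ---------------------------------------------------------------------------
# Histology blocks (NIfTI)
# ---------------------------------------------------------------------------


def write_block(block: HistologyBlock, path: str | Path) -> None:
    """Write a histology block as NIfTI with anisotropic voxel sizes."""
    sizes = np.array(
        [block.slice_spacing_mm, block.in_plane_res_mm, block.in_plane_res_mm]
    )
    order = [block.axis] + [a for a in range(3) if a != block.axis]
    affine = np.eye(4)
    affine[:3, :3] = 0.0
    for data_axis, world_axis in enumerate(order):
        affine[world_axis, data_axis] = sizes[data_axis]
    affine[:3, 3] = block.origin_mm + 0.5 * affine[:3, :3].sum(axis=1)
    nib.save(nib.Nifti1Image(block.slices.astype(np.float32), affine), str(path))


def read_block(path: str | Path) -> HistologyBlock:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if np.count_nonzero(rot) != 3:
        raise FormatError(f"{path.name}: block affine must be axis-aligned")
    world_axes = np.argmax(np.abs(rot), axis=0)
    sizes = rot[world_axes, np.arange(3)]
    if np.any(sizes <= 0):
        raise FormatError(f"{path.name}: negative or zero voxel sizes")
    origin = affine[:3, 3] - 0.5 * rot.sum(axis=1)
    return HistologyBlock(
        slices=np.asarray(img.dataobj, dtype=float),
        in_plane_res_mm=float(sizes[1]),
        slice_spacing_mm=float(sizes[0]),
        axis=int(world_axes[0]),
        origin_mm=origin,
    )


# ---------------------------------------------------------------------------
# Spikes (CSV + period sidecar)
# ---------------------------------------------------------------------------


def write_spikes(
    records: list[SpikeRecord], spikes_path: str | Path, periods_path: str | Path
) -> None:
    rows = [
        {"unit_id": r.unit_id, "time_s": t}
        for r in records
        for t in r.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit_id", "time_s"]).to_csv(
        spikes_path, index=False
    )
    prows = []
    for r in records:
        for name in ("OFF", "ON", "POST"):
            lo, hi = r.periods.bounds(name)
            prows.append(
                {"unit_id": r.unit_id, "period": name, "start_s": lo, "end_s": hi}
            )
    pd.DataFrame(prows).to_csv(periods_path, index=False)


def read_spikes(
    spikes_path: str | Path, periods_path: str | Path
) -> list[SpikeRecord]:
    """Read per-unit spike trains with their OFF/ON/POST boundaries.

    The periods sidecar either carries one row per (unit_id, period) or,
    without a ``unit_id`` column, one global set of boundaries applied to
    every unit.  Units listed in the sidecar but absent from the spikes
    file become empty records.  Spike times outside every period, or
    non-increasing within a unit, raise a validation error.
    """
    spikes = pd.read_csv(spikes_path)
    for col in ("unit_id", "time_s"):
        if col not in spikes.columns:
            raise FormatError(f"spikes CSV lacks column {col!r}")
    periods = pd.read_csv(periods_path)
    for col in ("period", "start_s", "end_s"):
        if col not in periods.columns:
            raise FormatError(f"periods CSV lacks column {col!r}")

    def to_periods(rows: pd.DataFrame) -> Periods:
        b = {
            str(r["period"]).upper(): (float(r["start_s"]), float(r["end_s"]))
            for _, r in rows.iterrows()
        }
        missing = {"OFF", "ON", "POST"} - set(b)
        if missing:
            raise FormatError(f"periods CSV missing {sorted(missing)}")
        return Periods(off=b["OFF"], on=b["ON"], post=b["POST"])

    per_unit = "unit_id" in periods.columns
    global_periods = None if per_unit else to_periods(periods)
    unit_ids = (
        list(dict.fromkeys(periods["unit_id"].astype(str)))
        if per_unit
        else list(dict.fromkeys(spikes["unit_id"].astype(str)))
    )
    records = []
    grouped = {str(k): g for k, g in spikes.groupby("unit_id", sort=False)}
    for uid in unit_ids:
        p = (
            to_periods(periods[periods["unit_id"].astype(str) == uid])
            if per_unit
            else global_periods
        )
        times = (
            grouped[uid]["time_s"].to_numpy(dtype=float)
            if uid in grouped
            else np.empty(0)
        )
        records.append(SpikeRecord(unit_id=uid, spike_times_s=times, periods=p))
    log.info("read_spikes: %d units <- %s", len(records), spikes_path)
    return records


def terminals_to_frame(terminals: list[TerminalGeometry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "streamline_id": t.streamline_id,
                "x_mm": t.crossing_point_mm[0],
                "y_mm": t.crossing_point_mm[1],
                "z_mm": t.crossing_point_mm[2],
                "depth_mm": t.depth_mm,
                "angle_deg": t.angle_deg,
                "region": t.region,
                "crossing_vertex": t.crossing_vertex,
            }
            for t in terminals
        ]
    )
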