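"""Streamline selection and terminal cortical geometry.

A candidate pathway between a deep nucleus and the cortex is carved out of a
whole-brain tractogram in three steps: select streamlines passing through a
small sphere at the injection site, measure each streamline's terminal
geometry relative to the cortical surface — the depth Δ of its cortical
end point below the surface crossing and the angle θ between its terminal
direction and the inward surface normal — and keep the terminals inside a
(Δ, θ) window.  Kept terminals are finally projected to a per-vertex
density map on the surface.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal, Sequence

import numpy as np

from .surface import LabeledSurface

log = logging.getLogger("optotract")


class NoCrossingError(ValueError):
    """The streamline never crosses the cortical surface."""


@dataclasses.dataclass
class Tractogram:
    """Ordered 3D point sequences in world millimetre space."""

    streamlines: list[np.ndarray]
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline must be an (N>=2, 3) array")
            if not np.isfinite(s).all():
                raise ValueError("streamline contains non-finite coordinates")
        if self.ids is None:
            self.ids = np.arange(len(self.streamlines))
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if len(self.ids) != len(self.streamlines):
                raise ValueError("ids length must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, mask: np.ndarray) -> "Tractogram":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Tractogram(
            [self.streamlines[i] for i in idx], ids=self.ids[idx]
        )


@dataclasses.dataclass
class SeedSphere:
    """Spherical region of interest centred on an injection site."""

    center_mm: np.ndarray
    diameter_mm: float = 1.0

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclasses.dataclass
class TerminalGeometry:
    """Cortical terminal descriptors of one streamline."""

    streamline_id: int
    crossing_point_mm: np.ndarray
    depth_mm: float
    angle_deg: float
    region: int
    crossing_vertex: int

    def __post_init__(self) -> None:
        if self.depth_mm < 0:
            raise ValueError("depth_mm must be >= 0")
        if not 0 <= self.angle_deg <= 180:
            raise ValueError("angle_deg must lie in [0, 180]")


@dataclasses.dataclass
class SurfaceMap:
    """Per-vertex scalar field on a LabeledSurface."""

    values: np.ndarray
    kind: Literal["density", "fluorescence", "correlation"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind in ("density", "fluorescence"):
            defined = self.values[np.isfinite(self.values)]
            if np.any(defined < 0):
                raise ValueError(f"{self.kind} map must be non-negative")


def select_by_seed(tractogram: Tractogram, sphere: SeedSphere) -> Tractogram:
    """Keep streamlines with at least one point inside the seed sphere.

    The boundary is inclusive: a point exactly at the radius counts.  Order
    and ids are preserved.
    """
    r = sphere.radius_mm
    keep = np.zeros(len(tractogram), dtype=bool)
    for i, s in enumerate(tractogram.streamlines):
        d2 = np.sum((s - sphere.center_mm) ** 2, axis=1)
        keep[i] = bool(np.any(d2 <= r * r + 1e-12 * max(r * r, 1.0)))
    out = tractogram.subset(keep)
    log.info(
        "select_by_seed: %d/%d streamlines within %.3g mm of %s",
        len(out), len(tractogram), r, np.round(sphere.center_mm, 3),
    )
    return out


def _tangent_direction(points: np.ndarray, k: int) -> np.ndarray:
    """Least-squares direction of the last ``k`` points, oriented toward the
    terminal (last) point."""
    pts = points[-max(k, 2):]
    centered = pts - pts.mean(axis=0)
    # principal axis of the terminal segment
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    travel = pts[-1] - pts[0]
    if np.dot(d, travel) < 0:
        d = -d
    return d / np.linalg.norm(d)


def _terminal_geometry_batch(
    oriented: list[np.ndarray],
    surface: LabeledSurface,
    tangent_points: int = 3,
    n_bisect: int = 12,
) -> list[TerminalGeometry | None]:
    """Terminal geometry of many terminal-oriented polylines at once.

    Signed-distance evaluations (the expensive mesh queries) are batched
    across streamlines, including the bisection that refines each last
    crossing.  Returns None for streamlines without a surface crossing.
    """
    lengths = np.array([len(p) for p in oriented])
    flat = np.concatenate(oriented) if oriented else np.empty((0, 3))
    signed_flat = surface.signed_distance(flat) if len(flat) else np.empty(0)
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    seg_i: list[int] = []        # index of the crossing segment per streamline
    active: list[int] = []       # streamlines with a crossing
    p0s, p1s, s0s, s1s = [], [], [], []
    for si, pts in enumerate(oriented):
        signed = signed_flat[offsets[si]: offsets[si + 1]]
        change = np.flatnonzero(signed[:-1] * signed[1:] <= 0)
        change = change[signed[change] != signed[change + 1]]
        if change.size == 0:
            seg_i.append(-1)
            continue
        i = int(change[-1])
        seg_i.append(i)
        active.append(si)
        p0s.append(pts[i])
        p1s.append(pts[i + 1])
        s0s.append(signed[i])
        s1s.append(signed[i + 1])

    results: list[TerminalGeometry | None] = [None] * len(oriented)
    if not active:
        return results

    p0 = np.array(p0s)
    p1 = np.array(p1s)
    s0 = np.array(s0s)
    lo = np.zeros(len(active))
    hi = np.ones(len(active))
    done = s0 == 0.0
    hi[done] = 0.0
    for _ in range(n_bisect):
        if done.all():
            break
        mid = 0.5 * (lo + hi)
        pts_mid = p0 + mid[:, None] * (p1 - p0)
        sm = surface.signed_distance(pts_mid[~done])
        sm_full = np.zeros(len(active))
        sm_full[~done] = sm
        same_side = (sm_full > 0) == (s0 > 0)
        upd_lo = ~done & same_side
        upd_hi = ~done & ~same_side
        lo[upd_lo] = mid[upd_lo]
        hi[upd_hi] = mid[upd_hi]
        newly_done = ~done & (sm_full == 0.0)
        lo[newly_done] = hi[newly_done] = mid[newly_done]
        done |= newly_done
    t = 0.5 * (lo + hi)
    crossing_free = p0 + t[:, None] * (p1 - p0)
    crossing, _, face = surface.closest_points(crossing_free)

    for row, si in enumerate(active):
        pts = oriented[si]
        i = seg_i[si]
        seg_lens = np.linalg.norm(np.diff(pts[i:], axis=0), axis=1)
        depth = float((1.0 - t[row]) * seg_lens[0] + seg_lens[1:].sum())
        tangent = _tangent_direction(pts, tangent_points)
        inward = -surface.interpolate_normal(crossing[row], int(face[row]))
        cosang = float(np.clip(np.dot(tangent, inward), -1.0, 1.0))
        vtx = surface.nearest_vertex_of_face(crossing[row], int(face[row]))
        results[si] = TerminalGeometry(
            streamline_id=-1,
            crossing_point_mm=crossing[row],
            depth_mm=depth,
            angle_deg=float(np.degrees(np.arccos(cosang))),
            region=int(surface.vertex_labels[vtx]),
            crossing_vertex=vtx,
        )
    return results


def terminal_geometry(
    streamline: np.ndarray,
    surface: LabeledSurface,
    end: Literal["first", "last"] = "last",
    tangent_points: int = 3,
) -> TerminalGeometry:
    """Depth and angle of a streamline's cortical terminal.

    The streamline is oriented so the chosen ``end`` is terminal; the last
    surface crossing before the terminal defines the crossing point.  Depth
    is the arc length from the crossing to the terminal; the angle is taken
    between the mean tangent of the last ``tangent_points`` points and the
    inward (anti-normal) direction interpolated at the crossing, so a fiber
    entering the cortex perpendicular to the surface scores θ = 0.
    """
    pts = np.asarray(streamline, dtype=float)
    if end == "first":
        pts = pts[::-1]
    (res,) = _terminal_geometry_batch([pts], surface, tangent_points)
    if res is None:
        raise NoCrossingError("streamline does not cross the surface")
    return res


def terminal_geometries(
    tractogram: Tractogram,
    surface: LabeledSurface,
    end: Literal["first", "last"] = "last",
    tangent_points: int = 3,
) -> list[TerminalGeometry]:
    """Terminal geometry for every streamline; non-crossing ones are dropped
    with a log entry."""
    oriented = [
        np.asarray(s, dtype=float)[:: -1 if end == "first" else 1]
        for s in tractogram.streamlines
    ]
    batch = _terminal_geometry_batch(oriented, surface, tangent_points)
    out: list[TerminalGeometry] = []
    n_skipped = 0
    for sid, res in zip(tractogram.ids, batch):
        if res is None:
            n_skipped += 1
            continue
        res.streamline_id = int(sid)
        out.append(res)
    log.info(
        "terminal_geometries: %d terminals computed, %d streamlines without "
        "surface crossing excluded", len(out), n_skipped,
    )
    return out


def filter_by_params(
    terminals: Sequence[TerminalGeometry],
    depth_mm: float,
    angle_deg: float,
    tol: tuple[float, float],
) -> list[TerminalGeometry]:
    """Keep terminals inside the window |depth − Δ| ≤ tol_d, |angle − θ| ≤ tol_a."""
    tol_d, tol_a = tol
    if tol_d < 0 or tol_a < 0:
        raise ValueError("tolerances must be >= 0")
    kept = [
        t
        for t in terminals
        if abs(t.depth_mm - depth_mm) <= tol_d and abs(t.angle_deg - angle_deg) <= tol_a
    ]
    log.info(
        "filter_by_params: kept %d/%d terminals at Δ=%.3g±%.3g mm, θ=%.3g±%.3g°",
        len(kept), len(terminals), depth_mm, tol_d, angle_deg, tol_a,
    )
    return kept


def density_map(
    terminals: Sequence[TerminalGeometry],
    surface: LabeledSurface,
    smoothing_mm: float = 0.0,
) -> SurfaceMap:
    """Project terminals to a per-vertex density map.

    Each terminal deposits unit mass at its crossing vertex; with
    ``smoothing_mm > 0`` the mass is spread over the geodesic neighborhood
    of that radius with Gaussian weights (σ = radius / 2), renormalized per
    terminal so total mass always equals the terminal count.
    """
    if smoothing_mm < 0:
        raise ValueError("smoothing_mm must be >= 0")
    values = np.zeros(surface.n_vertices)
    if not terminals:
        return SurfaceMap(values=values, kind="density")
    counts = np.zeros(surface.n_vertices)
    for t in terminals:
        counts[t.crossing_vertex] += 1.0
    if smoothing_mm == 0:
        values = counts
    else:
        from scipy.sparse.csgraph import dijkstra

        sources = np.flatnonzero(counts > 0)
        dist = dijkstra(
            surface.edge_graph(), directed=False, indices=sources, limit=smoothing_mm
        )
        sigma = smoothing_mm / 2.0
        for row, v in enumerate(sources):
            d = dist[row]
            nbr = np.flatnonzero(np.isfinite(d))
            w = np.exp(-0.5 * (d[nbr] / sigma) ** 2)
            values[nbr] += counts[v] * w / w.sum()
    return SurfaceMap(values=values, kind="density")
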