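"""Synthetic surfaces, tractograms, histology blocks and spike trains.

Every generator is a pure function of its parameters and an integer seed,
and returns ground-truth annotations rich enough to score any downstream
decision without re-deriving geometry.  The synthetic cortex is a
sinusoidally folded sheet rather than a sphere so that surface normals vary
and the angle-to-normal filter is exercised non-trivially; streamlines are
built with exactly known terminal depth and angle; decoy streamlines come
in three families (missing the seed sphere, wrong depth, wrong angle) so
each filtering clause is probed separately; spike trains are homogeneous
Poisson or gamma-renewal with a known ON-period rate multiplier.

Default rates mirror the tonic subthalamic firing regime of the study
system: 18.2 Hz baseline, ~1.45× rate increase under stimulation, 60 s
periods.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .histology import HistologyBlock
from .spikes import Periods, SpikeRecord
from .surface import LabeledSurface
from .tracts import SurfaceMap, Tractogram

log = logging.getLogger("optotract")

SHEET_EXTENT_MM = 30.0
SHEET_AMPLITUDE_MM = 1.5
SHEET_WAVELENGTH_MM = 15.0
RIBBON_THICKNESS_MM = 2.5


@dataclasses.dataclass
class TractGroundTruth:
    """Planted pathway parameters for a synthetic tractogram."""

    true_depth_mm: float = 2.0
    true_angle_deg: float = 30.0
    n_true: int = 50
    n_decoy: int = 30
    depth_jitter_mm: float = 0.0
    angle_jitter_deg: float = 0.0
    seed_center_mm: tuple[float, float, float] = (15.0, 15.0, -15.0)
    origin_region: int = 1
    decoy_depth_offset_mm: float = 2.0
    decoy_angle_offset_deg: float = 35.0

    def __post_init__(self) -> None:
        if self.true_depth_mm < 0 or not 0 <= self.true_angle_deg < 90:
            raise ValueError("need depth >= 0 and 0 <= angle < 90")
        if self.depth_jitter_mm < 0 or self.angle_jitter_deg < 0:
            raise ValueError("jitters must be >= 0")


@dataclasses.dataclass
class SpikeGroundTruth:
    """Planted firing-rate structure for one synthetic unit."""

    unit_id: str = "u0"
    baseline_rate_hz: float = 18.2
    on_rate_multiplier: float = 1.449
    process: str = "poisson"  # "poisson" | "gamma"
    gamma_shape: float = 1.0
    responsive: bool = True
    period_durations_s: tuple[float, float, float] = (60.0, 60.0, 60.0)
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.baseline_rate_hz <= 0 or self.on_rate_multiplier <= 0:
            raise ValueError("rates and multiplier must be > 0")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be > 0")
        if self.process not in ("poisson", "gamma"):
            raise ValueError("process must be 'poisson' or 'gamma'")


def make_labeled_surface(
    n_regions: int, mesh_resolution: int = 25, rng_seed: int = 0
) -> LabeledSurface:
    """Folded-sheet cortex partitioned into contiguous labeled patches.

    A ``mesh_resolution``² grid over a 30×30 mm plane is displaced by a
    sinusoid (amplitude 1.5 mm, wavelength 15 mm) and triangulated with
    upward (outward, +z) winding.  Labels 1..n_regions grow from randomly
    chosen seed vertices by multi-source shortest-path assignment, so every
    patch is edge-connected and non-empty.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    res = int(mesh_resolution)
    if n_regions > res * res:
        raise ValueError("n_regions exceeds vertex count")
    rng = np.random.default_rng(rng_seed)
    xs = np.linspace(0.0, SHEET_EXTENT_MM, res)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    k = 2 * np.pi / SHEET_WAVELENGTH_MM
    gz = SHEET_AMPLITUDE_MM * np.sin(k * gx) * np.cos(k * gy)
    vertices = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    tris = []
    for i in range(res - 1):
        for j in range(res - 1):
            v00 = i * res + j
            v10 = (i + 1) * res + j
            v01 = i * res + j + 1
            v11 = (i + 1) * res + j + 1
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    triangles = np.array(tris, dtype=np.int64)

    seeds = rng.choice(len(vertices), size=n_regions, replace=False)
    tmp = LabeledSurface(vertices, triangles, np.zeros(len(vertices), dtype=int))
    dist = dijkstra(tmp.edge_graph(), directed=False, indices=seeds)
    labels = np.argmin(dist, axis=0) + 1
    surf = LabeledSurface(vertices, triangles, labels)
    log.info(
        "make_labeled_surface: %d vertices, %d regions, seed %d",
        surf.n_vertices, n_regions, rng_seed,
    )
    return surf


def _orthonormal_tangent(normal: np.ndarray, phi: float) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, helper)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    return np.cos(phi) * u + np.sin(phi) * w


def _build_streamline(
    surface: LabeledSurface,
    vertex: int,
    depth: float,
    angle_deg: float,
    phi: float,
    start: np.ndarray,
    approach_mm: float = 0.8,
    step_mm: float = 0.3,
) -> np.ndarray:
    """Polyline from ``start`` through the surface at ``vertex``, ending at
    exactly ``depth`` mm beyond the crossing with terminal direction at
    ``angle_deg`` to the inward normal (straight terminal run)."""
    c = surface.vertices[vertex]
    n_in = -surface.vertex_normals[vertex]
    t = _orthonormal_tangent(n_in, phi)
    ang = np.radians(angle_deg)
    direction = np.cos(ang) * n_in + np.sin(ang) * t
    a = c - approach_mm * direction
    terminal = c + depth * direction
    run = np.linalg.norm(terminal - a)
    n_steps = max(int(np.ceil(run / step_mm)), 3)
    final = a + np.linspace(0.0, 1.0, n_steps + 1)[:, None] * (terminal - a)
    lead = start + np.linspace(0.0, 1.0, 4, endpoint=False)[1:, None] * (a - start)
    return np.vstack([start, lead, final])


def make_tractogram(
    surface: LabeledSurface,
    truth: TractGroundTruth,
    rng_seed: int = 0,
) -> tuple[Tractogram, pd.DataFrame]:
    """Synthetic pathway plus decoys, with per-streamline annotations.

    Returns the tractogram and a DataFrame with columns ``id``, ``family``
    (true / miss_sphere / wrong_depth / wrong_angle), ``depth_mm``,
    ``angle_deg``, ``crossing_vertex``, ``region`` and ``in_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    region_vtx = surface.region_vertices(truth.origin_region)
    center = np.asarray(truth.seed_center_mm, dtype=float)

    streamlines: list[np.ndarray] = []
    rows: list[dict] = []

    def sample_vertex() -> int:
        return int(rng.choice(region_vtx))

    def jittered(depth0: float, angle0: float) -> tuple[float, float]:
        d = max(depth0 + rng.normal(0.0, truth.depth_jitter_mm), 0.05) \
            if truth.depth_jitter_mm > 0 else depth0
        a = float(np.clip(
            angle0 + (rng.normal(0.0, truth.angle_jitter_deg)
                      if truth.angle_jitter_deg > 0 else 0.0),
            0.0, 75.0,
        ))
        return float(d), a

    for _ in range(truth.n_true):
        v = sample_vertex()
        d, a = jittered(truth.true_depth_mm, truth.true_angle_deg)
        s = _build_streamline(surface, v, d, a, rng.uniform(0, 2 * np.pi), center)
        rows.append(dict(family="true", depth_mm=d, angle_deg=a,
                         crossing_vertex=v, region=int(surface.vertex_labels[v]),
                         in_seed=True))
        streamlines.append(s)

    families = ["miss_sphere", "wrong_depth", "wrong_angle"]
    for idx in range(truth.n_decoy):
        fam = families[idx % 3]
        v = sample_vertex()
        d0, a0 = truth.true_depth_mm, truth.true_angle_deg
        start = center
        if fam == "miss_sphere":
            offset = _orthonormal_tangent(
                np.array([0.0, 0.0, 1.0]), rng.uniform(0, 2 * np.pi)
            )
            start = center + 5.0 * offset
        elif fam == "wrong_depth":
            d0 = truth.true_depth_mm + truth.decoy_depth_offset_mm
        else:
            a0 = min(truth.true_angle_deg + truth.decoy_angle_offset_deg, 75.0)
        d, a = jittered(d0, a0)
        s = _build_streamline(surface, v, d, a, rng.uniform(0, 2 * np.pi), start)
        rows.append(dict(family=fam, depth_mm=d, angle_deg=a,
                         crossing_vertex=v, region=int(surface.vertex_labels[v]),
                         in_seed=fam != "miss_sphere"))
        streamlines.append(s)

    annotations = pd.DataFrame(rows)
    annotations.insert(0, "id", np.arange(len(annotations)))
    log.info(
        "make_tractogram: %d true + %d decoy streamlines (seed %d)",
        truth.n_true, truth.n_decoy, rng_seed,
    )
    return Tractogram(streamlines), annotations


def region_origin_map(surface: LabeledSurface, region: int, peak: float = 1.0) -> SurfaceMap:
    """Smoothly graded fluorescence origin map supported on one region."""
    idx = surface.region_vertices(region)
    values = np.zeros(surface.n_vertices)
    center = surface.vertices[idx].mean(axis=0)
    d = np.linalg.norm(surface.vertices[idx] - center, axis=1)
    scale = max(d.max(), 1e-9)
    values[idx] = peak * (0.25 + 0.75 * np.exp(-((d / scale) ** 2)))
    return SurfaceMap(values=values, kind="fluorescence")


def make_histology_block(
    surface: LabeledSurface,
    origin_map: SurfaceMap,
    slice_spacing_mm: float = 0.32,
    in_plane_res_mm: float = 0.25,
    rng_seed: int = 0,
    ribbon_mm: float = RIBBON_THICKNESS_MM,
) -> HistologyBlock:
    """Voxelized fluorescence block under the surface locations weighted by
    ``origin_map``.

    Candidate voxels lie in the cortical ribbon (0 to ``ribbon_mm`` below
    the surface, judged at the nearest vertex); each is lit by a Bernoulli
    draw with probability proportional to the map value at that vertex, so
    the projected surface density recovers the origin map up to sampling
    noise while the expected fluorescent volume is resolution-independent.
    """
    weights = np.asarray(origin_map.values, dtype=float)
    if np.any(weights < 0):
        raise ValueError("origin_map must be non-negative")
    if in_plane_res_mm > ribbon_mm or slice_spacing_mm > ribbon_mm:
        log.warning(
            "voxel size coarser than the cortical ribbon (%g mm)", ribbon_mm
        )
    rng = np.random.default_rng(rng_seed)
    lo = surface.vertices.min(axis=0) - np.array([1.0, 1.0, ribbon_mm + 1.0])
    hi = surface.vertices.max(axis=0) + 1.0
    nx = max(int(np.ceil((hi[0] - lo[0]) / slice_spacing_mm)), 1)
    ny = max(int(np.ceil((hi[1] - lo[1]) / in_plane_res_mm)), 1)
    nz = max(int(np.ceil((hi[2] - lo[2]) / in_plane_res_mm)), 1)
    xs = lo[0] + (np.arange(nx) + 0.5) * slice_spacing_mm
    ys = lo[1] + (np.arange(ny) + 0.5) * in_plane_res_mm
    zs = lo[2] + (np.arange(nz) + 0.5) * in_plane_res_mm
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    wmax = weights.max()
    slices = np.zeros((nx, ny, nz), dtype=float)
    if wmax > 0:
        _, nn = surface.kdtree.query(centers)
        vpos = surface.vertices[nn]
        vnorm = surface.vertex_normals[nn]
        height = np.einsum("ij,ij->i", centers - vpos, vnorm)
        in_ribbon = (height <= 0.0) & (height >= -ribbon_mm)
        # Curvature makes concave vertices capture more ribbon voxels than
        # convex ones; scale each vertex's thinning probability by its
        # candidate count so expected projected mass tracks the origin map.
        counts = np.bincount(nn[in_ribbon], minlength=surface.n_vertices)
        support = np.flatnonzero(weights > 0)
        occupied = support[counts[support] > 0]
        ref = counts[occupied].min() if occupied.size else 1
        with np.errstate(divide="ignore"):
            calib = np.where(counts > 0, ref / np.maximum(counts, 1), 0.0)
        p = np.clip(weights[nn] / wmax * calib[nn], 0.0, 1.0)
        lit = in_ribbon & (rng.random(len(centers)) < p)
        slices.ravel()[np.flatnonzero(lit)] = 1.0

    block = HistologyBlock(
        slices=slices,
        in_plane_res_mm=in_plane_res_mm,
        slice_spacing_mm=slice_spacing_mm,
        axis=0,
        origin_mm=lo,
    )
    log.info(
        "make_histology_block: %d fluorescent voxels in %s grid (seed %d)",
        int(slices.sum()), slices.shape, rng_seed,
    )
    return block


def _renewal_train(
    rng: np.random.Generator, rate: float, t0: float, t1: float,
    process: str, shape: float,
) -> np.ndarray:
    """Event times in (t0, t1) from a renewal process with mean rate ``rate``."""
    duration = t1 - t0
    n_guess = int(rate * duration + 6 * np.sqrt(rate * duration) + 20)
    if process == "poisson":
        gaps = rng.exponential(1.0 / rate, size=n_guess)
    else:
        gaps = rng.gamma(shape, 1.0 / (shape * rate), size=n_guess)
    t = t0 + np.cumsum(gaps)
    while t.size and t[-1] < t1:
        extra = (
            rng.exponential(1.0 / rate, size=n_guess)
            if process == "poisson"
            else rng.gamma(shape, 1.0 / (shape * rate), size=n_guess)
        )
        t = np.concatenate([t, t[-1] + np.cumsum(extra)])
    return t[t < t1]


def make_spike_trains(
    population: list[SpikeGroundTruth], rng_seed: int = 0
) -> list[SpikeRecord]:
    """OFF/ON/POST spike trains for a population of synthetic units.

    OFF and POST run at the baseline rate; ON at baseline × multiplier for
    responsive units (multiplier forced to 1 otherwise).  Poisson trains use
    exponential gaps, gamma-renewal trains shape-scaled gamma gaps with the
    same mean rate.
    """
    rng = np.random.default_rng(rng_seed)
    records = []
    for gt in population:
        d_off, d_on, d_post = gt.period_durations_s
        if min(d_off, d_on, d_post) <= 0:
            raise ValueError("period durations must be > 0")
        periods = Periods(
            off=(0.0, d_off), on=(d_off, d_off + d_on),
            post=(d_off + d_on, d_off + d_on + d_post),
        )
        mult = gt.on_rate_multiplier if gt.responsive else 1.0
        times = []
        for (lo, hi), rate in (
            (periods.off, gt.baseline_rate_hz),
            (periods.on, gt.baseline_rate_hz * mult),
            (periods.post, gt.baseline_rate_hz),
        ):
            times.append(
                _renewal_train(rng, rate, lo, hi, gt.process, gt.gamma_shape)
            )
        spikes = np.concatenate(times)
        records.append(
            SpikeRecord(
                unit_id=gt.unit_id,
                spike_times_s=spikes,
                periods=periods,
                subject_id=gt.subject_id,
            )
        )
    log.info("make_spike_trains: %d units (seed %d)", len(records), rng_seed)
    return records


def study_population(
    n_units: int,
    n_responsive: int,
    baseline_rate_hz: float = 18.2,
    on_rate_multiplier: float = 1.449,
    process: str = "poisson",
    gamma_shape: float = 1.0,
    period_durations_s: tuple[float, float, float] = (60.0, 60.0, 60.0),
    subject_id: str = "",
    rate_jitter_hz: float = 1.9,
    rng_seed: int = 0,
) -> list[SpikeGroundTruth]:
    """Population ground truth mirroring the recorded-unit design: the first
    ``n_responsive`` units carry the ON-rate multiplier, the rest do not;
    per-unit baseline rates are jittered around the population mean."""
    rng = np.random.default_rng(rng_seed)
    pop = []
    for i in range(n_units):
        base = max(baseline_rate_hz + rng.normal(0.0, rate_jitter_hz), 1.0)
        pop.append(
            SpikeGroundTruth(
                unit_id=f"{subject_id or 'unit'}_{i:03d}",
                baseline_rate_hz=base,
                on_rate_multiplier=on_rate_multiplier,
                process=process,
                gamma_shape=gamma_shape,
                responsive=i < n_responsive,
                period_durations_s=period_durations_s,
                subject_id=subject_id,
            )
        )
    return pop
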