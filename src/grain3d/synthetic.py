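"""Synthetic grooved-grain clouds and stage scenes with exact ground truth.

A grain is modelled in three parts:

* a superellipsoid body ``|x/a|^e + |y/b|^e + |z/c|^e = 1`` (exponent 2 by
  default, semi-axes a >= b >= c in mm, length 2a in the 6-10 mm range);
* a "cheek" bulge: the width is scaled by ``g(z) = 1 + cheek *
  exp(-(z/cheek_width)^2)``, which localizes the section's width maximum
  at its mid-height the way a wheat section's cheeks do (a pure ellipse
  leaves the widest point direction degenerate, which no real grain has);
* a ventral crease cut into the underside: all material below the
  flat-bottomed (super-Gaussian) surface

      z_crease(y) = -c + (c - d) * exp(-(y / sigma)^(2 m))

  is removed, so the crease floor is a gently rounded U whose ridge sits
  exactly ``groove_depth`` = d mm below the grain's mid-width chord
  (z = 0) — precisely the quantity the slicing procedure reports as
  sulcus depth.  ``groove_depth = None`` disables the crease.

Points are sampled area-weighted on the composite surface by rejection
(no pole clustering) and jittered with isotropic Gaussian noise
emulating residual scanner noise after multi-view merging.  Ground
truth (l, w, h, V, S_a, D, sulcus cross-section area) is computed by
numeric quadrature of the same analytic solid, independently of the
measurement pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull
from scipy.special import erf

from .cloud_io import PointCloud

__all__ = ["GrainParams", "GroundTruth", "make_grain", "make_scene", "make_weight_dataset"]


@dataclass
class GrainParams:
    """Shape, groove, sampling and noise parameters of one synthetic grain.

    Semi-axes in mm with a >= b >= c > 0; ``groove_depth`` d in [0, 1) mm is
    the planted sulcus depth (crease floor below the mid-width chord; None =
    no crease); ``groove_width`` is the crease's full width 2*sigma (mm);
    ``crease_order`` m shapes the floor (m = 1 Gaussian V-fold, m = 2
    flat-bottomed U); ``cheek``/``cheek_width`` control the relative size
    and vertical extent of the width bulge; ``noise_sd`` the isotropic
    point jitter (mm).
    """

    semi_axes: tuple[float, float, float] = (4.0, 1.6, 1.4)
    groove_depth: Optional[float] = 0.5
    groove_width: float = 1.0
    crease_order: int = 2
    cheek: float = 0.10
    cheek_width: float = 0.25
    exponent: float = 2.0
    n_points: int = 2500
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes}")
        if self.groove_depth is not None:
            if not (0.0 <= self.groove_depth < c):
                raise ValueError("groove_depth must lie in [0, c)")
            if self.groove_width <= 0:
                raise ValueError("groove_width must be positive")
        if self.n_points < 100:
            raise ValueError("n_points must be at least 100")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.crease_order < 1:
            raise ValueError("crease_order must be >= 1")
        if self.cheek < 0 or self.cheek_width <= 0:
            raise ValueError("cheek must be >= 0 and cheek_width positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Analytic trait values of a generated grain or scene."""

    l: float
    w: float
    h: float
    V: float
    S_a: float
    D: float
    sulcus_area: float
    labels: Optional[np.ndarray] = None
    grains: Optional[list["GroundTruth"]] = None


# ---------------------------------------------------------------------------
# geometry primitives (base coordinates: pre-cheek-warp superellipsoid)
# ---------------------------------------------------------------------------

def _radial_scale(u: np.ndarray, e: float) -> np.ndarray:
    """Scale s(u) so that s * (a u1, b u2, c u3) lies on the superellipsoid."""
    return (np.abs(u) ** e).sum(axis=-1) ** (-1.0 / e)


def _cheek_scale(z, params: GrainParams):
    return 1.0 + params.cheek * np.exp(-((np.asarray(z) / params.cheek_width) ** 2))


def _cheek_antiderivative(z, params: GrainParams):
    """Antiderivative of the cheek scale g(z), for column integrals of V."""
    cw = params.cheek_width
    return np.asarray(z) + params.cheek * cw * np.sqrt(np.pi) / 2.0 * erf(np.asarray(z) / cw)


def _warp(p0: np.ndarray, params: GrainParams) -> np.ndarray:
    """Cheek warp (x, y0, z) -> (x, y0 * g(z), z)."""
    p = np.array(p0, dtype=np.float64, copy=True)
    p[..., 1] = p[..., 1] * _cheek_scale(p[..., 2], params)
    return p


def _surface_map(u: np.ndarray, params: GrainParams) -> np.ndarray:
    a, b, c = params.semi_axes
    s = _radial_scale(u, params.exponent)
    base = s[..., None] * (u * np.array([a, b, c]))
    return _warp(base, params)


def _base_surface(u: np.ndarray, params: GrainParams) -> np.ndarray:
    a, b, c = params.semi_axes
    s = _radial_scale(u, params.exponent)
    return s[..., None] * (u * np.array([a, b, c]))


def _area_element(u: np.ndarray, params: GrainParams, eps: float = 1e-4) -> np.ndarray:
    """Area scale |dp/dt1 x dp/dt2| of the sphere -> warped surface map."""
    ref = np.where(np.abs(u[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    t1 = np.cross(u, ref)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)

    def on_sphere(v):
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    d1 = (_surface_map(on_sphere(u + eps * t1), params)
          - _surface_map(on_sphere(u - eps * t1), params)) / (2 * eps)
    d2 = (_surface_map(on_sphere(u + eps * t2), params)
          - _surface_map(on_sphere(u - eps * t2), params)) / (2 * eps)
    return np.linalg.norm(np.cross(d1, d2), axis=1)


def _crease_surface(y, params: GrainParams):
    c = params.semi_axes[2]
    d = params.groove_depth
    sigma = params.groove_width / 2.0
    t = (np.asarray(y) / sigma) ** (2 * params.crease_order)
    return -c + (c - d) * np.exp(-t)


def _crease_slope(y, params: GrainParams):
    c = params.semi_axes[2]
    d = params.groove_depth
    sigma = params.groove_width / 2.0
    m = params.crease_order
    y = np.asarray(y, dtype=np.float64)
    t = (y / sigma) ** (2 * m)
    return (c - d) * np.exp(-t) * (-2.0 * m * np.sign(y) * np.abs(y) ** (2 * m - 1) / sigma ** (2 * m))


def _bottom_z(x, y0, params: GrainParams):
    """Lower base-surface z at base coordinates (x, y0); +inf outside."""
    a, b, c = params.semi_axes
    e = params.exponent
    r = np.abs(np.asarray(x) / a) ** e + np.abs(np.asarray(y0) / b) ** e
    inside = r < 1.0
    z = np.full(np.shape(r), np.inf)
    z[inside] = -c * (1.0 - r[inside]) ** (1.0 / e)
    return z


# ---------------------------------------------------------------------------
# ground truth by quadrature
# ---------------------------------------------------------------------------

def _section_polygon(params: GrainParams, n: int = 4000) -> np.ndarray:
    """Dense boundary polygon of the central (x = 0) final-frame section."""
    b, c = params.semi_axes[1], params.semi_axes[2]
    e = params.exponent
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    # superellipse boundary in base coordinates
    y0 = b * np.sign(np.cos(t)) * np.abs(np.cos(t)) ** (2.0 / e)
    z = c * np.sign(np.sin(t)) * np.abs(np.sin(t)) ** (2.0 / e)
    if params.groove_depth is not None:
        W = _crease_surface(y0, params)
        z = np.maximum(z, W)  # carve the crease into the lower arc
    y = y0 * _cheek_scale(z, params)
    return np.column_stack([y, z])


def _ground_truth_quadrature(params: GrainParams, resolution: int = 240) -> GroundTruth:
    a, b, c = params.semi_axes
    e = params.exponent
    d = params.groove_depth

    # volume + lowest surface point on a base (x, y0) midpoint grid
    nx = ny = resolution
    x = (np.arange(nx) + 0.5) / nx * 2 * a - a
    y0 = (np.arange(ny) + 0.5) / ny * 2 * b - b
    dxdy = (2 * a / nx) * (2 * b / ny)
    X, Y0 = np.meshgrid(x, y0, indexing="ij")
    r = np.abs(X / a) ** e + np.abs(Y0 / b) ** e
    inside = r < 1.0
    z_top = np.where(inside, c * np.clip(1.0 - r, 0, None) ** (1.0 / e), 0.0)
    z_bot = -z_top
    if d is not None:
        W = _crease_surface(Y0, params)
        cut = inside & (z_bot < W)
        z_low = np.where(cut, W, z_bot)
    else:
        cut = np.zeros_like(inside)
        z_low = z_bot
    G = _cheek_antiderivative
    V = float(((G(z_top, params) - G(z_low, params)) * inside).sum() * dxdy)
    kept_bot = inside & ~cut
    z_candidates = [z_bot[kept_bot].min() if kept_bot.any() else np.inf]
    if cut.any():
        z_candidates.append(W[cut].min())
    h = c + abs(min(z_candidates))

    # surface area: spherical quadrature of the body + planar crease wall
    nt, nph = resolution, 2 * resolution
    theta = (np.arange(nt) + 0.5) / nt * np.pi
    phi = (np.arange(nph) + 0.5) / nph * 2 * np.pi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    u = np.column_stack(
        [(np.sin(T) * np.cos(P)).ravel(), (np.sin(T) * np.sin(P)).ravel(), np.cos(T).ravel()]
    )
    m = _area_element(u, params)
    base = _base_surface(u, params)
    weights = m * np.sin(T).ravel() * (np.pi / nt) * (2 * np.pi / nph)
    if d is not None:
        kept = base[:, 2] >= _crease_surface(base[:, 1], params)
        S_body = float(weights[kept].sum())
        S_wall = float((_wall_element(Y0, params) * cut).sum() * dxdy)
        S_a = S_body + S_wall
    else:
        S_a = float(weights.sum())

    # central-section sulcus area = hull area - section area
    if d is not None:
        poly = _section_polygon(params)
        hull_area = float(ConvexHull(poly).volume)
        yy, zz = poly[:, 0], poly[:, 1]
        section_area = 0.5 * abs(float(np.dot(yy, np.roll(zz, -1)) - np.dot(zz, np.roll(yy, -1))))
        sulcus_area = hull_area - section_area
    else:
        sulcus_area = 0.0

    w = 2 * b * float(_cheek_scale(0.0, params))
    return GroundTruth(
        l=2 * a, w=w, h=float(h), V=V, S_a=S_a,
        D=float(d) if d is not None else 0.0, sulcus_area=float(sulcus_area),
    )


def _wall_element(y0, params: GrainParams):
    """Area element of the warped crease wall over base (x, y0)."""
    W = _crease_surface(y0, params)
    Wp = _crease_slope(y0, params)
    g = _cheek_scale(W, params)
    cw = params.cheek_width
    gp = params.cheek * np.exp(-((W / cw) ** 2)) * (-2.0 * W / cw**2)
    A = g + np.asarray(y0) * gp * Wp  # d(final y)/d(y0)
    return np.sqrt(A**2 + Wp**2)


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

def _sample_body(params: GrainParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted rejection sample of the (possibly cut) body surface."""
    probe_t = np.linspace(0.05, np.pi - 0.05, 60)
    probe_p = np.linspace(0.0, 2 * np.pi, 120, endpoint=False)
    T, P = np.meshgrid(probe_t, probe_p, indexing="ij")
    probe = np.column_stack(
        [(np.sin(T) * np.cos(P)).ravel(), (np.sin(T) * np.sin(P)).ravel(), np.cos(T).ravel()]
    )
    m_max = _area_element(probe, params).max() * 1.05
    out = []
    got = 0
    while got < n:
        batch = max(4 * (n - got), 1000)
        u = rng.standard_normal((batch, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        m = _area_element(u, params)
        accept = rng.random(batch) < m / m_max
        base = _base_surface(u[accept], params)
        if params.groove_depth is not None:
            base = base[base[:, 2] >= _crease_surface(base[:, 1], params)]
        out.append(_warp(base, params))
        got += len(out[-1])
    return np.vstack(out)[:n]


def _sample_wall(params: GrainParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Area-weighted sample of the crease wall surface."""
    a, b, _ = params.semi_axes
    # cut extent in y0 is widest at x = 0: find where floor meets the shell
    yy = np.linspace(-b, b, 2048)
    cut1d = _bottom_z(np.zeros_like(yy), yy, params) < _crease_surface(yy, params)
    if not cut1d.any():
        return np.empty((0, 3))
    y_lim = float(np.abs(yy[cut1d]).max()) + 2 * b / 2048
    w_max = float(_wall_element(np.linspace(-y_lim, y_lim, 512), params).max()) * 1.01
    out = []
    got = 0
    while got < n:
        batch = max(6 * (n - got), 1000)
        x = rng.uniform(-a, a, batch)
        y0 = rng.uniform(-y_lim, y_lim, batch)
        W = _crease_surface(y0, params)
        in_cut = _bottom_z(x, y0, params) < W
        accept = in_cut & (rng.random(batch) < _wall_element(y0, params) / w_max)
        base = np.column_stack([x[accept], y0[accept], W[accept]])
        out.append(_warp(base, params))
        got += int(accept.sum())
    return np.vstack(out)[:n]


def _wall_area(params: GrainParams, resolution: int) -> float:
    a, b, _ = params.semi_axes
    nx = ny = resolution
    x = (np.arange(nx) + 0.5) / nx * 2 * a - a
    y0 = (np.arange(ny) + 0.5) / ny * 2 * b - b
    X, Y0 = np.meshgrid(x, y0, indexing="ij")
    cut = _bottom_z(X, Y0, params) < _crease_surface(Y0, params)
    return float((_wall_element(Y0, params) * cut).sum() * (2 * a / nx) * (2 * b / ny))


def make_grain(
    params: GrainParams = GrainParams(),
    gt_resolution: int = 240,
) -> tuple[PointCloud, GroundTruth]:
    """Generate one grooved-grain surface cloud plus its analytic ground truth.

    Exactly ``params.n_points`` points, area-weighted over the carved
    surface, with isotropic Gaussian noise; deterministic for a fixed seed.
    ``gt_resolution`` controls the quadrature grids of the ground truth.
    """
    rng = np.random.default_rng(params.seed)
    gt = _ground_truth_quadrature(params, resolution=gt_resolution)
    if params.groove_depth is not None:
        # apportion points between body surface and crease wall by area
        n_wall = int(round(params.n_points * _wall_area(params, 160) / gt.S_a))
        n_wall = min(max(n_wall, 0), params.n_points - 10)
        wall = _sample_wall(params, n_wall, rng) if n_wall else np.empty((0, 3))
        body = _sample_body(params, params.n_points - len(wall), rng)
        pts = np.vstack([body, wall])
    else:
        pts = _sample_body(params, params.n_points, rng)
    if params.noise_sd > 0:
        pts = pts + rng.normal(0.0, params.noise_sd, pts.shape)
    return PointCloud(pts), gt


def _yaw(angle: float) -> np.ndarray:
    ca, sa = np.cos(angle), np.sin(angle)
    return np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])


def make_scene(
    n_grains: int = 25,
    layout_spacing: float = 12.0,
    stage_margin: float = 5.0,
    stage_point_spacing: float = 0.3,
    stage_noise_sd: float = 0.02,
    params: Optional[GrainParams] = None,
    size_jitter: float = 0.08,
    seed: int = 0,
) -> tuple[PointCloud, GroundTruth]:
    """A multi-grain stage scene with per-point ground-truth labels.

    Grains are placed on a square grid (pitch ``layout_spacing`` mm) above a
    planar stage sample at z = 0, each with a random yaw about the vertical
    and a fractional size jitter; stage points carry label -1 and grain i
    label i.  Deterministic for a fixed seed.
    """
    if n_grains < 1:
        raise ValueError("n_grains must be >= 1")
    rng = np.random.default_rng(seed)
    base = params if params is not None else GrainParams()
    if layout_spacing <= base.semi_axes[0]:  # > half the grain length
        raise ValueError(
            f"layout_spacing {layout_spacing} mm risks overlapping grains of "
            f"length {2 * base.semi_axes[0]} mm"
        )
    side = int(np.ceil(np.sqrt(n_grains)))
    coords = [(i, j) for i in range(side) for j in range(side)][:n_grains]
    offset = (side - 1) * layout_spacing / 2.0
    clouds, labels, per_grain = [], [], []
    for gi, (i, j) in enumerate(coords):
        scale = 1.0 + rng.uniform(-size_jitter, size_jitter)
        a, b, c = (s * scale for s in base.semi_axes)
        gp = GrainParams(
            semi_axes=(a, b, c), groove_depth=base.groove_depth,
            groove_width=base.groove_width, crease_order=base.crease_order,
            cheek=base.cheek, cheek_width=base.cheek_width, exponent=base.exponent,
            n_points=base.n_points, noise_sd=base.noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cloud, gt = make_grain(gp, gt_resolution=160)
        pts = cloud.points @ _yaw(rng.uniform(0, 2 * np.pi)).T
        pts[:, 2] -= pts[:, 2].min()  # rest the grain on the stage
        pts[:, 0] += i * layout_spacing - offset
        pts[:, 1] += j * layout_spacing - offset
        clouds.append(pts)
        labels.append(np.full(len(pts), gi))
        per_grain.append(gt)
    extent = offset + layout_spacing / 2.0 + stage_margin
    n_side = int(2 * extent / stage_point_spacing)
    g = np.linspace(-extent, extent, n_side)
    SX, SY = np.meshgrid(g, g, indexing="ij")
    stage = np.column_stack([SX.ravel(), SY.ravel(), np.zeros(SX.size)])
    stage[:, :2] += rng.uniform(-stage_point_spacing / 4, stage_point_spacing / 4, (len(stage), 2))
    stage[:, 2] += rng.normal(0.0, stage_noise_sd, len(stage))
    clouds.append(stage)
    labels.append(np.full(len(stage), -1))
    all_pts = np.vstack(clouds)
    all_labels = np.concatenate(labels)
    gt = GroundTruth(
        l=np.nan, w=np.nan, h=np.nan, V=np.nan, S_a=np.nan, D=np.nan,
        sulcus_area=np.nan, labels=all_labels, grains=per_grain,
    )
    return PointCloud(all_pts, labels=all_labels.copy()), gt


def make_weight_dataset(
    n: int = 500,
    noise_sd_mg: float = 0.5,
    density_mg_per_mm3: float = 1.05,
    seed: int = 0,
    n_points: int = 2000,
    signal: bool = True,
    config=None,
):
    """Trait table with a weight column, traits measured by the real pipeline.

    Grain shapes are drawn from ranges typical of wheat (length 6.4-9.6 mm,
    width ~2.8-3.3 mm, sulcus depth 0.3-0.8 mm); weight = density * true
    volume + N(0, noise_sd_mg), landing in the 25-50 mg band for the
    defaults.  ``signal=False`` replaces the weight with a uniform draw
    independent of shape (a no-signal null).  Returns a DataFrame with id,
    the 32 traits and weight.
    """
    import pandas as pd

    from .pipeline import PipelineConfig, extract_grain_traits

    if n < 20:
        raise ValueError("need at least 20 grains")
    cfg = config if config is not None else PipelineConfig()
    rng = np.random.default_rng(seed)
    rows = []
    attempts = 0
    while len(rows) < n and attempts < 3 * n:
        attempts += 1
        a = rng.uniform(3.2, 4.8)
        b = rng.uniform(1.40, 1.62)
        c = b * rng.uniform(0.86, 0.94)
        d = rng.uniform(0.30, 0.80)
        gp = GrainParams(
            semi_axes=(a, b, c), groove_depth=d, groove_width=rng.uniform(0.9, 1.2),
            n_points=n_points, noise_sd=0.01, seed=int(rng.integers(0, 2**31 - 1)),
        )
        cloud, gt = make_grain(gp, gt_resolution=200)
        try:
            record, _ = extract_grain_traits(cloud, cfg)
        except (ValueError, ZeroDivisionError):
            continue
        if signal:
            weight = density_mg_per_mm3 * gt.V + rng.normal(0.0, noise_sd_mg)
        else:
            weight = rng.uniform(25.0, 50.0)
        record = {"id": len(rows), **record, "weight": float(weight)}
        rows.append(record)
    if len(rows) < n:
        raise RuntimeError(f"could only generate {len(rows)}/{n} grains")
    return pd.DataFrame(rows)
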