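"""Geometric morphometrics: outlines and landmark configurations.

Leaf shape is described by elliptic Fourier analysis (EFA) of the closed
outline: the x/y increments along the polygon are expanded in Fourier
harmonics (Kuhl-Giardina chain integrals), normalized by the first-harmonic
ellipse (size to its semi-major axis, orientation and starting point to its
axes).  Harmonic power P_n = (a_n^2 + b_n^2 + c_n^2 + d_n^2)/2 measures how
much outline detail harmonic n carries; the cumulative power fraction is the
standard adequacy diagnostic for choosing the harmonic count.

Flower shape uses fixed landmark configurations (1 center + 4 petal tips +
32 petal-margin semilandmarks = 37 points) aligned by generalized (GLS)
Procrustes superimposition; semilandmarks are treated as fixed points, not
slid.  Shape scores come from a centered PCA of the aligned coordinates
(flowers) or the Fourier coefficients (leaves).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Outline handling
# ---------------------------------------------------------------------------

def resample_outline(points: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed polygon to points equally spaced by arc length.

    The first point and the traversal orientation are preserved; the closing
    edge back to the start is included in the arc length.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(target, cum, closed[:, 0])
    y = np.interp(target, cum, closed[:, 1])
    return np.column_stack([x, y])


def perimeter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# Elliptic Fourier analysis
# ---------------------------------------------------------------------------

@dataclass
class EFACoefficients:
    """Normalized Kuhl-Giardina coefficients, harmonics 1..H.

    ``coeffs`` has shape (H, 4) with columns (a_n, b_n, c_n, d_n) after
    normalization by the first-harmonic ellipse; ``raw`` holds the
    un-normalized coefficients, ``a0``/``c0`` the outline centroid terms, and
    the normalization record keeps (scale, rotation, start shift).
    """

    coeffs: np.ndarray
    raw: np.ndarray
    a0: float
    c0: float
    scale: float
    rotation: float
    start_shift: float

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def harmonic_power(self, normalized: bool = False) -> np.ndarray:
        c = self.coeffs if normalized else self.raw
        return 0.5 * (c ** 2).sum(axis=1)

    def cumulative_power(self) -> np.ndarray:
        """Cumulative fraction of total harmonic power, harmonics 1..H."""
        p = self.harmonic_power()
        return np.cumsum(p) / p.sum()


def _efa_raw(points: np.ndarray, n_harmonics: int,
             parameterization: str = "arc"):
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    dxy = np.diff(closed, axis=0)
    dt = np.linalg.norm(dxy, axis=1)
    keep = dt > 0
    dxy, dt = dxy[keep], dt[keep]
    if parameterization == "uniform":
        # constant step per vertex: treats the input sampling as the curve
        # parameter (an ellipse sampled at equal angles is then exactly its
        # first harmonic); "arc" is the classic chain-length parameterization
        dt = np.full_like(dt, dt.mean())
    elif parameterization != "arc":
        raise ValueError(f"unknown parameterization {parameterization!r}")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    big_t = t[-1]
    phi = 2.0 * np.pi * t / big_t
    n = np.arange(1, n_harmonics + 1)[:, None]
    const = big_t / (2.0 * (n.ravel() ** 2) * np.pi ** 2)
    dcos = np.cos(n * phi[None, 1:]) - np.cos(n * phi[None, :-1])
    dsin = np.sin(n * phi[None, 1:]) - np.sin(n * phi[None, :-1])
    vx = dxy[:, 0] / dt
    vy = dxy[:, 1] / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    d = const * (dsin @ vy)
    # centroid (DC) terms
    xi = np.cumsum(dxy[:, 0]) - dxy[:, 0] / 2.0
    delta = np.cumsum(dxy[:, 1]) - dxy[:, 1] / 2.0
    a0 = (closed[0, 0] + (xi * dt).sum() / big_t)
    c0 = (closed[0, 1] + (delta * dt).sum() / big_t)
    return np.column_stack([a, b, c, d]), float(a0), float(c0)


def _rotate_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        n = i + 1
        rot = np.array([[np.cos(n * theta), -np.sin(n * theta)],
                        [np.sin(n * theta), np.cos(n * theta)]])
        m = coeffs[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _rotate_frame(coeffs: np.ndarray, psi: float) -> np.ndarray:
    rot = np.array([[np.cos(psi), np.sin(psi)],
                    [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        out[i] = (rot @ coeffs[i].reshape(2, 2)).ravel()
    return out


def efa_transform(points: np.ndarray, n_harmonics: int = 15,
                  parameterization: str = "arc") -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed outline, normalized.

    Normalization follows the first-harmonic ellipse: the starting point is
    shifted to the end of its semi-major axis, the coordinate frame is
    rotated so that axis lies along x, and all coefficients are divided by
    the semi-major axis length.  After this, a_1 is 1 and the first-harmonic
    orientation angle is 0.
    """
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    n_pts = np.asarray(points).shape[0]
    if n_harmonics > n_pts / 2:
        raise ValueError(f"{n_harmonics} harmonics exceed the Nyquist limit "
                         f"for {n_pts} points")
    raw, a0, c0 = _efa_raw(points, n_harmonics, parameterization)
    a1, b1, c1, d1 = raw[0]
    theta = 0.5 * np.arctan2(2.0 * (a1 * b1 + c1 * d1),
                             a1 ** 2 + c1 ** 2 - b1 ** 2 - d1 ** 2)
    starred = _rotate_start(raw, theta)
    a1s, b1s, c1s, d1s = starred[0]
    if a1s ** 2 + c1s ** 2 < b1s ** 2 + d1s ** 2:
        # landed on the semi-minor axis; shift a quarter period
        theta += np.pi / 2.0
        starred = _rotate_start(raw, theta)
        a1s, b1s, c1s, d1s = starred[0]
    psi = np.arctan2(c1s, a1s)
    rotated = _rotate_frame(starred, psi)
    scale = np.hypot(a1s, c1s)
    return EFACoefficients(coeffs=rotated / scale, raw=raw, a0=a0, c0=c0,
                           scale=float(scale), rotation=float(psi),
                           start_shift=float(theta))


def efa_reconstruct(coeffs: EFACoefficients, n_points: int = 256,
                    normalized: bool = False, n_harmonics: int | None = None
                    ) -> np.ndarray:
    """Inverse Fourier synthesis of an outline from EFA coefficients."""
    c = coeffs.coeffs if normalized else coeffs.raw
    if n_harmonics is not None:
        c = c[:n_harmonics]
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, c.shape[0] + 1)[:, None]
    cos, sin = np.cos(n * t[None, :]), np.sin(n * t[None, :])
    x = c[:, 0] @ cos + c[:, 1] @ sin
    y = c[:, 2] @ cos + c[:, 3] @ sin
    if not normalized:
        x, y = x + coeffs.a0, y + coeffs.c0
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# Generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_scale(config: np.ndarray) -> np.ndarray:
    c = config - config.mean(axis=0)
    size = np.sqrt((c ** 2).sum())
    if size <= 0:
        raise ValueError("configuration with zero centroid size")
    return c / size


def _rotate_onto(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal 2-D rotation (no reflection) of config onto target."""
    u, _, vt = np.linalg.svd(target.T @ config)
    r = u @ vt
    if np.linalg.det(r) < 0:
        u[:, -1] *= -1.0
        r = u @ vt
    return config @ r.T


def centroid_size(config: np.ndarray) -> float:
    c = np.asarray(config, dtype=float)
    c = c - c.mean(axis=0)
    return float(np.sqrt((c ** 2).sum()))


def gpa_align(configs: list[np.ndarray], tol: float = 1e-10,
              max_iter: int = 100) -> tuple[list[np.ndarray], np.ndarray]:
    """GLS Procrustes superimposition of equal-sized landmark configurations.

    Configurations are translated to a common centroid, scaled to unit
    centroid size, and iteratively rotated to the running consensus until it
    stops changing.  The final frame is made deterministic (independent of
    input order) by rotating everything onto the principal axes of the
    consensus with a fixed sign convention.

    Returns (aligned configurations, consensus shape).
    """
    if len(configs) < 2:
        raise ValueError("need at least two configurations")
    shapes = [np.asarray(c, dtype=float) for c in configs]
    k = shapes[0].shape
    if any(s.shape != k for s in shapes):
        raise ValueError("configurations differ in landmark count")
    aligned = [_center_scale(s) for s in shapes]
    consensus = aligned[0].copy()
    for _ in range(max_iter):
        aligned = [_rotate_onto(s, consensus) for s in aligned]
        new = np.mean(aligned, axis=0)
        new = new / np.sqrt((new ** 2).sum())
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            break
        consensus = new
    # canonical frame: consensus principal axes, deterministic signs
    cov = consensus.T @ consensus
    evals, evecs = np.linalg.eigh(cov)
    evecs = evecs[:, ::-1]
    for j in range(2):
        col = consensus @ evecs[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            evecs[:, j] *= -1.0
    if np.linalg.det(evecs) < 0:
        evecs[:, 1] *= -1.0
    aligned = [s @ evecs for s in aligned]
    consensus = consensus @ evecs
    return aligned, consensus


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations."""
    sa, sb = _center_scale(np.asarray(a, float)), _center_scale(np.asarray(b, float))
    sb = _rotate_onto(sb, sa)
    return float(np.sqrt(((sa - sb) ** 2).sum()))


# ---------------------------------------------------------------------------
# Shape PCA and scalar measures
# ---------------------------------------------------------------------------

def shape_pca(rows: np.ndarray, n_axes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered (not standardized) PCA of flattened shape descriptors.

    Returns (scores, loadings, percent variance).  The sign of each axis is
    fixed so its largest-magnitude loading is positive; fewer informative
    dimensions than requested axes truncate the result with a warning.
    """
    x = np.asarray(rows, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 shapes for a PCA")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s ** 2 / (x.shape[0] - 1)
    n_avail = int(np.sum(s > 1e-12 * max(s[0], 1.0)))
    if n_avail < n_axes:
        log.warning("only %d informative axes available, %d requested",
                    n_avail, n_axes)
    n_keep = min(n_axes, max(n_avail, 1))
    loadings = vt[:n_keep].T
    for j in range(n_keep):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
    scores = xc @ loadings
    total = var.sum()
    pct = 100.0 * var[:n_keep] / total if total > 0 else np.zeros(n_keep)
    return scores, loadings, pct


def leaf_area(points: np.ndarray, scale: float = 1.0) -> float:
    """Polygon area (shoelace) times scale^2 — leaf lamina area in cm^2."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    return float(abs(signed)) * scale ** 2


def petal_length(config: np.ndarray, scale: float = 1.0) -> float:
    """Mean center-to-tip distance of the 4 petals (points 1..4), in mm."""
    c = np.asarray(config, dtype=float)
    center = c[0]
    tips = c[1:5]
    return float(np.mean(np.linalg.norm(tips - center, axis=1))) * scale


def derive_leaf_traits(outlines: list[tuple[str, np.ndarray]],
                       n_harmonics: int = 15, n_points: int = 256,
                       n_axes: int = 3):
    """EFA + PCA leaf-shape scores (V15..V17) for labelled outlines.

    Returns (labels, scores, pct variance); scores are centered across
    individuals.
    """
    labels = [lab for lab, _ in outlines]
    rows = []
    for _, xy in outlines:
        res = resample_outline(xy, n_points)
        rows.append(efa_transform(res, n_harmonics).coeffs.ravel())
    scores, _, pct = shape_pca(np.asarray(rows), n_axes)
    return labels, scores, pct


def derive_flower_traits(configs: list[tuple[str, np.ndarray]],
                         n_axes: int = 4):
    """GPA + PCA flower-shape scores (V11..V14) for labelled configurations."""
    labels = [lab for lab, _ in configs]
    aligned, _ = gpa_align([c for _, c in configs])
    rows = np.asarray([a.ravel() for a in aligned])
    scores, _, pct = shape_pca(rows, n_axes)
    return labels, scores, pct
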