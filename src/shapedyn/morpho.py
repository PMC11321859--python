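"""Outline morphometrics: normalization, elliptic Fourier analysis, PCA.

Raw closed 2-D outlines are centred, scaled to unit centroid size and
manually reoriented (the orientation angle is an input, never inferred),
then decomposed into elliptic Fourier harmonics (Kuhl-Giardina formulas,
chord-length parameterization of the closed polygon).  The number of
harmonics is chosen so that a stated fraction of the cumulative harmonic
power is retained.  Flattened coefficient vectors are finally projected
onto principal component axes (centred, covariance PCA) to yield
de-correlated continuous traits for phylogenetic inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "Outline",
    "EFACoefficients",
    "PCABasis",
    "TraitMatrix",
    "normalize_outline",
    "efa_transform",
    "inverse_efa",
    "harmonic_power",
    "choose_harmonics",
    "fit_pca",
    "project_coefficients",
    "shape_along_axis",
]


@dataclass
class Outline:
    """A closed 2-D outline: the first point follows the last."""

    specimen_id: str
    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 8:
            raise ValueError("an outline needs at least 8 points")
        # drop an explicitly repeated closing point, then check duplicates
        if np.allclose(self.points[0], self.points[-1]):
            self.points = self.points[:-1]
        diffs = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        if np.any(np.all(diffs == 0.0, axis=1)):
            raise ValueError("outline has consecutive duplicate points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def centroid_size(self) -> float:
        """Root mean squared distance of points to the centroid."""
        d = self.points - self.centroid()
        return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


@dataclass
class EFACoefficients:
    """Elliptic Fourier coefficients, one (a_n, b_n, c_n, d_n) row per
    harmonic.  ``a0``/``c0`` hold the outline's positional (DC) terms."""

    specimen_id: str
    harmonics: np.ndarray
    a0: float = 0.0
    c0: float = 0.0

    def __post_init__(self):
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        if self.harmonics.ndim != 2 or self.harmonics.shape[1] != 4:
            raise ValueError("harmonics must be an (H, 4) array")
        if len(self.harmonics) < 1:
            raise ValueError("need at least one harmonic")
        if not np.all(np.isfinite(self.harmonics)):
            raise ValueError("coefficients must be finite")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def flatten(self) -> np.ndarray:
        return self.harmonics.ravel()


@dataclass
class PCABasis:
    """Centred PCA basis over flattened coefficient vectors."""

    mean_vector: np.ndarray
    loadings: np.ndarray      # (p, r), orthonormal columns
    eigenvalues: np.ndarray   # (r,), non-increasing

    def __post_init__(self):
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10):
            raise ValueError("loadings must be orthonormal")

    @property
    def rank(self) -> int:
        return self.loadings.shape[1]


@dataclass
class TraitMatrix:
    """Taxa-by-trait matrix of PC scores with the explained-variance curve."""

    taxa: list
    values: np.ndarray
    explained: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.explained = np.asarray(self.explained, dtype=float)
        if len(self.taxa) != self.values.shape[0]:
            raise ValueError("one row of values per taxon required")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def subset(self, taxa: Sequence[str], n_traits: Optional[int] = None
               ) -> "TraitMatrix":
        idx = {t: i for i, t in enumerate(self.taxa)}
        rows = [idx[t] for t in taxa]
        k = n_traits if n_traits is not None else self.k
        return TraitMatrix(list(taxa), self.values[np.ix_(rows, range(k))],
                           self.explained[:k] if self.explained.size else np.empty(0))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_outline(raw: Outline, orientation_angle: float = 0.0,
                      start_index: int = 0) -> Outline:
    """Centre, scale to unit centroid size, rotate, and re-index.

    ``orientation_angle`` (radians, counterclockwise) is the manual
    per-specimen reorientation; ``start_index`` designates the homologous
    point, which becomes the first point of the outline.
    """
    pts = raw.points - raw.points.mean(axis=0)
    size = np.sqrt(np.mean(np.sum(pts * pts, axis=1)))
    if size == 0.0:
        raise ValueError(f"degenerate outline {raw.specimen_id!r} (zero size)")
    pts = pts / size
    if orientation_angle != 0.0:
        c, s = np.cos(orientation_angle), np.sin(orientation_angle)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    pts = np.roll(pts, -int(start_index) % len(pts), axis=0)
    return Outline(raw.specimen_id, pts)


# ---------------------------------------------------------------------------
# elliptic Fourier analysis
# ---------------------------------------------------------------------------

def _chord_params(points: np.ndarray):
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)                    # (K, 2) segment steps
    dt = np.sqrt(np.sum(d * d, axis=1))            # chord lengths
    t = np.concatenate([[0.0], np.cumsum(dt)])     # cumulative arc length
    return d, dt, t, t[-1]


def efa_transform(outline: Union[Outline, np.ndarray],
                  n_harmonics: int) -> EFACoefficients:
    """Standard elliptic Fourier coefficients of a closed polygon.

    The polygon is parameterized by chord (arc) length; the integrals are
    evaluated exactly for the piecewise-linear curve.  No size or rotation
    normalization is applied here — that lives in :func:`normalize_outline`.
    """
    if isinstance(outline, Outline):
        pts, sid = outline.points, outline.specimen_id
    else:
        pts, sid = np.asarray(outline, dtype=float), ""
    n_max = len(pts) // 2
    if not 1 <= n_harmonics <= n_max:
        raise ValueError(
            f"n_harmonics must be in [1, {n_max}] for {len(pts)} points")
    d, dt, t, T = _chord_params(pts)

    n = np.arange(1, n_harmonics + 1)[:, None]     # (H, 1)
    phi = 2.0 * np.pi * n * t[None, :] / T         # (H, K+1)
    dcos = np.diff(np.cos(phi), axis=1)            # (H, K)
    dsin = np.diff(np.sin(phi), axis=1)
    const = T / (2.0 * (n.ravel() ** 2) * np.pi ** 2)
    dx_dt = d[:, 0] / dt
    dy_dt = d[:, 1] / dt
    a = const * (dcos @ dx_dt)
    b = const * (dsin @ dx_dt)
    c = const * (dcos @ dy_dt)
    e = const * (dsin @ dy_dt)

    # DC terms: exact average of the piecewise-linear curve over arc length
    closed = np.vstack([pts, pts[:1]])
    seg_mean = 0.5 * (closed[:-1] + closed[1:])
    a0, c0 = (seg_mean * dt[:, None]).sum(axis=0) / T
    return EFACoefficients(sid, np.column_stack([a, b, c, e]),
                           a0=float(a0), c0=float(c0))


def inverse_efa(coeffs: EFACoefficients, n_points: int) -> Outline:
    """Evaluate the elliptic Fourier series at ``n_points`` parameters."""
    if n_points < 8:
        raise ValueError("n_points must be at least 8")
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.a0 + a @ cos + b @ sin
    y = coeffs.c0 + c @ cos + d @ sin
    return Outline(coeffs.specimen_id or "reconstruction",
                   np.column_stack([x, y]))


def harmonic_power(coeffs: EFACoefficients) -> np.ndarray:
    """Cumulative harmonic power fractions.

    Per-harmonic power is (a^2 + b^2 + c^2 + d^2) / 2; the returned array
    is the running sum normalized by the total.
    """
    power = 0.5 * np.sum(coeffs.harmonics ** 2, axis=1)
    total = power.sum()
    if total == 0.0:
        raise ValueError("all-zero coefficients have no harmonic power")
    return np.cumsum(power) / total


def choose_harmonics(outline: Outline, threshold: float,
                     h_max: Optional[int] = None) -> int:
    """Smallest harmonic count whose cumulative power reaches ``threshold``.

    Power fractions are measured against the total power at the outline's
    full harmonic resolution (half the point count), so a small ``h_max``
    can genuinely fail to reach the threshold.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    h_full = outline.n_points // 2
    h_max = h_full if h_max is None else min(h_max, h_full)
    cum = harmonic_power(efa_transform(outline, h_full))
    idx = np.nonzero(cum >= threshold)[0]
    if idx.size == 0 or idx[0] + 1 > h_max:
        raise ValueError(
            f"threshold {threshold} not reached within {h_max} harmonics")
    return int(idx[0]) + 1


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def fit_pca(coeff_table, taxa: Optional[Sequence[str]] = None,
            tol: float = 1e-12) -> tuple[PCABasis, TraitMatrix]:
    """Centred (covariance) PCA of flattened coefficient vectors.

    ``coeff_table`` is either an (n, p) array or a list of
    :class:`EFACoefficients` (taxa then default to the specimen ids).  Only
    centring is applied — no per-column unit-variance scaling.  Axes with
    numerically zero variance are dropped, so the returned rank is the true
    rank of the centred data (at most n - 1).
    """
    if not isinstance(coeff_table, np.ndarray):
        items = list(coeff_table)
        if items and isinstance(items[0], EFACoefficients):
            if taxa is None:
                taxa = [c.specimen_id for c in items]
            coeff_table = np.vstack([c.flatten() for c in items])
        else:
            coeff_table = np.asarray(coeff_table, dtype=float)
    x = np.atleast_2d(np.asarray(coeff_table, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 specimens")
    if taxa is None:
        taxa = [f"s{i}" for i in range(n)]
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    rank = int(np.sum(eig > tol * max(eig[0], 1.0)))
    rank = max(rank, 1)
    basis = PCABasis(mean, vt[:rank].T, eig[:rank])
    scores = xc @ basis.loadings
    total = eig.sum()
    explained = np.cumsum(eig[:rank]) / total if total > 0 else np.ones(rank)
    return basis, TraitMatrix(list(taxa), scores, explained)


def project_coefficients(basis: PCABasis, flat: np.ndarray) -> np.ndarray:
    """PC scores of one or more flattened coefficient vectors."""
    return (np.atleast_2d(flat) - basis.mean_vector) @ basis.loadings


def shape_along_axis(basis: PCABasis, axis: int, multiple: float,
                     n_points: int = 300) -> Outline:
    """Mean shape displaced ``multiple`` standard deviations along one axis."""
    if not 0 <= axis < basis.rank:
        raise ValueError(f"axis {axis} out of range (rank {basis.rank})")
    flat = (basis.mean_vector
            + multiple * np.sqrt(basis.eigenvalues[axis]) * basis.loadings[:, axis])
    coeffs = EFACoefficients(f"pc{axis + 1}_{multiple:+g}sd",
                             flat.reshape(-1, 4))
    return inverse_efa(coeffs, n_points)
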