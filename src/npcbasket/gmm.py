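"""Gaussian mixtures standing in for density maps and bead models.

The model-to-map score used throughout is the normalized overlap
(cross-correlation) between two mixtures,

    CC(f, g) = <f, g> / sqrt(<f, f> <g, g>),

where ``<f, g> = sum_ij w_i v_j integral N_i(x) M_j(x) dx`` and the integral
of a product of two isotropic 3-D Gaussians has the closed form

    (2 pi (s_i^2 + t_j^2))^(-3/2) * exp(-|mu_i - nu_j|^2 / (2 (s_i^2 + t_j^2))).

CC is symmetric, lies in [0, 1] for nonnegative weights, and is invariant to
rescaling either mixture's weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["GaussianMixture", "gmm_overlap", "cross_correlation", "model_to_gmm",
           "fit_gmm_to_grid"]


@dataclass
class GaussianMixture:
    """Weighted isotropic 3-D Gaussians (one row per component)."""

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float).reshape(-1, 3)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.sigmas)):
            raise ValueError("component arrays must have equal length")
        if len(self.weights) == 0:
            raise ValueError("a mixture needs at least one component")
        if np.any(self.sigmas <= 0):
            raise ValueError("all sigmas must be positive")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.weights)

    def normalized(self) -> "GaussianMixture":
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("zero-norm mixture")
        return GaussianMixture(self.weights / total, self.means, self.sigmas)

    def density(self, points: np.ndarray) -> np.ndarray:
        """Mixture density evaluated at (n, 3) ``points``."""
        points = np.atleast_2d(points)
        d2 = cdist(points, self.means, "sqeuclidean")
        norm = (2.0 * np.pi * self.sigmas**2) ** 1.5
        return (self.weights / norm * np.exp(-0.5 * d2 / self.sigmas**2)).sum(axis=1)


def gmm_overlap(a: GaussianMixture, b: GaussianMixture) -> float:
    """Analytic overlap integral <f, g> of two mixtures."""
    s2 = a.sigmas[:, None] ** 2 + b.sigmas[None, :] ** 2
    d2 = cdist(a.means, b.means, "sqeuclidean")
    kern = (2.0 * np.pi * s2) ** -1.5 * np.exp(-0.5 * d2 / s2)
    return float(a.weights @ kern @ b.weights)


def cross_correlation(a: GaussianMixture, b: GaussianMixture) -> float:
    """Normalized overlap CC in [0, 1]; symmetric; weight-scale invariant."""
    num = gmm_overlap(a, b)
    den = gmm_overlap(a, a) * gmm_overlap(b, b)
    if den <= 0:
        raise ValueError("zero-norm mixture")
    return float(num / np.sqrt(den))


def model_to_gmm(state, sigma_scale: float = 1.0) -> GaussianMixture:
    """One Gaussian per coarse bead: sigma = sigma_scale * radius, weight
    proportional to the bead's residue count."""
    if state.n_beads == 0:
        raise ValueError("empty assembly state")
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be positive")
    idx = state.coarse_idx
    return GaussianMixture(
        weights=state.nres[idx].astype(float),
        means=state.coords[idx],
        sigmas=sigma_scale * state.radii[idx],
    )


def fit_gmm_to_grid(
    values: np.ndarray,
    origin: np.ndarray,
    voxel_size: float,
    n_components: int,
    seed: int = 0,
    n_samples: int = 20000,
) -> GaussianMixture:
    """Fit an isotropic GMM to a voxel grid by expectation-maximization.

    Density weighting is realized by resampling voxel centers with
    probability proportional to (nonnegative) density, then running EM with
    k-means initialization (seed-controlled) on the sample.
    """
    from sklearn.mixture import GaussianMixture as SkGMM

    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be a 3-D voxel grid")
    pos = np.clip(values, 0.0, None)
    total = pos.sum()
    if total <= 0:
        raise ValueError("grid has no positive density")
    rng = np.random.default_rng(seed)
    flat = pos.ravel() / total
    pick = rng.choice(flat.size, size=n_samples, p=flat)
    ijk = np.column_stack(np.unravel_index(pick, values.shape)).astype(float)
    pts = np.asarray(origin) + (ijk + 0.5) * voxel_size
    pts += rng.uniform(-0.5, 0.5, size=pts.shape) * voxel_size  # de-quantize
    sk = SkGMM(
        n_components=n_components,
        covariance_type="spherical",
        init_params="k-means++",
        n_init=5,
        random_state=int(seed) % (2**31),
        max_iter=200,
    ).fit(pts)
    return GaussianMixture(
        weights=sk.weights_, means=sk.means_, sigmas=np.sqrt(sk.covariances_)
    )
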