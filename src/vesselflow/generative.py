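"""Latent-space analysis and synthesis of new anatomies.

Once trained, the latent codes of the cohort define an empirical
distribution over shapes: new anatomies are decoded by sampling a code
from N(0, Sigma_z) — Sigma_z the unbiased covariance of the training
codes — and integrating the flow backward in time from the template.
Interpolation (linear or spherical-linear) between two codes yields
smooth in-between anatomies; small code perturbations probe latent
stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .cloud import WeightedPointCloud
from .integrator import inverse_map_explicit
from .network import VelocityFieldModel

__all__ = [
    "LatentSpaceModel",
    "fit_latent_space",
    "sample_codes",
    "interpolate_codes",
    "perturb_code_snr",
    "generate_shape",
]


@dataclass
class LatentSpaceModel:
    codes: np.ndarray  # (N_s, N_z)
    mean: np.ndarray  # (N_z,)
    covariance: np.ndarray  # (N_z, N_z), unbiased
    pca: PCA  # 2-D projection of the code set

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.pca.explained_variance_ratio_

    def project(self, codes: np.ndarray) -> np.ndarray:
        return self.pca.transform(np.atleast_2d(codes))

    def backproject(self, coords2d: np.ndarray) -> np.ndarray:
        return self.pca.inverse_transform(np.atleast_2d(coords2d))


def fit_latent_space(codes: np.ndarray) -> LatentSpaceModel:
    """Unbiased covariance (n-1 denominator) and a 2-D PCA of the codes."""
    codes = np.atleast_2d(np.asarray(codes, dtype=np.float64))
    if len(codes) < 2:
        raise ValueError("covariance needs at least 2 codes")
    mean = codes.mean(axis=0)
    centred = codes - mean
    cov = centred.T @ centred / (len(codes) - 1)
    pca = PCA(n_components=min(2, *codes.shape), svd_solver="full")
    pca.fit(codes)
    return LatentSpaceModel(codes=codes, mean=mean, covariance=cov, pca=pca)


def sample_codes(latent: LatentSpaceModel, n: int, seed: int = 0) -> np.ndarray:
    """Draw n codes from N(0, Sigma_z); sampling is centred at the origin
    (where the w_z shrinkage pulls the codes), not at the empirical mean.

    The covariance square root comes from an eigendecomposition; small
    negative eigenvalues from numerical noise are clipped at zero.
    """
    rng = np.random.default_rng(seed)
    evals, evecs = np.linalg.eigh(latent.covariance)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    xi = rng.standard_normal((n, latent.covariance.shape[0]))
    return xi @ root.T


def interpolate_codes(z_a: np.ndarray, z_b: np.ndarray, t: float, mode: str = "linear"):
    """Interpolate between two codes: convex combination or great-arc SLERP."""
    z_a = np.asarray(z_a, dtype=np.float64)
    z_b = np.asarray(z_b, dtype=np.float64)
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must lie in [0, 1]")
    if mode == "linear":
        return (1.0 - t) * z_a + t * z_b
    if mode != "slerp":
        raise ValueError(f"unknown interpolation mode: {mode!r}")
    if t == 0.0:
        return z_a.copy()
    if t == 1.0:
        return z_b.copy()
    na, nb = np.linalg.norm(z_a), np.linalg.norm(z_b)
    if na == 0 or nb == 0:
        warnings.warn("slerp undefined for a zero code; falling back to linear")
        return (1.0 - t) * z_a + t * z_b
    cosw = np.clip(z_a @ z_b / (na * nb), -1.0, 1.0)
    if cosw < -1.0 + 1e-9:  # (near-)antipodal: the great arc is ill-defined
        warnings.warn("slerp on near-antipodal codes; falling back to linear")
        return (1.0 - t) * z_a + t * z_b
    if cosw > 1.0 - 1e-12:  # parallel codes: slerp degenerates to linear
        return (1.0 - t) * z_a + t * z_b
    omega = np.arccos(cosw)
    return (np.sin((1.0 - t) * omega) * z_a + np.sin(t * omega) * z_b) / np.sin(omega)


def perturb_code_snr(z: np.ndarray, snr_fraction: float, seed: int = 0) -> np.ndarray:
    """Add white Gaussian noise rescaled so ||e|| = snr_fraction * ||z||.

    The noise level is interpreted as a noise-to-signal Euclidean-norm
    ratio (an SNR of 5% displaces the code by 5% of its norm).
    """
    if snr_fraction < 0:
        raise ValueError("snr_fraction must be >= 0")
    z = np.asarray(z, dtype=np.float64)
    if snr_fraction == 0:
        return z.copy()
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(z.shape)
    e *= snr_fraction * np.linalg.norm(z) / np.linalg.norm(e)
    return z + e


def generate_shape(
    code: np.ndarray,
    template: WeightedPointCloud,
    model: VelocityFieldModel,
    K: int = 10,
) -> WeightedPointCloud:
    """Decode a latent code: apply the inverse map to the template cloud.

    The synthetic cloud carries the template's weights (and point count),
    so cloud-level topology is preserved by construction.
    """
    traj = inverse_map_explicit(template.points, model, np.asarray(code), K)
    return template.with_points(traj.endpoint, label="generated")
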