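"""Scikit-learn style facade over the registration pipeline.

``SVFAtlasRegistration`` fits a shared velocity field plus one latent code
per cohort shape (``fit``), maps sources onto the template (``transform``)
and the template onto sources (``inverse_transform``), embeds unseen
shapes by code-only optimization (``encode``), and synthesizes new
anatomies from the fitted latent distribution (``sample``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .attachment import bidirectional_error
from .cloud import WeightedPointCloud
from .generative import fit_latent_space, generate_shape, sample_codes
from .integrator import forward_map, inverse_map_explicit
from .network import NetConfig
from .trainer import TrainConfig, infer_latent, train

__all__ = ["SVFAtlasRegistration"]


class SVFAtlasRegistration(BaseEstimator):
    """Simultaneous diffeomorphic registration of a shape cohort to a template.

    Parameters mirror the network and training configurations; fitted
    state lives in ``model_`` (velocity field), ``codes_`` (latent codes,
    one per training shape), ``template_`` and ``history_``.

    Examples
    --------
    >>> reg = SVFAtlasRegistration(n_z=32, epochs=50, sample_points=200)
    >>> reg.fit(source_clouds, template_cloud)     # doctest: +SKIP
    >>> mapped = reg.transform()                   # doctest: +SKIP
    """

    def __init__(
        self,
        n_z: int = 256,
        g_z: int = 2,
        fa_layers: int = 3,
        fa_width: int = 64,
        df_layers: int = 5,
        df_width: int = 256,
        n_e: int = 3,
        leaky_slope: float = 0.2,
        epochs: int = 500,
        batch_size: int = 8,
        sample_points: int = 2000,
        adaptive_fraction: float = 0.15,
        lr: float = 1e-3,
        w_z: float = 1e-3,
        w_v: float = 1e-4,
        w_theta: float = 0.0,
        w_n: float = 1e-2,
        measure: str = "cd",
        K: int = 10,
        random_state: int = 0,
    ):
        self.n_z = n_z
        self.g_z = g_z
        self.fa_layers = fa_layers
        self.fa_width = fa_width
        self.df_layers = df_layers
        self.df_width = df_width
        self.n_e = n_e
        self.leaky_slope = leaky_slope
        self.epochs = epochs
        self.batch_size = batch_size
        self.sample_points = sample_points
        self.adaptive_fraction = adaptive_fraction
        self.lr = lr
        self.w_z = w_z
        self.w_v = w_v
        self.w_theta = w_theta
        self.w_n = w_n
        self.measure = measure
        self.K = K
        self.random_state = random_state

    # -- config plumbing -----------------------------------------------------
    def _net_config(self) -> NetConfig:
        return NetConfig(
            fa_layers=self.fa_layers, fa_width=self.fa_width,
            df_layers=self.df_layers, df_width=self.df_width,
            n_e=self.n_e, leaky_slope=self.leaky_slope,
            n_z=self.n_z, g_z=self.g_z,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            sample_points=self.sample_points,
            adaptive_fraction=self.adaptive_fraction,
            lr=self.lr, w_z=self.w_z, w_v=self.w_v, w_theta=self.w_theta,
            w_n=self.w_n, measure=self.measure, K=self.K, seed=self.random_state,
        )

    # -- estimator API -------------------------------------------------------
    def fit(self, X: list[WeightedPointCloud], y: WeightedPointCloud = None):
        """Fit the velocity field and codes; X is the source cohort, y the template."""
        if y is None:
            raise ValueError("fit requires the template cloud as y")
        if not X:
            raise ValueError("fit requires at least one source cloud")
        self.model_, self.codebank_, self.history_ = train(
            list(X), y, self._net_config(), self._train_config()
        )
        self.codes_ = self.codebank_.matrix.T  # (N_s, N_z)
        self.template_ = y
        self.sources_ = list(X)
        return self

    def transform(self, X: list[WeightedPointCloud] | None = None):
        """Map the fitted sources (or unseen clouds, via encode) onto the template."""
        check_is_fitted(self, "model_")
        if X is None:
            return [
                s.with_points(forward_map(s.points, self.model_, z, self.K).endpoint)
                for s, z in zip(self.sources_, self.codes_)
            ]
        return [self.register(c)[0] for c in X]

    def inverse_transform(self, codes: np.ndarray | None = None):
        """Decode codes (default: the fitted ones) into template deformations."""
        check_is_fitted(self, "model_")
        codes = self.codes_ if codes is None else np.atleast_2d(codes)
        return [generate_shape(z, self.template_, self.model_, self.K) for z in codes]

    def encode(self, cloud: WeightedPointCloud):
        """Latent inference for an unseen shape (network frozen)."""
        check_is_fitted(self, "model_")
        return infer_latent(cloud, self.template_, self.model_, self._train_config())

    def register(self, cloud: WeightedPointCloud):
        """Encode an unseen shape and return (mapped cloud, inference result)."""
        res = self.encode(cloud)
        return res.forward_mapped, res

    def sample(self, n: int, seed: int = 0):
        """Draw codes from N(0, Sigma_z) and decode them into new anatomies."""
        check_is_fitted(self, "model_")
        latent = fit_latent_space(self.codes_)
        return [
            generate_shape(z, self.template_, self.model_, self.K)
            for z in sample_codes(latent, n, seed=seed)
        ]

    def score(self, X=None, y=None) -> float:
        """Negative mean bidirectional Chamfer error over the fitted cohort."""
        check_is_fitted(self, "model_")
        errs = []
        for s, z in zip(self.sources_, self.codes_):
            fwd = s.with_points(forward_map(s.points, self.model_, z, self.K).endpoint)
            inv = self.template_.with_points(
                inverse_map_explicit(self.template_.points, self.model_, z, self.K).endpoint
            )
            errs.append(bidirectional_error(s, self.template_, fwd, inv, "cd"))
        return -float(np.mean(errs))
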