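"""Cross-spectral data features via multivariate autoregressive modelling.

Thirty-second multichannel epochs are summarised by a vector autoregression
x_n = sum_m A_m x_{n-m} + e_n fitted by least squares; the CSD follows from
the AR transfer function H(f) = (I - sum_m A_m exp(-i 2 pi f m / Fs))^-1 as
G(f) = H(f) Sigma H(f)^H / Fs (one-sided density per Hz).  The default
order p = 8 supports at least four spectral peaks across the 10-35 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.vector_ar.var_model import VAR

from .spectra import CrossSpectra, default_grid

DEFAULT_AR_ORDER = 8


@dataclass
class TimeSeriesRecord:
    """time x channel samples with sampling rate (Hz) and channel labels."""

    samples: np.ndarray
    sampling_rate: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] < 2:
            raise ValueError("samples must be time x channel with >= 2 channels")
        if self.samples.shape[1] != len(self.channels):
            raise ValueError("channel label count must match sample columns")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class VARModel:
    """Order-p vector autoregression: coefficient stack A (p, C, C) and
    residual covariance Sigma (C, C)."""

    order: int
    coeffs: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.order < 1 or self.coeffs.shape[0] != self.order:
            raise ValueError("coefficient stack must have shape (p, C, C)")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("residual covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion_spectral_radius(self) -> float:
        p, C = self.order, self.n_channels
        comp = np.zeros((p * C, p * C))
        comp[:C, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[C:, :-C] = np.eye((p - 1) * C)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def is_stable(self) -> bool:
        return self.companion_spectral_radius() < 1.0


def fit_var(rec: TimeSeriesRecord, order: int = DEFAULT_AR_ORDER) -> VARModel:
    """Least-squares VAR fit (no intercept; inputs are zero-mean LFPs)."""
    C = rec.samples.shape[1]
    if rec.n_samples < 10 * order * C:
        raise ValueError(
            f"series too short: {rec.n_samples} samples for order {order}, "
            f"{C} channels"
        )
    res = VAR(rec.samples - rec.samples.mean(axis=0)).fit(maxlags=order, trend="n")
    if res.k_ar != order:
        raise RuntimeError("VAR fit did not use the requested order")
    coeffs = np.asarray(res.coefs)  # (p, C, C)
    resid = np.asarray(res.resid)
    sigma = resid.T @ resid / resid.shape[0]
    return VARModel(order=order, coeffs=coeffs, sigma=sigma)


def var_to_csd(model: VARModel, grid=None, sampling_rate: float = 250.0,
               channels: list[str] | None = None) -> CrossSpectra:
    """CSD of a stable VAR model on ``grid`` (Hz)."""
    if not model.is_stable():
        raise ValueError(
            f"VAR model unstable (companion spectral radius "
            f"{model.companion_spectral_radius():.4f} >= 1)"
        )
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    C = model.n_channels
    channels = channels or [f"ch{i}" for i in range(C)]
    values = np.empty((C, C, len(grid)), dtype=complex)
    eye = np.eye(C)
    for fi, f in enumerate(grid):
        Af = eye.astype(complex).copy()
        for m in range(1, model.order + 1):
            Af -= model.coeffs[m - 1] * np.exp(-2j * np.pi * f * m / sampling_rate)
        H = np.linalg.inv(Af)
        G = H @ model.sigma @ H.conj().T / sampling_rate
        values[:, :, fi] = 0.5 * (G + G.conj().T)
    return CrossSpectra(grid, values, list(channels), sampling_rate)


def extract_features(rec: TimeSeriesRecord, order: int = DEFAULT_AR_ORDER,
                     grid=None) -> CrossSpectra:
    """fit_var followed by var_to_csd on the analysis grid."""
    model = fit_var(rec, order=order)
    return var_to_csd(model, grid=grid, sampling_rate=rec.sampling_rate,
                      channels=list(rec.channels))
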