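"""Cross-spectral forward model and z-domain system characterisation.

The linearised circuit acts as a multi-input multi-output filter: white+pink
neuronal innovations at five sites are shaped by the transfer functions
T(w) = C (iwI - J)^-1 B and summed with channel-noise spectra to give the
predicted cross-spectral density matrix on the analysis grid (10-35 Hz by
default).  The same state-space model yields a Laplace-domain pole-zero
description which, after a bilinear s->z map, places resonances on the unit
circle with the associated arctan frequency warping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .circuit import (
    CircuitSpec,
    ParameterVector,
    fixed_point,
    innovation_matrix,
    jacobian_at,
    observation_matrix,
)

DEFAULT_SAMPLING_RATE = 250.0  # Hz; Nyquist 125 Hz for the z-domain analysis

CSD_FORMAT_VERSION = "1"


def default_grid() -> np.ndarray:
    """The 26-frequency analysis grid: 10, 11, ..., 35 Hz."""
    return np.arange(10.0, 36.0, 1.0)


def extended_grid(fmax: float = 100.0) -> np.ndarray:
    """1 Hz grid from 10 Hz to ``fmax``, for out-of-band (e.g. gamma)
    predictions."""
    return np.arange(10.0, fmax + 1.0, 1.0)


@dataclass
class CrossSpectra:
    """Channels x channels x frequency complex CSD on a declared grid.

    Hermitian at each frequency; diagonals real and nonnegative.
    """

    grid: np.ndarray
    values: np.ndarray  # (C, C, F) complex
    channels: list[str]
    sampling_rate: float = DEFAULT_SAMPLING_RATE

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        C, F = len(self.channels), len(self.grid)
        if self.values.shape != (C, C, F):
            raise ValueError(f"values must have shape ({C},{C},{F})")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def is_hermitian(self, tol: float = 1e-8) -> bool:
        scale = max(1.0, float(np.max(np.abs(self.values))))
        return bool(
            np.all(
                np.abs(self.values - self.values.conj().transpose(1, 0, 2))
                <= tol * scale
            )
        )

    def auto_spectra(self) -> np.ndarray:
        """(C, F) real auto-spectra."""
        return np.real(np.einsum("iif->if", self.values))

    def copy(self) -> "CrossSpectra":
        return CrossSpectra(self.grid.copy(), self.values.copy(),
                            list(self.channels), self.sampling_rate)


@dataclass
class NoiseSpectrumParams:
    """White + pink (1/f) levels for the innovation sites and the three
    channel-noise components (cortex electrode, per-BG electrode, common BG
    volume-conduction)."""

    u_white: float
    u_pink: float
    u_scales: dict[str, float]
    ctx_white: float
    ctx_pink: float
    bg_white: float
    bg_pink: float
    bgc_white: float
    bgc_pink: float

    @classmethod
    def from_params(cls, params: ParameterVector) -> "NoiseSpectrumParams":
        circuit = params.circuit
        return cls(
            u_white=params.physical("u_white"),
            u_pink=params.physical("u_pink"),
            u_scales={s: params.physical(f"u_scale_{s}") for s in circuit.innovation_sites},
            ctx_white=params.physical("n_ctx_white"),
            ctx_pink=params.physical("n_ctx_pink"),
            bg_white=params.physical("n_bg_white"),
            bg_pink=params.physical("n_bg_pink"),
            bgc_white=params.physical("n_bgc_white"),
            bgc_pink=params.physical("n_bgc_pink"),
        )


def innovation_spectrum(freq, white: float, pink: float):
    """Power density of a white + pink mixture: white + pink/f."""
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    return white + pink / f


class UnstableModelError(RuntimeError):
    pass


def transfer_functions(J: np.ndarray, B: np.ndarray, C: np.ndarray,
                       grid, warn_unstable: bool = True) -> np.ndarray:
    """Frequency responses T(w) = C (iwI - J)^-1 B.

    ``J`` is in ms^-1 units, ``grid`` in Hz; returns (channels, inputs, F)
    complex.  Raises :class:`UnstableModelError` only on a singular resolvent;
    an unstable J triggers a warning since the spectra are then meaningless.
    """
    grid = np.asarray(grid, dtype=float)
    eig = np.linalg.eigvals(J)
    if warn_unstable and np.max(eig.real) >= 0:
        import warnings

        warnings.warn("Jacobian is not stable; spectra are not stationary",
                      RuntimeWarning, stacklevel=2)
    n = J.shape[0]
    omega = 2.0 * np.pi * grid / 1000.0  # rad/ms
    A = 1j * omega[:, None, None] * np.eye(n)[None] - J[None]
    try:
        X = np.linalg.solve(A, np.broadcast_to(B, (len(grid), *B.shape)))
    except np.linalg.LinAlgError as e:
        raise UnstableModelError("(iwI - J) singular on the grid") from e
    T = C[None] @ X  # (F, channels, inputs)
    return np.transpose(T, (1, 2, 0))


def _channel_groups(circuit: CircuitSpec):
    ctx = [i for i, s in enumerate(circuit.observed_sources) if s == "ctx"]
    bg = [i for i, s in enumerate(circuit.observed_sources) if s != "ctx"]
    return ctx, bg


def channel_noise_csd(circuit: CircuitSpec, noise: NoiseSpectrumParams,
                      grid) -> np.ndarray:
    """Channel-noise contribution to the CSD: independent cortex and per-BG
    electrode noise on the diagonals plus a fully coherent common BG term on
    every BG x BG entry."""
    grid = np.asarray(grid, dtype=float)
    C = len(circuit.observed_sources)
    out = np.zeros((C, C, len(grid)), dtype=complex)
    ctx_idx, bg_idx = _channel_groups(circuit)
    for i in ctx_idx:
        out[i, i, :] += innovation_spectrum(grid, noise.ctx_white, noise.ctx_pink)
    for i in bg_idx:
        out[i, i, :] += innovation_spectrum(grid, noise.bg_white, noise.bg_pink)
    common = innovation_spectrum(grid, noise.bgc_white, noise.bgc_pink)
    for i in bg_idx:
        for j in bg_idx:
            out[i, j, :] += common
    return out


def predict_csd(params: ParameterVector, circuit: CircuitSpec | None = None,
                grid=None, include_channel_noise: bool = True,
                require_stable: bool = True) -> CrossSpectra:
    """Predicted cross-spectral density on ``grid``.

    G_ij(w) = sum_k T_ik(w) g_uk(w) conj(T_jk(w)) + channel noise, where
    g_uk is the k-th innovation spectrum (site scale times the shared
    white+pink mixture).
    """
    circuit = circuit or params.circuit
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    xstar = fixed_point(circuit, params)
    J = jacobian_at(xstar, circuit, params)
    if require_stable and np.max(np.linalg.eigvals(J).real) >= 0:
        raise UnstableModelError("Jacobian has a nonnegative eigenvalue")
    B = innovation_matrix(circuit, params)
    Cmat = observation_matrix(circuit, params)
    T = transfer_functions(J, B, Cmat, grid, warn_unstable=not require_stable)
    noise = NoiseSpectrumParams.from_params(params)
    gu = np.stack([
        noise.u_scales[site] * innovation_spectrum(grid, noise.u_white, noise.u_pink)
        for site in circuit.innovation_sites
    ])  # (K, F)
    G = np.einsum("ikf,kf,jkf->ijf", T, gu, T.conj())
    if include_channel_noise:
        G = G + channel_noise_csd(circuit, noise, grid)
    # enforce exact Hermitian symmetry against rounding
    G = 0.5 * (G + G.conj().transpose(1, 0, 2))
    return CrossSpectra(grid, G, list(circuit.observed_sources))


# ---------------------------------------------------------------------------
# z-domain characterisation
# ---------------------------------------------------------------------------

@dataclass
class PoleZeroSummary:
    """z-plane poles/zeros of one input->channel transfer function under the
    bilinear map, with each pole's unit-circle (warped) frequency and radius."""

    sampling_rate: float
    poles_s: np.ndarray
    poles_z: np.ndarray
    zeros_z: np.ndarray
    pole_freqs: np.ndarray   # Hz read off the unit circle (warped)
    pole_radii: np.ndarray
    channel: str = ""
    input_site: str = ""

    def dominant_pole(self, fmin: float = 0.0, fmax: float | None = None) -> int:
        """Index of the pole closest to the unit circle among those with
        warped frequency in [fmin, fmax]."""
        fmax = self.sampling_rate / 2 if fmax is None else fmax
        mask = (self.pole_freqs >= fmin) & (self.pole_freqs <= fmax)
        if not np.any(mask):
            raise ValueError(f"no pole with warped frequency in [{fmin}, {fmax}]")
        idx = np.flatnonzero(mask)
        return int(idx[np.argmax(self.pole_radii[idx])])


def warp_frequency(freq, sampling_rate: float = DEFAULT_SAMPLING_RATE):
    """Bilinear-transform frequency warping f -> (Fs/pi) atan(pi f / Fs).

    Continuous frequencies are compressed toward the Nyquist rate when the
    s-plane response is mapped onto the unit circle; e.g. 13 Hz -> 12.89 Hz
    at 250 Hz sampling (125 Hz Nyquist).
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f < 0) or np.any(f >= sampling_rate / 2):
        raise ValueError("frequency must lie in [0, Nyquist)")
    return (sampling_rate / np.pi) * np.arctan(np.pi * f / sampling_rate)


def bilinear_map(s, sampling_rate: float):
    """s-plane (rad/s) to z-plane: z = (1 + sT/2)/(1 - sT/2), T = 1/Fs."""
    T = 1.0 / sampling_rate
    s = np.asarray(s, dtype=complex)
    denom = 1.0 - s * T / 2.0
    if np.any(np.abs(denom) < 1e-12):
        raise ValueError("pole at the bilinear singularity s = 2/T")
    return (1.0 + s * T / 2.0) / denom


def pole_zero(params: ParameterVector, sampling_rate: float = DEFAULT_SAMPLING_RATE,
              channel_pair: tuple[str, str] = ("ctx_ss", "stn"),
              circuit: CircuitSpec | None = None) -> PoleZeroSummary:
    """Pole-zero summary of the (innovation site -> channel) transfer
    function.  s-domain poles are the eigenvalues of the delay-corrected
    Jacobian; poles and zeros are mapped to the z-plane bilinearly and each
    pole is annotated with its unit-circle frequency (Hz) and radius."""
    circuit = circuit or params.circuit
    input_site, channel = channel_pair
    if input_site not in circuit.innovation_sites:
        raise ValueError(f"{input_site!r} is not an innovation site")
    if channel not in circuit.observed_sources:
        raise ValueError(f"{channel!r} is not a recorded source")
    xstar = fixed_point(circuit, params)
    J = jacobian_at(xstar, circuit, params)
    B = innovation_matrix(circuit, params)
    Cmat = observation_matrix(circuit, params)
    k = circuit.innovation_sites.index(input_site)
    ch = circuit.observed_sources.index(channel)
    # J is in ms^-1; convert to rad/s for the bilinear map
    A_s = J * 1000.0
    b = B[:, [k]] * 1000.0
    c = Cmat[[ch], :]
    import warnings

    with warnings.catch_warnings():
        # the numerator polynomial of a 16-state SISO reduction is poorly
        # conditioned; zeros are reported as-is, poles are unaffected
        warnings.simplefilter("ignore", scipy.signal.BadCoefficients)
        zeros_s, poles_s, _gain = scipy.signal.ss2zpk(A_s, b, c, np.zeros((1, 1)))
    poles_z = bilinear_map(poles_s, sampling_rate)
    zeros_z = bilinear_map(zeros_s, sampling_rate)
    pole_freqs = np.abs(np.angle(poles_z)) * sampling_rate / (2.0 * np.pi)
    pole_radii = np.abs(poles_z)
    return PoleZeroSummary(
        sampling_rate=sampling_rate,
        poles_s=poles_s,
        poles_z=poles_z,
        zeros_z=zeros_z,
        pole_freqs=pole_freqs,
        pole_radii=pole_radii,
        channel=channel,
        input_site=input_site,
    )


def unit_circle_response(summary: PoleZeroSummary, grid) -> np.ndarray:
    """|T| along the unit circle at the (already warped) frequencies in
    ``grid``: product of distances to zeros over product of distances to
    poles."""
    grid = np.asarray(grid, dtype=float)
    z = np.exp(2j * np.pi * grid / summary.sampling_rate)
    num = np.ones(len(grid))
    for z0 in summary.zeros_z:
        num = num * np.abs(z - z0)
    den = np.ones(len(grid))
    for p in summary.poles_z:
        den = den * np.abs(z - p)
    return num / den
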