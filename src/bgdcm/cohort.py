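"""Synthetic cohorts emulating control and dopamine-lesioned spectral regimes.

The original rat recordings behind this analysis are not publicly
deposited, so every pipeline stage is exercised on data generated from the
circuit model itself.  Two calibrated ground-truth parameter regimes are
shipped: a "control" regime with broadband, low-power spectra and a weak
gamma (~50 Hz) resonance, and a "parkinsonian" regime whose channel-averaged
spectrum is dominated by a beta peak at 17 Hz.  The parkinsonian regime
differs from control only in a strengthened hyperdirect (cortex->STN)
connection, a weakened STN->GPe connection and documented noise-level
differences.  Subjects are drawn around a regime with log-normal
between-subject variability; their data are synthesised in the frequency
domain (exact to the spectral target) or as Wishart-style averaged CSD
draws.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .circuit import CircuitSpec, ParameterVector, build_standard_circuit
from .spectra import (
    CrossSpectra,
    NoiseSpectrumParams,
    UnstableModelError,
    default_grid,
    fixed_point,
    innovation_matrix,
    innovation_spectrum,
    jacobian_at,
    observation_matrix,
    predict_csd,
    transfer_functions,
)
from .ar import TimeSeriesRecord

FIXTURE_VERSION = "1"
DEFAULT_BETWEEN_SD = 0.1  # log units
REGIMES = ("control", "parkinsonian")

# Parameter classes that carry between-subject variability.
VARIABLE_CLASSES = ("connectivity", "synaptic")


def _fixture_data() -> dict:
    ref = importlib.resources.files("bgdcm") / "data" / "fixtures.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


@dataclass
class RegimeFixture:
    """Versioned ground-truth parameter regime."""

    regime: str
    deviations: dict[str, float]
    target_beta_hz: float
    gamma_pole_hz: float
    version: str = FIXTURE_VERSION

    def params(self, circuit: CircuitSpec | None = None) -> ParameterVector:
        circuit = circuit or build_standard_circuit()
        return ParameterVector(circuit, self.deviations)


def make_fixture(regime: str) -> RegimeFixture:
    """Load the calibrated fixture for ``regime`` (control | parkinsonian)."""
    if regime not in REGIMES:
        raise ValueError(f"regime must be one of {REGIMES}")
    data = _fixture_data()
    base = dict(data["base_deviations"] or {})
    over = dict(data["regimes"][regime]["deviations"] or {})
    deviations = {**base, **over}
    meta = data["regimes"][regime]
    return RegimeFixture(
        regime=regime,
        deviations=deviations,
        target_beta_hz=float(meta.get("target_beta_hz", 17.0)),
        gamma_pole_hz=float(meta.get("gamma_pole_hz", 50.0)),
        version=str(data.get("version", FIXTURE_VERSION)),
    )


@dataclass
class SyntheticSubject:
    """One simulated animal: ground-truth parameters around a regime."""

    subject_id: str
    regime: str
    params: ParameterVector
    seed: int
    n_resampled: int = 0
    record: TimeSeriesRecord | None = None
    csd: CrossSpectra | None = None


def _is_stable(params: ParameterVector) -> bool:
    try:
        xs = fixed_point(params.circuit, params)
        J = jacobian_at(xs, params.circuit, params)
    except Exception:
        return False
    return float(np.max(np.linalg.eigvals(J).real)) < 0


def sample_subject(fixture: RegimeFixture, between_sd: float = DEFAULT_BETWEEN_SD,
                   seed: int = 0, circuit: CircuitSpec | None = None,
                   subject_id: str | None = None,
                   max_resample: int = 50) -> SyntheticSubject:
    """Draw one subject: Gaussian log-deviations (SD ``between_sd``) added to
    the regime ground truth on the connectivity and synaptic parameters.
    Unstable draws are resampled (count recorded on the subject)."""
    if between_sd < 0:
        raise ValueError("between_sd must be nonnegative")
    circuit = circuit or build_standard_circuit()
    base = fixture.params(circuit)
    rng = np.random.default_rng(seed)
    variable = [n for n, (_m, cls) in base.table.items() if cls in VARIABLE_CLASSES]
    n_resampled = 0
    for _attempt in range(max_resample + 1):
        pv = base.copy()
        if between_sd > 0:
            noise = rng.normal(0.0, between_sd, size=len(variable))
            for name, d in zip(variable, noise):
                pv[name] = pv[name] + d
        if between_sd == 0 or _is_stable(pv):
            return SyntheticSubject(
                subject_id=subject_id or f"{fixture.regime}_{seed}",
                regime=fixture.regime,
                params=pv,
                seed=seed,
                n_resampled=n_resampled,
            )
        n_resampled += 1
    raise UnstableModelError(
        f"no stable subject found after {max_resample} resamples"
    )


# ---------------------------------------------------------------------------
# Data synthesis
# ---------------------------------------------------------------------------

def simulate_timeseries(subject: SyntheticSubject | ParameterVector,
                        duration: float = 30.0, sampling_rate: float = 250.0,
                        seed: int = 0) -> TimeSeriesRecord:
    """Stationary multichannel series by frequency-domain synthesis.

    Complex Gaussian innovations shaped by the innovation spectra pass
    through the transfer functions; independent cortex/per-BG and a common
    BG channel-noise process are added; the inverse FFT returns the real
    series.  The periodogram is unbiased for the forward CSD by
    construction.
    """
    params = subject.params if isinstance(subject, SyntheticSubject) else subject
    circuit = params.circuit
    n = int(round(duration * sampling_rate))
    if n < 16:
        raise ValueError("duration too short")
    xs = fixed_point(circuit, params)
    J = jacobian_at(xs, circuit, params)
    if float(np.max(np.linalg.eigvals(J).real)) >= 0:
        raise UnstableModelError("subject parameters are unstable")
    B = innovation_matrix(circuit, params)
    Cmat = observation_matrix(circuit, params)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    pos = freqs > 0
    fpos = freqs[pos]
    T = transfer_functions(J, B, Cmat, fpos)  # (C, K, Fpos)
    noise = NoiseSpectrumParams.from_params(params)
    rng = np.random.default_rng(seed)
    n_ch = len(circuit.observed_sources)
    K = len(circuit.innovation_sites)
    nf = len(fpos)

    def cnormal(size):
        return (rng.standard_normal(size) + 1j * rng.standard_normal(size)) / np.sqrt(2.0)

    scale = np.sqrt(sampling_rate * n)
    X = np.zeros((n_ch, len(freqs)), dtype=complex)
    # neuronal innovations
    gu = np.stack([
        noise.u_scales[s] * innovation_spectrum(fpos, noise.u_white, noise.u_pink)
        for s in circuit.innovation_sites
    ])
    w = cnormal((K, nf))
    X[:, pos] = np.einsum("ckf,kf->cf", T, np.sqrt(gu) * w) * scale
    # channel noise
    ctx_idx = [i for i, s in enumerate(circuit.observed_sources) if s == "ctx"]
    bg_idx = [i for i, s in enumerate(circuit.observed_sources) if s != "ctx"]
    s_ctx = np.sqrt(innovation_spectrum(fpos, noise.ctx_white, noise.ctx_pink))
    s_bg = np.sqrt(innovation_spectrum(fpos, noise.bg_white, noise.bg_pink))
    s_bgc = np.sqrt(innovation_spectrum(fpos, noise.bgc_white, noise.bgc_pink))
    for i in ctx_idx:
        X[i, pos] += s_ctx * cnormal(nf) * scale
    for i in bg_idx:
        X[i, pos] += s_bg * cnormal(nf) * scale
    common = s_bgc * cnormal(nf) * scale
    for i in bg_idx:
        X[i, pos] += common
    samples = np.fft.irfft(X, n=n, axis=1).T  # (n, C)
    return TimeSeriesRecord(samples=samples, sampling_rate=sampling_rate,
                            channels=list(circuit.observed_sources))


def sample_csd(subject: SyntheticSubject | ParameterVector, n_segments: int = 60,
               seed: int = 0, grid=None) -> CrossSpectra:
    """Average of ``n_segments`` rank-one complex-Wishart draws around the
    forward CSD; converges to the forward CSD as n_segments grows."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    params = subject.params if isinstance(subject, SyntheticSubject) else subject
    circuit = params.circuit
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    G = predict_csd(params, circuit, grid)
    rng = np.random.default_rng(seed)
    C = G.n_channels
    out = np.zeros_like(G.values)
    for fi in range(len(grid)):
        Gf = G.values[:, :, fi]
        w, V = np.linalg.eigh(0.5 * (Gf + Gf.conj().T))
        w = np.clip(w, 0.0, None)
        L = V * np.sqrt(w)[None, :]
        z = (rng.standard_normal((C, n_segments)) +
             1j * rng.standard_normal((C, n_segments))) / np.sqrt(2.0)
        x = L @ z  # (C, n_segments)
        out[:, :, fi] = (x @ x.conj().T) / n_segments
    out = 0.5 * (out + out.conj().transpose(1, 0, 2))
    return CrossSpectra(grid, out, list(G.channels), G.sampling_rate)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _subject_seed(master_seed: int, index: int, stage: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index), int(stage)])
    return int(ss.generate_state(1)[0] % (2**31))

@dataclass
class CohortBundle:
    subjects: list[SyntheticSubject]
    manifest: dict

    def by_regime(self, regime: str) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.regime == regime]


def make_cohort(n_control: int = 8, n_parkinsonian: int = 9,
                settings: dict | None = None, seed: int = 0,
                outdir: str | Path | None = None) -> CohortBundle:
    """Generate a full synthetic cohort (default 8 control + 9 lesioned).

    ``settings`` keys (all optional): between_sd, duration, sampling_rate,
    n_segments, data ("csd" | "timeseries" | "both").
    """
    if n_control < 1 or n_parkinsonian < 1:
        raise ValueError("need at least one subject per group")
    settings = dict(settings or {})
    between_sd = float(settings.get("between_sd", DEFAULT_BETWEEN_SD))
    duration = float(settings.get("duration", 30.0))
    fs = float(settings.get("sampling_rate", 250.0))
    n_segments = int(settings.get("n_segments", 60))
    data_kind = settings.get("data", "csd")
    circuit = build_standard_circuit()
    subjects: list[SyntheticSubject] = []
    plan = [("control", i) for i in range(n_control)] + \
           [("parkinsonian", i) for i in range(n_parkinsonian)]
    for idx, (regime, i) in enumerate(plan):
        fixture = make_fixture(regime)
        s_seed = _subject_seed(seed, idx, 0)
        subj = sample_subject(fixture, between_sd=between_sd, seed=s_seed,
                              circuit=circuit, subject_id=f"{regime}_{i:02d}")
        d_seed = _subject_seed(seed, idx, 1)
        if data_kind in ("csd", "both"):
            subj.csd = sample_csd(subj, n_segments=n_segments, seed=d_seed)
        if data_kind in ("timeseries", "both"):
            subj.record = simulate_timeseries(subj, duration=duration,
                                              sampling_rate=fs, seed=d_seed)
        subjects.append(subj)
    manifest = {
        "version": FIXTURE_VERSION,
        "seed": int(seed),
        "n_control": n_control,
        "n_parkinsonian": n_parkinsonian,
        "settings": {
            "between_sd": between_sd,
            "duration": duration,
            "sampling_rate": fs,
            "n_segments": n_segments,
            "data": data_kind,
        },
        "subjects": [
            {
                "id": s.subject_id,
                "regime": s.regime,
                "seed": s.seed,
                "data_seed": _subject_seed(seed, idx, 1),
                "n_resampled": s.n_resampled,
            }
            for idx, s in enumerate(subjects)
        ],
    }
    bundle = CohortBundle(subjects=subjects, manifest=manifest)
    if outdir is not None:
        from . import io as _io

        _io.write_cohort(bundle, outdir)
    return bundle
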