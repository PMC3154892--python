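"""Group-level inference and the contribution (sensitivity) analysis.

Per-subject Gaussian posteriors are combined by Bayesian parameter
averaging (precision weighting); differences between group posteriors are
assessed as Gaussian tail probabilities with a 99.99% decision threshold.
The contribution analysis differentiates band-limited neuronal power
(the beta peak summed over 16-18 Hz, channel noise omitted, averaged over
the four recorded channels) with respect to each extrinsic log-connection,
and the cohort of per-subject derivatives is summarised by a one-way ANOVA
over connections plus Bonferroni-corrected one-sample t tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import CircuitSpec, ParameterVector
from .inversion import Posterior
from .spectra import default_grid, extended_grid, predict_csd

BETA_BAND = (16.0, 18.0)
GAMMA_BAND = (59.0, 61.0)
FD_STEP = 1e-3  # central-difference step on the log scale
PROB_THRESHOLD = 0.9999
N_COMPARISONS = 9  # Bonferroni family: the extrinsic connections


# ---------------------------------------------------------------------------
# Bayesian parameter averaging
# ---------------------------------------------------------------------------

@dataclass
class GroupPosterior:
    """Precision-weighted group posterior over log-scale parameters."""

    names: list[str]
    mean: np.ndarray
    cov: np.ndarray
    n_subjects: int

    def marginal(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.mean[i]), float(math.sqrt(max(self.cov[i, i], 0.0)))

    def credible_interval(self, name: str, z: float = 1.96) -> tuple[float, float]:
        m, s = self.marginal(name)
        return (m - z * s, m + z * s)


def bayesian_parameter_average(posteriors: list[Posterior | GroupPosterior],
                               jitter: float = 1e-12) -> GroupPosterior:
    """Sigma_g = (sum_i Sigma_i^-1)^-1; mu_g = Sigma_g sum_i Sigma_i^-1 mu_i."""
    if not posteriors:
        raise ValueError("need at least one posterior")
    names = list(posteriors[0].names)
    p = len(names)
    prec_sum = np.zeros((p, p))
    weighted = np.zeros(p)
    for post in posteriors:
        if list(post.names) != names:
            raise ValueError("posteriors have mismatched parameter names")
        cov = np.asarray(post.cov, dtype=float)
        try:
            prec = np.linalg.inv(cov + jitter * np.eye(p))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError("singular subject covariance") from e
        prec_sum += prec
        weighted += prec @ np.asarray(post.mean, dtype=float)
    cov_g = np.linalg.inv(prec_sum)
    cov_g = 0.5 * (cov_g + cov_g.T)
    mean_g = cov_g @ weighted
    n = sum(getattr(post, "n_subjects", 1) for post in posteriors)
    return GroupPosterior(names=names, mean=mean_g, cov=cov_g, n_subjects=n)


def prob_difference(group_a: GroupPosterior, group_b: GroupPosterior,
                    name: str) -> float:
    """P(theta_A > theta_B) under independent Gaussian marginals:
    Phi((mu_A - mu_B) / sqrt(s_A^2 + s_B^2))."""
    ma, sa = group_a.marginal(name)
    mb, sb = group_b.marginal(name)
    denom = math.sqrt(sa**2 + sb**2)
    if denom == 0:
        return 0.5 if ma == mb else (1.0 if ma > mb else 0.0)
    return float(stats.norm.cdf((ma - mb) / denom))


# ---------------------------------------------------------------------------
# Band power and contributions
# ---------------------------------------------------------------------------

def _band_bins(grid: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    if lo < grid[0] or hi > grid[-1]:
        raise ValueError(f"band {band} outside grid [{grid[0]}, {grid[-1]}]")
    return np.flatnonzero((grid >= lo) & (grid <= hi))


def band_power(params: ParameterVector, band: tuple[float, float] = BETA_BAND,
               grid=None, circuit: CircuitSpec | None = None) -> float:
    """Neuronal auto-spectral power summed over the band bins and averaged
    over the recorded channels; channel noise is omitted."""
    circuit = circuit or params.circuit
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    bins = _band_bins(grid, band)
    cs = predict_csd(params, circuit, grid, include_channel_noise=False)
    auto = cs.auto_spectra()  # (C, F)
    return float(np.mean(np.sum(auto[:, bins], axis=1)))


def contribution(params: ParameterVector, connection: str,
                 band: tuple[float, float] = BETA_BAND, grid=None,
                 circuit: CircuitSpec | None = None,
                 step: float = FD_STEP) -> float:
    """Central finite-difference derivative of band power with respect to
    one extrinsic log-connection strength, at the supplied (posterior-mean)
    parameters."""
    circuit = circuit or params.circuit
    extrinsic = {circuit.connection_param(c) for c in circuit.extrinsic_connections()}
    if connection not in extrinsic:
        raise ValueError(f"{connection!r} is not an extrinsic connection")
    up = params.copy()
    up[connection] = params[connection] + step
    dn = params.copy()
    dn[connection] = params[connection] - step
    return (band_power(up, band, grid, circuit) -
            band_power(dn, band, grid, circuit)) / (2.0 * step)


def gamma_contribution(params: ParameterVector, connection: str,
                       circuit: CircuitSpec | None = None,
                       step: float = FD_STEP) -> float:
    """Contribution derivative for the gamma band centred at 60 Hz
    (59-61 Hz), evaluated on an extended grid."""
    grid = extended_grid(100.0)
    return contribution(params, connection, band=GAMMA_BAND, grid=grid,
                        circuit=circuit, step=step)


def perturbed_spectrum(params: ParameterVector, connection: str, scale: float,
                       grid=None, circuit: CircuitSpec | None = None) -> np.ndarray:
    """Channel-averaged neuronal auto-spectrum with one extrinsic connection
    multiplied by (1 + scale); raises if the scaled system is unstable."""
    circuit = circuit or params.circuit
    extrinsic = {circuit.connection_param(c) for c in circuit.extrinsic_connections()}
    if connection not in extrinsic:
        raise ValueError(f"{connection!r} is not an extrinsic connection")
    if scale <= -1.0:
        raise ValueError("scale must exceed -1")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    p = params.copy()
    p[connection] = params[connection] + math.log1p(scale)
    cs = predict_csd(p, circuit, grid, include_channel_noise=False)
    return np.mean(cs.auto_spectra(), axis=0)


# ---------------------------------------------------------------------------
# Cohort summary statistics
# ---------------------------------------------------------------------------

@dataclass
class ContributionTable:
    """subjects x extrinsic-connections matrix of band-power derivatives."""

    values: np.ndarray
    connections: list[str]
    band: tuple[float, float] = BETA_BAND
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.connections):
            raise ValueError("values must be subjects x connections")
        if not self.subject_ids:
            self.subject_ids = [f"s{i}" for i in range(self.values.shape[0])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids,
                            columns=self.connections)


def contribution_table(param_sets: list[ParameterVector],
                       band: tuple[float, float] = BETA_BAND, grid=None,
                       circuit: CircuitSpec | None = None,
                       subject_ids: list[str] | None = None) -> ContributionTable:
    """Per-subject contribution derivatives for every extrinsic connection."""
    circuit = circuit or param_sets[0].circuit
    conns = [circuit.connection_param(c) for c in circuit.extrinsic_connections()]
    rows = [
        [contribution(p, c, band=band, grid=grid, circuit=circuit) for c in conns]
        for p in param_sets
    ]
    return ContributionTable(np.array(rows), conns, band=band,
                             subject_ids=subject_ids or [])


def cohort_stats(table: ContributionTable,
                 n_comparisons: int = N_COMPARISONS) -> dict:
    """One-way ANOVA with connection as a factor (from sums of squares) plus
    per-connection two-sided one-sample t tests against zero with Bonferroni
    correction (adjusted p = min(1, n_comparisons * p))."""
    X = table.values
    n_sub, n_conn = X.shape
    if n_sub < 2:
        raise ValueError("need at least two subjects")
    grand = X.mean()
    col_means = X.mean(axis=0)
    ss_between = n_sub * float(np.sum((col_means - grand) ** 2))
    ss_within = float(np.sum((X - col_means[None, :]) ** 2))
    df_between = n_conn - 1
    df_within = n_sub * n_conn - n_conn
    if ss_within <= 0 or df_within <= 0:
        raise ValueError("degenerate within-group variance")
    F = (ss_between / df_between) / (ss_within / df_within)
    p_anova = float(stats.f.sf(F, df_between, df_within))
    rows = []
    for j, conn in enumerate(table.connections):
        col = X[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate variance for connection {conn}")
        t = col.mean() / (sd / math.sqrt(n_sub))
        p = 2.0 * float(stats.t.sf(abs(t), n_sub - 1))
        rows.append({
            "connection": conn,
            "mean": float(col.mean()),
            "sem": float(sd / math.sqrt(n_sub)),
            "t": float(t),
            "p": p,
            "p_bonferroni": min(1.0, n_comparisons * p),
        })
    return {
        "anova_f": float(F),
        "anova_df": (df_between, df_within),
        "anova_p": p_anova,
        "ttests": pd.DataFrame(rows),
    }
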