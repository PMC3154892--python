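"""Neural mass model of the cortico-basal ganglia-thalamocortical circuit.

The circuit couples six sources: a three-subpopulation cortical column
(glutamatergic spiny stellate cells, glutamatergic pyramidal cells,
GABAergic interneurons), single-population striatum (GABAergic), external
globus pallidus GPe (GABAergic), subthalamic nucleus STN (glutamatergic),
entopeduncular nucleus EPN (GABAergic, hidden) and thalamus (glutamatergic,
hidden).  Each subpopulation is a damped second-order synaptic convolution
(alpha kernel) driven by the sigmoid-transformed, connection-weighted firing
of its afferents; extrinsic connections carry conduction delays.

Units: time in ms, rate constants in ms^-1, voltages in mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

# Sigmoid convention (centred logistic): slope rho and threshold V0 follow
# the conventional neural-mass values; centring puts the fixed point at the
# state-space origin.
SIGMOID_V0 = 6.0  # mV

# Synaptic kernel prior means: excitatory 8 mV / 4 ms, inhibitory 32 mV / 16 ms.
H_EXC, TAU_EXC = 8.0, 4.0
H_INH, TAU_INH = 32.0, 16.0

# Prior-mean conduction delays (ms).
DELAY_INTRINSIC = 2.0
DELAY_EXTRINSIC = 4.0

CIRCUIT_VERSION = "1"


@dataclass(frozen=True)
class SynapticKernelParams:
    """Alpha-kernel parameters: peak amplitude H (mV), rate constant
    kappa (ms^-1) and synaptic sign (+1 excitatory, -1 inhibitory)."""

    H: float
    kappa: float
    sign: int

    def __post_init__(self) -> None:
        if self.H <= 0 or self.kappa <= 0:
            raise ValueError("H and kappa must be positive")
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")


EXC_KERNEL = SynapticKernelParams(H=H_EXC, kappa=1.0 / TAU_EXC, sign=+1)
INH_KERNEL = SynapticKernelParams(H=H_INH, kappa=1.0 / TAU_INH, sign=-1)


@dataclass(frozen=True)
class Subpopulation:
    id: str
    source: str
    kernel: SynapticKernelParams
    sigmoid_slope: float = 0.56  # mV^-1, dimensionless once voltage is scaled

    def __post_init__(self) -> None:
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid_slope must be positive")


@dataclass(frozen=True)
class Connection:
    """Directed coupling between subpopulations.

    ``strength`` is the prior-mean gain (dimensionless multiplier on firing
    rate), ``sign`` the transmitter sign inherited from the source
    population, ``delay`` the conduction delay in ms.
    """

    src: str
    dst: str
    strength: float
    delay: float
    scope: str  # "intrinsic" | "extrinsic"
    sign: int

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("strength must be nonnegative")
        if self.delay < 0:
            raise ValueError("delay must be nonnegative")
        if self.scope not in ("intrinsic", "extrinsic"):
            raise ValueError("scope must be intrinsic or extrinsic")


@dataclass
class CircuitSpec:
    """The six-source circuit graph with its prior-mean parameterisation."""

    subpopulations: list[Subpopulation]
    connections: list[Connection]
    innovation_sites: list[str]
    observed_sources: list[str]
    version: str = CIRCUIT_VERSION

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subpopulations]
        if len(set(ids)) != len(ids):
            raise ValueError("subpopulation ids must be unique")
        by_id = {s.id: s for s in self.subpopulations}
        for c in self.connections:
            if c.src not in by_id or c.dst not in by_id:
                raise ValueError(f"connection {c.src}->{c.dst} references unknown id")
            same_source = by_id[c.src].source == by_id[c.dst].source
            if c.scope == "extrinsic" and same_source:
                raise ValueError("extrinsic connection inside one source")
        for site in self.innovation_sites:
            if site not in by_id:
                raise ValueError(f"unknown innovation site {site}")

    # -- indexing helpers ---------------------------------------------------
    @property
    def n_subpop(self) -> int:
        return len(self.subpopulations)

    @property
    def n_states(self) -> int:
        return 2 * self.n_subpop

    def subpop_index(self, sid: str) -> int:
        for k, s in enumerate(self.subpopulations):
            if s.id == sid:
                return k
        raise KeyError(sid)

    @property
    def sources(self) -> list[str]:
        seen: list[str] = []
        for s in self.subpopulations:
            if s.source not in seen:
                seen.append(s.source)
        return seen

    def extrinsic_connections(self) -> list[Connection]:
        return [c for c in self.connections if c.scope == "extrinsic"]

    def connection_param(self, c: Connection) -> str:
        if c.scope == "intrinsic":
            return f"g_{c.src}_{c.dst}"
        by_id = {s.id: s for s in self.subpopulations}
        return f"c_{by_id[c.src].source}_{by_id[c.dst].source}"

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "subpopulations": [
                {
                    "id": s.id,
                    "source": s.source,
                    "H": s.kernel.H,
                    "kappa": s.kernel.kappa,
                    "sign": s.kernel.sign,
                    "sigmoid_slope": s.sigmoid_slope,
                }
                for s in self.subpopulations
            ],
            "connections": [
                {
                    "src": c.src,
                    "dst": c.dst,
                    "strength": c.strength,
                    "delay": c.delay,
                    "scope": c.scope,
                    "sign": c.sign,
                }
                for c in self.connections
            ],
            "innovation_sites": list(self.innovation_sites),
            "observed_sources": list(self.observed_sources),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        subs = [
            Subpopulation(
                id=s["id"],
                source=s["source"],
                kernel=SynapticKernelParams(s["H"], s["kappa"], s["sign"]),
                sigmoid_slope=s["sigmoid_slope"],
            )
            for s in d["subpopulations"]
        ]
        conns = [Connection(**c) for c in d["connections"]]
        return cls(
            subpopulations=subs,
            connections=conns,
            innovation_sites=list(d["innovation_sites"]),
            observed_sources=list(d["observed_sources"]),
            version=str(d.get("version", CIRCUIT_VERSION)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CircuitSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Standard circuit
# ---------------------------------------------------------------------------

# Prior-mean coupling gains, expressed through the steady-state link gain
# each connection realises at the fixed point: a unit presynaptic rate
# deviation moves the postsynaptic voltage by (H/kappa)*strength, and a
# voltage deviation moves the rate by S'(0), so the dimensionless link gain
# is (H/kappa)*strength*S'(0).  Normalising the raw strengths by the
# receiver's DC gain keeps every loop product of order one regardless of
# whether the receiver carries the fast excitatory or the slow inhibitory
# kernel.
def _strength_for_link_gain(gain: float, kernel: SynapticKernelParams,
                            rho: float = 0.56, v0: float = SIGMOID_V0) -> float:
    from scipy.special import expit

    s = expit(-rho * v0)
    slope0 = rho * s * (1.0 - s)
    return float(gain / (kernel.H / kernel.kappa * slope0))


# Target link gains (dimensionless); receivers are looked up when the
# circuit is built.
INTRINSIC_LINK_GAINS = {
    ("ctx_py", "ctx_ss"): 0.8,
    ("ctx_ss", "ctx_py"): 0.8,
    ("ctx_py", "ctx_ii"): 0.8,
    ("ctx_ii", "ctx_py"): 0.8,
}
EXTRINSIC_LINK_GAINS = {
    ("ctx", "str"): 0.6,
    ("ctx", "stn"): 0.6,
    ("str", "gpe"): 0.6,
    ("str", "epn"): 0.6,
    ("gpe", "stn"): 0.6,
    ("stn", "gpe"): 0.6,
    ("stn", "epn"): 0.6,
    ("epn", "tha"): 0.6,
    ("tha", "ctx"): 0.6,
}

# Which subpopulation in each source receives extrinsic afferents and which
# emits them.  The cortical source receives thalamic input on the spiny
# stellate cells and projects via the pyramidal cells.
_SOURCE_IN = {"ctx": "ctx_ss", "str": "str", "gpe": "gpe", "stn": "stn", "epn": "epn", "tha": "tha"}
_SOURCE_OUT = {"ctx": "ctx_py", "str": "str", "gpe": "gpe", "stn": "stn", "epn": "epn", "tha": "tha"}


def _subpopulations() -> list[Subpopulation]:
    return [
        Subpopulation("ctx_ss", "ctx", EXC_KERNEL),
        Subpopulation("ctx_py", "ctx", EXC_KERNEL),
        Subpopulation("ctx_ii", "ctx", INH_KERNEL),
        Subpopulation("str", "str", INH_KERNEL),
        Subpopulation("gpe", "gpe", INH_KERNEL),
        Subpopulation("stn", "stn", EXC_KERNEL),
        Subpopulation("epn", "epn", INH_KERNEL),
        Subpopulation("tha", "tha", EXC_KERNEL),
    ]


def build_standard_circuit(gpe_self_inhibition: bool = False) -> CircuitSpec:
    """The standard six-source loop with nine extrinsic connections.

    Extrinsic edges: cortex->striatum, cortex->STN (hyperdirect),
    striatum->GPe (indirect), striatum->EPN (direct), GPe->STN, STN->GPe,
    STN->EPN, EPN->thalamus, thalamus->cortex.  Signs follow the source
    transmitter (pyramidal/STN/thalamus glutamatergic; striatum/GPe/EPN
    GABAergic).  EPN and thalamus are hidden (no recording channel).
    """
    subs = _subpopulations()
    sign_of = {s.id: s.kernel.sign for s in subs}
    kernel_of = {s.id: s.kernel for s in subs}
    conns: list[Connection] = []
    for (src, dst), g in INTRINSIC_LINK_GAINS.items():
        w = _strength_for_link_gain(g, kernel_of[dst])
        conns.append(Connection(src, dst, w, DELAY_INTRINSIC, "intrinsic", sign_of[src]))
    for (src, dst), g in EXTRINSIC_LINK_GAINS.items():
        s, d = _SOURCE_OUT[src], _SOURCE_IN[dst]
        w = _strength_for_link_gain(g, kernel_of[d])
        conns.append(Connection(s, d, w, DELAY_EXTRINSIC, "extrinsic", sign_of[s]))
    if gpe_self_inhibition:
        conns.append(Connection("gpe", "gpe",
                                _strength_for_link_gain(0.3, kernel_of["gpe"]),
                                DELAY_INTRINSIC, "intrinsic", -1))
    return CircuitSpec(
        subpopulations=subs,
        connections=conns,
        innovation_sites=["ctx_ss", "str", "gpe", "stn", "tha"],
        observed_sources=["ctx", "str", "gpe", "stn"],
    )


VARIANTS = {"gpe_to_epn": ("gpe", "epn"), "gpe_to_striatum": ("gpe", "str")}


def build_variant_circuit(variant: str) -> CircuitSpec:
    """Standard circuit plus one pallidofugal (GPe-efferent, GABAergic)
    connection: GPe->EPN or GPe->striatum."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    base = build_standard_circuit()
    src, dst = VARIANTS[variant]
    kernel_of = {s.id: s.kernel for s in base.subpopulations}
    extra = Connection(
        _SOURCE_OUT[src], _SOURCE_IN[dst],
        _strength_for_link_gain(0.6, kernel_of[_SOURCE_IN[dst]]),
        DELAY_EXTRINSIC, "extrinsic", -1,
    )
    return CircuitSpec(
        subpopulations=base.subpopulations,
        connections=base.connections + [extra],
        innovation_sites=base.innovation_sites,
        observed_sources=base.observed_sources,
    )


# ---------------------------------------------------------------------------
# Sigmoid and kernels
# ---------------------------------------------------------------------------

def sigmoid_rate(v, slope: float, v0: float = SIGMOID_V0):
    """Centred logistic firing-rate function: S(v) = sig(slope*(v - v0)) -
    sig(-slope*v0).  Monotone, bounded, and S(0) = 0 so the origin is a
    fixed point of the noise-free dynamics."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    from scipy.special import expit

    return expit(slope * (np.asarray(v, dtype=float) - v0)) - expit(-slope * v0)


def sigmoid_slope_at(v, slope: float, v0: float = SIGMOID_V0):
    """Analytic derivative dS/dv of :func:`sigmoid_rate`."""
    from scipy.special import expit

    s = expit(slope * (np.asarray(v, dtype=float) - v0))
    return slope * s * (1.0 - s)


def synaptic_kernel(params: SynapticKernelParams, t):
    """Alpha-function impulse response sign*H*kappa*t*exp(-kappa*t) (mV);
    peaks at t = 1/kappa."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    return params.sign * params.H * params.kappa * t * np.exp(-params.kappa * t)


# ---------------------------------------------------------------------------
# Parameter vector and physical parameterisation
# ---------------------------------------------------------------------------

# Prior variances per class.  Connectivity priors are deliberately flat
# (+-2 SD spans one order of magnitude); synaptic priors are tighter
# (+-2 SD spans a factor of four); delays and gains tighter still.
PRIOR_VARIANCES = {
    "connectivity": (math.log(10.0) / 4.0) ** 2,
    "synaptic": (math.log(4.0) / 4.0) ** 2,
    "noise": 0.5,
    "gain": 1.0 / 16.0,
    "delay": 1.0 / 16.0,
}

# Prior-mean physical values of the global (non-graph) parameters.
GLOBAL_PRIOR_MEANS = {
    "rho": 0.56,
    "u_white": 0.05,
    "u_pink": 0.5,
    "n_ctx_white": 0.002,
    "n_ctx_pink": 0.02,
    "n_bg_white": 0.002,
    "n_bg_pink": 0.02,
    "n_bgc_white": 0.001,
    "n_bgc_pink": 0.01,
}


def parameter_table(circuit: CircuitSpec) -> dict[str, tuple[float, str]]:
    """Ordered map name -> (prior-mean physical value, prior class) for every
    free parameter of the model attached to ``circuit``.

    All parameters are positive scale parameters; the free coordinates are
    log deviations from these prior means.
    """
    tab: dict[str, tuple[float, str]] = {}
    for s in circuit.subpopulations:
        tab[f"H_{s.id}"] = (s.kernel.H, "synaptic")
    for s in circuit.subpopulations:
        tab[f"kappa_{s.id}"] = (s.kernel.kappa, "synaptic")
    tab["rho"] = (GLOBAL_PRIOR_MEANS["rho"], "synaptic")
    seen = set()
    for c in circuit.connections:
        name = circuit.connection_param(c)
        if name in seen:
            raise ValueError(f"duplicate connection parameter {name}")
        seen.add(name)
        tab[name] = (c.strength, "connectivity")
    tab["delay_intrinsic"] = (1.0, "delay")
    tab["delay_extrinsic"] = (1.0, "delay")
    tab["u_white"] = (GLOBAL_PRIOR_MEANS["u_white"], "noise")
    tab["u_pink"] = (GLOBAL_PRIOR_MEANS["u_pink"], "noise")
    for site in circuit.innovation_sites:
        tab[f"u_scale_{site}"] = (1.0, "noise")
    for key in ("n_ctx_white", "n_ctx_pink", "n_bg_white", "n_bg_pink",
                "n_bgc_white", "n_bgc_pink"):
        tab[key] = (GLOBAL_PRIOR_MEANS[key], "noise")
    for src in circuit.observed_sources:
        tab[f"gain_{src}"] = (1.0, "gain")
    return tab


class ParameterVector:
    """Named log-scale deviations from the prior means of a circuit.

    ``pv["c_ctx_stn"]`` is the log multiplier on the prior-mean hyperdirect
    gain; ``pv.physical("c_ctx_stn")`` the resulting physical value.
    """

    def __init__(self, circuit: CircuitSpec, values: dict[str, float] | None = None):
        self.circuit = circuit
        self.table = parameter_table(circuit)
        self._dev = {name: 0.0 for name in self.table}
        if values:
            for k, v in values.items():
                self[k] = v

    @property
    def names(self) -> list[str]:
        return list(self.table)

    def __getitem__(self, name: str) -> float:
        return self._dev[name]

    def __setitem__(self, name: str, value: float) -> None:
        if name not in self._dev:
            raise KeyError(name)
        self._dev[name] = float(value)

    def __contains__(self, name: str) -> bool:
        return name in self._dev

    def physical(self, name: str) -> float:
        mean, _cls = self.table[name]
        return mean * math.exp(self._dev[name])

    def as_array(self) -> np.ndarray:
        return np.array([self._dev[n] for n in self.table], dtype=float)

    @classmethod
    def from_array(cls, circuit: CircuitSpec, arr) -> "ParameterVector":
        pv = cls(circuit)
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(pv.table),):
            raise ValueError("array length does not match parameter table")
        for n, v in zip(pv.table, arr):
            pv._dev[n] = float(v)
        return pv

    def copy(self) -> "ParameterVector":
        pv = ParameterVector(self.circuit)
        pv._dev = dict(self._dev)
        return pv

    def updated(self, values: dict[str, float]) -> "ParameterVector":
        pv = self.copy()
        for k, v in values.items():
            pv[k] = v
        return pv

    def to_dict(self) -> dict[str, float]:
        return dict(self._dev)


# ---------------------------------------------------------------------------
# Dynamics, fixed point and Jacobian
# ---------------------------------------------------------------------------

def _physical_graph(circuit: CircuitSpec, params: ParameterVector):
    """Resolve kernel, connectivity and delay arrays at the physical values
    implied by ``params``."""
    n = circuit.n_subpop
    H = np.empty(n)
    kappa = np.empty(n)
    for j, s in enumerate(circuit.subpopulations):
        H[j] = params.physical(f"H_{s.id}")
        kappa[j] = params.physical(f"kappa_{s.id}")
    rho = params.physical("rho")
    W = np.zeros((n, n))  # signed gain from subpop l -> subpop j
    D = np.zeros((n, n))  # delay (ms) on that edge
    d_int = params.physical("delay_intrinsic")
    d_ext = params.physical("delay_extrinsic")
    for c in circuit.connections:
        j = circuit.subpop_index(c.dst)
        l = circuit.subpop_index(c.src)
        W[j, l] += c.sign * params.physical(circuit.connection_param(c))
        scale = d_int if c.scope == "intrinsic" else d_ext
        D[j, l] = c.delay * scale
    return H, kappa, rho, W, D


def state_derivative(state, circuit: CircuitSpec, params: ParameterVector,
                     inputs=None) -> np.ndarray:
    """Flow f(x, u): dv/dt = i; di/dt = kappa*H*u - 2*kappa*i - kappa^2*v,
    with presynaptic drive u = sum of signed, weighted sigmoid rates of
    afferents plus innovations at the innovation sites.  Delays are ignored
    here (they enter the linearised model); this flow defines the fixed
    point and the instantaneous Jacobian."""
    x = np.asarray(state, dtype=float)
    if x.shape != (circuit.n_states,):
        raise ValueError(f"state must have length {circuit.n_states}")
    H, kappa, rho, W, _D = _physical_graph(circuit, params)
    v = x[0::2]
    cur = x[1::2]
    rates = sigmoid_rate(v, rho)
    drive = W @ rates
    if inputs is not None:
        u = np.asarray(inputs, dtype=float)
        if u.shape != (len(circuit.innovation_sites),):
            raise ValueError("inputs must have one value per innovation site")
        for k, site in enumerate(circuit.innovation_sites):
            drive[circuit.subpop_index(site)] += u[k]
    dx = np.empty_like(x)
    dx[0::2] = cur
    dx[1::2] = kappa * H * drive - 2.0 * kappa * cur - kappa**2 * v
    return dx


class FixedPointError(RuntimeError):
    pass


def fixed_point(circuit: CircuitSpec, params: ParameterVector,
                start=None, tol: float = 1e-9, max_iter: int = 100) -> np.ndarray:
    """Damped-Newton solution of f(x) = 0 from a zero start.

    With the centred sigmoid the origin is an analytic root; the solver
    guards against non-centred configurations.
    """
    x = np.zeros(circuit.n_states) if start is None else np.asarray(start, dtype=float).copy()
    for _ in range(max_iter):
        f = state_derivative(x, circuit, params)
        if np.max(np.abs(f)) < tol:
            return x
        J = jacobian_at(x, circuit, params, delay_correction=False)
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as e:
            raise FixedPointError("singular Jacobian in Newton step") from e
        lam = 1.0
        fn = np.linalg.norm(f)
        while lam > 1e-4:
            xn = x + lam * step
            if np.linalg.norm(state_derivative(xn, circuit, params)) < fn:
                break
            lam *= 0.5
        x = x + lam * step
    f = state_derivative(x, circuit, params)
    if np.max(np.abs(f)) < tol:
        return x
    raise FixedPointError(f"fixed point not found (residual {np.max(np.abs(f)):.3g})")


def jacobian_at(state, circuit: CircuitSpec, params: ParameterVector,
                delay_correction: bool = True) -> np.ndarray:
    """Analytic Jacobian of the flow at ``state``; optionally applies the
    first-order delay correction J_d = (I - D.J)^-1 J, with D the matrix of
    pairwise conduction delays (elementwise product)."""
    x = np.asarray(state, dtype=float)
    n = circuit.n_subpop
    H, kappa, rho, W, D = _physical_graph(circuit, params)
    v = x[0::2]
    sp = sigmoid_slope_at(v, rho)
    J = np.zeros((2 * n, 2 * n))
    for j in range(n):
        J[2 * j, 2 * j + 1] = 1.0
        J[2 * j + 1, 2 * j] += -kappa[j] ** 2
        J[2 * j + 1, 2 * j + 1] = -2.0 * kappa[j]
        for l in range(n):
            if W[j, l] != 0.0:
                J[2 * j + 1, 2 * l] += kappa[j] * H[j] * W[j, l] * sp[l]
    if not delay_correction:
        return J
    Dfull = np.zeros_like(J)
    for j in range(n):
        for l in range(n):
            if D[j, l] != 0.0:
                Dfull[2 * j + 1, 2 * l] = D[j, l]
    A = np.eye(2 * n) - Dfull * J
    try:
        return np.linalg.solve(A, J)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular delay-correction operator") from e


def jacobian(circuit: CircuitSpec, params: ParameterVector,
             delay_correction: bool = True) -> np.ndarray:
    """Delay-corrected Jacobian at the fixed point."""
    xstar = fixed_point(circuit, params)
    return jacobian_at(xstar, circuit, params, delay_correction=delay_correction)


def innovation_matrix(circuit: CircuitSpec, params: ParameterVector) -> np.ndarray:
    """Input matrix B (2N x K) mapping the K innovation processes onto the
    current equations of their target subpopulations, scaled by kappa*H."""
    n = circuit.n_subpop
    H = np.array([params.physical(f"H_{s.id}") for s in circuit.subpopulations])
    kappa = np.array([params.physical(f"kappa_{s.id}") for s in circuit.subpopulations])
    B = np.zeros((2 * n, len(circuit.innovation_sites)))
    for k, site in enumerate(circuit.innovation_sites):
        j = circuit.subpop_index(site)
        B[2 * j + 1, k] = kappa[j] * H[j]
    return B


# Cortical channel mixture over (pyramidal, interneuron, stellate) voltages.
CORTEX_MIX = {"ctx_py": 0.6, "ctx_ii": 0.2, "ctx_ss": 0.2}


def observation_matrix(circuit: CircuitSpec, params: ParameterVector) -> np.ndarray:
    """Observation matrix C (channels x 2N): each recorded source's channel
    reads its population voltage times the electrode gain; the cortical
    channel mixes pyramidal (60%), interneuron (20%) and stellate (20%)
    depolarisations."""
    n = circuit.n_subpop
    C = np.zeros((len(circuit.observed_sources), 2 * n))
    for ch, src in enumerate(circuit.observed_sources):
        gain = params.physical(f"gain_{src}")
        if src == "ctx":
            for sid, w in CORTEX_MIX.items():
                C[ch, 2 * circuit.subpop_index(sid)] = gain * w
        else:
            members = [s.id for s in circuit.subpopulations if s.source == src]
            for sid in members:
                C[ch, 2 * circuit.subpop_index(sid)] = gain
    return C
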