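"""Conductance-based neural-mass model of a multi-region evoked network.

Each region contains four populations — spiny stellate cells (ss),
superficial pyramidal cells (sp), inhibitory interneurons (ii) and deep
pyramidal cells (dp) — with AMPA-, GABA- and NMDA-type channel kinetics.
Per population, the membrane potential obeys

    Cm dV/dt = g_L (V_L - V) + g_ampa (V_E - V) + g_gaba (V_I - V)
             + g_nmda m(V) (V_E - V) + C u(t)

with the voltage-dependent magnesium-block gate
``m(V) = 1 / (1 + 0.2 exp(-a_mg V))`` on the NMDA channel, and each
dimensionless channel conductance relaxes toward its presynaptic drive

    dg_k/dt = kappa_k (sum_pre gamma_pre * sigma(V_pre) - g_k)

where ``sigma`` is a logistic firing-rate function and ``kappa_k`` the
receptor rate constant (inverse of the channel time constant). Intrinsic
excitatory connections (ss->sp, ss->ii, sp->dp, dp->ii) are carried by AMPA
and NMDA, intrinsic inhibition (ii->ss, ii->sp, ii->dp plus the four
inhibitory self-gains) by GABA. Between regions, superficial pyramidal
cells send forward projections to spiny stellate cells, and deep pyramidal
cells send backward projections to superficial pyramidal cells and
inhibitory interneurons, each with separate AMPA and NMDA drive gains.

All tunable quantities are log-scalings of shipped defaults; the observed
evoked response per region is a fixed mixture J of population
depolarizations about the resting state, scaled by a per-region gain.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from ._assemble import (EXC_CONNS, INH_CONNS, POPULATIONS, SimTemplate,
                        conn_name, param_names)
from .network_models import CONDITIONS, NetworkSpec

__all__ = [
    "POPULATIONS",
    "PopulationState",
    "ModelParameters",
    "ERPDataset",
    "firing_rate",
    "nmda_gate",
    "dstates",
    "steady_state",
    "integrate",
    "generate_erp",
    "pack_states",
    "unpack_states",
    "param_names",
]

#: fixed membrane / gating constants and receptor time constants (ms)
DEFAULT_CONSTANTS = {
    "V_L": -70.0, "V_E": 60.0, "V_I": -90.0,
    "V_thr": -40.0, "s": 8.0, "a_mg": 0.06,
    "g_L": 1.0, "Cm": 32.0,
    "tau_ampa": 2.2, "tau_gaba": 5.0, "tau_nmda": 100.0,
}

#: default coupling magnitudes; log-scalings are applied on top of these.
#: Chosen so the default fixed point is stable and the default evoked
#: response peaks within 100-250 ms.
DEFAULT_MAGNITUDES = {
    "g_exc_ss_to_sp": 3.0, "g_exc_ss_to_ii": 1.5,
    "g_exc_sp_to_dp": 1.5, "g_exc_dp_to_ii": 1.0,
    # NMDA-to-AMPA weight ratio on intrinsic excitatory connections;
    # the granular-to-superficial projection is NMDA-dominated so that
    # receptor kinetics shape a pronounced slow response component
    "nmda_ratio": 0.5, "nmda_ratio_ss_to_sp": 8.0,
    "g_inh_ii_to_ss": 3.0, "g_inh_ii_to_sp": 3.0, "g_inh_ii_to_dp": 3.0,
    "g_inh_self_ss": 2.0, "g_inh_self_sp": 3.0,
    "g_inh_self_ii": 1.0, "g_inh_self_dp": 1.0,
    "ext_fwd_ampa": 2.5, "ext_fwd_nmda": 0.25,
    "ext_bwd_ampa": 0.5, "ext_bwd_nmda": 0.12,
    "input_onset": 64.0, "input_width": 16.0, "input_amp": 30.0,
    "obs_gain": 1.0,
}

#: observation mixture over (ss, sp, ii, dp) depolarizations
DEFAULT_J = (0.2, 0.8, 0.0, 0.2)


@dataclass
class PopulationState:
    """State of one population: membrane potential (mV) and conductances."""

    V: float
    g_ampa: float
    g_gaba: float
    g_nmda: float


@dataclass
class ModelParameters:
    """All tunable neural-mass quantities as named log-scalings of defaults.

    ``values`` maps parameter names (see :func:`param_names`) to log-scaling
    coefficients; an absent name means 0 (the shipped default). Treat
    instances as immutable — use :meth:`copy_with` — so that internal
    simulation templates can be cached safely.
    """

    values: dict = field(default_factory=dict)
    constants: dict = field(default_factory=lambda: dict(DEFAULT_CONSTANTS))
    magnitudes: dict = field(default_factory=lambda: dict(DEFAULT_MAGNITUDES))
    j_weights: tuple = DEFAULT_J

    def __post_init__(self):
        self._templates = {}

    @classmethod
    def default(cls, spec: NetworkSpec) -> "ModelParameters":
        return cls(values={n: 0.0 for n in param_names(spec)})

    def copy_with(self, updates: dict) -> "ModelParameters":
        vals = dict(self.values)
        vals.update(updates)
        return dataclasses.replace(self, values=vals)

    def validate(self, spec: NetworkSpec) -> None:
        known = set(param_names(spec))
        unknown = set(self.values) - known
        if unknown:
            raise ValueError(f"parameters not defined for this network: "
                             f"{sorted(unknown)}")
        edge_b = {n for n in known if n.startswith("B:")}
        missing = edge_b - set(self.values)
        if missing:
            raise ValueError(f"missing emotion modulators: {sorted(missing)}")

    def template(self, spec: NetworkSpec, condition: str) -> SimTemplate:
        key = (spec.model_id, spec.forward_edges, condition)
        if key not in self._templates:
            self._templates[key] = SimTemplate(self, spec, condition)
        return self._templates[key]

    def extrinsic_gain(self, edge, spec: NetworkSpec):
        """Base (AMPA, NMDA) extrinsic drive gain for a directed edge."""
        src, dst = edge
        if edge in spec.forward_edges:
            a0, n0 = self.magnitudes["ext_fwd_ampa"], self.magnitudes["ext_fwd_nmda"]
        elif edge in spec.backward_edges:
            a0, n0 = self.magnitudes["ext_bwd_ampa"], self.magnitudes["ext_bwd_nmda"]
        else:
            raise ValueError(f"edge {edge} not part of the network")
        a = a0 * np.exp(self.values.get(f"A_ampa:{src}->{dst}", 0.0))
        n = n0 * np.exp(self.values.get(f"A_nmda:{src}->{dst}", 0.0))
        return a, n


# ---------------------------------------------------------------------------
# state packing

def pack_states(states) -> np.ndarray:
    """Pack nested [region][population] PopulationState into a StateVector.

    Ordering: region-major, populations (ss, sp, ii, dp), fields
    (V, g_ampa, g_gaba, g_nmda) — 16 numbers per region.
    """
    out = []
    for reg in states:
        if len(reg) != 4:
            raise ValueError("exactly four populations per region")
        for p in reg:
            out += [p.V, p.g_ampa, p.g_gaba, p.g_nmda]
    x = np.asarray(out, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite state")
    return x


def unpack_states(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    if x.size % 16:
        raise ValueError(f"state vector length {x.size} is not 16 * n_regions")
    out = []
    for r in range(x.size // 16):
        reg = []
        for p in range(4):
            i = 16 * r + 4 * p
            reg.append(PopulationState(x[i], x[i + 1], x[i + 2], x[i + 3]))
        out.append(reg)
    return out


def _to_kernel(x: np.ndarray, nr: int) -> np.ndarray:
    """Public region-major layout -> kernel channel-major layout."""
    x4 = x.reshape(nr * 4, 4)  # (pop, field)
    return x4.T.reshape(-1).copy()


def _from_kernel(X: np.ndarray, nr: int) -> np.ndarray:
    x4 = X.reshape(4, nr * 4).T
    return x4.reshape(-1).copy()


# ---------------------------------------------------------------------------
# elementary nonlinearities

def firing_rate(V, params: ModelParameters):
    """Logistic firing rate sigma(V) = 1 / (1 + exp(-(V - V_thr) / s))."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    k = params.constants
    out = 1.0 / (1.0 + np.exp(-(V - k["V_thr"]) / k["s"]))
    return float(out) if out.ndim == 0 else out


def nmda_gate(V, a_mg: float):
    """Voltage-dependent magnesium-block gate m(V) = 1/(1 + 0.2 exp(-a_mg V))."""
    if a_mg <= 0:
        raise ValueError(f"a_mg must be > 0, got {a_mg}")
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + 0.2 * np.exp(-a_mg * V))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# dynamics

def _dense_mats(params: ModelParameters, spec: NetworkSpec, condition: str):
    tpl = params.template(spec, condition)
    arr = tpl.materialize(tpl.values_matrix(params))
    n = 4 * len(spec.regions)
    mats = {}
    for ch, (rows, cols) in (("A", (tpl.rowsA, tpl.colsA)),
                             ("G", (tpl.rowsG, tpl.colsG)),
                             ("N", (tpl.rowsN, tpl.colsN))):
        M = np.zeros((n, n))
        np.add.at(M, (rows, cols), arr["w" + ch][0])
        mats[ch] = M
    return tpl, arr, mats


def dstates(t, x, params: ModelParameters, spec: NetworkSpec, u,
            condition: str = "angry") -> np.ndarray:
    """Time derivative of the packed state vector (reference implementation)."""
    nr = len(spec.regions)
    x = np.asarray(x, dtype=float)
    if x.size != 16 * nr:
        raise ValueError(f"state vector length {x.size} != {16 * nr}")
    tpl, arr, mats = _dense_mats(params, spec, condition)
    X = _to_kernel(x, nr)
    n = 4 * nr
    V, ga, gg, gn = X[:n], X[n:2 * n], X[2 * n:3 * n], X[3 * n:]
    k = params.constants
    sig = firing_rate(V, params)
    m = nmda_gate(V, k["a_mg"])
    dV = (k["g_L"] * (k["V_L"] - V) + ga * (k["V_E"] - V)
          + gg * (k["V_I"] - V) + gn * m * (k["V_E"] - V)
          + tpl.cmask * float(u)) / k["Cm"]
    dga = arr["kapA"][0] * (mats["A"] @ sig - ga)
    dgg = arr["kapG"][0] * (mats["G"] @ sig - gg)
    dgn = arr["kapN"][0] * (mats["N"] @ sig - gn)
    return _from_kernel(np.concatenate([dV, dga, dgg, dgn]), nr)


def _fixed_point_kernel(tpl, arr, tol, maxiter=100):
    """Batched fixed point: damped Newton with a settle-and-retry fallback.

    Elements whose Newton solve stalls are integrated input-free for 3 s
    (so transients decay toward the attractor) and re-solved from there.
    """
    k = tpl.consts
    B = arr["wA"].shape[0]

    def newton(Vinit):
        return _kernels.fixed_point(
            arr["wA"], arr["wG"], arr["wN"], tpl.rowsA, tpl.colsA,
            tpl.rowsG, tpl.colsG, tpl.rowsN, tpl.colsN,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6],
            Vinit, tol, maxiter)

    Xeq, resid = newton(np.full((B, 16), k[0]))
    bad = resid > tol
    if np.any(bad):
        idx = np.flatnonzero(bad)
        sub = {n: arr[n][idx] for n in ("wA", "wG", "wN", "kapA", "kapG",
                                        "kapN", "obsg")}
        zero = np.zeros(idx.size)
        _, _, Xf = _kernels.rk4_run(
            Xeq[idx], tpl.rowsA, tpl.colsA, sub["wA"], tpl.rowsG, tpl.colsG,
            sub["wG"], tpl.rowsN, tpl.colsN, sub["wN"],
            sub["kapA"], sub["kapG"], sub["kapN"], tpl.cmask,
            zero + 1.0, zero + 1.0, zero,  # amp = 0: no input
            0.0, 1.0, 3000,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7],
            tpl.jw, sub["obsg"], Xeq[idx, :16].copy(), False)
        sub_arr = dict(sub)
        Xeq2, resid2 = _kernels.fixed_point(
            sub_arr["wA"], sub_arr["wG"], sub_arr["wN"], tpl.rowsA, tpl.colsA,
            tpl.rowsG, tpl.colsG, tpl.rowsN, tpl.colsN,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6],
            Xf[:, :16].copy(), tol, maxiter)
        Xeq[idx] = Xeq2
        resid[idx] = resid2
    return Xeq, resid


def steady_state(params: ModelParameters, spec: NetworkSpec,
                 condition: str = "angry", tol: float = 1e-8) -> np.ndarray:
    """Deterministic fixed point of the zero-input dynamics.

    The returned state satisfies ``max |dstates| < tol``; raises if the
    damped Newton solve does not reach that residual.
    """
    tpl = params.template(spec, condition)
    arr = tpl.materialize(tpl.values_matrix(params))
    cm = params.constants["Cm"]
    Xeq, resid = _fixed_point_kernel(tpl, arr, tol * cm * 0.5)
    if resid[0] > tol * cm:
        dx = dstates(0.0, _from_kernel(Xeq[0], len(spec.regions)), params,
                     spec, 0.0, condition)
        worst = int(np.argmax(np.abs(dx)))
        raise RuntimeError(
            f"fixed-point solve did not converge; worst residual "
            f"{np.abs(dx).max():.3e} at state index {worst}")
    return _from_kernel(Xeq[0], len(spec.regions))


def _check_tgrid(t_grid):
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("t_grid must be a 1-D array of at least 2 times")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("t_grid must be uniformly spaced for RK4")
    return t, float(dt[0])


def integrate(params: ModelParameters, spec: NetworkSpec, input_fn=None,
              t_grid=None, condition: str = "angry") -> np.ndarray:
    """Integrate the network with fixed-step RK4 from its steady state.

    ``t_grid`` is a uniformly spaced time axis in ms (default -100..1000 at
    1 ms). When ``input_fn`` is None the parameterized Gaussian input bump
    is used (fast compiled path); otherwise ``input_fn(t)`` supplies the
    drive and a pure-python RK4 over :func:`dstates` is used.
    Returns the (n_t, 16 * n_regions) state trajectory.
    """
    if t_grid is None:
        t_grid = np.arange(-100.0, 1000.0 + 0.5, 1.0)
    t, dt = _check_tgrid(t_grid)
    nr = len(spec.regions)
    x0 = steady_state(params, spec, condition)
    if input_fn is None:
        tpl = params.template(spec, condition)
        arr = tpl.materialize(tpl.values_matrix(params))
        k = tpl.consts
        X0 = _to_kernel(x0, nr)[None, :]
        _, traj, _ = _kernels.rk4_run(
            X0, tpl.rowsA, tpl.colsA, arr["wA"], tpl.rowsG, tpl.colsG,
            arr["wG"], tpl.rowsN, tpl.colsN, arr["wN"],
            arr["kapA"], arr["kapG"], arr["kapN"], tpl.cmask,
            arr["onset"], arr["width"], arr["amp"],
            t[0], dt, t.size - 1,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7],
            tpl.jw, arr["obsg"], X0[:, :16].copy(), True)
        out = np.empty((t.size, 16 * nr))
        for i in range(t.size):
            out[i] = _from_kernel(traj[0, i], nr)
    else:
        out = np.empty((t.size, 16 * nr))
        out[0] = x0
        x = x0
        for i in range(t.size - 1):
            ti = t[i]
            k1 = dstates(ti, x, params, spec, input_fn(ti), condition)
            k2 = dstates(ti + dt / 2, x + dt / 2 * k1, params, spec,
                         input_fn(ti + dt / 2), condition)
            k3 = dstates(ti + dt / 2, x + dt / 2 * k2, params, spec,
                         input_fn(ti + dt / 2), condition)
            k4 = dstates(ti + dt, x + dt * k3, params, spec,
                         input_fn(ti + dt), condition)
            x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            out[i + 1] = x
    if not np.all(np.isfinite(out)):
        raise RuntimeError("trajectory diverged (non-finite states); "
                           "reduce parameter scalings")
    return out


def observe(params: ModelParameters, spec: NetworkSpec, traj: np.ndarray,
            x0: np.ndarray) -> np.ndarray:
    """Project a state trajectory to the observed per-region signal."""
    nr = len(spec.regions)
    j = np.asarray(params.j_weights)
    V = traj.reshape(traj.shape[0], nr, 4, 4)[:, :, :, 0]
    V0 = np.asarray(x0).reshape(nr, 4, 4)[:, :, 0]
    dep = V - V0[None]
    gains = np.array([
        params.magnitudes["obs_gain"]
        * np.exp(params.values.get(f"obs_gain:{r}", 0.0))
        for r in spec.regions])
    return np.einsum("trp,p->rt", dep, j) * gains[:, None]


# ---------------------------------------------------------------------------
# evoked-response dataset container

@dataclass
class ERPDataset:
    """Evoked responses: cells x regions x time with cell metadata.

    ``index`` carries one row per cell with columns subject_id, group,
    session, condition; ``amplitudes`` has shape (n_cells, n_regions, n_t).
    """

    amplitudes: np.ndarray
    index: pd.DataFrame
    regions: tuple
    times_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a = np.asarray(self.amplitudes, dtype=float)
        if a.ndim != 3 or a.shape[0] != len(self.index):
            raise ValueError("amplitudes must be (n_cells, n_regions, n_t) "
                             "matching the index")
        if a.shape[1] != len(self.regions) or a.shape[2] != len(self.times_ms):
            raise ValueError("amplitudes shape does not match regions/times")
        self.amplitudes = a

    @property
    def dt_ms(self) -> float:
        return float(np.diff(self.times_ms)[0])

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, meta in self.index.reset_index(drop=True).iterrows():
            for r, region in enumerate(self.regions):
                df = pd.DataFrame({
                    "time_ms": self.times_ms,
                    "amplitude": self.amplitudes[i, r],
                })
                for c in ("subject_id", "group", "session", "condition"):
                    df[c] = meta.get(c, "")
                df["region"] = region
                rows.append(df)
        cols = ["subject_id", "group", "session", "condition", "region",
                "time_ms", "amplitude"]
        return pd.concat(rows, ignore_index=True)[cols]

    def select(self, **match) -> "ERPDataset":
        mask = np.ones(len(self.index), dtype=bool)
        for k, v in match.items():
            mask &= (self.index[k] == v).to_numpy()
        return ERPDataset(self.amplitudes[mask],
                          self.index[mask].reset_index(drop=True),
                          self.regions, self.times_ms, dict(self.meta))

    def window(self, t0: float, t1: float) -> "ERPDataset":
        m = (self.times_ms >= t0) & (self.times_ms <= t1)
        return ERPDataset(self.amplitudes[:, :, m], self.index.copy(),
                          self.regions, self.times_ms[m], dict(self.meta))


def predict_erp(params: ModelParameters, spec: NetworkSpec, conditions,
                t_grid) -> np.ndarray:
    """Noiseless observed responses, shape (n_conditions, n_regions, n_t)."""
    t, dt = _check_tgrid(t_grid)
    nr = len(spec.regions)
    out = np.empty((len(conditions), nr, t.size))
    for ci, cond in enumerate(conditions):
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}")
        tpl = params.template(spec, cond)
        arr = tpl.materialize(tpl.values_matrix(params))
        k = tpl.consts
        cm = params.constants["Cm"]
        Xeq, resid = _fixed_point_kernel(tpl, arr, 1e-8 * cm * 0.5)
        y, _, _ = _kernels.rk4_run(
            Xeq, tpl.rowsA, tpl.colsA, arr["wA"], tpl.rowsG, tpl.colsG,
            arr["wG"], tpl.rowsN, tpl.colsN, arr["wN"],
            arr["kapA"], arr["kapG"], arr["kapN"], tpl.cmask,
            arr["onset"], arr["width"], arr["amp"],
            t[0], dt, t.size - 1,
            k[0], k[1], k[2], k[3], k[4], k[5], k[6], k[7],
            tpl.jw, arr["obsg"], Xeq[:, :16].copy(), False)
        out[ci] = y[0]
    return out


def generate_erp(params: ModelParameters, spec: NetworkSpec, conditions,
                 t_grid, noise_sd: float, seed, subject_id: str = "sim",
                 group: str = "", session: str = "") -> ERPDataset:
    """Simulate one subject-session evoked dataset with additive noise.

    The happy condition applies exp(B) to every extrinsic connection; angry
    is the reference. Observation noise is i.i.d. Gaussian per sample.
    """
    conditions = tuple(conditions)
    signal = predict_erp(params, spec, conditions, t_grid)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    t, _ = _check_tgrid(t_grid)
    index = pd.DataFrame({
        "subject_id": subject_id, "group": group, "session": session,
        "condition": list(conditions)})
    return ERPDataset(signal, index, tuple(spec.regions), t,
                      meta={"noise_sd": noise_sd, "seed": seed})
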