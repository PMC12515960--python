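"""Firing-rate dynamics of the microcircuit.

Pyramidal cells are two-compartment units: the somatic activation h^E obeys

    tau_E dh/dt = -h + (I - Theta),        r = [h]_+

with total somatic current

    I = (1 - lambda_E) I^syn_E + sum_k lambda_D [I^syn_Dk + c_k]_+

where c_k is a threshold-triggered dendritic calcium event of amplitude
c_amp, fired when the within-dendrite input I0 = lambda_E I^syn_E +
(1 - lambda_D) I^syn_Dk strictly exceeds theta_c.  Interneurons are point
units without a rheobase.  Only rates are rectified; activations may go
negative.

Steady states can be obtained by explicit Euler integration over the phase
duration (``method='euler'``) or by damped fixed-point relaxation
(``method='relax'``), which converges to the same fixed point and is used in
the training loop.  The update order within a step is fixed: synaptic
currents, then calcium, then activations, then rectification, so runs are
bit-reproducible for a given seed and dt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._numerics import relu
from .connectivity import Connectivity
from .params import ModelParams
from .stimuli import PhaseInputs, StimulusPhase, TuningBank, phase_inputs


@dataclass
class NetworkState:
    """Activation variables and rectified rates for all populations."""

    h_e: np.ndarray
    h_p: np.ndarray
    h_s: np.ndarray
    h_v: np.ndarray

    @property
    def r_e(self) -> np.ndarray:
        return relu(self.h_e)

    @property
    def r_p(self) -> np.ndarray:
        return relu(self.h_p)

    @property
    def r_s(self) -> np.ndarray:
        return relu(self.h_s)

    @property
    def r_v(self) -> np.ndarray:
        return relu(self.h_v)

    @classmethod
    def zeros(cls, conn: Connectivity) -> "NetworkState":
        pop = conn.pop
        return cls(
            h_e=np.zeros(pop.n_pc),
            h_p=np.zeros(pop.n_pv),
            h_s=np.zeros(pop.n_som),
            h_v=np.zeros(pop.n_vip),
        )


@dataclass
class SteadyState:
    """Converged rates plus the per-compartment currents behind them."""

    r_e: np.ndarray
    r_p: np.ndarray
    r_s: np.ndarray
    r_v: np.ndarray
    i_e_syn: np.ndarray  # somatic synaptic current, (n_pc,)
    i_d_syn: np.ndarray  # dendritic synaptic currents, (n_dendrites, n_pc)
    calcium: np.ndarray  # calcium event per branch, (n_dendrites, n_pc)
    converged: bool
    residual: float
    inputs: PhaseInputs
    state: "NetworkState | None" = None  # final activations (warm-start reuse)

    @property
    def dendritic_activity(self) -> np.ndarray:
        """A^Dk = I^syn_Dk + c_k, the plasticity-relevant dendritic activity."""
        return self.i_d_syn + self.calcium

    def rates_martinotti(self, conn: Connectivity) -> np.ndarray:
        return self.r_s[conn.pop.martinotti_mask]

    def rates_nonmartinotti(self, conn: Connectivity) -> np.ndarray:
        return self.r_s[~conn.pop.martinotti_mask]


def somatic_synaptic_input(
    conn: Connectivity, r_e: np.ndarray, r_p: np.ndarray, r_nm: np.ndarray,
    x_e: np.ndarray,
) -> np.ndarray:
    """I^syn_E = x^E + W^EE r^E - W^EP r^P - W^EnM r^nM (no self-connections)."""
    w = conn.weights
    if r_e.shape[0] != w["EE"].shape[1]:
        raise ValueError("rate vector does not match connectivity size")
    return x_e + w["EE"] @ r_e - w["EP"] @ r_p - w["EnM"] @ r_nm


def dendritic_synaptic_input(
    conn: Connectivity, branch: int, r_e: np.ndarray, r_m: np.ndarray,
    x_d: np.ndarray,
) -> np.ndarray:
    """I^syn_Dk = x^Dk + W^DkE r^E - W^DkM r^M for branch k (0-based)."""
    if not 0 <= branch < conn.pop.n_dendrites:
        raise ValueError(f"invalid branch index {branch}")
    w = conn.weights
    key = f"D{branch + 1}"
    return x_d + w[key + "E"] @ r_e - w[key + "M"] @ r_m


def dendritic_calcium(i0: np.ndarray, params: ModelParams) -> np.ndarray:
    """Calcium event current: c_amp where I0 strictly exceeds theta_c.

    The Heaviside convention at threshold is H(0) = 0: the input must
    strictly exceed the threshold to trigger an event.
    """
    return np.where(i0 > params.theta_c, params.c_amp, 0.0)


def total_somatic_current(
    i_e_syn: np.ndarray,
    i_d_syn: np.ndarray,
    calcium: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """I = (1 - lambda_E) I^syn_E + sum_k lambda_D [I^syn_Dk + c_k]_+."""
    dend = params.lambda_d * relu(i_d_syn + calcium).sum(axis=0)
    return (1.0 - params.lambda_e) * i_e_syn + dend


def _currents(
    conn: Connectivity, params: ModelParams, inputs: PhaseInputs, state: NetworkState
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All drives for one step: (drive_e, drive_p, drive_s, drive_v, i_d_syn, calcium)."""
    pop = conn.pop
    mart = pop.martinotti_mask
    r_e, r_p, r_s, r_v = state.r_e, state.r_p, state.r_s, state.r_v
    r_m, r_nm = r_s[mart], r_s[~mart]
    w = conn.weights

    i_e = somatic_synaptic_input(conn, r_e, r_p, r_nm, inputs.x_e)
    i_d = np.empty((pop.n_dendrites, pop.n_pc))
    for k in range(pop.n_dendrites):
        i_d[k] = dendritic_synaptic_input(conn, k, r_e, r_m, inputs.x_d[k])
    i0 = params.lambda_e * i_e + (1.0 - params.lambda_d) * i_d
    calcium = dendritic_calcium(i0, params)
    if params.shared_calcium and pop.n_dendrites > 1:
        calcium[:] = calcium[0]

    drive_e = total_somatic_current(i_e, i_d, calcium, params) - params.theta
    drive_p = inputs.x_p + w["PE"] @ r_e - w["PP"] @ r_p - w["PS"] @ r_s - w["PV"] @ r_v
    drive_s = inputs.x_s + w["SE"] @ r_e - w["SV"] @ r_v
    drive_v = inputs.x_v + w["VE"] @ r_e - w["VS"] @ r_s
    return drive_e, drive_p, drive_s, drive_v, i_e, i_d, calcium


def _jacobian(
    conn: Connectivity, params: ModelParams, state: NetworkState,
    bracket_open: np.ndarray,
) -> np.ndarray:
    """Piecewise Jacobian dF/dh of the drive map at the current state.

    Rectifier subgradients use the open half-line (h > 0); calcium events are
    piecewise constant and contribute nothing.  ``bracket_open`` holds the
    per-branch indicator of [I^syn_Dk + c_k]_+ being in its linear region.
    """
    pop = conn.pop
    n_e, n_p, n_s, n_v = pop.n_pc, pop.n_pv, pop.n_som, pop.n_vip
    n = n_e + n_p + n_s + n_v
    sl_e = slice(0, n_e)
    sl_p = slice(n_e, n_e + n_p)
    sl_s = slice(n_e + n_p, n_e + n_p + n_s)
    sl_v = slice(n_e + n_p + n_s, n)
    mart = pop.martinotti_mask
    w = conn.weights
    le, ld = params.lambda_e, params.lambda_d

    de = (state.h_e > 0).astype(float)
    dp = (state.h_p > 0).astype(float)
    ds = (state.h_s > 0).astype(float)
    dv = (state.h_v > 0).astype(float)

    j = np.zeros((n, n))
    j_ee = (1 - le) * w["EE"]
    j_es_m = np.zeros((n_e, mart.sum()))
    for k in range(pop.n_dendrites):
        gate = ld * bracket_open[k][:, None]
        j_ee = j_ee + gate * w[f"D{k + 1}E"]
        j_es_m = j_es_m - gate * w[f"D{k + 1}M"]
    j[sl_e, sl_e] = j_ee * de[None, :]
    j[sl_e, sl_p] = -(1 - le) * w["EP"] * dp[None, :]
    s_block = np.zeros((n_e, n_s))
    s_block[:, mart] = j_es_m
    s_block[:, ~mart] = -(1 - le) * w["EnM"]
    j[sl_e, sl_s] = s_block * ds[None, :]

    j[sl_p, sl_e] = w["PE"] * de[None, :]
    j[sl_p, sl_p] = -w["PP"] * dp[None, :]
    j[sl_p, sl_s] = -w["PS"] * ds[None, :]
    j[sl_p, sl_v] = -w["PV"] * dv[None, :]

    j[sl_s, sl_e] = w["SE"] * de[None, :]
    j[sl_s, sl_v] = -w["SV"] * dv[None, :]

    j[sl_v, sl_e] = w["VE"] * de[None, :]
    j[sl_v, sl_s] = -w["VS"] * ds[None, :]
    return j


def step(
    state: NetworkState,
    inputs: PhaseInputs,
    conn: Connectivity,
    params: ModelParams,
) -> NetworkState:
    """One explicit Euler step h <- h + (dt / tau) (-h + drive)."""
    drive_e, drive_p, drive_s, drive_v, *_ = _currents(conn, params, inputs, state)
    ke, ki = params.dt / params.tau_e, params.dt / params.tau_i
    new = NetworkState(
        h_e=state.h_e + ke * (drive_e - state.h_e),
        h_p=state.h_p + ki * (drive_p - state.h_p),
        h_s=state.h_s + ki * (drive_s - state.h_s),
        h_v=state.h_v + ki * (drive_v - state.h_v),
    )
    for h in (new.h_e, new.h_p, new.h_s, new.h_v):
        if not np.all(np.isfinite(h)):
            raise FloatingPointError("non-finite network state during integration")
    return new


def run_to_steady_state(
    conn: Connectivity,
    phase: StimulusPhase | PhaseInputs,
    params: ModelParams,
    bank: TuningBank | None = None,
    *,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
    init: NetworkState | None = None,
    method: str = "relax",
    relax_alpha: float = 0.5,
    max_relax_iter: int = 5000,
    relax_tol: float = 1e-9,
) -> SteadyState:
    """Steady-state response to one stimulus phase.

    ``method='euler'`` integrates the rate equations over the phase duration
    with step ``params.dt`` and flags non-convergence when max |dr|/dt over
    the final 10% of the phase exceeds ``params.steady_tol``.
    ``method='relax'`` (default) applies damped fixed-point iteration
    h <- h + alpha (drive - h), which has the same fixed points and
    converges to machine precision in far fewer evaluations.
    """
    if isinstance(phase, PhaseInputs):
        inputs = phase
        duration = 1.0
    else:
        if bank is None:
            raise ValueError("bank required when passing a StimulusPhase")
        inputs = phase_inputs(phase, bank, params, conn.pop, rng=rng, noise_sigma=noise_sigma)
        duration = phase.duration

    state = init if init is not None else NetworkState.zeros(conn)
    state = NetworkState(
        h_e=state.h_e.copy(), h_p=state.h_p.copy(),
        h_s=state.h_s.copy(), h_v=state.h_v.copy(),
    )

    if method == "euler":
        n_steps = max(1, int(round(duration / params.dt)))
        window = max(1, n_steps // 10)
        max_dr = np.inf
        prev_r = np.concatenate([state.r_e, state.r_p, state.r_s, state.r_v])
        for i in range(n_steps):
            state = step(state, inputs, conn, params)
            if i >= n_steps - window:
                r = np.concatenate([state.r_e, state.r_p, state.r_s, state.r_v])
                max_dr = min(max_dr, np.max(np.abs(r - prev_r)) / params.dt)
                prev_r = r
            else:
                prev_r = np.concatenate([state.r_e, state.r_p, state.r_s, state.r_v])
        converged = bool(max_dr < params.steady_tol)
        residual = float(max_dr)
    elif method == "relax":
        residual = np.inf
        converged = False
        for _ in range(max_relax_iter):
            drive_e, drive_p, drive_s, drive_v, *_ = _currents(conn, params, inputs, state)
            d_e = drive_e - state.h_e
            d_p = drive_p - state.h_p
            d_s = drive_s - state.h_s
            d_v = drive_v - state.h_v
            residual = max(
                np.max(np.abs(d_e)), np.max(np.abs(d_p)),
                np.max(np.abs(d_s)), np.max(np.abs(d_v)),
            )
            if residual < relax_tol:
                converged = True
                break
            state.h_e += relax_alpha * d_e
            state.h_p += relax_alpha * d_p
            state.h_s += relax_alpha * d_s
            state.h_v += relax_alpha * d_v
            if not np.isfinite(residual):
                raise FloatingPointError("non-finite state during relaxation")
        residual = float(residual)
    elif method == "newton":
        # semismooth Newton on the fixed-point residual g(h) = F(h) - h,
        # with damped-relaxation fallback when a step fails to contract
        pop = conn.pop
        sizes = np.cumsum([pop.n_pc, pop.n_pv, pop.n_som, pop.n_vip])
        residual = np.inf
        converged = False
        for _ in range(60):
            (drive_e, drive_p, drive_s, drive_v,
             i_e, i_d, calcium) = _currents(conn, params, inputs, state)
            g = np.concatenate([
                drive_e - state.h_e, drive_p - state.h_p,
                drive_s - state.h_s, drive_v - state.h_v,
            ])
            residual = float(np.max(np.abs(g)))
            if residual < relax_tol:
                converged = True
                break
            bracket_open = (i_d + calcium) > 0
            jac = _jacobian(conn, params, state, bracket_open)
            try:
                delta = np.linalg.solve(np.eye(len(g)) - jac, g)
            except np.linalg.LinAlgError:
                delta = relax_alpha * g
            h_new = np.split(
                np.concatenate([state.h_e, state.h_p, state.h_s, state.h_v]) + delta,
                sizes[:-1],
            )
            trial = NetworkState(*h_new)
            t_drives = _currents(conn, params, inputs, trial)
            t_res = max(
                np.max(np.abs(t_drives[0] - trial.h_e)),
                np.max(np.abs(t_drives[1] - trial.h_p)),
                np.max(np.abs(t_drives[2] - trial.h_s)),
                np.max(np.abs(t_drives[3] - trial.h_v)),
            )
            if not np.isfinite(t_res) or t_res > residual:
                # fall back to one damped relaxation step
                state.h_e += relax_alpha * (drive_e - state.h_e)
                state.h_p += relax_alpha * (drive_p - state.h_p)
                state.h_s += relax_alpha * (drive_s - state.h_s)
                state.h_v += relax_alpha * (drive_v - state.h_v)
            else:
                state = trial
        if not converged:
            # polish (or rescue) with plain relaxation
            out = run_to_steady_state(
                conn, inputs, params, bank, init=state, method="relax",
                relax_alpha=relax_alpha, max_relax_iter=max_relax_iter,
                relax_tol=relax_tol,
            )
            out.inputs = inputs
            return out
        residual = float(residual)
    else:
        raise ValueError(f"unknown method {method!r}")

    drive_e, drive_p, drive_s, drive_v, i_e, i_d, calcium = _currents(
        conn, params, inputs, state
    )
    return SteadyState(
        r_e=state.r_e, r_p=state.r_p, r_s=state.r_s, r_v=state.r_v,
        i_e_syn=i_e, i_d_syn=i_d, calcium=calcium,
        converged=converged, residual=residual, inputs=inputs, state=state,
    )


def linear_steady_state(w_grouped: np.ndarray, s_grouped: np.ndarray,
                        max_condition: float = 1e12) -> np.ndarray:
    """Grouped linear steady state r = -(W_grouped)^-1 S_grouped.

    W_grouped is the grouped coefficient matrix minus the identity (see
    connectivity.grouped_weight_matrix); the solution stacks PC-soma rates,
    dendritic activities and interneuron rates.
    """
    w_grouped = np.asarray(w_grouped, dtype=float)
    s_grouped = np.asarray(s_grouped, dtype=float)
    cond = np.linalg.cond(w_grouped)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"grouped weight matrix is ill-conditioned (cond={cond:.3e})"
        )
    return -np.linalg.solve(w_grouped, s_grouped)
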