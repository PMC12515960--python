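"""Inhibitory plasticity rules and the training loop.

Five inhibitory pathways are plastic: PV->soma (E<-P), non-Martinotti
SOM->soma (E<-nM), Martinotti SOM->dendrite (D_k<-M), SOM->PV (P<-S) and
VIP->PV (P<-V).  Weights are reparameterized as w = softplus(v) so they stay
strictly positive; the factor dW/dv below is the logistic function.

The rules, applied after the network settles to a steady state for each
stimulus presentation:

  soma:      dv_ij = eta (r_i^E - rho_i) sigma(v_ij) r_j
  dendrite:  dv_ij = eta (lambda_D (r_i^E - rho_i) + (A_i^Dk - eps_i)) sigma(v_ij) r_j
  PV input:  dv_ij = -eta [sum_k (r_k^E - rho_k) W_ki^EP] sigma(v_ij) r_j

where A^Dk = I^syn_Dk + c is the dendritic activity and the bracketed term
backpropagates the pyramidal-cell error through the E<-P weights onto PV
neuron i.  All updates of one presentation are computed from the same frozen
steady state and applied jointly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._numerics import logistic, relu, softplus, softplus_inverse
from .connectivity import Connectivity
from .dynamics import SteadyState, run_to_steady_state
from .params import ModelParams, PlasticityParams
from .stimuli import Protocol, StimulusPhase, TuningBank

__all__ = [
    "softplus",
    "softplus_inverse",
    "update_soma_inhibition",
    "update_dendrite_inhibition",
    "update_pv_afferents",
    "measure_dendritic_target",
    "train",
    "TrainingHistory",
]


def update_soma_inhibition(
    steady: SteadyState,
    conn: Connectivity,
    plast: PlasticityParams,
    pathway: str,
) -> np.ndarray:
    """Delta-v for the somatic inhibitory weights from PV ('P') or
    non-Martinotti SOM ('nM') cells."""
    if pathway == "P":
        key, eta, r_pre = "EP", plast.eta_ep, steady.r_p
    elif pathway == "nM":
        key, eta, r_pre = "EnM", plast.eta_es, steady.rates_nonmartinotti(conn)
    else:
        raise ValueError(f"pathway must be 'P' or 'nM', got {pathway!r}")
    err = steady.r_e - plast.rho
    dv = eta * err[:, None] * logistic(conn.v_params[key]) * r_pre[None, :]
    return np.where(conn.masks[key], dv, 0.0)


def update_dendrite_inhibition(
    steady: SteadyState,
    conn: Connectivity,
    params: ModelParams,
    plast: PlasticityParams,
    branch: int,
    epsilon: np.ndarray | float,
) -> np.ndarray:
    """Delta-v for the Martinotti weights onto dendritic branch ``branch``."""
    key = f"D{branch + 1}M"
    if key not in conn.v_params:
        raise ValueError(f"invalid branch index {branch}")
    a = steady.dendritic_activity[branch]
    err = params.lambda_d * (steady.r_e - plast.rho) + (a - np.asarray(epsilon))
    r_m = steady.rates_martinotti(conn)
    dv = plast.eta_ds * err[:, None] * logistic(conn.v_params[key]) * r_m[None, :]
    return np.where(conn.masks[key], dv, 0.0)


def update_pv_afferents(
    steady: SteadyState,
    conn: Connectivity,
    plast: PlasticityParams,
    pathway: str,
) -> np.ndarray:
    """Delta-v for the inhibitory afferents of PV cells from SOM ('S') or
    VIP ('V') cells, driven by the backpropagated pyramidal-cell error."""
    if pathway == "S":
        key, eta, r_pre = "PS", plast.eta_ps, steady.r_s
    elif pathway == "V":
        key, eta, r_pre = "PV", plast.eta_pv, steady.r_v
    else:
        raise ValueError(f"pathway must be 'S' or 'V', got {pathway!r}")
    backprop = conn.weights["EP"].T @ (steady.r_e - plast.rho)  # per PV neuron
    dv = -eta * backprop[:, None] * logistic(conn.v_params[key]) * r_pre[None, :]
    return np.where(conn.masks[key], dv, 0.0)


def measure_dendritic_target(
    conn: Connectivity, params: ModelParams, bank: TuningBank
) -> np.ndarray:
    """Per-neuron dendritic target: rectified baseline dendritic synaptic input.

    Measured once on the (untrained) network at baseline; shape
    (n_dendrites, n_pc).
    """
    ndim = bank.ndim
    absent = np.full(ndim, -1.0)
    baseline = StimulusPhase(P=absent, S=absent, label="baseline")
    steady = run_to_steady_state(conn, baseline, params, bank)
    return relu(steady.i_d_syn)


@dataclass
class TrainingHistory:
    """Per-presentation convergence records."""

    presentation: list[int] = field(default_factory=list)
    phase_label: list[str] = field(default_factory=list)
    rate_deviation: list[float] = field(default_factory=list)  # mean |r_E - rho|
    dendrite_deviation: list[float] = field(default_factory=list)  # mean |A - eps|
    batch_size: list[int] = field(default_factory=list)
    weight_totals: dict[str, list[float]] = field(default_factory=dict)
    stopped_early: bool = False

    def record_weights(self, conn: Connectivity) -> None:
        for key in conn.plastic_keys():
            self.weight_totals.setdefault(key, []).append(
                float(conn.weights[key].sum(axis=1).mean())
            )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "presentation": self.presentation,
                "phase": self.phase_label,
                "rate_deviation": self.rate_deviation,
                "dendrite_deviation": self.dendrite_deviation,
            }
        )


def _apply(conn: Connectivity, key: str, dv: np.ndarray, clip: float | None) -> None:
    if clip is not None:
        dv = np.clip(dv, -clip, clip)
    conn.v_params[key][conn.masks[key]] += dv[conn.masks[key]]


def train(
    conn: Connectivity,
    protocol: Protocol,
    params: ModelParams,
    plast: PlasticityParams,
    bank: TuningBank,
    seed: int | np.random.Generator = 0,
    *,
    solver: str = "newton",
) -> tuple[Connectivity, TrainingHistory]:
    """Run the plasticity protocol and return the trained connectivity.

    The base phase sequence of ``protocol`` is cycled until
    ``plast.n_presentations`` stimulus presentations (phases) have been
    applied, drawing fresh feature noise per phase.  After each steady
    state all plastic pathways are updated jointly.  Training stops early
    when the mean somatic deviation stays below
    ``early_stop_tol * rho`` for ``early_stop_window`` consecutive updates,
    and aborts if the smoothed deviation grows tenfold.

    ``plast.update_batch`` > 1 coarsens the discretization of the learning
    dynamics: each computed steady state stands in for that many identical
    presentations and its update is applied with the corresponding
    multiplier.  The learning rates themselves are untouched; the smallest
    per-presentation steps (the slow pathways) are simply integrated in
    larger increments, like a larger dt on a stiff but slow ODE.
    ``update_batch = 0`` (default) ramps the batch geometrically from
    ``batch_min`` to ``batch_max`` over ``max_solves`` steps: fine-grained
    integration early, while the fast PV->soma pathway equilibrates, and
    coarse steps late, when only the slow pathways still move.  The run ends
    after ``n_presentations`` effective presentations or ``max_solves``
    computed steady states, whichever comes first, and is fully determined by
    its arguments and seed.
    """
    rng = np.random.default_rng(seed)
    conn = conn.copy()
    epsilon = (
        measure_dendritic_target(conn, params, bank)
        if plast.epsilon is None
        else np.full((conn.pop.n_dendrites, conn.pop.n_pc), float(plast.epsilon))
    )

    history = TrainingHistory()
    consecutive_ok = 0
    best_loss: float | None = None
    phase_cycle = itertools.cycle(protocol.phases)
    warm_starts: dict[str, object] = {}  # phase label -> last activations
    ramp = plast.update_batch == 0
    if ramp:
        growth = (plast.batch_max / plast.batch_min) ** (1.0 / max(plast.max_solves - 1, 1))
    batch = float(plast.batch_min if ramp else plast.update_batch)

    presented = 0
    step_i = 0
    while presented < plast.n_presentations and step_i < plast.max_solves:
        if ramp:
            batch = plast.batch_min * growth**step_i
        phase = next(phase_cycle)
        steady = run_to_steady_state(
            conn, phase, params, bank,
            rng=rng, noise_sigma=protocol.noise_sigma, method=solver,
            init=warm_starts.get(phase.label),
        )
        warm_starts[phase.label] = steady.state
        is_baseline = phase.label == "baseline"
        deviation = float(np.mean(np.abs(steady.r_e - plast.rho)))
        dend_dev = float(np.mean(np.abs(steady.dendritic_activity - epsilon)))
        history.presentation.append(presented)
        history.phase_label.append(phase.label)
        history.rate_deviation.append(deviation)
        history.dendrite_deviation.append(dend_dev)
        history.batch_size.append(int(batch))
        if step_i % 50 == 0:
            history.record_weights(conn)

        if not is_baseline or plast.update_on_baseline:
            k_eff = int(round(min(batch, plast.n_presentations - presented)))
            dv_ep = update_soma_inhibition(steady, conn, plast, "P")
            dv_es = update_soma_inhibition(steady, conn, plast, "nM")
            dv_d = [
                update_dendrite_inhibition(steady, conn, params, plast, k, epsilon[k])
                for k in range(conn.pop.n_dendrites)
            ]
            dv_ps = update_pv_afferents(steady, conn, plast, "S")
            dv_pv = update_pv_afferents(steady, conn, plast, "V")
            _apply(conn, "EP", k_eff * dv_ep, plast.update_clip)
            _apply(conn, "EnM", k_eff * dv_es, plast.update_clip)
            for k, dv in enumerate(dv_d):
                _apply(conn, f"D{k + 1}M", k_eff * dv, plast.update_clip)
            _apply(conn, "PS", k_eff * dv_ps, plast.update_clip)
            _apply(conn, "PV", k_eff * dv_pv, plast.update_clip)
            conn.sync_weights_from_v()

            if deviation < plast.early_stop_tol * plast.rho:
                consecutive_ok += 1
            else:
                consecutive_ok = 0
            if consecutive_ok >= plast.early_stop_window:
                history.stopped_early = True
                break

        presented += int(round(batch))
        step_i += 1

        # divergence guard on a smoothed window
        if step_i >= 200 and step_i % 50 == 0:
            recent = float(np.mean(history.rate_deviation[-50:]))
            if best_loss is None:
                best_loss = recent
            elif recent > 10.0 * best_loss:
                raise RuntimeError(
                    f"training diverged after {presented} presentations: smoothed "
                    f"deviation {recent:.3g} vs best {best_loss:.3g}"
                )
            best_loss = min(best_loss, recent)

    history.record_weights(conn)
    return conn, history
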