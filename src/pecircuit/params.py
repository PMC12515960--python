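"""Scalar constants of the circuit model.

All rates and currents are in 1/s (Hz), times in seconds.  The defaults are
the reference parameter set of the prediction-error microcircuit: a somatic
rheobase of 14/s, dendrite/soma leak fractions lambda_D = 0.27 and
lambda_E = 0.31, a dendritic Ca2+ event of 7/s triggered above 28/s, constant
background drives x^E = 28, x^P = x^S = x^V = 2, x^D = 0, and a target
baseline pyramidal-cell rate of 1.25 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass
class ModelParams:
    """Constants of the rate dynamics, inputs and classification thresholds.

    Parameters
    ----------
    tau_e, tau_i:
        Rate time constants of pyramidal cells and interneurons (s).  The
        interneuron time constant is not constrained by the circuit's
        reference parameter set; fast kinetics (2 ms) are the default.
    theta:
        Somatic rheobase (1/s).  The somatic drive is I - theta, unrectified;
        only the firing rate is rectified.
    lambda_d, lambda_e:
        Fractions of current leaking from dendrite and soma.
    c_amp, theta_c:
        Amplitude (1/s) and threshold (1/s) of the dendritic calcium event.
        The Heaviside convention is strict: exactly at threshold no event is
        triggered.
    x_e, x_p, x_s, x_v, x_d:
        Constant background inputs per population (1/s).
    sensory_drive_pv, prediction_drive_vip:
        Amplitudes of the untuned sensory drive to PV cells and the untuned
        prediction drive to VIP cells whenever the respective signal is
        present.  Default: the tuned-input peak rate (30 Hz).
    rho_e:
        Target (baseline) pyramidal-cell rate (Hz).
    dt:
        Euler integration step (s); must satisfy dt <= tau_i / 10.
    steady_tol:
        Convergence tolerance on max |dr|/dt (1/s^2).
    shared_calcium:
        If True, one calcium event (from branch 1) is shared by all branches
        instead of each branch computing its own.
    mismatch_min, match_max:
        Prediction-error classification thresholds on Delta R / R.
    """

    tau_e: float = 0.060
    tau_i: float = 0.002
    theta: float = 14.0
    lambda_d: float = 0.27
    lambda_e: float = 0.31
    c_amp: float = 7.0
    theta_c: float = 28.0
    x_e: float = 28.0
    x_p: float = 2.0
    x_s: float = 2.0
    x_v: float = 2.0
    x_d: float = 0.0
    sensory_drive_pv: float = 30.0
    prediction_drive_vip: float = 30.0
    rho_e: float = 1.25
    dt: float = 1e-4
    steady_tol: float = 1e-4
    shared_calcium: bool = False
    mismatch_min: float = 0.20
    match_max: float = 0.10

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0 or self.dt <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.dt > self.tau_i / 10 + 1e-15:
            raise ValueError(
                f"dt={self.dt} too large for tau_i={self.tau_i}; need dt <= tau_i/10"
            )
        for name in ("lambda_d", "lambda_e"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class PlasticityParams:
    """Learning rates and targets of the inhibitory plasticity rules.

    eta_ep .. eta_pv are the reference per-pathway learning rates.  ``rho``
    is the somatic target rate; the dendritic target ``epsilon`` defaults to
    None, in which case it is measured per neuron as the rectified dendritic
    synaptic input of the untrained network at baseline.
    """

    eta_ep: float = 1e-4
    eta_es: float = 1e-7
    eta_ds: float = 1e-6
    eta_ps: float = 1e-6
    eta_pv: float = 1e-6
    rho: float = 1.25
    epsilon: float | None = None
    n_presentations: int = 20_000_000  # effective phase presentations
    update_batch: int = 2000  # presentations per computed steady state; 0 = ramped
    batch_min: int = 100
    batch_max: int = 20_000
    max_solves: int = 10_000  # cap on steady-state computations per training run
    update_clip: float | None = 0.5
    update_on_baseline: bool = True
    early_stop_tol: float = 0.05
    early_stop_window: int = 100

    def __post_init__(self) -> None:
        for name in ("eta_ep", "eta_es", "eta_ds", "eta_ps", "eta_pv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.update_batch < 0:
            raise ValueError("update_batch must be >= 1, or 0 for adaptive")
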