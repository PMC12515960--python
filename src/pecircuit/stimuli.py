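"""Tuned and untuned external inputs.

Stimulus features are abstract scalar dimensions (orientation, color, ...),
restricted by default to {0, 1, 2, 3} in one dimension and to
{(0,2), (0,3), (1,2), (1,3)} in two.  A feature value of -1 denotes the
absence of the stimulus in that dimension.  Tuned drive follows a Gaussian
tuning curve with peak rate 30 Hz and width 0.8 (PCs) or 1.0 (SOM cells);
selective attention scales the feature-difference term of the attended
dimension by its gain before the Gaussian is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectivity import PopulationSpec
from .params import ModelParams

ABSENT = -1.0

DEFAULT_FEATURE_SPACE_1D = ((0.0,), (1.0,), (2.0,), (3.0,))
DEFAULT_FEATURE_SPACE_2D = ((0.0, 2.0), (0.0, 3.0), (1.0, 2.0), (1.0, 3.0))


@dataclass
class TuningBank:
    """Per-neuron preferred stimuli and tuning widths.

    ``som_untuned`` implements the SOM-selectivity ablation: SOM cells then
    receive the untuned peak-rate drive whenever a sensory stimulus is
    present, like PV cells.
    """

    preferred_pc: np.ndarray  # (n_pc, ndim)
    preferred_som: np.ndarray  # (n_som, ndim)
    pc_groups: np.ndarray  # (n_pc,) selectivity-group label
    som_groups: np.ndarray  # (n_som,)
    feature_space: tuple[tuple[float, ...], ...]
    sigma_pc: float = 0.8
    sigma_som: float = 1.0
    r_max: float = 30.0
    som_untuned: bool = False

    def __post_init__(self) -> None:
        if self.sigma_pc <= 0 or self.sigma_som <= 0:
            raise ValueError("tuning widths must be positive")

    @property
    def ndim(self) -> int:
        return self.preferred_pc.shape[1]

    def group_feature(self, group: int) -> np.ndarray:
        return np.asarray(self.feature_space[group], dtype=float)


def _even_assignment(n: int, n_groups: int) -> np.ndarray:
    """Distribute n units over n_groups as evenly as possible (sorted blocks)."""
    return (np.arange(n) * n_groups) // n


def assign_preferred_stimuli(
    pop: PopulationSpec,
    feature_space: tuple[tuple[float, ...], ...] | None = None,
    *,
    sigma_pc: float = 0.8,
    sigma_som: float = 1.0,
    r_max: float = 30.0,
    som_untuned: bool = False,
    force: bool = False,
) -> TuningBank:
    """Evenly distribute preferred stimuli over PCs and SOM cells.

    Preferred stimuli are assigned in contiguous blocks matching the PC
    group assignment; Martinotti and non-Martinotti SOM subsets are each
    spread evenly over the feature space so that dendrite- and
    soma-targeting inhibition both cover every feature.
    """
    if feature_space is None:
        feature_space = (
            DEFAULT_FEATURE_SPACE_1D if pop.n_dendrites == 1 else DEFAULT_FEATURE_SPACE_2D
        )
    feature_space = tuple(tuple(float(x) for x in np.atleast_1d(f)) for f in feature_space)
    n_feat = len(feature_space)
    if n_feat == 0:
        raise ValueError("feature space must be nonempty")
    if n_feat != pop.n_groups:
        raise ValueError(
            f"feature space size {n_feat} must match n_groups={pop.n_groups}"
        )
    if pop.n_pc % n_feat and not force:
        raise ValueError(
            f"n_pc={pop.n_pc} not divisible by |feature space|={n_feat}; "
            "pass force=True to allow uneven groups"
        )
    space = np.asarray(feature_space, dtype=float)
    pc_groups = pop.group_assignment
    m_groups = _even_assignment(pop.n_martinotti, n_feat)
    nm_groups = _even_assignment(pop.n_nonmartinotti, n_feat)
    som_groups = np.concatenate([m_groups, nm_groups])
    return TuningBank(
        preferred_pc=space[pc_groups],
        preferred_som=space[som_groups],
        pc_groups=pc_groups,
        som_groups=som_groups,
        feature_space=feature_space,
        sigma_pc=sigma_pc,
        sigma_som=sigma_som,
        r_max=r_max,
        som_untuned=som_untuned,
    )


def gaussian_response(
    s_max: np.ndarray,
    s: np.ndarray,
    sigma: float,
    r_max: float = 30.0,
    attention_gain: np.ndarray | float = 1.0,
    dims: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian tuning-curve response, skipping absent (-1) dimensions.

    r_max * exp(-(1 / 2 sigma^2) * sum_d (g_d (s[d] - s_max[d]))^2) over the
    dimensions d where s[d] != -1 (restricted to ``dims`` if given).  Returns
    0 when every evaluated dimension is absent.
    """
    s_max = np.atleast_2d(np.asarray(s_max, dtype=float))
    s = np.asarray(s, dtype=float).ravel()
    if s_max.shape[1] != s.size:
        raise ValueError(f"dimension mismatch: s_max has {s_max.shape[1]}, s has {s.size}")
    gain = np.broadcast_to(np.asarray(attention_gain, dtype=float).ravel(), s.shape)
    present = s != ABSENT
    if dims is not None:
        sel = np.zeros_like(present)
        sel[np.atleast_1d(dims)] = True
        present = present & sel
    if not present.any():
        return np.zeros(s_max.shape[0])
    diff = gain[present] * (s[present] - s_max[:, present])
    return r_max * np.exp(-0.5 * np.sum(diff**2, axis=1) / sigma**2)


@dataclass
class StimulusPhase:
    """One stimulus epoch: prediction P and sensory input S (-1 = absent)."""

    P: np.ndarray
    S: np.ndarray
    duration: float = 1.0
    attention_gain: np.ndarray | float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.P = np.atleast_1d(np.asarray(self.P, dtype=float))
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        if self.P.shape != self.S.shape:
            raise ValueError("P and S must have the same dimension")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if not self.label:
            self.label = phase_label(self.P, self.S)
        if self.label == "baseline" and (self.p_present or self.s_present):
            raise ValueError("baseline label requires all-absent P and S")

    @property
    def p_present(self) -> bool:
        return bool(np.any(self.P != ABSENT))

    @property
    def s_present(self) -> bool:
        return bool(np.any(self.S != ABSENT))


def phase_label(P: np.ndarray, S: np.ndarray) -> str:
    P = np.atleast_1d(P)
    S = np.atleast_1d(S)
    p_on, s_on = np.any(P != ABSENT), np.any(S != ABSENT)
    if not p_on and not s_on:
        return "baseline"
    if p_on and not s_on:
        return "prediction_only"
    if s_on and not p_on:
        return "sensory_only"
    return "match" if np.array_equal(P, S) else "mismatch"


def _fmt(v: np.ndarray) -> str:
    v = np.atleast_1d(v)
    if v.size == 1:
        return f"{v[0]:g}"
    return "(" + ",".join(f"{x:g}" for x in v) + ")"


def phase_name(phase: StimulusPhase) -> str:
    """Compact 'P-S' identifier, e.g. '0-1' or '(0,2)-(0,3)'."""
    return f"{_fmt(phase.P)}-{_fmt(phase.S)}"


@dataclass
class Protocol:
    """Ordered sequence of stimulus phases with feature-space noise."""

    phases: list[StimulusPhase]
    noise_sigma: float = 0.35
    repetitions: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def protocol_table(protocol: Protocol):
    """Tidy phase table (one row per phase) for CSV export."""
    import pandas as pd

    rows = []
    for i, ph in enumerate(protocol.phases):
        gain = np.broadcast_to(
            np.asarray(ph.attention_gain, dtype=float).ravel(), ph.P.shape
        )
        rows.append({
            "phase": i,
            "label": ph.label,
            "P": "/".join(f"{x:g}" for x in ph.P),
            "S": "/".join(f"{x:g}" for x in ph.S),
            "duration": ph.duration,
            "attention_gain": "/".join(f"{g:g}" for g in gain),
        })
    return pd.DataFrame(rows)


@dataclass
class PhaseInputs:
    """Per-population external input vectors for one phase."""

    x_e: np.ndarray  # PC soma, (n_pc,)
    x_d: np.ndarray  # dendritic branches, (n_dendrites, n_pc)
    x_p: np.ndarray  # PV, (n_pv,)
    x_s: np.ndarray  # SOM, (n_som,)
    x_v: np.ndarray  # VIP, (n_vip,)


def _perturb(value: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Apply additive feature noise to the present dimensions."""
    out = value.copy()
    present = out != ABSENT
    out[present] += noise[present]
    return out


def phase_inputs(
    phase: StimulusPhase,
    bank: TuningBank,
    params: ModelParams,
    pop: PopulationSpec,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
) -> PhaseInputs:
    """External drive to every population for one stimulus phase.

    Background constants are always present.  A sensory stimulus S adds
    tuned drive to PC somata and SOM cells and untuned drive to PV cells; a
    prediction P adds, per dendritic branch k, drive tuned to that branch's
    feature dimension, plus untuned drive to VIP cells.  Feature values are
    perturbed by additive Gaussian noise before the tuning curves are
    evaluated (the stimulus is perturbed, not the neurons); one draw per
    phase and dimension is shared by P and S, so a match phase remains a
    true match at the jittered feature value (coupled sensorimotor
    experience).
    """
    n_d = pop.n_dendrites
    x_e = np.full(pop.n_pc, params.x_e)
    x_d = np.full((n_d, pop.n_pc), params.x_d)
    x_p = np.full(pop.n_pv, params.x_p)
    x_s = np.full(pop.n_som, params.x_s)
    x_v = np.full(pop.n_vip, params.x_v)

    gain = np.broadcast_to(
        np.asarray(phase.attention_gain, dtype=float).ravel(), phase.S.shape
    )

    if noise_sigma > 0 and rng is not None:
        noise = rng.normal(0.0, noise_sigma, size=phase.S.shape)
    else:
        noise = np.zeros(phase.S.shape)

    if phase.s_present:
        s_noisy = _perturb(phase.S, noise)
        x_e += gaussian_response(
            bank.preferred_pc, s_noisy, bank.sigma_pc, bank.r_max, gain
        )
        if bank.som_untuned:
            x_s += bank.r_max
        else:
            x_s += gaussian_response(
                bank.preferred_som, s_noisy, bank.sigma_som, bank.r_max, gain
            )
        x_p += params.sensory_drive_pv

    if phase.p_present:
        p_noisy = _perturb(phase.P, noise)
        for k in range(n_d):
            # in a one-branch model the single branch carries every dimension
            dims = None if n_d == 1 else np.array([k])
            x_d[k] += gaussian_response(
                bank.preferred_pc, p_noisy, bank.sigma_pc, bank.r_max, gain, dims=dims
            )
        x_v += params.prediction_drive_vip

    return PhaseInputs(x_e=x_e, x_d=x_d, x_p=x_p, x_s=x_s, x_v=x_v)


# --------------------------------------------------------------------------
# protocol builders
# --------------------------------------------------------------------------

def _baseline(ndim: int, duration: float = 1.0) -> StimulusPhase:
    absent = np.full(ndim, ABSENT)
    return StimulusPhase(P=absent, S=absent, duration=duration, label="baseline")


def build_protocol(kind: str, *, noise_sigma: float = 0.35, repetitions: int = 1,
                   attended_dim: int | None = None, gain: float = 1.2) -> Protocol:
    """Standard phase sequences.

    kind:
      - ``train_1d`` / ``train_2d``: alternating match (P = S = 0, resp.
        (0, 2)) and baseline phases, ``repetitions`` pairs.
      - ``test_1d``: 0-type match, all 0-S mismatches, prediction-only
        (P=0, S=-1), sensory-only probes S in {0..3}, and baseline.
      - ``test_2d``: match (0,2)-(0,2) and mismatches over the 2D feature
        space, prediction-only, and baseline.
      - ``attention``: the 2D mismatch grid with gain ``gain`` on
        ``attended_dim`` (None = unbiased).
      - ``reduction``: dimensional-reduction cases P=(0,-1) and P=(-1,2).
    """
    space_1d = [f[0] for f in DEFAULT_FEATURE_SPACE_1D]
    space_2d = [np.array(f) for f in DEFAULT_FEATURE_SPACE_2D]

    if kind == "train_1d":
        phases = []
        for _ in range(repetitions):
            phases.append(StimulusPhase(P=[0.0], S=[0.0], label="match"))
            phases.append(_baseline(1))
        return Protocol(phases=phases, noise_sigma=noise_sigma, name=kind)

    if kind == "train_2d":
        phases = []
        for _ in range(repetitions):
            phases.append(StimulusPhase(P=[0.0, 2.0], S=[0.0, 2.0], label="match"))
            phases.append(_baseline(2))
        return Protocol(phases=phases, noise_sigma=noise_sigma, name=kind)

    if kind == "test_1d":
        phases = [_baseline(1)]
        for s in space_1d:
            phases.append(StimulusPhase(P=[0.0], S=[s]))
        phases.append(StimulusPhase(P=[0.0], S=[ABSENT], label="prediction_only"))
        for s in space_1d:
            phases.append(StimulusPhase(P=[ABSENT], S=[s], label="sensory_only"))
        return Protocol(phases=phases, noise_sigma=noise_sigma,
                        repetitions=repetitions, name=kind)

    if kind == "test_2d" or kind == "attention":
        g = np.ones(2)
        if kind == "attention" and attended_dim is not None:
            g = g.copy()
            g[attended_dim] = gain
        phases = [_baseline(2)]
        for s in space_2d:
            phases.append(
                StimulusPhase(P=[0.0, 2.0], S=s, attention_gain=g)
            )
        phases.append(
            StimulusPhase(P=[0.0, 2.0], S=[ABSENT, ABSENT],
                          attention_gain=g, label="prediction_only")
        )
        for s in space_2d:
            phases.append(
                StimulusPhase(P=[ABSENT, ABSENT], S=s, attention_gain=g,
                              label="sensory_only")
            )
        return Protocol(phases=phases, noise_sigma=noise_sigma,
                        repetitions=repetitions, name=kind)

    if kind == "reduction":
        phases = [_baseline(2)]
        for s in ([0.0, ABSENT], [1.0, ABSENT]):
            phases.append(StimulusPhase(P=[0.0, ABSENT], S=s))
        for s in ([ABSENT, 2.0], [ABSENT, 3.0]):
            phases.append(StimulusPhase(P=[ABSENT, 2.0], S=s))
        return Protocol(phases=phases, noise_sigma=noise_sigma,
                        repetitions=repetitions, name=kind)

    raise ValueError(f"unknown protocol kind: {kind!r}")
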