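"""End-to-end experiment drivers.

These functions wire the modules together the way the in-silico protocols
use them: build a random network, train the inhibitory synapses on
match/baseline alternation, probe it with a test protocol, and measure PE
classification, selectivity, mismatch scaling, tuning stability and pathway
balance.  Every run is fully determined by (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .connectivity import (
    Connectivity,
    ConnectivitySpec,
    PopulationSpec,
    grouped_input_vector,
    grouped_weight_matrix,
    homogenize_plastic_weights,
    sample_connectivity,
)
from .dynamics import run_to_steady_state
from .params import ModelParams, PlasticityParams
from .plasticity import train
from .stimuli import (
    Protocol,
    StimulusPhase,
    TuningBank,
    assign_preferred_stimuli,
    build_protocol,
    phase_inputs,
    phase_name,
)


def default_network(
    seed: int,
    *,
    two_dim: bool = False,
    som_untuned: bool = False,
    sigma_som: float = 1.0,
    homogeneous_plastic: bool = False,
    pop: PopulationSpec | None = None,
    conn_spec: ConnectivitySpec | None = None,
    params: ModelParams | None = None,
    feature_space=None,
) -> tuple[Connectivity, TuningBank, ModelParams]:
    """Build the default 1D or 2D network with its tuning bank."""
    if pop is None:
        pop = PopulationSpec(n_dendrites=2 if two_dim else 1)
    if conn_spec is None:
        conn_spec = ConnectivitySpec()
    if params is None:
        params = ModelParams()
    conn = sample_connectivity(pop, conn_spec, seed)
    if homogeneous_plastic:
        conn = homogenize_plastic_weights(conn)
    bank = assign_preferred_stimuli(
        pop, feature_space, sigma_som=sigma_som, som_untuned=som_untuned
    )
    return conn, bank, params


def phase_key(phase: StimulusPhase) -> str:
    """Stable short name for a phase within a protocol."""
    if phase.label == "baseline":
        return "baseline"
    if phase.label == "prediction_only":
        return "pred_only"
    if phase.label == "sensory_only":
        s = np.atleast_1d(phase.S)
        body = f"{s[0]:g}" if s.size == 1 else "(" + ",".join(f"{x:g}" for x in s) + ")"
        return f"sensory_{body}"
    return phase_name(phase)


@dataclass
class ProtocolResponses:
    """Steady PC responses per phase, averaged over noisy repetitions."""

    keys: list[str]
    mean_rates: dict[str, np.ndarray]  # key -> (n_pc,)
    rep_rates: dict[str, np.ndarray]  # key -> (repetitions, n_pc)
    protocol: Protocol

    @property
    def baseline(self) -> np.ndarray:
        return self.mean_rates["baseline"]

    def group_means(self, key: str, pc_groups: np.ndarray) -> np.ndarray:
        r = self.mean_rates[key]
        return np.array([r[pc_groups == g].mean() for g in np.unique(pc_groups)])

    def to_dataframe(self, pc_groups: np.ndarray) -> pd.DataFrame:
        rows = []
        for key in self.keys:
            r = self.mean_rates[key]
            for i, rate in enumerate(r):
                rows.append(
                    {"phase": key, "neuron": i, "group": int(pc_groups[i]), "rate": rate}
                )
        return pd.DataFrame(rows)


def evaluate_protocol(
    conn: Connectivity,
    bank: TuningBank,
    params: ModelParams,
    protocol: Protocol,
    seed: int | np.random.Generator = 0,
    *,
    method: str = "relax",
) -> ProtocolResponses:
    """Run every phase of a protocol to steady state, repetitions with fresh noise."""
    rng = np.random.default_rng(seed)
    keys, mean_rates, rep_rates = [], {}, {}
    for phase in protocol.phases:
        key = phase_key(phase)
        if key in mean_rates:
            continue
        reps = np.empty((protocol.repetitions, conn.pop.n_pc))
        for rep in range(protocol.repetitions):
            steady = run_to_steady_state(
                conn, phase, params, bank,
                rng=rng, noise_sigma=protocol.noise_sigma, method=method,
            )
            reps[rep] = steady.r_e
        keys.append(key)
        rep_rates[key] = reps
        mean_rates[key] = reps.mean(axis=0)
    return ProtocolResponses(keys=keys, mean_rates=mean_rates,
                             rep_rates=rep_rates, protocol=protocol)


def designated_mismatch_phases(
    bank: TuningBank, trained_prediction: np.ndarray
) -> tuple[str, list[str | None]]:
    """Match-phase key and per-neuron designated mismatch key.

    The match phase is the trained P = S condition.  A neuron's mismatch
    phase is the one whose actual stimulus equals the neuron's preferred
    feature; for neurons preferring the trained prediction itself that phase
    is the match phase, so no mismatch requirement applies (their PE
    signature is staying at baseline while the prediction is fulfilled).
    """
    p = np.atleast_1d(np.asarray(trained_prediction, dtype=float))
    match = phase_name(StimulusPhase(P=p, S=p, label="match"))
    mismatch: list[str | None] = []
    for pref in bank.preferred_pc:
        if np.allclose(pref, p):
            mismatch.append(None)
        else:
            mismatch.append(phase_name(StimulusPhase(P=p, S=pref)))
    return match, mismatch


def classify_responses(
    responses: ProtocolResponses,
    bank: TuningBank,
    params: ModelParams,
    trained_prediction: np.ndarray,
) -> analysis.PEClassification:
    match, mismatch = designated_mismatch_phases(bank, trained_prediction)
    return analysis.classify_pe(
        responses.mean_rates,
        responses.baseline,
        match,
        mismatch,
        mismatch_min=params.mismatch_min,
        match_max=params.match_max,
    )


def prediction_only_selectivity(
    responses: ProtocolResponses, bank: TuningBank
) -> analysis.SelectivityResult:
    """Selectivity coefficient gamma(P) under prediction-only input.

    Computed on the rectified suppression depths of the group means relative
    to the baseline phase: gamma is 0 when the prediction suppresses nothing
    and positive when suppression is deepest for the predicted feature.
    """
    return analysis.suppression_selectivity(
        responses.group_means("pred_only", bank.pc_groups),
        responses.group_means("baseline", bank.pc_groups),
    )


def pathway_balance(
    conn: Connectivity,
    bank: TuningBank,
    params: ModelParams,
    phase: StimulusPhase,
) -> analysis.PathwayDecomposition:
    """Grouped pathway E/I decomposition under a (noise-free) stimulus phase.

    Dendritic calcium at the operating point is taken from the full
    nonlinear steady state and held fixed in the linearization.
    """
    pop = conn.pop
    steady = run_to_steady_state(conn, phase, params, bank)
    groups = [np.flatnonzero(pop.group_assignment == g) for g in range(pop.n_groups)]
    calcium = np.array(
        [[steady.calcium[k][g].mean() for g in groups] for k in range(pop.n_dendrites)]
    )
    grouped = grouped_weight_matrix(conn, pop, params, bank.som_groups)
    inputs = phase_inputs(phase, bank, params, pop)
    s_vec = grouped_input_vector(inputs, pop, params, bank.som_groups, calcium)
    return analysis.pathway_decomposition(
        grouped.matrix, s_vec, pop.n_groups, pop.n_dendrites
    )


# --------------------------------------------------------------------------
# experiment configuration and runner
# --------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Fully determines one experiment (together with each seed)."""

    name: str = "emergence_1d"
    two_dim: bool = False
    train_kind: str | None = "train_1d"
    test_kind: str = "test_1d"
    som_untuned: bool = False
    sigma_som: float = 1.0
    homogeneous_plastic: bool = False
    calcium_off: bool = False
    attended_dim: int | None = None
    noise_sigma: float = 0.35
    test_repetitions: int = 5
    n_presentations: int = 20_000_000
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5)
    output_dir: str = "results"
    save_connectivity: bool = False
    resume_from: str | None = None  # directory with a serialized connectivity
    model: dict = field(default_factory=dict)
    plasticity: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "seeds" in data:
            data["seeds"] = tuple(data["seeds"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["seeds"] = list(self.seeds)
        Path(path).write_text(yaml.safe_dump(data))


PRESETS: dict[str, dict] = {
    # 1D emergence of PE neurons through training
    "emergence_1d": {},
    # SOM-selectivity ablation
    "som_ablation": {"som_untuned": True},
    # control with SOM tuning width equal to the PC width
    "som_equal_width": {"sigma_som": 0.8},
    # two-dimensional feature model
    "two_dim": {"two_dim": True, "train_kind": "train_2d", "test_kind": "test_2d"},
    # attention bias on one feature dimension
    "attention": {"two_dim": True, "train_kind": "train_2d", "test_kind": "attention",
                  "attended_dim": 0},
    # dimensional reduction (one feature silenced)
    "reduction": {"two_dim": True, "train_kind": "train_2d", "test_kind": "reduction"},
}


def preset_config(name: str, **overrides) -> ExperimentConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(PRESETS)}")
    opts = {"name": name, **PRESETS[name], **overrides}
    return ExperimentConfig(**opts)


def _trained_prediction(two_dim: bool) -> np.ndarray:
    return np.array([0.0, 2.0]) if two_dim else np.array([0.0])


def run_seed(config: ExperimentConfig, seed: int):
    """Train (if configured) and test one seed; return a result bundle."""
    params = ModelParams(**config.model)
    if config.calcium_off:
        params = params.with_(c_amp=0.0)
    plast = PlasticityParams(
        n_presentations=config.n_presentations, **config.plasticity
    )
    conn, bank, params = default_network(
        seed,
        two_dim=config.two_dim,
        som_untuned=config.som_untuned,
        sigma_som=config.sigma_som,
        homogeneous_plastic=config.homogeneous_plastic,
        params=params,
    )
    history = None
    if config.resume_from:
        conn = Connectivity.from_dir(config.resume_from)
    elif config.train_kind:
        train_protocol = build_protocol(
            config.train_kind, noise_sigma=config.noise_sigma, repetitions=1
        )
        conn, history = train(conn, train_protocol, params, plast, bank, seed=seed + 1)

    test_protocol = build_protocol(
        config.test_kind,
        noise_sigma=config.noise_sigma,
        repetitions=config.test_repetitions,
        attended_dim=config.attended_dim,
    )
    responses = evaluate_protocol(conn, bank, params, test_protocol, seed=seed + 2)
    return conn, bank, params, responses, history


def run_experiment(config: ExperimentConfig, output_dir: str | Path | None = None) -> dict:
    """Execute an experiment across its seeds and write the result bundle.

    Writes, per seed: per-phase steady rates (CSV), PE classification (CSV),
    and a summary JSON with gamma, PE fraction, baseline rate and pathway
    balance; plus the config echo.  Returns the aggregate summary dict.
    """
    out = Path(output_dir or config.output_dir) / config.name
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    per_seed = []
    for seed in config.seeds:
        seed_dir = out / f"seed_{seed}"
        seed_dir.mkdir(exist_ok=True)
        try:
            conn, bank, params, responses, history = run_seed(config, seed)
            responses.to_dataframe(bank.pc_groups).to_csv(
                seed_dir / "steady_rates.csv", index=False
            )
            summary: dict = {"seed": seed}
            summary["baseline_rate"] = float(responses.baseline.mean())
            if "pred_only" in responses.mean_rates:
                sel = prediction_only_selectivity(responses, bank)
                summary["gamma"] = sel.gamma
                summary["gamma_significant"] = bool(sel.significant)
            trained_p = _trained_prediction(config.two_dim)
            match_key = phase_name(StimulusPhase(P=trained_p, S=trained_p))
            if match_key in responses.mean_rates:
                cls = classify_responses(responses, bank, params, trained_p)
                cls.delta_r.to_csv(seed_dir / "pe_classification.csv", index=False)
                summary["pe_fraction"] = cls.fraction_pe
            if history is not None:
                history.to_dataframe().to_csv(seed_dir / "training.csv", index=False)
                summary["final_rate_deviation"] = history.rate_deviation[-1]
            if config.two_dim and config.train_kind:
                match2d = StimulusPhase(P=trained_p, S=trained_p)
                dec = pathway_balance(conn, bank, params, match2d)
                pd.DataFrame({
                    "group": np.arange(conn.pop.n_groups),
                    "soma_E": dec.soma_e, "soma_I": dec.soma_i,
                    "dend1_E": dec.dend_e[0], "dend1_I": dec.dend_i[0],
                    "dend2_E": dec.dend_e[1], "dend2_I": dec.dend_i[1],
                }).to_csv(seed_dir / "pathway_decomposition.csv", index=False)
                summary["soma_ei_imbalance"] = float(np.max(
                    np.abs(dec.soma_e - dec.soma_i)
                    / np.maximum(dec.soma_e, dec.soma_i)
                ))
            if config.save_connectivity:
                conn.to_dir(seed_dir / "connectivity")
            (seed_dir / "summary.json").write_text(json.dumps(summary, indent=2))
            per_seed.append(summary)
        except Exception as exc:  # preserve partial outputs with a manifest
            (seed_dir / "error.json").write_text(
                json.dumps({"seed": seed, "error": str(exc)})
            )
            raise
    aggregate = summarize(out)
    return aggregate


def summarize(results_dir: str | Path) -> dict:
    """Aggregate per-seed summaries: mean and SD of every numeric field."""
    results_dir = Path(results_dir)
    summaries = []
    skipped = []
    for seed_dir in sorted(results_dir.glob("seed_*")):
        f = seed_dir / "summary.json"
        if f.exists():
            summaries.append(json.loads(f.read_text()))
        else:
            skipped.append(seed_dir.name)
    if not summaries:
        raise ValueError(f"no completed seeds under {results_dir}")
    keys = sorted({k for s in summaries for k in s if isinstance(s[k], (int, float))})
    aggregate: dict = {"n_seeds": len(summaries), "skipped": skipped}
    for k in keys:
        vals = np.array([float(s[k]) for s in summaries if k in s])
        aggregate[k] = {"mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=0)) if vals.size > 1 else 0.0}
    (results_dir / "aggregate.json").write_text(json.dumps(aggregate, indent=2))
    df = pd.DataFrame(summaries)
    df.to_csv(results_dir / "aggregate.csv", index=False)
    return aggregate
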