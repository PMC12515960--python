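"""Random network construction.

The circuit has five connection "types" in the probability / mean-strength
tables -- E (PC soma), D (PC dendrite), P (PV), S (SOM), V (VIP) -- realized
here as per-pathway weight matrices.  Somatostatin cells split into
Martinotti cells (dendrite-targeting) and non-Martinotti cells
(soma-targeting); the E<-S entry of the tables is delivered by the
non-Martinotti subset and the D<-S entry by the Martinotti subset, while PV
and VIP receive SOM input from the full population.

All weights are stored as nonnegative magnitudes; inhibitory signs are
applied inside the dynamics equations.  Plastic pathways additionally carry
unconstrained parameters v with w = softplus(v).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._numerics import softplus, softplus_inverse

#: pathway key -> (postsynaptic population, presynaptic population)
#: D-pathways are templates instantiated once per dendritic branch (D1E, ...).
PATHWAY_ENDPOINTS = {
    "EE": ("E", "E"),
    "EP": ("E", "P"),
    "EnM": ("E", "nM"),
    "DE": ("D", "E"),
    "DM": ("D", "M"),
    "PE": ("P", "E"),
    "PP": ("P", "P"),
    "PS": ("P", "S"),
    "PV": ("P", "V"),
    "SE": ("S", "E"),
    "SV": ("S", "V"),
    "VE": ("V", "E"),
    "VS": ("V", "S"),
}

PLASTIC_PATHWAYS = ("EP", "EnM", "DM", "PS", "PV")


@dataclass
class PopulationSpec:
    """Population sizes and the grouping of PCs into homogeneous selectivity groups."""

    n_pc: int = 280
    n_pv: int = 40
    n_som: int = 40
    n_vip: int = 40
    martinotti_fraction: float = 0.7
    n_dendrites: int = 1
    n_groups: int = 4

    def __post_init__(self) -> None:
        if self.n_pc % self.n_groups:
            raise ValueError(
                f"n_pc={self.n_pc} must be divisible by n_groups={self.n_groups}"
            )
        if self.n_dendrites not in (1, 2):
            raise ValueError("n_dendrites must be 1 or 2")
        if not 0.0 <= self.martinotti_fraction <= 1.0:
            raise ValueError("martinotti_fraction must lie in [0, 1]")

    @property
    def n_martinotti(self) -> int:
        return int(round(self.martinotti_fraction * self.n_som))

    @property
    def n_nonmartinotti(self) -> int:
        return self.n_som - self.n_martinotti

    @property
    def martinotti_mask(self) -> np.ndarray:
        """Boolean mask over SOM indices; Martinotti cells come first."""
        mask = np.zeros(self.n_som, dtype=bool)
        mask[: self.n_martinotti] = True
        return mask

    @property
    def group_assignment(self) -> np.ndarray:
        """PC index -> selectivity-group label (contiguous blocks)."""
        return np.repeat(np.arange(self.n_groups), self.n_pc // self.n_groups)

    def size(self, population: str) -> int:
        return {
            "E": self.n_pc,
            "D": self.n_pc,
            "P": self.n_pv,
            "S": self.n_som,
            "M": self.n_martinotti,
            "nM": self.n_nonmartinotti,
            "V": self.n_vip,
        }[population]


@dataclass(frozen=True)
class PathwaySpec:
    prob: float
    mean_weight: float
    plastic: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"connection probability must lie in [0,1], got {self.prob}")
        if self.mean_weight < 0:
            raise ValueError("mean weights are magnitudes and must be nonnegative")


def default_pathways() -> dict[str, PathwaySpec]:
    """The reference probability and mean-total-strength tables.

    Probabilities are applied against the presynaptic subpopulation actually
    delivering the pathway (non-Martinotti for E<-S, Martinotti for D<-S).
    The D<-E entry of the probability table (p = 1) is the structural
    within-cell dendrite-to-soma coupling already expressed by the leak
    fractions, so it does not appear as a synaptic pathway here.
    """
    return {
        "EE": PathwaySpec(0.8, 0.42),
        "EP": PathwaySpec(0.6, 1.75, plastic=True),
        "EnM": PathwaySpec(0.54, 0.35, plastic=True),
        "DE": PathwaySpec(0.1, 0.42),
        "DM": PathwaySpec(0.55, 0.35, plastic=True),
        "PE": PathwaySpec(0.45, 2.5),
        "PP": PathwaySpec(0.5, 0.5),
        "PS": PathwaySpec(0.6, 0.3, plastic=True),
        "PV": PathwaySpec(0.5, 0.6, plastic=True),
        "SE": PathwaySpec(0.35, 1.0),
        "SV": PathwaySpec(0.5, 0.6),
        "VE": PathwaySpec(0.1, 1.0),
        "VS": PathwaySpec(0.45, 0.5),
    }


@dataclass
class ConnectivitySpec:
    """Connection probabilities and mean total strengths per pathway."""

    pathways: dict[str, PathwaySpec] = field(default_factory=default_pathways)
    init_spread: float = 0.5  # weights drawn from U((1-s) wbar, (1+s) wbar) / N_w

    def __post_init__(self) -> None:
        unknown = set(self.pathways) - set(PATHWAY_ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown pathways: {sorted(unknown)}")
        if not 0.0 <= self.init_spread < 1.0:
            raise ValueError("init_spread must lie in [0, 1)")


def _branch_keys(template: str, n_dendrites: int) -> list[str]:
    return [f"D{k + 1}{template[1:]}" for k in range(n_dendrites)]


def realized_pathway_keys(pop: PopulationSpec) -> list[str]:
    keys = []
    for key in PATHWAY_ENDPOINTS:
        if key.startswith("D"):
            keys.extend(_branch_keys(key, pop.n_dendrites))
        else:
            keys.append(key)
    return keys


def _template_of(key: str) -> str:
    return "D" + key[2:] if key.startswith("D") and key[1].isdigit() else key


@dataclass
class Connectivity:
    """Realized per-pathway weight matrices (row = postsynaptic index)."""

    pop: PopulationSpec
    spec: ConnectivitySpec
    weights: dict[str, np.ndarray]
    masks: dict[str, np.ndarray]
    v_params: dict[str, np.ndarray]

    def plastic_keys(self) -> list[str]:
        return sorted(self.v_params)

    def is_plastic(self, key: str) -> bool:
        return key in self.v_params

    def sync_weights_from_v(self) -> None:
        """Re-derive w = softplus(v) on existing plastic synapses."""
        for key, v in self.v_params.items():
            mask = self.masks[key]
            w = self.weights[key]
            w[...] = 0.0
            w[mask] = softplus(v[mask])

    def copy(self) -> "Connectivity":
        return Connectivity(
            pop=self.pop,
            spec=self.spec,
            weights={k: w.copy() for k, w in self.weights.items()},
            masks={k: m.copy() for k, m in self.masks.items()},
            v_params={k: v.copy() for k, v in self.v_params.items()},
        )

    # -- serialization -----------------------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "pop": {
                "n_pc": self.pop.n_pc,
                "n_pv": self.pop.n_pv,
                "n_som": self.pop.n_som,
                "n_vip": self.pop.n_vip,
                "martinotti_fraction": self.pop.martinotti_fraction,
                "n_dendrites": self.pop.n_dendrites,
                "n_groups": self.pop.n_groups,
            },
            "init_spread": self.spec.init_spread,
            "pathways": {
                k: {"prob": p.prob, "mean_weight": p.mean_weight, "plastic": p.plastic}
                for k, p in self.spec.pathways.items()
            },
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        for key, w in self.weights.items():
            np.savetxt(path / f"W_{key}.csv", w, delimiter=",")

    @classmethod
    def from_dir(cls, path: str | Path) -> "Connectivity":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        pop = PopulationSpec(**meta["pop"])
        spec = ConnectivitySpec(
            pathways={k: PathwaySpec(**v) for k, v in meta["pathways"].items()},
            init_spread=meta["init_spread"],
        )
        weights, masks, v_params = {}, {}, {}
        for key in realized_pathway_keys(pop):
            w = np.loadtxt(path / f"W_{key}.csv", delimiter=",", ndmin=2)
            weights[key] = w
            masks[key] = w > 0
            if spec.pathways[_template_of(key)].plastic:
                v = np.zeros_like(w)
                v[w > 0] = softplus_inverse(w[w > 0])
                v_params[key] = v
        return cls(pop=pop, spec=spec, weights=weights, masks=masks, v_params=v_params)


def sample_connectivity(
    pop: PopulationSpec, spec: ConnectivitySpec, seed: int | np.random.Generator
) -> Connectivity:
    """Draw the random adjacency and initial weights.

    Each postsynaptic unit in population X receives on average p^XY * N_Y
    afferents from Y (independent Bernoulli draws); each realized synapse is
    drawn from U((1-s) wbar, (1+s) wbar) / N_w, where N_w is that neuron's
    realized afferent count for the pathway, so the expected total afferent
    strength equals wbar exactly.
    """
    rng = np.random.default_rng(seed)
    weights: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    v_params: dict[str, np.ndarray] = {}

    for key in realized_pathway_keys(pop):
        template = _template_of(key)
        pspec = spec.pathways[template]
        post, pre = PATHWAY_ENDPOINTS[template]
        n_post, n_pre = pop.size(post), pop.size(pre)
        mask = rng.random((n_post, n_pre)) < pspec.prob
        if template in ("EE", "PP"):  # no self-connections
            np.fill_diagonal(mask, False)
        w = np.zeros((n_post, n_pre))
        counts = mask.sum(axis=1)
        if pspec.prob > 0 and np.any(counts == 0):
            warnings.warn(
                f"pathway {key}: {(counts == 0).sum()} postsynaptic units with no "
                "afferents; rows left zero",
                stacklevel=2,
            )
        lo, hi = 1.0 - spec.init_spread, 1.0 + spec.init_spread
        draws = rng.uniform(lo, hi, size=mask.shape) * pspec.mean_weight
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(mask, draws / np.maximum(counts[:, None], 1), 0.0)
        weights[key] = w
        masks[key] = mask
        if pspec.plastic:
            v = np.zeros_like(w)
            active = mask & (w > 0)
            v[active] = softplus_inverse(w[active])
            w[active] = softplus(v[active])  # canonical w = s+(v) to the last bit
            v_params[key] = v

    return Connectivity(pop=pop, spec=spec, weights=weights, masks=masks, v_params=v_params)


def homogenize_plastic_weights(conn: Connectivity) -> Connectivity:
    """Set every plastic synapse to its pathway mean (wbar / N_w per neuron).

    Returns a copy; the untrained "homogeneous weights" condition.
    """
    out = conn.copy()
    for key in out.plastic_keys():
        pspec = out.spec.pathways[_template_of(key)]
        mask = out.masks[key]
        counts = mask.sum(axis=1)
        w = np.zeros_like(out.weights[key])
        rows = counts > 0
        w[rows] = mask[rows] * (pspec.mean_weight / counts[rows, None])
        v = np.zeros_like(w)
        active = mask & (w > 0)
        v[active] = softplus_inverse(w[active])
        w[active] = softplus(v[active])
        out.weights[key] = w
        out.v_params[key] = v
    return out


@dataclass
class GroupedMatrix:
    """Population-level linearized coefficient matrix.

    ``matrix`` is C - I, where C holds the mean total connection strengths
    between homogeneous groups with the signs and leak fractions of the rate
    equations applied, so that the grouped steady state (with all rectifiers
    interior and calcium fixed) solves (C - I) z + S = 0, i.e.
    z = -(C - I)^{-1} S.  ``z`` stacks PC-soma group rates, per-branch
    dendritic activities A^Dk, and interneuron group rates, in the order of
    ``labels``.
    """

    matrix: np.ndarray
    labels: list[str]
    n_groups: int
    n_dendrites: int

    @property
    def soma_rows(self) -> slice:
        return slice(0, self.n_groups)

    def dendrite_rows(self, branch: int) -> slice:
        start = self.n_groups * (1 + branch)
        return slice(start, start + self.n_groups)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _block_total(w: np.ndarray, post_groups: list[np.ndarray],
                 pre_groups: list[np.ndarray]) -> np.ndarray:
    """Mean (over postsynaptic group) of total afferent strength per pre group."""
    out = np.empty((len(post_groups), len(pre_groups)))
    for a, pi in enumerate(post_groups):
        sub = w[pi]
        for b, pj in enumerate(pre_groups):
            out[a, b] = sub[:, pj].sum(axis=1).mean()
    return out


def _som_subgroups(pop: PopulationSpec, som_groups: np.ndarray | None):
    """Index lists for Martinotti and non-Martinotti groups (by preference)."""
    mart = pop.martinotti_mask
    if som_groups is None:
        som_groups = np.zeros(pop.n_som, dtype=int)
    m_ids = sorted(set(som_groups[mart]))
    nm_ids = sorted(set(som_groups[~mart]))
    m_idx_full = [np.flatnonzero(mart & (som_groups == g)) for g in m_ids]
    nm_idx_full = [np.flatnonzero(~mart & (som_groups == g)) for g in nm_ids]
    # indices within the subtype-restricted matrices (D<-M, E<-nM)
    m_local = [np.flatnonzero(som_groups[mart] == g) for g in m_ids]
    nm_local = [np.flatnonzero(som_groups[~mart] == g) for g in nm_ids]
    return m_ids, nm_ids, m_idx_full, nm_idx_full, m_local, nm_local


def grouped_weight_matrix(
    conn: Connectivity,
    pop: PopulationSpec,
    params,
    som_groups: np.ndarray | None = None,
) -> GroupedMatrix:
    """Collapse the realized network onto homogeneous selectivity groups.

    Blocks are mean total connection strengths between groups, inhibitory
    entries negative, with the leak fractions (1 - lambda_E), lambda_D
    applied where the rate equations apply them.  Dendritic branches enter
    as separate "dendritic element" rows whose variables are the dendritic
    activities A^Dk; the within-cell dendrite-to-soma coupling appears as
    lambda_D on the matching group's dendritic column.
    """
    groups = [np.flatnonzero(pop.group_assignment == g) for g in range(pop.n_groups)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("singular grouping: every PC group must be nonempty")
    m_ids, nm_ids, _, _, m_local, nm_local = _som_subgroups(pop, som_groups)
    if not m_local or not nm_local or any(len(i) == 0 for i in m_local + nm_local):
        raise ValueError("singular grouping: empty SOM subgroup")

    n = pop.n_groups
    n_d = pop.n_dendrites
    labels = [f"E{g}" for g in range(n)]
    for k in range(n_d):
        labels += [f"D{k + 1}:{g}" for g in range(n)]
    labels += ["P"]
    labels += [f"M{g}" for g in m_ids]
    labels += [f"nM{g}" for g in nm_ids]
    labels += ["V"]
    size = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((size, size))

    w = conn.weights
    pv_idx = [np.arange(pop.n_pv)]
    vip_idx = [np.arange(pop.n_vip)]
    som_all = _som_subgroups(pop, som_groups)
    m_full, nm_full = som_all[2], som_all[3]

    le, ld = params.lambda_e, params.lambda_d

    # E rows
    b_ee = _block_total(w["EE"], groups, groups)
    b_ep = _block_total(w["EP"], groups, pv_idx)
    b_enm = _block_total(w["EnM"], groups, nm_local)
    for g in range(n):
        for g2 in range(n):
            c[idx[f"E{g}"], idx[f"E{g2}"]] = (1 - le) * b_ee[g, g2]
        for k in range(n_d):
            c[idx[f"E{g}"], idx[f"D{k + 1}:{g}"]] = ld
        c[idx[f"E{g}"], idx["P"]] = -(1 - le) * b_ep[g, 0]
        for b, gid in enumerate(nm_ids):
            c[idx[f"E{g}"], idx[f"nM{gid}"]] = -(1 - le) * b_enm[g, b]

    # dendritic rows (variables are A^Dk; unit coefficient on nothing else)
    for k in range(n_d):
        b_de = _block_total(w[f"D{k + 1}E"], groups, groups)
        b_dm = _block_total(w[f"D{k + 1}M"], groups, m_local)
        for g in range(n):
            row = idx[f"D{k + 1}:{g}"]
            for g2 in range(n):
                c[row, idx[f"E{g2}"]] = b_de[g, g2]
            for b, gid in enumerate(m_ids):
                c[row, idx[f"M{gid}"]] = -b_dm[g, b]

    # PV row
    b_pe = _block_total(w["PE"], pv_idx, groups)
    b_pp = _block_total(w["PP"], pv_idx, pv_idx)
    b_pm = _block_total(w["PS"], pv_idx, m_full)
    b_pnm = _block_total(w["PS"], pv_idx, nm_full)
    b_pv = _block_total(w["PV"], pv_idx, vip_idx)
    for g in range(n):
        c[idx["P"], idx[f"E{g}"]] = b_pe[0, g]
    c[idx["P"], idx["P"]] = -b_pp[0, 0]
    for b, gid in enumerate(m_ids):
        c[idx["P"], idx[f"M{gid}"]] = -b_pm[0, b]
    for b, gid in enumerate(nm_ids):
        c[idx["P"], idx[f"nM{gid}"]] = -b_pnm[0, b]
    c[idx["P"], idx["V"]] = -b_pv[0, 0]

    # SOM rows (Martinotti and non-Martinotti groups)
    for sub_ids, sub_full, tag in ((m_ids, m_full, "M"), (nm_ids, nm_full, "nM")):
        b_se = _block_total(w["SE"], sub_full, groups)
        b_sv = _block_total(w["SV"], sub_full, vip_idx)
        for a, gid in enumerate(sub_ids):
            row = idx[f"{tag}{gid}"]
            for g in range(n):
                c[row, idx[f"E{g}"]] = b_se[a, g]
            c[row, idx["V"]] = -b_sv[a, 0]

    # VIP row
    b_ve = _block_total(w["VE"], vip_idx, groups)
    b_vm = _block_total(w["VS"], vip_idx, m_full)
    b_vnm = _block_total(w["VS"], vip_idx, nm_full)
    for g in range(n):
        c[idx["V"], idx[f"E{g}"]] = b_ve[0, g]
    for b, gid in enumerate(m_ids):
        c[idx["V"], idx[f"M{gid}"]] = -b_vm[0, b]
    for b, gid in enumerate(nm_ids):
        c[idx["V"], idx[f"nM{gid}"]] = -b_vnm[0, b]

    return GroupedMatrix(
        matrix=c - np.eye(size), labels=labels, n_groups=n, n_dendrites=n_d
    )


def grouped_input_vector(
    inputs,
    pop: PopulationSpec,
    params,
    som_groups: np.ndarray | None = None,
    calcium: np.ndarray | None = None,
) -> np.ndarray:
    """Group-averaged external input aligned with grouped_weight_matrix labels.

    E entries carry (1 - lambda_E) x^E - Theta; dendritic entries carry the
    branch input plus an (optionally supplied) fixed calcium current per
    group; interneuron entries carry their external drive.
    """
    groups = [np.flatnonzero(pop.group_assignment == g) for g in range(pop.n_groups)]
    m_ids, nm_ids, m_full, nm_full, _, _ = _som_subgroups(pop, som_groups)
    n, n_d = pop.n_groups, pop.n_dendrites
    if calcium is None:
        calcium = np.zeros((n_d, n))

    parts = [
        np.array([(1 - params.lambda_e) * inputs.x_e[g].mean() - params.theta
                  for g in groups])
    ]
    for k in range(n_d):
        parts.append(
            np.array([inputs.x_d[k][g].mean() + calcium[k, gi]
                      for gi, g in enumerate(groups)])
        )
    parts.append(np.array([inputs.x_p.mean()]))
    parts.append(np.array([inputs.x_s[i].mean() for i in m_full]))
    parts.append(np.array([inputs.x_s[i].mean() for i in nm_full]))
    parts.append(np.array([inputs.x_v.mean()]))
    return np.concatenate(parts)


def perturb_connectivity(
    conn: Connectivity, range_fraction: float, seed: int | np.random.Generator
) -> Connectivity:
    """Scale every nonzero weight by an independent U(1-f, 1+f) draw."""
    if not 0.0 <= range_fraction < 1.0:
        raise ValueError("range_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = conn.copy()
    if range_fraction == 0.0:
        return out
    for key, w in out.weights.items():
        nz = w > 0
        factors = rng.uniform(1.0 - range_fraction, 1.0 + range_fraction, size=w.shape)
        w[nz] *= factors[nz]
        if key in out.v_params:
            v = out.v_params[key]
            v[nz] = softplus_inverse(w[nz])
            w[nz] = softplus(v[nz])
    return out
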