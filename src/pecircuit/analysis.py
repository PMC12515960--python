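"""Measurement layer: PE classification, selectivity, tuning fits, pathways.

A pyramidal cell is a prediction-error (PE) neuron when its rate stays near
baseline in the trained match phase (|Delta R / R| < 10%) and rises above
baseline (Delta R / R > 20%) in its designated mismatch phase.  Feature
specificity of top-down suppression is summarized by the selectivity
coefficient gamma, a skewness-style statistic over the group-mean responses;
|gamma| > 0.5 is taken as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stimuli import TuningBank, gaussian_response


# --------------------------------------------------------------------------
# PE classification
# --------------------------------------------------------------------------

@dataclass
class PEClassification:
    delta_r: pd.DataFrame  # neurons x phases, Delta R / R
    is_pe: np.ndarray
    unclassifiable: np.ndarray
    match_phase: str
    mismatch_phase: list[str | None]  # per neuron
    mismatch_min: float
    match_max: float

    @property
    def fraction_pe(self) -> float:
        ok = ~self.unclassifiable
        return float(self.is_pe[ok].mean()) if ok.any() else float("nan")


def classify_pe(
    phase_rates: dict[str, np.ndarray],
    baseline_rates: np.ndarray,
    match_phase: str,
    mismatch_phase: list[str | None],
    mismatch_min: float = 0.20,
    match_max: float = 0.10,
) -> PEClassification:
    """Classify PCs as prediction-error neurons.

    ``phase_rates`` maps phase names to per-neuron steady rates;
    ``mismatch_phase`` designates, per neuron, which phase counts as its
    corresponding mismatch (None = no mismatch requirement, used for neurons
    whose preferred feature equals the trained prediction, for which the
    match phase itself is the informative condition).  Neurons with zero
    baseline rate are flagged unclassifiable.
    """
    baseline_rates = np.asarray(baseline_rates, dtype=float)
    n = baseline_rates.size
    if len(mismatch_phase) != n:
        raise ValueError("mismatch_phase must designate one phase per neuron")
    if match_phase not in phase_rates:
        raise ValueError(f"match phase {match_phase!r} missing from responses")

    unclassifiable = baseline_rates <= 0
    safe_bl = np.where(unclassifiable, 1.0, baseline_rates)
    delta = {
        name: (np.asarray(r, dtype=float) - baseline_rates) / safe_bl
        for name, r in phase_rates.items()
    }
    df = pd.DataFrame(delta)

    match_ok = np.abs(delta[match_phase]) < match_max
    mm_ok = np.ones(n, dtype=bool)
    for i, ph in enumerate(mismatch_phase):
        if ph is not None:
            mm_ok[i] = delta[ph][i] > mismatch_min
    is_pe = match_ok & mm_ok & ~unclassifiable
    return PEClassification(
        delta_r=df,
        is_pe=is_pe,
        unclassifiable=unclassifiable,
        match_phase=match_phase,
        mismatch_phase=list(mismatch_phase),
        mismatch_min=mismatch_min,
        match_max=match_max,
    )


# --------------------------------------------------------------------------
# selectivity coefficient
# --------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    gamma: float
    group_means: np.ndarray
    grand_mean: float
    significant: bool


def selectivity_coefficient(
    group_mean_rates: np.ndarray,
    significance_threshold: float = 0.5,
    variance_tol: float = 1e-12,
) -> SelectivityResult:
    """Skewness-style selectivity coefficient over group-mean responses.

    gamma = <(r_s - rbar)^3>_s / <(r_s - rbar)^2>_s^{3/2}, plain averaging
    over the selectivity groups.  When the across-group variance falls below
    ``variance_tol`` the coefficient is exactly 0 (no differentiation).
    """
    means = np.asarray(group_mean_rates, dtype=float)
    if means.size < 3:
        raise ValueError("selectivity coefficient requires at least 3 groups")
    grand = float(means.mean())
    dev = means - grand
    m2 = float(np.mean(dev**2))
    if m2 < variance_tol:
        return SelectivityResult(0.0, means, grand, False)
    gamma = float(np.mean(dev**3) / m2**1.5)
    return SelectivityResult(gamma, means, grand, abs(gamma) > significance_threshold)


def suppression_selectivity(
    group_mean_rates: np.ndarray,
    baseline_rates: np.ndarray | float,
    significance_threshold: float = 0.5,
    variance_tol: float = 1e-12,
) -> SelectivityResult:
    """Selectivity of prediction-driven suppression.

    The skewness statistic applied to the rectified suppression depths
    [baseline - r_s]_+ of the group means: only activity reductions below
    baseline count as suppression.  A network whose groups all sit at or
    above baseline is unselective by construction (gamma = 0); graded
    suppression that is deepest for the predicted feature yields a positive
    coefficient.
    """
    means = np.asarray(group_mean_rates, dtype=float)
    depths = np.maximum(np.asarray(baseline_rates, dtype=float) - means, 0.0)
    result = selectivity_coefficient(depths, significance_threshold, variance_tol)
    return SelectivityResult(result.gamma, means, float(np.mean(means)),
                             result.significant)


# --------------------------------------------------------------------------
# similarity
# --------------------------------------------------------------------------

def similarity(
    s_max: np.ndarray,
    s0: np.ndarray,
    bank: TuningBank,
    mode: str | None = None,
    norm: str = "euclidean",
) -> float:
    """Similarity RS between a preferred stimulus and a probe stimulus.

    1D: ratio of the tuning-curve value to its peak.  2D: 1 minus the mean
    absolute component difference scaled by the sum of the vector norms
    (Euclidean by default, L1 optional).
    """
    s_max = np.atleast_1d(np.asarray(s_max, dtype=float))
    s0 = np.atleast_1d(np.asarray(s0, dtype=float))
    if s_max.shape != s0.shape:
        raise ValueError("stimulus vectors must share a dimension")
    if mode is None:
        mode = "1d" if s_max.size == 1 else "2d"
    if mode == "1d":
        f = gaussian_response(s_max[None, :], s0, bank.sigma_pc, bank.r_max)
        return float(f[0] / bank.r_max)
    if mode == "2d":
        ord_ = {"euclidean": 2, "l1": 1}[norm]
        denom = np.linalg.norm(s_max, ord_) + np.linalg.norm(s0, ord_)
        if denom == 0:
            raise ValueError("2D similarity undefined for two zero-norm vectors")
        return float(1.0 - np.mean(np.abs(s_max - s0)) / denom)
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# tuning-curve fits
# --------------------------------------------------------------------------

@dataclass
class TuningFit:
    amplitude: float
    peak: float
    width: float
    converged: bool


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * (x - mu) ** 2 / sigma**2)


def fit_tuning_curves(
    stimulus_values: np.ndarray,
    group_responses: np.ndarray,
    bank: TuningBank | None = None,
) -> list[TuningFit]:
    """Least-squares Gaussian fit of each group's response-vs-stimulus curve.

    ``group_responses`` is (n_groups, n_stimuli).  A non-convergent fit is
    flagged (converged=False) with the raw peak location as fallback.
    """
    x = np.asarray(stimulus_values, dtype=float)
    responses = np.atleast_2d(np.asarray(group_responses, dtype=float))
    if x.size < 4:
        raise ValueError("need at least 4 stimulus values per fit")
    sigma0 = bank.sigma_pc if bank is not None else 1.0
    fits = []
    for row in responses:
        mu0 = float(x[np.argmax(row)])
        a0 = float(max(row.max(), 1e-6))
        try:
            popt, _ = optimize.curve_fit(
                _gauss, x, row, p0=[a0, mu0, sigma0],
                bounds=([0, x.min() - 2, 1e-3], [np.inf, x.max() + 2, 100]),
                maxfev=10000,
            )
            fits.append(TuningFit(float(popt[0]), float(popt[1]), float(popt[2]), True))
        except RuntimeError:
            fits.append(TuningFit(a0, mu0, float(sigma0), False))
    return fits


def peak_shifts(fits_a: list[TuningFit], fits_b: list[TuningFit]) -> np.ndarray:
    """Per-group fitted-peak displacement between two conditions."""
    return np.array([b.peak - a.peak for a, b in zip(fits_a, fits_b)])


# --------------------------------------------------------------------------
# mismatch scaling and subtractive integration
# --------------------------------------------------------------------------

@dataclass
class MismatchScaling:
    table: pd.DataFrame  # columns: distance, response
    spearman_rho: float
    monotone_increasing: bool


def mismatch_scaling(
    distances: np.ndarray, responses: np.ndarray
) -> MismatchScaling:
    """Response of the S-preferring group versus feature distance |S - P|.

    Duplicate distances are averaged; the verdict is the sign of the
    Spearman rank correlation.
    """
    df = pd.DataFrame({"distance": np.asarray(distances, dtype=float),
                       "response": np.asarray(responses, dtype=float)})
    table = df.groupby("distance", as_index=False)["response"].mean()
    if len(table) < 2:
        raise ValueError("need at least 2 distinct feature distances")
    rho = float(stats.spearmanr(table["distance"], table["response"]).statistic)
    return MismatchScaling(table=table, spearman_rho=rho, monotone_increasing=rho > 0)


# --------------------------------------------------------------------------
# pathway decomposition
# --------------------------------------------------------------------------

@dataclass
class PathwayDecomposition:
    inverse: np.ndarray  # M = W_grouped^{-1}
    soma_e: np.ndarray
    soma_i: np.ndarray
    dend_e: list[np.ndarray]  # per branch
    dend_i: list[np.ndarray]
    net_soma: np.ndarray  # M_soma @ S (conservation identity)
    net_dend: list[np.ndarray]

    def conservation_error(self) -> float:
        err = np.max(np.abs(self.soma_e - self.soma_i - self.net_soma))
        for e, i, net in zip(self.dend_e, self.dend_i, self.net_dend):
            err = max(err, np.max(np.abs(e - i - net)))
        return float(err)


def pathway_decomposition(
    w_grouped: np.ndarray,
    s_grouped: np.ndarray,
    n_groups: int,
    n_dendrites: int = 1,
) -> PathwayDecomposition:
    """Split steady-state input pathways into excitatory and inhibitory sums.

    M = W_grouped^{-1}; the first n rows of M carry the pathways onto PC
    somata, the next n_dendrites blocks of n rows those onto the dendritic
    branches.  Each row block is Hadamard-masked by the sign of its entries
    and contracted with the grouped input vector S: pathX_E collects the
    positive entries, pathX_I the magnitude of the negative ones, so that
    pathX_E - pathX_I = M_X . S exactly.
    """
    w = np.asarray(w_grouped, dtype=float)
    s = np.asarray(s_grouped, dtype=float)
    cond = np.linalg.cond(w)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"singular grouped matrix (cond={cond:.3e})")
    m = np.linalg.inv(w)

    def split(rows: np.ndarray):
        # |M o Gamma_{M<0}|: magnitudes of the negative entries, then contract
        pos = np.where(rows > 0, rows, 0.0) @ s
        neg = -np.where(rows < 0, rows, 0.0) @ s
        return pos, neg, rows @ s

    soma_e, soma_i, net_soma = split(m[:n_groups])
    dend_e, dend_i, net_dend = [], [], []
    for k in range(n_dendrites):
        block = m[n_groups * (1 + k): n_groups * (2 + k)]
        e, i, net = split(block)
        dend_e.append(e)
        dend_i.append(i)
        net_dend.append(net)
    return PathwayDecomposition(
        inverse=m, soma_e=soma_e, soma_i=soma_i,
        dend_e=dend_e, dend_i=dend_i,
        net_soma=net_soma, net_dend=net_dend,
    )


# --------------------------------------------------------------------------
# two-condition comparison
# --------------------------------------------------------------------------

@dataclass
class ConditionComparison:
    t_statistic: float
    t_pvalue: float
    u_statistic: float
    u_pvalue: float
    significant: bool  # p < 0.05 on both tests; no multiple-comparison correction


def compare_conditions(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> ConditionComparison:
    """Two-sample t-test and Mann-Whitney U-test between per-neuron responses."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each condition needs at least 2 samples")
    t = stats.ttest_ind(a, b)
    u = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ConditionComparison(
        t_statistic=float(t.statistic), t_pvalue=float(t.pvalue),
        u_statistic=float(u.statistic), u_pvalue=float(u.pvalue),
        significant=bool(t.pvalue < alpha and u.pvalue < alpha),
    )
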