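"""Circuit-level summaries and cohort statistics.

Covers the statistical toolkit used to compare circuit configurations:
per-circuit connectivity/suppression proportions, the Kruskal-Wallis test
(nonparametric one-way ANOVA) with rank-based pairwise post-hoc
comparisons, the Benjamini-Krieger-Yekutieli two-stage step-up FDR
procedure, and a logistic regression of connection probability on soma
location (AP/ML/DV).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "CohortSummary",
    "ComparisonResult",
    "LocationRegressionResult",
    "summarize_cohort",
    "kruskal_wallis",
    "bky_two_stage_fdr",
    "pairwise_rank_comparisons",
    "location_connection_regression",
    "round_percent",
]


def round_percent(k: int, n: int) -> int:
    """Integer percentage, rounded half away from zero (as printed in reports)."""
    if n == 0:
        raise ValueError("cannot compute a percentage of zero cells")
    return int(np.floor(100.0 * k / n + 0.5))


@dataclass
class CohortSummary:
    """Counts, percentages and response statistics for one circuit.

    Connectivity and suppression are assessed in (potentially) different
    cells, so each proportion is reported against its own tested count.
    Amplitude statistics are reported in nA, latency in ms, both over
    connected cells only.
    """

    circuit: str
    n_connectivity_tested: int = 0
    n_connected: int = 0
    n_suppression_tested: int = 0
    n_suppressed: int = 0
    amplitude_stats_na: Optional[dict] = None
    latency_stats_ms: Optional[dict] = None

    COLUMNS = (
        "circuit", "n_connectivity_tested", "n_connected", "pct_connected",
        "n_suppression_tested", "n_suppressed", "pct_suppressed",
        "amplitude_mean_na", "amplitude_sd_na", "amplitude_min_na", "amplitude_max_na",
        "latency_mean_ms", "latency_sd_ms", "latency_min_ms", "latency_max_ms",
    )

    @property
    def pct_connected(self) -> Optional[int]:
        if self.n_connectivity_tested == 0:
            return None
        return round_percent(self.n_connected, self.n_connectivity_tested)

    @property
    def pct_suppressed(self) -> Optional[int]:
        if self.n_suppression_tested == 0:
            return None
        return round_percent(self.n_suppressed, self.n_suppression_tested)

    def to_row(self) -> dict:
        amp = self.amplitude_stats_na or {}
        lat = self.latency_stats_ms or {}
        return {
            "circuit": self.circuit,
            "n_connectivity_tested": self.n_connectivity_tested,
            "n_connected": self.n_connected,
            "pct_connected": self.pct_connected,
            "n_suppression_tested": self.n_suppression_tested,
            "n_suppressed": self.n_suppressed,
            "pct_suppressed": self.pct_suppressed,
            "amplitude_mean_na": amp.get("mean"),
            "amplitude_sd_na": amp.get("sd"),
            "amplitude_min_na": amp.get("min"),
            "amplitude_max_na": amp.get("max"),
            "latency_mean_ms": lat.get("mean"),
            "latency_sd_ms": lat.get("sd"),
            "latency_min_ms": lat.get("min"),
            "latency_max_ms": lat.get("max"),
        }


@dataclass
class ComparisonResult:
    """One statistical comparison, with its FDR-adjusted discovery flag."""

    test: str
    statistic: float
    p_value: float
    groups: tuple = ()
    discovered: Optional[bool] = None

    COLUMNS = ("test", "groups", "statistic", "p_value", "discovered")

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    def to_row(self) -> dict:
        return {
            "test": self.test,
            "groups": "|".join(map(str, self.groups)),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "discovered": self.discovered,
        }


def _stats_dict(values: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def summarize_cohort(results: Sequence, circuit: Optional[str] = None) -> CohortSummary:
    """Summarize per-cell results (QC-passed cells) for one circuit.

    ``results`` are CellResult-like objects; cells with ``connected`` (or
    ``suppressed``) set to None did not undergo that assay and are not
    counted in the corresponding denominator.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot summarize an empty cohort")
    if circuit is None:
        circuit = results[0].circuit
    conn_tested = [r for r in results if r.connected is not None]
    connected = [r for r in conn_tested if r.connected]
    supp_tested = [r for r in results if r.suppressed is not None]
    suppressed = [r for r in supp_tested if r.suppressed]
    amps = np.asarray([r.mean_amplitude_pa for r in connected
                       if r.mean_amplitude_pa is not None]) / 1000.0  # pA -> nA
    lats = np.asarray([r.mean_latency_ms for r in connected
                       if r.mean_latency_ms is not None])
    return CohortSummary(
        circuit=circuit,
        n_connectivity_tested=len(conn_tested),
        n_connected=len(connected),
        n_suppression_tested=len(supp_tested),
        n_suppressed=len(suppressed),
        amplitude_stats_na=_stats_dict(amps) if amps.size else None,
        latency_stats_ms=_stats_dict(lats) if lats.size else None,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]], labels: tuple = ()) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected) across two or more groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        # degenerate: every observation identical; no evidence of any difference
        return ComparisonResult("kruskal_wallis", 0.0, 1.0, tuple(labels))
    h, p = stats.kruskal(*arrays)
    return ComparisonResult("kruskal_wallis", float(h), float(p), tuple(labels))


def _bh_rejections(p: np.ndarray, level: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejections at the given level."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = level * np.arange(1, m + 1) / m
    below = p[order] <= thresholds
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        reject[order[:k + 1]] = True
    return reject


def bky_two_stage_fdr(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Krieger-Yekutieli two-stage step-up FDR control.

    Stage 1 runs Benjamini-Hochberg at q' = q/(1+q) to estimate the number
    of true null hypotheses m0 = m - r1; stage 2 reruns BH at level
    q' * m / m0. Returns a boolean discovery flag per hypothesis.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q_prime = q / (1.0 + q)
    stage1 = _bh_rejections(p, q_prime)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(p.size, dtype=bool)
    if r1 == p.size:
        return np.ones(p.size, dtype=bool)
    m0 = p.size - r1
    return _bh_rejections(p, q_prime * p.size / m0)


def pairwise_rank_comparisons(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str],
    q: float = 0.05,
) -> list[ComparisonResult]:
    """Post-hoc pairwise Mann-Whitney tests with BKY-adjusted discoveries."""
    if len(groups) != len(labels):
        raise ValueError("labels must match groups")
    comparisons = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(groups), 2):
        u, p = stats.mannwhitneyu(gi, gj, alternative="two-sided")
        comparisons.append(ComparisonResult(
            "mann_whitney", float(u), float(p), (labels[i], labels[j])))
    flags = bky_two_stage_fdr([c.p_value for c in comparisons], q=q)
    for c, f in zip(comparisons, flags):
        c.discovered = bool(f)
    return comparisons


@dataclass
class LocationRegressionResult:
    """Logistic regression of connection probability on soma location."""

    coefficients: dict      # const, ap_mm, ml_mm, dv_mm -> log-odds slope per mm
    p_values: dict          # Wald p per coefficient (NaN under separation)
    llr_p_value: float      # likelihood-ratio test against the intercept-only model
    n_cells: int
    separated: bool = False


def location_connection_regression(
    locations_mm: np.ndarray,
    connected: Sequence[bool],
) -> LocationRegressionResult:
    """Fit P(connected) ~ logistic(AP, ML, DV).

    The binary outcome makes this the two-class case of a multinomial
    model. Complete or quasi-complete separation (likely in small
    cohorts) is flagged and handled by a small ridge penalty; Wald
    p-values are not reported in that case.
    """
    X = np.asarray(locations_mm, dtype=float)
    y = np.asarray(connected, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("locations must be an (n, 3) array of AP/ML/DV in mm")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 cells")
    if y.min() == y.max():
        raise ValueError("both connected and unconnected cells are required")
    names = ["const", "ap_mm", "ml_mm", "dv_mm"]
    Xc = sm.add_constant(X)
    model = sm.Logit(y, Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            res = model.fit(disp=False)
        if not res.mle_retvals.get("converged", True) or np.any(np.abs(res.params) > 50):
            raise PerfectSeparationError("implausible coefficients")
        return LocationRegressionResult(
            coefficients=dict(zip(names, map(float, res.params))),
            p_values=dict(zip(names, map(float, res.pvalues))),
            llr_p_value=float(res.llr_pvalue),
            n_cells=X.shape[0],
        )
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning, Exception) as err:
        if not isinstance(err, (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning)):
            # statsmodels wraps separation in several exception types
            if "Singular" not in str(err) and "separation" not in str(err).lower():
                raise
        warnings.warn("separation detected; fitting with a small ridge penalty",
                      stacklevel=2)
        glm = sm.GLM(y, Xc, family=sm.families.Binomial())
        res = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
        nan = float("nan")
        return LocationRegressionResult(
            coefficients=dict(zip(names, map(float, res.params))),
            p_values={k: nan for k in names},
            llr_p_value=nan,
            n_cells=X.shape[0],
            separated=True,
        )
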