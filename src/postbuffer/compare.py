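"""Comparative analysis between the two exposure methods.

Per land-cover class the two methods' per-unit percentage vectors are
compared with a two-sample Kolmogorov-Smirnov test (distributional
difference), Kendall's tau-b (rank correlation robust to the many tied zeros
typical of habitat covers), and — stratified by unit size class, region, and
urban/rural status — the Mann-Whitney U test (directional location shift).
Differences are always reported as typical − proposed.

Unit size classes are logarithmically spaced area bins; the default edges
[0.5, 5, 50] km² yield four classes, with the smallest (< 0.5 km²) split off
because most units fall there.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .geodata import ExposureTable, ParameterError, StatUnit

logger = logging.getLogger(__name__)

DEFAULT_SIZE_CLASS_EDGES_KM2 = (0.5, 5.0, 50.0)

SIGNIFICANCE_THRESHOLDS = (0.05, 0.01, 0.001)


def significance_stars(p: float) -> str:
    """Conventional star coding: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Size classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeClassScheme:
    """Half-open, lower-inclusive area bins partitioning (0, inf) km²."""

    edges_km2: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES_KM2

    def __post_init__(self) -> None:
        edges = self.edges_km2
        if not edges or any(e <= 0 for e in edges):
            raise ParameterError("size-class edges must be positive")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ParameterError("size-class edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        edges = self.edges_km2
        out = [f"<{edges[0]:g}"]
        out += [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
        out.append(f">={edges[-1]:g}")
        return out


def assign_size_class(area_km2: float, scheme: SizeClassScheme | None = None) -> str:
    """Label of the half-open interval [lower, upper) containing ``area_km2``."""
    if scheme is None:
        scheme = SizeClassScheme()
    if area_km2 <= 0:
        raise ParameterError(f"area must be > 0, got {area_km2}")
    labels = scheme.labels
    for i, edge in enumerate(scheme.edges_km2):
        if area_km2 < edge:
            return labels[i]
    return labels[-1]


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: D = sup |ECDF_a − ECDF_b| with the
    asymptotic two-sided p-value."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("ks_two_sample: both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def kendall_tau_b(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with normal-approximation p-value.

    Zero variance in either vector leaves tau undefined; (nan, nan) is
    returned and a warning logged.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size != b.size:
        raise ParameterError("kendall_tau_b: length mismatch")
    if a.size < 2:
        raise ParameterError("kendall_tau_b: need at least 2 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        logger.warning("kendall_tau_b: zero variance; tau undefined")
        return (math.nan, math.nan)
    if a.size == 2:
        # single pair: tau is ±1; no meaningful p-value at n = 2
        tau = 1.0 if (a[1] - a[0]) * (b[1] - b[0]) > 0 else -1.0
        return tau, math.nan
    res = stats.kendalltau(a, b, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(
    a: Sequence[float], b: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U = #{a_i > b_j} + ½·#{a_i = b_j}).

    ``method='asymptotic'`` uses the tie-corrected normal approximation;
    ``method='exact'`` uses permutation enumeration (small samples only —
    feasible up to roughly 15 per group; larger exact requests fall back
    to a seeded randomized permutation test).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("mann_whitney: both samples must be non-empty")
    if method == "asymptotic":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        def u_stat(x, y):
            return stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).statistic

        res = stats.permutation_test(
            (a, b),
            u_stat,
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=200_000,
            rng=np.random.default_rng(0),
        )
        u = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").statistic
        return float(u), float(res.pvalue)
    raise ParameterError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------


@dataclass
class ClassStats:
    ks_stat: float
    ks_p: float
    tau: float
    tau_p: float
    n: int


@dataclass
class StratumStats:
    mwu_stat: float
    mwu_p: float
    median_diff: float  # median of (typical − proposed) within the stratum
    n: int


@dataclass
class ComparisonReport:
    """Per-class tests, stratified location tests, and per-unit differences
    (always typical − proposed)."""

    per_class: dict[str, ClassStats]
    stratified: dict[tuple[str, str, str], StratumStats]
    difference: dict[str, dict[str, float]]
    classes: list[str] = field(default_factory=list)


def build_report(
    proposed: ExposureTable,
    typical: ExposureTable,
    units: Sequence[StatUnit],
    scheme: SizeClassScheme | None = None,
) -> ComparisonReport:
    """Run the full comparative suite over the units common to both tables."""
    if scheme is None:
        scheme = SizeClassScheme()
    unit_by_id = {u.unit_id: u for u in units}
    common = sorted(
        (set(proposed.rows) & set(typical.rows)) & set(unit_by_id)
    )
    dropped = (set(proposed.rows) | set(typical.rows)) - set(common)
    if dropped:
        logger.info("build_report: %d units not common to both tables", len(dropped))
    if not common:
        raise ParameterError("build_report: no common non-missing units")

    classes = [c for c in proposed.class_catalogue if c in typical.class_catalogue]

    p_mat = {c: np.array([proposed.rows[u].get(c, 0.0) for u in common]) for c in classes}
    t_mat = {c: np.array([typical.rows[u].get(c, 0.0) for u in common]) for c in classes}

    per_class: dict[str, ClassStats] = {}
    for c in classes:
        ks_d, ks_p = ks_two_sample(t_mat[c], p_mat[c])
        if len(common) >= 2:
            tau, tau_p = kendall_tau_b(t_mat[c], p_mat[c])
        else:
            tau, tau_p = math.nan, math.nan
        per_class[c] = ClassStats(ks_d, ks_p, tau, tau_p, len(common))

    difference = {
        u: {c: t_mat[c][i] - p_mat[c][i] for c in classes}
        for i, u in enumerate(common)
    }

    strata: dict[tuple[str, str], list[int]] = {}
    for i, u in enumerate(common):
        unit = unit_by_id[u]
        for kind, value in (
            ("size_class", assign_size_class(unit.area_km2, scheme)),
            ("region", unit.region),
            ("urban_rural", unit.urban_rural),
        ):
            strata.setdefault((kind, value), []).append(i)

    stratified: dict[tuple[str, str, str], StratumStats] = {}
    for (kind, value), idx in sorted(strata.items()):
        idx_arr = np.asarray(idx)
        for c in classes:
            t_vec, p_vec = t_mat[c][idx_arr], p_mat[c][idx_arr]
            u_stat, p_val = mann_whitney(t_vec, p_vec)
            stratified[(kind, value, c)] = StratumStats(
                u_stat, p_val, float(np.median(t_vec - p_vec)), len(idx)
            )

    return ComparisonReport(per_class, stratified, difference, classes)


def write_report(report: ComparisonReport, outdir: str | Path) -> None:
    """Persist the report as three CSVs: per-class stats, stratified stats,
    per-unit differences."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "per_class.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "n", "ks_stat", "ks_p", "tau", "tau_p", "tau_stars"])
        for c in report.classes:
            s = report.per_class[c]
            w.writerow([c, s.n, f"{s.ks_stat:.6f}", f"{s.ks_p:.6g}",
                        f"{s.tau:.6f}", f"{s.tau_p:.6g}",
                        significance_stars(s.tau_p) if not math.isnan(s.tau_p) else ""])
    with open(outdir / "stratified.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["stratum_kind", "stratum", "class", "n",
                    "mwu_stat", "mwu_p", "stars", "median_diff"])
        for (kind, value, c), s in sorted(report.stratified.items()):
            w.writerow([kind, value, c, s.n, f"{s.mwu_stat:.6f}",
                        f"{s.mwu_p:.6g}", significance_stars(s.mwu_p),
                        f"{s.median_diff:.6f}"])
    with open(outdir / "differences.csv", "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["unit_id", *report.classes])
        for uid in sorted(report.difference):
            row = report.difference[uid]
            w.writerow([uid, *[f"{row[c]:.6f}" for c in report.classes]])


# ---------------------------------------------------------------------------
# GAM smoother (visual aid for method-vs-method scatter)
# ---------------------------------------------------------------------------


def gam_smooth_curve(
    x: Sequence[float],
    y: Sequence[float],
    basis_dim: int = 10,
    alpha: float = 1.0,
    grid: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalized B-spline smoother for visualising the relationship between
    the two methods' values.

    The penalty acts on curvature, so exactly linear data are reproduced
    exactly regardless of ``alpha``.  Returns (grid, fitted values).

    Gaussian identity-link smoothing has a closed-form penalized
    least-squares solution, so the fit solves (X'X + alpha*S) beta = X'y
    directly on the statsmodels B-spline basis and its curvature penalty.
    """
    from statsmodels.gam.smooth_basis import BSplines

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ParameterError("gam_smooth_curve: length mismatch")
    if x.size < basis_dim + 1:
        raise ParameterError(
            f"gam_smooth_curve: need at least basis_dim+1={basis_dim + 1} points"
        )
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    bs = BSplines(xs[:, None], df=[basis_dim], degree=[3],
                  include_intercept=True)
    design = bs.basis
    penalty = bs.penalty_matrices[0]
    lhs = design.T @ design + alpha * penalty
    beta = np.linalg.solve(lhs, design.T @ ys)
    if grid is None:
        grid = np.linspace(xs.min(), xs.max(), 200)
    grid = np.asarray(grid, float)
    fitted = bs.transform(grid[:, None]) @ beta
    return grid, np.asarray(fitted, float)
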