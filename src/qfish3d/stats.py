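"""Distribution modeling and hierarchical hypothesis testing.

Per-telomere features are grouped by cell and condition (e.g. cell
cycle phase).  Pooling the spots of many cells and applying an
ordinary t-test treats correlated spots as independent observations
(pseudo-replication) and yields spuriously small p-values; the nested
tests here treat the condition as a fixed effect and the cell as a
random grouping factor, testing the condition mean square against the
between-cell mean square.

Brightness-like features follow lognormal distributions, so they are
log10-transformed before testing and effects are reported as percent
changes of geometric means.  Frequency distributions are modeled by

    Gaussian:   Y = A * exp(-0.5 * ((X - mu) / sigma)^2)
    lognormal:  Y = (A / X) * exp(-0.5 * (ln(X / GeoMean) / ln(GeoSD))^2)

fitted to Scott's-rule histograms, and pairs of datasets are compared
with the extra-sum-of-squares F test (can one shared curve describe
both histograms?).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit, least_squares

__all__ = [
    "GaussianHistFit",
    "LognormalHistFit",
    "NestedTestResult",
    "fit_histogram",
    "compare_fits_f_test",
    "nested_test",
    "pooled_t_test",
    "summarize_cells",
    "detection_coverage",
]


@dataclass
class GaussianHistFit:
    A: float
    mu: float
    sigma: float
    r2: float


@dataclass
class LognormalHistFit:
    A: float
    geo_mean: float
    geo_sd: float
    r2: float


@dataclass
class NestedTestResult:
    """Result of the two-level nested comparison.

    ``p_group`` tests the condition effect against between-cell
    variation; ``p_cells`` tests between-cell variation within
    condition against the within-cell residual.  ``effect_pct`` is the
    percent change of the second condition relative to the first
    (geometric means when ``transform='log10'``).
    """

    p_group: float
    p_cells: float
    df_num: float
    df_den: float
    effect_pct: Optional[float]
    transform: str
    f_group: float
    f_cells: float


def _gauss_model(x: np.ndarray, A: float, mu: float, sigma: float) -> np.ndarray:
    return A * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _lognorm_model(x: np.ndarray, A: float, gm: float, gsd: float) -> np.ndarray:
    return (A / x) * np.exp(-0.5 * (np.log(x / gm) / np.log(gsd)) ** 2)


def _histogram(values: np.ndarray, bins=None) -> tuple[np.ndarray, np.ndarray]:
    counts, edges = np.histogram(values, bins=bins if bins is not None else "scott")
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def _fit_curve(model, x, y, p0, lb, ub, robust: bool):
    if robust:
        def resid(p):
            return model(x, *p) - y

        sol = least_squares(
            resid, p0, bounds=(lb, ub), loss="soft_l1", f_scale=1.0, max_nfev=5000
        )
        if not sol.success:
            raise RuntimeError("robust histogram fit did not converge")
        popt = sol.x
    else:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=(lb, ub), maxfev=5000)
    ss_res = float(np.sum((y - model(x, *popt)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return popt, r2, ss_res


def fit_histogram(
    values: Sequence[float],
    model: str = "gaussian",
    robust: bool = False,
    bins=None,
):
    """Fit a Gaussian or lognormal curve to the value histogram.

    Scott's-rule binning, bin centers as X.  ``robust=True`` uses a
    soft-L1 loss (scale 1) on the bin-count residuals; the default is
    plain least squares.  Requires >= 20 values; lognormal additionally
    requires all values positive.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 values for a histogram fit")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: zero-width histogram")
    centers, counts = _histogram(x, bins)
    if model == "gaussian":
        p0 = (counts.max(), float(x.mean()), float(x.std(ddof=1)))
        popt, r2, _ = _fit_curve(
            _gauss_model, centers, counts, p0, [0, -np.inf, 1e-12], [np.inf, np.inf, np.inf], robust
        )
        return GaussianHistFit(float(popt[0]), float(popt[1]), float(abs(popt[2])), r2)
    if model == "lognormal":
        if x.min() <= 0:
            raise ValueError("lognormal fit requires all values > 0")
        logs = np.log(x)
        gm0, gsd0 = float(np.exp(logs.mean())), float(np.exp(max(logs.std(ddof=1), 1e-6)))
        A0 = counts.max() * gm0
        popt, r2, _ = _fit_curve(
            _lognorm_model,
            centers,
            counts,
            (A0, gm0, max(gsd0, 1.0 + 1e-6)),
            [0, 1e-12, 1.0 + 1e-9],
            [np.inf, np.inf, np.inf],
            robust,
        )
        return LognormalHistFit(float(popt[0]), float(popt[1]), float(popt[2]), r2)
    raise ValueError(f"unknown model {model!r}")


def compare_fits_f_test(
    data_a: Sequence[float],
    data_b: Sequence[float],
    model: str = "lognormal",
    robust: bool = False,
) -> float:
    """Extra-sum-of-squares F test on two histogram fits.

    Both datasets are binned on a common Scott's-rule grid (computed
    from the pooled values).  The null model fits one shared parameter
    set to both histograms; the alternative fits each separately.

        F = ((SS_shared - SS_sep) / (df_shared - df_sep)) / (SS_sep / df_sep)

    Returns the p-value from the F distribution; identical datasets
    give p = 1.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    pooled = np.concatenate([a, b])
    _, edges = np.histogram(pooled, bins="scott")
    xs, ys = [], []
    for d in (a, b):
        c, cnt = _histogram(d, bins=edges)
        xs.append(c)
        ys.append(cnt)
    # restrict the fit to populated bins: sparse tail bins have tiny
    # Poisson variance and miscalibrate the unweighted F statistic
    keep = (ys[0] + ys[1]) >= 5
    xs = [x[keep] for x in xs]
    ys = [y[keep] for y in ys]
    mdl = _gauss_model if model == "gaussian" else _lognorm_model

    def seed(d, counts):
        if model == "gaussian":
            return (counts.max(), float(d.mean()), float(d.std(ddof=1))), [0, -np.inf, 1e-12]
        logs = np.log(d)
        gm = float(np.exp(logs.mean()))
        gsd = float(np.exp(max(logs.std(ddof=1), 1e-6)))
        return (counts.max() * gm, gm, max(gsd, 1 + 1e-6)), [0, 1e-12, 1.0 + 1e-9]

    k = 3
    ss_sep = 0.0
    for d, x, y in zip((a, b), xs, ys):
        p0, lb = seed(d, y)
        _, _, ss = _fit_curve(mdl, x, y, p0, lb, [np.inf] * k, robust)
        ss_sep += ss
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    p0, lb = seed(pooled, np.concatenate(ys))
    _, _, ss_shared = _fit_curve(mdl, x_all, y_all, p0, lb, [np.inf] * k, robust)
    n_points = x_all.size
    df_sep = n_points - 2 * k
    df_shared = n_points - k
    if df_sep <= 0:
        raise ValueError("too few histogram bins for the F test")
    ss_shared = max(ss_shared, ss_sep)  # shared model can never beat separate fits
    f = ((ss_shared - ss_sep) / (df_shared - df_sep)) / (ss_sep / df_sep) if ss_sep > 0 else np.inf
    if ss_sep == 0.0 and ss_shared == ss_sep:
        return 1.0
    return float(sps.f.sf(f, df_shared - df_sep, df_sep))


def nested_test(
    cells_by_condition: Mapping[str, Sequence[Sequence[float]]],
    transform: str = "log10",
) -> NestedTestResult:
    """Two-level nested (hierarchical) comparison of conditions.

    ``cells_by_condition`` maps each condition label to a list of
    per-cell value arrays.  The condition is a fixed effect and the
    cell a random effect within condition; the test is formulated
    through expected mean squares with a Satterthwaite-synthesized
    denominator for unequal spot counts per cell.  With ``log10`` the
    values are transformed first (lognormal features), and the effect
    is the percent change of geometric means.

    A condition with a single cell raises: spots within a cell are not
    independent replicates, and testing them as such produces falsely
    low p-values (pseudo-replication).
    """
    labels = list(cells_by_condition.keys())
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    groups: list[list[np.ndarray]] = []
    for lab in labels:
        cells = [np.asarray(c, dtype=float) for c in cells_by_condition[lab]]
        if len(cells) < 2:
            raise ValueError(
                f"condition {lab!r} has a single cell: spots within one cell are "
                "pseudo-replicates and cannot support a between-condition test"
            )
        for c in cells:
            if c.size < 2:
                raise ValueError("each cell needs at least 2 values")
        if transform == "log10":
            if any(np.any(c <= 0) for c in cells):
                raise ValueError("log10 transform requires strictly positive values")
            cells = [np.log10(c) for c in cells]
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        groups.append(cells)

    g = len(groups)
    cell_ns = [np.array([c.size for c in cells]) for cells in groups]
    cell_means = [np.array([c.mean() for c in cells]) for cells in groups]
    N_i = np.array([ns.sum() for ns in cell_ns], dtype=float)
    N = float(N_i.sum())
    C = int(sum(len(cells) for cells in groups))
    grand = sum(float(np.concatenate(cells).sum()) for cells in groups) / N
    group_means = np.array(
        [float(np.concatenate(cells).sum()) / n for cells, n in zip(groups, N_i)]
    )

    ss_group = float(np.sum(N_i * (group_means - grand) ** 2))
    ss_cells = 0.0
    ss_within = 0.0
    for cells, ns, means, gm in zip(groups, cell_ns, cell_means, group_means):
        ss_cells += float(np.sum(ns * (means - gm) ** 2))
        for c, m in zip(cells, means):
            ss_within += float(np.sum((c - m) ** 2))

    df_group = g - 1
    df_cells = C - g
    df_within = int(N) - C
    ms_group = ss_group / df_group
    ms_cells = ss_cells / df_cells if df_cells > 0 else 0.0
    ms_within = ss_within / df_within if df_within > 0 else 0.0

    # EMS coefficients of the random cell effect (unbalanced design)
    sum_n2_over_Ni = float(sum((ns**2).sum() / n for ns, n in zip(cell_ns, N_i)))
    sum_n2 = float(sum((ns**2).sum() for ns in cell_ns))
    k2 = (N - sum_n2_over_Ni) / df_cells if df_cells > 0 else 1.0
    k1 = (sum_n2_over_Ni - sum_n2 / N) / df_group

    # Satterthwaite-synthesized denominator matching E[MS_group] under H0
    a = k1 / k2 if k2 > 0 else 1.0
    ms_den = a * ms_cells + (1.0 - a) * ms_within
    if ms_den > 0:
        df_den = ms_den**2 / (
            (a * ms_cells) ** 2 / df_cells + ((1.0 - a) * ms_within) ** 2 / max(df_within, 1)
        )
    else:
        df_den = float(df_cells)

    if ms_den <= 0:
        f_group = 0.0 if ms_group <= 0 else np.inf
        p_group = 1.0 if ms_group <= 0 else 0.0
    else:
        f_group = ms_group / ms_den
        p_group = float(sps.f.sf(f_group, df_group, df_den))
    if ms_within <= 0:
        f_cells = 0.0 if ms_cells <= 0 else np.inf
        p_cells = 1.0 if ms_cells <= 0 else 0.0
    else:
        f_cells = ms_cells / ms_within
        p_cells = float(sps.f.sf(f_cells, df_cells, df_within))

    effect_pct: Optional[float] = None
    if g == 2:
        # condition estimate: unweighted mean of cell means (cells are
        # the experimental units)
        m_a = float(cell_means[0].mean())
        m_b = float(cell_means[1].mean())
        if transform == "log10":
            effect_pct = 100.0 * (10.0 ** (m_b - m_a) - 1.0)
        else:
            effect_pct = 100.0 * (m_b - m_a) / m_a if m_a != 0 else None

    return NestedTestResult(
        p_group=p_group,
        p_cells=p_cells,
        df_num=float(df_group),
        df_den=float(df_den),
        effect_pct=effect_pct,
        transform=transform,
        f_group=float(f_group),
        f_cells=float(f_cells),
    )


def pooled_t_test(
    cells_by_condition: Mapping[str, Sequence[Sequence[float]]],
    transform: str = "log10",
) -> float:
    """Naive pooled two-sample t-test (all spots treated as independent).

    Provided for comparison only: it ignores the cell grouping and is
    anti-conservative whenever cells differ (pseudo-replication).
    """
    labels = list(cells_by_condition.keys())
    if len(labels) != 2:
        raise ValueError("pooled t-test requires exactly 2 conditions")
    pools = []
    for lab in labels:
        vals = np.concatenate([np.asarray(c, dtype=float) for c in cells_by_condition[lab]])
        if transform == "log10":
            vals = np.log10(vals)
        pools.append(vals)
    return float(sps.ttest_ind(pools[0], pools[1]).pvalue)


def _geomean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def detection_coverage(mean_count: float, expected_count: float) -> float:
    """Detected fraction of the expected telomere complement, percent."""
    if expected_count <= 0:
        raise ValueError("expected_count must be > 0")
    return 100.0 * mean_count / expected_count


def summarize_cells(
    records: Sequence,
    expected_counts: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-condition summary of cell records.

    Counts, brightness and FWHM are computed over non-rejected spots.
    Brightness and density are summarized by geometric means (lognormal
    features).  When ``expected_counts`` supplies the anticipated
    telomere number per phase, the detection coverage (percent) is
    reported.
    """
    if not records:
        raise ValueError("no records supplied")
    rows = []
    by_phase: dict[str, list] = {}
    for rec in records:
        by_phase.setdefault(rec.phase, []).append(rec)
    for phase, recs in by_phase.items():
        counts = np.array(
            [sum(1 for f in r.features if f.quality_flag != "rejected") for r in recs],
            dtype=float,
        )
        feats = [f for r in recs for f in r.features if f.quality_flag != "rejected"]
        fwhms = [f.fwhm_x_nm for f in feats if f.fwhm_x_nm is not None]
        fwhms += [f.fwhm_y_nm for f in feats if f.fwhm_y_nm is not None]
        bright = np.array(
            [f.brightness_peak for f in feats if f.brightness_peak and f.brightness_peak > 0]
        )
        dens = np.array(
            [f.signal_density for f in feats if f.signal_density and f.signal_density > 0]
        )
        row = {
            "phase": phase,
            "n_cells": len(recs),
            "mean_count": float(counts.mean()),
            "sd_count": float(counts.std(ddof=1)) if counts.size > 1 else None,
            "cv_count_pct": (
                100.0 * float(counts.std(ddof=1) / counts.mean())
                if counts.size > 1 and counts.mean() > 0
                else None
            ),
            "mean_fwhm_nm": float(np.mean(fwhms)) if fwhms else None,
            "geomean_brightness": _geomean(bright) if bright.size else None,
            "geomean_density": _geomean(dens) if dens.size else None,
        }
        if expected_counts and phase in expected_counts:
            row["coverage_pct"] = detection_coverage(row["mean_count"], expected_counts[phase])
        else:
            row["coverage_pct"] = None
        rows.append(row)
    return pd.DataFrame(rows).set_index("phase")
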