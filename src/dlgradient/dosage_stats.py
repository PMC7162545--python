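"""Dosage-response statistics for gradient and gene-expression measurements.

Covers the quantification layer around the models: best-fit slopes of
log-log dosage plots (empirical sensitivity coefficients with a 68%
confidence interval, i.e. +/- one standard error), inverse-variance weighted
qPCR delta-CT statistics and fold-change estimates, the canonical nuclear
cycle 14 amplitude curve from live-embryo traces, bootstrap distributions of
amplitude ratios between genotypes, and the least-squares search for the
1x/4x gradient amplitudes that best explain the observed (robust) borders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .borders import BorderObservation, extract_border_many

__all__ = [
    "DosageSeries",
    "AmplitudeTrace",
    "SlopeResult",
    "loglog_sensitivity",
    "qpcr_weighted_stats",
    "relative_abundance",
    "canonical_amplitude_curve",
    "bootstrap_amplitude_ratios",
    "normal_range_probability",
    "optimize_amplitude_pair",
]


@dataclass(frozen=True)
class DosageSeries:
    """Per-embryo measurements grouped by dosage multiplier."""

    measurements: Mapping[float, np.ndarray]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.measurements):
            raise ValueError("dosages must be positive")
        if any(len(np.atleast_1d(v)) < 1 for v in self.measurements.values()):
            raise ValueError("need >= 1 measurement per dosage")


@dataclass(frozen=True)
class SlopeResult:
    slope: float
    ci68: float  # +/- one standard error of the slope
    n: int


def loglog_sensitivity(series: DosageSeries) -> SlopeResult:
    """OLS slope of ln(measurement) on ln(dosage) over individual embryos.

    The slope estimates the dosage-sensitivity coefficient; the 68%
    confidence interval equals one standard error.  Non-positive
    measurements cannot be logged and are excluded with a warning.
    """
    xs, ys = [], []
    for dose, vals in series.measurements.items():
        vals = np.atleast_1d(np.asarray(vals, float))
        bad = vals <= 0
        if bad.any():
            warnings.warn(
                f"excluding {bad.sum()} non-positive measurement(s) at dosage {dose}"
            )
            vals = vals[~bad]
        xs.extend([np.log(dose)] * vals.size)
        ys.extend(np.log(vals))
    if len(set(xs)) < 2:
        raise ValueError("need measurements at >= 2 distinct dosages")
    res = sps.linregress(xs, ys)
    se = res.stderr if np.isfinite(res.stderr) else 0.0
    return SlopeResult(slope=float(res.slope), ci68=float(se), n=len(xs))


# ---------------------------------------------------------------------------
# qPCR


def qpcr_weighted_stats(
    table: pd.DataFrame,
    method: str = "paper",
    max_inverse_sd: float = 1e6,
) -> pd.DataFrame:
    """Per-genotype weighted mean and weighted s.e.m. of delta-CT values.

    ``table`` has columns genotype, replicate (a run/biological-replicate
    label), delta_ct.  Replicates with fewer than two valid technical
    delta-CT values are discarded.  Per retained replicate i of genotype g,
    y_ig is the mean of the technical values and s_ig their standard
    deviation; weights are w_ig = (1/s_ig) / sum_j (1/s_jg).

    method='paper' uses

        S_g = sqrt( [1/(n-1)] sum_i w_ig (y_ig - ybar_g)^2 / [(1/n) sum_i w_ig] )

    (the weights sum to one, so this is sqrt(n/(n-1) * sum w (y-ybar)^2)).
    method='conventional' replaces the n/(n-1) scaling with 1/(n-1), the
    usual weighted-variance-of-the-mean form, for comparison.  Zero s_ig
    would give infinite weight; 1/s is capped at ``max_inverse_sd``.

    Returns a frame indexed by genotype with columns weighted_mean,
    weighted_sem (NaN when n < 2), n_replicates.
    """
    if method not in ("paper", "conventional"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for (g, rep), grp in table.groupby(["genotype", "replicate"]):
        vals = grp["delta_ct"].dropna().to_numpy(float)
        if vals.size < 2:
            continue  # fewer than two valid technical replicates: discard
        rows.append({"genotype": g, "y": vals.mean(), "s": vals.std(ddof=1)})
    columns = ["genotype", "weighted_mean", "weighted_sem", "n_replicates"]
    if not rows:
        return pd.DataFrame(columns=columns).set_index("genotype")
    per_rep = pd.DataFrame(rows)
    out = []
    for g, grp in per_rep.groupby("genotype"):
        y = grp["y"].to_numpy()
        s = grp["s"].to_numpy()
        n = y.size
        inv = np.minimum(np.divide(1.0, s, out=np.full_like(s, np.inf), where=s > 0),
                         max_inverse_sd)
        w = inv / inv.sum()
        ybar = float(np.sum(w * y))
        if n < 2:
            sem = np.nan
        else:
            dev = float(np.sum(w * (y - ybar) ** 2))
            if method == "paper":
                sem = np.sqrt(dev / (n - 1) / (np.sum(w) / n))
            else:
                sem = np.sqrt(dev / (n - 1))
        out.append(
            {"genotype": g, "weighted_mean": ybar, "weighted_sem": sem,
             "n_replicates": n}
        )
    return pd.DataFrame(out).set_index("genotype")


def relative_abundance(
    stats_table: pd.DataFrame, reference: str = "2x"
) -> pd.DataFrame:
    """Fold-change abundance 2^(-(ybar_g - ybar_ref)) with propagated s.e.m.

    One qPCR cycle equals a factor of two; the first-order error propagation
    of the delta-delta-CT is fold * ln(2) * sqrt(S_g^2 + S_ref^2).
    """
    if reference not in stats_table.index:
        raise ValueError(f"reference genotype {reference!r} missing")
    ref_mean = stats_table.loc[reference, "weighted_mean"]
    ref_sem = stats_table.loc[reference, "weighted_sem"]
    rows = []
    for g, row in stats_table.iterrows():
        ddct = row["weighted_mean"] - ref_mean
        fold = 2.0 ** (-ddct)
        if g == reference:
            sem = fold * np.log(2) * ref_sem
        else:
            sem = fold * np.log(2) * np.sqrt(row["weighted_sem"] ** 2 + ref_sem**2)
        rows.append({"genotype": g, "fold": fold, "fold_sem": sem})
    return pd.DataFrame(rows).set_index("genotype")


# ---------------------------------------------------------------------------
# live-embryo amplitude dynamics


@dataclass
class AmplitudeTrace:
    """Gradient amplitude vs time for one live embryo.

    ``nc14_start`` and ``gastrulation`` are indices into ``times`` that
    demarcate nc14 interphase.
    """

    times: np.ndarray
    amplitude: np.ndarray
    nc14_start: int
    gastrulation: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.amplitude = np.asarray(self.amplitude, float)
        if not 0 <= self.nc14_start < self.gastrulation < self.times.size:
            raise ValueError("require 0 <= nc14_start < gastrulation < len(times)")

    @property
    def t_nc14(self) -> float:
        return float(self.times[self.gastrulation] - self.times[self.nc14_start])


def canonical_amplitude_curve(
    traces: Sequence[AmplitudeTrace], n_grid: int = 61
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build the canonical nc14 amplitude curve and per-embryo peaks.

    Each qualifying trace's nc14 window is normalized by its own maximum and
    its time axis stretched so nc14 lasts one hour; the curves are averaged
    on a common grid to give the canonical shape.  Each raw trace is then
    refit to the canonical curve by a least-squares scale factor, and the
    embryo's peak amplitude is that scale times the canonical maximum.

    Returns ``(tau_grid, canonical, peaks)`` with tau in [0, 1] hours.
    """
    tau = np.linspace(0.0, 1.0, n_grid)
    curves = []
    windows = []
    for tr in traces:
        sl = slice(tr.nc14_start, tr.gastrulation + 1)
        t = tr.times[sl]
        a = tr.amplitude[sl]
        if a.max() <= 0 or tr.t_nc14 <= 0:
            continue
        scaled_t = (t - t[0]) / tr.t_nc14  # stretch nc14 to one hour
        curves.append(np.interp(tau, scaled_t, a / a.max()))
        windows.append((scaled_t, a))
    if not curves:
        raise ValueError("no qualifying traces")
    canonical = np.mean(curves, axis=0)
    cmax = canonical.max()
    peaks = np.empty(len(windows))
    for i, (scaled_t, a) in enumerate(windows):
        c = np.interp(scaled_t, tau, canonical)
        scale = float(np.dot(a, c) / np.dot(c, c))
        peaks[i] = scale * cmax
    return tau, canonical, peaks


def bootstrap_amplitude_ratios(
    peaks_num: np.ndarray,
    peaks_den: np.ndarray,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Bootstrap distribution of the ratio of genotype mean amplitudes.

    Resamples each genotype's peak amplitudes with replacement and forms the
    ratio of resampled means, ``n_boot`` times.  Returns (mean, sd, samples).
    """
    num = np.atleast_1d(np.asarray(peaks_num, float))
    den = np.atleast_1d(np.asarray(peaks_den, float))
    if num.size < 2 or den.size < 2:
        raise ValueError("need >= 2 embryos per genotype")
    rng = np.random.default_rng(seed)
    nm = rng.choice(num, size=(n_boot, num.size), replace=True).mean(axis=1)
    dm = rng.choice(den, size=(n_boot, den.size), replace=True).mean(axis=1)
    ratios = nm / dm
    return float(ratios.mean()), float(ratios.std(ddof=1)), ratios


def normal_range_probability(
    mean: float, sd: float, lo: float, hi: float
) -> float:
    """P(lo < Z < hi) for Z ~ Normal(mean, sd)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if lo >= hi:
        raise ValueError("require lo < hi")
    return float(sps.norm.cdf(hi, mean, sd) - sps.norm.cdf(lo, mean, sd))


# ---------------------------------------------------------------------------
# best-fit 1x/4x amplitudes against observed borders


def optimize_amplitude_pair(
    avg_gradients: Mapping[str, tuple[np.ndarray, np.ndarray]],
    obs: Sequence[BorderObservation],
    alpha_range: tuple[float, float] = (0.25, 2.5),
    step: float = 0.01,
    not_expressed_x: float = 0.0,
):
    """Grid search for the 1x and 4x gradient amplitudes that best predict
    the observed borders, with the 2x amplitude fixed at one.

    Per-border thresholds are calibrated on the 2x mean curve at the 2x
    observed border.  For each candidate (alpha_1x, alpha_4x) on the grid,
    the predicted borders are the threshold crossings of the scaled 1x/4x
    curves, and the objective is the weighted SSE against the 1x and 4x
    observations.  Scaling a genotype's curve only affects that genotype's
    error, so the SSE surface separates into a sum of two 1-D profiles.

    Returns a dict with the minimizer, SSE surface, grid axes, and the
    infeasible-region mask (alpha_1x > 1 or alpha_4x < 1, which dosage
    cannot realistically produce).
    """
    alphas = np.arange(alpha_range[0], alpha_range[1] + step / 2, step)
    by_gene: dict[str, dict[str, BorderObservation]] = {}
    for o in obs:
        by_gene.setdefault(o.gene, {})[o.genotype] = o

    x2, c2 = (np.asarray(v, float) for v in avg_gradients["2x"])
    thetas = {}
    for gene, gobs in by_gene.items():
        if "2x" not in gobs:
            raise ValueError(f"no 2x observation for border {gene!r}")
        thetas[gene] = float(np.interp(gobs["2x"].x_exp, x2, c2))

    def genotype_errors(genotype: str) -> np.ndarray:
        x, c = (np.asarray(v, float) for v in avg_gradients[genotype])
        err = np.zeros_like(alphas)
        for gene, gobs in by_gene.items():
            if genotype not in gobs:
                continue
            o = gobs[genotype]
            # scaling the curve by alpha == dividing theta by alpha
            pos, expressed = extract_border_many(x, c, thetas[gene] / alphas)
            xm = np.where(expressed, pos, not_expressed_x)
            err += ((xm - o.x_exp) / o.sigma_exp) ** 2
        return err

    e1 = genotype_errors("1x")
    e4 = genotype_errors("4x")
    sse = e1[:, None] + e4[None, :]  # [alpha_1x, alpha_4x]
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    infeasible = (alphas[:, None] > 1.0) | (alphas[None, :] < 1.0)
    return {
        "alpha_1x": float(alphas[i]),
        "alpha_4x": float(alphas[j]),
        "sse_min": float(sse[i, j]),
        "alphas": alphas,
        "sse": sse,
        "infeasible": infeasible,
    }
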