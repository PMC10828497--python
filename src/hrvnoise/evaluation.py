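"""Monte Carlo noise-sensitivity evaluation of HRV parameters.

For each 5-min segment the ground-truth profile x is computed once; for each
(noise family, sigma) the beat times are perturbed and the profile
recomputed, giving the estimate x_hat.  Per segment and parameter the error
e = x_hat - x and the pair average a = (x_hat + x)/2 are recorded; cells are
then aggregated into

* systematic bias  Delta = mean(e),
* mean absolute error  MAE = mean(|e|),
* root-mean-square error  RMSE = sqrt(mean(e^2)),
* 5th/95th error percentiles,

and, across the sigma grid, a through-origin linear fit

    Delta(sigma) = alpha_bias / 100% * sigma * x_bar

(and likewise for MAE and RMSE) quantifies each parameter's relative noise
sensitivity in %/ms, normalized by the group mean x_bar of the ground
truth.  Two-sample Kolmogorov-Smirnov tests compare error distributions
between noise families, and Bland-Altman statistics assess whether the bias
depends on the true parameter value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Segment, Tachogram, sample_segments
from .metrics import PARAMETERS, hrv_profile
from .noise import NoiseSpec, perturb_beats

__all__ = [
    "RunConfig",
    "MonteCarloResult",
    "compute_error_records",
    "summarize_errors",
    "fit_linear_sensitivity",
    "ks_compare",
    "ks_table",
    "bland_altman",
    "required_sample_size",
    "convergence_table",
    "run_monte_carlo",
    "results_tables",
]

logger = logging.getLogger(__name__)

DEFAULT_SIGMA_GRID = tuple(float(s) for s in range(1, 11))
CONVERGENCE_THRESHOLD = 0.02
SAMPLE_CEILING = 15000


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one Monte Carlo sweep."""

    n_segments: int = 500
    window: float = 300.0
    families: tuple[str, ...] = ("gaussian",)
    sigma_grid: tuple[float, ...] = DEFAULT_SIGMA_GRID
    t_mode: str = "variance_matched"
    seed: int = 0
    params: tuple[str, ...] | None = None  # None -> all 34
    ks_sigmas: tuple[float, ...] = (5.0, 7.0)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAMETERS if self.params is None else self.params


@dataclass
class MonteCarloResult:
    """All tables produced by one sweep."""

    config: RunConfig
    records: pd.DataFrame          # per (parameter, segment, family, sigma)
    summary: pd.DataFrame          # bias/MAE/RMSE/percentiles per cell
    alpha: pd.DataFrame            # linear sensitivities per (parameter, family)
    ks: pd.DataFrame               # family-pair KS comparisons
    ba: pd.DataFrame               # Bland-Altman summary
    group_means: pd.Series         # ground-truth group mean per parameter
    clean_profiles: pd.DataFrame = field(default_factory=pd.DataFrame)


def compute_error_records(
    clean: pd.DataFrame,
    noisy: pd.DataFrame,
    family: str,
    sigma: float,
) -> pd.DataFrame:
    """Pair clean and noisy profile tables into tidy error records.

    Rows are (parameter, segment, family, sigma, truth, estimate, error,
    average); pairs where either side is a sentinel (NaN) are dropped and
    counted in ``DataFrame.attrs['n_sentinel']`` per parameter.
    """
    if len(clean) != len(noisy):
        raise ValueError("clean and noisy profile lists differ in length")
    frames = []
    n_sentinel: dict[str, int] = {}
    for p in clean.columns:
        x = clean[p].to_numpy(dtype=float)
        xh = noisy[p].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(xh)
        n_sentinel[p] = int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "parameter": p,
                    "segment": np.flatnonzero(ok),
                    "family": family,
                    "sigma": sigma,
                    "truth": x[ok],
                    "estimate": xh[ok],
                    "error": xh[ok] - x[ok],
                    "average": (xh[ok] + x[ok]) / 2.0,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records.attrs["n_sentinel"] = n_sentinel
    return records


def summarize_errors(records: pd.DataFrame) -> pd.DataFrame:
    """Bias, MAE, RMSE and 5th/95th error percentiles per
    (parameter, family, sigma) cell."""
    if records.empty:
        raise ValueError("no error records to summarize")

    def _cell(g: pd.DataFrame) -> pd.Series:
        e = g["error"].to_numpy()
        return pd.Series(
            {
                "bias": e.mean(),
                "mae": np.abs(e).mean(),
                "rmse": float(np.sqrt(np.mean(e * e))),
                "prc5": float(np.percentile(e, 5)),
                "prc95": float(np.percentile(e, 95)),
                "n_valid": len(e),
            }
        )

    out = (
        records.groupby(["parameter", "family", "sigma"], sort=False)
        .apply(_cell, include_groups=False)
        .reset_index()
    )
    out["n_valid"] = out["n_valid"].astype(int)
    sentinel = records.attrs.get("n_sentinel")
    if sentinel is not None:
        out["n_sentinel"] = out["parameter"].map(sentinel).astype(int)
    return out


def _through_origin(y: np.ndarray, z: np.ndarray) -> float:
    denom = float(np.dot(z, z))
    return float(np.dot(z, y) / denom) if denom > 0 else float("nan")


def _pearson(y: np.ndarray, sigma: np.ndarray) -> float:
    if np.std(y) == 0 or np.std(sigma) == 0:
        return float("nan")
    return float(np.corrcoef(y, sigma)[0, 1])


def fit_linear_sensitivity(
    summary: pd.DataFrame, group_means: pd.Series
) -> pd.DataFrame:
    """Normalized linear sensitivities alpha (%/ms) per (parameter, family).

    Each statistic (bias, MAE, RMSE) is regressed through the origin on
    sigma * x_bar / 100; the fit quality r is the Pearson correlation of
    the statistic with sigma.  The bias fit uses the signed group mean (so
    alpha_bias may be negative), while the MAE and RMSE fits normalize by
    |x_bar| and are therefore non-negative.  Parameters with x_bar = 0 are
    flagged NaN.
    """
    rows = []
    for (p, fam), g in summary.groupby(["parameter", "family"], sort=False):
        if len(g) < 3:
            raise ValueError(f"need >= 3 sigma levels for {p}/{fam}")
        x_bar = float(group_means[p])
        sigma = g["sigma"].to_numpy(dtype=float)
        row = {"parameter": p, "family": fam, "x_bar": x_bar}
        for stat in ("bias", "mae", "rmse"):
            scale = x_bar if stat == "bias" else abs(x_bar)
            z = sigma * scale / 100.0
            y = g[stat].to_numpy(dtype=float)
            alpha = _through_origin(y, z) if x_bar != 0 else float("nan")
            row[f"alpha_{stat}"] = alpha
            row[f"r_{stat}"] = _pearson(y, sigma)
        rows.append(row)
    return pd.DataFrame(rows)


def ks_compare(errors_a: np.ndarray, errors_b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and p-value."""
    errors_a = np.asarray(errors_a, dtype=float)
    errors_b = np.asarray(errors_b, dtype=float)
    if errors_a.size < 10 or errors_b.size < 10:
        raise ValueError("need at least 10 errors per sample")
    res = stats.ks_2samp(errors_a, errors_b)
    return float(res.statistic), float(res.pvalue)


def ks_table(
    records: pd.DataFrame,
    sigmas: tuple[float, ...],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """KS comparison of error distributions for every pair of noise
    families, per parameter and noise level."""
    families = sorted(records["family"].unique())
    rows = []
    for i, fam_a in enumerate(families):
        for fam_b in families[i + 1 :]:
            for sigma in sigmas:
                sub = records[records["sigma"] == sigma]
                for p, g in sub.groupby("parameter", sort=False):
                    ea = g.loc[g["family"] == fam_a, "error"].to_numpy()
                    eb = g.loc[g["family"] == fam_b, "error"].to_numpy()
                    if ea.size < 10 or eb.size < 10:
                        continue
                    d, pval = ks_compare(ea, eb)
                    rows.append(
                        {
                            "parameter": p,
                            "family_a": fam_a,
                            "family_b": fam_b,
                            "sigma": sigma,
                            "D": d,
                            "p_value": pval,
                            "significant": pval < alpha,
                        }
                    )
    return pd.DataFrame(rows)


def bland_altman(records: pd.DataFrame) -> pd.DataFrame:
    """Bland-Altman summary per parameter.

    For each parameter: Pearson correlation r between pair averages a and
    differences e (NaN when the differences are degenerate), the bias line
    Delta, and the 95% limits of agreement Delta +/- 1.96 SD(e).
    """
    rows = []
    for p, g in records.groupby("parameter", sort=False):
        if len(g) < 3:
            raise ValueError(f"need >= 3 records for {p}")
        a = g["average"].to_numpy()
        e = g["error"].to_numpy()
        sd = e.std(ddof=1)
        r = float("nan")
        if sd > 0 and a.std() > 0:
            r = float(np.corrcoef(a, e)[0, 1])
        bias = float(e.mean())
        rows.append(
            {
                "parameter": p,
                "r": r,
                "bias": bias,
                "loa_low": bias - 1.96 * sd,
                "loa_high": bias + 1.96 * sd,
                "n": len(g),
            }
        )
    return pd.DataFrame(rows)


def required_sample_size(
    mu_s: float,
    sigma_s: float,
    threshold: float = CONVERGENCE_THRESHOLD,
    ceiling: int = SAMPLE_CEILING,
) -> float:
    """Smallest n with normalized standard error 1.96 sigma_s/(sqrt(n) mu_s)
    strictly below ``threshold``, capped at ``ceiling``; NaN when mu_s = 0."""
    if sigma_s < 0:
        raise ValueError("sigma_s must be >= 0")
    if mu_s == 0:
        return float("nan")
    if sigma_s == 0:
        return 1
    n = int(np.floor((1.96 * sigma_s / (threshold * abs(mu_s))) ** 2)) + 1
    return min(n, ceiling)


def convergence_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter convergence check of the segment sample.

    Reports sample mean, SD, the normalized standard error
    S_e/mu = 1.96 sigma_s / (sqrt(n) mu_s) and the sample size needed to
    push it below the 2% threshold.
    """
    rows = []
    for p in profiles.columns:
        vals = profiles[p].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        n = vals.size
        mu = float(vals.mean()) if n else float("nan")
        sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
        se = 1.96 * sd / np.sqrt(n) if n > 1 else float("nan")
        rows.append(
            {
                "parameter": p,
                "mu_s": mu,
                "sigma_s": sd,
                "n": n,
                "S_e": se,
                "ratio": se / abs(mu) if mu not in (0.0,) else float("nan"),
                "n_required": required_sample_size(mu, sd)
                if n > 1
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def _profiles_frame(
    segments: list[Segment], params: tuple[str, ...]
) -> pd.DataFrame:
    return pd.DataFrame([hrv_profile(s, params).values for s in segments])


def run_monte_carlo(
    cohort: list[Tachogram], config: RunConfig
) -> MonteCarloResult:
    """Run the full sweep: sample segments, compute clean profiles, perturb
    per (family, sigma), and aggregate every evaluation statistic.

    Fully seeded: the master seed spawns independent streams for segment
    sampling and for every (family, sigma) noise condition, so reruns with
    the same config are bit-identical and families are compared on
    independent noise draws.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(1 + len(config.families) * len(config.sigma_grid))
    segments = sample_segments(
        cohort,
        config.n_segments,
        window=config.window,
        seed=np.random.default_rng(children[0]),
    )
    params = config.param_names
    clean = _profiles_frame(segments, params)
    group_means = clean.mean(skipna=True)

    record_frames = []
    stream = 1
    for family in config.families:
        for sigma in config.sigma_grid:
            rng = np.random.default_rng(children[stream])
            stream += 1
            spec = NoiseSpec(family=family, sigma=sigma, t_mode=config.t_mode)
            noisy_profiles = []
            for seg in segments:
                noisy_tach = perturb_beats(seg.tachogram, spec, rng)
                noisy_profiles.append(hrv_profile(noisy_tach, params).values)
            noisy = pd.DataFrame(noisy_profiles)
            record_frames.append(
                compute_error_records(clean, noisy, family, sigma)
            )
            logger.info(
                "run_monte_carlo: family=%s sigma=%g done (%d segments)",
                family,
                sigma,
                len(segments),
            )
    n_sentinel: dict[str, int] = {}
    for f in record_frames:
        for p, c in f.attrs["n_sentinel"].items():
            n_sentinel[p] = n_sentinel.get(p, 0) + c
    records = pd.concat(record_frames, ignore_index=True)
    records.attrs["n_sentinel"] = n_sentinel
    if n_sentinel and any(n_sentinel.values()):
        logger.info("run_monte_carlo: sentinel pairs dropped: %s", n_sentinel)

    summary = summarize_errors(records)
    if len(set(config.sigma_grid)) >= 3:
        alpha = fit_linear_sensitivity(summary, group_means)
    else:  # too few noise levels for the linear fit
        alpha = pd.DataFrame(
            columns=[
                "parameter", "family", "x_bar",
                "alpha_bias", "r_bias", "alpha_mae", "r_mae",
                "alpha_rmse", "r_rmse",
            ]
        )
    ks_sigmas = tuple(s for s in config.ks_sigmas if s in config.sigma_grid)
    ks = (
        ks_table(records, ks_sigmas)
        if len(config.families) > 1 and ks_sigmas
        else pd.DataFrame(
            columns=[
                "parameter", "family_a", "family_b", "sigma",
                "D", "p_value", "significant",
            ]
        )
    )
    ba_records = records[
        (records["family"] == config.families[0])
        & (records["sigma"] == max(config.sigma_grid))
    ]
    ba = bland_altman(ba_records)
    return MonteCarloResult(
        config=config,
        records=records,
        summary=summary,
        alpha=alpha,
        ks=ks,
        ba=ba,
        group_means=group_means,
        clean_profiles=clean,
    )


def results_tables(result: MonteCarloResult) -> dict[str, pd.DataFrame]:
    """Named tables for :func:`hrvnoise.io.write_results`.

    ``alpha`` is sorted ascending by alpha_rmse (most noise-tolerant
    parameters first); per-parameter Bland-Altman pair tables are included
    as ``ba_<parameter>``.
    """
    tables = {
        "summary": result.summary,
        "alpha": result.alpha.sort_values("alpha_rmse").reset_index(drop=True),
        "ks": result.ks,
        "ba_summary": result.ba,
        "convergence": convergence_table(result.clean_profiles),
    }
    ba_records = result.records[
        (result.records["family"] == result.config.families[0])
        & (result.records["sigma"] == max(result.config.sigma_grid))
    ]
    for p, g in ba_records.groupby("parameter", sort=False):
        tables[f"ba_{p}".replace("/", "_")] = g[
            ["segment", "truth", "estimate", "error", "average"]
        ].reset_index(drop=True)
    return tables
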