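"""Number-Needed-to-Label: converting F1 gains into annotation effort.

The baseline's learning curve over the label fraction alpha is modeled as a
straight line F1(alpha) = a + b*alpha, fit by ordinary least squares to the
four grid points. A weak pre-training gain of ΔF1 points at a low-label
operating point alpha0 is then worth an extra label fraction
Δalpha = ΔF1 / b, and the Number Needed to Label is

    NNL = Δalpha * N_train

additional step-annotated videos the baseline would need to match the
weakly pre-trained model at the same alpha0. NNL scales with the training
pool: the same Δalpha costs more videos in a larger dataset, which is what
makes it useful for budgeting annotation at deployment sites.

The primary mode is split-wise: the curve is fit per split (seed), ΔF1,
Δalpha and NNL are computed per split, and the mean with a t-based 95% CI
over splits is reported. A pooled mode (single fit to per-alpha means) is
provided for comparison. Displayed NNLs are rounded to the nearest video;
arithmetic stays exact internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .stats import EvalTable

__all__ = [
    "CurveFit",
    "NNLResult",
    "fit_baseline_curve",
    "nnl",
    "nnl_from_table",
    "annotation_hours",
    "select_best_weak_label",
    "render_nnl_markdown",
]

#: slopes flatter than this (F1 points per unit alpha) make Δalpha = ΔF1/b
#: numerically meaningless; such fits are flagged non-estimable
SLOPE_TOLERANCE = 0.5


@dataclass
class CurveFit:
    """OLS line through (alpha, F1) points, optionally one fit per split."""

    procedure: str
    intercept: float                      # a, F1 points at alpha = 0
    slope: float                          # b, F1 points per unit alpha
    residuals: np.ndarray
    per_split: list[tuple[float, float]] | None = None  # [(a_s, b_s), ...]

    @property
    def estimable(self) -> bool:
        return abs(self.slope) >= SLOPE_TOLERANCE


def _ols_line(alphas: np.ndarray, f1s: np.ndarray) -> tuple[float, float]:
    if len(np.unique(alphas)) < 2:
        raise ValueError("need >= 2 distinct alpha values for a line fit")
    slope, intercept = np.polyfit(alphas, f1s, 1)
    return float(intercept), float(slope)


def fit_baseline_curve(
    f1_by_alpha: dict[float, float] | dict[float, np.ndarray],
    procedure: str = "",
    per_split: bool = False,
) -> CurveFit:
    """Fit F1 = a + b*alpha by OLS over the alpha grid.

    ``f1_by_alpha`` maps each alpha to either a scalar mean F1 (pooled fit)
    or a per-seed array (required when ``per_split`` is set, in which case
    one line is fit per seed and the pooled fit is reported as their mean
    curve's fit).
    """
    alphas = np.array(sorted(f1_by_alpha))
    values = [np.atleast_1d(np.asarray(f1_by_alpha[a], dtype=float))
              for a in alphas]
    per_split_fits: list[tuple[float, float]] | None = None
    if per_split:
        n_seeds = {len(v) for v in values}
        if len(n_seeds) != 1 or n_seeds == {1}:
            raise ValueError(
                "per-split fit needs the same number (>1) of per-seed F1s "
                f"at every alpha, got sizes {[len(v) for v in values]}"
            )
        k = n_seeds.pop()
        per_split_fits = []
        for s in range(k):
            f1s = np.array([v[s] for v in values])
            a, b = _ols_line(alphas, f1s)
            per_split_fits.append((a, b))
    means = np.array([v.mean() for v in values])
    intercept, slope = _ols_line(alphas, means)
    residuals = means - (intercept + slope * alphas)
    return CurveFit(procedure, intercept, slope, residuals, per_split_fits)


@dataclass
class NNLResult:
    """NNL estimate with split-wise uncertainty where available."""

    procedure: str
    scenario: str
    alpha0: float
    n_train: int
    delta_f1: float                       # mean ΔF1 at alpha0, points
    delta_f1_ci: tuple[float, float] | None
    delta_alpha: float                    # ΔF1 / slope
    delta_alpha_ci: tuple[float, float] | None
    nnl_exact: float                      # Δalpha * N_train, unrounded
    nnl_ci: tuple[float, float] | None
    estimable: bool

    @property
    def nnl(self) -> int:
        """Display value: nearest integer number of videos."""
        return int(round(self.nnl_exact))

    def hours(self, minutes_per_case: float) -> float:
        return annotation_hours(self.nnl_exact, minutes_per_case)


def _t_ci(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = values.mean()
    sd = values.std(ddof=1)
    half = float(sps.t.ppf(0.975, n - 1)) * sd / np.sqrt(n)
    return float(mean - half), float(mean + half)


def nnl(
    delta_f1_at_alpha0: float | np.ndarray,
    curve_fit: CurveFit,
    n_train: int,
    alpha0: float = 0.25,
    scenario: str = "",
) -> NNLResult:
    """Compute Δalpha = ΔF1/b and NNL = Δalpha * N_train.

    With a scalar ΔF1 and a pooled fit this is the worked-example
    arithmetic. With per-seed ΔF1s and a per-split fit (the primary mode),
    Δalpha and NNL are computed per seed and summarized by their mean and
    t-based 95% CI. Near-zero slopes are flagged non-estimable instead of
    producing an unbounded video count.
    """
    deltas = np.atleast_1d(np.asarray(delta_f1_at_alpha0, dtype=float))
    split_wise = curve_fit.per_split is not None and len(deltas) > 1
    if split_wise:
        assert curve_fit.per_split is not None
        if len(curve_fit.per_split) != len(deltas):
            raise ValueError(
                f"{len(deltas)} per-seed deltas but "
                f"{len(curve_fit.per_split)} per-split fits"
            )
        slopes = np.array([b for _, b in curve_fit.per_split])
        estimable = bool(np.all(np.abs(slopes) >= SLOPE_TOLERANCE))
        if not estimable:
            slopes = np.where(np.abs(slopes) < SLOPE_TOLERANCE, np.nan, slopes)
        da = deltas / slopes
        nnls = da * n_train
        d_mean = float(deltas.mean())
        return NNLResult(
            procedure=curve_fit.procedure, scenario=scenario, alpha0=alpha0,
            n_train=n_train, delta_f1=d_mean, delta_f1_ci=_t_ci(deltas),
            delta_alpha=float(np.nanmean(da)),
            delta_alpha_ci=_t_ci(da) if estimable else None,
            nnl_exact=float(np.nanmean(nnls)),
            nnl_ci=_t_ci(nnls) if estimable else None,
            estimable=estimable,
        )
    delta = float(deltas.mean())
    estimable = curve_fit.estimable
    b = curve_fit.slope if estimable else np.nan
    da = delta / b
    return NNLResult(
        procedure=curve_fit.procedure, scenario=scenario, alpha0=alpha0,
        n_train=n_train, delta_f1=delta,
        delta_f1_ci=_t_ci(deltas) if len(deltas) > 1 else None,
        delta_alpha=float(da), delta_alpha_ci=None,
        nnl_exact=float(da * n_train), nnl_ci=None,
        estimable=estimable,
    )


def nnl_from_table(
    table: EvalTable,
    procedure: str,
    scenario: str,
    n_train: int,
    alpha0: float = 0.25,
    baseline: str = "Baseline",
    mode: str = "split",
) -> NNLResult:
    """End-to-end NNL for one scenario from a long-form evaluation table."""
    from .stats import paired_delta  # local import avoids cycle at import time

    if mode not in ("split", "pooled"):
        raise ValueError(f"mode must be 'split' or 'pooled', got {mode!r}")
    df = table.df
    base = df[(df["procedure"] == procedure) & (df["scenario"] == baseline)]
    if base.empty:
        raise ValueError(f"no {baseline} rows for procedure {procedure!r}")
    scale = 100.0 if df["weighted_f1"].max() <= 1.0 else 1.0
    f1_by_alpha = {
        float(a): grp.sort_values("seed")["weighted_f1"].to_numpy() * scale
        for a, grp in base.groupby("alpha")
    }
    fit = fit_baseline_curve(f1_by_alpha, procedure, per_split=(mode == "split"))
    d = paired_delta(table, procedure, scenario, alpha0, baseline)
    deltas = d.deltas if mode == "split" else d.mean
    return nnl(deltas, fit, n_train, alpha0, scenario)


def annotation_hours(nnl_videos: float, minutes_per_case: float) -> float:
    """Convert an NNL in videos into person-hours of annotation effort."""
    if nnl_videos < 0 or minutes_per_case < 0:
        raise ValueError("nnl_videos and minutes_per_case must be >= 0")
    return nnl_videos * minutes_per_case / 60.0


def select_best_weak_label(results: dict[str, "DeltaLike"]) -> str:
    """Pick the best scenario: highest mean ΔF1, ties by narrower CI, then name.

    ``results`` maps scenario name to any object with ``mean``, ``ci_low``
    and ``ci_high`` attributes (e.g. stats.DeltaResult).
    """
    if not results:
        raise ValueError("no scenarios to select from")

    def key(name: str):
        r = results[name]
        width = r.ci_high - r.ci_low
        return (-r.mean, width, name)

    return min(results, key=key)


class DeltaLike:  # typing helper only
    mean: float
    ci_low: float
    ci_high: float


def render_nnl_markdown(results: list[NNLResult]) -> str:
    """Markdown summary: ΔF1 [CI], N_train, Δalpha [CI], NNL [CI] per row."""
    lines = [
        "| Procedure | Best weak label | ΔF1 [95% CI] | N_train | Δα [95% CI] | NNL [95% CI] |",
        "|---|---|---|---|---|---|",
    ]

    def ci(pair, fmt):
        return "n/a" if pair is None else f"[{pair[0]:{fmt}}, {pair[1]:{fmt}}]"

    for r in results:
        lines.append(
            f"| {r.procedure} | {r.scenario} | "
            f"{r.delta_f1:.2f} {ci(r.delta_f1_ci, '.2f')} | {r.n_train} | "
            f"{r.delta_alpha:.2f} {ci(r.delta_alpha_ci, '.2f')} | "
            f"**{r.nnl}** {ci(tuple(round(x) for x in r.nnl_ci) if r.nnl_ci else None, 'd')} |"
        )
    return "\n".join(lines)
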