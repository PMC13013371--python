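"""Paired evaluation statistics for scenario-vs-baseline comparisons.

Performance is the weighted-average F1 over step classes on the held-out
test set. Scenarios are compared to the no-pre-training baseline by paired
differences: the pairing unit is the random split (seed), whose labeled
subsets are held constant between the two arms. Reported per cell are the
mean paired ΔF1, a 95% confidence interval from the t distribution with
(n_seeds - 1) degrees of freedom, the two-sided paired t-test p-value, and
a Bonferroni-corrected star string. The "Hypothetical Max" reference is the
baseline's mean F1 at alpha = 1.0 (full supervision, no weak pre-training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import f1_score

from .ontology import UNLABELED

__all__ = [
    "weighted_f1",
    "EvalTable",
    "DeltaResult",
    "paired_delta",
    "bonferroni_stars",
    "hypothetical_max",
    "delta_table",
    "render_delta_markdown",
]

EVAL_COLUMNS = ["procedure", "scenario", "alpha", "seed", "weighted_f1"]


def weighted_f1(true_labels, predicted_labels) -> float:
    """Support-weighted mean of per-class F1 scores, in [0, 1].

    Frames whose true label is the reserved UNLABELED token are excluded
    before scoring. Classes absent from the truth get weight zero; classes
    that are predicted but never true contribute only through the precision
    of other classes. A class with no predictions scores F1 = 0.
    """
    y_true = np.asarray(true_labels)
    y_pred = np.asarray(predicted_labels)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} truth vs {y_pred.shape} predictions"
        )
    keep = y_true != UNLABELED
    y_true, y_pred = y_true[keep], y_pred[keep]
    if y_true.size == 0:
        raise ValueError("no labeled frames to score")
    return float(
        f1_score(y_true, y_pred, average="weighted", zero_division=0)
    )


@dataclass
class EvalTable:
    """Long-form results: one row per (procedure, scenario, alpha, seed)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"EvalTable missing columns {missing}")

    @classmethod
    def from_records(cls, records) -> "EvalTable":
        return cls(pd.DataFrame.from_records(records, columns=EVAL_COLUMNS))

    def cell(self, procedure: str, scenario: str, alpha: float) -> pd.DataFrame:
        df = self.df
        out = df[
            (df["procedure"] == procedure)
            & (df["scenario"] == scenario)
            & (np.isclose(df["alpha"], alpha))
        ].sort_values("seed")
        return out

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EvalTable":
        return cls(pd.read_csv(path))


@dataclass
class DeltaResult:
    """Paired scenario-vs-baseline comparison for one (procedure, alpha)."""

    procedure: str
    scenario: str
    alpha: float
    deltas: np.ndarray          # per-seed paired differences, F1 points
    mean: float                 # arithmetic mean of the paired deltas
    ci_low: float
    ci_high: float
    p_value: float
    degenerate_variance: bool   # per-seed deltas all identical

    def stars(self, n_comparisons: int) -> str:
        return bonferroni_stars(self.p_value, n_comparisons)


def _paired_t(deltas: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Mean, 95% CI and two-sided p of paired deltas; closed-form t.

    Zero-variance deltas make the t statistic undefined; the p-value is
    reported as its limit (0 if the mean differs from 0, else 1) with the
    degenerate flag set.
    """
    n = len(deltas)
    if n < 2:
        raise ValueError(f"need >= 2 paired differences, got {n}")
    mean = float(np.mean(deltas))
    sd = float(np.std(deltas, ddof=1))
    tq = float(sps.t.ppf(0.975, n - 1))
    half = tq * sd / np.sqrt(n)
    if sd == 0.0:
        p = 1.0 if mean == 0.0 else 0.0
        return mean, mean - half, mean + half, p, True
    t_stat = mean / (sd / np.sqrt(n))
    p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
    return mean, mean - half, mean + half, p, False


def paired_delta(
    table: EvalTable,
    procedure: str,
    scenario: str,
    alpha: float,
    baseline: str = "Baseline",
) -> DeltaResult:
    """Per-seed paired ΔF1 (scenario minus baseline) with CI and t-test.

    Both arms must have been evaluated on exactly the same seeds; the
    differences are formed seed by seed. F1 values are compared on the
    percentage-point scale (a table stored in [0,1] is scaled by 100).
    """
    a = table.cell(procedure, scenario, alpha)
    b = table.cell(procedure, baseline, alpha)
    if a.empty or b.empty:
        raise ValueError(
            f"missing rows for {procedure}/{scenario} or {procedure}/{baseline} "
            f"at alpha={alpha}"
        )
    if list(a["seed"]) != list(b["seed"]):
        raise ValueError(
            f"seed mismatch between {scenario} ({list(a['seed'])}) and "
            f"{baseline} ({list(b['seed'])})"
        )
    scale = 100.0 if table.df["weighted_f1"].max() <= 1.0 else 1.0
    deltas = (a["weighted_f1"].to_numpy() - b["weighted_f1"].to_numpy()) * scale
    mean, lo, hi, p, degen = _paired_t(deltas)
    return DeltaResult(procedure, scenario, alpha, deltas, mean, lo, hi, p, degen)


def bonferroni_stars(p: float, n_comparisons: int) -> str:
    """Star string after Bonferroni correction of a single p-value.

    '' for N*p >= 0.05, '*' for 0.01 <= N*p < 0.05, '**' for
    0.001 <= N*p < 0.01, '***' for N*p < 0.001.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if n_comparisons < 1:
        raise ValueError(f"n_comparisons must be >= 1, got {n_comparisons}")
    np_ = n_comparisons * p
    if np_ < 0.001:
        return "***"
    if np_ < 0.01:
        return "**"
    if np_ < 0.05:
        return "*"
    return ""


def hypothetical_max(
    table: EvalTable, procedure: str, baseline: str = "Baseline"
) -> float:
    """Mean baseline F1 at alpha = 1.0: the full-supervision reference."""
    cell = table.cell(procedure, baseline, 1.0)
    if cell.empty:
        raise ValueError(
            f"no {baseline} rows at alpha=1.0 for procedure {procedure!r}"
        )
    return float(cell["weighted_f1"].mean())


def delta_table(
    table: EvalTable,
    procedures,
    scenarios,
    alpha: float,
    n_comparisons: int | None = None,
    baseline: str = "Baseline",
) -> pd.DataFrame:
    """All scenario-vs-baseline comparisons at one alpha, as a DataFrame.

    ``n_comparisons`` defaults to len(procedures) * len(scenarios), the
    number of cells in the reported table.
    """
    procedures = list(procedures)
    scenarios = [s for s in scenarios if s != baseline]
    if n_comparisons is None:
        n_comparisons = len(procedures) * len(scenarios)
    rows = []
    for proc in procedures:
        for sc in scenarios:
            d = paired_delta(table, proc, sc, alpha, baseline)
            rows.append({
                "procedure": proc, "scenario": sc, "alpha": alpha,
                "mean_delta_f1": d.mean, "ci_low": d.ci_low,
                "ci_high": d.ci_high, "p_value": d.p_value,
                "stars": d.stars(n_comparisons),
                "degenerate_variance": d.degenerate_variance,
            })
    return pd.DataFrame(rows)


def render_delta_markdown(deltas: pd.DataFrame) -> str:
    """Markdown table of mean ΔF1 [CI] + stars, best-per-procedure in bold."""
    procs = list(dict.fromkeys(deltas["procedure"]))
    scens = list(dict.fromkeys(deltas["scenario"]))
    best = {
        p: deltas[deltas["procedure"] == p]
        .set_index("scenario")["mean_delta_f1"].idxmax()
        for p in procs
    }
    lines = ["| Pre-training strategy | " + " | ".join(procs) + " |",
             "|---" * (len(procs) + 1) + "|"]
    for sc in scens:
        cells = []
        for p in procs:
            row = deltas[(deltas["procedure"] == p) & (deltas["scenario"] == sc)]
            r = row.iloc[0]
            text = (f"{r['mean_delta_f1']:.2f} "
                    f"[{r['ci_low']:.2f}, {r['ci_high']:.2f}]{r['stars']}")
            if best[p] == sc:
                text = f"**{text}**"
            cells.append(text)
        lines.append(f"| {sc} | " + " | ".join(cells) + " |")
    return "\n".join(lines)
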