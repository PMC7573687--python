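"""Interrater agreement statistics: weighted kappa and single-rater ICC.

Two raters are compared with Cohen's weighted kappa using linear weights
``w_ij = 1 - |i - j|/(k - 1)`` (partial credit for near-miss categories;
quadratic weights are available but off by default because they systematically
inflate agreement).  The large-sample standard error follows Fleiss, Cohen &
Everitt (1969), giving a Wald 95% confidence interval.

More than two raters are compared with the single-rater intraclass
correlation under a two-way model (McGraw & Wong):

* consistency form  ICC(C,1) = (MSR - MSE) / (MSR + (m-1) MSE)
* absolute agreement ICC(A,1) = (MSR - MSE) /
      (MSR + (m-1) MSE + m/n (MSC - MSE))

where MSR, MSC, MSE are the mean squares for rows (subjects), columns
(raters) and error of the two-way ANOVA with n subjects and m raters.
Confidence intervals use the F-based formulas of McGraw & Wong (Satterthwaite
degrees of freedom for the absolute-agreement form).  Ordinal scores are
treated as interval numbers, the convention of standard reliability software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingTable",
    "WeightedKappaResult",
    "IccResult",
    "linear_weights",
    "linear_weighted_kappa",
    "weighted_kappa",
    "icc_single",
    "per_fold_kappa_report",
    "plot_fold_kappa",
]


@dataclass(frozen=True)
class RatingTable:
    """Complete frames x raters table of ordinal scores in 1..k.

    ``scores`` has shape (n_frames, n_raters).  No missing cells are allowed;
    the published rating tables are complete and imputation would distort the
    agreement statistics.
    """

    scores: np.ndarray
    frame_ids: tuple[str, ...]
    video_ids: tuple[str, ...]
    raters: tuple[str, ...]
    n_categories: int = 4

    def __post_init__(self) -> None:
        s = np.asarray(self.scores)
        if s.ndim != 2:
            raise ValueError("scores must be 2-D (frames x raters)")
        if np.isnan(s.astype(float)).any():
            raise ValueError("missing ratings are not allowed")
        s = s.astype(np.int64)
        if s.size and ((s < 1) | (s > self.n_categories)).any():
            raise ValueError(f"scores must lie in 1..{self.n_categories}")
        if len(self.frame_ids) != s.shape[0] or len(self.raters) != s.shape[1]:
            raise ValueError("frame_ids/raters lengths must match the score matrix")
        object.__setattr__(self, "scores", s)

    @property
    def n_frames(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]

    def column(self, rater: str) -> np.ndarray:
        return self.scores[:, self.raters.index(rater)]

    def subset(self, row_mask: np.ndarray) -> "RatingTable":
        idx = np.flatnonzero(row_mask)
        return RatingTable(
            scores=self.scores[idx],
            frame_ids=tuple(self.frame_ids[i] for i in idx),
            video_ids=tuple(self.video_ids[i] for i in idx),
            raters=self.raters,
            n_categories=self.n_categories,
        )

    @classmethod
    def from_long(
        cls, df: pd.DataFrame, n_categories: int = 4,
        frame_col: str = "frame_id", video_col: str = "video_id",
        rater_col: str = "rater", score_col: str = "score",
    ) -> "RatingTable":
        """Build from long CSV layout ``frame_id,video_id,rater,score``."""
        wide = df.pivot(index=frame_col, columns=rater_col, values=score_col)
        if wide.isna().any().any():
            raise ValueError("incomplete rating table (missing frame x rater cells)")
        videos = df.drop_duplicates(frame_col).set_index(frame_col)[video_col]
        frame_ids = tuple(str(f) for f in wide.index)
        return cls(
            scores=wide.to_numpy(),
            frame_ids=frame_ids,
            video_ids=tuple(str(videos.loc[f]) for f in wide.index),
            raters=tuple(str(r) for r in wide.columns),
            n_categories=n_categories,
        )

    @classmethod
    def from_wide_csv(
        cls, path: str | Path, rater_columns: list[str] | None = None,
        n_categories: int = 4,
    ) -> "RatingTable":
        """Read wide CSV ``frame_id,video_id,<rater1>,<rater2>,...``."""
        df = pd.read_csv(path)
        raters = rater_columns or [c for c in df.columns if c not in ("frame_id", "video_id")]
        return cls(
            scores=df[raters].to_numpy(),
            frame_ids=tuple(df["frame_id"].astype(str)),
            video_ids=tuple(df["video_id"].astype(str)),
            raters=tuple(raters),
            n_categories=n_categories,
        )


@dataclass(frozen=True)
class WeightedKappaResult:
    kappa: float
    ci95: tuple[float, float]
    se: float
    weights: np.ndarray
    n: int
    defined: bool = True


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci95: tuple[float, float]
    form: str  # "C1" or "A1"
    msr: float
    msc: float
    mse: float
    n: int
    m: int
    defined: bool = True


def linear_weights(k: int) -> np.ndarray:
    """Agreement weight matrix w_ij = 1 - |i - j| / (k - 1)."""
    i = np.arange(k)
    return 1.0 - np.abs(i[:, None] - i[None, :]) / (k - 1)


def quadratic_weights(k: int) -> np.ndarray:
    i = np.arange(k)
    return 1.0 - (i[:, None] - i[None, :]) ** 2 / (k - 1) ** 2


def weighted_kappa(
    a: np.ndarray, b: np.ndarray, k: int = 4, weights: np.ndarray | None = None
) -> WeightedKappaResult:
    """Cohen's weighted kappa between two raters with a 95% Wald CI.

    ``weights`` defaults to linear weights; pass an identity matrix to recover
    unweighted Cohen's kappa.  Degenerate marginals (expected agreement 1) set
    ``defined`` to False and kappa to NaN.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 rated frames")
    for v in (a, b):
        if ((v < 1) | (v > k)).any():
            raise ValueError(f"categories must lie in 1..{k}")
    w = linear_weights(k) if weights is None else np.asarray(weights, dtype=np.float64)
    f = np.zeros((k, k))
    np.add.at(f, (a - 1, b - 1), 1.0)
    p = f / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * (r[:, None] * c[None, :])).sum())
    if 1.0 - pe < 1e-15:
        return WeightedKappaResult(
            kappa=float("nan"), ci95=(float("nan"), float("nan")), se=float("nan"),
            weights=w, n=n, defined=False,
        )
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss-Cohen-Everitt large-sample variance
    wbar_row = (w * c[None, :]).sum(axis=1)  # expected weight given rater A's category
    wbar_col = (w * r[:, None]).sum(axis=0)  # expected weight given rater B's category
    term = w - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - kappa)
    var = ((p * term**2).sum() - (kappa - pe * (1.0 - kappa)) ** 2) / (n * (1.0 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    ci = (kappa - 1.96 * se, kappa + 1.96 * se)
    return WeightedKappaResult(kappa=float(kappa), ci95=ci, se=se, weights=w, n=n)


def linear_weighted_kappa(a: np.ndarray, b: np.ndarray, k: int = 4) -> WeightedKappaResult:
    """Linearly weighted Cohen's kappa (the default agreement statistic)."""
    return weighted_kappa(a, b, k=k, weights=None)


def _anova(x: np.ndarray) -> tuple[float, float, float]:
    """Two-way ANOVA mean squares (rows, columns, error) of an n x m table."""
    n, m = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = m * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (m - 1)
    mse = sse / ((n - 1) * (m - 1))
    return float(msr), float(msc), float(max(mse, 0.0))


def icc_single(table: RatingTable | np.ndarray, form: str = "C1") -> IccResult:
    """Single-rater ICC of a complete ratings table, consistency or agreement form.

    ``form`` is "C1" (two-way consistency, ignores systematic rater offsets) or
    "A1" (two-way absolute agreement, penalises them).  A constant table has no
    subject variance and yields ``defined=False``.
    """
    x = table.scores if isinstance(table, RatingTable) else np.asarray(table)
    x = x.astype(np.float64)
    n, m = x.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 frames and 2 raters")
    if form not in ("C1", "A1"):
        raise ValueError("form must be 'C1' or 'A1'")
    msr, msc, mse = _anova(x)
    if np.ptp(x) == 0:
        return IccResult(float("nan"), (float("nan"), float("nan")), form,
                         msr, msc, mse, n, m, defined=False)
    if form == "C1":
        denom = msr + (m - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else float("nan")
        ci = _ci_c1(msr, mse, n, m)
    else:
        denom = msr + (m - 1) * mse + m / n * (msc - mse)
        icc = (msr - mse) / denom if denom > 0 else float("nan")
        ci = _ci_a1(icc, msr, msc, mse, n, m)
    return IccResult(float(icc), ci, form, msr, msc, mse, n, m,
                     defined=bool(np.isfinite(icc)))


def _ci_c1(msr: float, mse: float, n: int, m: int, alpha: float = 0.05) -> tuple[float, float]:
    if mse <= 0:
        return (1.0, 1.0)
    f = msr / mse
    df1, df2 = n - 1, (n - 1) * (m - 1)
    fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
    return ((fl - 1) / (fl + m - 1), (fu - 1) / (fu + m - 1))


def _ci_a1(
    icc: float, msr: float, msc: float, mse: float, n: int, m: int, alpha: float = 0.05
) -> tuple[float, float]:
    if not np.isfinite(icc) or mse <= 0 and msc <= 0:
        return (float("nan"), float("nan"))
    a = m * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + m * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    if not np.isfinite(a):
        return (1.0, 1.0)
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (m - 1) + (b * mse) ** 2 / ((n - 1) * (m - 1))
    v = num / den if den > 0 else 1.0
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (m * msc + (m * n - m - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        m * msc + (m * n - m - n) * mse + n * f_u * msr
    )
    return (float(lower), float(upper))


def per_fold_kappa_report(
    table: RatingTable, folds: dict[str, int], k: int | None = None
) -> pd.DataFrame:
    """Linearly weighted kappa per rater pair, per fold and pooled.

    ``folds`` maps video_id -> fold index and must cover every video in the
    table (grouping by video keeps a patient's frames together).  Returns a
    DataFrame with columns pair, fold ("all" for the concatenation), kappa,
    ci_low, ci_high, n.
    """
    k = k or table.n_categories
    missing = {v for v in table.video_ids if v not in folds}
    if missing:
        raise ValueError(f"videos without fold assignment: {sorted(missing)}")
    fold_of_frame = np.array([folds[v] for v in table.video_ids])
    rows = []
    pairs = [
        (i, j) for i in range(table.n_raters) for j in range(i + 1, table.n_raters)
    ]
    fold_ids = sorted(set(fold_of_frame))
    for i, j in pairs:
        pair = f"{table.raters[i]} vs {table.raters[j]}"
        for f in fold_ids:
            sel = fold_of_frame == f
            if sel.sum() < 2:
                raise ValueError(f"fold {f} has fewer than 2 frames")
            res = linear_weighted_kappa(table.scores[sel, i], table.scores[sel, j], k=k)
            rows.append((pair, str(f), res.kappa, res.ci95[0], res.ci95[1], res.n))
        res = linear_weighted_kappa(table.scores[:, i], table.scores[:, j], k=k)
        rows.append((pair, "all", res.kappa, res.ci95[0], res.ci95[1], res.n))
    return pd.DataFrame(rows, columns=["pair", "fold", "kappa", "ci_low", "ci_high", "n"])


def plot_fold_kappa(report: pd.DataFrame, path: str | Path | None = None):
    """Per-fold kappa points with 95% CI whiskers, one colour per rater pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    pairs = report["pair"].unique()
    folds = list(report["fold"].unique())
    width = 0.8 / max(len(pairs), 1)
    for pi, pair in enumerate(pairs):
        sub = report[report["pair"] == pair]
        x = np.array([folds.index(f) for f in sub["fold"]]) + pi * width
        yerr = np.vstack([sub["kappa"] - sub["ci_low"], sub["ci_high"] - sub["kappa"]])
        ax.errorbar(x, sub["kappa"], yerr=yerr, fmt="o", capsize=3, label=pair)
    ax.set_xticks(np.arange(len(folds)) + 0.4 - width / 2)
    ax.set_xticklabels(folds)
    ax.set_xlabel("fold")
    ax.set_ylabel(r"weighted kappa $\kappa_1$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
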