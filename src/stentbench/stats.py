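"""Statistical comparison layer.

Paired comparisons between the two imaging systems:

* continuous metrics (diameter error, blooming %, distinction %) — paired
  Student t-test; reported as mean +/- SD,
* ordinal reader scores — Wilcoxon signed-rank test with the zero-drop
  convention, mid-ranks for tied absolute differences, exact enumeration of
  the sign distribution for small untied samples and a tie- and
  continuity-corrected normal approximation otherwise; reported as
  median with Q1-Q3 interquartile range (linear-interpolation quantiles),
* reader reliability — two-way mixed-effects consistency ICC for the mean
  of k raters, ICC(C,k) = (MS_items - MS_error) / MS_items, with the
  conventional poor / moderate / good / excellent bands,
* normality screening — Shapiro-Wilk (delegated to scipy).

Significance is declared two-tailed at p < 0.05 throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateSampleError, InvalidParameterError, PairingError

ALPHA = 0.05

#: Largest sample size for which the exact sign-enumeration Wilcoxon
#: distribution is used (ties always force the normal approximation).
EXACT_WILCOXON_MAX_N = 15


# --------------------------------------------------------------------------
# Wilcoxon signed-rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    p_value: float
    n: int  # pairs remaining after dropping zero differences
    method: str  # "exact", "normal", or "degenerate"
    w_plus: float
    w_minus: float

    def __iter__(self):
        return iter((self.statistic, self.p_value))


def _signed_rank_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of W+ values over all sign assignments of integer ranks."""
    total = int(ranks.sum())
    c = np.zeros(total + 1, dtype=np.int64)
    c[0] = 1
    for r in ranks.astype(int):
        c[r:] = c[r:] + c[:-r]
    return c


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float] | None = None) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive
    mid-ranks.  With at most :data:`EXACT_WILCOXON_MAX_N` untied pairs the
    p-value is exact (full enumeration of the 2^n sign assignments via the
    signed-rank distribution); otherwise a normal approximation with tie
    correction and a continuity correction is used.  If every difference is
    zero the test is degenerate and p = 1.
    """
    x = np.asarray(list(x), dtype=float)
    if y is not None:
        y = np.asarray(list(y), dtype=float)
        if y.shape != x.shape:
            raise InvalidParameterError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", 0.0, 0.0)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        counts = _signed_rank_counts(ranks)
        p = 2.0 * counts[: int(round(w)) + 1].sum() / 2.0**n
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= (tie_counts**3 - tie_counts).sum() / 48.0
        if var <= 0:
            return WilcoxonResult(w, 1.0, n, "degenerate", w_plus, w_minus)
        z = (w - mu + 0.5) / math.sqrt(var)
        p = 2.0 * sps.norm.cdf(z)
        method = "normal"
    return WilcoxonResult(w, float(min(p, 1.0)), n, method, w_plus, w_minus)


# --------------------------------------------------------------------------
# paired t


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float

    def __iter__(self):
        return iter((self.t, self.df, self.p_value))


def paired_t(x: Sequence[float], y: Sequence[float] | None = None) -> PairedTResult:
    """Two-tailed paired-samples t-test: t = mean(d) / (sd(d) / sqrt(n))."""
    x = np.asarray(list(x), dtype=float)
    if y is not None:
        y = np.asarray(list(y), dtype=float)
        if y.shape != x.shape:
            raise InvalidParameterError("paired samples must have equal length")
        d = x - y
    else:
        d = x
    n = d.size
    if n < 2:
        raise InvalidParameterError("paired t-test needs at least 2 pairs")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise DegenerateSampleError(
            "differences have zero variance; the t statistic is undefined"
        )
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(t, n - 1, p)


# --------------------------------------------------------------------------
# ICC


@dataclass(frozen=True)
class ICCResult:
    value: float
    ms_items: float
    ms_error: float
    n_items: int
    k_raters: int
    interpretation: str
    undefined: bool = False


def interpret_icc(value: float) -> str:
    """Conventional reliability bands for ICC point estimates."""
    if math.isnan(value):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


def icc_consistency_avg(ratings: np.ndarray) -> ICCResult:
    """Two-way mixed-effects consistency ICC for the average of k raters.

    ``ratings`` is an items x raters matrix.  A two-way ANOVA without
    interaction partitions variance into items, raters and residual;
    ICC(C,k) = (MS_items - MS_error) / MS_items.  Additive per-rater shifts
    land in the rater term and leave the estimate unchanged.  With no
    between-item variance the coefficient is undefined and NaN is returned
    with a flag.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InvalidParameterError("ratings must be items x raters with n>=2, k>=2")
    if np.isnan(m).any():
        raise InvalidParameterError("ratings must be complete (no missing cells)")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((m - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows <= 0:
        return ICCResult(float("nan"), ms_rows, ms_err, n, k, "undefined", undefined=True)
    icc = (ms_rows - ms_err) / ms_rows
    return ICCResult(float(icc), float(ms_rows), float(ms_err), n, k, interpret_icc(icc))


# --------------------------------------------------------------------------
# normality


def normality_check(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    x = np.asarray(list(x), dtype=float)
    if not 3 <= x.size <= 5000:
        raise InvalidParameterError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample has no distribution to test")
    w, p = sps.shapiro(x)
    return float(w), float(p)


# --------------------------------------------------------------------------
# summary report


@dataclass
class ComparisonReport:
    """Per-metric, per-FOV, per-system summary with paired-test p-values.

    ``quantitative`` rows: metric, fov, system, mean, sd, n, p_value,
    significant (p refers to the si_pcct vs eidct comparison at that
    metric x FOV and is repeated on both system rows).  ``qualitative``
    rows carry median and Q1/Q3 instead of mean/sd.  ``icc`` holds pooled
    reliability coefficients when reader scores were supplied.
    """

    quantitative: pd.DataFrame
    qualitative: pd.DataFrame | None = None
    icc: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "quantitative": self.quantitative.to_dict(orient="records"),
            "qualitative": (
                self.qualitative.to_dict(orient="records")
                if self.qualitative is not None
                else None
            ),
            "icc": self.icc,
        }
        text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path) -> None:
        frames = [self.quantitative.assign(kind="quantitative")]
        if self.qualitative is not None:
            frames.append(self.qualitative.assign(kind="qualitative"))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _paired_p(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return paired_t(x, y).p_value
    except DegenerateSampleError:
        # identical paired measurements carry no evidence of a difference
        return 1.0 if np.allclose(x, y) else 0.0


def summarize(
    measurements: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    systems: tuple[str, str] = ("si_pcct", "eidct"),
) -> ComparisonReport:
    """Build the per-metric x FOV x system comparison table.

    ``measurements`` is tidy with columns metric, fov, system, stent,
    location, value (continuous metrics).  ``scores`` is tidy with columns
    metric, fov, system, item, reader, session, score (ordinal 1-5).  Both
    systems must cover identical (stent, location) / (item, reader) sets
    per metric x FOV; anything unpaired raises :class:`PairingError`.
    """
    required = {"metric", "fov", "system", "stent", "location", "value"}
    if not required.issubset(measurements.columns):
        raise PairingError(f"measurements must have columns {sorted(required)}")
    sys_a, sys_b = systems
    q_rows = []
    for (metric, fov), grp in measurements.groupby(["metric", "fov"], sort=True):
        pivots = {}
        for system in systems:
            sub = grp[grp["system"] == system].set_index(["stent", "location"])["value"]
            sub = sub.sort_index()
            pivots[system] = sub
        if not pivots[sys_a].index.equals(pivots[sys_b].index):
            raise PairingError(
                f"unpaired measurements for metric={metric!r}, fov={fov!r}"
            )
        if len(pivots[sys_a]) < 2:
            raise PairingError(f"need >=2 paired values for metric={metric!r}, fov={fov!r}")
        p = _paired_p(pivots[sys_a].to_numpy(), pivots[sys_b].to_numpy())
        for system in systems:
            v = pivots[system].to_numpy()
            q_rows.append(
                {
                    "metric": metric,
                    "fov": fov,
                    "system": system,
                    "mean": float(np.mean(v)),
                    "sd": float(np.std(v, ddof=1)),
                    "n": int(v.size),
                    "test": "paired_t",
                    "p_value": p,
                    "significant": bool(p < ALPHA),
                }
            )
    quantitative = pd.DataFrame(q_rows)

    qualitative = None
    icc: dict = {}
    if scores is not None:
        s_required = {"metric", "fov", "system", "item", "reader", "session", "score"}
        if not s_required.issubset(scores.columns):
            raise PairingError(f"scores must have columns {sorted(s_required)}")
        o_rows = []
        for (metric, fov), grp in scores.groupby(["metric", "fov"], sort=True):
            paired = {}
            for system in systems:
                sub = grp[grp["system"] == system]
                # one rating per item x reader: sessions averaged
                paired[system] = (
                    sub.groupby(["item", "reader"])["score"].mean().sort_index()
                )
            if not paired[sys_a].index.equals(paired[sys_b].index):
                raise PairingError(f"unpaired scores for metric={metric!r}, fov={fov!r}")
            p = wilcoxon_signed_rank(
                paired[sys_a].to_numpy(), paired[sys_b].to_numpy()
            ).p_value
            for system in systems:
                raw = grp[grp["system"] == system]["score"].to_numpy(dtype=float)
                o_rows.append(
                    {
                        "metric": metric,
                        "fov": fov,
                        "system": system,
                        "median": float(np.median(raw)),
                        "q1": float(np.percentile(raw, 25)),
                        "q3": float(np.percentile(raw, 75)),
                        "n": int(raw.size),
                        "test": "wilcoxon_signed_rank",
                        "p_value": p,
                        "significant": bool(p < ALPHA),
                    }
                )
        qualitative = pd.DataFrame(o_rows)
        icc = reliability_iccs(scores)
    return ComparisonReport(quantitative=quantitative, qualitative=qualitative, icc=icc)


def reliability_iccs(scores: pd.DataFrame, pooling: str = "pooled") -> dict:
    """Inter- and intra-reader ICC(C,2) across all evaluations.

    ``pooling='pooled'`` concatenates every (metric, fov, system, item)
    combination into one item list; ``pooling='per_metric'`` computes one
    ICC per metric and averages the coefficients.  Inter-reader agreement
    uses the first session of each reader; intra-reader agreement treats a
    reader's two sessions as the two "raters" and stacks readers as items.
    """
    if pooling not in ("pooled", "per_metric"):
        raise InvalidParameterError("pooling must be 'pooled' or 'per_metric'")
    keys = ["metric", "fov", "system", "item"]

    def _icc_or_nan(mat: pd.DataFrame) -> float:
        arr = mat.to_numpy()
        if arr.shape[0] < 2 or arr.shape[1] < 2 or np.isnan(arr).any():
            return float("nan")
        return icc_consistency_avg(arr).value

    def _inter(df: pd.DataFrame) -> float:
        first = df[df["session"] == df["session"].min()]
        return _icc_or_nan(first.pivot_table(index=keys, columns="reader", values="score"))

    def _intra(df: pd.DataFrame) -> float:
        return _icc_or_nan(
            df.pivot_table(index=keys + ["reader"], columns="session", values="score")
        )

    if pooling == "pooled":
        inter = _inter(scores)
        intra = _intra(scores)
    else:
        inters, intras = [], []
        for _, grp in scores.groupby("metric"):
            inters.append(_inter(grp))
            intras.append(_intra(grp))
        inter = float(np.mean(inters))
        intra = float(np.mean(intras))
    return {
        "inter_reader": inter,
        "intra_reader": intra,
        "inter_reader_band": interpret_icc(inter),
        "intra_reader_band": interpret_icc(intra),
        "pooling": pooling,
    }
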