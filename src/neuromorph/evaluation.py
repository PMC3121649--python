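"""Scoring of point detections, tracing agreement, and dose-response fits.

Point-detection performance is scored against a manual (ground-truth) count
``Ma`` and a detected count ``Ne`` with true/false positives and false
negatives:

* accuracy  = 100 * TP / Ma   (correctly detected points over manual points)
* error rate = 100 * (FP + FN) / Ne  (all wrongly assigned points over
  detected points)

Note the error rate includes the false negatives in the numerator while
normalizing by the detected count; this is the convention that reproduces
published per-image scores for this family of measurements.

Tracing agreement between two methods is summarized by Pearson's r together
with a paired two-tailed t-test on the per-image differences.

Dose-response data are fit with the four-parameter logistic (4PL)

    response(c) = bottom + (top - bottom) / (1 + (c / ic50) ** hill)

by least squares in log-concentration space, yielding the IC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PointEval",
    "DoseResponseFit",
    "DoseResponseFitError",
    "match_points",
    "eval_from_counts",
    "average_eval",
    "pearson_r",
    "fit_dose_response",
]


@dataclass(frozen=True)
class PointEval:
    """Ma/Ne/TP/FP/FN record with derived error rate and accuracy (percent).

    ``error_rate`` is None when no points were detected (Ne = 0) and
    ``accuracy`` is None when there is no ground truth (Ma = 0).
    """

    ma: int
    ne: int
    tp: int
    fp: int
    fn: int

    @property
    def error_rate(self) -> float | None:
        return 100.0 * (self.fp + self.fn) / self.ne if self.ne else None

    @property
    def accuracy(self) -> float | None:
        return 100.0 * self.tp / self.ma if self.ma else None


def eval_from_counts(ma: int, ne: int, tp: int, fp: int, fn: int) -> PointEval:
    """Build a :class:`PointEval` from raw counts."""
    for name, v in (("ma", ma), ("ne", ne), ("tp", tp), ("fp", fp), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    return PointEval(ma=ma, ne=ne, tp=tp, fp=fp, fn=fn)


def match_points(
    detected: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    radius: float,
) -> PointEval:
    """Greedy nearest-neighbor matching of detected points to ground truth.

    Candidate pairs within ``radius`` are accepted in order of increasing
    distance, each detected and each truth point matched at most once.
    TP = matched pairs, FP = unmatched detections, FN = unmatched truth.
    """
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    det = np.asarray(detected, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    tp = 0
    if len(det) and len(tru):
        d = np.linalg.norm(det[:, None, :] - tru[None, :, :], axis=2)
        pairs = [
            (d[i, j], i, j)
            for i in range(len(det))
            for j in range(len(tru))
            if d[i, j] <= radius
        ]
        pairs.sort()
        used_det: set[int] = set()
        used_tru: set[int] = set()
        for _, i, j in pairs:
            if i not in used_det and j not in used_tru:
                used_det.add(i)
                used_tru.add(j)
                tp += 1
    return eval_from_counts(
        ma=len(tru), ne=len(det), tp=tp, fp=len(det) - tp, fn=len(tru) - tp
    )


def average_eval(rows: list[PointEval]) -> tuple[float, float]:
    """Unweighted mean error rate and accuracy over per-image records.

    Averages are taken over the *unrounded* per-image values; rows whose
    error rate or accuracy is undefined are excluded from that mean.
    """
    if not rows:
        raise ValueError("need at least one PointEval row")
    errors = [r.error_rate for r in rows if r.error_rate is not None]
    accs = [r.accuracy for r in rows if r.accuracy is not None]
    mean_error = float(np.mean(errors)) if errors else float("nan")
    mean_accuracy = float(np.mean(accs)) if accs else float("nan")
    return mean_error, mean_accuracy


def pearson_r(x: list[float], y: list[float]) -> tuple[float, float]:
    """Pearson's r plus the p-value of a paired two-tailed t-test.

    The t-test is on the per-pair differences; a zero-variance difference
    (x == y everywhere up to a constant shift of zero) returns p = 1 by
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    r, _ = stats.pearsonr(x, y)
    diff = x - y
    if np.std(diff) == 0:
        # zero-variance differences: identical pairs are indistinguishable
        # (p = 1); a constant non-zero shift is unambiguously different.
        p = 1.0 if diff[0] == 0 else 0.0
    else:
        p = float(stats.ttest_rel(x, y).pvalue)
    return float(r), p


# ---------------------------------------------------------------------------
# dose-response (4PL) fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic fit of an inhibition curve."""

    bottom: float
    top: float
    ic50: float
    hill: float
    residual: float  # sum of squared errors


class DoseResponseFitError(RuntimeError):
    """Raised when the 4PL fit cannot be performed or does not converge."""

    def __init__(self, message: str, init: dict | None = None, residual: float | None = None):
        super().__init__(message)
        self.init = init
        self.residual = residual


def _four_pl(log_c: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (log_c - log_ic50)))


def fit_dose_response(
    conc: list[float], response: list[float]
) -> DoseResponseFit:
    """Least-squares 4PL fit; deterministic given the data.

    Zero (control) concentrations are excluded from the log-domain fit but
    contribute to the top-plateau initialization.  Initialization: top = max
    response, bottom = min response, ic50 = geometric midpoint of the
    positive doses, hill = 1.
    """
    conc = np.asarray(conc, dtype=float)
    response = np.asarray(response, dtype=float)
    if conc.shape != response.shape:
        raise ValueError("conc and response must have equal length")
    pos = conc > 0
    c, y = conc[pos], response[pos]
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct positive concentrations")
    if np.ptp(response) == 0:
        raise DoseResponseFitError("constant response: bottom equals top (degenerate)")
    top0 = float(response.max())  # controls, if any, inform the top plateau
    bottom0 = float(response.min())
    log_c = np.log(c)
    log_ic50_0 = float((np.log(c.min()) + np.log(c.max())) / 2.0)
    p0 = (bottom0, top0, log_ic50_0, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            _four_pl, log_c, y, p0=p0, maxfev=20000, method="lm"
        )
    except RuntimeError as exc:
        raise DoseResponseFitError(
            "4PL fit did not converge",
            init={"bottom": bottom0, "top": top0, "ic50": float(np.exp(log_ic50_0)), "hill": 1.0},
            residual=float(np.sum((_four_pl(log_c, *p0) - y) ** 2)),
        ) from exc
    bottom, top, log_ic50, hill = popt
    if bottom > top:  # canonical orientation: reflect hill
        bottom, top, hill = top, bottom, -hill
    residual = float(np.sum((_four_pl(log_c, *popt) - y) ** 2))
    return DoseResponseFit(
        bottom=float(bottom),
        top=float(top),
        ic50=float(np.exp(log_ic50)),
        hill=float(hill),
        residual=residual,
    )
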