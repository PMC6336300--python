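"""Scoring estimated stem maps against reference (tape-measured) tables.

Detection bookkeeping follows plot-inventory convention: an estimate
matched to a reference stem within the tolerance is a *correct detection*,
an unmatched estimate a *false detection*, an unmatched reference stem an
*omission*; the detection rate is correct / number of reference stems.
Accuracy of paired quantities is summarized as bias (mean estimated minus
reference), RMSE, and both as percentages of the reference mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchResult", "ErrorStats", "match_trees", "error_stats"]


@dataclass
class MatchResult:
    """Outcome of one-to-one position matching."""

    pairs: list[tuple[int, int]]  # (estimated index, reference index)
    n_reference: int
    n_estimated: int

    @property
    def correct(self) -> int:
        return len(self.pairs)

    @property
    def omission(self) -> int:
        return self.n_reference - self.correct

    @property
    def false(self) -> int:
        return self.n_estimated - self.correct

    @property
    def detection_rate(self) -> float:
        if self.n_reference == 0:
            return 0.0
        return self.correct / self.n_reference


@dataclass
class ErrorStats:
    """Bias / RMSE summary of paired estimates.

    ``bias = mean(est - ref)``; ``rmse = sqrt(mean((est - ref)^2))``;
    percentages are relative to the reference mean.  ``rmse^2 = bias^2 +
    var(errors)`` holds by construction.
    """

    bias: float
    bias_pct: float
    rmse: float
    rmse_pct: float
    n: int


def match_trees(estimated, reference, max_dist: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of plan positions within ``max_dist``.

    Pairs are claimed globally nearest-first, so the result does not depend
    on input ordering beyond exact-tie resolution.  ``estimated`` and
    ``reference`` are (n, 2) arrays of (x, y) in metres.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    est = np.atleast_2d(np.asarray(estimated, dtype=float)) if len(estimated) else np.zeros((0, 2))
    ref = np.atleast_2d(np.asarray(reference, dtype=float)) if len(reference) else np.zeros((0, 2))
    pairs: list[tuple[int, int]] = []
    if len(est) and len(ref):
        d = np.linalg.norm(est[:, None, :] - ref[None, :, :], axis=2)
        d = d.copy()
        while True:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] > max_dist:
                break
            pairs.append((int(i), int(j)))
            d[i, :] = np.inf
            d[:, j] = np.inf
            if not np.isfinite(d).any():
                break
    return MatchResult(pairs=pairs, n_reference=len(ref), n_estimated=len(est))


def error_stats(estimates, references) -> ErrorStats:
    """Bias and RMSE of paired scalar estimates.

    Percentages are the statistic divided by the mean reference value,
    times 100.
    """
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape or e.ndim != 1:
        raise ValueError("estimates and references must be equal-length 1-D")
    if e.size == 0:
        raise ValueError("empty pairing")
    err = e - r
    bias = float(err.mean())
    rmse = float(np.sqrt(np.mean(err**2)))
    ref_mean = float(r.mean())
    scale = 100.0 / ref_mean if ref_mean != 0 else float("nan")
    return ErrorStats(
        bias=bias,
        bias_pct=bias * scale,
        rmse=rmse,
        rmse_pct=rmse * scale,
        n=e.size,
    )
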