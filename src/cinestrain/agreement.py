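"""Agreement statistics between two curves: Pearson r, MSE, Bland-Altman.

Used to compare strain curves across modalities (cine vs tagged) and
against phantom ground truth.  The Bland-Altman analysis reports the bias
(mean pairwise difference) and the 95 % limits of agreement
bias +- 1.96 x SD of the differences.  With ``normalize=True`` each curve
is first divided by its maximum absolute value and the MSE is reported in
percent (x100), the scale used for normalized-curve comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedTermError

#: 95 % limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96


@dataclass
class AgreementReport:
    corcoef: float
    mse: float            # units^2, or % when normalized
    bias: float
    loa_low: float
    loa_high: float
    n: int
    normalized: bool = False
    differences: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "corcoef": self.corcoef, "mse": self.mse, "bias": self.bias,
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "n": self.n, "normalized": self.normalized,
        }


def curve_agreement(a, b, normalize: bool = False) -> AgreementReport:
    """Compare two equal-length curves (n >= 3)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("curves must be 1-D and of equal length")
    if len(a) < 3:
        raise ValueError("agreement needs at least 3 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedTermError("zero-variance curve: correlation undefined")

    if normalize:
        a = a / np.max(np.abs(a))
        b = b / np.max(np.abs(b))

    r = float(stats.pearsonr(a, b).statistic)
    mse = float(np.mean((a - b) ** 2))
    if normalize:
        mse *= 100.0
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(
        corcoef=r,
        mse=mse,
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        n=len(a),
        normalized=normalize,
        differences=diff,
    )
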