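"""Reproducibility metrics for repeated measurements and repeated ordinal readings.

* ``rms_cv`` — precision error of repeated continuous measurements (e.g. the
  same cartilage segmented three times): root mean square across subjects of
  the per-subject coefficient of variation, in percent.
* ``icc`` — two-way, absolute-agreement, single-measure intraclass
  correlation (ICC(2,1) in the Shrout-Fleiss taxonomy).
* ``quadratic_weighted_kappa`` — chance-corrected agreement for two raters on
  an ordinal scale with quadratic disagreement weights; numerically close to
  the agreement ICC on the same data, which is why either serves as the
  reliability summary for ordinal scores.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .exceptions import DegenerateDataError, InputError

__all__ = ["rms_cv", "icc", "quadratic_weighted_kappa"]


def rms_cv(data: Mapping[object, Sequence[float]] | Sequence[Sequence[float]]) -> float:
    """RMS coefficient of variation (%) over subjects with >= 2 repeats each.

    Per subject CV = sample SD (ddof=1) / mean; the result is
    ``100 * sqrt(mean(CV^2))``. Subject means must be positive.
    """
    groups = list(data.values()) if isinstance(data, Mapping) else list(data)
    if not groups:
        raise InputError("no subjects")
    cvs = []
    for reps in groups:
        reps = np.asarray(reps, dtype=float)
        if reps.size < 2:
            raise InputError("every subject needs >= 2 repeated measurements")
        m = reps.mean()
        if m <= 0:
            raise InputError("subject mean must be > 0 for a CV")
        cvs.append(reps.std(ddof=1) / m)
    return float(100.0 * np.sqrt(np.mean(np.square(cvs))))


def icc(ratings) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n subjects x k raters/occasions) array with no missing
    cells. Computed from the standard mean-squares decomposition.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("ratings must be n x k with n >= 2 subjects, k >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise DegenerateDataError("zero total variance in ratings")
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_rows = k * np.sum((row_m - grand) ** 2)
    ss_cols = n * np.sum((col_m - grand) ** 2)
    ss_err = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("degenerate mean squares")
    return float((msr - mse) / denom)


def quadratic_weighted_kappa(r1: Sequence[float], r2: Sequence[float],
                             scale: Sequence[float] | None = None) -> float:
    """Weighted kappa with quadratic weights ``w(i,j) = (i-j)^2 / (k-1)^2``.

    ``scale`` declares the ordered categories; by default the sorted union of
    observed scores. Returns ``1 - sum(w*O) / sum(w*E)`` with O the observed
    and E the chance-expected (outer product of marginals) pair proportions.
    """
    a = np.asarray(r1, dtype=float)
    b = np.asarray(r2, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InputError("r1 and r2 must be equal-length 1D score vectors")
    cats = np.asarray(sorted(set(a) | set(b)) if scale is None else list(scale),
                      dtype=float)
    k = cats.size
    if k < 2:
        raise DegenerateDataError("both raters used a single category")
    ia = np.searchsorted(cats, a)
    ib = np.searchsorted(cats, b)
    if np.any(cats[ia] != a) or np.any(cats[ib] != b):
        raise InputError("scores outside the declared scale")
    n = a.size
    obs = np.zeros((k, k))
    np.add.at(obs, (ia, ib), 1.0 / n)
    expd = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    w = (cats[:, None] - cats[None, :]) ** 2 / (cats[-1] - cats[0]) ** 2
    we = np.sum(w * expd)
    if we == 0:
        raise DegenerateDataError("degenerate marginals: no expected disagreement")
    return float(1.0 - np.sum(w * obs) / we)
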