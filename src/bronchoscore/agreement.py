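"""Chance-corrected inter-rater agreement coefficients.

Implements Gwet's AC1/AC2 for any number of raters with agreement weights,
a linearized (influence-function) variance estimator with Student-t
confidence intervals, Cohen's weighted kappa for two-rater cross tables
(methodological comparison only), percent agreement, pairwise coefficients,
and Landis-Koch interpretation bands.

Notation
--------
For n subjects, R raters and q categories, let ``r_ik`` be the number of
raters assigning subject i to category k and ``r_i = sum_k r_ik``.  With
agreement weights ``w_kl`` (1 on the diagonal), the weighted rater count is
``r*_ik = sum_l w_kl r_il``.  Observed weighted agreement averages

    p_a|i = sum_k r_ik (r*_ik - 1) / (r_i (r_i - 1))

over the n' subjects with at least two raters.  Chance agreement uses the
mean category prevalences ``pi_k = (1/n) sum_i r_ik / r_i``:

    p_e = T_w / (q (q - 1)) * sum_k pi_k (1 - pi_k),   T_w = sum_kl w_kl.

The coefficient is ``(p_a - p_e) / (1 - p_e)``; with identity weights this
is the unweighted AC1.  Chance correction through mean prevalences (rather
than per-rater marginals, as in kappa) is what makes the coefficient robust
to strongly imbalanced category distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

BANDS = ("slight_poor", "fair", "moderate", "substantial", "almost_perfect")

WEIGHT_KINDS = ("identity", "linear", "quadratic", "ordinal")


class AgreementError(ValueError):
    """Raised when an agreement coefficient is undefined for the input."""


def interpret_band(coefficient: float) -> str:
    """Landis-Koch verbal interpretation of an agreement coefficient.

    Contiguous half-open intervals: <=0.20 slight_poor, (0.20, 0.40] fair,
    (0.40, 0.60] moderate, (0.60, 0.80] substantial, >0.80 almost_perfect.
    Total on the reals: values above 1 map to almost_perfect, negative
    values to slight_poor.
    """
    c = float(coefficient)
    if c <= 0.20:
        return "slight_poor"
    if c <= 0.40:
        return "fair"
    if c <= 0.60:
        return "moderate"
    if c <= 0.80:
        return "substantial"
    return "almost_perfect"


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric q x q agreement weights with unit diagonal."""

    kind: str
    q: int
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        if w.shape != (self.q, self.q):
            raise ValueError(f"weight matrix must be {self.q}x{self.q}")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("weight matrix diagonal must be 1")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("weights must lie in [0, 1]")
        object.__setattr__(self, "w", w)

    @property
    def total(self) -> float:
        """T_w, the sum of all weights (q for identity weights)."""
        return float(self.w.sum())


def make_weights(kind: str, q: int) -> WeightMatrix:
    """Build an agreement weight matrix over ``q`` ordered categories.

    ``identity``: w_kl = 1{k=l} (unweighted; AC1).
    ``linear``:   w_kl = 1 - d/(q-1).
    ``quadratic``: w_kl = 1 - d^2/(q-1)^2.
    ``ordinal``:  w_kl = 1 - d(d+1)/(q(q-1)),
    with d = |k - l|.
    """
    if q < 2:
        raise AgreementError(
            f"agreement is undefined for a single category (q={q})"
        )
    if kind not in WEIGHT_KINDS:
        raise ValueError(f"unknown weight kind {kind!r}; use {WEIGHT_KINDS}")
    k = np.arange(q)
    d = np.abs(k[:, None] - k[None, :]).astype(float)
    if kind == "identity":
        w = (d == 0).astype(float)
    elif kind == "linear":
        w = 1.0 - d / (q - 1)
    elif kind == "quadratic":
        w = 1.0 - d**2 / (q - 1) ** 2
    else:  # ordinal
        w = 1.0 - d * (d + 1) / (q * (q - 1))
    return WeightMatrix(kind=kind, q=q, w=w)


@dataclass(frozen=True)
class AgreementEstimate:
    """One agreement coefficient with its uncertainty and interpretation."""

    method: str
    coefficient: float
    p_a: float
    p_e: float
    se: float
    ci_low: float
    ci_high: float
    n_subjects: int
    weights_kind: str
    band: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "band", interpret_band(self.coefficient))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "coefficient": self.coefficient,
            "p_a": self.p_a,
            "p_e": self.p_e,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_subjects": self.n_subjects,
            "weights_kind": self.weights_kind,
            "band": self.band,
        }


def counts_from_assignments(
    assignments: np.ndarray | pd.DataFrame, q: int
) -> np.ndarray:
    """Reduce a (subjects x raters) category table to per-subject counts.

    ``assignments`` holds integer categories in ``[0, q)``; missing ratings
    are NaN (DataFrame) or negative (ndarray).  Returns the n x q matrix of
    rater counts r_ik.
    """
    arr = np.asarray(assignments, dtype=float)
    if arr.ndim != 2:
        raise ValueError("assignments must be 2-D (subjects x raters)")
    counts = np.zeros((arr.shape[0], q), dtype=int)
    valid = ~np.isnan(arr)
    vals = arr[valid]
    if vals.size and (vals.min() < 0 or vals.max() >= q):
        raise ValueError(
            f"category out of range [0, {q}): "
            f"min={vals.min()}, max={vals.max()}"
        )
    rows = np.nonzero(valid)[0]
    np.add.at(counts, (rows, vals.astype(int)), 1)
    return counts


def pair_table_to_counts(table: np.ndarray) -> np.ndarray:
    """Expand a two-rater q x q cross table into per-subject count rows."""
    table = np.asarray(table, dtype=int)
    q = table.shape[0]
    rows = []
    for k in range(q):
        for l in range(q):
            m = table[k, l]
            if m == 0:
                continue
            row = np.zeros(q, dtype=int)
            row[k] += 1
            row[l] += 1
            rows.append(np.tile(row, (m, 1)))
    if not rows:
        raise AgreementError("empty cross table")
    return np.vstack(rows)


def gwet_agreement(
    counts: np.ndarray,
    weights: WeightMatrix,
    *,
    alpha: float = 0.05,
    fpc: float = 0.0,
) -> AgreementEstimate:
    """Gwet's AC1/AC2 from per-subject category counts.

    Parameters
    ----------
    counts
        n x q integer matrix ``r_ik``; subjects with fewer than two raters
        contribute to prevalences but not to observed agreement.
    weights
        Agreement weights; identity weights give the unweighted AC1.
    alpha
        Two-sided CI level (default 95%).
    fpc
        Finite-population sampling fraction f; 0 treats the subjects as a
        sample from an infinite population.

    Notes
    -----
    The variance is the linearized per-subject estimator: with
    gamma_i = (n/n') (p_a|i - p_e) / (1 - p_e) (zero p_a|i and p_e for
    single-rated subjects) and the chance-agreement linearization
    p_e|i = T_w/(q(q-1)) sum_k (r_ik/r_i)(1 - pi_k),

        gamma*_i = gamma_i - 2 (1 - gamma) (p_e|i - p_e) / (1 - p_e),
        var = (1 - f) / (n (n - 1)) * sum_i (gamma*_i - gamma)^2.

    The CI is gamma +/- t_{1-alpha/2, n-1} * se, deliberately not truncated
    to [-1, 1].
    """
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (subjects x categories)")
    n, q = counts.shape
    if q != weights.q:
        raise ValueError(
            f"counts have {q} categories but weights are for {weights.q}"
        )
    r_i = counts.sum(axis=1)
    multi = r_i >= 2
    n_multi = int(multi.sum())
    if n_multi == 0:
        raise AgreementError(
            "observed agreement undefined: no subject has >= 2 ratings"
        )
    w = weights.w
    # prevalences over all rated subjects
    rated = r_i > 0
    pi = np.zeros(q)
    pi[:] = (counts[rated] / r_i[rated, None]).sum(axis=0) / n

    rstar = counts @ w.T  # r*_ik = sum_l w_kl r_il
    num = (counts * (rstar - 1.0)).sum(axis=1)
    denom = r_i * (r_i - 1.0)
    pa_i = np.zeros(n)
    pa_i[multi] = num[multi] / denom[multi]
    p_a = float(pa_i[multi].mean())

    t_w = weights.total
    p_e = float(t_w / (q * (q - 1)) * (pi * (1.0 - pi)).sum())
    if p_e >= 1.0 - 1e-15:
        raise AgreementError("degenerate chance agreement (p_e = 1)")
    coef = (p_a - p_e) / (1.0 - p_e)

    # linearized variance
    if n > 1:
        scale = n / n_multi
        gamma_i = scale * (pa_i - p_e * multi) / (1.0 - p_e)
        pe_i = np.zeros(n)
        pe_i[rated] = (
            t_w / (q * (q - 1))
            * (counts[rated] * (1.0 - pi)[None, :]).sum(axis=1)
            / r_i[rated]
        )
        gamma_star = gamma_i - 2.0 * (1.0 - coef) * (pe_i - p_e) / (1.0 - p_e)
        var = (1.0 - fpc) / (n * (n - 1)) * ((gamma_star - coef) ** 2).sum()
        se = float(np.sqrt(max(var, 0.0)))
        tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
    else:
        se = float("nan")
        tcrit = float("nan")
    method = "gwet_ac1" if weights.kind == "identity" else "gwet_ac2"
    return AgreementEstimate(
        method=method,
        coefficient=float(coef),
        p_a=p_a,
        p_e=p_e,
        se=se,
        ci_low=float(coef - tcrit * se),
        ci_high=float(coef + tcrit * se),
        n_subjects=n,
        weights_kind=weights.kind,
    )


def percent_agreement(counts: np.ndarray) -> AgreementEstimate:
    """Raw (unweighted, chance-uncorrected) pairwise percent agreement."""
    counts = np.asarray(counts)
    n, q = counts.shape
    r_i = counts.sum(axis=1)
    multi = r_i >= 2
    if not multi.any():
        raise AgreementError(
            "observed agreement undefined: no subject has >= 2 ratings"
        )
    num = (counts * (counts - 1.0)).sum(axis=1)
    pa_i = num[multi] / (r_i[multi] * (r_i[multi] - 1.0))
    p_a = float(pa_i.mean())
    m = pa_i.size
    se = float(pa_i.std(ddof=1) / np.sqrt(m)) if m > 1 else float("nan")
    tcrit = float(stats.t.ppf(0.975, m - 1)) if m > 1 else float("nan")
    return AgreementEstimate(
        method="percent_agreement",
        coefficient=p_a,
        p_a=p_a,
        p_e=0.0,
        se=se,
        ci_low=p_a - tcrit * se,
        ci_high=p_a + tcrit * se,
        n_subjects=n,
        weights_kind="identity",
    )


def cohen_weighted_kappa(
    pair_table: np.ndarray,
    weights: WeightMatrix,
    *,
    alpha: float = 0.05,
) -> AgreementEstimate:
    """Cohen's weighted kappa for a two-rater q x q cross table.

    p_a = sum_kl w_kl p_kl; p_e = sum_kl w_kl p_k+ p_+l;
    kappa_w = (p_a - p_e)/(1 - p_e).  The standard error is the
    Fleiss-Cohen-Everitt large-sample estimator; the CI uses t(N-1).
    Kappa corrects chance through the product of the two raters' marginals,
    which is what exposes it to the prevalence paradox on imbalanced data.
    """
    table = np.asarray(pair_table, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError("pair_table must be square (q x q)")
    if table.shape[0] != weights.q:
        raise ValueError("pair_table and weights disagree on q")
    total = table.sum()
    if total < 1:
        raise AgreementError("empty cross table")
    p = table / total
    w = weights.w
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_a = float((w * p).sum())
    p_e = float((w * np.outer(row, col)).sum())
    if p_e >= 1.0 - 1e-15:
        raise AgreementError("degenerate chance agreement (p_e = 1)")
    kappa = (p_a - p_e) / (1.0 - p_e)

    wbar_row = w @ col  # wbar_k. = sum_l w_kl p_+l
    wbar_col = row @ w  # wbar_.l = sum_k w_kl p_k+
    term = (
        w * (1.0 - p_e)
        - (wbar_row[:, None] + wbar_col[None, :]) * (1.0 - p_a)
    )
    var = (
        (p * term**2).sum() - (p_a * p_e - 2 * p_e + p_a) ** 2
    ) / (total * (1.0 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    n = int(round(total))
    tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1)) if n > 1 else float("nan")
    return AgreementEstimate(
        method="cohen_weighted_kappa",
        coefficient=float(kappa),
        p_a=p_a,
        p_e=p_e,
        se=se,
        ci_low=float(kappa - tcrit * se),
        ci_high=float(kappa + tcrit * se),
        n_subjects=n,
        weights_kind=weights.kind,
    )


def pairwise_agreement(
    assignments: pd.DataFrame,
    weights: WeightMatrix,
    *,
    alpha: float = 0.05,
) -> list[tuple[str, str, Optional[AgreementEstimate], Optional[str]]]:
    """Gwet coefficient for every unordered rater pair.

    Parameters
    ----------
    assignments
        Subjects x raters DataFrame of integer categories (NaN = missing).

    Returns
    -------
    List of ``(rater_a, rater_b, estimate, reason)`` in column order; a pair
    with no co-rated subjects is flagged absent (estimate None with a
    reason) rather than reported as zero.
    """
    raters = list(assignments.columns)
    if len(raters) < 2:
        raise AgreementError("pairwise agreement needs at least 2 raters")
    out: list[tuple[str, str, Optional[AgreementEstimate], Optional[str]]] = []
    for a_idx in range(len(raters)):
        for b_idx in range(a_idx + 1, len(raters)):
            a, b = raters[a_idx], raters[b_idx]
            sub = assignments[[a, b]].dropna()
            if sub.empty:
                out.append((a, b, None, "no co-rated subjects"))
                continue
            counts = counts_from_assignments(sub.to_numpy(), weights.q)
            try:
                est = gwet_agreement(counts, weights, alpha=alpha)
            except AgreementError as exc:
                out.append((a, b, None, str(exc)))
                continue
            out.append((a, b, est, None))
    return out


def jackknife_se(counts: np.ndarray, weights: WeightMatrix) -> float:
    """Leave-one-subject-out jackknife SE of the Gwet coefficient.

    Independent of the linearized estimator; used to validate it.
    """
    counts = np.asarray(counts)
    n = counts.shape[0]
    if n < 2:
        raise AgreementError("jackknife needs >= 2 subjects")
    loo = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        sub = counts[idx != i]
        loo[i] = gwet_agreement(sub, weights).coefficient
    return float(np.sqrt((n - 1) / n * ((loo - loo.mean()) ** 2).sum()))
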