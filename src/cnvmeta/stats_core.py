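"""Statistical kernels for stratified carrier association and burden tests.

The workhorse is the Cochran–Mantel–Haenszel (CMH) score test over
per-stratum 2x2 carrier tables, paired with the Mantel–Haenszel common odds
ratio and its Robins–Breslow–Greenland (RBG) confidence interval. Loci with
no carriers in a stratum contribute nothing to that stratum's score or
variance; a locus whose every stratum is degenerate is flagged rather than
dropped.

Genome-wide significance is calibrated empirically by min(P) permutation:
case/control labels are shuffled *within* each stratum (so the stratum case
counts, and hence the conditioning, are preserved), all per-locus CMH
p-values are recomputed, and the minimum across loci is recorded per
iteration. The alpha-quantile of those minima is the family-wise
significance threshold, and per-locus FWER-adjusted p-values use the
(r + 1) / (n + 1) convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StratumCounts",
    "StratifiedCountTable",
    "TestResult",
    "PermutationNull",
    "MinPResult",
    "cmh_test",
    "fisher_or",
    "fit_burden_logistic",
    "minp_permutation",
    "adjust_two_rounds",
    "genomic_lambda",
    "NULL_CHI2_MEDIAN",
]

# median of chi-square with 1 df; denominator of the inflation factor
NULL_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.45494


@dataclass(frozen=True)
class StratumCounts:
    """One stratum's 2x2 carrier table: carriers / totals per arm."""

    stratum_id: str
    case_carriers: int
    case_total: int
    control_carriers: int
    control_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.case_carriers <= self.case_total):
            raise ValueError(
                f"stratum {self.stratum_id}: case carriers {self.case_carriers} "
                f"outside [0, {self.case_total}]"
            )
        if not (0 <= self.control_carriers <= self.control_total):
            raise ValueError(
                f"stratum {self.stratum_id}: control carriers {self.control_carriers} "
                f"outside [0, {self.control_total}]"
            )

    def as_2x2(self) -> tuple[int, int, int, int]:
        """(a, b, c, d): case carriers/non-carriers, control carriers/non-carriers."""
        return (
            self.case_carriers,
            self.case_total - self.case_carriers,
            self.control_carriers,
            self.control_total - self.control_carriers,
        )


@dataclass(frozen=True)
class StratifiedCountTable:
    """Per-locus carrier counts across strata — the exchange format used to
    fold in external datasets available only as summary counts."""

    locus_id: str
    cnv_type: str
    strata: tuple[StratumCounts, ...]

    def __post_init__(self) -> None:
        seen = set()
        for s in self.strata:
            if s.stratum_id in seen:
                raise ValueError(f"duplicate stratum {s.stratum_id} in {self.locus_id}")
            seen.add(s.stratum_id)


@dataclass
class TestResult:
    """A single association/burden test outcome."""

    statistic: float
    p: float
    or_mh: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_strata_informative: int = 0
    degenerate: bool = False
    p_adjusted: float | None = None


@dataclass
class PermutationNull:
    """The empirical min(P) null distribution for one test family."""

    n_perm: int
    min_p: np.ndarray
    alpha: float
    threshold: float
    seed: int


@dataclass
class MinPResult:
    null: PermutationNull
    p_observed: np.ndarray
    p_adjusted: np.ndarray


# ---------------------------------------------------------------------------
# CMH test and MH odds ratio
# ---------------------------------------------------------------------------

def _cmh_terms(tables: Sequence[tuple[int, int, int, int]]):
    """Score numerator terms, hypergeometric variances, and MH OR sums."""
    num = 0.0          # sum of (a - E[a])
    var = 0.0          # sum of Var(a)
    R = 0.0            # sum a*d/n
    S = 0.0            # sum b*c/n
    # RBG variance components
    sPR = sPSQR = sQS = 0.0
    n_informative = 0
    for a, b, c, d in tables:
        n = a + b + c + d
        if n == 0:
            continue
        n1 = a + b  # cases
        n0 = c + d  # controls
        m1 = a + c  # carriers
        m0 = b + d
        if m1 == 0 or m0 == 0 or n1 == 0 or n0 == 0:
            # no contrast available in this stratum
            continue
        n_informative += 1
        num += a - n1 * m1 / n
        if n > 1:
            var += n1 * n0 * m1 * m0 / (n * n * (n - 1))
        R += a * d / n
        S += b * c / n
        P = (a + d) / n
        Q = (b + c) / n
        sPR += P * (a * d / n)
        sPSQR += P * (b * c / n) + Q * (a * d / n)
        sQS += Q * (b * c / n)
    return num, var, R, S, sPR, sPSQR, sQS, n_informative


def cmh_test(
    table: StratifiedCountTable | Sequence[tuple[int, int, int, int]],
    continuity: bool = False,
    ci_level: float = 0.95,
) -> TestResult:
    """Cochran–Mantel–Haenszel test with MH common OR and RBG CI.

    The statistic is ``(sum_i (a_i - E[a_i]))^2 / sum_i Var(a_i)`` with the
    hypergeometric moments per stratum, referred to chi-square with 1 df
    (two-sided). The common odds ratio is the Mantel–Haenszel estimator
    ``sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``; its CI uses the
    Robins–Breslow–Greenland variance of the log OR. Strata with a zero
    carrier or arm margin are skipped (they carry no information about the
    odds ratio); if every stratum is degenerate the result is flagged with
    ``p = 1`` and an undefined OR.
    """
    if isinstance(table, StratifiedCountTable):
        tables = [s.as_2x2() for s in table.strata]
    else:
        tables = [tuple(int(x) for x in t) for t in table]
    if not tables:
        raise ValueError("need at least one stratum")
    num, var, R, S, sPR, sPSQR, sQS, n_inf = _cmh_terms(tables)

    if n_inf == 0 or var <= 0:
        return TestResult(statistic=0.0, p=1.0, degenerate=True,
                          n_strata_informative=n_inf)

    if continuity:
        stat = max(0.0, abs(num) - 0.5) ** 2 / var
    else:
        stat = num * num / var
    p = float(stats.chi2.sf(stat, 1))
    p = min(max(p, np.finfo(float).tiny), 1.0)

    or_mh = ci_low = ci_high = None
    if S > 0 and R == 0:
        or_mh = 0.0  # carriers only in the control arm; CI undefined
    elif S > 0 and R > 0:
        or_mh = R / S
        var_log = sPR / (2 * R * R) + sPSQR / (2 * R * S) + sQS / (2 * S * S)
        z = stats.norm.ppf(0.5 + ci_level / 2)
        half = z * np.sqrt(var_log)
        ci_low = float(np.exp(np.log(or_mh) - half))
        ci_high = float(np.exp(np.log(or_mh) + half))
    elif S == 0 and R > 0:
        or_mh = float("inf")

    return TestResult(
        statistic=float(stat), p=p, or_mh=or_mh, ci_low=ci_low, ci_high=ci_high,
        n_strata_informative=n_inf,
    )


def fisher_or(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Sample odds ratio and two-sided exact p for one 2x2 table.

    Returns ``(or, p)`` with ``or = (a*d)/(b*c)`` (``inf`` when ``b*c = 0``
    and ``a*d > 0``) and p from Fisher's exact hypergeometric test.
    """
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"cell {name} must be nonnegative, got {v}")
    if a + b + c + d == 0:
        raise ValueError("all-zero 2x2 table")
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else float("nan")
    else:
        sample_or = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return sample_or, float(p)


# ---------------------------------------------------------------------------
# Burden logistic regression
# ---------------------------------------------------------------------------

class NonIdentifiableModelError(RuntimeError):
    """The burden model cannot be fit (constant burden or perfect separation)."""


def fit_burden_logistic(
    status: Sequence[int] | np.ndarray,
    burden: Sequence[float] | np.ndarray,
    group: Sequence[str],
    lrr_sd: Sequence[float] | np.ndarray,
    n_cnv_raw: Sequence[int] | np.ndarray,
    ci_level: float = 0.95,
) -> TestResult:
    """Fit ``status ~ burden + GROUP + lrr_sd + n_cnv_raw`` by logistic ML.

    GROUP (the stratum label) enters as categorical indicators; the returned
    OR is ``exp`` of the burden coefficient with a Wald CI and p-value.
    Constant burden or (quasi-)perfect separation raises
    :class:`NonIdentifiableModelError` rather than returning a runaway
    estimate.
    """
    import pandas as pd
    import statsmodels.api as sm

    y = np.asarray(status, dtype=float)
    x = np.asarray(burden, dtype=float)
    if np.ptp(x) == 0:
        raise NonIdentifiableModelError("burden metric is constant across samples")
    groups = pd.Series([str(g) for g in group], name="GROUP")
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("GROUP must have at least 2 levels")
    dummies = pd.get_dummies(groups, prefix="GROUP", drop_first=True, dtype=float)
    X = pd.DataFrame({
        "burden": x,
        "lrr_sd": np.asarray(lrr_sd, dtype=float),
        "n_cnv_raw": np.asarray(n_cnv_raw, dtype=float),
    })
    # zero-variance nuisance covariates are collinear with the intercept
    for col in ("lrr_sd", "n_cnv_raw"):
        if np.ptp(X[col].to_numpy()) == 0:
            X = X.drop(columns=col)
    X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparation or numerical blowup
            raise NonIdentifiableModelError(f"logistic fit failed: {exc}") from exc
    beta = res.params["burden"]
    se = res.bse["burden"]
    if not np.isfinite(beta) or not np.isfinite(se) or se > 50:
        raise NonIdentifiableModelError(
            "burden coefficient not identifiable (separation suspected)"
        )
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return TestResult(
        statistic=float(beta / se),
        p=float(res.pvalues["burden"]),
        or_mh=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        n_strata_informative=len(levels),
    )


# ---------------------------------------------------------------------------
# min(P) permutation machinery
# ---------------------------------------------------------------------------

def _cmh_score_arrays(
    carrier: np.ndarray,
    stratum_indices: Sequence[np.ndarray],
    is_case: np.ndarray,
):
    """Per-locus CMH score numerator and variance, summed over strata.

    Within a stratum the carrier totals per locus are fixed margins, so the
    hypergeometric expectation and variance of the case-carrier count depend
    only on (stratum size, case count, carrier count) — the ingredients the
    permutation loop reuses.
    """
    n_loci = carrier.shape[1]
    num = np.zeros(n_loci)
    var = np.zeros(n_loci)
    for idx in stratum_indices:
        sub = carrier[idx]
        case_mask = is_case[idx]
        n = len(idx)
        n1 = int(case_mask.sum())
        m1 = sub.sum(axis=0).astype(float)
        a = sub[case_mask].sum(axis=0).astype(float)
        e = n1 * m1 / n
        num += a - e
        if n > 1:
            var += n1 * (n - n1) * m1 * (n - m1) / (n * n * (n - 1.0))
    return num, var


def _p_from_score(num: np.ndarray, var: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, num * num / np.maximum(var, 1e-300), 0.0)
    p = stats.chi2.sf(chi2, 1)
    p[var <= 0] = 1.0
    return np.clip(p, np.finfo(float).tiny, 1.0)


def minp_permutation(
    carrier_matrix: np.ndarray,
    stratum_indices: Sequence[np.ndarray],
    is_case: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    external_num: np.ndarray | None = None,
    external_var: np.ndarray | None = None,
    chunk: int = 512,
) -> MinPResult:
    """Stratified min(P) permutation null for a family of locus tests.

    ``carrier_matrix`` is (n_samples, n_loci) carrier indicators;
    ``stratum_indices`` lists each stratum's row indices; ``is_case`` is the
    observed label vector. Each iteration reassigns case labels uniformly at
    random within every stratum (stratum case counts preserved), recomputes
    every locus's CMH p, and records the minimum. The significance
    threshold is the k-th smallest minimum with ``k = max(1, floor(alpha *
    n_perm))``; adjusted p-values use ``(r + 1) / (n_perm + 1)``.

    External summary-count strata, which have no permutable labels, enter
    as fixed per-locus score/variance contributions (``external_num``,
    ``external_var``) held constant across iterations.
    """
    carrier = np.ascontiguousarray(carrier_matrix, dtype=np.float32)
    if carrier.ndim != 2 or carrier.shape[1] == 0:
        raise ValueError("carrier_matrix must be (n_samples, n_loci) with >= 1 locus")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; threshold will be noisy", stacklevel=2)
    is_case = np.asarray(is_case, dtype=bool)
    n_loci = carrier.shape[1]
    ext_num = np.zeros(n_loci) if external_num is None else np.asarray(external_num, float)
    ext_var = np.zeros(n_loci) if external_var is None else np.asarray(external_var, float)

    obs_num, obs_var = _cmh_score_arrays(carrier, stratum_indices, is_case)
    p_obs = _p_from_score(obs_num + ext_num, obs_var + ext_var)

    rng = np.random.default_rng(seed)
    # per-stratum fixed pieces
    strata_info = []
    for idx in stratum_indices:
        sub = carrier[idx]  # (n_s, n_loci)
        n = len(idx)
        n1 = int(is_case[idx].sum())
        m1 = sub.sum(axis=0, dtype=np.float64)
        e = n1 * m1 / n
        v = n1 * (n - n1) * m1 * (n - m1) / (n * n * max(n - 1, 1)) if n > 1 else np.zeros(n_loci)
        strata_info.append((sub, n, n1, e, v))
    var_total = ext_var + sum(v for *_, v in strata_info)

    min_p = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        num = np.tile(ext_num, (b, 1))
        for sub, n, n1, e, _v in strata_info:
            base = np.zeros((b, n), dtype=np.float32)
            base[:, :n1] = 1.0
            mask = rng.permuted(base, axis=1)
            a = mask @ sub  # (b, n_loci)
            num += a.astype(np.float64) - e
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(var_total > 0, num * num / np.maximum(var_total, 1e-300), 0.0)
        p = stats.chi2.sf(chi2, 1)
        p[:, var_total <= 0] = 1.0
        min_p[done:done + b] = np.clip(p, np.finfo(float).tiny, 1.0).min(axis=1)
        done += b

    k = max(1, int(np.floor(alpha * n_perm)))
    threshold = float(np.sort(min_p)[k - 1])
    exceed = (min_p[None, :] <= p_obs[:, None]).sum(axis=1)
    p_adj = (1.0 + exceed) / (n_perm + 1.0)
    null = PermutationNull(n_perm=n_perm, min_p=min_p, alpha=alpha,
                           threshold=threshold, seed=seed)
    return MinPResult(null=null, p_observed=p_obs, p_adjusted=p_adj)


def external_score_terms(tables: Sequence[StratifiedCountTable], locus_order: Sequence[str]):
    """Fixed per-locus (score numerator, variance) from summary-count strata."""
    pos = {locus: i for i, locus in enumerate(locus_order)}
    num = np.zeros(len(locus_order))
    var = np.zeros(len(locus_order))
    for t in tables:
        if t.locus_id not in pos:
            continue
        i = pos[t.locus_id]
        n_, v_, *_rest = _cmh_terms([s.as_2x2() for s in t.strata])
        num[i] += n_
        var[i] += v_
    return num, var


# ---------------------------------------------------------------------------
# p-value bookkeeping
# ---------------------------------------------------------------------------

def adjust_two_rounds(p: float | np.ndarray) -> float | np.ndarray:
    """Bonferroni-style doubling for the two test rounds, capped at 1."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    out = np.minimum(2.0 * arr, 1.0)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def genomic_lambda(p_values: Sequence[float] | np.ndarray) -> float:
    """Genomic inflation factor: median implied chi-square / null median.

    Each p is mapped to the 1-df chi-square quantile it implies; the median
    of those, divided by the null chi-square median (~0.455), is lambda.
    Values near 1 indicate calibrated tests; > 1 indicates inflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / NULL_CHI2_MEDIAN)
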