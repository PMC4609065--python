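"""Exact-test statistical primitives for genetic-model association analysis.

Implements the contingency machinery used throughout the pipeline:

* genetic-model table construction (allele / dominant / recessive / genotype)
  from per-group genotype counts,
* two-sided Fisher exact tests for 2x2 and general r x c tables,
* odds ratios under the sample (cross-product) and conditional-MLE
  conventions, with Woolf and conditional-exact confidence intervals,
* the Hardy-Weinberg exact test, and
* Benjamini-Hochberg q-values.

The two-sided Fisher p is defined as the sum of conditional point
probabilities not exceeding the observed table's probability (relative tie
tolerance 1e-7), the convention used by the common statistical environments
that produced the study's printed p-values.  The conditional-MLE odds ratio
is the estimate those environments print alongside it; "OR = 0" corresponds
to an observed count at the boundary of its conditional support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

__all__ = [
    "GENETIC_MODELS",
    "TIE_REL_TOL",
    "ModelTable",
    "AssociationResult",
    "build_model_table",
    "model_table_from_doses",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "fisher_p_lookup",
    "odds_ratio",
    "or_confidence_interval",
    "conditional_mle_or",
    "hwe_exact_test",
    "bh_adjust",
    "associate",
]

GENETIC_MODELS = ("allele", "dominant", "recessive", "genotype")

#: relative tolerance when comparing point probabilities for ties
TIE_REL_TOL = 1e-7


@dataclass
class ModelTable:
    """Integer contingency table with genetic-model provenance."""

    cells: np.ndarray
    model: str
    snp_id: str | None = None
    row_labels: tuple[str, ...] = ("CR+PR", "NC+PD")
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if (self.cells < 0).any():
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return int(self.cells.sum())


@dataclass
class AssociationResult:
    snp_id: str | None
    model: str
    table: ModelTable
    p_value: float
    odds_ratio: float | None
    ci_low: float | None = None
    ci_high: float | None = None
    q_value: float | None = None


def build_model_table(
    resp_counts, nonresp_counts, model: str, snp_id: str | None = None
) -> ModelTable:
    """Build the genetic-model table from per-group genotype counts.

    ``resp_counts``/``nonresp_counts`` are ``(n0, n1, n2)`` counts of
    minor-allele dose among responders / non-responders.

    allele     -> 2x2 of allele counts (each subject contributes 2 alleles),
                  columns (minor, major)
    dominant   -> carriers (dose >= 1) vs non-carriers
    recessive  -> homozygous minor (dose 2) vs others
    genotype   -> 2x3 of doses (0, 1, 2)
    """
    x = np.asarray(resp_counts, dtype=np.int64)
    y = np.asarray(nonresp_counts, dtype=np.int64)
    if x.shape != (3,) or y.shape != (3,):
        raise ValueError("genotype counts must be length-3 (dose 0, 1, 2)")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("genotype counts must be non-negative")
    if model == "allele":
        cells = [
            [x[1] + 2 * x[2], 2 * x[0] + x[1]],
            [y[1] + 2 * y[2], 2 * y[0] + y[1]],
        ]
        cols = ("minor", "major")
    elif model == "dominant":
        cells = [[x[1] + x[2], x[0]], [y[1] + y[2], y[0]]]
        cols = ("carrier", "non-carrier")
    elif model == "recessive":
        cells = [[x[2], x[0] + x[1]], [y[2], y[0] + y[1]]]
        cols = ("hom-minor", "other")
    elif model == "genotype":
        cells = [list(x), list(y)]
        cols = ("dose 0", "dose 1", "dose 2")
    else:
        raise ValueError(f"unknown genetic model {model!r}")
    return ModelTable(np.array(cells), model, snp_id, col_labels=cols)


def model_table_from_doses(doses, response, model: str, snp_id=None) -> ModelTable:
    """Genotype-count tables from per-sample doses (NaN doses excluded pairwise)."""
    d = np.asarray(doses, dtype=float)
    r = np.asarray(response, dtype=int)
    ok = np.isfinite(d)
    d, r = d[ok], r[ok]
    resp = [(d[r == 1] == k).sum() for k in (0, 1, 2)]
    non = [(d[r == 0] == k).sum() for k in (0, 1, 2)]
    return build_model_table(resp, non, model, snp_id)


# ---------------------------------------------------------------------------
# hypergeometric machinery
# ---------------------------------------------------------------------------

def _log_hyper_pmf(support: np.ndarray, N: int, K: int, n1: int) -> np.ndarray:
    """log P(A = a) for the central hypergeometric at margins (N, K, n1)."""
    a = support
    return (
        gammaln(K + 1)
        - gammaln(a + 1)
        - gammaln(K - a + 1)
        + gammaln(N - K + 1)
        - gammaln(n1 - a + 1)
        - gammaln(N - K - n1 + a + 1)
        - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
    )


def _support(N: int, K: int, n1: int) -> np.ndarray:
    return np.arange(max(0, n1 - (N - K)), min(n1, K) + 1)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sum of hypergeometric point probabilities (margins fixed) not exceeding
    the observed table's probability, with relative tie tolerance 1e-7.
    Any zero row/column margin gives p = 1 by convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 requires a 2x2 table")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    a, b = t[0]
    c, d = t[1]
    N = int(a + b + c + d)
    K = int(a + c)
    n1 = int(a + b)
    if N == 0 or K == 0 or K == N or n1 == 0 or n1 == N:
        return 1.0
    support = _support(N, K, n1)
    pmf = np.exp(_log_hyper_pmf(support, N, K, n1))
    p_obs = pmf[int(a) - support[0]]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum()))


def fisher_p_lookup(N: int, K, n1: int) -> tuple[np.ndarray, int]:
    """Vectorized two-sided Fisher p over every possible top-left count.

    Parameters
    ----------
    N, n1
        Grand total and first-row margin (scalars).
    K
        First-column margin; scalar or 1-d array (one lookup row per value).

    Returns
    -------
    p : array of shape (len(K), n1 + 1)
        ``p[i, a]`` is the two-sided p for top-left count ``a`` at margins
        ``(N, K[i], n1)``; entries outside the support are NaN.
    """
    K_arr = np.atleast_1d(np.asarray(K, dtype=np.int64))
    a = np.arange(n1 + 1)
    Kc = K_arr[:, None]
    valid = (a >= np.maximum(0, n1 - (N - Kc))) & (a <= np.minimum(n1, Kc))
    with np.errstate(invalid="ignore"):
        logpmf = (
            gammaln(Kc + 1)
            - gammaln(a + 1)
            - gammaln(np.where(valid, Kc - a, 0) + 1)
            + gammaln(N - Kc + 1)
            - gammaln(n1 - a + 1)
            - gammaln(np.where(valid, N - Kc - n1 + a, 0) + 1)
            - (gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1))
        )
    pmf = np.where(valid, np.exp(np.where(valid, logpmf, -np.inf)), 0.0)
    degenerate = (K_arr == 0) | (K_arr == N) | (n1 == 0) | (n1 == N)
    order = np.argsort(pmf, axis=1, kind="stable")
    sorted_pmf = np.take_along_axis(pmf, order, axis=1)
    csum = np.cumsum(sorted_pmf, axis=1)
    p = np.full_like(pmf, np.nan)
    for i in range(pmf.shape[0]):
        if degenerate[i]:
            p[i, valid[i]] = 1.0
            continue
        thresh = pmf[i] * (1.0 + TIE_REL_TOL)
        idx = np.searchsorted(sorted_pmf[i], thresh, side="right") - 1
        row = np.where(idx >= 0, csum[i][np.maximum(idx, 0)], 0.0)
        p[i] = np.where(valid[i], np.minimum(row, 1.0), np.nan)
    return p, pmf.shape[1]


# ---------------------------------------------------------------------------
# r x c exact test
# ---------------------------------------------------------------------------

def fisher_exact_rxc(
    table,
    max_total: int = 400,
    monte_carlo: bool = False,
    n_replicates: int = 100_000,
    seed: int | None = None,
) -> float:
    """Two-sided Fisher exact p for an r x c table by conditional enumeration.

    Enumerates every table with the observed margins, summing the conditional
    (multivariate hypergeometric) probabilities of tables no more probable
    than the observed one.  Reduces to :func:`fisher_exact_2x2` when the
    table is 2x2.  Totals above ``max_total`` raise unless ``monte_carlo``
    is set, in which case the p-value is estimated from ``n_replicates``
    margin-preserving draws (add-one estimator).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if (t < 0).any():
        raise ValueError("cells must be non-negative")
    # drop all-zero rows/columns: they do not affect the conditional law
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.size == 0 or t.shape[0] == 1 or t.shape[1] == 1:
        return 1.0
    if t.shape == (2, 2):
        return fisher_exact_2x2(t)
    N = int(t.sum())
    row_m = t.sum(axis=1)
    col_m = t.sum(axis=0)
    log_norm = gammaln(N + 1) - gammaln(row_m + 1).sum() - gammaln(col_m + 1).sum()

    def log_prob(tab: np.ndarray) -> float:
        return -float(gammaln(tab + 1).sum()) - float(log_norm)

    lp_obs = log_prob(t)
    if N > max_total:
        if not monte_carlo:
            raise ValueError(
                f"table total {N} exceeds enumeration bound {max_total}; "
                "pass monte_carlo=True for a seeded estimate"
            )
        rng = np.random.default_rng(seed)
        hits = 0
        labels = np.repeat(np.arange(len(col_m)), col_m)
        starts = np.concatenate([[0], np.cumsum(row_m)])
        for _ in range(n_replicates):
            rng.shuffle(labels)
            sim = np.stack(
                [
                    np.bincount(labels[starts[i]: starts[i + 1]], minlength=len(col_m))
                    for i in range(len(row_m))
                ]
            )
            if log_prob(sim) <= lp_obs + np.log1p(TIE_REL_TOL):
                hits += 1
        return (hits + 1) / (n_replicates + 1)

    # depth-first enumeration over rows; the last row is forced
    r, c = t.shape
    total_logp = []
    tie = np.log1p(TIE_REL_TOL)

    def rec(row: int, remaining_cols: np.ndarray, acc_logp: float) -> None:
        if row == r - 1:
            lp = acc_logp - float(gammaln(remaining_cols + 1).sum()) - float(log_norm)
            if lp <= lp_obs + tie:
                total_logp.append(lp)
            return
        ri = int(row_m[row])
        for combo in _compositions(ri, remaining_cols):
            rec(
                row + 1,
                remaining_cols - combo,
                acc_logp - float(gammaln(combo + 1).sum()),
            )

    rec(0, col_m.copy(), 0.0)
    return float(min(1.0, np.exp(np.array(total_logp)).sum()))


def _compositions(total: int, caps: np.ndarray):
    """All non-negative integer vectors summing to ``total`` with per-cell caps."""
    k = len(caps)

    def gen(i: int, left: int, prefix: list[int]):
        if i == k - 1:
            if left <= caps[i]:
                yield np.array(prefix + [left], dtype=np.int64)
            return
        tail_cap = int(caps[i + 1:].sum())
        lo = max(0, left - tail_cap)
        hi = min(int(caps[i]), left)
        for v in range(lo, hi + 1):
            yield from gen(i + 1, left - v, prefix + [v])

    yield from gen(0, total, [])


# ---------------------------------------------------------------------------
# odds ratios and intervals
# ---------------------------------------------------------------------------

def odds_ratio(table, convention: str = "sample") -> float | None:
    """Odds ratio of a 2x2 table.

    ``sample``: cross-product (t11*t22)/(t12*t21); 0 when the numerator
    product is zero and the denominator is not, ``inf`` in the opposite case,
    None (undefined) when both products vanish.

    ``cmle``: conditional maximum-likelihood estimate given the margins (the
    estimate R's ``fisher.test`` reports); boundary tables give 0 or ``inf``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("odds_ratio requires a 2x2 table")
    if convention == "sample":
        num = int(t[0, 0]) * int(t[1, 1])
        den = int(t[0, 1]) * int(t[1, 0])
        if num == 0 and den == 0:
            return None
        if den == 0:
            return float("inf")
        return num / den
    if convention == "cmle":
        return conditional_mle_or(t)
    raise ValueError(f"unknown odds-ratio convention {convention!r}")


def conditional_mle_or(table) -> float | None:
    """Conditional MLE of the odds ratio (noncentral hypergeometric model)."""
    t = np.asarray(table, dtype=np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    N, K, n1 = a + b + c + d, a + c, a + b
    support = _support(N, K, n1)
    if len(support) <= 1:
        return None  # margins fix the table: OR not estimable
    if a == support[0]:
        return 0.0
    if a == support[-1]:
        return float("inf")
    logw = _log_hyper_pmf(support, N, K, n1)

    def mean_shift(log_psi: float) -> float:
        z = logw + support * log_psi
        z -= z.max()
        w = np.exp(z)
        return float((support * w).sum() / w.sum()) - a

    return float(np.exp(brentq(mean_shift, -80.0, 80.0, xtol=1e-13)))


def or_confidence_interval(
    table, level: float = 0.95, method: str = "woolf"
) -> tuple[float, float]:
    """Confidence interval for the 2x2 odds ratio.

    ``woolf``: exp(ln OR +/- z * sqrt(sum 1/cell)); a zero cell sends the
    corresponding limit to 0 or infinity.
    ``exact``: conditional exact (tail-inversion) interval consistent with
    the conditional-MLE estimate.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("or_confidence_interval requires a 2x2 table")
    a, b, c, d = int(t[0, 0]), int(t[0, 1]), int(t[1, 0]), int(t[1, 1])
    if method == "woolf":
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2)
        if min(a, b, c, d) == 0:
            # log-limits: a zero numerator cell sends the lower bound to 0,
            # a zero denominator cell the upper bound to infinity; the
            # remaining finite bound uses the Haldane 0.5 correction
            lo_h, hi_h = _woolf_haldane(t, z)
            low = 0.0 if a * d == 0 else lo_h
            high = float("inf") if b * c == 0 else hi_h
            return (low, high)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(a * d / (b * c)) - z * se)
        hi = np.exp(np.log(a * d / (b * c)) + z * se)
        return (float(lo), float(hi))
    if method == "exact":
        return _exact_or_ci(t, level)
    raise ValueError(f"unknown CI method {method!r}")


def _woolf_haldane(t: np.ndarray, z: float) -> tuple[float, float]:
    """Woolf interval with Haldane 0.5 correction, for zero-cell tables."""
    a, b, c, d = (t + 0.5).ravel().astype(float)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    mid = np.log(a * d / (b * c))
    return (float(np.exp(mid - z * se)), float(np.exp(mid + z * se)))


def _exact_or_ci(t: np.ndarray, level: float) -> tuple[float, float]:
    a = int(t[0, 0])
    N, K, n1 = int(t.sum()), int(t[:, 0].sum()), int(t[0].sum())
    support = _support(N, K, n1)
    if len(support) <= 1:
        return (0.0, float("inf"))
    logw = _log_hyper_pmf(support, N, K, n1)
    alpha = 1.0 - level

    def tail(log_psi: float, upper: bool) -> float:
        z = logw + support * log_psi
        z -= z.max()
        w = np.exp(z)
        w /= w.sum()
        mask = support >= a if upper else support <= a
        return float(w[mask].sum())

    if a == support[0]:
        low = 0.0
    else:
        low = float(np.exp(brentq(lambda lp: tail(lp, True) - alpha / 2, -80, 80)))
    if a == support[-1]:
        high = float("inf")
    else:
        high = float(np.exp(brentq(lambda lp: tail(lp, False) - alpha / 2, -80, 80)))
    return (low, high)


# ---------------------------------------------------------------------------
# HWE exact test and BH adjustment
# ---------------------------------------------------------------------------

def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact Hardy-Weinberg test conditioning on the allele counts.

    ``(n0, n1, n2)`` are genotype counts by minor-allele dose.  The p-value
    sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities no greater than the observed one.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    n_minor = n1 + 2 * n2
    hets = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    if len(hets) <= 1:
        return 1.0
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
    )
    logp -= logp.max()
    pmf = np.exp(logp)
    pmf /= pmf.sum()
    p_obs = pmf[list(hets).index(n1)]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum()))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    ok = np.isfinite(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# convenience: one SNP, one model
# ---------------------------------------------------------------------------

def associate(
    doses,
    response,
    model: str = "allele",
    snp_id: str | None = None,
    or_convention: str = "cmle",
    ci_method: str = "woolf",
) -> AssociationResult:
    """Table + Fisher p + OR (+ CI) for one SNP under one genetic model."""
    table = model_table_from_doses(doses, response, model, snp_id)
    if model == "genotype":
        p = fisher_exact_rxc(table.cells)
        return AssociationResult(snp_id, model, table, p, None)
    p = fisher_exact_2x2(table.cells)
    orv = odds_ratio(table.cells, or_convention)
    lo, hi = or_confidence_interval(table.cells, method=ci_method)
    return AssociationResult(snp_id, model, table, p, orv, lo, hi)
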