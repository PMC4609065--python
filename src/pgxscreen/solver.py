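"""Inverse reconstruction of integer contingency tables from published
rounded statistics.

Papers often print a test's p-value and odds ratio but not the underlying
table.  Because Fisher-exact statistics take few distinct values over the
finite set of tables of a given size, printing them to 2-3 significant
digits can pin the table down completely.  This module enumerates every
2x3 genotype-by-response table whose genetic-model statistics reproduce a
set of printed (p, OR) pairs at their printed precision, so published
allele/dominant/recessive statistics can be cross-validated against each
other without patient-level data.

The search is staged for speed: allele-model 2x2 tables (which depend only
on the allele counts) are enumerated first under the allele constraint,
vectorized over the count grid, and only the survivors are expanded into
their compatible genotype splits, which the remaining constraints then
filter.  Both row orientations and both odds-ratio conventions
(cross-product and conditional MLE) are tried; every solution records which
matched.  Solutions are reported in canonical orientation (allele OR <= 1).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .stats import conditional_mle_or, fisher_exact_2x2, fisher_exact_rxc, odds_ratio

__all__ = [
    "PrintedValue",
    "StatConstraint",
    "SolverSolution",
    "match_printed",
    "printed_band",
    "solve_counts_from_rate",
    "solve_genotype_table",
]

_MODELS = ("allele", "dominant", "recessive")


@dataclass(frozen=True)
class PrintedValue:
    """A number as printed, with its number of significant digits."""

    value: float
    sig_digits: int

    def __post_init__(self) -> None:
        if self.sig_digits < 1:
            raise ValueError("printed precision must be >= 1 significant digit")

    @classmethod
    def from_string(cls, text: str) -> "PrintedValue":
        """Parse e.g. "1.02e-6", "0.084", "0" keeping the printed precision."""
        s = text.strip().lower().replace("x 10^", "e").replace("×10^", "e")
        m = re.fullmatch(r"([+-]?\d*\.?\d+)(?:e([+-]?\d+))?", s)
        if not m:
            raise ValueError(f"cannot parse printed value {text!r}")
        mantissa = m.group(1)
        digits = mantissa.replace(".", "").replace("-", "").replace("+", "")
        stripped = digits.lstrip("0")
        sig = len(stripped) if stripped else 1
        return cls(float(s), sig)


def printed_band(
    target: float, sig_digits: int, mode: str = "round"
) -> tuple[float, float]:
    """Half-open interval of values that print as ``target``.

    ``round``: half-up rounding of the significand; ``truncate``: the
    significand is cut, not rounded.
    """
    if target == 0:
        return (0.0, 0.0)
    exp = math.floor(math.log10(abs(target)))
    scale = 10.0 ** (exp - sig_digits + 1)
    m = round(abs(target) / scale)
    sign = 1.0 if target > 0 else -1.0
    if mode == "round":
        lo, hi = (m - 0.5) * scale, (m + 0.5) * scale
    elif mode == "truncate":
        lo, hi = m * scale, (m + 1) * scale
    else:
        raise ValueError(f"unknown match mode {mode!r}")
    return (sign * lo, sign * hi) if sign > 0 else (sign * hi, sign * lo)


def match_printed(
    value: float | None, target: float, sig_digits: int, mode: str = "round"
) -> bool:
    """True iff ``value`` prints as ``target`` at the given precision."""
    if value is None or not np.isfinite(value):
        return False
    if target == 0:
        return value == 0
    lo, hi = printed_band(target, sig_digits, mode)
    return lo <= value < hi


def solve_counts_from_rate(
    percent: float, max_total: int
) -> tuple[tuple[int, int] | None, list[tuple[int, int]]]:
    """Fractions k/d (d <= max_total) printing as ``percent`` to one decimal.

    Returns the minimal-denominator solution (None if no solution) and the
    full list, both ordered by denominator.  Rounding is half-up.
    """
    if not 0.0 <= percent <= 100.0:
        raise ValueError("percent must lie in [0, 100]")
    if max_total < 1:
        raise ValueError("max_total must be >= 1")
    out = []
    for d in range(1, max_total + 1):
        for k in range(0, d + 1):
            rounded = math.floor(1000.0 * k / d + 0.5) / 10.0
            if rounded == round(percent, 1):
                out.append((k, d))
    return (out[0] if out else None), out


@dataclass(frozen=True)
class StatConstraint:
    """Printed (p, OR) pair for one genetic model."""

    model: str
    p: PrintedValue
    odds_ratio: PrintedValue

    @classmethod
    def parse(cls, model: str, p: str, odds_ratio: str) -> "StatConstraint":
        return cls(model, PrintedValue.from_string(p), PrintedValue.from_string(odds_ratio))


@dataclass
class SolverSolution:
    """A genotype-by-response table satisfying every constraint.

    ``resp_counts``/``nonresp_counts`` hold genotype counts (dose 0, 1, 2)
    for the group with the lower minor-allele odds first ("resp" by the
    study's protective-allele orientation, where the allele OR is <= 1).
    """

    resp_counts: tuple[int, int, int]
    nonresp_counts: tuple[int, int, int]
    n: int
    or_convention: str
    stats: dict = field(default_factory=dict)
    #: model -> decade shift applied to its printed p to obtain a solution
    #: (non-empty only when the exponent-slack rescue was needed)
    p_exponent_correction: dict = field(default_factory=dict)

    def key(self) -> tuple:
        return (self.resp_counts, self.nonresp_counts)


def _model_cells(x, y, model):
    if model == "allele":
        return (x[1] + 2 * x[2], 2 * x[0] + x[1], y[1] + 2 * y[2], 2 * y[0] + y[1])
    if model == "dominant":
        return (x[1] + x[2], x[0], y[1] + y[2], y[0])
    if model == "recessive":
        return (x[2], x[0] + x[1], y[2], y[0] + y[1])
    raise ValueError(f"unknown model {model!r}")


def _or_value(cells, convention):
    t = np.array(cells, dtype=np.int64).reshape(2, 2)
    return odds_ratio(t, convention)


def _genotype_splits(minor_alleles: int, group_n: int):
    """(n0, n1, n2) with n1 + 2*n2 = minor_alleles summing to group_n."""
    for n2 in range(max(0, minor_alleles - group_n), minor_alleles // 2 + 1):
        n1 = minor_alleles - 2 * n2
        n0 = group_n - n1 - n2
        if n0 >= 0:
            yield (n0, n1, n2)


def _allele_stage(
    n_range, r_range, constraint: StatConstraint, convention: str, mode: str
):
    """Enumerate allele-model 2x2 tables matching the allele constraint.

    Yields ``(n, r, a, c, swapped)``: r = size of group 1, a/c = minor-allele
    counts in groups 1/2, swapped = True when the constraint matched with
    rows exchanged.  For each (n, r) block the two-sided p over the whole
    (column margin, top-left count) grid comes from one vectorized
    hypergeometric lookup; the odds-ratio constraint is then checked only on
    the p-band survivors.
    """
    from .stats import fisher_p_lookup

    p_lo, p_hi = printed_band(constraint.p.value, constraint.p.sig_digits, mode)
    or_t = constraint.odds_ratio
    for n in n_range:
        for r in r_range(n):
            n1, n2 = 2 * r, 2 * (n - r)
            N = n1 + n2
            grid, _ = fisher_p_lookup(N, np.arange(N + 1), n1)
            with np.errstate(invalid="ignore"):
                Ks, As = np.nonzero((grid >= p_lo) & (grid < p_hi))
            for K, a in zip(Ks, As):
                c = int(K) - int(a)
                if not 0 <= c <= n2:
                    continue
                cells = (int(a), n1 - int(a), c, n2 - c)
                for swapped, cs in (
                    (False, cells),
                    (True, (cells[2], cells[3], cells[0], cells[1])),
                ):
                    if _match_pv(_or_value(cs, convention), or_t, mode):
                        yield (n, r, int(a), c, swapped)
                        break


def _match_pv(value, pv: PrintedValue, mode: str) -> bool:
    if pv.value == 0:
        return value == 0
    return match_printed(value, pv.value, pv.sig_digits, mode)


def solve_genotype_table(
    constraints: list[StatConstraint],
    n_range,
    response_total_range=None,
    or_conventions: tuple[str, ...] = ("cmle", "sample"),
    mode: str = "round",
    exponent_slack: int = 0,
) -> list[SolverSolution]:
    """All 2x3 genotype-by-response tables reproducing the printed statistics.

    Parameters
    ----------
    constraints
        At least two (p, OR) constraints over distinct genetic models; one
        must be the allele model (it drives the staged enumeration).
    n_range
        Iterable of admissible table totals (allows totals below the cohort
        size to absorb unreported per-SNP missingness).
    response_total_range
        Optional iterable restricting the size of the first (responder)
        group; by default all splits 1..n-1 are searched.
    or_conventions
        Conventions tried, in order; a solution's statistics must all match
        under a single convention, recorded on the solution.
    exponent_slack
        Decimal-exponent misprints are a common failure mode of printed
        p-values (the mantissa survives transcription, the power of ten does
        not).  When the constraints as printed admit no table and
        ``exponent_slack`` is positive, the search is retried with a single
        constraint's p shifted by up to that many decades (smallest shift
        first); rescued solutions record the shift in
        ``p_exponent_correction``.

    Solutions are deduplicated across orientations and returned in canonical
    orientation (allele OR <= 1, protective-allele group first).
    """
    if len(constraints) < 2:
        raise ValueError("need at least two constraints")
    by_model = {c.model: c for c in constraints}
    if len(by_model) != len(constraints):
        raise ValueError("duplicate model constraints")
    if "allele" not in by_model:
        raise ValueError("staged search requires an allele-model constraint")
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty n_range")

    def r_values(n):
        if response_total_range is None:
            return range(1, n)
        return [r for r in response_total_range if 0 < r < n]

    def search(cons_list: list[StatConstraint]) -> list[SolverSolution]:
        allele_c = next(c for c in cons_list if c.model == "allele")
        others = [c for c in cons_list if c.model != "allele"]
        solutions: dict[tuple, SolverSolution] = {}
        for convention in or_conventions:
            for (n, r, a, c, swapped) in _allele_stage(
                n_range, r_values, allele_c, convention, mode
            ):
                for x in _genotype_splits(a, r):
                    for y in _genotype_splits(c, n - r):
                        g1, g2 = (y, x) if swapped else (x, y)
                        ok = True
                        for cons in others:
                            cells = _model_cells(g1, g2, cons.model)
                            if not _match_pv(
                                _or_value(cells, convention), cons.odds_ratio, mode
                            ):
                                ok = False
                                break
                            p = fisher_exact_2x2(np.array(cells).reshape(2, 2))
                            if not _match_pv(p, cons.p, mode):
                                ok = False
                                break
                        if not ok:
                            continue
                        sol = _finalize(g1, g2, n, convention)
                        solutions.setdefault((sol.key(), convention), sol)
        return sorted(
            solutions.values(), key=lambda s: (s.n, s.resp_counts, s.nonresp_counts)
        )

    found = search(constraints)
    if found or exponent_slack < 1:
        return found
    for shift_abs in range(1, exponent_slack + 1):
        for shift in (shift_abs, -shift_abs):
            for target in constraints:
                adjusted = [
                    StatConstraint(
                        c.model,
                        PrintedValue(c.p.value * 10.0 ** shift, c.p.sig_digits),
                        c.odds_ratio,
                    )
                    if c is target
                    else c
                    for c in constraints
                ]
                rescued = search(adjusted)
                if rescued:
                    for sol in rescued:
                        sol.p_exponent_correction = {target.model: shift}
                    return rescued
    return []


def _finalize(g1, g2, n, convention) -> SolverSolution:
    stats = {}
    for model in _MODELS:
        cells = _model_cells(g1, g2, model)
        t = np.array(cells, dtype=np.int64).reshape(2, 2)
        stats[model] = {
            "table": cells,
            "p": fisher_exact_2x2(t),
            "or_sample": odds_ratio(t, "sample"),
            "or_cmle": conditional_mle_or(t),
        }
    x0, x1, x2 = map(int, g1)
    y0, y1, y2 = map(int, g2)
    sol = SolverSolution((x0, x1, x2), (y0, y1, y2), n, convention, stats)
    gt = np.array([[x0, x1, x2], [y0, y1, y2]], dtype=np.int64)
    sol.stats["genotype"] = {
        "table": tuple(gt.ravel().tolist()),
        "p": fisher_exact_rxc(gt),
    }
    return sol
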