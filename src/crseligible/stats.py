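"""Statistical kernel: exact 2x2 Fisher test, reporting arithmetic, summaries.

Pure functions with no dependency on the rest of the package so the cohort
reports can state their own guarantees: every percentage they print is
``percent(numerator, denominator)`` of counts printed alongside it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

#: Relative tolerance when comparing table probabilities to the observed
#: table's probability (probability-mass two-sided convention).
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class FisherResult:
    """Two-sided Fisher exact test result.

    ``odds_ratio`` is the unconditional sample odds ratio a*d / (b*c);
    ``None`` when b*c == 0 with a*d > 0 (infinite) and when 0/0.
    """

    p_two_sided: float
    odds_ratio: Optional[float]


def _coerce_table(table) -> Tuple[int, int, int, int]:
    if hasattr(table, "a"):  # ContingencyTable2x2 duck type
        cells = (table.a, table.b, table.c, table.d)
    else:
        rows = list(table)
        if len(rows) == 4 and all(isinstance(x, (int, np.integer)) for x in rows):
            cells = tuple(rows)
        else:
            (a, b), (c, d) = rows
            cells = (a, b, c, d)
    out = []
    for x in cells:
        xi = int(x)
        if xi != x:
            raise ValueError(f"table entries must be integers, got {x!r}")
        if xi < 0:
            raise ValueError(f"table entries must be non-negative, got {x}")
        out.append(xi)
    return tuple(out)


def fisher_exact_two_sided(table) -> FisherResult:
    """Two-sided Fisher exact test on a 2x2 table by full enumeration.

    Accepts an ``((a, b), (c, d))`` nested sequence, a flat ``(a, b, c, d)``,
    or any object with ``a, b, c, d`` attributes.  Conditional on both
    margins, the top-left cell follows a hypergeometric law; the two-sided p
    is the total probability of all tables no more probable than the
    observed one (probability-mass method, with relative tolerance 1e-7 on
    the comparison).  Probabilities are accumulated on the log scale via
    ``lgamma`` so registry-scale counts cannot overflow.
    """
    a, b, c, d = _coerce_table(table)
    n = a + b + c + d
    if n == 0:
        raise ValueError("table has no observations")
    row1, col1 = a + b, a + c

    lg = math.lgamma

    def log_binom(n_, k_):
        return lg(n_ + 1) - lg(k_ + 1) - lg(n_ - k_ + 1)

    denom = log_binom(n, col1)
    lo = max(0, col1 - (n - row1))
    hi = min(row1, col1)
    logp = [log_binom(row1, x) + log_binom(n - row1, col1 - x) - denom
            for x in range(lo, hi + 1)]
    p_obs = math.exp(logp[a - lo])
    p = sum(math.exp(lp) for lp in logp
            if math.exp(lp) <= p_obs * (1.0 + _FISHER_RELTOL))
    p = min(p, 1.0)

    if b * c > 0:
        odds_ratio: Optional[float] = (a * d) / (b * c)
    else:
        odds_ratio = None
    return FisherResult(p_two_sided=p, odds_ratio=odds_ratio)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 at the cut always rounds away from zero),
    matching how the cohort tables print percentages."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def median_iqr(values: Iterable[float]) -> Tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics
    (quantile positions p*(n-1)+1); missing entries (None/NaN) are dropped."""
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one non-missing value")
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75], method="linear")
    return float(med), float(q1), float(q3)
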