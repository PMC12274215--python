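"""Independent manual LMS oracle.

This module re-enacts, step by step, what a clinician does with a printed
reference table: find the two tabulated ages bracketing the patient's age,
linearly interpolate L, M and S by hand, and evaluate the printed z-score
formula.  It exists as a *separate code path* for agreement checking: it must
not import anything from :mod:`agrowth.core` and uses only the standard
library, so that 100% engine-vs-oracle agreement is evidence of correctness
rather than a tautology.
"""

from __future__ import annotations

import math

# Kept deliberately local (not imported from core): below this |L| the
# Box-Cox formula is replaced by its logarithmic limit.
_L_EPS = 1e-7


def manual_zscore(rows: list[dict], parameter: str, sex: str, age: float,
                  value: float, mode: str) -> float:
    """Manually evaluate one z-score from plain reference-table rows.

    ``rows`` are dicts with keys parameter, sex, age_years, L, M, S — the
    flattened form of a reference bundle.  ``mode`` is ``"identity"`` for
    Z = (X - M)/S or ``"boxcox"`` for Z = ((X/M)^L - 1)/(L*S).
    """
    table = [(float(r["age_years"]), float(r["L"]), float(r["M"]),
              float(r["S"]))
             for r in rows
             if r["parameter"] == parameter and r["sex"] == sex]
    if not table:
        raise ValueError(f"no table rows for ({parameter}, {sex})")
    table.sort(key=lambda t: t[0])
    if age < table[0][0] or age > table[-1][0]:
        raise ValueError(
            f"age {age} outside table range "
            f"[{table[0][0]}, {table[-1][0]}] for ({parameter}, {sex})")

    L = M = S = None
    for a, lv, mv, sv in table:
        if a == age:
            L, M, S = lv, mv, sv
            break
    if L is None:
        lo = hi = None
        for entry in table:
            if entry[0] < age:
                lo = entry
            elif entry[0] > age and hi is None:
                hi = entry
        assert lo is not None and hi is not None
        a0, l0, m0, s0 = lo
        a1, l1, m1, s1 = hi
        t = (age - a0) / (a1 - a0)
        L = l0 + t * (l1 - l0)
        M = m0 + t * (m1 - m0)
        S = s0 + t * (s1 - s0)

    if mode == "identity":
        return (value - M) / S
    if mode == "boxcox":
        if abs(L) < _L_EPS:
            return math.log(value / M) / S
        return ((value / M) ** L - 1.0) / (L * S)
    raise ValueError(f"unknown mode {mode!r}")


def manual_percentile(z: float) -> float:
    """Standard-normal CDF times 100, via the error function."""
    return 50.0 * (1.0 + math.erf(z / math.sqrt(2.0)))
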