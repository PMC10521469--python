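"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here re-derives a pipeline quantity by direct enumeration or
closed form, sharing no code with the implementation it checks.
"""

import numpy as np


def sliding_cv_oracle(x: np.ndarray, window: int = 10) -> np.ndarray:
    """Minimum CV over every contiguous window containing each index, by
    exhaustive enumeration of window start positions."""
    n = len(x)
    out = np.zeros(n)
    for i in range(n):
        best = np.inf
        for s in range(i - window + 1, i + 1):
            a, b = max(0, s), min(n, s + window)
            if b - a < 2:
                continue
            seg = x[a:b]
            m = seg.mean()
            cv = 0.0 if m <= 0 else seg.std(ddof=1) / m * 100.0
            best = min(best, cv)
        out[i] = 0.0 if best == np.inf else best
    return out


def choi_oracle(
    values: np.ndarray,
    min_period: int = 90,
    spike_tolerance: int = 2,
    max_interrupt_minutes: int = 2,
    flank: int = 30,
    zero_threshold: float = 1.0,
) -> np.ndarray:
    """Minute-by-minute forward scan applying the non-wear rule directly:
    from every zero minute, extend a candidate window while interruptions
    stay short, few, and flanked by enough zeros; mark windows that reach
    the minimum length."""
    n = len(values)
    zero = np.asarray(values) < zero_threshold
    # zeros immediately before / after each index, over the whole series
    before = np.zeros(n, dtype=int)
    after = np.zeros(n, dtype=int)
    for i in range(1, n):
        before[i] = before[i - 1] + 1 if zero[i - 1] else 0
    for i in range(n - 2, -1, -1):
        after[i] = after[i + 1] + 1 if zero[i + 1] else 0

    nonwear = np.zeros(n, dtype=bool)
    for a in range(n):
        if not zero[a]:
            continue
        total_interrupt = 0
        j = a
        while j < n:
            if zero[j]:
                if j + 1 - a >= min_period:
                    nonwear[a : j + 1] = True
                j += 1
                continue
            # nonzero run starting at j
            k = j
            while k < n and not zero[k]:
                k += 1
            run = k - j
            ok = (
                run <= spike_tolerance
                and total_interrupt + run <= max_interrupt_minutes
                and before[j] >= flank
                and (k < n and after[k - 1] >= flank)
            )
            if not ok:
                break
            total_interrupt += run
            j = k
    return nonwear


def balanced_anova_fit(y: np.ndarray, k: int, m: int):
    """Closed-form one-way random-effects solution (MSB/MSW method) for a
    balanced design of k participants x m occasions.  Coincides with REML
    when MSB > MSW."""
    Y = np.asarray(y, dtype=float).reshape(k, m)
    grand = Y.mean()
    means = Y.mean(axis=1)
    msw = ((Y - means[:, None]) ** 2).sum() / (k * (m - 1))
    msb = m * ((means - grand) ** 2).sum() / (k - 1)
    var_b = max(0.0, (msb - msw) / m)
    se = np.sqrt((m * var_b + msw) / (k * m))
    return {
        "intercept": grand,
        "se": se,
        "sd_between": np.sqrt(var_b),
        "sd_resid": np.sqrt(msw),
        "interior": msb > msw,
    }
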