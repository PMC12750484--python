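"""Independent oracle implementations used only by the test suite.

These are deliberately naive transcriptions — a literal case-by-case
rendering of the composite rulebook, and a pure-Python direct summation of
the agreement formulas — kept structurally independent of the package's
vectorised implementations.
"""

from __future__ import annotations

import numpy as np


def composite_rules_oracle(scores, per_lobe_max: int) -> int:
    """Literal transcription of the five-lobe composite rulebook.

    Walk candidate composite values from most to least severe: composite
    c is awarded if at least three of the five lobes reach level c-1
    (majority promotion), or if at least one lobe reaches level c itself.
    Composite 0 iff every lobe is 0.
    """
    scores = list(scores)
    assert len(scores) == 5, "rulebook is stated for five lobes"
    if all(s == 0 for s in scores):
        return 0
    for c in range(per_lobe_max + 1, 0, -1):
        promote_level = c - 1
        if 1 <= promote_level <= per_lobe_max:
            if sum(s >= promote_level for s in scores) >= 3:
                return c
        if c <= per_lobe_max and sum(s >= c for s in scores) >= 1:
            return c
    raise AssertionError("unreachable: some lobe is nonzero")


def gwet_oracle(counts, w):
    """Direct per-subject summation of the weighted agreement coefficient.

    Returns (coefficient, p_a, p_e).  Loops everywhere on purpose.
    """
    counts = [list(map(int, row)) for row in np.asarray(counts)]
    w = [list(map(float, row)) for row in np.asarray(w)]
    n = len(counts)
    q = len(counts[0])
    per_subject = []
    for row in counts:
        r_i = sum(row)
        if r_i < 2:
            continue
        total = 0.0
        for k in range(q):
            rstar = sum(w[k][l] * row[l] for l in range(q))
            total += row[k] * (rstar - 1.0)
        per_subject.append(total / (r_i * (r_i - 1.0)))
    p_a = sum(per_subject) / len(per_subject)
    pi = [0.0] * q
    for row in counts:
        r_i = sum(row)
        if r_i == 0:
            continue
        for k in range(q):
            pi[k] += row[k] / r_i / n
    t_w = sum(sum(row) for row in w)
    p_e = t_w / (q * (q - 1)) * sum(p * (1.0 - p) for p in pi)
    return (p_a - p_e) / (1.0 - p_e), p_a, p_e
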