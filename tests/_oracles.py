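"""Brute-force record-enumeration oracles, independent of the package.

Every function here recomputes a metric by literally counting over the
(reference, coder) pairs of a cohort, with no shared code with the
implementation under test. Pure Python on purpose.
"""

from __future__ import annotations

from fractions import Fraction


def tally(pairs: list[tuple[str, str]], causes: list[str]) -> dict[str, dict[str, int]]:
    """Nested dict counts[ref][coder] over the given category list."""
    counts = {r: {c: 0 for c in causes} for r in causes}
    for ref, coder in pairs:
        counts[ref][coder] += 1
    return counts


def oracle_sensitivity(pairs, cause):
    tp = sum(1 for r, c in pairs if r == cause and c == cause)
    denom = sum(1 for r, _ in pairs if r == cause)
    return None if denom == 0 else tp / denom


def oracle_ppv(pairs, cause):
    tp = sum(1 for r, c in pairs if r == cause and c == cause)
    denom = sum(1 for _, c in pairs if c == cause)
    return None if denom == 0 else tp / denom


def oracle_ccc(pairs, cause, C):
    sens = oracle_sensitivity(pairs, cause)
    if sens is None:
        return None
    return (sens - 1 / C) / (1 - 1 / C)


def oracle_overall_agreement(pairs):
    return sum(1 for r, c in pairs if r == c) / len(pairs)


def oracle_kappa(pairs, causes):
    """Kappa by exact cell enumeration with rational arithmetic."""
    n = len(pairs)
    counts = tally(pairs, causes)
    p_o = Fraction(sum(counts[c][c] for c in causes), n)
    p_e = Fraction(0)
    for c in causes:
        row = sum(counts[c].values())
        col = sum(counts[r][c] for r in causes)
        p_e += Fraction(row, n) * Fraction(col, n)
    if p_e == 1:
        return None
    return float((p_o - p_e) / (1 - p_e))


def oracle_csmf_accuracy(true_fracs: list[float], pred_fracs: list[float]) -> float:
    total = sum(abs(t - p) for t, p in zip(true_fracs, pred_fracs))
    return 1 - total / (2 * (1 - min(true_fracs)))
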