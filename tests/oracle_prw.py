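"""Independent brute-force oracle for the Parzen-window ranker.

Evaluates the prior x kernel-sum product literally in arbitrary-precision
arithmetic (mpmath), with no log-space tricks, exactly as the closed-form
definitions read:

    score(class a) = (N_a / N) * (1 / N_a) * sum_{j in a} K(x, x_j)
    K(x, x_j)      = (h * sqrt(2*pi))**(-d) * exp(-m_j / (2 h**2))

Classes are ordered by descending score, ties by ascending class id — the
same contract the fast implementation promises.  Kept deliberately naive and
separate from the package so it can serve as a cross-check.
"""

from __future__ import annotations

import mpmath as mp


def oracle_scores(query, members_by_class, h, d, n_total):
    """Exact scores per class; ``members_by_class`` maps class id -> list of
    0/1 bit lists."""
    with mp.workdps(120):
        const = (mp.mpf(h) * mp.sqrt(2 * mp.pi)) ** (-d)
        scores = {}
        for cid, members in members_by_class.items():
            total = mp.mpf(0)
            for mem in members:
                m = sum(int(a != b) for a, b in zip(query, mem))
                total += const * mp.e ** (-mp.mpf(m) / (2 * mp.mpf(h) ** 2))
            scores[cid] = total / mp.mpf(n_total)
        return scores


def oracle_ranking(query, members_by_class, h, d, n_total):
    """Class ids ordered best-first under the deterministic tie rule."""
    scores = oracle_scores(query, members_by_class, h, d, n_total)
    return sorted(scores, key=lambda c: (-scores[c], c))


def oracle_log_score(query, members, h, d, n_total):
    """Natural log of one class's score (for closed-form comparisons)."""
    with mp.workdps(120):
        s = oracle_scores(query, {"c": members}, h, d, n_total)["c"]
        return float(mp.log(s))


def oracle_log_scores(query, members_by_class, h, d, n_total):
    """Exact per-class log scores, rounded to float at the end."""
    with mp.workdps(120):
        scores = oracle_scores(query, members_by_class, h, d, n_total)
        return {c: float(mp.log(s)) for c, s in scores.items()}


def ranking_agrees(fast_order, exact_logs, tol=1e-9):
    """True iff a ranking never inverts an exactly-resolvable score gap.

    Classes whose exact log scores differ by less than ``tol`` are ties at
    double precision; within such groups any order consistent with the
    implementation's deterministic tie rule is acceptable, so the check is
    that exact scores are non-increasing along the ranking up to ``tol``.
    """
    if sorted(fast_order) != sorted(exact_logs):
        return False
    logs = [exact_logs[c] for c in fast_order]
    return all(later <= earlier + tol for earlier, later in zip(logs, logs[1:]))
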