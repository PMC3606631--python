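"""Recombination breakpoint detection in aligned parent/recombinant triplets.

Given an alignment of a putative recombinant (query) with two candidate
parent sequences, the informative sites are the columns where the parents
differ and the query matches exactly one of them.  A crossover shows up as
a switch in which parent the query tracks; each boundary between
consecutive informative sites is tested with a chi-square on the 2x2 table
of (left/right flank) x (supports A/B), Bonferroni-corrected over the
number of boundaries, at a significance threshold of 0.001.  Pairwise
percent-identity profiles localize the same events visually.

The flank window counts informative sites by default (20 per side); an
alignment-column window is available via ``window_unit="columns"``.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import AnalysisError
from .simulate import AlignedTriplet

DEFAULT_WINDOW = 20
DEFAULT_ALPHA = 0.001

_GAPLIKE = set("-N")


@dataclass(frozen=True)
class InformativeSite:
    column: int      # 0-based alignment column
    supports: str    # "A" or "B"


@dataclass(frozen=True)
class BreakpointCall:
    """A located crossover: the interval between flanking informative sites."""

    interval: tuple[int, int]   # 0-based, half-open
    statistic: float
    p_adjusted: float
    left_support: tuple[int, int]    # (A, B) counts in the left flank
    right_support: tuple[int, int]


def informative_sites(triplet: AlignedTriplet):
    """Informative sites in ascending column order, plus diagnostics.

    Columns with a gap or N in any sequence, columns where the parents
    agree, and columns where the query matches neither parent are excluded;
    the count of three-way mismatches is recorded on the returned list's
    ``diagnostics`` attribute.
    """
    sites = []
    three_way = 0
    for i, (q, a, b) in enumerate(zip(triplet.query, triplet.parent_a,
                                      triplet.parent_b)):
        if q in _GAPLIKE or a in _GAPLIKE or b in _GAPLIKE or a == b:
            continue
        if q == a:
            sites.append(InformativeSite(i, "A"))
        elif q == b:
            sites.append(InformativeSite(i, "B"))
        else:
            three_way += 1

    class _SiteList(list):
        pass

    out = _SiteList(sites)
    out.diagnostics = {"three_way_mismatches": three_way,
                       "n_sites": len(sites)}
    return out


def _chi2_2x2(table: np.ndarray) -> float:
    """Chi-square statistic with continuity correction when any cell < 5."""
    correction = bool((table < 5).any())
    try:
        stat, _, _, _ = stats.chi2_contingency(table, correction=correction)
    except ValueError:  # a zero marginal
        return 0.0
    return float(stat)


def scan_triplet(triplet: AlignedTriplet, window: int = DEFAULT_WINDOW,
                 alpha: float = DEFAULT_ALPHA, correction: str = "bonferroni",
                 window_unit: str = "sites"):
    """Chi-square sliding-flank scan for crossovers in an aligned triplet.

    At each boundary between consecutive informative sites the preceding
    and following ``window`` informative sites (or all sites within
    ``window`` alignment columns when ``window_unit="columns"``) are
    tabulated by the parent they support and tested with a 2x2 chi-square;
    p-values are Bonferroni-corrected by the number of boundaries tested.
    Maximal significant non-overlapping calls are returned sorted by
    position.
    """
    if correction != "bonferroni":
        raise AnalysisError(f"unsupported correction {correction!r}")
    if window_unit not in ("sites", "columns"):
        raise AnalysisError(f"unsupported window_unit {window_unit!r}")
    if triplet.length < 2 * window:
        raise AnalysisError(
            f"alignment ({triplet.length} columns) shorter than two "
            f"windows ({2 * window})"
        )
    sites = informative_sites(triplet)
    n = len(sites)
    if n < 2:
        return []
    cols = [s.column for s in sites]
    isa = np.array([s.supports == "A" for s in sites], dtype=int)
    cum_a = np.concatenate([[0], np.cumsum(isa)])  # A-count among sites[:k]

    def flank_counts(k: int):
        """(A, B) counts left and right of the boundary before site k."""
        if window_unit == "sites":
            lo, hi = max(0, k - window), min(n, k + window)
        else:
            left_col = cols[k - 1] - window + 1
            right_col = cols[k] + window - 1
            lo = bisect.bisect_left(cols, left_col)
            hi = bisect.bisect_right(cols, right_col)
        la = int(cum_a[k] - cum_a[lo])
        lb = (k - lo) - la
        ra = int(cum_a[hi] - cum_a[k])
        rb = (hi - k) - ra
        return (la, lb), (ra, rb)

    n_tests = n - 1
    results = []
    for k in range(1, n):
        (la, lb), (ra, rb) = flank_counts(k)
        if (la + lb) == 0 or (ra + rb) == 0:
            continue
        stat = _chi2_2x2(np.array([[la, lb], [ra, rb]], dtype=float))
        p = float(stats.chi2.sf(stat, df=1))
        p_adj = min(1.0, p * n_tests)
        if p_adj <= alpha:
            results.append(BreakpointCall(
                interval=(cols[k - 1] + 1, cols[k] + 1),
                statistic=stat,
                p_adjusted=p_adj,
                left_support=(la, lb),
                right_support=(ra, rb),
            ))
    # maximal non-overlapping selection: strongest call wins its neighbourhood
    results.sort(key=lambda c: (-c.statistic, c.interval))
    chosen: list[BreakpointCall] = []
    for call in results:
        if all(call.interval[1] <= c.interval[0] or
               call.interval[0] >= c.interval[1] for c in chosen):
            # also suppress calls whose flanks overlap an accepted call's
            # boundary region: neighbouring boundaries re-test the same
            # switch, so require disjoint flank spans
            lo = call.interval[0] - (window if window_unit == "columns"
                                     else _span(cols, call.interval[0], window))
            hi = call.interval[1] + (window if window_unit == "columns"
                                     else _span(cols, call.interval[1], window))
            if all(hi <= c.interval[0] or lo >= c.interval[1] for c in chosen):
                chosen.append(call)
    chosen.sort(key=lambda c: c.interval)
    return chosen


def _span(cols, col, window):
    """Alignment-column span covered by `window` informative sites at col."""
    i = bisect.bisect_left(cols, col)
    lo = max(0, i - window)
    hi = min(len(cols) - 1, i + window)
    return max(col - cols[lo], cols[hi] - col)


def identity_profile(query: str, references, window: int = 400,
                     step: int = 100):
    """Sliding-window percent identity of a query to each reference.

    Windows are 0-based half-open ``[start, start+window)``; positions with
    a gap or N in either sequence are excluded from a window's denominator,
    and a window with no comparable positions yields NaN.  Returns a list
    of ``(start, identity_ref1, identity_ref2, ...)`` rows.
    """
    refs = list(references)
    for r in refs:
        if len(r) != len(query):
            raise AnalysisError("identity profile requires aligned sequences")
    L = len(query)
    if window > L:
        raise AnalysisError("window larger than alignment")
    q = np.frombuffer(query.encode(), dtype="S1")
    rows = []
    mats = []
    for r in refs:
        rr = np.frombuffer(r.encode(), dtype="S1")
        ok = ~(np.isin(q, [b"-", b"N"]) | np.isin(rr, [b"-", b"N"]))
        match = (q == rr) & ok
        mats.append((np.concatenate([[0], np.cumsum(match)]),
                     np.concatenate([[0], np.cumsum(ok)])))
    for start in range(0, L - window + 1, step):
        end = start + window
        row = [start]
        for cm, cok in mats:
            denom = cok[end] - cok[start]
            num = cm[end] - cm[start]
            row.append(100.0 * num / denom if denom else float("nan"))
        rows.append(tuple(row))
    return rows


def switch_point(profile_rows) -> int | None:
    """Window start where the nearest reference switches (first of two refs
    to second), or None if no switch occurs."""
    prev = None
    for row in profile_rows:
        _, ia, ib = row[0], row[1], row[2]
        cur = "A" if ia >= ib else "B"
        if prev == "A" and cur == "B":
            return row[0]
        prev = cur
    return None
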