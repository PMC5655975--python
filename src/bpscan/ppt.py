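"""Polypyrimidine-tract (PPT) detection.

The PPT is the C/T-rich element between the branch point and the 3' splice
site, bound by U2AF65.  A candidate tract is accepted when it satisfies five
rules, applied here exactly as stated by the heuristic they come from:

1. both the 5' and the 3' end of the tract are pyrimidines (C/T);
2. no more than two continuous purines occur anywhere in the tract;
3. every purine segment of length ``l`` (necessarily l < 3 by rule 2) is
   surrounded by at least ``4*l`` flanking pyrimidines in total, with the
   upstream and the downstream pyrimidine segment each of length >= ``l``;
4. T(GT)n stretches are allowed: G's inside a maximal T(GT)n run are treated
   as pyrimidines for rules 2-3 and neither break the tract nor count as a
   purine segment;
5. the tract is at least 9 nt long OR contains at least 5 T's (uridines in
   the transcript).

When several tracts qualify, tracts are maximal ("maximizing for length",
i.e. not extendable by one base on either side into a still-valid tract) and
the one whose 3' end is closest to the 3'ss wins; at an equal 3' end the
longest wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .intron_io import Intron, Region

_PYRIMIDINE = frozenset("CT")
_TGT_RUN = re.compile(r"T(?:GT)+")


@dataclass(frozen=True)
class PPTRules:
    """Thresholds for the five tract rules (defaults are the canonical ones)."""

    max_purine_run: int = 2
    flank_total_factor: int = 4
    min_length: int = 9
    min_uridines: int = 5

    def __post_init__(self) -> None:
        for name in ("max_purine_run", "flank_total_factor", "min_length", "min_uridines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"PPTRules.{name} must be positive")


DEFAULT_RULES = PPTRules()


def _effective_pyrimidine_mask(s: str) -> list[bool]:
    """True where a base behaves as a pyrimidine (C/T, or G inside T(GT)n)."""
    mask = [c in _PYRIMIDINE for c in s]
    for m in _TGT_RUN.finditer(s):
        for i in range(m.start(), m.end()):
            mask[i] = True
    return mask


def is_valid_ppt(s: str, rules: PPTRules = DEFAULT_RULES) -> bool:
    """Check the five PPT rules on ``s`` (A/C/G/T only)."""
    if not s:
        raise ValueError("empty candidate tract")
    if set(s) - set("ACGT"):
        raise ValueError(f"invalid alphabet in tract {s!r}")
    # rule 1: literal ends, T(GT)n exemption does not apply to the termini
    if s[0] not in _PYRIMIDINE or s[-1] not in _PYRIMIDINE:
        return False
    mask = _effective_pyrimidine_mask(s)
    # rules 2-3 on maximal runs of effective purines
    i = 0
    n = len(s)
    while i < n:
        if mask[i]:
            i += 1
            continue
        j = i
        while j < n and not mask[j]:
            j += 1
        run = j - i
        if run > rules.max_purine_run:
            return False
        # flanking pyrimidine segments (exempt G's count as pyrimidines)
        up = 0
        k = i - 1
        while k >= 0 and mask[k]:
            up += 1
            k -= 1
        down = 0
        k = j
        while k < n and mask[k]:
            down += 1
            k += 1
        if up < run or down < run or up + down < rules.flank_total_factor * run:
            return False
        i = j
    # rule 5: length or uridine content
    return n >= rules.min_length or s.count("T") >= rules.min_uridines


def find_ppt(
    intron: Intron, search: Region, rules: PPTRules = DEFAULT_RULES
) -> Region | None:
    """Best PPT within ``search``, or None.

    Enumerates all maximal (non-extendable) valid tracts in the window and
    selects the one with the 3'-most end, breaking ties toward the longest.
    """
    window = intron.slice(search.start, search.end)
    m = len(window)
    if m == 0:
        return None

    def valid(i: int, j: int) -> bool:
        return is_valid_ppt(window[i : j + 1], rules)

    best: tuple[int, int] | None = None  # (end, length) maximised
    best_region: Region | None = None
    for j in range(m - 1, -1, -1):
        for i in range(j + 1):
            if not valid(i, j):
                continue
            if (i > 0 and valid(i - 1, j)) or (j < m - 1 and valid(i, j + 1)):
                continue  # extendable: not maximal
            key = (j, j - i + 1)
            if best is None or key > best:
                best = key
                best_region = Region(
                    start=search.start + i, end=search.start + j, label="PPT"
                )
    return best_region
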