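"""AG exclusion zone (AGEZ) and the shortened AGEZ.

The branch point of a human intron lies upstream of an AG-free stretch before
the 3'ss: scanning 5'-ward from the splice site, the first AG dinucleotide
encountered (ignoring any AG within the 12 positions adjacent to the 3'ss,
which includes the 3'ss AG itself) defines the zone.  An extra L nucleotides
upstream of that defining AG are included so that a branch point sitting right
on the zone boundary is not missed.  The branch-point search region used by
the scorer is the AGEZ with the pyrimidine-rich 3' end of the PPT excluded
("shortened AGEZ"): branch sites do not occur inside that run.
"""

from __future__ import annotations

from dataclasses import dataclass

from .intron_io import Intron, Region
from .ppt import _PYRIMIDINE


class RegionError(ValueError):
    """The requested zone cannot be formed on this intron."""


@dataclass(frozen=True)
class AgezParams:
    """L: extension upstream of the defining AG, nt (7-12, default 9)."""

    L: int = 9
    ignore_zone: int = 12

    def __post_init__(self) -> None:
        if not (7 <= self.L <= 12):
            raise ValueError(f"L must be in 7..12, got {self.L}")
        if self.ignore_zone <= 0:
            raise ValueError("ignore_zone must be positive")


DEFAULT_PARAMS = AgezParams()


def defining_ag(intron: Intron, params: AgezParams = DEFAULT_PARAMS) -> int | None:
    """3'ss-relative position of the A of the AGEZ-defining AG, or None.

    The scan runs 5'-ward starting at the first position outside the ignore
    zone; an AG whose A sits at -(ignore_zone+1) is *not* ignored, since only
    AGs found within the first ``ignore_zone`` nucleotides are.
    """
    n = len(intron)
    if n <= params.ignore_zone + 1:
        raise RegionError(
            f"intron {intron.id!r} (length {n}) shorter than the "
            f"{params.ignore_zone}-nt ignore zone plus the 3'ss AG"
        )
    for a in range(-(params.ignore_zone + 1), -n - 1, -1):
        if intron.base(a) == "A" and intron.base(a + 1) == "G":
            return a
    return None


def find_agez(intron: Intron, params: AgezParams = DEFAULT_PARAMS) -> Region:
    """AGEZ: [defining-AG position - L, -1], clamped to the intron start.

    With no upstream AG the zone is the whole intron.
    """
    a = defining_ag(intron, params)
    n = len(intron)
    start = -n if a is None else max(-n, a - params.L)
    return Region(start=start, end=-1, label="AGEZ")


def agez_core(intron: Intron, params: AgezParams = DEFAULT_PARAMS) -> Region:
    """The AGEZ without the L-extension: defining AG to the 3'ss.

    This is the window within which the PPT is sought; it contains no AG
    dinucleotide between the defining AG and the ignore zone by construction.
    """
    a = defining_ag(intron, params)
    start = -len(intron) if a is None else a
    return Region(start=start, end=-1, label="AGEZ_CORE")


def shorten_agez(agez: Region, ppt: Region | None, intron: Intron) -> Region:
    """Exclude the PPT's terminal pyrimidine run from the AGEZ 3' boundary.

    The excluded stretch is the maximal all-pyrimidine suffix of the PPT; the
    shortened zone ends immediately 5' of it.  If the whole PPT is pyrimidine
    the boundary is just 5' of the PPT.  Without a PPT the AGEZ is returned
    unchanged.
    """
    if ppt is None:
        return Region(start=agez.start, end=agez.end, label="SHORT_AGEZ")
    run_start = ppt.end
    while run_start - 1 >= ppt.start and intron.base(run_start - 1) in _PYRIMIDINE:
        run_start -= 1
    new_end = run_start - 1
    if new_end < agez.start:
        raise RegionError(
            f"intron {intron.id!r}: shortened AGEZ is empty "
            f"(PPT pyrimidine run reaches back to {run_start})"
        )
    return Region(start=agez.start, end=new_end, label="SHORT_AGEZ")
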