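"""Deterministic synthetic introns with a planted branch-point architecture.

Real 3' intron ends share a stereotyped layout: a branch-point heptamer, a
downstream polypyrimidine tract, an AG-free zone running up to the 3'ss AG,
and AG dinucleotides further upstream that bound the AGEZ.  The generator
plants exactly that layout on a random background so that every stage of the
pipeline — AGEZ detection, PPT finding, zone shortening, scanning, scoring —
can be exercised end-to-end with a known answer and no external data.

Layout on an intron of length n (3'ss-relative coordinates)::

    5' ...decoy AGs... AG ....[heptamer]....[PPT]..AG 3'
                       ^d     b-5 ... b+1         -2,-1
    d = b - 8 (defining AG), PPT ends at -3, guarded 5' by a purine.

Identical seeds give identical sequences (byte-for-byte identical FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .freq import BASES, FrequencyMatrix
from .intron_io import Intron, to_offset
from .ppt import DEFAULT_RULES, is_valid_ppt

CONSENSUS = "TACTAAC"  # yeast branch-point consensus; perfect U2 complement


class GenerationError(ValueError):
    """The fixture specification is internally inconsistent."""


@dataclass(frozen=True)
class FixtureSpec:
    """Blueprint for one synthetic intron.

    Defaults give a 120-nt intron with the consensus heptamer branching at
    -25, a 15-nt pure-pyrimidine PPT ending at -3, the AGEZ-defining AG 8 nt
    upstream of the branch site, two decoy AGs further upstream, and a 40%
    GC background.
    """

    intron_length: int = 120
    branch_pos: int = -25
    bps_heptamer: str = CONSENSUS  # or "sample-from-matrix"
    ppt_length: int = 15
    agez_decoy_ag_positions: tuple[int, ...] = (-70, -90)
    gc_background: float = 0.40
    seed: int = 0
    defining_ag_offset: int = 8  # AG sits this far 5' of the branch site

    def __post_init__(self) -> None:
        n, b = self.intron_length, self.branch_pos
        ppt_start = -(self.ppt_length + 2)
        d = b - self.defining_ag_offset
        if self.ppt_length < DEFAULT_RULES.min_length:
            raise GenerationError(
                f"ppt_length {self.ppt_length} below the minimum tract length"
            )
        if b - 5 < -n:
            raise GenerationError(f"heptamer at branch {b} exits the intron 5' end")
        if b + 1 >= ppt_start:
            raise GenerationError(
                f"heptamer end {b + 1} overlaps the PPT starting at {ppt_start}"
            )
        if d - 1 < -n:
            raise GenerationError(f"defining AG at {d} exits the intron")
        if not (0.0 <= self.gc_background <= 1.0):
            raise GenerationError("gc_background must be in [0, 1]")
        for p in self.agez_decoy_ag_positions:
            if p > d - 2:
                raise GenerationError(
                    f"decoy AG at {p} would fall inside the intended AGEZ core "
                    f"(defining AG at {d})"
                )
            if p < -n:
                raise GenerationError(f"decoy AG at {p} exits the intron")


def _sample_heptamer(rng: np.random.Generator, matrix: FrequencyMatrix) -> str:
    cols = matrix.f / matrix.f.sum(axis=0)
    return "".join(
        BASES[rng.choice(4, p=cols[:, i])] for i in range(7)
    )


def generate(spec: FixtureSpec, matrix: FrequencyMatrix | None = None) -> Intron:
    """Build one annotated intron from ``spec``; deterministic in its seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.intron_length
    gc = spec.gc_background
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    chars = [BASES[i] for i in rng.choice(4, size=n, p=probs)]

    def put(p: int, s: str) -> None:
        for off, ch in enumerate(s):
            chars[to_offset(p, n) + off] = ch

    protected: set[int] = set()

    def protect(p: int, length: int) -> None:
        protected.update(range(to_offset(p, n), to_offset(p, n) + length))

    # terminal 3'ss
    put(-2, "AG")
    protect(-2, 2)
    # polypyrimidine tract ending at -3, with the uridine floor guaranteed
    ppt_start = -(spec.ppt_length + 2)
    tract = [("T" if rng.random() < 0.6 else "C") for _ in range(spec.ppt_length)]
    t_short = DEFAULT_RULES.min_uridines - tract.count("T")
    if t_short > 0:
        for i in np.flatnonzero(np.array(tract) == "C")[:t_short]:
            tract[int(i)] = "T"
    put(ppt_start, "".join(tract))
    protect(ppt_start, spec.ppt_length)
    # purine guard so the tract is not extendable 5'
    put(ppt_start - 1, "A")
    protect(ppt_start - 1, 1)
    # the branch-point heptamer
    if spec.bps_heptamer == "sample-from-matrix":
        if matrix is None:
            raise GenerationError("sample-from-matrix requires a frequency matrix")
        hept = _sample_heptamer(rng, matrix)
    else:
        hept = spec.bps_heptamer.upper()
        if len(hept) != 7 or set(hept) - set(BASES):
            raise GenerationError(f"bps_heptamer {hept!r} is not an ACGT heptamer")
    put(spec.branch_pos - 5, hept)
    protect(spec.branch_pos - 5, 7)
    # AGEZ-defining AG and upstream decoys
    d = spec.branch_pos - spec.defining_ag_offset
    put(d, "AG")
    protect(d, 2)
    for p in spec.agez_decoy_ag_positions:
        put(p, "AG")
    # break every stray AG 3' of the defining AG (G -> C removes the
    # dinucleotide and cannot create a new one)
    for p in range(d + 2, -2):
        i = to_offset(p, n)
        if chars[i] == "A" and chars[i + 1] == "G" and (i + 1) not in protected:
            chars[i + 1] = "C"

    # break stray copies of the planted heptamer so it is the unique optimum
    # (C/T substitutions can neither create an AG nor a new copy silently:
    # rescan until none remain)
    hept_off = to_offset(spec.branch_pos - 5, n)
    while True:
        s = "".join(chars)
        stray = [
            i for i in range(n - 6) if s[i : i + 7] == hept and i != hept_off
        ]
        if not stray:
            break
        broke_any = False
        for i in stray:
            for q in range(i + 6, i - 1, -1):
                if q not in protected:
                    chars[q] = "C" if chars[q] != "C" else "T"
                    broke_any = True
                    break
            # a fully protected copy can only sit in the guard/PPT/3'ss
            # block, which lies 3' of the shortened AGEZ: it never competes
        if not broke_any:
            break

    seq = "".join(chars)
    intron = Intron(
        id=f"fix-seed{spec.seed}", seq=seq, branch_sites=(spec.branch_pos,)
    )
    assert is_valid_ppt(intron.slice(ppt_start, -3)), "planted PPT failed its own rules"
    return intron


def generate_set(
    n: int, seed: int, spec: FixtureSpec | None = None, matrix: FrequencyMatrix | None = None
) -> list[Intron]:
    """n fixtures with per-intron seeds derived from ``seed`` (below 2**31)."""
    base = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i, s in enumerate(seeds):
        one = FixtureSpec(
            intron_length=base.intron_length,
            branch_pos=base.branch_pos,
            bps_heptamer=base.bps_heptamer,
            ppt_length=base.ppt_length,
            agez_decoy_ag_positions=base.agez_decoy_ag_positions,
            gc_background=base.gc_background,
            seed=int(s),
            defining_ag_offset=base.defining_ag_offset,
        )
        intron = generate(one, matrix=matrix)
        out.append(
            Intron(id=f"fix{i:03d}-seed{s}", seq=intron.seq, branch_sites=intron.branch_sites)
        )
    return out
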