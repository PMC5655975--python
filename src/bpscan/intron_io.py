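"""Intron sequences, 3'ss-relative coordinates, and FASTA I/O.

Coordinate convention
---------------------
All positions are 3'ss-relative and 1-based negative: position -1 is the last
intron nucleotide (the G of the terminal AG), -2 the A, and so on.  A sequence
of length n spans positions [-n, -1].  This matches how branch-point distances
are quoted in the splicing literature ("-14 to -45 nts of the 3'ss").

Branch-site annotations travel in the FASTA header as a ``bp=`` token, e.g.::

    >intron7 bp=-24,-31

meaning the intron has two experimentally supported branch sites, 24 and 31
nucleotides upstream of the 3' splice site.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = set("ACGTN")
_BP_TOKEN = re.compile(r"\bbp=(-\d+(?:,-\d+)*)\b")


class FastaParseError(ValueError):
    """A FASTA record could not be read; the message names the record."""


class AnnotationError(ValueError):
    """A branch-site annotation is malformed or out of range."""


class CoordinateError(ValueError):
    """A 3'ss-relative position is outside [-n, -1]."""


@dataclass(frozen=True)
class Intron:
    """One intron, 5'->3', ending at the 3'ss AG.

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        Uppercase DNA (A/C/G/T/N); U is mapped to T on read.
    branch_sites : tuple of int
        Annotated branch sites, 3'ss-relative (negative); may be empty.
    """

    id: str
    seq: str
    branch_sites: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"intron {self.id!r}: empty sequence")
        bad = set(self.seq) - _VALID
        if bad:
            raise FastaParseError(
                f"intron {self.id!r}: invalid symbols {sorted(bad)}"
            )
        n = len(self.seq)
        for p in self.branch_sites:
            if not (-n <= p <= -1):
                raise AnnotationError(
                    f"intron {self.id!r}: branch site {p} outside [-{n}, -1]"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def has_canonical_3ss(self) -> bool:
        return self.seq.endswith("AG")

    def base(self, p: int) -> str:
        """Nucleotide at 3'ss-relative position ``p``."""
        return self.seq[to_offset(p, len(self.seq))]

    def slice(self, start: int, end: int) -> str:
        """Subsequence spanning 3'ss-relative positions [start, end]."""
        n = len(self.seq)
        return self.seq[to_offset(start, n) : to_offset(end, n) + 1]


@dataclass(frozen=True)
class Region:
    """Closed interval [start, end] in 3'ss-relative coordinates."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end or self.end > -1:
            raise ValueError(
                f"invalid region [{self.start}, {self.end}] ({self.label})"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, p: int) -> bool:
        return self.start <= p <= self.end


def to_offset(p: int, n: int) -> int:
    """Map a 3'ss-relative position to a 0-based string offset.

    -1 -> n-1 (last base), -n -> 0 (first base).
    """
    if not (-n <= p <= -1):
        raise CoordinateError(f"position {p} outside [-{n}, -1]")
    return n + p


def from_offset(i: int, n: int) -> int:
    """Inverse of :func:`to_offset`."""
    if not (0 <= i <= n - 1):
        raise CoordinateError(f"offset {i} outside [0, {n - 1}]")
    return i - n


def _parse_branch_sites(description: str, record_id: str) -> tuple[int, ...]:
    m = _BP_TOKEN.search(description)
    if m is None:
        return ()
    try:
        return tuple(int(tok) for tok in m.group(1).split(","))
    except ValueError as exc:  # pragma: no cover - regex precludes this
        raise AnnotationError(f"record {record_id!r}: bad bp= token") from exc


def read_fasta(
    path: str | Path | TextIO,
    annotation_key: str = "bp",
    permissive_3ss: bool = False,
) -> list[Intron]:
    """Read introns from FASTA, in file order.

    Sequences are uppercased and U is mapped to T.  Records containing
    symbols other than A/C/G/T/N are rejected.  Unless ``permissive_3ss``
    is set, each sequence must end in the canonical 3'ss dinucleotide AG;
    with the flag, a warning is recorded instead.
    """
    del annotation_key  # single bp= convention; hook kept for converters
    introns: list[Intron] = []
    for rec in SeqIO.parse(path if not isinstance(path, Path) else str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FastaParseError(f"record {rec.id!r}: empty sequence")
        sites = _parse_branch_sites(rec.description, rec.id)
        intron = Intron(id=rec.id, seq=seq, branch_sites=sites)
        if not intron.has_canonical_3ss:
            if permissive_3ss:
                warnings.warn(
                    f"intron {rec.id!r} lacks the canonical 3'ss AG",
                    stacklevel=2,
                )
            else:
                raise FastaParseError(
                    f"record {rec.id!r}: does not end in AG "
                    "(pass permissive_3ss=True to accept)"
                )
        introns.append(intron)
    return introns


def write_fasta(introns: Iterable[Intron], path: str | Path | TextIO) -> None:
    """Write introns to FASTA, encoding branch sites as a ``bp=`` token."""
    records = []
    for it in introns:
        desc = ""
        if it.branch_sites:
            desc = "bp=" + ",".join(str(p) for p in it.branch_sites)
        records.append(SeqRecord(Seq(it.seq), id=it.id, description=desc))
    SeqIO.write(records, path if not isinstance(path, Path) else str(path), "fasta")


def write_regions_tsv(
    rows: Iterable[tuple[str, Region]], path: str | Path | TextIO
) -> None:
    """Write (intron_id, Region) pairs as TSV: intron_id, label, start, end."""
    close = False
    if isinstance(path, (str, Path)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("intron_id\tlabel\tstart\tend\n")
        for intron_id, region in rows:
            fh.write(f"{intron_id}\t{region.label}\t{region.start}\t{region.end}\n")
    finally:
        if close:
            fh.close()
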