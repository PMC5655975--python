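"""Heptamer position-frequency matrices, PSSM scoring and information content.

The branch-point motif is modelled as a 4x7 matrix of per-position relative
nucleotide frequencies f(i, x), i = 1..7, x in {A, C, G, T}.  A heptamer X
gets the position-specific (PSSM) score

    S(X) = sum_{i=1..7} log2 f(i, X_i)        [bits]

with S = -inf whenever any f(i, X_i) = 0: in a matrix with fixed positions
(the "TNA" class, f(4,T) = 1 and f(6,A) = 1) a heptamer violating the fixed
bases is excluded outright rather than smoothed with pseudocounts.

Per-position conservation is the information content under a uniform
background, IC_i = 2 + sum_x f(i,x) log2 f(i,x), in [0, 2] bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
WIDTH = 7


@dataclass(frozen=True)
class FrequencyMatrix:
    """Relative frequencies f[base, position] with shape (4, 7), rows A/C/G/T."""

    f: np.ndarray
    source: str = "custom"

    def __post_init__(self) -> None:
        arr = np.asarray(self.f, dtype=float)
        if arr.shape != (4, WIDTH):
            raise ValueError(f"expected a 4x{WIDTH} matrix, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("negative frequencies")
        sums = arr.sum(axis=0)
        if np.abs(sums - 1.0).max() > 1e-3:
            raise ValueError(f"position frequencies do not sum to 1: {sums}")
        arr = arr / sums  # renormalize the <=1e-3 drift
        object.__setattr__(self, "f", arr)

    def freq(self, position: int, base: str) -> float:
        """f at 1-based heptamer ``position`` for ``base``."""
        if not (1 <= position <= WIDTH):
            raise ValueError(f"position {position} outside 1..{WIDTH}")
        return float(self.f[_BASE_INDEX[base], position - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.f, index=list(BASES), columns=[f"pos{i}" for i in range(1, WIDTH + 1)]
        )


@dataclass(frozen=True)
class ICProfile:
    per_position: tuple[float, ...]
    total: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.per_position) != WIDTH:
            raise ValueError("IC profile must have 7 positions")
        object.__setattr__(self, "total", float(sum(self.per_position)))


#: Synthetic stand-in matrices bundled with the package.  They emulate the
#: three model classes used for prediction — a strict TNA-fixed motif
#: (f(4,T) = f(6,A) = 1, other positions peaked on the yeast consensus), a
#: degenerate motif of the YUNAY kind, and a genome-wide-style YTNAY motif —
#: but are NOT transcriptions of any published frequency table.
BUNDLED_MATRICES = {
    "tna-strict": "s1_tna_synthetic.tsv",
    "degenerate": "s2_degenerate_synthetic.tsv",
    "genomewide": "genomewide_synthetic.tsv",
}


def bundled_matrix(name: str) -> "FrequencyMatrix":
    """One of the bundled synthetic matrices (see :data:`BUNDLED_MATRICES`)."""
    from importlib import resources

    try:
        fname = BUNDLED_MATRICES[name]
    except KeyError:
        raise KeyError(
            f"unknown bundled matrix {name!r}; available: {sorted(BUNDLED_MATRICES)}"
        ) from None
    with resources.as_file(resources.files("bpscan.data").joinpath(fname)) as p:
        return load_matrix(p, source=f"bundled:{name} (synthetic)")


def load_matrix(path: str | Path, source: str | None = None) -> FrequencyMatrix:
    """Read a frequency matrix from TSV.

    Expected layout: header ``pos1..pos7``, row labels A/C/G/T.  The transpose
    (rows pos1..pos7, columns A/C/G/T) is auto-detected from the header.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [str(c) for c in df.columns]
    if set(cols) >= set(BASES):
        df = df[list(BASES)].T  # transposed layout on disk
    df.index = [str(i).upper() for i in df.index]
    try:
        df = df.loc[list(BASES)]
    except KeyError as exc:
        raise ValueError(f"{path}: expected rows A/C/G/T, got {list(df.index)}") from exc
    if df.shape != (4, WIDTH):
        raise ValueError(f"{path}: expected 4x{WIDTH}, got {df.shape}")
    return FrequencyMatrix(f=df.to_numpy(dtype=float), source=source or str(path))


def save_matrix(matrix: FrequencyMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6f")


def position_score(x: str, matrix: FrequencyMatrix) -> float:
    """PSSM score S(X) in bits; -inf if any position has zero frequency."""
    if len(x) != WIDTH:
        raise ValueError(f"heptamer must have length {WIDTH}, got {x!r}")
    if set(x) - set(BASES):
        raise ValueError(f"invalid alphabet in heptamer {x!r}")
    score = 0.0
    for i, base in enumerate(x, start=1):
        f = matrix.freq(i, base)
        if f == 0.0:
            return float("-inf")
        score += np.log2(f)
    return float(score)


def info_content(matrix: FrequencyMatrix) -> ICProfile:
    """Per-position information content in bits, uniform background."""
    f = matrix.f
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    per_pos = 2.0 + plogp.sum(axis=0)
    return ICProfile(per_position=tuple(float(v) for v in per_pos))
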