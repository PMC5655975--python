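"""Binding energy between candidate branch-point hexamers and U2 snRNA.

During spliceosome A-complex formation the conserved GUAGUA motif of U2
snRNA base-pairs with the branch-point heptamer, bulging out the branch
adenosine.  The stability of that duplex is modelled as the minimum free
energy (kcal/mol, 37 degC) of co-folding the hexamer — the heptamer with the
branch position (or a neighbour, k in {5, 6, 7}) deleted — against GUAGUA.

Energies for all 4096 hexamers are computed once and cached in an
:class:`EnergyTable`; per-candidate queries are dictionary lookups, so
genome-scale scans never shell out per heptamer.  Three backends exist:

``cofold``
    ViennaRNA's co-folding MFE (``RNA.cofold``, falling back to the
    ``RNAcofold`` executable), default parameters (Turner, 37 degC).
``nn``
    A self-contained nearest-neighbor evaluator: best single helix over all
    antiparallel registers of the two hexamers, Turner-style Watson-Crick
    stacks plus a coarse wobble term, duplex initiation and terminal AU/GU
    penalties.  No loops are modelled.  Useful where ViennaRNA is absent;
    it agrees with ``cofold`` on ranking the perfect complement minimal.
``file:<path>``
    A previously serialized table.

More negative means more stable; a duplex with no favourable pairing is
assigned 0 kcal/mol so that the scoring scheme degrades gracefully to the
pure PSSM score.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

U2_MOTIF = "GUAGUA"
RNA_BASES = "ACGU"
PERFECT_COMPLEMENT = "UACUAC"  # reverse complement of GUAGUA

_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}
_WEAK_PAIRS = {"AU", "UA", "GU", "UG"}

# Turner 2004 Watson-Crick stack free energies, kcal/mol at 37 degC.
# Key "XY/WZ" means 5'-XY-3' over 3'-WZ-5'; symmetry fills the rest.
_WC_STACKS = {
    "AA/UU": -0.93,
    "AU/UA": -1.10,
    "UA/AU": -1.33,
    "CU/GA": -2.08,
    "CA/GU": -2.11,
    "GU/CA": -2.24,
    "GA/CU": -2.35,
    "CG/GC": -2.36,
    "GG/CC": -3.26,
    "GC/CG": -3.42,
}
_GU_STACK = -1.0  # coarse single value for any stack involving a wobble pair
_DUPLEX_INIT = 4.09
_TERMINAL_AU = 0.45


class EnergyBackendError(RuntimeError):
    pass


class EnergyUndefined(ValueError):
    """The hexamer contains N; no energy can be assigned."""


@dataclass(frozen=True)
class EnergyTable:
    energies: dict[str, float]
    backend_label: str
    parameter_note: str = ""

    def __post_init__(self) -> None:
        if len(self.energies) != 4**6:
            raise ValueError(
                f"energy table incomplete: {len(self.energies)} of {4 ** 6} hexamers"
            )

    def __getitem__(self, hexamer: str) -> float:
        return self.energies[hexamer]


def all_hexamers() -> list[str]:
    return ["".join(p) for p in itertools.product(RNA_BASES, repeat=6)]


def to_rna(s: str) -> str:
    return s.upper().replace("T", "U")


def delete_position(x: str, k: int) -> str:
    """Heptamer with 1-based position ``k`` removed, as RNA."""
    if len(x) != 7:
        raise ValueError(f"heptamer must have length 7, got {x!r}")
    if k not in (5, 6, 7):
        raise ValueError(f"k must be 5, 6 or 7, got {k}")
    return to_rna(x[: k - 1] + x[k:])


def binding_energy(x: str, k: int, table: EnergyTable) -> float:
    """BE(X/X_k): co-fold MFE of the k-deleted hexamer with GUAGUA."""
    hexamer = delete_position(x, k)
    if "N" in hexamer:
        raise EnergyUndefined(f"hexamer {hexamer!r} contains N")
    return table[hexamer]


def _stack_energy(top: str, bottom: str) -> float:
    # the 10 unique WC entries plus strand symmetry cover all WC stacks;
    # anything falling through involves a wobble pair
    key = f"{top}/{bottom}"
    if key in _WC_STACKS:
        return _WC_STACKS[key]
    sym = f"{bottom[::-1]}/{top[::-1]}"
    if sym in _WC_STACKS:
        return _WC_STACKS[sym]
    return _GU_STACK


def _nn_energy(hexamer: str, target: str = U2_MOTIF) -> float:
    """Best single-helix nearest-neighbor energy over all registers."""
    rt = target[::-1]  # bottom strand written 3'->5' alongside the top
    best = 0.0
    for d in range(-(len(hexamer) - 1), len(rt)):
        paired = [
            i
            for i in range(len(hexamer))
            if 0 <= i + d < len(rt) and hexamer[i] + rt[i + d] in _PAIRS
        ]
        # contiguous runs of pairs form helices; score each
        run: list[int] = []
        for i in paired + [None]:  # type: ignore[list-item]
            if run and (i is None or i != run[-1] + 1):
                if len(run) >= 2:
                    e = _DUPLEX_INIT
                    for a, b in zip(run, run[1:]):
                        e += _stack_energy(
                            hexamer[a] + hexamer[b], rt[a + d] + rt[b + d]
                        )
                    for end in (run[0], run[-1]):
                        if hexamer[end] + rt[end + d] in _WEAK_PAIRS:
                            e += _TERMINAL_AU
                    best = min(best, e)
                run = []
            if i is not None:
                run.append(i)
    return best


def _cofold_energies(hexamers: list[str]) -> dict[str, float]:
    try:
        import RNA  # ViennaRNA python bindings

        return {
            h: min(0.0, RNA.cofold(f"{h}&{U2_MOTIF}")[1]) for h in hexamers
        }
    except ImportError:
        pass
    exe = shutil.which("RNAcofold")
    if exe is None:
        raise EnergyBackendError(
            "cofold backend unavailable: neither the ViennaRNA python module "
            "nor the RNAcofold executable was found; use backend='nn' or "
            "backend='file:<path>'"
        )
    stdin = "\n".join(f"{h}&{U2_MOTIF}" for h in hexamers) + "\n"
    out = subprocess.run(
        [exe, "--noPS"], input=stdin, capture_output=True, text=True, check=True
    ).stdout
    energies: dict[str, float] = {}
    lines = [ln for ln in out.splitlines() if ln.strip()]
    for seq_line, struct_line in zip(lines[::2], lines[1::2]):
        h = seq_line.split("&")[0].strip()
        mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
        energies[h] = min(0.0, mfe)
    return energies


_TABLE_CACHE: dict[str, EnergyTable] = {}


def build_energy_table(backend: str = "cofold", use_cache: bool = True) -> EnergyTable:
    """Energies of all 4096 hexamers against GUAGUA, cached per backend."""
    if use_cache and backend in _TABLE_CACHE:
        return _TABLE_CACHE[backend]
    hexamers = all_hexamers()
    if backend == "cofold":
        table = EnergyTable(
            energies=_cofold_energies(hexamers),
            backend_label="cofold",
            parameter_note="ViennaRNA co-folding MFE, default parameters (37C)",
        )
    elif backend == "nn":
        table = EnergyTable(
            energies={h: _nn_energy(h) for h in hexamers},
            backend_label="nn",
            parameter_note=(
                "nearest-neighbor single-helix scan, Turner WC stacks, "
                "coarse wobble term, init 4.09, terminal AU/GU 0.45"
            ),
        )
    elif backend.startswith("file:"):
        table = read_energy_table(backend[len("file:") :])
    else:
        raise EnergyBackendError(
            f"unknown backend {backend!r}; choose cofold, nn or file:<path>"
        )
    if use_cache:
        _TABLE_CACHE[backend] = table
    return table


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# backend={table.backend_label}\n")
        fh.write(f"# note={table.parameter_note}\n")
        fh.write("hexamer\tenergy_kcal_mol\n")
        for h in sorted(table.energies):
            fh.write(f"{h}\t{table.energies[h]:.2f}\n")


def read_energy_table(path: str | Path) -> EnergyTable:
    backend_label, note = "file", ""
    energies: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# backend="):
                backend_label = line.split("=", 1)[1]
            elif line.startswith("# note="):
                note = line.split("=", 1)[1]
            elif line and not line.startswith(("#", "hexamer")):
                h, e = line.split("\t")
                energies[h] = float(e)
    return EnergyTable(energies=energies, backend_label=backend_label, parameter_note=note)
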