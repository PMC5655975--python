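"""The S* scoring family and branch-point prediction.

A candidate branch-point heptamer X (branch adenosine at position 6) is
scored by combining three signals:

* motif conservation — the PSSM score S(X) = sum_i log2 f(i, X_i);
* duplex stability — the binding energy BE(X/X_k) between U2 snRNA's GUAGUA
  and the hexamer obtained by deleting position k of X, for k = 5, 6, 7
  (the branch site or a neighbour, since branch positions mapped from cDNA
  can be off by a base);
* branch-site base preference — the frequency f(k, X_k) of the deleted base.

The family is parameterized by weights P = (P1, P2, P3) and exponents
Q = (Q1, Q2, Q3), all in [0, 1], with term j using k = j + 4:

    S*(X) = S(X) - [ sum_j  P_j * BE(X/X_{j+4}) * f(j+4, X_{j+4})^{Q_j} ]
                   / sum_j P_j

With all P_j = 0 the energy term is dropped and S* reduces to the plain
PSSM score ("score0").  "score8" activates only the branch-site term
(P = (0, 1, 0), Q2 = 1), so S* = S - BE(X/X_6) * f(6, X_6); since BE is
negative for a stable duplex, a strong U2 pairing raises the score.

Prediction scans every N-free heptamer whose branch position lies in the
shortened AGEZ and returns the top scorer; ties resolve toward the 3'ss,
where observed human branch points concentrate (-18..-32 nt).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .agez import AgezParams, DEFAULT_PARAMS, agez_core, find_agez, shorten_agez
from .energy import EnergyTable, binding_energy
from .freq import FrequencyMatrix, position_score
from .intron_io import Intron, Region
from .ppt import DEFAULT_RULES, PPTRules, find_ppt

_HEPTAMER_BASES = set("ACGT")


@dataclass(frozen=True)
class ScoreConfig:
    """One member of the S* family: weights P and exponents Q for k=5,6,7."""

    name: str
    P: tuple[float, float, float]
    Q: tuple[float, float, float]

    def __post_init__(self) -> None:
        for vec, label in ((self.P, "P"), (self.Q, "Q")):
            if len(vec) != 3 or any(not (0.0 <= v <= 1.0) for v in vec):
                raise ValueError(f"{self.name}: {label} must be three values in [0,1]")

    @property
    def energy_active(self) -> bool:
        return sum(self.P) > 0.0


def load_score_configs(path: str | Path | None = None) -> dict[str, ScoreConfig]:
    """Read the named scoring configurations (score0..score14 by default)."""
    if path is None:
        text = resources.files("bpscan.data").joinpath("score_configs.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    configs = {}
    for name, pq in raw.items():
        configs[name] = ScoreConfig(
            name=name, P=tuple(float(v) for v in pq["P"]), Q=tuple(float(v) for v in pq["Q"])
        )
    return configs


def get_score_config(name: str) -> ScoreConfig:
    configs = load_score_configs()
    try:
        return configs[name]
    except KeyError:
        raise KeyError(
            f"unknown score config {name!r}; available: {sorted(configs)}"
        ) from None


@dataclass(frozen=True)
class Candidate:
    heptamer: str
    branch_pos: int
    score: float


@dataclass(frozen=True)
class Prediction:
    intron_id: str
    best: Candidate | None
    ppt: Region | None
    agez: Region
    short_agez: Region
    config_name: str
    matrix_source: str
    flag: str = ""

    @property
    def branch_pos(self) -> int | None:
        return None if self.best is None else self.best.branch_pos


def score_star(
    x: str, matrix: FrequencyMatrix, table: EnergyTable, cfg: ScoreConfig
) -> float:
    """S*(X); -inf propagates from a zero-frequency PSSM position."""
    s = position_score(x, matrix)
    if not cfg.energy_active or s == float("-inf"):
        return s
    total_p = sum(cfg.P)
    term = 0.0
    for j in range(3):
        if cfg.P[j] == 0.0:
            continue
        k = j + 5
        be = binding_energy(x, k, table)
        fk = matrix.freq(k, x[k - 1])
        term += cfg.P[j] * be * fk ** cfg.Q[j]
    return s - term / total_p


def enumerate_candidates(intron: Intron, short_agez: Region) -> list[Candidate]:
    """All N-free heptamers whose branch position (6) lies in the zone.

    The heptamer spans positions [p-5, p+1]; it must lie wholly inside the
    intron, but only the branch position itself is required to be in the
    shortened AGEZ.  Scores are filled in later.
    """
    n = len(intron)
    out = []
    for p in range(short_agez.start, short_agez.end + 1):
        if p - 5 < -n or p + 1 > -1:
            continue
        hept = intron.slice(p - 5, p + 1)
        if set(hept) <= _HEPTAMER_BASES:
            out.append(Candidate(heptamer=hept, branch_pos=p, score=float("nan")))
    return out


def predict(
    intron: Intron,
    matrix: FrequencyMatrix,
    table: EnergyTable,
    cfg: ScoreConfig,
    params: AgezParams = DEFAULT_PARAMS,
    rules: PPTRules = DEFAULT_RULES,
) -> Prediction:
    """Full pipeline: AGEZ -> PPT -> shortened AGEZ -> scan -> argmax."""
    agez = find_agez(intron, params)
    core = agez_core(intron, params)
    ppt = find_ppt(intron, core, rules)
    short = shorten_agez(agez, ppt, intron)
    candidates = enumerate_candidates(intron, short)
    if not candidates:
        return Prediction(
            intron_id=intron.id, best=None, ppt=ppt, agez=agez, short_agez=short,
            config_name=cfg.name, matrix_source=matrix.source,
            flag="no-candidates: shortened AGEZ admits no scoreable heptamer",
        )
    scored = [
        Candidate(c.heptamer, c.branch_pos, score_star(c.heptamer, matrix, table, cfg))
        for c in candidates
    ]
    finite = [c for c in scored if c.score != float("-inf")]
    flag = ""
    if finite:
        # ties toward the 3'ss: branch_pos is negative, larger = closer
        best = max(finite, key=lambda c: (c.score, c.branch_pos))
    else:
        best = min(scored, key=lambda c: binding_energy(c.heptamer, 6, table))
        flag = "all-excluded: every candidate hit a zero-frequency position; " \
               "reporting the most stable U2 duplex"
    return Prediction(
        intron_id=intron.id, best=best, ppt=ppt, agez=agez, short_agez=short,
        config_name=cfg.name, matrix_source=matrix.source, flag=flag,
    )


def write_predictions_tsv(
    predictions: Iterable[Prediction], path, header_lines: Sequence[str] = ()
) -> None:
    """Prediction table: one row per intron, regions included for provenance."""
    cols = (
        "intron_id\theptamer\tbranch_pos\tscore\tscore_name\tppt_start\tppt_end"
        "\tagez_start\tshort_agez_start\tshort_agez_end\tflag"
    )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(cols + "\n")
        for pr in predictions:
            hept = pr.best.heptamer if pr.best else "."
            pos = pr.best.branch_pos if pr.best else "."
            score = f"{pr.best.score:.4f}" if pr.best else "."
            ps = pr.ppt.start if pr.ppt else "."
            pe = pr.ppt.end if pr.ppt else "."
            fh.write(
                f"{pr.intron_id}\t{hept}\t{pos}\t{score}\t{pr.config_name}\t{ps}\t{pe}"
                f"\t{pr.agez.start}\t{pr.short_agez.start}\t{pr.short_agez.end}"
                f"\t{pr.flag or '.'}\n"
            )
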