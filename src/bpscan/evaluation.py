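"""Accuracy reporting and literature-style baselines.

Accuracy is the fraction of introns whose predicted branch position matches
an annotated branch site exactly; for introns with several experimentally
supported branch sites, hitting any one of them counts as correct.

Two baseline predictors are provided for comparison:

* a fixed-window consensus scan: minimize the Hamming distance to the strict
  consensus TACTAAC over the last 100 or 200 nt of the intron;
* a PSSM scan over the full (un-shortened) AGEZ — an approximate stand-in
  for AGEZ+PWM methods, useful to quantify what the shortened zone and the
  energy term each buy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .agez import AgezParams, DEFAULT_PARAMS, find_agez
from .fixtures import CONSENSUS
from .freq import FrequencyMatrix, position_score
from .intron_io import Intron, Region
from .scorer import Candidate, Prediction, enumerate_candidates


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class Verdict:
    intron_id: str
    predicted: int | None
    annotated: tuple[int, ...]
    correct: bool


@dataclass(frozen=True)
class EvalReport:
    n_introns: int
    n_correct: int
    accuracy_percent: float
    verdicts: tuple[Verdict, ...]


def evaluate(introns: Sequence[Intron], preds: Sequence[Prediction]) -> EvalReport:
    """Match predictions to annotations by intron id and score them."""
    by_id = {p.intron_id: p for p in preds}
    if len(by_id) != len(preds):
        raise EvaluationError("duplicate intron ids among predictions")
    verdicts = []
    for it in introns:
        if not it.branch_sites:
            raise EvaluationError(f"intron {it.id!r} has no branch-site annotation")
        if it.id not in by_id:
            raise EvaluationError(f"no prediction for intron {it.id!r}")
        pred = by_id[it.id]
        hit = pred.branch_pos is not None and pred.branch_pos in it.branch_sites
        verdicts.append(
            Verdict(
                intron_id=it.id, predicted=pred.branch_pos,
                annotated=tuple(it.branch_sites), correct=hit,
            )
        )
    n = len(verdicts)
    n_correct = sum(v.correct for v in verdicts)
    return EvalReport(
        n_introns=n,
        n_correct=n_correct,
        accuracy_percent=round(100.0 * n_correct / n, 2) if n else 0.0,
        verdicts=tuple(verdicts),
    )


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance needs equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def hamming_baseline(
    intron: Intron, window: int, consensus: str = CONSENSUS
) -> Prediction:
    """Closest-to-consensus heptamer in the intron's last ``window`` nt.

    The window is measured from the intron 3' end (terminal AG included) and
    clamps to the intron length; ties resolve toward the 3'ss.
    """
    n = len(intron)
    w = min(window, n)
    zone = Region(start=-w, end=-1, label="WINDOW")
    best: Candidate | None = None
    for p in range(zone.start, zone.end + 1):
        if p - 5 < -n or p + 1 > -1 or p - 5 < zone.start:
            continue
        hept = intron.slice(p - 5, p + 1)
        if "N" in hept:
            continue
        d = hamming_distance(hept, consensus)
        if best is None or (-d, p) > (best.score, best.branch_pos):
            best = Candidate(heptamer=hept, branch_pos=p, score=float(-d))
    return Prediction(
        intron_id=intron.id, best=best, ppt=None, agez=zone, short_agez=zone,
        config_name=f"hamming{window}", matrix_source="consensus:TACTAAC",
        flag="" if best else "no-candidates: window narrower than a heptamer",
    )


def pwm_agez_baseline(
    intron: Intron, matrix: FrequencyMatrix, params: AgezParams = DEFAULT_PARAMS
) -> Prediction:
    """PSSM argmax over the full AGEZ (no PPT shortening, no energy term)."""
    agez = find_agez(intron, params)
    candidates = enumerate_candidates(intron, agez)
    best: Candidate | None = None
    for c in candidates:
        s = position_score(c.heptamer, matrix)
        if s == float("-inf"):
            continue
        if best is None or (s, c.branch_pos) > (best.score, best.branch_pos):
            best = Candidate(heptamer=c.heptamer, branch_pos=c.branch_pos, score=s)
    return Prediction(
        intron_id=intron.id, best=best, ppt=None, agez=agez, short_agez=agez,
        config_name="pwm-agez", matrix_source=matrix.source,
        flag="" if best else "no-candidates: every in-zone heptamer excluded",
    )


def write_report_tsv(report: EvalReport, path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("intron_id\tpredicted\tannotated\tcorrect\n")
        for v in report.verdicts:
            ann = ",".join(str(p) for p in v.annotated)
            pred = "." if v.predicted is None else str(v.predicted)
            fh.write(f"{v.intron_id}\t{pred}\t{ann}\t{int(v.correct)}\n")
        fh.write(
            f"# summary\tn={report.n_introns}\tcorrect={report.n_correct}"
            f"\taccuracy={report.accuracy_percent:.2f}%\n"
        )
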