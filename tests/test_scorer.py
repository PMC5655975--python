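"""S* scoring family, candidate enumeration and the prediction pipeline."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bpscan.agez import agez_core, find_agez, shorten_agez
from bpscan.energy import binding_energy
from bpscan.fixtures import FixtureSpec, generate
from bpscan.freq import BASES, FrequencyMatrix, position_score
from bpscan.intron_io import Intron, Region
from bpscan.ppt import find_ppt
from bpscan.scorer import (
    ScoreConfig,
    enumerate_candidates,
    get_score_config,
    load_score_configs,
    predict,
    score_star,
)

HEPTAMERS = st.text(alphabet="ACGT", min_size=7, max_size=7)


def random_matrix(seed: int) -> FrequencyMatrix:
    rng = np.random.default_rng(seed)
    return FrequencyMatrix(f=rng.dirichlet(np.ones(4), size=7).T, source=f"rand{seed}")


def test_all_fifteen_configs_load():
    configs = load_score_configs()
    assert sorted(configs) == sorted(f"score{i}" for i in range(15))
    assert configs["score0"].P == (0.0, 0.0, 0.0)
    assert configs["score8"].P == (0.0, 1.0, 0.0)
    assert configs["score8"].Q[1] == 1.0


def test_config_bounds_enforced():
    with pytest.raises(ValueError):
        ScoreConfig(name="bad", P=(0, 2, 0), Q=(1, 1, 1))
    with pytest.raises(KeyError):
        get_score_config("score99")


@given(x=HEPTAMERS, seed=st.integers(0, 2**31 - 1))
def test_score_star_with_zero_p_equals_pssm_score(x, seed, nn_table):
    """With P = (0,0,0) the energy term is dropped entirely: S* == S."""
    m = random_matrix(seed)
    cfg = get_score_config("score0")
    assert score_star(x, m, nn_table, cfg) == position_score(x, m)


def test_score8_difference_is_branch_site_energy_when_f6_is_one(nn_table):
    """With f(6, X_6) = 1 the score8-score0 gap is exactly BE(X/X_6)."""
    f = np.full((4, 7), 0.25)
    f[:, 5] = [1.0, 0.0, 0.0, 0.0]  # A fixed at the branch position
    m = FrequencyMatrix(f=f)
    x = "TACTAAC"
    s0 = score_star(x, m, nn_table, get_score_config("score0"))
    s8 = score_star(x, m, nn_table, get_score_config("score8"))
    assert s8 - s0 == pytest.approx(-binding_energy(x, 6, nn_table))


def test_uniform_matrix_zero_energy_any_config(uniform_matrix, zero_table):
    for name in ("score0", "score8", "score14"):
        cfg = get_score_config(name)
        assert score_star("TACTAAC", uniform_matrix, zero_table, cfg) == pytest.approx(-14.0)


def test_score8_never_below_score0_for_stable_duplexes(nn_table):
    """Subtracting a non-positive BE can only raise the score."""
    rng = np.random.default_rng(5)
    m = random_matrix(17)
    s0, s8 = get_score_config("score0"), get_score_config("score8")
    for _ in range(200):
        x = "".join(BASES[i] for i in rng.integers(0, 4, size=7))
        assert score_star(x, m, nn_table, s8) >= score_star(x, m, nn_table, s0)


def test_minus_inf_propagates_through_energy_term(tna_matrix, nn_table):
    cfg = get_score_config("score8")
    assert score_star("TACCAAC", tna_matrix, nn_table, cfg) == float("-inf")


def test_enumerate_width_one_zone():
    intron = Intron(id="t", seq="T" * 58 + "AG")
    cands = enumerate_candidates(intron, Region(-20, -20, "SHORT_AGEZ"))
    assert len(cands) == 1 and cands[0].branch_pos == -20
    assert cands[0].heptamer == intron.slice(-25, -19)


def test_enumerate_excludes_heptamers_leaving_the_intron():
    intron = Intron(id="t", seq="T" * 8 + "AG")  # length 10
    cands = enumerate_candidates(intron, Region(-10, -1, "SHORT_AGEZ"))
    # branch at p needs p-5 >= -10 and p+1 <= -1: p in {-5..-2}
    assert [c.branch_pos for c in cands] == [-5, -4, -3, -2]


def test_enumerate_skips_heptamers_containing_n():
    seq = "T" * 20 + "N" + "T" * 37 + "AG"
    intron = Intron(id="t", seq=seq)
    cands = enumerate_candidates(intron, Region(-45, -30, "SHORT_AGEZ"))
    n_pos = -40  # the N sits here; heptamers spanning it are absent
    for c in cands:
        assert not (c.branch_pos - 5 <= n_pos <= c.branch_pos + 1)
    assert len(cands) == 16 - 7


def test_predict_recovers_planted_site(tna_matrix, nn_table):
    intron = generate(FixtureSpec(seed=1))
    pred = predict(intron, tna_matrix, nn_table, get_score_config("score8"))
    assert pred.branch_pos == intron.branch_sites[0]
    assert pred.best.heptamer == "TACTAAC"
    assert pred.flag == ""


def test_equal_scores_tie_toward_3prime(nn_table):
    """Under a uniform matrix every in-zone heptamer scores the same, so
    the selected branch position must be the 3'-most candidate."""
    hept = "TACTAAC"
    seq = ("T" * 20 + "AG" + "TT" + hept + "TTT" + hept
           + "T" * 3 + "A" + "T" * 12 + "AG")
    intron = Intron(id="twin", seq=seq)
    m = FrequencyMatrix(f=np.full((4, 7), 0.25))
    pred = predict(intron, m, nn_table, get_score_config("score0"))
    agez = find_agez(intron)
    short = shorten_agez(agez, find_ppt(intron, agez_core(intron)), intron)
    assert pred.branch_pos == short.end


def test_all_excluded_falls_back_to_most_stable_duplex(tna_matrix, nn_table):
    # zone full of G/C: every heptamer violates the fixed T/A positions
    seq = "AG" + "GC" * 12 + "C" + "T" * 13 + "AG"
    intron = Intron(id="gc", seq=seq)
    pred = predict(intron, tna_matrix, nn_table, get_score_config("score8"))
    assert pred.best is not None
    assert "all-excluded" in pred.flag


def test_predict_is_deterministic(tna_matrix, nn_table):
    intron = generate(FixtureSpec(seed=9))
    cfg = get_score_config("score8")
    a = predict(intron, tna_matrix, nn_table, cfg)
    b = predict(intron, tna_matrix, nn_table, cfg)
    assert a == b


def naive_predict(intron, matrix, table, cfg):
    """First-principles rescan: recompute regions, scores and the argmax
    without reusing the scorer's enumeration/selection code."""
    agez = find_agez(intron)
    ppt = find_ppt(intron, agez_core(intron))
    short = shorten_agez(agez, ppt, intron)
    best = None
    n = len(intron)
    for p in range(short.start, short.end + 1):
        if p - 5 < -n or p + 1 > -1:
            continue
        x = intron.slice(p - 5, p + 1)
        if "N" in x:
            continue
        s = position_score(x, matrix)
        if s != float("-inf") and sum(cfg.P) > 0:
            acc = 0.0
            for j, (pw, q) in enumerate(zip(cfg.P, cfg.Q)):
                k = j + 5
                acc += pw * binding_energy(x, k, table) * matrix.freq(k, x[k - 1]) ** q
            s -= acc / sum(cfg.P)
        if s == float("-inf"):
            continue
        if best is None or (s, p) > best[:2]:
            best = (s, p)
    return best


def test_predict_matches_naive_rescan_on_random_fixtures(nn_table):
    """End-to-end agreement with an independent first-principles scan."""
    s8 = get_score_config("score8")
    rng = np.random.default_rng(2024)
    for i in range(30):
        m = random_matrix(int(rng.integers(2**31)))
        intron = generate(
            FixtureSpec(seed=int(rng.integers(2**31)), bps_heptamer="sample-from-matrix"),
            matrix=m,
        )
        pred = predict(intron, m, nn_table, s8)
        oracle = naive_predict(intron, m, nn_table, s8)
        assert oracle is not None
        assert pred.branch_pos == oracle[1]
        assert pred.best.score == pytest.approx(oracle[0])
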