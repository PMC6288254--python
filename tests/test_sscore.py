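"""Splice-signal scoring: PWM training/scoring, BPS/PPT detection, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kirsplice import sscore
from kirsplice.sscore import (DONOR, MatrixModel, SiteWindow, compare_sites,
                              find_branch_point, ppt_metrics, score_window,
                              train_matrix)


def _windows(seqs, kind=DONOR):
    return [SiteWindow(kind, s) for s in seqs]


def test_window_width_enforced():
    with pytest.raises(ValueError):
        SiteWindow(DONOR, "ACGT")
    with pytest.raises(ValueError):
        SiteWindow("weird", "ACGTACGTA")


def test_identical_training_set_scores_itself_at_max():
    w = _windows(["AAGGTAAGT"] * 12)
    model = train_matrix(w)
    raw, cv = score_window(model, w[0])
    assert cv == pytest.approx(100.0)
    assert raw == pytest.approx(model.score_range[1])


def test_uniform_training_set_flagged_low_information():
    rng = np.random.default_rng(0)
    seqs = ["".join(rng.choice(list("ACGT"), 9)) for _ in range(200)]
    model = train_matrix(_windows(seqs))
    assert model.low_information


def test_weights_match_hand_computed_log_odds():
    """Three-window toy set: weight = log2((count+pc)/(total+4pc)/0.25)."""
    seqs = ["AAGGTAAGT", "CAGGTAAGT", "AAGGTGAGT"]
    model = train_matrix(_windows(seqs * 4), pseudocount=1.0)
    # position 0: A appears 8/12 times -> freq (8+1)/(12+4)
    want_a = math.log2(((8 + 1) / 16) / 0.25)
    want_c = math.log2(((4 + 1) / 16) / 0.25)
    assert model.weights[0, 0] == pytest.approx(want_a)
    assert model.weights[0, 1] == pytest.approx(want_c)


def test_training_validation():
    with pytest.raises(ValueError, match="at least 10"):
        train_matrix(_windows(["AAGGTAAGT"] * 5))
    mixed = _windows(["AAGGTAAGT"] * 10) + \
        [SiteWindow("acceptor_region", "T" * 23)]
    with pytest.raises(ValueError, match="share kind"):
        train_matrix(mixed)


def test_substitution_monotonicity_and_bounds(human_models):
    donors = sscore.collect_training_windows(human_models, DONOR)
    model = train_matrix(donors)
    argmax = "".join("ACGT"[i] for i in model.weights.argmax(axis=1))
    best_raw, best_cv = score_window(model, SiteWindow(DONOR, argmax))
    assert best_cv == pytest.approx(100.0)
    for pos in range(9):
        for b in "ACGT":
            if b == argmax[pos]:
                continue
            mut = argmax[:pos] + b + argmax[pos + 1:]
            raw, cv = score_window(model, SiteWindow(DONOR, mut))
            if model.weights[pos, "ACGT".index(b)] < \
                    model.weights[pos, "ACGT".index(argmax[pos])]:
                assert raw < best_raw
            assert 0.0 <= cv <= 100.0
    argmin = "".join("ACGT"[i] for i in model.weights.argmin(axis=1))
    assert score_window(model, SiteWindow(DONOR, argmin))[1] == \
        pytest.approx(0.0)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=9, max_size=9))
def test_consensus_value_always_bounded(human_models, seq):
    donors = sscore.collect_training_windows(human_models, DONOR)
    model = train_matrix(donors)
    _, cv = score_window(model, SiteWindow(DONOR, seq))
    assert 0.0 <= cv <= 100.0


def test_self_training_never_lowers_score(human_models):
    donors = sscore.collect_training_windows(human_models, DONOR)
    probe = donors[0]
    before = score_window(train_matrix(donors[1:]), probe)[0]
    after = score_window(train_matrix(donors[1:] + [probe]), probe)[0]
    assert after >= before


def test_weakened_kir2dl4_exon7_donor_ranks_below_consensus(human_models):
    """The fixture KIR2DL4 exon-7 donor carries the weakening substitution and
    must rank below the lineage-III donor, mirroring the suboptimal-site
    explanation of exon-7 skipping."""
    model = train_matrix(sscore.collect_training_windows(human_models, DONOR))
    by_gene = {m.key: m for m in human_models}
    sites = [("KIR2DL4", sscore.donor_window(by_gene["KIR2DL4*002"], 7)),
             ("lineageIII", sscore.donor_window(by_gene["KIR2DL1*001"], 7))]
    report = compare_sites(model, sites)
    assert report.iloc[0]["site"] == "lineageIII"
    assert report.iloc[1]["delta_vs_top"] < 0
    single = compare_sites(model, sites[:1])
    assert single.iloc[0]["rank"] == 1 and single.iloc[0]["delta_vs_top"] == 0


def test_interrupted_ppt_detected_on_kir2dl4_exon7_acceptor(model_of):
    """Two adenines interrupt the exon-7 polypyrimidine tract of KIR2DL4."""
    m = model_of("KIR2DL4*002")
    up = sscore.acceptor_upstream(m, 6)
    frac, longest, inter = ppt_metrics(up)
    assert inter == 2
    clean = sscore.acceptor_upstream(model_of("KIR2DL1*001"), 6)
    assert ppt_metrics(clean)[2] == 0


def test_ppt_metrics_counts():
    assert ppt_metrics("G" * 40 + "T" * 20) == (1.0, 15, 0)
    alt = ("GT" * 30)
    frac, longest, inter = ppt_metrics(alt)
    assert frac == pytest.approx(7 / 15)  # 15-nt window on alternating GT
    seq = "G" * 40 + "TTTTTATTTTATTTTTTTTT"
    assert ppt_metrics(seq)[2] == 2


def test_branch_point_detection(model_of):
    m = model_of("KIR3DL01*001")
    up = sscore.acceptor_upstream(m, 4)
    hit = find_branch_point(up)
    assert hit is not None
    assert hit.motif == "CTCAC"  # the stamped YUNAY-conformant BPS
    assert -50 <= hit.position <= -20
    assert find_branch_point("G" * 60) is None
    # tie-break: the match nearer the acceptor wins
    two = "G" * 10 + "CTAAC" + "G" * 15 + "CTAAC" + "G" * 20
    hit = find_branch_point(two, window=(-50, -15))
    assert hit.position == -25


def test_matrix_model_json_round_trip(tmp_path, human_models):
    model = train_matrix(sscore.collect_training_windows(human_models, DONOR))
    model.to_json(tmp_path / "donor.json")
    back = MatrixModel.from_json(tmp_path / "donor.json")
    assert back.kind == model.kind
    assert np.allclose(back.weights, model.weights)
    probe = SiteWindow(DONOR, "AAGGTAAGT")
    assert score_window(back, probe) == score_window(model, probe)
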