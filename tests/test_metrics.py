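"""Deviation statistics vs independent brute-force loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchaudit import (
    PairedPredictions,
    PredictionRecord,
    ShortcutReport,
    deviation_summary,
    flip_fraction,
    mad,
    pearson_fidelity,
    record,
    sens_spec,
)

# ---------------------------------------------------------------------------
# Independent oracles: explicit per-pair loops, no vectorisation.
# ---------------------------------------------------------------------------

def true_p(rec, label):
    return rec.p_malignant if label == "malignant" else rec.p_benign


def mad_oracle(pairs):
    total = 0.0
    for o, a, lab in zip(pairs.original, pairs.altered, pairs.labels):
        total += abs(true_p(a, lab) - true_p(o, lab))
    return total / len(pairs.original)


def deviation_oracle(pairs):
    n_dec, acc = 0, 0.0
    for o, a, lab in zip(pairs.original, pairs.altered, pairs.labels):
        d = true_p(a, lab) - true_p(o, lab)
        if d < 0:
            n_dec += 1
            acc += -d
    frac = n_dec / len(pairs.original)
    return frac, (acc / n_dec if n_dec else None)


def flip_oracle(pairs, threshold, restrict=True):
    n_correct, n_flip = 0, 0
    for o, a, lab in zip(pairs.original, pairs.altered, pairs.labels):
        pred_o = "malignant" if o.p_malignant >= threshold else "benign"
        pred_a = "malignant" if a.p_malignant >= threshold else "benign"
        if pred_o == lab:
            n_correct += 1
            if pred_a != lab:
                n_flip += 1
    return n_flip / (n_correct if restrict else len(pairs.original))


def sens_spec_oracle(preds, labels, threshold):
    tp = fn = tn = fp = 0
    for r, lab in zip(preds, labels):
        pred = "malignant" if r.p_malignant >= threshold else "benign"
        if lab == "malignant":
            tp += pred == "malignant"
            fn += pred == "benign"
        else:
            tn += pred == "benign"
            fp += pred == "malignant"
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    return sens, spec


def pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sum((a - mx) ** 2 for a in x) ** 0.5
    sy = sum((b - my) ** 2 for b in y) ** 0.5
    return sxy / (sx * sy)


def random_pairs(rng, n=None):
    n = n or int(rng.integers(1, 30))
    po = rng.random(n)
    pa = rng.random(n)
    labels = tuple(rng.choice(["benign", "malignant"], n))
    return PairedPredictions(
        tuple(record(f"i{k}", po[k]) for k in range(n)),
        tuple(record(f"i{k}", pa[k]) for k in range(n)),
        labels,
        "patch_removed",
    )


def test_oracle_equivalence_on_1000_random_sets():
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        pairs = random_pairs(rng)
        thr = float(rng.uniform(0.1, 0.9))
        assert mad(pairs) == pytest.approx(mad_oracle(pairs), abs=1e-9)
        frac, mnd = deviation_summary(pairs)
        frac_o, mnd_o = deviation_oracle(pairs)
        assert frac == pytest.approx(frac_o, abs=1e-9)
        if mnd_o is None:
            assert mnd is None
        else:
            assert mnd == pytest.approx(mnd_o, abs=1e-9)
        labels = list(pairs.labels)
        preds = list(pairs.original)
        s, p = sens_spec(preds, labels, thr)
        s_o, p_o = sens_spec_oracle(preds, labels, thr)
        assert (s is None) == (s_o is None)
        assert (p is None) == (p_o is None)
        if s is not None:
            assert s == pytest.approx(s_o, abs=1e-9)
        if p is not None:
            assert p == pytest.approx(p_o, abs=1e-9)
        try:
            expected = flip_oracle(pairs, thr)
        except ZeroDivisionError:
            with pytest.raises(ValueError):
                flip_fraction(pairs, thr)
        else:
            assert flip_fraction(pairs, thr) == pytest.approx(expected, abs=1e-9)
            assert flip_fraction(pairs, thr, restrict_to_correct=False) == (
                pytest.approx(flip_oracle(pairs, thr, False), abs=1e-9)
            )


def test_pearson_fidelity_against_loop_oracle():
    rng = np.random.default_rng(7)
    n = 40
    ids = [f"i{k}" for k in range(n)]
    pa = [record(i, float(p)) for i, p in zip(ids, rng.random(n))]
    pb = [record(i, float(p)) for i, p in zip(ids, rng.random(n))]
    sub = {"first_half": ids[: n // 2], "second_half": ids[n // 2 :]}
    got = pearson_fidelity(pa, pb, sub)
    da = {r.id: r.p_malignant for r in pa}
    db = {r.id: r.p_malignant for r in pb}
    for name, members in (("overall", ids), *sub.items()):
        expected = pearson_oracle([da[i] for i in members], [db[i] for i in members])
        assert got[name] == pytest.approx(expected, abs=1e-9)


class TestWorkedExamples:
    def test_mad_three_pairs(self):
        # true-class probs 0.8->0.5, 0.2->0.4, 0.6->0.5 for benign pairs
        pairs = PairedPredictions(
            tuple(record(i, 1 - p) for i, p in zip("abc", (0.8, 0.2, 0.6))),
            tuple(record(i, 1 - p) for i, p in zip("abc", (0.5, 0.4, 0.5))),
            ("benign",) * 3,
            "patch_removed",
        )
        assert mad(pairs) == pytest.approx(0.2)

    def test_single_pair_extremes(self):
        pairs = PairedPredictions(
            (record("a", 0.0),), (record("a", 1.0),), ("benign",), "x"
        )
        assert mad(pairs) == pytest.approx(1.0)

    def test_deviation_summary_mixed_signs(self):
        pairs = PairedPredictions(
            (record("a", 0.5), record("b", 0.5)),
            (record("a", 0.8), record("b", 0.3)),
            ("malignant", "malignant"),
            "x",
        )
        # deviations +0.3 and -0.2 on the malignant probability
        frac, mnd = deviation_summary(pairs)
        assert frac == pytest.approx(0.5)
        assert mnd == pytest.approx(0.2)

    def test_mnd_undefined_when_nothing_decreases(self):
        pairs = PairedPredictions(
            (record("a", 0.5),), (record("a", 0.6),), ("malignant",), "x"
        )
        frac, mnd = deviation_summary(pairs)
        assert frac == 0.0
        assert mnd is None

    def test_flip_fraction_with_low_sensitivity_threshold(self):
        # malignant pairs 0.9->0.3, 0.5->0.45, 0.3->0.2 at threshold 0.4:
        # originally correct {0.9, 0.5}; only 0.9->0.3 crosses -> 1/2
        pairs = PairedPredictions(
            tuple(record(i, p) for i, p in zip("abc", (0.9, 0.5, 0.3))),
            tuple(record(i, p) for i, p in zip("abc", (0.3, 0.45, 0.2))),
            ("malignant",) * 3,
            "patch_inserted",
        )
        assert flip_fraction(pairs, 0.4) == pytest.approx(0.5)

    def test_no_crossing_gives_zero(self):
        pairs = PairedPredictions(
            (record("a", 0.9),), (record("a", 0.8),), ("malignant",), "x"
        )
        assert flip_fraction(pairs, 0.4) == 0.0

    def test_boundary_tie_classified_malignant(self):
        sens, _ = sens_spec([record("a", 0.4)], ["malignant"], 0.4)
        assert sens == 1.0

    def test_sens_spec_worked_example(self):
        sens, spec = sens_spec(
            [record("a", 0.5), record("b", 0.3)], ["malignant"] * 2, 0.4
        )
        assert sens == pytest.approx(0.5)
        assert spec is None  # no benign samples: not applicable

    def test_pearson_trivial_cases(self):
        ids = ["a", "b", "c"]
        x = [record(i, p) for i, p in zip(ids, (0.1, 0.2, 0.3))]
        assert pearson_fidelity(x, x)["overall"] == pytest.approx(1.0)
        y = [record(i, p) for i, p in zip(ids, (0.2, 0.4, 0.6))]
        assert pearson_fidelity(x, y)["overall"] == pytest.approx(1.0)
        z = [record(i, p) for i, p in zip(ids, (0.3, 0.2, 0.1))]
        assert pearson_fidelity(x, z)["overall"] == pytest.approx(-1.0)

    def test_pearson_zero_variance_flagged_undefined(self):
        ids = ["a", "b", "c"]
        x = [record(i, 0.5) for i in ids]
        y = [record(i, p) for i, p in zip(ids, (0.1, 0.2, 0.3))]
        assert pearson_fidelity(x, y)["overall"] is None


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.permutations(range(8)))
def test_statistics_invariant_under_pair_permutation(seed, order):
    rng = np.random.default_rng(seed)
    pairs = random_pairs(rng, n=8)
    permuted = PairedPredictions(
        tuple(pairs.original[i] for i in order),
        tuple(pairs.altered[i] for i in order),
        tuple(pairs.labels[i] for i in order),
        pairs.alteration,
    )
    assert mad(pairs) == pytest.approx(mad(permuted), abs=1e-12)
    assert deviation_summary(pairs)[0] == pytest.approx(
        deviation_summary(permuted)[0], abs=1e-12
    )
    try:
        f = flip_fraction(pairs, 0.4)
    except ValueError:
        pass
    else:
        assert f == pytest.approx(flip_fraction(permuted, 0.4), abs=1e-12)


def test_probability_sum_invariant_enforced():
    with pytest.raises(ValueError):
        PredictionRecord(id="a", p_malignant=0.6, p_benign=0.6)


def test_id_mismatch_rejected():
    with pytest.raises(ValueError):
        PairedPredictions(
            (record("a", 0.5),), (record("b", 0.5),), ("benign",), "x"
        )


def test_empty_pairs_error():
    empty = PairedPredictions((), (), (), "x")
    for fn in (mad, deviation_summary):
        with pytest.raises(ValueError):
            fn(empty)


def test_report_round_trips_through_json():
    rng = np.random.default_rng(3)
    pairs = random_pairs(rng, n=12)
    rep = ShortcutReport.from_pairs(pairs)
    back = ShortcutReport.from_json(rep.to_json())
    assert back == rep
    assert back.to_json() == rep.to_json()
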