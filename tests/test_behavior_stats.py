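"""Ethogram summaries, kappa, repeated-measures ANOVA and mixed-model LRTs."""

import numpy as np
import pandas as pd
import pytest

from aviforage.behavior_stats import (
    cohens_kappa,
    lmm_lrt,
    rm_anova,
    rm_anova_within,
    summarize_ethogram,
)
from aviforage.config import BEHAVIORS, BODY_ORIENTED
from aviforage.errors import InputError

CONDITIONS = ("Wall", "Mirror", "Stranger")


def _table_from_sums(sums: dict, n_birds=8, n_sessions=6) -> pd.DataFrame:
    """Distribute per-condition behavior totals over bird x session cells."""
    rows = []
    n_cells = n_birds * n_sessions
    for behavior, by_cond in sums.items():
        for cond, total in by_cond.items():
            base, extra = divmod(int(total), n_cells)
            i = 0
            for b in range(n_birds):
                for s in range(1, n_sessions + 1):
                    rows.append(
                        {
                            "bird_id": f"b{b:02d}",
                            "condition": cond,
                            "session": s,
                            "behavior": behavior,
                            "count": base + (1 if i < extra else 0),
                            "rater": "R1",
                        }
                    )
                    i += 1
    return pd.DataFrame(rows)


def _design(rng, effect=None, n_birds=8, n_sessions=6, base=8.0):
    """Poisson counts over the full design, optional additive condition effects."""
    effect = effect or {}
    rows = []
    for b in range(n_birds):
        bird_level = rng.normal(0, 1)
        for cond in CONDITIONS:
            for s in range(1, n_sessions + 1):
                lam = max(base + effect.get(cond, 0.0) + bird_level, 0.5)
                rows.append(
                    {
                        "bird_id": f"b{b:02d}",
                        "condition": cond,
                        "session": s,
                        "behavior": "preening",
                        "count": rng.poisson(lam),
                        "rater": "R1",
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ethogram summaries
# --------------------------------------------------------------------------


def test_summary_means_are_sum_over_48():
    sums = {
        "shaking": {"Stranger": 228},
        "preening": {"Stranger": 359},
        "head scratching": {"Stranger": 12},
    }
    out = summarize_ethogram(_table_from_sums(sums))
    got = {r["behavior"]: r for _, r in out.iterrows()}
    assert got["shaking"]["sum"] == 228
    assert got["shaking"]["mean"] == pytest.approx(228 / 48)
    assert got["preening"]["mean"] == pytest.approx(359 / 48)
    assert got["head scratching"]["mean"] == pytest.approx(0.25)


def test_all_zero_behavior_summary():
    out = summarize_ethogram(_table_from_sums({"attack": {"Wall": 0}}))
    row = out.iloc[0]
    assert row["sum"] == 0 and row["mean"] == 0 and row["sem"] == 0


# --------------------------------------------------------------------------
# Cohen's kappa
# --------------------------------------------------------------------------


def test_identical_raters_get_kappa_one():
    labels = np.array(["a", "b", "a", "c", "b", "a"])
    assert cohens_kappa(labels, labels) == pytest.approx(1.0)


def test_kappa_hand_computed_contingency():
    """Agreement table [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4."""
    a = np.array(["x"] * 25 + ["y"] * 25)
    b = np.array(["x"] * 20 + ["y"] * 5 + ["x"] * 10 + ["y"] * 15)
    assert cohens_kappa(a, b) == pytest.approx(0.4)


def test_independent_raters_have_near_zero_kappa(rng):
    a = rng.choice(list("abc"), size=10_000)
    b = rng.choice(list("abc"), size=10_000)
    assert abs(cohens_kappa(a, b)) < 0.05


def test_constant_raters_undefined():
    with pytest.warns(UserWarning):
        k = cohens_kappa(np.array(["a"] * 10), np.array(["a"] * 10))
    assert np.isnan(k)


def test_kappa_input_validation():
    with pytest.raises(InputError):
        cohens_kappa(np.array(["a", "b"]), np.array(["a"]))


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------


def test_rm_anova_degrees_of_freedom_match_design(rng):
    """8 subjects x 3 conditions x 6 sessions gives condition df (2, 14)
    and session df (5, 35)."""
    res = rm_anova(_design(rng), behaviors=("preening",))
    assert res.term("condition")["df"] == "(2, 14)"
    assert res.term("session")["df"] == "(5, 35)"
    assert res.term("condition:session")["df"] == "(10, 70)"
    assert 0 <= res.term("condition")["effect_size"] <= 1


def test_identical_conditions_give_null_f(rng):
    df = _design(rng, n_birds=6)
    wall = df[df["condition"] == "Wall"]
    clones = []
    for cond in CONDITIONS:
        c = wall.copy()
        c["condition"] = cond
        clones.append(c)
    res = rm_anova(pd.concat(clones, ignore_index=True), behaviors=("preening",))
    assert res.term("condition")["statistic"] == pytest.approx(0.0, abs=1e-10)
    assert res.term("condition")["p"] > 0.99


def test_unbalanced_design_rejected(rng):
    df = _design(rng).iloc[:-1]
    with pytest.raises(InputError):
        rm_anova(df, behaviors=("preening",))


def test_tukey_detects_configured_stranger_shift():
    """Power >= 0.8 for the Stranger-Mirror contrast at a +4 counts/session
    shift (200 simulated experiments)."""
    hits = 0
    reps = 200
    master = np.random.default_rng(123)
    for _ in range(reps):
        df = _design(master, effect={"Stranger": 4.0})
        res = rm_anova(df, behaviors=("preening",))
        row = res.posthoc.set_index("comparison")
        name = "Stranger-Mirror" if "Stranger-Mirror" in row.index else "Mirror-Stranger"
        hits += row.loc[name, "p_corrected"] < 0.05
    assert hits / reps >= 0.8


def test_within_condition_session_anova_df(rng):
    res = rm_anova_within(_design(rng), "Mirror", behaviors=("preening",))
    assert res.term("session|Mirror")["df"] == "(5, 35)"


# --------------------------------------------------------------------------
# mixed-model LRTs
# --------------------------------------------------------------------------


def _latency_frame(rng, interaction=0.0, n_birds=8, n_sessions=6):
    rows = []
    for b in range(n_birds):
        bird = rng.normal(0, 2)
        for cond in CONDITIONS:
            for s in range(1, n_sessions + 1):
                y = 15 + bird - 1.2 * s + rng.normal(0, 3)
                if cond == "Mirror" and s == 1:
                    y += interaction
                rows.append(
                    {
                        "bird_id": f"b{b:02d}",
                        "condition": cond,
                        "session": s,
                        "latency_s": y,
                        "censored": False,
                    }
                )
    return pd.DataFrame(rows)


def test_lmm_reports_all_terms(rng):
    res = lmm_lrt(_latency_frame(rng), "latency_s")
    assert set(res.terms["term"]) == {"condition", "session", "condition:session"}
    assert ((res.terms["p"] >= 0) & (res.terms["p"] <= 1)).all()
    assert ((res.terms["effect_size"] >= 0) & (res.terms["effect_size"] <= 1)).all()
    assert len(res.posthoc) == 3


def test_lmm_effect_size_invariant_to_outcome_rescaling(rng):
    df = _latency_frame(rng)
    a = lmm_lrt(df, "latency_s")
    df2 = df.assign(latency_s=df["latency_s"] * 37.0)
    b = lmm_lrt(df2, "latency_s")
    assert np.allclose(
        a.terms["effect_size"].to_numpy(), b.terms["effect_size"].to_numpy(), atol=1e-6
    )


def test_lmm_detects_mirror_first_session_elevation():
    """Condition x session interaction power >= 0.8 at a +12 s session-1
    elevation in the Mirror condition (60 simulated experiments)."""
    master = np.random.default_rng(77)
    hits = 0
    reps = 60
    for _ in range(reps):
        df = _latency_frame(master, interaction=12.0)
        res = lmm_lrt(df, "latency_s")
        hits += res.term("condition:session")["p"] < 0.05
    assert hits / reps >= 0.8


def test_censored_sessions_excluded_and_counted(rng):
    df = _latency_frame(rng)
    df.loc[df.index[:5], "censored"] = True
    res = lmm_lrt(df, "latency_s")
    assert res.notes["n_censored"] == 5
    assert res.notes["n"] == len(df) - 5


def test_lmm_requires_two_subjects(rng):
    df = _latency_frame(rng, n_birds=1)
    with pytest.raises(InputError):
        lmm_lrt(df, "latency_s")
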