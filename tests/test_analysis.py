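import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.linalg import null_space

from headingbias import (
    ObserverParams,
    central_tendency_contrast,
    decompose_bias,
    fit_center_bias,
    mean_ph_bias,
    rm_anova,
    serial_dependence,
    simulate_cohort,
    test_slopes_vs_one,
)
from headingbias.analysis import SerialDependenceResult


# ------------------------------------------------------------- center bias


def test_identity_data_gives_unit_slope(identity_table):
    fits = fit_center_bias(identity_table)
    assert len(fits) == 2
    for f in fits:
        assert f.slope == pytest.approx(1.0, abs=1e-12)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)


def test_pure_center_bias_gives_zero_slope(identity_table):
    tab = identity_table.assign(ph_deg=0.0)
    for f in fit_center_bias(tab):
        assert f.slope == pytest.approx(0.0, abs=1e-12)


def test_single_heading_block_rejected(identity_table):
    tab = identity_table.assign(ah_deg=3.0)
    with pytest.raises(ValueError, match="single"):
        fit_center_bias(tab)


def test_residuals_orthogonal_to_heading(exp1_cohort):
    for f in fit_center_bias(exp1_cohort):
        block = exp1_cohort[
            (exp1_cohort["participant"] == f.participant_id)
            & (exp1_cohort["condition"] == f.condition)
        ]
        ah = block["ah_deg"].to_numpy()
        dot = abs(np.dot(f.residuals, ah - ah.mean()))
        scale = np.linalg.norm(f.residuals) * np.linalg.norm(ah - ah.mean())
        assert dot <= 1e-8 * max(scale, 1.0)
        assert abs(f.residuals.mean()) < 1e-10


def test_slope_recovery_from_generator():
    """Mean fitted slope tracks the generative slope under noise."""
    est = []
    for rep in range(10):
        tab = simulate_cohort(
            ["symmetric_wide_uniform"],
            10,
            ObserverParams(slope_s=0.8, noise_sigma=2.0),
            seed=300 + rep,
        )
        est.append(np.mean([f.slope for f in fit_center_bias(tab)]))
    assert np.mean(est) == pytest.approx(0.8, abs=0.02)


# ------------------------------------------------------- slope t-test


def test_unit_slopes_give_null_statistics():
    tab = []
    for pid in range(5):
        ah = np.array([-9.0, -3.0, 3.0, 9.0] * 3)
        tab.append(
            pd.DataFrame(
                {
                    "participant": f"p{pid}",
                    "condition": "c",
                    "trial": np.arange(1, ah.size + 1),
                    "ah_deg": ah,
                    "ph_deg": ah,
                }
            )
        )
    res = test_slopes_vs_one(fit_center_bias(pd.concat(tab)))
    assert res.t == pytest.approx(0.0, abs=1e-9)
    assert res.cohens_d == pytest.approx(0.0, abs=1e-9)


class _Fit:
    def __init__(self, slope):
        self.slope = slope


def test_t_statistic_matches_textbook_formula():
    slopes = [0.7, 0.8, 0.9]
    res = test_slopes_vs_one([_Fit(s) for s in slopes])
    # independent textbook computation
    m, sd, n = np.mean(slopes), np.std(slopes, ddof=1), len(slopes)
    t = (m - 1.0) / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    assert res.t == pytest.approx(t, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)
    assert res.df == n - 1
    assert res.cohens_d == pytest.approx(abs(m - 1) / sd, abs=1e-12)


def test_summary_statistics_reproduce_reported_magnitudes():
    """A slope sample with mean 0.79 and SE 0.031 (n=20) gives t near -6.8
    and Cohen's d near 1.5, the magnitudes typical of center-bias data."""
    n, mean, se = 20, 0.79, 0.031
    pattern = np.arange(n) - (n - 1) / 2
    pattern = pattern / pattern.std(ddof=1)
    slopes = mean + se * np.sqrt(n) * pattern  # exact mean and SD
    res = test_slopes_vs_one([_Fit(s) for s in slopes])
    assert res.mean_slope == pytest.approx(0.79, abs=1e-9)
    assert res.se == pytest.approx(0.031, abs=1e-9)
    assert res.t == pytest.approx(-6.79, abs=0.05)
    assert res.cohens_d == pytest.approx(1.52, abs=0.05)


def test_cohens_d_invariant():
    rng = np.random.default_rng(1)
    for _ in range(20):
        slopes = rng.normal(0.8, 0.1, size=rng.integers(3, 30))
        res = test_slopes_vs_one([_Fit(s) for s in slopes])
        assert res.cohens_d * res.se * np.sqrt(res.n) == pytest.approx(
            abs(res.mean_slope - 1.0), abs=1e-12
        )


def test_too_few_participants_rejected():
    with pytest.raises(ValueError):
        test_slopes_vs_one([_Fit(0.8)])


# ------------------------------------------------------------------- ANOVA


def _table_from_cells(Y):
    """(n_subj, a, b) cell array -> long response table."""
    n, a, b = Y.shape
    rows = []
    for s in range(n):
        for i in range(a):
            for j in range(b):
                rows.append(
                    {
                        "participant": f"s{s}",
                        "condition": f"a{i}",
                        "ah_deg": float(j),
                        "trial": 1,
                        "ph_deg": Y[s, i, j],
                    }
                )
    return pd.DataFrame(rows)


def _rm_anova_oracle(Y):
    """Matrix-algebra two-way repeated-measures ANOVA with GG epsilon."""
    n, a, b = Y.shape
    g = Y.mean()
    mA, mB, mS = Y.mean(axis=(0, 2)), Y.mean(axis=(0, 1)), Y.mean(axis=(1, 2))
    mSA, mSB, mAB = Y.mean(axis=2), Y.mean(axis=1), Y.mean(axis=0)
    SS_A = n * b * np.sum((mA - g) ** 2)
    SS_B = n * a * np.sum((mB - g) ** 2)
    SS_AB = n * np.sum((mAB - mA[:, None] - mB[None, :] + g) ** 2)
    SS_AS = b * np.sum((mSA - mS[:, None] - mA[None, :] + g) ** 2)
    SS_BS = a * np.sum((mSB - mS[:, None] - mB[None, :] + g) ** 2)
    SS_ABS = np.sum(
        (
            Y
            - mSA[:, :, None]
            - mSB[:, None, :]
            - mAB[None]
            + mS[:, None, None]
            + mA[None, :, None]
            + mB[None, None, :]
            - g
        )
        ** 2
    )

    def eps(C, X):
        E = C @ np.cov(X, rowvar=False) @ C.T
        return np.trace(E) ** 2 / (C.shape[0] * np.sum(E * E))

    CA = null_space(np.ones((1, a))).T
    CB = null_space(np.ones((1, b))).T
    out = {}
    for name, ss, df1, sse, df2, e in (
        ("A", SS_A, a - 1, SS_AS, (a - 1) * (n - 1), eps(CA, mSA)),
        ("B", SS_B, b - 1, SS_BS, (b - 1) * (n - 1), eps(CB, mSB)),
        (
            "AB",
            SS_AB,
            (a - 1) * (b - 1),
            SS_ABS,
            (a - 1) * (b - 1) * (n - 1),
            eps(np.kron(CA, CB), Y.reshape(n, a * b)),
        ),
    ):
        out[name] = {
            "F": (ss / df1) / (sse / df2),
            "df1": df1,
            "df2": df2,
            "eps": e,
            "np2": ss / (ss + sse),
        }
    return out


def test_two_way_rm_anova_matches_matrix_oracle():
    """4-subject 2x3 integer fixture: F, df, GG epsilon and partial eta
    squared agree with a from-scratch matrix-algebra computation."""
    rng = np.random.default_rng(5)
    Y = rng.integers(0, 20, size=(4, 2, 3)).astype(float)
    oracle = _rm_anova_oracle(Y)
    res = rm_anova(_table_from_cells(Y), within=["condition", "ah_deg"])
    mapping = {"condition": "A", "ah_deg": "B", "condition:ah_deg": "AB"}
    for effect_name, key in mapping.items():
        e = res[effect_name]
        o = oracle[key]
        assert e.F == pytest.approx(o["F"], abs=1e-8)
        assert e.eta_sq == pytest.approx(o["np2"], abs=1e-8)
        if o["df1"] > 1:  # GG applied only to >2-level within effects
            assert e.gg_epsilon == pytest.approx(o["eps"], abs=1e-8)
            assert e.df1 == pytest.approx(o["df1"] * o["eps"], abs=1e-8)
            assert e.df2 == pytest.approx(o["df2"] * o["eps"], abs=1e-8)
        else:
            assert e.gg_epsilon is None
            assert (e.df1, e.df2) == (o["df1"], o["df2"])


def test_identical_cell_means_give_zero_condition_effect():
    rng = np.random.default_rng(2)
    base = rng.normal(size=(6, 1, 4))
    Y = np.concatenate([base, base], axis=1)  # both conditions identical
    res = rm_anova(_table_from_cells(Y), within=["condition", "ah_deg"])
    assert res["condition"].F == pytest.approx(0.0, abs=1e-9)


def test_compound_symmetry_gives_epsilon_one():
    """Exchangeable covariance across levels satisfies sphericity."""
    rng = np.random.default_rng(3)
    n, k = 2000, 4
    subj = rng.normal(size=(n, 1))  # shared component -> compound symmetry
    Y = (subj + rng.normal(size=(n, k)))[:, None, :]
    Y = np.concatenate([Y, subj[:, :, None] + rng.normal(size=(n, 1, k))], axis=1)
    res = rm_anova(_table_from_cells(Y), within=["condition", "ah_deg"])
    assert res["ah_deg"].gg_epsilon == pytest.approx(1.0, abs=0.02)


def test_epsilon_bounds_on_random_covariances():
    """1/(k-1) <= GG epsilon <= 1 for arbitrary within-subject data."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        k = int(rng.integers(3, 6))
        n = int(rng.integers(k + 2, 15))
        A = rng.normal(size=(k, k))
        L = np.linalg.cholesky(A @ A.T + k * np.eye(k))
        Y = (rng.normal(size=(n, k)) @ L.T)[:, None, :]
        Y = np.concatenate([Y, Y + rng.normal(size=(n, 1, k))], axis=1)
        res = rm_anova(_table_from_cells(Y), within=["condition", "ah_deg"])
        eps = res["ah_deg"].gg_epsilon
        assert 1 / (k - 1) - 1e-9 <= eps <= 1 + 1e-9


def test_missing_cells_listed():
    tab = _table_from_cells(np.zeros((3, 2, 3)))
    tab = tab[~((tab["participant"] == "s1") & (tab["ah_deg"] == 2.0))]
    with pytest.raises(ValueError, match="missing cells"):
        rm_anova(tab, within=["condition", "ah_deg"])


def test_mixed_anova_runs_with_between_factor():
    rng = np.random.default_rng(6)
    Y = rng.normal(size=(12, 1, 3))
    tab = _table_from_cells(Y)
    tab["group"] = np.where(tab["participant"].isin([f"s{i}" for i in range(6)]), "g1", "g2")
    res = rm_anova(tab, within="ah_deg", between="group")
    names = [e.name for e in res.effects]
    assert "group" in names and "ah_deg" in names and "group:ah_deg" in names
    assert res["ah_deg"].gg_epsilon is not None


# ------------------------------------------- central-tendency contrast


def test_contrast_of_table_with_itself_is_zero(identity_table):
    diffs, aov = central_tendency_contrast(
        identity_table, identity_table, [-9.0, -3.0, 3.0, 9.0]
    )
    assert np.allclose(diffs.to_numpy(), 0.0)
    assert aov["distribution"].F == pytest.approx(0.0, abs=1e-9)


def test_central_tendency_signature_detected():
    """ct_weight > 0 toward the 18-deg mean lifts responses at shared
    headings below 18 relative to the symmetric design."""
    pull = ObserverParams(slope_s=0.8, ct_weight=0.3)
    sym = simulate_cohort(["symmetric_wide_uniform"], 4, pull, seed=0)
    shf = simulate_cohort(["right_shifted_narrow_uniform"], 4, pull, seed=0)
    diffs, aov = central_tendency_contrast(sym, shf, [3.0, 9.0, 15.0])
    assert (diffs > 0).all()
    assert aov["distribution"].p < 0.01


def test_empty_shared_set_rejected(identity_table):
    with pytest.raises(ValueError):
        central_tendency_contrast(identity_table, identity_table, [])
    with pytest.raises(ValueError, match="lacks"):
        central_tendency_contrast(identity_table, identity_table, [45.0])


# -------------------------------------------------------- serial dependence


def test_serial_dependence_sign_convention_and_recovery():
    """A repulsive generator (sd_coef < 0) yields a negative s' close to
    the generative coefficient."""
    tab = simulate_cohort(
        ["right_heavied_nonuniform"],
        10,
        ObserverParams(slope_s=0.8, noise_sigma=3.0, sd_coef=-0.01),
        seed=11,
    )
    res = serial_dependence(tab, "right_heavied_nonuniform", n_boot=500, seed=0)
    assert res.sd_slope < 0
    assert res.sd_slope == pytest.approx(-0.01, abs=0.004)
    assert res.ci95[0] <= res.sd_slope <= res.ci95[1]
    # first trial of each block excluded
    assert res.rh.size == 10 * 599


def test_serial_dependence_null_ci_coverage():
    """Without a generative serial effect the bootstrap CI covers zero at
    roughly its nominal rate (allowing the occasional type-I miss)."""
    covered = 0
    for rep in range(12):
        tab = simulate_cohort(
            ["symmetric_uniform_exp3"],
            10,
            ObserverParams(slope_s=0.8, noise_sigma=3.0),
            seed=500 + rep,
        )
        res = serial_dependence(tab, "symmetric_uniform_exp3", n_boot=1000, seed=0)
        covered += res.ci95[0] < 0 < res.ci95[1]
    assert covered >= 9


def test_serial_dependence_unknown_condition(identity_table):
    with pytest.raises(ValueError, match="absent"):
        serial_dependence(identity_table, "nope")


# ------------------------------------------------------------ decomposition


def _sd_result(cond, slope, rh):
    return SerialDependenceResult(
        condition=cond,
        rh=np.asarray(rh, dtype=float),
        rhe=np.zeros(len(rh)),
        sd_slope=slope,
        ci95=(slope, slope),
    )


def test_decomposition_reproduces_reported_arithmetic():
    """An induced difference of -0.031 deg against a total bias difference
    of -1.98 deg is a 1.57% share."""
    res = decompose_bias(
        {
            "uniform": _sd_result("uniform", 0.0, [1.0]),
            "nonuniform": _sd_result("nonuniform", -0.031, [1.0]),
        },
        None,
        total_bias_difference=-1.98,
        conditions=("uniform", "nonuniform"),
    )
    assert res.sd_induced_difference == pytest.approx(-0.031, abs=1e-12)
    assert round(res.fraction_pct, 2) == 1.57


def test_zero_slopes_give_zero_fraction():
    res = decompose_bias(
        {
            "u": _sd_result("u", 0.0, [3.0, -1.0]),
            "n": _sd_result("n", 0.0, [2.0, 5.0]),
        },
        None,
        total_bias_difference=-2.0,
    )
    assert res.fraction_pct == 0.0


def test_zero_total_bias_rejected():
    with pytest.raises(ValueError, match="undefined"):
        decompose_bias(
            {"u": _sd_result("u", 0.0, [1.0]), "n": _sd_result("n", 0.1, [1.0])},
            None,
            total_bias_difference=0.0,
        )


def test_symmetric_schedules_have_negligible_mean_rh():
    """On shuffled symmetric schedules mean RH is ~0, so any s' induces
    almost no net bias."""
    means = []
    for seed in range(30):
        tab = simulate_cohort(
            ["symmetric_uniform_exp3"], 1, ObserverParams(), seed=seed
        )
        ah = tab.sort_values("trial")["ah_deg"].to_numpy()
        means.append(np.mean(ah[:-1] - ah[1:]))
    assert abs(np.mean(means)) < 0.2


def test_decomposition_fraction_scale_invariant():
    """Scaling all PH by a constant rescales both the induced and the total
    difference, leaving the percentage unchanged."""
    params = {
        "symmetric_uniform_exp3": ObserverParams(slope_s=0.8, noise_sigma=2.0),
        "right_heavied_nonuniform": ObserverParams(
            slope_s=0.8, noise_sigma=2.0, shift_delta=-2.0, sd_coef=-0.01
        ),
    }
    tab = simulate_cohort(list(params), 4, params, seed=13)
    conds = ("symmetric_uniform_exp3", "right_heavied_nonuniform")

    def fraction(t):
        sd = {c: serial_dependence(t, c, n_boot=10, seed=0) for c in conds}
        biases = {c: mean_ph_bias(t, c, n_boot=10, seed=0).value for c in conds}
        total = biases[conds[1]] - biases[conds[0]]
        return decompose_bias(sd, None, total, conditions=conds).fraction_pct

    scaled = tab.assign(ph_deg=tab["ph_deg"] * 3.0)
    assert fraction(scaled) == pytest.approx(fraction(tab), rel=1e-9)


# ---------------------------------------------------------------- mean bias


def test_identity_symmetric_bias_is_zero(identity_table):
    res = mean_ph_bias(identity_table, "sym", n_boot=200, seed=0)
    assert res.value == pytest.approx(0.0, abs=1e-12)


def test_constant_shift_recovered():
    tab = simulate_cohort(
        ["right_heavied_nonuniform"],
        8,
        ObserverParams(slope_s=0.8, noise_sigma=2.0, shift_delta=-2.0),
        seed=14,
    )
    res = mean_ph_bias(tab, "right_heavied_nonuniform", n_boot=2000, seed=0)
    assert res.value == pytest.approx(-2.0, abs=0.5)
    assert res.ci95[0] <= res.value <= res.ci95[1]


def test_mean_bias_unknown_condition(identity_table):
    with pytest.raises(ValueError, match="absent"):
        mean_ph_bias(identity_table, "nope")
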