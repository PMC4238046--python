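"""The Z-ratio differential engine against brute-force oracles and its contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from transwitch import diffxl
from transwitch.errors import ConfigurationError, NumericalError
from transwitch.expression_io import SampleContrast

from conftest import TOY_MATRIX, TOY_SAMPLES, make_study

TEST_SAMPLES = TOY_SAMPLES[3:]
REF_SAMPLES = TOY_SAMPLES[:3]


# -- detection filter ---------------------------------------------------------


@pytest.mark.parametrize(
    "p_all, expected",
    [(0.001, 5), (0.5, 0)],
    ids=["all-detected", "none-detected"],
)
def test_detection_filter_extremes(p_all, expected, toy_contrast):
    study = make_study(TOY_MATRIX, detection=np.full(TOY_MATRIX.shape, p_all))
    with pytest.warns(UserWarning) if expected == 0 else _no_warning():
        retained = diffxl.detection_filter(study, toy_contrast)
    assert len(retained) == expected


def _no_warning():
    import contextlib

    return contextlib.nullcontext()


def test_detection_majority_rule_single_group(toy_contrast):
    # gene g1 detected in 2/3 test samples only: ceil(3/2)=2 -> retained
    det = np.full(TOY_MATRIX.shape, 0.9)
    det[0, 3] = det[0, 4] = 0.001
    study = make_study(TOY_MATRIX, detection=det)
    retained = diffxl.detection_filter(study, toy_contrast)
    assert list(retained) == ["g1"]
    # the stricter "all" rule drops it, "any" keeps it
    assert len(diffxl.detection_filter(study, toy_contrast, rule="all")) == 0
    det[0, 5] = 0.001
    study = make_study(TOY_MATRIX, detection=det)
    assert list(diffxl.detection_filter(study, toy_contrast, rule="all")) == ["g1"]


# -- Z-scoring ----------------------------------------------------------------


def test_zscore_three_point_column():
    df = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
    z = diffxl.zscore_normalize(df)["s"].to_numpy()
    assert z == pytest.approx([-1.224744871, 0.0, 1.224744871], abs=1e-9)


def test_zscore_columns_standardized(toy_study):
    z = diffxl.zscore_normalize(toy_study.log_intensity)
    assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)


def test_zscore_constant_column_names_sample():
    df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(NumericalError, match="flat"):
        diffxl.zscore_normalize(df)


@settings(max_examples=25, deadline=None)
@given(
    a=st.floats(min_value=0.1, max_value=50),
    b=st.floats(min_value=-100, max_value=100),
)
def test_zscore_affine_invariance(a, b):
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("xyz"))
    scaled = df.copy()
    scaled["y"] = a * scaled["y"] + b
    z1 = diffxl.zscore_normalize(df)
    z2 = diffxl.zscore_normalize(scaled)
    np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


# -- Z-ratio ------------------------------------------------------------------


def test_z_ratio_matches_brute_force_oracle(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    got = diffxl.z_ratio(zmat, TEST_SAMPLES, REF_SAMPLES)
    expected = oracles.z_ratios(TOY_MATRIX.tolist(), [3, 4, 5], [0, 1, 2])
    np.testing.assert_allclose(got.to_numpy(), expected, atol=1e-12)


def test_z_ratio_antisymmetric_under_reversal(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    fwd = diffxl.z_ratio(zmat, TEST_SAMPLES, REF_SAMPLES)
    rev = diffxl.z_ratio(zmat, REF_SAMPLES, TEST_SAMPLES)
    np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)


def test_z_ratio_identical_groups_guarded():
    m = np.hstack([TOY_MATRIX[:, :3], TOY_MATRIX[:, :3]])
    study = make_study(m)
    zmat = diffxl.zscore_normalize(study.log_intensity)
    with pytest.warns(UserWarning, match="identical"):
        zr = diffxl.z_ratio(zmat, TOY_SAMPLES[3:], TOY_SAMPLES[:3])
    assert (zr == 0).all()


def test_z_ratio_requires_two_replicates(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    with pytest.raises(NumericalError):
        diffxl.z_ratio(zmat, TEST_SAMPLES[:1], REF_SAMPLES)


# -- per-gene p-values --------------------------------------------------------


def test_gene_pvalues_match_textbook_t(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    got = diffxl.gene_pvalues(zmat, TEST_SAMPLES, REF_SAMPLES)
    for gene in zmat.index:
        a = zmat.loc[gene, TEST_SAMPLES].tolist()
        b = zmat.loc[gene, REF_SAMPLES].tolist()
        assert got[gene] == pytest.approx(oracles.t_test_pvalue(a, b), abs=1e-12)


def test_gene_pvalues_degenerate_and_separated():
    m = np.array(
        [
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # identical groups -> p = 1
            [0.0, 0.001, -0.001, 1.0, 1.001, 0.999],  # separated -> p ~ 0
            [2.0, 2.5, 1.5, 2.0, 2.5, 1.5],
        ]
    )
    # bypass z-scoring (a constant row is fine for the t-test itself)
    df = pd.DataFrame(m, index=["flat", "sep", "same"], columns=TOY_SAMPLES)
    p = diffxl.gene_pvalues(df, TEST_SAMPLES, REF_SAMPLES)
    assert p["flat"] == 1.0
    assert p["sep"] < 1e-6
    assert p["same"] == 1.0


# -- variance exclusion -------------------------------------------------------


def test_variance_exclusion_flags_outlier_gene():
    rng = np.random.default_rng(3)
    m = 2.0 + rng.normal(0, 0.05, size=(100, 6))
    m[7] = 2.0 + rng.normal(0, 0.5, size=6)  # 10x within-group SD
    study = make_study(m)
    zmat = diffxl.zscore_normalize(study.log_intensity)
    excluded = diffxl.variance_exclusion(zmat, TEST_SAMPLES, REF_SAMPLES)
    assert "g8" in excluded
    # ~5% excluded at the default 95th-percentile quantile
    assert 1 <= len(excluded) <= 10


def test_variance_exclusion_disabled_at_full_quantile(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    excluded = diffxl.variance_exclusion(
        zmat, TEST_SAMPLES, REF_SAMPLES, threshold=1.0
    )
    assert len(excluded) == 0


def test_variance_exclusion_unknown_method(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    with pytest.raises(ConfigurationError):
        diffxl.variance_exclusion(zmat, TEST_SAMPLES, REF_SAMPLES, method="magic")


def test_variance_exclusion_anova_mode(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    rep = toy_study.sample_meta["replicate"]
    excluded = diffxl.variance_exclusion(
        zmat, TEST_SAMPLES, REF_SAMPLES, method="anova", threshold=0.05,
        replicate_index=rep,
    )
    assert set(excluded) <= set(zmat.index)


# -- empirical FDR ------------------------------------------------------------


def test_fdr_monotone_in_abs_zratio(toy_study):
    zmat = diffxl.zscore_normalize(toy_study.log_intensity)
    zr = diffxl.z_ratio(zmat, TEST_SAMPLES, REF_SAMPLES)
    fdr = diffxl.empirical_fdr(zmat, TEST_SAMPLES, REF_SAMPLES, zr, seed=0)
    df = pd.DataFrame({"absz": zr.abs(), "fdr": fdr}).sort_values("absz")
    assert (df["fdr"].diff().dropna() <= 1e-12).all()
    assert fdr[zr.abs().idxmax()] == fdr.min()


def test_fdr_strong_planted_effects_are_confident():
    from transwitch import synthdata

    cfg = synthdata.GenConfig(n_genes=2000, effect_size=4, seed=5)
    study, truth = synthdata.gen_expression(cfg)
    tl, _ = synthdata.default_contrasts(cfg)
    res = diffxl.run_contrast(study, tl, seed=5)
    planted = truth.index[truth["class"] == "tl_only"]
    assert res.table.loc[planted, "fdr"].median() < 0.05


# -- significance calling -----------------------------------------------------


@pytest.mark.parametrize(
    "z, fdr, p, expect_sig, expect_dir",
    [
        (1.6, 0.2, 0.01, True, "up"),
        (1.6, 0.2, 0.2, False, "none"),
        (-1.5, 0.3, 0.049, True, "down"),  # inclusive z and fdr boundaries
        (-1.5, 0.3, 0.05, False, "none"),  # p gate is strict
        (1.49, 0.01, 0.001, False, "none"),
    ],
)
def test_call_significant_gates(z, fdr, p, expect_sig, expect_dir):
    table = pd.DataFrame(
        {
            "z_ratio": [z],
            "fdr": [fdr],
            "p_value": [p],
            "excluded_by_detection": [False],
            "excluded_by_variance": [False],
        },
        index=["g"],
    )
    out = diffxl.call_significant(table, diffxl.DiffParams())
    assert bool(out.loc["g", "significant"]) is expect_sig
    assert out.loc["g", "direction"] == expect_dir


def test_excluded_gene_never_significant():
    table = pd.DataFrame(
        {
            "z_ratio": [5.0, 5.0],
            "fdr": [0.0, 0.0],
            "p_value": [0.001, 0.001],
            "excluded_by_detection": [True, False],
            "excluded_by_variance": [False, True],
        },
        index=["a", "b"],
    )
    out = diffxl.call_significant(table, diffxl.DiffParams())
    assert not out["significant"].any()


# -- full contrast ------------------------------------------------------------


def test_run_contrast_full_oracle_equivalence(toy_study, toy_contrast):
    res = diffxl.run_contrast(toy_study, toy_contrast, seed=0)
    expected_zr = oracles.z_ratios(TOY_MATRIX.tolist(), [3, 4, 5], [0, 1, 2])
    np.testing.assert_allclose(
        res.table["z_ratio"].to_numpy(dtype=float), expected_zr, atol=1e-12
    )
    z = oracles.zscore_columns(TOY_MATRIX.tolist())
    for i, gene in enumerate(res.table.index):
        expected_p = oracles.t_test_pvalue(
            [z[i][j] for j in (3, 4, 5)], [z[i][j] for j in (0, 1, 2)]
        )
        assert res.table.loc[gene, "p_value"] == pytest.approx(expected_p, abs=1e-12)


def test_run_contrast_reversal_negates_z_ratios(toy_study, toy_contrast):
    fwd = diffxl.run_contrast(toy_study, toy_contrast, seed=0)
    rev = diffxl.run_contrast(toy_study, toy_contrast.reversed(), seed=0)
    np.testing.assert_allclose(
        fwd.table["z_ratio"].to_numpy(dtype=float),
        -rev.table["z_ratio"].to_numpy(dtype=float),
        atol=1e-12,
    )


def test_run_contrast_empty_after_detection(toy_contrast):
    study = make_study(TOY_MATRIX, detection=np.full(TOY_MATRIX.shape, 0.5))
    with pytest.warns(UserWarning, match="no genes"):
        res = diffxl.run_contrast(study, toy_contrast, seed=0)
    assert res.table["excluded_by_detection"].all()
    assert not res.table["significant"].any()


def test_diffparams_validation():
    with pytest.raises(ConfigurationError):
        diffxl.DiffParams(zratio_min=0)
    with pytest.raises(ConfigurationError):
        diffxl.DiffParams(detection_rule="most")
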