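"""Z-ratio differential expression for translatome/transcriptome contrasts.

The engine follows the classic microarray Z-ratio recipe: observations are
filtered by detection p-value, each array (column) is Z-score normalized
across the retained genes, and the per-gene effect statistic is the Z-ratio

    z_ratio(g) = (mean Z_test(g) - mean Z_ref(g)) / SD_genes(mean Z diff)

i.e. the difference of group-mean Z-scores scaled by the population SD of
those differences across all retained genes, so the statistic is
self-normalizing with respect to the overall spread of effects.

Significance calling combines three gates, each configurable:
|z_ratio| >= 1.5, an equal-variance two-tailed t-test p < 0.05 on the
per-sample Z-scores, and a label-permutation empirical FDR <= 0.3 with
q-value-style monotone smoothing. Genes with excessive within-group
variance can additionally be excluded (quantile rule or one-way ANOVA
across replicate batches).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, NumericalError
from .expression_io import ExpressionStudy, SampleContrast

DetectionRule = Literal["half", "all", "any"]

RESULT_COLUMNS = [
    "mean_z_test",
    "mean_z_ref",
    "z_ratio",
    "p_value",
    "fdr",
    "excluded_by_detection",
    "excluded_by_variance",
    "significant",
    "direction",
]


@dataclass(frozen=True)
class DiffParams:
    """Thresholds and method switches for one differential contrast.

    Defaults mirror the standard Z-ratio workflow: detection p <= 0.02,
    |Z-ratio| >= 1.5, permutation FDR <= 0.3, t-test p < 0.05.
    """

    detection_p_max: float = 0.02
    zratio_min: float = 1.5
    fdr_max: float = 0.3
    p_max: float = 0.05
    detection_rule: DetectionRule = "half"
    variance_method: Literal["within_group_sd", "anova", "none"] = "within_group_sd"
    variance_threshold: float = 0.95  # quantile for SD rule, p cut for ANOVA
    equal_var: bool = True  # Welch's t when False
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        if self.zratio_min <= 0:
            raise ConfigurationError("zratio_min must be positive")
        for name in ("detection_p_max", "fdr_max", "p_max", "variance_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.detection_rule not in ("half", "all", "any"):
            raise ConfigurationError(f"unknown detection_rule {self.detection_rule!r}")
        if self.variance_method not in ("within_group_sd", "anova", "none"):
            raise ConfigurationError(f"unknown variance_method {self.variance_method!r}")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")


@dataclass
class DiffResult:
    """Per-gene differential result for one contrast plus run metadata."""

    table: pd.DataFrame  # indexed by gene; columns RESULT_COLUMNS
    contrast: SampleContrast
    params: DiffParams
    metadata: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene")


def read_result_tsv(path) -> pd.DataFrame:
    """Read back a DiffResult table written by :meth:`DiffResult.to_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    for col in ("excluded_by_detection", "excluded_by_variance", "significant"):
        df[col] = df[col].astype(bool)
    return df


# -- pipeline stages ----------------------------------------------------------


def detection_filter(
    study: ExpressionStudy,
    contrast: SampleContrast,
    p_max: float = 0.02,
    rule: DetectionRule = "half",
) -> pd.Index:
    """Genes passing the detection gate within the contrast's samples.

    Under the default ``half`` rule a gene is retained iff its detection
    p-value is <= ``p_max`` in at least ceil(n/2) samples of at least one of
    the two groups; ``all`` and ``any`` tighten / loosen that to every or a
    single sample of a group.
    """
    test, ref = study.contrast_samples(contrast)
    detected = study.detection_p[test + ref] <= p_max
    keep = np.zeros(len(study.genes), dtype=bool)
    for arm in (test, ref):
        n = len(arm)
        need = {"half": -(-n // 2), "all": n, "any": 1}[rule]
        keep |= (detected[arm].sum(axis=1) >= need).to_numpy()
    retained = study.genes[keep]
    if len(retained) == 0:
        warnings.warn("detection filter retained no genes; downstream result is empty")
    return retained


def zscore_normalize(log_intensity: pd.DataFrame) -> pd.DataFrame:
    """Per-column Z-scores over the supplied (already filtered) genes.

    Uses the population SD; a constant column is an error because it makes
    the transform undefined.
    """
    x = log_intensity.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise NumericalError(
            f"zero intensity SD in sample {log_intensity.columns[zero[0]]!r}"
        )
    return pd.DataFrame(
        (x - mu) / sd, index=log_intensity.index, columns=log_intensity.columns
    )


def _mean_diff(z: np.ndarray, test_idx: np.ndarray, ref_idx: np.ndarray) -> np.ndarray:
    return z[:, test_idx].mean(axis=1) - z[:, ref_idx].mean(axis=1)


def _scale_diffs(diffs: np.ndarray) -> np.ndarray:
    """Z-ratios from raw mean Z differences; guarded when all diffs agree."""
    sd = diffs.std()  # population SD across genes
    if sd == 0:
        warnings.warn("all per-gene Z differences identical; z_ratios set to 0")
        return np.zeros_like(diffs)
    return diffs / sd


def z_ratio(
    zmat: pd.DataFrame, test_samples: list[str], ref_samples: list[str]
) -> pd.Series:
    """Per-gene Z-ratio for one contrast over the retained genes in ``zmat``."""
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise NumericalError("z_ratio requires >= 2 replicates per group")
    z = zmat.to_numpy(dtype=float)
    t_idx = np.array([zmat.columns.get_loc(s) for s in test_samples])
    r_idx = np.array([zmat.columns.get_loc(s) for s in ref_samples])
    return pd.Series(_scale_diffs(_mean_diff(z, t_idx, r_idx)), index=zmat.index)


def gene_pvalues(
    zmat: pd.DataFrame,
    test_samples: list[str],
    ref_samples: list[str],
    equal_var: bool = True,
) -> pd.Series:
    """Two-sample two-tailed t-test per gene on per-sample Z-scores.

    Genes with zero pooled variance get p = 1 (no evidence of difference).
    """
    if len(test_samples) < 2 or len(ref_samples) < 2:
        raise NumericalError("gene_pvalues requires >= 2 replicates per group")
    a = zmat[test_samples].to_numpy(dtype=float)
    b = zmat[ref_samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p[degenerate & (a.mean(axis=1) == b.mean(axis=1))] = 1.0
    p[degenerate & (a.mean(axis=1) != b.mean(axis=1))] = 0.0
    p[np.isnan(p)] = 1.0
    return pd.Series(p, index=zmat.index)


def variance_exclusion(
    zmat: pd.DataFrame,
    test_samples: list[str],
    ref_samples: list[str],
    method: str = "within_group_sd",
    threshold: float = 0.95,
    replicate_index: pd.Series | None = None,
) -> pd.Index:
    """Genes flagged as having excessive variance.

    ``within_group_sd`` (default): a gene is excluded when its pooled
    within-group SD of Z-scores exceeds the ``threshold`` quantile of all
    genes (strictly above, so quantile 1.0 disables the rule).

    ``anova``: one-way ANOVA of Z-scores across replicate batches; genes
    with p < ``threshold`` are excluded. Requires ``replicate_index``
    mapping sample id -> batch label.
    """
    if method == "none":
        return pd.Index([], dtype=zmat.index.dtype)
    if method == "within_group_sd":
        a = zmat[test_samples].to_numpy(dtype=float)
        b = zmat[ref_samples].to_numpy(dtype=float)
        pooled = np.sqrt((a.var(axis=1) + b.var(axis=1)) / 2.0)
        cut = np.quantile(pooled, threshold)
        return zmat.index[pooled > cut]
    if method == "anova":
        if replicate_index is None:
            raise ConfigurationError("anova variance exclusion needs replicate_index")
        samples = test_samples + ref_samples
        batches: dict = {}
        for s in samples:
            batches.setdefault(replicate_index[s], []).append(s)
        groups = [zmat[cols].to_numpy(dtype=float) for cols in batches.values()]
        if len(groups) < 2:
            return pd.Index([], dtype=zmat.index.dtype)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.f_oneway(*groups, axis=1)
        p = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
        return zmat.index[p < threshold]
    raise ConfigurationError(f"unknown variance exclusion method {method!r}")


def _enumerate_splits(n_test: int, n_ref: int, n_permutations: int, rng: np.random.Generator):
    """Index splits of range(n_test+n_ref) into (test, ref) label assignments.

    The observed assignment (first n_test indices = test) is never part of
    the null: including it would put every gene's own statistic into its
    null pool. Complementary splits are collapsed for balanced designs since
    only |z_ratio| enters the FDR. All remaining distinct splits are used
    when there are no more than requested (e.g. 9 informative splits for a
    3v3 design); otherwise random reassignments are sampled.
    """
    n = n_test + n_ref
    observed = frozenset(range(n_test))
    balanced = n_test == n_ref

    def is_observed(c: frozenset) -> bool:
        return c == observed or (balanced and c == frozenset(range(n_test, n)))

    total = comb(n, n_test)
    if balanced:
        total //= 2
    total -= 1  # the observed assignment
    if total < 1:
        raise NumericalError("no non-trivial label splits available for permutation FDR")
    if total <= n_permutations:
        if total < n_permutations:
            warnings.warn(
                f"only {total} distinct label splits available; using all of them"
            )
        splits = []
        for c in combinations(range(n), n_test):
            cs = frozenset(c)
            if balanced and 0 not in cs:
                continue  # complement already enumerated
            if is_observed(cs):
                continue
            t = np.array(sorted(cs))
            r = np.array(sorted(set(range(n)) - cs))
            splits.append((t, r))
        return splits
    splits = []
    while len(splits) < n_permutations:
        perm = rng.permutation(n)
        if is_observed(frozenset(perm[:n_test].tolist())):
            continue
        splits.append((perm[:n_test], perm[n_test:]))
    return splits


def empirical_fdr(
    zmat: pd.DataFrame,
    test_samples: list[str],
    ref_samples: list[str],
    z_ratios: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Label-permutation tail-area FDR per gene, monotone in |z_ratio|.

    For each gene's threshold t = |z_ratio|, the raw estimate is
    (mean permutation count of null |z*| >= t) / (observed count >= t);
    the reported value is the q-value-style running minimum over
    thresholds <= t, so a larger |z_ratio| never gets a larger FDR.

    Permuted mean-Z differences are scaled by the *observed* cross-gene SD
    of differences, not each permutation's own: the observed denominator is
    what shrinks the real z_ratios, and re-standardizing every permutation
    would inflate the null tail (hence the FDR) whenever a substantial
    share of genes is genuinely regulated. On null data the two scalings
    coincide in distribution.
    """
    rng = np.random.default_rng(seed)
    sub = zmat[test_samples + ref_samples].to_numpy(dtype=float)
    nt, nr = len(test_samples), len(ref_samples)
    splits = _enumerate_splits(nt, nr, n_permutations, rng)
    n_perm = len(splits)

    obs_idx_t = np.arange(nt)
    obs_idx_r = np.arange(nt, nt + nr)
    obs_sd = _mean_diff(sub, obs_idx_t, obs_idx_r).std()
    if obs_sd == 0:
        return pd.Series(np.ones(len(z_ratios)), index=z_ratios.index)
    null_abs = np.concatenate(
        [np.abs(_mean_diff(sub, t, r) / obs_sd) for t, r in splits]
    )
    null_abs.sort()

    obs_abs = np.abs(z_ratios.to_numpy(dtype=float))
    order = np.argsort(obs_abs)  # ascending |z|
    sorted_abs = obs_abs[order]
    g = len(obs_abs)
    # counts >= t via searchsorted on sorted arrays
    obs_ge = g - np.searchsorted(sorted_abs, sorted_abs, side="left")
    null_ge = (null_abs.size - np.searchsorted(null_abs, sorted_abs, side="left")) / n_perm
    raw = np.minimum(1.0, null_ge / np.maximum(obs_ge, 1))
    # running minimum along ascending |z|: each gene receives the best
    # (smallest) FDR achievable at any threshold it passes
    smoothed = np.minimum.accumulate(raw)
    fdr = np.empty(g)
    fdr[order] = smoothed
    return pd.Series(fdr, index=z_ratios.index)


def call_significant(table: pd.DataFrame, params: DiffParams) -> pd.DataFrame:
    """Apply the three significance gates and assign a direction.

    Gates: |z_ratio| >= zratio_min (boundary inclusive), fdr <= fdr_max,
    p_value < p_max, and the gene is not excluded by detection or variance.
    """
    t = table.copy()
    ok = (
        (t["z_ratio"].abs() >= params.zratio_min)
        & (t["fdr"] <= params.fdr_max)
        & (t["p_value"] < params.p_max)
        & ~t["excluded_by_detection"]
        & ~t["excluded_by_variance"]
    )
    t["significant"] = ok.fillna(False)
    direction = np.where(t["z_ratio"] > 0, "up", "down")
    t["direction"] = np.where(t["significant"], direction, "none")
    return t


def run_contrast(
    study: ExpressionStudy,
    contrast: SampleContrast,
    params: DiffParams | None = None,
    seed: int = 0,
) -> DiffResult:
    """Full differential pipeline for one contrast.

    Stages: detection filter -> per-array Z-scores over retained genes ->
    Z-ratio -> t-test p -> variance exclusion -> permutation FDR ->
    significance call. Genes failing detection appear in the output with
    ``excluded_by_detection`` set and NaN statistics.
    """
    params = params or DiffParams()
    test, ref = study.contrast_samples(contrast)
    retained = detection_filter(study, contrast, params.detection_p_max, params.detection_rule)

    table = pd.DataFrame(index=study.genes, columns=RESULT_COLUMNS)
    table["excluded_by_detection"] = ~study.genes.isin(retained)
    table["excluded_by_variance"] = False
    table["significant"] = False
    table["direction"] = "none"

    meta = {
        "contrast": str(contrast),
        "n_test": len(test),
        "n_ref": len(ref),
        "n_genes": len(study.genes),
        "n_retained": len(retained),
        "seed": seed,
        "fdr_method": "label-permutation tail-area FDR, monotone smoothed",
        "zscore_sd": "population",
        "log_base": 10,
        "t_test": "equal-variance" if params.equal_var else "welch",
        "detection_rule": params.detection_rule,
        "variance_method": params.variance_method,
        "boundary": "|z_ratio| >= zratio_min, fdr <= fdr_max, p < p_max",
    }

    if len(retained) == 0:
        table[["mean_z_test", "mean_z_ref", "z_ratio", "p_value", "fdr"]] = np.nan
        return DiffResult(table, contrast, params, meta)

    zmat = zscore_normalize(study.log_intensity.loc[retained, test + ref])
    zr = z_ratio(zmat, test, ref)
    pv = gene_pvalues(zmat, test, ref, equal_var=params.equal_var)
    excluded_var = variance_exclusion(
        zmat,
        test,
        ref,
        method=params.variance_method,
        threshold=params.variance_threshold,
        replicate_index=study.sample_meta["replicate"],
    )
    fdr = empirical_fdr(zmat, test, ref, zr, params.n_permutations, seed)

    table.loc[retained, "mean_z_test"] = zmat[test].mean(axis=1)
    table.loc[retained, "mean_z_ref"] = zmat[ref].mean(axis=1)
    table.loc[retained, "z_ratio"] = zr
    table.loc[retained, "p_value"] = pv
    table.loc[retained, "fdr"] = fdr
    table.loc[excluded_var, "excluded_by_variance"] = True
    for col in ("mean_z_test", "mean_z_ref", "z_ratio", "p_value", "fdr"):
        table[col] = table[col].astype(float)

    table = call_significant(table, params)
    meta["n_significant"] = int(table["significant"].sum())
    return DiffResult(table, contrast, params, meta)
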