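"""Spike-in-normalized quantification across sucrose-gradient fractions.

Each gradient fraction's RNA is spiked with a fixed quantity of exogenous
luciferase mRNA before reverse transcription, so the relative quantity of a
target transcript in fraction f is efficiency^(Ct_spike,f - Ct_target,f):
per-fraction recovery differences shift both Cts equally and cancel. The
per-fraction percentages (summing to 100) describe how the transcript
distributes over the gradient; the share in the heavy polysome fractions
(#9-11 of an 11-fraction gradient by default) measures active translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataValidationError

DEFAULT_HEAVY_SET = frozenset({9, 10, 11})

CT_COLUMNS = ("fraction", "target_ct", "spike_ct")


@dataclass
class FractionProfile:
    """Spike-normalized distribution of one transcript over the gradient."""

    fractions: np.ndarray  # 1..F
    quantity: np.ndarray  # relative, spike-normalized
    percent: np.ndarray  # 100 * quantity / sum
    heavy_set: frozenset[int] = DEFAULT_HEAVY_SET

    def __post_init__(self) -> None:
        if np.any(self.quantity < 0):
            raise DataValidationError("quantities must be non-negative")
        if abs(self.percent.sum() - 100.0) > 1e-9:
            raise DataValidationError("percentages must sum to 100")
        if not self.heavy_set <= set(self.fractions.tolist()):
            raise ConfigurationError("heavy_set contains unknown fraction indices")


def normalize_fractions(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    heavy_set: frozenset[int] = DEFAULT_HEAVY_SET,
) -> FractionProfile:
    """Ct table (columns fraction, target_ct, spike_ct) -> FractionProfile.

    quantity_f = efficiency^(Ct_spike,f - Ct_target,f); percent_f is the
    quantity share x 100. Every fraction must carry both Cts exactly once.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ConfigurationError("amplification efficiency must lie in (1, 2]")
    for col in CT_COLUMNS:
        if col not in ct_table.columns:
            raise DataValidationError(f"Ct table missing column {col!r}")
    df = ct_table.sort_values("fraction")
    fr = df["fraction"].to_numpy()
    if len(np.unique(fr)) != len(fr):
        raise DataValidationError("duplicate fraction index in Ct table")
    if df[["target_ct", "spike_ct"]].isna().to_numpy().any():
        missing = df.loc[df[["target_ct", "spike_ct"]].isna().any(axis=1), "fraction"]
        raise DataValidationError(f"missing Ct for fraction {int(missing.iloc[0])}")
    if len(fr) < 2:
        raise DataValidationError("need at least 2 fractions")
    quantity = efficiency ** (
        df["spike_ct"].to_numpy(dtype=float) - df["target_ct"].to_numpy(dtype=float)
    )
    percent = 100.0 * quantity / quantity.sum()
    return FractionProfile(fr.astype(int), quantity, percent, frozenset(heavy_set))


def heavy_share(profile: FractionProfile) -> float:
    """Percent of the transcript recovered in the heavy polysome fractions."""
    mask = np.isin(profile.fractions, list(profile.heavy_set))
    return float(profile.percent[mask].sum())


def profiles_by_replicate(
    ct_table: pd.DataFrame,
    efficiency: float = 2.0,
    heavy_set: frozenset[int] = DEFAULT_HEAVY_SET,
) -> dict[tuple[str, int], FractionProfile]:
    """Split a long Ct table (condition, replicate columns) into profiles.

    Percentages are computed per replicate, then compared/averaged across
    replicates — matching the per-experiment spike normalization.
    """
    for col in ("condition", "replicate"):
        if col not in ct_table.columns:
            raise DataValidationError(f"Ct table missing column {col!r}")
    out = {}
    for (cond, rep), sub in ct_table.groupby(["condition", "replicate"], sort=True):
        out[(cond, rep)] = normalize_fractions(sub, efficiency, heavy_set)
    return out


def _guarded_ttest(a: np.ndarray, b: np.ndarray) -> float:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


@dataclass
class ProfileComparison:
    """Replicate-level comparison of two fraction-profile sets."""

    per_fraction: pd.DataFrame  # fraction, mean_a, mean_b, diff, p_value
    heavy_diff: float  # mean heavy share a - b, percentage points
    heavy_p: float
    direction: str  # "a_heavier" / "b_heavier" / "none"
    n_a: int = 0
    n_b: int = 0


def compare_profiles(
    a: list[FractionProfile], b: list[FractionProfile]
) -> ProfileComparison:
    """Per-fraction and heavy-share t-tests between two replicate sets."""
    if len(a) < 2 or len(b) < 2:
        raise DataValidationError("need >= 2 replicate profiles per condition")
    fr = a[0].fractions
    for p in a + b:
        if not np.array_equal(p.fractions, fr):
            raise DataValidationError("profiles have mismatched fraction counts")
    pa = np.vstack([p.percent for p in a])
    pb = np.vstack([p.percent for p in b])
    rows = []
    for j, f in enumerate(fr):
        rows.append(
            {
                "fraction": int(f),
                "mean_a": pa[:, j].mean(),
                "mean_b": pb[:, j].mean(),
                "diff": pa[:, j].mean() - pb[:, j].mean(),
                "p_value": _guarded_ttest(pa[:, j], pb[:, j]),
            }
        )
    ha = np.array([heavy_share(p) for p in a])
    hb = np.array([heavy_share(p) for p in b])
    hdiff = float(ha.mean() - hb.mean())
    hp = _guarded_ttest(ha, hb)
    direction = "none" if hdiff == 0 else ("a_heavier" if hdiff > 0 else "b_heavier")
    return ProfileComparison(
        per_fraction=pd.DataFrame(rows),
        heavy_diff=hdiff,
        heavy_p=hp,
        direction=direction,
        n_a=len(a),
        n_b=len(b),
    )
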