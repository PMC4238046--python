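"""Translatome-exclusive gene calling: combine a TL and a TR contrast.

A gene significantly altered in the translatome (heavy-polysome RNA) is kept
as *translatome-exclusive* only when no concurrent significant change is seen
in the transcriptome (total RNA); the symmetric rule defines the
transcriptome-exclusive set. Together with the shared and null sets this
forms a disjoint Venn partition of the analyzed gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, DataValidationError

PARTITION_LABELS = ("exclusive_tl", "exclusive_tr", "shared", "null")


@dataclass
class SwitchPartition:
    """Disjoint cover of the analyzed gene universe for one contrast pair."""

    exclusive_tl: set[str]
    exclusive_tr: set[str]
    shared: set[str]
    null: set[str]
    #: genes assigned to ``null`` because they failed detection in TL or TR
    detection_flagged: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        sets = [self.exclusive_tl, self.exclusive_tr, self.shared, self.null]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if total != len(union):
            raise DataValidationError("partition sets are not disjoint")

    @property
    def universe(self) -> set[str]:
        return self.exclusive_tl | self.exclusive_tr | self.shared | self.null

    def counts(self) -> dict[str, int]:
        return {label: len(getattr(self, label)) for label in PARTITION_LABELS}

    def labels(self) -> pd.Series:
        """gene -> partition label, sorted by gene id."""
        rows = {
            g: label for label in PARTITION_LABELS for g in getattr(self, label)
        }
        return pd.Series(rows, name="set").sort_index()

    def to_frame(self) -> pd.DataFrame:
        df = self.labels().to_frame()
        df["detection_flagged"] = df.index.isin(sorted(self.detection_flagged))
        return df


def _significant_mask(table: pd.DataFrame) -> pd.Series:
    return table["significant"].astype(bool)


def partition(
    tl: pd.DataFrame,
    tr: pd.DataFrame,
    direction_matched: bool = False,
) -> SwitchPartition:
    """Partition the common gene universe of a TL and a TR result table.

    ``tl``/``tr`` are DiffResult tables (or ``DiffResult.table``). A gene is
    *shared* when significant in both compartments — by default regardless of
    direction; with ``direction_matched`` a transcriptome change only
    "eliminates" a translatome call when both move the same way, so
    discordant double-significant genes land in ``exclusive_tl``/``_tr``
    according to the compartment they are significant in (both → shared only
    when concordant).

    Genes failing the detection filter in either compartment are assigned to
    ``null`` and flagged rather than dropped.
    """
    tl = getattr(tl, "table", tl)
    tr = getattr(tr, "table", tr)
    common = tl.index.intersection(tr.index)
    if len(common) == 0:
        raise DataValidationError("TL and TR results have disjoint gene universes")
    if len(common) != len(tl.index) or len(common) != len(tr.index):
        warnings.warn(
            f"gene universes differ; using intersection of {len(common)} genes"
        )
    tl = tl.loc[common]
    tr = tr.loc[common]

    undetected = (
        tl["excluded_by_detection"].astype(bool)
        | tr["excluded_by_detection"].astype(bool)
    )
    sig_tl = _significant_mask(tl) & ~undetected
    sig_tr = _significant_mask(tr) & ~undetected

    if direction_matched:
        concordant = tl["direction"] == tr["direction"]
        shared = sig_tl & sig_tr & concordant
        excl_tl = sig_tl & ~shared
        excl_tr = sig_tr & ~shared & ~excl_tl
    else:
        shared = sig_tl & sig_tr
        excl_tl = sig_tl & ~sig_tr
        excl_tr = sig_tr & ~sig_tl
    null = ~(shared | excl_tl | excl_tr)

    return SwitchPartition(
        exclusive_tl=set(common[excl_tl]),
        exclusive_tr=set(common[excl_tr]),
        shared=set(common[shared]),
        null=set(common[null]),
        detection_flagged=set(common[undetected]),
    )


def venn_counts(part: SwitchPartition) -> dict[str, int]:
    """Set sizes plus the two-set Venn summary (TL-only / TR-only / overlap)."""
    c = part.counts()
    c["venn_tl_only"] = c["exclusive_tl"]
    c["venn_tr_only"] = c["exclusive_tr"]
    c["venn_overlap"] = c["shared"]
    c["universe"] = len(part.universe)
    return c


def top_table(
    part: SwitchPartition,
    tl: pd.DataFrame,
    tr: pd.DataFrame,
    n: int = 50,
) -> dict[str, pd.DataFrame]:
    """Top-n exclusive genes per compartment, ranked by |z_ratio|.

    Ties break by ascending p-value, then gene id; sets smaller than ``n``
    are returned whole.
    """
    if n < 1:
        raise ConfigurationError("top_table requires n >= 1")
    tl = getattr(tl, "table", tl)
    tr = getattr(tr, "table", tr)
    out = {}
    for label, table in (("exclusive_tl", tl), ("exclusive_tr", tr)):
        genes = sorted(getattr(part, label))
        sub = table.loc[genes, ["z_ratio", "p_value", "fdr", "direction"]].copy()
        sub["abs_z"] = sub["z_ratio"].abs()
        sub = sub.sort_values(
            by=["abs_z", "p_value"], ascending=[False, True], kind="mergesort"
        ).drop(columns="abs_z")
        out[label] = sub.head(n)
    return out


def confusion_matrix(part: SwitchPartition, truth: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate planted truth classes against partition labels.

    ``truth`` is a TruthTable frame indexed by gene with a ``class`` column
    (tl_only / tr_only / both / null). Only genes present in the partition
    universe are counted.
    """
    labels = part.labels()
    common = labels.index.intersection(truth.index)
    return pd.crosstab(truth.loc[common, "class"], labels.loc[common]).rename_axis(
        index="truth", columns="called"
    )
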