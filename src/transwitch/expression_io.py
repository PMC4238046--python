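"""I/O and validation for expression studies.

An :class:`ExpressionStudy` bundles a gene x sample log10-intensity matrix,
the matching per-observation detection p-values, and a sample sheet assigning
each array to a condition group, a compartment (``TL`` = translatome, i.e.
RNA from heavy polysome fractions; ``TR`` = transcriptome, i.e. total RNA)
and a replicate index.

All tabular interchange is tab-separated UTF-8 with ``#`` comment lines and
the gene identifier in the first column. 5'-UTR sequences travel as FASTA
with the TSS at sequence position 0 (handled by :func:`read_fasta`).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataValidationError

COMPARTMENTS = ("TL", "TR")

SAMPLE_SHEET_COLUMNS = ("group", "compartment", "replicate")


@dataclass(frozen=True)
class SampleContrast:
    """A test-vs-reference comparison inside one compartment.

    E.g. ``SampleContrast("E1", "EV", "TL")`` compares the translatome of
    eIF4E1-overexpressing cells against the empty-vector translatome.
    """

    test: str
    reference: str
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise DataValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if self.test == self.reference:
            raise DataValidationError("test and reference groups must differ")

    def reversed(self) -> "SampleContrast":
        return SampleContrast(self.reference, self.test, self.compartment)

    def __str__(self) -> str:  # used in output file names / messages
        return f"{self.test}_vs_{self.reference}_{self.compartment}"


@dataclass
class ExpressionStudy:
    """Validated in-memory representation of one expression study.

    Attributes
    ----------
    log_intensity
        Genes x samples matrix of log10 intensities.
    detection_p
        Same shape; per-observation detection p-values in [0, 1].
    sample_meta
        Indexed by sample id; columns ``group``, ``compartment``,
        ``replicate``.
    """

    log_intensity: pd.DataFrame
    detection_p: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        li, dp, meta = self.log_intensity, self.detection_p, self.sample_meta
        if li.index.has_duplicates:
            dupes = li.index[li.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if not li.index.equals(dp.index) or not li.columns.equals(dp.columns):
            raise DataValidationError(
                "log_intensity and detection_p must share genes and samples"
            )
        if not li.columns.equals(meta.index):
            missing = set(li.columns).symmetric_difference(meta.index)
            raise DataValidationError(
                f"sample sheet does not match matrix columns; offending: {sorted(missing)[:5]}"
            )
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in meta.columns:
                raise DataValidationError(f"sample sheet missing column {col!r}")
        bad = meta.loc[~meta["compartment"].isin(COMPARTMENTS)]
        if len(bad):
            raise DataValidationError(
                f"unknown compartment {bad['compartment'].iloc[0]!r} "
                f"for sample {bad.index[0]!r}; expected one of {COMPARTMENTS}"
            )
        vals = dp.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise DataValidationError("detection p-values must lie in [0, 1]")
        counts = meta.groupby(["group", "compartment"], sort=False).size()
        thin = counts[counts < 2]
        if len(thin):
            g, c = thin.index[0]
            raise DataValidationError(
                f"group {g!r} compartment {c!r} has {thin.iloc[0]} replicate(s); need >= 2"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> pd.Index:
        return self.log_intensity.index

    @property
    def samples(self) -> pd.Index:
        return self.log_intensity.columns

    def samples_for(self, group: str, compartment: str) -> list[str]:
        m = self.sample_meta
        sel = m.index[(m["group"] == group) & (m["compartment"] == compartment)]
        return list(sel)

    def contrast_samples(self, contrast: SampleContrast) -> tuple[list[str], list[str]]:
        """Sample ids of the (test, reference) arms of a contrast."""
        test = self.samples_for(contrast.test, contrast.compartment)
        ref = self.samples_for(contrast.reference, contrast.compartment)
        for name, arm in (("test", test), ("reference", ref)):
            if len(arm) < 2:
                raise DataValidationError(
                    f"{name} group {getattr(contrast, name if name == 'test' else 'reference')!r} "
                    f"has {len(arm)} sample(s) in compartment {contrast.compartment!r}; need >= 2"
                )
        return test, ref


def _read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_study(
    matrix_path: str | Path,
    detection_path: str | Path,
    sample_sheet_path: str | Path,
    na_sentinel: float | str | None = None,
) -> ExpressionStudy:
    """Load and validate a study from its three TSV files.

    The sample sheet may carry an optional ``scale`` column per sample with
    values ``log10`` (default) or ``linear``; linear columns are log10
    transformed on load and must be strictly positive.

    NaN intensities are rejected unless ``na_sentinel`` is given, in which
    case matrix cells equal to the sentinel become NaN and are tolerated.
    """
    li = _read_tsv_matrix(matrix_path)
    dp = _read_tsv_matrix(detection_path)
    meta = pd.read_csv(sample_sheet_path, sep="\t", comment="#", index_col=0)
    meta.index = meta.index.astype(str)

    if na_sentinel is not None:
        li = li.replace(na_sentinel, np.nan)
    elif li.isna().to_numpy().any():
        gene = li.index[li.isna().any(axis=1)][0]
        raise DataValidationError(
            f"NaN intensity for gene {gene!r}; configure na_sentinel to allow missing values"
        )

    if "scale" in meta.columns:
        scales = meta["scale"].fillna("log10")
        bad = scales[~scales.isin(["log10", "linear"])]
        if len(bad):
            raise DataValidationError(
                f"unknown intensity scale {bad.iloc[0]!r} for sample {bad.index[0]!r}"
            )
        linear_cols = [s for s in li.columns if s in scales.index and scales[s] == "linear"]
        if linear_cols:
            block = li[linear_cols]
            if (block <= 0).to_numpy().any():
                col = block.columns[(block <= 0).any(axis=0)][0]
                raise DataValidationError(
                    f"non-positive linear intensity in sample {col!r}; cannot log10-transform"
                )
            li = li.copy()
            li[linear_cols] = np.log10(block)
        meta = meta.drop(columns=["scale"])

    return ExpressionStudy(log_intensity=li, detection_p=dp, sample_meta=meta)


def write_study(
    study: ExpressionStudy,
    matrix_path: str | Path,
    detection_path: str | Path,
    sample_sheet_path: str | Path,
) -> None:
    """Write the three TSV files that :func:`read_study` reads back."""
    study.log_intensity.to_csv(matrix_path, sep="\t", index_label="gene")
    study.detection_p.to_csv(detection_path, sep="\t", index_label="gene")
    study.sample_meta.to_csv(sample_sheet_path, sep="\t", index_label="sample")


# -- FASTA / gene lists -------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {gene id: sequence}; position 0 of each sequence is the TSS."""
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in utrs:
            raise DataValidationError(f"duplicate FASTA identifier {rec.id!r}")
        utrs[rec.id] = str(rec.seq).upper()
    return utrs


def write_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in utrs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")
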