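"""Seeded generators for every input the pipeline consumes.

The generators emulate the data structure of a polysome-profiling study:
paired translatome (TL) / transcriptome (TR) log10-intensity matrices with
planted regulation classes, per-observation detection p-values, TSS-anchored
5'-UTR sequences with planted motifs, spike-in qPCR Ct tables over an
11-fraction sucrose gradient, and exponential decay time courses. Every
generator is deterministic given its configuration and seed, and returns the
planted ground truth needed for parameter-recovery tests.

Planted expression effects are additive offsets on the log10 scale whose
size is calibrated, once per generation on the realized noise draw, so the
mean |Z-ratio| of regulated genes matches the requested effect size (the
Z-ratio denominator is itself data-dependent, so a fixed offset would not).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError
from .expression_io import ExpressionStudy, SampleContrast

#: Reported eIF4E1 protein half-life (hours) under cycloheximide chase; the
#: generator's default kinetic parameter for protein-decay courses.
EIF4E1_PROTEIN_HALF_LIFE_H = 4.5

CLASSES = ("tl_only", "tr_only", "both", "null")

#: Largest additive log10 offset the effect calibration will consider
#: (a 1000-fold change; beyond this the Z-ratio has saturated anyway).
MAX_EFFECT_OFFSET = 3.0


@dataclass(frozen=True)
class GenConfig:
    """Configuration of the paired TL/TR expression generator.

    Defaults emulate the study design the pipeline targets: three
    biological replicates per arm, a two-condition contrast (reference
    first), log10-scale intensities, detection failures at the array's
    nominal rate. ``class_fractions`` are kept small so the self-normalizing
    Z-ratio denominator does not saturate below ``effect_size``.
    """

    n_genes: int = 2000
    n_reps: int = 3
    groups: tuple[str, str] = ("EV", "OE")
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"tl_only": 0.05, "tr_only": 0.05, "both": 0.05, "null": 0.85}
    )
    effect_size: float = 3.0  # target mean |Z-ratio| of regulated genes
    noise_sd: float = 0.1  # within-group SD, log10 scale
    baseline_range: tuple[float, float] = (1.0, 4.0)  # log10 intensity span
    detection_fail_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps <= 0:
            raise ConfigurationError("n_genes and n_reps must be positive")
        if self.n_reps < 2:
            raise ConfigurationError("need n_reps >= 2")
        if len(self.groups) != 2:
            raise ConfigurationError("generator supports exactly two condition groups")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if set(self.class_fractions) != set(CLASSES):
            raise ConfigurationError(f"class_fractions must cover {CLASSES}")
        if abs(sum(self.class_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("class_fractions must sum to 1")
        if not 0 <= self.detection_fail_rate <= 1:
            raise ConfigurationError("detection_fail_rate must be a probability")


def _mean_abs_zratio(values: np.ndarray, n_reps: int, regulated: np.ndarray) -> float:
    """Realized mean |Z-ratio| of regulated genes for one compartment matrix.

    ``values``: genes x (2*n_reps) with reference replicates first. Mirrors
    the pipeline's statistic (per-column Z-scores, population SDs).
    """
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    z = (values - mu) / sd
    diffs = z[:, n_reps:].mean(axis=1) - z[:, :n_reps].mean(axis=1)
    denom = diffs.std()
    if denom == 0:
        return 0.0
    return float(np.abs(diffs[regulated] / denom).mean())


def gen_expression(cfg: GenConfig) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Generate a paired TL/TR study plus its planted TruthTable.

    Returns ``(study, truth)`` where ``truth`` is indexed by gene with
    columns ``class`` (tl_only / tr_only / both / null) and ``direction``
    (+1 / -1). The planted additive log10 offset is calibrated by scalar
    root-finding so the realized mean |Z-ratio| of TL-regulated genes in the
    TL contrast equals ``effect_size`` (capped at a 1000-fold offset when
    the requested size exceeds the statistic's saturation point).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    probs = [cfg.class_fractions[c] for c in CLASSES]
    classes = rng.choice(len(CLASSES), size=cfg.n_genes, p=probs)
    direction = rng.choice([1, -1], size=cfg.n_genes)

    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    n_cols = 2 * cfg.n_reps  # reference reps then test reps
    noise = {
        comp: rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_cols))
        for comp in ("TL", "TR")
    }

    class_names = np.array(CLASSES)[classes]
    affected = {
        "TL": np.isin(class_names, ["tl_only", "both"]),
        "TR": np.isin(class_names, ["tr_only", "both"]),
    }

    def matrix(comp: str, delta: float) -> np.ndarray:
        m = baseline[:, None] + noise[comp]
        shift = np.where(affected[comp], direction * delta, 0.0)
        m[:, cfg.n_reps :] += shift[:, None]
        return m

    if cfg.effect_size == 0 or not affected["TL"].any():
        delta = 0.0
    else:
        def realized(d: float) -> float:
            return _mean_abs_zratio(matrix("TL", d), cfg.n_reps, affected["TL"])

        # realized(d) is not monotone: very large offsets inflate the test
        # columns' SD and dilute the per-column Z-scores, so the curve rises,
        # peaks and falls. Bracket the first upward crossing on a grid; when
        # the target exceeds the peak (Z-ratio saturation), use the argmax.
        grid = np.linspace(0.0, MAX_EFFECT_OFFSET, 31)
        values = np.array([realized(d) for d in grid])
        above = np.flatnonzero(values >= cfg.effect_size)
        if above.size:
            i = above[0]
            delta = (
                float(grid[i])
                if i == 0
                else brentq(
                    lambda d: realized(d) - cfg.effect_size, grid[i - 1], grid[i], xtol=1e-6
                )
            )
        else:
            delta = float(grid[int(values.argmax())])

    frames = {}
    for comp in ("TL", "TR"):
        cols = [
            f"{grp}_{comp}_r{r + 1}"
            for grp in cfg.groups
            for r in range(cfg.n_reps)
        ]
        frames[comp] = pd.DataFrame(matrix(comp, delta), index=genes, columns=cols)

    log_intensity = pd.concat([frames["TL"], frames["TR"]], axis=1)

    fail = rng.random(size=log_intensity.shape) < cfg.detection_fail_rate
    detection = np.where(
        fail,
        rng.uniform(0.02, 1.0, size=log_intensity.shape),
        rng.uniform(0.0, 0.02, size=log_intensity.shape),
    )
    detection_p = pd.DataFrame(detection, index=genes, columns=log_intensity.columns)

    meta_rows = []
    for comp in ("TL", "TR"):
        for grp in cfg.groups:
            for r in range(cfg.n_reps):
                meta_rows.append(
                    {"sample": f"{grp}_{comp}_r{r + 1}", "group": grp,
                     "compartment": comp, "replicate": r + 1}
                )
    sample_meta = pd.DataFrame(meta_rows).set_index("sample").loc[log_intensity.columns]

    truth = pd.DataFrame(
        {"class": class_names, "direction": direction}, index=pd.Index(genes, name="gene")
    )
    study = ExpressionStudy(log_intensity, detection_p, sample_meta)
    return study, truth


def read_truth_table(path) -> pd.DataFrame:
    """Read back a written TruthTable; the class label "null" is literal."""
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    df["direction"] = df["direction"].astype(int)
    return df


def default_contrasts(cfg: GenConfig):
    """The TL and TR test-vs-reference contrasts implied by a GenConfig."""
    ref, test = cfg.groups
    return (
        SampleContrast(test, ref, "TL"),
        SampleContrast(test, ref, "TR"),
    )


# -- 5'-UTR generator ---------------------------------------------------------


def gen_utrs(
    n_target: int = 50,
    n_background: int = 500,
    motif: str = "ATGCATGCAT",
    plant_rate: float = 0.8,
    window: tuple[int, int] = (0, 200),
    seed: int = 0,
    utr_length: int = 300,
    gc: float = 0.5,
) -> tuple[dict[str, str], list[str], list[str]]:
    """Random 5'-UTRs (TSS at position 0) with a motif planted in targets.

    Returns ``(utrs, targets, universe)``; the universe is targets plus
    background. Each target sequence carries at least one planted motif
    start inside the window with probability ``plant_rate``; all sequences
    are i.i.d. nucleotides with the requested GC content.
    """
    motif = motif.upper()
    if not motif:
        raise ConfigurationError("motif must be non-empty")
    if not set(motif) <= set("ACGT") or not 1 <= len(motif) <= 20:
        raise ConfigurationError("motif must be ACGT, length 1-20")
    if not 0.0 <= plant_rate <= 1.0:
        raise ConfigurationError("plant_rate must lie in [0, 1]")
    if utr_length < window[1] + len(motif):
        raise ConfigurationError("utr_length too short for the window plus motif")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))

    def random_seq() -> str:
        return "".join(rng.choice(alphabet, size=utr_length, p=p))

    utrs: dict[str, str] = {}
    targets, background = [], []
    for i in range(n_target):
        name = f"T{i + 1:04d}"
        seq = random_seq()
        if rng.random() < plant_rate:
            start = int(rng.integers(window[0], window[1]))
            seq = seq[:start] + motif + seq[start + len(motif) :]
        utrs[name] = seq
        targets.append(name)
    for i in range(n_background):
        name = f"B{i + 1:04d}"
        utrs[name] = random_seq()
        background.append(name)
    return utrs, targets, targets + background


# -- sucrose-gradient generator -----------------------------------------------


def _base_profile(n_fractions: int, shape: str) -> np.ndarray:
    idx = np.arange(1, n_fractions + 1, dtype=float)
    if shape == "flat":
        prof = np.ones(n_fractions)
    elif shape == "bimodal":
        # monosome peak (early fractions) + broad polysome mass (late)
        mono = np.exp(-0.5 * ((idx - 3.0) / 1.0) ** 2)
        poly = np.exp(-0.5 * ((idx - 0.75 * n_fractions) / 2.0) ** 2)
        prof = 0.4 * mono / mono.sum() + 0.6 * poly / poly.sum()
    else:
        raise ConfigurationError(f"unknown profile shape {shape!r}")
    return prof / prof.sum()


def _shift_heavy(profile: np.ndarray, heavy: np.ndarray, shift: float) -> np.ndarray:
    """Move ``shift`` of the total mass (as a fraction) into the heavy set."""
    s = profile[heavy].sum()
    target = min(max(s + shift, 0.0), 0.99)
    out = profile.copy()
    if s > 0:
        out[heavy] *= target / s
    if s < 1:
        out[~heavy] *= (1 - target) / (1 - s)
    return out / out.sum()


def gen_fractions(
    n_fractions: int = 11,
    shape: str = "bimodal",
    shift: float = 0.0,
    seed: int = 0,
    n_reps: int = 1,
    cv: float = 0.0,
    condition: str = "cond",
    heavy_set: Sequence[int] = (9, 10, 11),
) -> pd.DataFrame:
    """Per-fraction qPCR Ct table (target + luciferase spike) for a gradient.

    The target transcript follows a mixture profile (monosome peak plus
    polysome mass by default); ``shift`` moves that fraction of the total
    mass into the heavy fractions. Per-fraction RNA recovery varies and
    shifts target and spike Cts together, so spike normalization cancels it;
    ``cv`` adds multiplicative (lognormal) quantity noise to the target.

    Columns: condition, replicate, fraction, target_ct, spike_ct.
    """
    if n_fractions < 2:
        raise ConfigurationError("need n_fractions >= 2")
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    heavy = np.isin(np.arange(1, n_fractions + 1), list(heavy_set))
    profile = _shift_heavy(_base_profile(n_fractions, shape), heavy, shift)

    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for rep in range(1, n_reps + 1):
        recovery = rng.lognormal(mean=0.0, sigma=0.3, size=n_fractions)
        noise = (
            rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=n_fractions)
            if cv > 0
            else np.ones(n_fractions)
        )
        quantity = profile * noise
        target_ct = 25.0 - np.log2(quantity * recovery)
        spike_ct = 20.0 - np.log2(recovery)
        for f in range(n_fractions):
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep,
                    "fraction": f + 1,
                    "target_ct": target_ct[f],
                    "spike_ct": spike_ct[f],
                }
            )
    return pd.DataFrame(rows)


# -- decay-course generator ---------------------------------------------------


def gen_decay(
    half_life: float = EIF4E1_PROTEIN_HALF_LIFE_H,
    times: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0),
    cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Chase time course: abundance(t) = 2^(-t / half_life) x lognormal noise.

    The multiplicative noise has mean 1 and coefficient of variation ``cv``
    (cv = 0 gives the exact exponential series). Columns: time_h, replicate,
    abundance.
    """
    if half_life <= 0:
        raise ConfigurationError("half_life must be positive")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ConfigurationError("times must be non-negative")
    if 0.0 not in t:
        raise ConfigurationError("times must include 0")
    if cv < 0:
        raise ConfigurationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    rows = []
    for rep in range(1, n_reps + 1):
        clean = 2.0 ** (-t / half_life)
        noise = (
            rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=t.size)
            if cv > 0
            else np.ones(t.size)
        )
        for ti, ai in zip(t, clean * noise):
            rows.append({"time_h": ti, "replicate": rep, "abundance": ai})
    return pd.DataFrame(rows)
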