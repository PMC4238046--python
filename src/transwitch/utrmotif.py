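"""Window-constrained 5'-UTR motif over-representation.

Motifs (exact k-mers, optionally IUPAC-degenerate) are scanned in a
TSS-anchored window (default the first 200 nt of each 5'-UTR, 0-based,
half-open; a match counts when its *start* lies inside the window).
Over-representation of a motif in a target gene set against a gene universe
is scored with the hypergeometric tail P[X >= k] on gene-level counts
(a gene counts once however many sites it has), with the enrichment factor
(k/n)/(K/N). Discovery enumerates the k-mers actually present in target
windows, scores each, and Bonferroni-adjusts over the candidates scored.

Diagnostics cover the classic confounders of set-vs-universe motif tests:
GC and length bias (rank tests), strand bias (exact binomial on sense vs
reverse-complement site counts) and positional localization (KS against a
uniform law on the window). A candidate PWM can be compared with a reference
(e.g. the 5'TOP terminal-oligopyrimidine motif) by maximal mean per-column
Pearson correlation over ungapped offsets.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, DataValidationError

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

DEFAULT_WINDOW = (0, 200)

NUCLEOTIDES = "ACGT"

#: Reference PWM for the 5' terminal oligopyrimidine (TOP) motif: an
#: invariant C at the cap site followed by a pyrimidine (C/T) tract.
TOP_PWM = np.array(
    [
        # A     C     G     T      (rows) x position (columns)
        [0.00, 0.025, 0.025, 0.025, 0.025, 0.025, 0.025, 0.05],
        [1.00, 0.475, 0.475, 0.475, 0.475, 0.475, 0.475, 0.45],
        [0.00, 0.025, 0.025, 0.025, 0.025, 0.025, 0.025, 0.05],
        [0.00, 0.475, 0.475, 0.475, 0.475, 0.475, 0.475, 0.45],
    ]
)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ConfigurationError("motif must be non-empty")
    bad = set(motif) - set(IUPAC)
    if bad:
        raise DataValidationError(f"motif contains non-IUPAC characters: {sorted(bad)}")
    return motif


def _motif_regex(motif: str) -> re.Pattern:
    # lookahead so overlapping sites are all reported
    body = "".join(c if len(IUPAC[c]) == 1 else f"[{IUPAC[c]}]" for c in motif)
    return re.compile(f"(?=({body}))")


def scan_window(
    seq: str,
    motif: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> list[int]:
    """Start offsets (from the TSS at position 0) of motif matches.

    The window is half-open: a match starting at ``window[1]`` is not
    reported, but a match starting inside may extend past the window end.
    Overlapping matches are all counted.
    """
    motif = _validate_motif(motif)
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise DataValidationError(f"sequence contains non-IUPAC characters: {sorted(bad)}")
    w0, w1 = window
    if w0 < 0 or w1 <= w0:
        raise ConfigurationError(f"invalid window {window}")
    pat = _motif_regex(motif)
    return [
        m.start() for m in pat.finditer(seq) if w0 <= m.start() < w1
    ]


@dataclass
class MotifEnrichment:
    """Hypergeometric over-representation of one motif in a target set.

    N genes in the universe, K of them with >= 1 window match, n targets,
    k targets with >= 1 match; ``p_hg`` = P[X >= k] for
    X ~ Hypergeometric(N, K, n).
    """

    motif: str
    N: int
    K: int
    n: int
    k: int
    p_hg: float
    enrichment: float
    p_adj: float
    positions: list[int]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise DataValidationError("inconsistent hypergeometric counts")


def _check_gene_sets(
    targets: Sequence[str], universe: Sequence[str]
) -> tuple[list[str], list[str]]:
    if len(set(targets)) != len(targets):
        raise DataValidationError("duplicate entries in target gene list")
    if len(set(universe)) != len(universe):
        raise DataValidationError("duplicate entries in universe gene list")
    missing = set(targets) - set(universe)
    if missing:
        raise DataValidationError(
            f"targets not contained in universe: {sorted(missing)[:5]}"
        )
    return list(targets), list(universe)


def _with_utrs(genes: Sequence[str], utrs: Mapping[str, str], role: str) -> list[str]:
    present = [g for g in genes if g in utrs]
    dropped = len(genes) - len(present)
    if dropped:
        warnings.warn(f"{dropped} {role} gene(s) lack a UTR sequence; excluded")
    return present


def enrich(
    targets: Sequence[str],
    universe: Sequence[str],
    utrs: Mapping[str, str],
    motif: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
    n_tests: int = 1,
) -> MotifEnrichment:
    """Score one motif's over-representation in ``targets`` vs ``universe``."""
    motif = _validate_motif(motif)
    targets, universe = _check_gene_sets(targets, universe)
    universe = _with_utrs(universe, utrs, "universe")
    targets = _with_utrs(targets, utrs, "target")

    target_set = set(targets)
    K = 0
    k = 0
    positions: list[int] = []
    for g in universe:
        hits = scan_window(utrs[g], motif, window)
        if hits:
            K += 1
            if g in target_set:
                k += 1
                positions.extend(hits)
    N, n = len(universe), len(targets)
    p_hg = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
    enr = (k / n) / (K / N) if (n and K) else 0.0
    p_adj = min(1.0, p_hg * max(n_tests, 1))
    return MotifEnrichment(motif, N, K, n, k, p_hg, enr, p_adj, positions)


def _window_kmers(seq: str, k_len: int, window: tuple[int, int]) -> set[str]:
    w0, w1 = window
    # the last start inside the window may extend past the end, like scan_window
    region = seq.upper()
    return {
        region[s : s + k_len]
        for s in range(w0, min(w1, len(region) - k_len + 1))
        if set(region[s : s + k_len]) <= set(NUCLEOTIDES)
    }


def discover(
    targets: Sequence[str],
    universe: Sequence[str],
    utrs: Mapping[str, str],
    k_len: int = 10,
    window: tuple[int, int] = DEFAULT_WINDOW,
    top_m: int = 50,
    min_target_genes: int = 2,
) -> list[MotifEnrichment]:
    """Enumerate and rank candidate k-mers over-represented in target windows.

    Candidates are the exact k-mers present in at least ``min_target_genes``
    target windows (not all 4^k); each is scored by the hypergeometric tail.
    Bonferroni adjustment is over every distinct k-mer observed in any
    target window — the hypothesis family actually searched — because the
    ``min_target_genes`` filter is a selection from that family and
    correcting only over its survivors would understate the family-wise
    error. The top ``top_m`` motifs are returned ranked by p_hg (ties: more
    target genes first, then lexicographic motif).
    """
    if k_len < 1:
        raise ConfigurationError("k_len must be >= 1")
    targets, universe = _check_gene_sets(targets, universe)
    universe = _with_utrs(universe, utrs, "universe")
    targets = _with_utrs(targets, utrs, "target")
    target_set = set(targets)

    kmer_univ: dict[str, int] = {}
    kmer_targ: dict[str, int] = {}
    for g in universe:
        kmers = _window_kmers(utrs[g], k_len, window)
        in_target = g in target_set
        for km in kmers:
            kmer_univ[km] = kmer_univ.get(km, 0) + 1
            if in_target:
                kmer_targ[km] = kmer_targ.get(km, 0) + 1

    candidates = [km for km, c in kmer_targ.items() if c >= min_target_genes]
    if not candidates:
        warnings.warn("no candidate k-mers occur in enough target windows")
        return []

    N, n = len(universe), len(targets)
    Ks = np.array([kmer_univ[km] for km in candidates])
    ks = np.array([kmer_targ[km] for km in candidates])
    p = stats.hypergeom.sf(ks - 1, N, Ks, n)
    m = len(kmer_targ)  # full searched family, not just the >=2-gene survivors
    order = sorted(
        range(len(candidates)), key=lambda i: (p[i], -ks[i], candidates[i])
    )[: max(top_m, 1)]

    out = []
    for i in order:
        km = candidates[i]
        positions = [s for g in targets for s in scan_window(utrs[g], km, window)]
        out.append(
            MotifEnrichment(
                motif=km,
                N=N,
                K=int(Ks[i]),
                n=n,
                k=int(ks[i]),
                p_hg=float(p[i]),
                enrichment=(ks[i] / n) / (Ks[i] / N),
                p_adj=min(1.0, float(p[i]) * m),
                positions=positions,
            )
        )
    return out


@dataclass
class BiasReport:
    """Confounder diagnostics for a motif enrichment result."""

    gc_stat: float
    gc_p: float
    length_stat: float
    length_p: float
    strand_sense: int
    strand_antisense: int
    strand_p: float
    localization_stat: float | None
    localization_p: float | None
    localization_note: str | None = None


def _gc_content(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in NUCLEOTIDES)
    return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0


def bias_diagnostics(
    targets: Sequence[str],
    universe: Sequence[str],
    utrs: Mapping[str, str],
    motif: str,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> BiasReport:
    """GC, length, strand and localization diagnostics for one motif.

    GC and length compare targets against the non-target background with
    Mann-Whitney U. Strand bias counts sites on the sense window vs the
    window's reverse complement (exact binomial, null 0.5). Localization
    tests target match starts against a uniform law on the window (KS);
    with fewer than 5 matches it is reported as NA.
    """
    motif = _validate_motif(motif)
    targets, universe = _check_gene_sets(targets, universe)
    universe = _with_utrs(universe, utrs, "universe")
    targets = _with_utrs(targets, utrs, "target")
    background = [g for g in universe if g not in set(targets)]

    tgt_gc = [_gc_content(utrs[g]) for g in targets]
    bg_gc = [_gc_content(utrs[g]) for g in background]
    tgt_len = [len(utrs[g]) for g in targets]
    bg_len = [len(utrs[g]) for g in background]
    gc_res = stats.mannwhitneyu(tgt_gc, bg_gc, alternative="two-sided")
    len_res = stats.mannwhitneyu(tgt_len, bg_len, alternative="two-sided")

    w0, w1 = window
    sense = 0
    anti = 0
    positions: list[int] = []
    for g in targets:
        win = utrs[g].upper()[w0 : w1 + len(motif) - 1]
        fwd = scan_window(win, motif, (0, w1 - w0))
        rev = scan_window(reverse_complement(win), motif, (0, w1 - w0))
        sense += len(fwd)
        anti += len(rev)
        positions.extend(p + w0 for p in fwd)
    total = sense + anti
    strand_p = float(stats.binomtest(sense, total, 0.5).pvalue) if total else 1.0

    if len(positions) < 5:
        loc_stat = loc_p = None
        note = f"only {len(positions)} matches; need >= 5 for localization test"
    else:
        ks = stats.kstest(positions, stats.uniform(loc=w0, scale=w1 - w0).cdf)
        loc_stat, loc_p, note = float(ks.statistic), float(ks.pvalue), None

    return BiasReport(
        gc_stat=float(gc_res.statistic),
        gc_p=float(gc_res.pvalue),
        length_stat=float(len_res.statistic),
        length_p=float(len_res.pvalue),
        strand_sense=sense,
        strand_antisense=anti,
        strand_p=strand_p,
        localization_stat=loc_stat,
        localization_p=loc_p,
        localization_note=note,
    )


# -- PWM comparison -----------------------------------------------------------


def pwm_from_sites(sites: Sequence[str], pseudocount: float = 0.0) -> np.ndarray:
    """Column-stochastic 4 x L PWM (rows A,C,G,T) from aligned sites."""
    if not sites:
        raise DataValidationError("need at least one site to build a PWM")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise DataValidationError("sites must share one length")
    counts = np.full((4, L), pseudocount, dtype=float)
    for s in sites:
        for j, c in enumerate(s.upper()):
            counts[NUCLEOTIDES.index(c), j] += 1
    return counts / counts.sum(axis=0)


def _check_pwm(pwm: np.ndarray, name: str) -> np.ndarray:
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4:
        raise DataValidationError(f"{name} PWM must be 4 x L (rows A,C,G,T)")
    if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-6):
        raise DataValidationError(f"{name} PWM columns must sum to 1 +- 1e-6")
    return pwm


def compare_pwm(
    candidate: np.ndarray,
    reference: np.ndarray,
    min_overlap: int = 4,
) -> tuple[float, int]:
    """Best (score, offset) alignment of two PWMs without gaps.

    The score at an offset is the mean Pearson correlation of overlapping
    columns (4-vectors); a column with zero variance (e.g. uniform)
    contributes 0. Offsets with fewer than ``min_overlap`` overlapping
    columns are not considered. Ties prefer the smaller |offset|.
    """
    cand = _check_pwm(candidate, "candidate")
    ref = _check_pwm(reference, "reference")
    Lc, Lr = cand.shape[1], ref.shape[1]
    best: tuple[float, int] | None = None
    for offset in range(-(Lc - min_overlap), Lr - min_overlap + 1):
        # candidate column j aligns with reference column j + offset
        j0 = max(0, -offset)
        j1 = min(Lc, Lr - offset)
        if j1 - j0 < min_overlap:
            continue
        cors = []
        for j in range(j0, j1):
            a, b = cand[:, j], ref[:, j + offset]
            if a.std() == 0 or b.std() == 0:
                cors.append(0.0)
            else:
                cors.append(float(np.corrcoef(a, b)[0, 1]))
        score = float(np.mean(cors))
        key = (score, -abs(offset), -offset)
        if best is None or key > (best[0], -abs(best[1]), -best[1]):
            best = (score, offset)
    if best is None:
        raise ConfigurationError(
            f"PWMs of lengths {Lc} and {Lr} cannot overlap by {min_overlap} columns"
        )
    return best
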