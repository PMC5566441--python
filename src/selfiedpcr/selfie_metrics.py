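"""Derived biology-level statistics from paired RT+/RT- measurements.

The central statistic is transcripts per gene,

    t/g = (N_RT+ - N_RT-) / N_RT-  ,

the absolute number of RNA transcripts per copy of the encoding gene: the
RT- aliquot measures double-stranded gene copies only, while the RT+ aliquot
additionally measures cDNA reverse-transcribed from the gene's transcripts.
Negative values are reported as-is (they arise by sampling noise when a gene
is not transcribed); ``detected`` is False whenever the CI spans zero.

On top of t/g the module derives copies per genome (ratio of a target to a
single-copy reference gene), transcripts per genome (product), strand-specific
mitochondrial transcription summaries, percent observed-vs-expected
differences, RNAi silencing percentages, provirus integration counts, and
replicate-level statistics (mean ± SEM, one-way ANOVA with Bonferroni
post-hoc pairwise comparisons).

Uncertainty propagation is first-order (delta method) on independent
estimates; all ratio/difference statistics cancel volumes, so they are
identical whether computed on copies per reaction or copies per µl.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError
from .quantify import ConcentrationEstimate

__all__ = [
    "SelfiePair", "SelfieResult", "GenomeNormalized", "StrandReport",
    "transcripts_per_gene", "transcripts_per_gene_from_pair", "rna_copies",
    "copies_per_genome", "transcripts_per_genome", "strand_metrics",
    "percent_difference", "silencing_percent", "integrations_per_genome",
    "aggregate_replicates", "compare_groups",
]


@dataclass(frozen=True)
class SelfiePair:
    """A matched RT+/RT- measurement for one sample and target."""

    sample_id: str
    target: str
    rt_plus: ConcentrationEstimate
    rt_minus: ConcentrationEstimate

    def __post_init__(self) -> None:
        if self.rt_plus.saturated or self.rt_minus.saturated:
            raise ContractError(
                f"{self.sample_id}/{self.target}: saturated estimate in pair")


@dataclass(frozen=True)
class SelfieResult:
    """Transcripts-per-gene with propagated uncertainty."""

    transcripts_per_gene: float
    se: float
    ci_low: float
    ci_high: float
    detected: bool
    sample_id: str = ""
    target: str = ""


@dataclass(frozen=True)
class GenomeNormalized:
    copies_per_genome: float
    se: float
    ci_low: float
    ci_high: float
    reference_gene: str = ""


@dataclass(frozen=True)
class StrandReport:
    """Heavy/light mitochondrial strand transcription summary."""

    h: SelfieResult
    l: SelfieResult
    total: float              # H + L, summed point estimates
    total_se: float
    percent_excess_h: float   # 100 · (H - L) / L
    combined: SelfieResult | None = None
    consistency_z: float | None = None  # (H+L) vs combined, 0 when absent


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ContractError("confidence level must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + level / 2))


def transcripts_per_gene(rt_plus: float, rt_minus: float,
                         var_plus: float = 0.0, var_minus: float = 0.0,
                         level: float = 0.95,
                         sample_id: str = "", target: str = "") -> SelfieResult:
    """t/g = (RT+ - RT-)/RT- on matched units, delta-method CI.

    ``rt_plus``/``rt_minus`` are copy-number estimates on any common scale
    (per reaction or per µl); the ratio cancels the scale.
    """
    if rt_minus <= 0:
        raise ContractError("gene not detected: RT- estimate must be > 0")
    tpg = (rt_plus - rt_minus) / rt_minus
    # d(t/g)/dRT+ = 1/RT-,  d(t/g)/dRT- = -RT+/RT-^2
    var = var_plus / rt_minus**2 + (rt_plus**2 / rt_minus**4) * var_minus
    se = math.sqrt(max(var, 0.0))
    half = _z(level) * se
    lo, hi = tpg - half, tpg + half
    return SelfieResult(transcripts_per_gene=tpg, se=se, ci_low=lo, ci_high=hi,
                        detected=not (lo <= 0.0 <= hi),
                        sample_id=sample_id, target=target)


def transcripts_per_gene_from_pair(pair: SelfiePair, level: float = 0.95) -> SelfieResult:
    if pair.rt_minus.copies_per_ul_sample <= 0:
        raise ContractError(
            f"{pair.sample_id}/{pair.target}: gene not detected in RT- aliquot")
    return transcripts_per_gene(
        pair.rt_plus.copies_per_ul_sample, pair.rt_minus.copies_per_ul_sample,
        pair.rt_plus.variance_per_ul, pair.rt_minus.variance_per_ul,
        level=level, sample_id=pair.sample_id, target=pair.target)


def rna_copies(rt_plus: float, rt_minus: float,
               var_plus: float = 0.0, var_minus: float = 0.0) -> tuple[float, float]:
    """Transcript copies by subtraction, RT+ - RT-, with propagated SE."""
    return rt_plus - rt_minus, math.sqrt(var_plus + var_minus)


def copies_per_genome(target_copies: float, single_copy_copies: float,
                      var_target: float = 0.0, var_single: float = 0.0,
                      level: float = 0.95,
                      reference_gene: str = "") -> GenomeNormalized:
    """Target copy number per genome: ratio to a single-copy nuclear gene.

    Both inputs must be DNA-only (RT-) estimates normalized to copies per µl
    of the same original sample, so differing dilution chains cancel.
    """
    if single_copy_copies <= 0:
        raise ContractError("single-copy reference estimate must be > 0")
    r = target_copies / single_copy_copies
    var = (var_target / single_copy_copies**2
           + (target_copies**2 / single_copy_copies**4) * var_single)
    se = math.sqrt(max(var, 0.0))
    half = _z(level) * se
    return GenomeNormalized(copies_per_genome=r, se=se,
                            ci_low=r - half, ci_high=r + half,
                            reference_gene=reference_gene)


def copies_per_genome_from_estimates(target_est: ConcentrationEstimate,
                                     single_copy_est: ConcentrationEstimate,
                                     level: float = 0.95) -> GenomeNormalized:
    return copies_per_genome(
        target_est.copies_per_ul_sample, single_copy_est.copies_per_ul_sample,
        target_est.variance_per_ul, single_copy_est.variance_per_ul,
        level=level, reference_gene=single_copy_est.target)


def transcripts_per_genome(t_per_gene: float, copies_per_genome: float) -> float:
    """Total transcripts per genome: t/g × gene copies per genome."""
    if not (math.isfinite(t_per_gene) and math.isfinite(copies_per_genome)):
        raise ContractError("transcripts_per_genome requires finite inputs")
    return t_per_gene * copies_per_genome


def strand_metrics(h: SelfieResult, l: SelfieResult,
                   combined: SelfieResult | None = None) -> StrandReport:
    """Summarize strand-specific mitochondrial transcription.

    Reports H, L, their sum, the percent excess of heavy- over light-strand
    transcription 100·(H-L)/L, and — when a simultaneous H+L measurement is
    supplied — a z-score for the consistency of the sum with the combined
    measurement (both should estimate total mtDNA transcription).
    """
    if l.transcripts_per_gene <= 0:
        raise ContractError("percent excess undefined for non-positive L strand")
    total = h.transcripts_per_gene + l.transcripts_per_gene
    total_se = math.sqrt(h.se**2 + l.se**2)
    excess = 100.0 * (h.transcripts_per_gene - l.transcripts_per_gene) / l.transcripts_per_gene
    z = None
    if combined is not None:
        denom = math.sqrt(total_se**2 + combined.se**2)
        z = 0.0 if denom == 0 else (total - combined.transcripts_per_gene) / denom
    return StrandReport(h=h, l=l, total=total, total_se=total_se,
                        percent_excess_h=excess, combined=combined,
                        consistency_z=z)


def percent_difference(observed: float, expected: float) -> float:
    """Signed percent difference 100 · (observed - expected) / expected."""
    if expected == 0:
        raise ContractError("percent difference undefined for expected = 0")
    return 100.0 * (observed - expected) / expected


def silencing_percent(unsilenced: float, silenced: float) -> float:
    """Percent reduction of expression relative to the unsilenced baseline."""
    if unsilenced <= 0:
        raise ContractError("silencing requires a positive baseline")
    return 100.0 * (unsilenced - silenced) / unsilenced


def integrations_per_genome(provirus_copies: float, genome_copies: float,
                            native_copies: int = 1,
                            var_provirus: float = 0.0, var_genome: float = 0.0,
                            level: float = 0.95) -> tuple[GenomeNormalized, float]:
    """Provirus integrations per genome and total template genes per genome.

    The provirus marker (e.g. a WPRE element) is normalized to a single-copy
    genome reference measured on the same lysate; total template genes add
    the organism's native gene copies.
    """
    if native_copies < 0:
        raise ContractError("native_copies must be >= 0")
    integ = copies_per_genome(provirus_copies, genome_copies,
                              var_provirus, var_genome, level=level)
    return integ, integ.copies_per_genome + native_copies


def aggregate_replicates(values: Iterable[float]) -> tuple[float, float | None, int]:
    """Mean, SEM (sample SD / sqrt(n); None when n = 1) and n."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n == 0:
        raise ContractError("no replicate values")
    mean = float(arr.mean())
    if n == 1:
        return mean, None, 1
    sem = float(arr.std(ddof=1) / math.sqrt(n))
    return mean, sem, n


@dataclass(frozen=True)
class GroupComparison:
    f_statistic: float
    p_value: float
    pairwise: tuple[tuple[str, str, float, float], ...]  # (a, b, raw p, adjusted p)


def compare_groups(groups: Mapping[str, Sequence[float]]) -> GroupComparison:
    """One-way ANOVA across labeled groups with Bonferroni post-hoc t tests.

    Adjusted pairwise p-values are raw two-sample t-test p-values multiplied
    by the number of pairs, capped at 1.
    """
    if len(groups) < 2:
        raise ContractError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ContractError(f"group {k!r} needs n >= 2")
    if all(a.std(ddof=1) == 0 for a in arrays.values()) and \
            len({a.mean() for a in arrays.values()}) == 1:
        pairs = tuple((a, b, 1.0, 1.0) for a, b in combinations(arrays, 2))
        return GroupComparison(f_statistic=0.0, p_value=1.0, pairwise=pairs)
    f, p = stats.f_oneway(*arrays.values())
    n_pairs = math.comb(len(arrays), 2)
    pairwise = []
    for a, b in combinations(arrays, 2):
        t, raw = stats.ttest_ind(arrays[a], arrays[b])
        pairwise.append((a, b, float(raw), min(1.0, float(raw) * n_pairs)))
    return GroupComparison(f_statistic=float(f), p_value=float(p),
                           pairwise=tuple(pairwise))
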