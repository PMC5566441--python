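"""Poisson occupancy correction and absolute concentration estimation.

With N templates thrown at random into n droplets, the per-droplet occupancy
is Poisson and the fraction of negative droplets estimates exp(-λ), where λ
is the mean templates per droplet.  Hence

    λ̂ = -ln(negatives / total),   var(λ̂) ≈ (1 - p̂) / (total · p̂),

with p̂ = negatives/total (delta method on the binomial negative fraction).
Copies per reaction is λ̂ · total, and division by the effective sample
volume of the dilution chain gives copies per µl of original sample (N/µl).

Confidence intervals use the normal approximation on λ̂, falling back to an
exact Clopper-Pearson interval on the negative fraction (log-transformed)
whenever either droplet class is small, per digital-MIQE practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .classify import ClassifiedCounts
from .droplet_io import DilutionChain, effective_sample_volume
from .errors import ContractError

#: Nominal droplet volume (nl) for the droplet generator used; configurable.
DEFAULT_DROPLET_VOLUME_NL = 0.85
#: Upper limit of the dynamic range, copies per reaction.
DYNAMIC_RANGE_CEILING = 1e5
#: Wells with fewer accepted droplets than this are flagged.
DROPLET_FLOOR = 10_000
#: Relative CI half-width above which subsampling error is flagged.
SUBSAMPLING_CAP = 0.25
#: Positive droplets tolerated in a no-template control.
NTC_CEILING = 5
#: Below this count in either class the normal approximation is replaced by
#: an exact binomial interval.
EXACT_CI_FLOOR = 30

FLAG_SATURATED = "SATURATED"
FLAG_TOO_FEW_DROPLETS = "TOO_FEW_DROPLETS"
FLAG_HIGH_SUBSAMPLING_ERROR = "HIGH_SUBSAMPLING_ERROR"
FLAG_NTC_CONTAMINATION = "NTC_CONTAMINATION"


@dataclass(frozen=True)
class LambdaEstimate:
    """Mean copies per droplet with its sampling variance."""

    lam: float
    variance: float
    positives: int
    negatives: int
    total: int
    saturated: bool = False


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute concentration for one well/condition, with CI and QC flags."""

    lam: float
    lam_variance: float
    copies_per_reaction: float
    copies_per_ul_sample: float
    ci_low: float
    ci_high: float
    level: float
    n_droplets: int
    droplet_volume_nl: float
    scale_per_ul: float = 0.0  # copies/µl sample per unit λ (= n / v_eff)
    flags: frozenset[str] = field(default_factory=frozenset)
    sample_id: str = ""
    target: str = ""
    rt_condition: str = ""

    @property
    def variance_per_ul(self) -> float:
        """Sampling variance of copies_per_ul_sample (delta method on λ)."""
        if not math.isfinite(self.lam):
            return math.nan
        return self.lam_variance * self.scale_per_ul ** 2

    @property
    def saturated(self) -> bool:
        return FLAG_SATURATED in self.flags


def estimate_lambda(counts: ClassifiedCounts) -> LambdaEstimate:
    """Poisson-corrected mean copies per droplet from classified counts."""
    total = counts.total
    if total < 1:
        raise ContractError("cannot estimate occupancy from an empty well")
    if counts.negatives == 0:
        return LambdaEstimate(lam=math.inf, variance=math.nan,
                              positives=counts.positives, negatives=0,
                              total=total, saturated=True)
    p_neg = counts.negatives / total
    lam = -math.log(p_neg)
    variance = (1.0 - p_neg) / (total * p_neg)
    return LambdaEstimate(lam=lam, variance=variance,
                          positives=counts.positives,
                          negatives=counts.negatives, total=total)


def confidence_interval(est: LambdaEstimate, level: float = 0.95) -> tuple[float, float]:
    """Two-sided CI on λ at the given confidence level."""
    if not 0 < level < 1:
        raise ContractError("confidence level must be in (0, 1)")
    if est.saturated:
        raise ContractError("no interval for a saturated well; check flags")
    if est.positives < EXACT_CI_FLOOR or est.negatives < EXACT_CI_FLOOR:
        # Clopper-Pearson on the negative fraction, mapped through -ln.
        alpha = 1.0 - level
        n, k = est.total, est.negatives
        p_lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        p_hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        lam_low = -math.log(p_hi)
        lam_high = math.inf if p_lo == 0 else -math.log(p_lo)
        return (max(lam_low, 0.0), lam_high)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(est.variance)
    return (max(est.lam - half, 0.0), est.lam + half)


def to_sample_concentration(est: LambdaEstimate, chain: DilutionChain,
                            droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
                            level: float = 0.95,
                            sample_id: str = "", target: str = "",
                            rt_condition: str = "") -> ConcentrationEstimate:
    """Back-calculate copies per µl of original sample through the chain.

    The accepted droplets of the well are treated as the analyzed partition
    set, so copies/reaction = λ · n_droplets and copies/µl sample divides by
    the chain's effective sample volume.  The CI transforms by the same
    linear scale factor.
    """
    if droplet_volume_nl <= 0:
        raise ContractError("droplet_volume must be > 0")
    v_eff = effective_sample_volume(chain)
    if est.saturated:
        return ConcentrationEstimate(
            lam=math.inf, lam_variance=math.nan,
            copies_per_reaction=math.inf, copies_per_ul_sample=math.inf,
            ci_low=math.nan, ci_high=math.nan, level=level,
            n_droplets=est.total, droplet_volume_nl=droplet_volume_nl,
            flags=frozenset({FLAG_SATURATED}),
            sample_id=sample_id, target=target, rt_condition=rt_condition)
    scale = est.total / v_eff  # copies/µl per unit λ
    lo, hi = confidence_interval(est, level)
    return ConcentrationEstimate(
        lam=est.lam, lam_variance=est.variance,
        copies_per_reaction=est.lam * est.total,
        copies_per_ul_sample=est.lam * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
        level=level, n_droplets=est.total,
        droplet_volume_nl=droplet_volume_nl,
        scale_per_ul=scale,
        sample_id=sample_id, target=target, rt_condition=rt_condition)


def qc_flags(est: ConcentrationEstimate,
             ntc_counts: ClassifiedCounts | None = None,
             dynamic_range_ceiling: float = DYNAMIC_RANGE_CEILING,
             droplet_floor: int = DROPLET_FLOOR,
             subsampling_cap: float = SUBSAMPLING_CAP,
             ntc_ceiling: int = NTC_CEILING) -> frozenset[str]:
    """QC flag set for one concentration estimate.

    SATURATED when no negatives remain or copies/reaction exceeds the
    dynamic-range ceiling; TOO_FEW_DROPLETS below the droplet floor;
    HIGH_SUBSAMPLING_ERROR when the relative CI half-width exceeds the cap;
    NTC_CONTAMINATION when the paired no-template control shows more
    positives than tolerated.
    """
    flags = set(est.flags)
    if est.copies_per_reaction > dynamic_range_ceiling or not math.isfinite(est.lam):
        flags.add(FLAG_SATURATED)
    if est.n_droplets < droplet_floor:
        flags.add(FLAG_TOO_FEW_DROPLETS)
    if FLAG_SATURATED not in flags and est.copies_per_ul_sample > 0:
        half = max(est.copies_per_ul_sample - est.ci_low,
                   est.ci_high - est.copies_per_ul_sample)
        if half / est.copies_per_ul_sample > subsampling_cap:
            flags.add(FLAG_HIGH_SUBSAMPLING_ERROR)
    if ntc_counts is not None and ntc_counts.positives > ntc_ceiling:
        flags.add(FLAG_NTC_CONTAMINATION)
    return frozenset(flags)


def with_qc(est: ConcentrationEstimate, **kwargs) -> ConcentrationEstimate:
    """Return a copy of ``est`` with its QC flags recomputed."""
    return replace(est, flags=qc_flags(est, **kwargs))


def merge_wells(wells: list[ClassifiedCounts]) -> ClassifiedCounts:
    """Pool replicate wells of one condition into a single partition set.

    Counts add; threshold provenance is retained per source well.  For
    equal-size wells the pooled estimate equals the precision-weighted
    combination of per-well estimates.
    """
    if not wells:
        raise ContractError("merge_wells requires at least one well")
    key = {(w.sample_id, w.target, w.rt_condition) for w in wells}
    if len(key) > 1:
        raise ContractError(f"cannot merge wells from mixed conditions: {sorted(key)}")
    first = wells[0]
    sources = tuple(s for w in wells for s in w.sources)
    thresholds = {w.threshold for w in wells}
    return ClassifiedCounts(
        positives=sum(w.positives for w in wells),
        negatives=sum(w.negatives for w in wells),
        threshold=first.threshold if len(thresholds) == 1 else math.nan,
        method=first.method,
        sample_id=first.sample_id, target=first.target,
        rt_condition=first.rt_condition,
        flagged=any(w.flagged for w in wells),
        sources=sources)
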