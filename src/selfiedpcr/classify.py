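"""Positive/negative droplet calling from raw fluorescence amplitudes.

EvaGreen end-point dPCR yields a bimodal amplitude distribution: a negative
cloud of empty droplets and a positive cloud of droplets that amplified
template.  The automatic threshold here is a two-class variance-maximizing
split (Otsu) of the 1-D amplitude histogram — deterministic, parameter-light,
and invariant to droplet order.  Wells whose distribution shows no credible
two-mode structure are flagged and classified all-negative rather than
split arbitrarily; this is the correct behaviour for no-template controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .droplet_io import DropletWell
from .errors import ContractError

#: Histogram resolution for the automatic threshold.
OTSU_BINS = 256
#: Minimum distance between class means, in units of pooled within-class
#: standard deviation, for a split to count as genuinely bimodal.
MIN_MODE_SEPARATION = 4.0
#: Wells below this droplet count are too sparse for histogram thresholding.
MIN_DROPLETS_AUTO = 100


@dataclass(frozen=True)
class AutoThreshold:
    value: float
    flagged: bool  # True: no valley found, well classifies all-negative


@dataclass(frozen=True)
class ClassifiedCounts:
    """Positive/negative droplet counts and the threshold that produced them."""

    positives: int
    negatives: int
    threshold: float
    method: str  # "auto" | "manual"
    sample_id: str = ""
    target: str = ""
    rt_condition: str = ""
    flagged: bool = False
    #: (well_id, threshold) provenance per merged source well.
    sources: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.positives < 0 or self.negatives < 0:
            raise ContractError("droplet counts must be non-negative")

    @property
    def total(self) -> int:
        return self.positives + self.negatives


def _otsu_split(amplitudes: np.ndarray, bins: int = OTSU_BINS) -> float:
    """Threshold maximizing between-class variance on a fixed-bin histogram."""
    counts, edges = np.histogram(amplitudes, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_m = np.cumsum(w * centers)
    mean_all = cum_m[-1] / total
    # between-class variance for split after bin k
    w0 = cum_w[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.where(w0 > 0, cum_m[:-1] / np.maximum(w0, 1), 0.0)
    mu1 = np.where(w1 > 0, (cum_m[-1] - cum_m[:-1]) / np.maximum(w1, 1), 0.0)
    sigma_b = np.where(valid, w0 * w1 * (mu1 - mu0) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def auto_threshold(well: DropletWell, min_droplets: int = MIN_DROPLETS_AUTO,
                   bins: int = OTSU_BINS,
                   min_separation: float = MIN_MODE_SEPARATION) -> AutoThreshold:
    """Locate the positive/negative amplitude boundary for one well.

    Returns a flagged threshold at ``max(amplitude) + 1`` (all droplets
    negative) when the amplitude distribution is degenerate or unimodal —
    i.e. when the best two-class split separates the class means by fewer
    than ``min_separation`` pooled within-class standard deviations.
    """
    amps = well.amplitudes
    if amps.size < min_droplets:
        raise ContractError(
            f"well {well.well_id}: {amps.size} droplets < floor of {min_droplets}"
        )
    if np.ptp(amps) == 0:
        return AutoThreshold(float(amps.max()) + 1.0, flagged=True)

    thr = _otsu_split(amps, bins=bins)
    lo = amps[amps <= thr]
    hi = amps[amps > thr]
    if lo.size == 0 or hi.size == 0:
        return AutoThreshold(float(amps.max()) + 1.0, flagged=True)
    pooled = np.sqrt((lo.size * lo.var() + hi.size * hi.var()) / amps.size)
    if pooled == 0 or (hi.mean() - lo.mean()) / pooled < min_separation:
        return AutoThreshold(float(amps.max()) + 1.0, flagged=True)
    return AutoThreshold(thr, flagged=False)


def classify_droplets(well: DropletWell, threshold: float,
                      method: str = "manual", flagged: bool = False) -> ClassifiedCounts:
    """Count droplets strictly above ``threshold`` as positive.

    Droplets exactly at the threshold are negative (fixed tie-break).
    """
    if well.accepted_droplets == 0:
        raise ContractError(f"well {well.well_id}: empty well cannot be classified")
    if not np.isfinite(threshold):
        raise ContractError("threshold must be finite")
    positives = int(np.count_nonzero(well.amplitudes > threshold))
    return ClassifiedCounts(
        positives=positives,
        negatives=well.accepted_droplets - positives,
        threshold=float(threshold),
        method=method,
        sample_id=well.sample_id,
        target=well.target,
        rt_condition=well.rt_condition,
        flagged=flagged,
        sources=((well.well_id, float(threshold)),),
    )


def classify_well(well: DropletWell, manual_threshold: float | None = None,
                  **auto_kwargs) -> ClassifiedCounts:
    """Classify one well, with the automatic threshold unless overridden."""
    if manual_threshold is not None:
        return classify_droplets(well, manual_threshold, method="manual")
    thr = auto_threshold(well, **auto_kwargs)
    return classify_droplets(well, thr.value, method="auto", flagged=thr.flagged)
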