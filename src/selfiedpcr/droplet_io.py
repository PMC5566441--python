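"""Reading and validation of droplet amplitude tables, plate layouts and dilution chains.

A droplet digital PCR run produces, per well, one fluorescence amplitude per
accepted droplet.  This module defines the in-memory containers for those raw
observables (:class:`DropletWell`), the plate design that pairs each RT+ well
with its RT- duplicate (:class:`PlateLayout`), and the volumetric bookkeeping
that traces how much of the original solubilized sample ends up in one dPCR
reaction (:class:`DilutionChain`).

File dialects are deliberately plain: long-format delimited text with a header
row, comma by default, tab accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ParseError, ValidationError

RT_CONDITIONS = ("RT_PLUS", "RT_MINUS", "NTC")

AMPLITUDE_COLUMNS = ["well", "channel", "amplitude"]
LAYOUT_COLUMNS = ["well", "sample", "target", "rt_condition", "dilution_chain", "replicate"]


# ---------------------------------------------------------------------------
# Dilution chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DilutionChain:
    """Volumetric path from solubilized sample to one dPCR reaction.

    Parameters
    ----------
    sample_input_volume
        Microliters of original sample entering the first step.
    steps
        Ordered ``(aliquot_taken, final_volume)`` pairs in µl.  Each step mixes
        the carried-over aliquot up to ``final_volume``; ``aliquot_taken`` is
        the volume drawn from that mix into the next step (the last step's
        aliquot enters the reaction).
    reaction_volume
        Final dPCR reaction volume in µl.
    """

    sample_input_volume: float
    steps: tuple[tuple[float, float], ...]
    reaction_volume: float

    def __post_init__(self) -> None:
        if self.sample_input_volume <= 0:
            raise ContractError("sample_input_volume must be > 0")
        if self.reaction_volume <= 0:
            raise ContractError("reaction_volume must be > 0")
        for aliquot, final in self.steps:
            if aliquot <= 0 or final <= 0:
                raise ContractError("all chain volumes must be > 0")
            if aliquot > final:
                raise ContractError(
                    f"aliquot {aliquot} µl exceeds the {final} µl it is drawn from"
                )

    @property
    def dilution_factor(self) -> float:
        """Product of per-step volume fractions (dimensionless, ≤ 1)."""
        f = 1.0
        for aliquot, final in self.steps:
            f *= aliquot / final
        return f

    def then(self, other: "DilutionChain") -> "DilutionChain":
        """Concatenate two chains; dilution factors multiply."""
        return DilutionChain(self.sample_input_volume, self.steps + other.steps,
                             other.reaction_volume)


def effective_sample_volume(chain: DilutionChain) -> float:
    """Volume (µl) of the original sample contained in one dPCR reaction."""
    v = chain.sample_input_volume * chain.dilution_factor
    if v <= 0:
        raise ContractError("effective sample volume must be > 0")
    return v


#: Default protocol chain: 0.5 µl sample pre-annealed in 5 µl, carried whole
#: into a 10 µl RT reaction, diluted to 95 µl, of which 9.5 µl enter the
#: 20 µl dPCR reaction.  Effective sample volume: 0.5 × 9.5/95 = 0.05 µl.
METHODS_CHAIN = DilutionChain(
    sample_input_volume=0.5,
    steps=((5.0, 5.0), (10.0, 10.0), (9.5, 95.0)),
    reaction_volume=20.0,
)


# ---------------------------------------------------------------------------
# Wells and plate layout
# ---------------------------------------------------------------------------

@dataclass
class DropletWell:
    """Raw per-droplet fluorescence amplitudes for one well plus metadata."""

    well_id: str
    sample_id: str
    target: str
    rt_condition: str
    amplitudes: np.ndarray
    dilution_chain_id: str = "default"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.rt_condition not in RT_CONDITIONS:
            raise ValidationError(
                f"well {self.well_id}: rt_condition {self.rt_condition!r} "
                f"not one of {RT_CONDITIONS}"
            )
        if self.amplitudes.ndim != 1:
            raise ValidationError(f"well {self.well_id}: amplitudes must be 1-D")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValidationError(f"well {self.well_id}: non-finite amplitude")

    @property
    def accepted_droplets(self) -> int:
        return int(self.amplitudes.size)


@dataclass(frozen=True)
class WellMeta:
    well_id: str
    sample_id: str
    target: str
    rt_condition: str
    dilution_chain_id: str = "default"
    replicate_index: int = 0


@dataclass
class PlateLayout:
    """Plate design: well metadata plus the RT+/RT- pairing contract.

    Every RT_PLUS well for a (sample, target) must have an RT_MINUS partner;
    the transcripts-per-gene statistic is undefined without one.  Each target
    must carry at least one no-template control unless ``require_ntc=False``.
    """

    wells: tuple[WellMeta, ...]
    require_ntc: bool = True

    def __post_init__(self) -> None:
        self.wells = tuple(self.wells)
        ids = [w.well_id for w in self.wells]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate well ids in layout: {dupes}")
        for w in self.wells:
            if w.rt_condition not in RT_CONDITIONS:
                raise ValidationError(
                    f"well {w.well_id}: unknown rt_condition {w.rt_condition!r}"
                )
        plus = {(w.sample_id, w.target) for w in self.wells if w.rt_condition == "RT_PLUS"}
        minus = {(w.sample_id, w.target) for w in self.wells if w.rt_condition == "RT_MINUS"}
        unpaired = sorted(plus - minus)
        if unpaired:
            raise ValidationError(
                f"RT_PLUS wells without an RT_MINUS partner: {unpaired}"
            )
        if self.require_ntc:
            targets = {w.target for w in self.wells if w.rt_condition != "NTC"}
            ntc_targets = {w.target for w in self.wells if w.rt_condition == "NTC"}
            missing = sorted(targets - ntc_targets)
            if missing:
                raise ValidationError(f"targets without an NTC well: {missing}")

    def __iter__(self):
        return iter(self.wells)

    def by_well_id(self) -> dict[str, WellMeta]:
        return {w.well_id: w for w in self.wells}


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _read_table(path, expected_columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str,
                         skipinitialspace=True)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in expected_columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; found {list(df.columns)}")
    return df


def read_layout(path, require_ntc: bool = True) -> PlateLayout:
    """Read a plate layout table (`well,sample,target,rt_condition,dilution_chain,replicate`)."""
    df = _read_table(path, LAYOUT_COLUMNS)
    wells = []
    for _, row in df.iterrows():
        wells.append(WellMeta(
            well_id=row["well"],
            sample_id=row["sample"],
            target=row["target"],
            rt_condition=row["rt_condition"].strip().upper(),
            dilution_chain_id=row["dilution_chain"],
            replicate_index=int(row["replicate"]),
        ))
    return PlateLayout(tuple(wells), require_ntc=require_ntc)


def read_amplitude_table(path, layout: PlateLayout) -> list[DropletWell]:
    """Read a long-format amplitude table (`well,channel,amplitude`) into wells.

    Raises
    ------
    ValidationError
        If the file references wells absent from the layout (listed by id).
    ParseError
        On non-numeric amplitudes (with 1-based data row numbers).
    """
    df = _read_table(path, AMPLITUDE_COLUMNS)
    meta = layout.by_well_id()
    unknown = sorted(set(df["well"]) - set(meta))
    if unknown:
        raise ValidationError(f"{path}: wells not present in layout: {unknown}")
    amplitudes = pd.to_numeric(df["amplitude"], errors="coerce")
    bad = np.flatnonzero(amplitudes.isna().to_numpy())
    if bad.size:
        rows = (bad + 1).tolist()[:10]
        raise ParseError(f"{path}: non-numeric amplitude at data row(s) {rows}")
    df = df.assign(amplitude=amplitudes.to_numpy())

    wells: list[DropletWell] = []
    for (well_id, _channel), grp in df.groupby(["well", "channel"], sort=True):
        m = meta[well_id]
        wells.append(DropletWell(
            well_id=well_id,
            sample_id=m.sample_id,
            target=m.target,
            rt_condition=m.rt_condition,
            amplitudes=grp["amplitude"].to_numpy(dtype=float),
            dilution_chain_id=m.dilution_chain_id,
            replicate_index=m.replicate_index,
        ))
    return wells


def write_amplitude_table(wells: Iterable[DropletWell], path, channel: int = 1) -> None:
    """Write wells in the long amplitude dialect; fixed formatting so runs
    with identical inputs are byte-identical."""
    with open(path, "w") as fh:
        fh.write(",".join(AMPLITUDE_COLUMNS) + "\n")
        for w in wells:
            for a in w.amplitudes:
                fh.write(f"{w.well_id},{channel},{a:.4f}\n")


def write_layout(layout: PlateLayout, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(LAYOUT_COLUMNS) + "\n")
        for w in layout:
            fh.write(f"{w.well_id},{w.sample_id},{w.target},{w.rt_condition},"
                     f"{w.dilution_chain_id},{w.replicate_index}\n")
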