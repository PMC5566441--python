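"""End-to-end orchestration: config -> read -> classify -> quantify -> metrics.

A run is driven by a single YAML config (the CLI only overrides keys).  It
emits three delimited tables — classified counts, concentrations, derived
metrics — plus a JSON manifest recording the config hash, seed, software
version and the well ids behind every reported number, so each figure in a
report traces back to raw droplets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats as _stats

from . import __version__
from .classify import ClassifiedCounts, classify_well
from .droplet_io import (DilutionChain, DropletWell, METHODS_CHAIN,
                         read_amplitude_table, read_layout)
from .errors import ContractError, ValidationError
from .quantify import (ConcentrationEstimate, DEFAULT_DROPLET_VOLUME_NL,
                       DROPLET_FLOOR, DYNAMIC_RANGE_CEILING, NTC_CEILING,
                       SUBSAMPLING_CAP, estimate_lambda, merge_wells, qc_flags,
                       to_sample_concentration)
from .selfie_metrics import (SelfiePair, aggregate_replicates,
                             copies_per_genome_from_estimates,
                             transcripts_per_gene_from_pair,
                             transcripts_per_genome)


@dataclass
class RunConfig:
    """Validated run configuration (single source of truth for a run)."""

    amplitude_table: str
    layout: str
    dilution_chains: dict[str, DilutionChain] = field(default_factory=dict)
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    ci_level: float = 0.95
    dynamic_range_ceiling: float = DYNAMIC_RANGE_CEILING
    droplet_floor: int = DROPLET_FLOOR
    ntc_ceiling: int = NTC_CEILING
    subsampling_cap: float = SUBSAMPLING_CAP
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    single_copy_reference: str | None = None
    seed: int = 0
    require_ntc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ContractError("ci_level must be in (0, 1)")
        for name in ("dynamic_range_ceiling", "droplet_floor", "ntc_ceiling",
                     "subsampling_cap"):
            if getattr(self, name) <= 0 and name != "ntc_ceiling":
                raise ContractError(f"{name} must be positive")
        self.dilution_chains.setdefault("default", METHODS_CHAIN)


def _chain_from_dict(d: dict) -> DilutionChain:
    return DilutionChain(
        sample_input_volume=float(d["sample_input_volume"]),
        steps=tuple((float(a), float(b)) for a, b in d["steps"]),
        reaction_volume=float(d["reaction_volume"]),
    )


def _chain_to_dict(c: DilutionChain) -> dict:
    return {"sample_input_volume": c.sample_input_volume,
            "steps": [list(s) for s in c.steps],
            "reaction_volume": c.reaction_volume}


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    chains = {k: _chain_from_dict(v)
              for k, v in (raw.get("dilution_chains") or {}).items()}
    base = Path(path).parent

    def _resolve(p: str) -> str:
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    return RunConfig(
        amplitude_table=_resolve(raw["amplitude_table"]),
        layout=_resolve(raw["layout"]),
        dilution_chains=chains,
        droplet_volume_nl=float(raw.get("droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)),
        ci_level=float(raw.get("ci_level", 0.95)),
        dynamic_range_ceiling=float(raw.get("dynamic_range_ceiling", DYNAMIC_RANGE_CEILING)),
        droplet_floor=int(raw.get("droplet_floor", DROPLET_FLOOR)),
        ntc_ceiling=int(raw.get("ntc_ceiling", NTC_CEILING)),
        subsampling_cap=float(raw.get("subsampling_cap", SUBSAMPLING_CAP)),
        manual_thresholds={k: float(v)
                           for k, v in (raw.get("manual_thresholds") or {}).items()},
        single_copy_reference=raw.get("single_copy_reference"),
        seed=int(raw.get("seed", 0)),
        require_ntc=bool(raw.get("require_ntc", True)),
    )


def config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["dilution_chains"] = {k: _chain_to_dict(v)
                                  for k, v in config.dilution_chains.items()}
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    counts: list[ClassifiedCounts]
    concentrations: list[ConcentrationEstimate]
    metrics: list[dict]
    manifest: dict


def run(config: RunConfig) -> RunResult:
    """Execute the full analysis for one plate."""
    layout = read_layout(config.layout, require_ntc=config.require_ntc)
    wells = read_amplitude_table(config.amplitude_table, layout)

    # --- classify ----------------------------------------------------------
    counts: dict[str, ClassifiedCounts] = {}
    chain_by_well: dict[str, str] = {}
    for w in wells:
        thr = config.manual_thresholds.get(w.target)
        counts[w.well_id] = classify_well(w, manual_threshold=thr)
        chain_by_well[w.well_id] = w.dilution_chain_id

    ntc_by_target: dict[str, ClassifiedCounts] = {}
    for w in wells:
        if w.rt_condition == "NTC":
            prev = ntc_by_target.get(w.target)
            cur = counts[w.well_id]
            if prev is None or cur.positives > prev.positives:
                ntc_by_target[w.target] = cur

    # --- quantify ----------------------------------------------------------
    concentrations: dict[str, ConcentrationEstimate] = {}
    for w in wells:
        if w.rt_condition == "NTC":
            continue
        chain = config.dilution_chains.get(w.dilution_chain_id)
        if chain is None:
            raise ValidationError(
                f"well {w.well_id}: unknown dilution chain {w.dilution_chain_id!r}")
        est = to_sample_concentration(
            estimate_lambda(counts[w.well_id]), chain,
            droplet_volume_nl=config.droplet_volume_nl, level=config.ci_level,
            sample_id=w.sample_id, target=w.target, rt_condition=w.rt_condition)
        est = dataclasses.replace(est, flags=qc_flags(
            est, ntc_counts=ntc_by_target.get(w.target),
            dynamic_range_ceiling=config.dynamic_range_ceiling,
            droplet_floor=config.droplet_floor,
            subsampling_cap=config.subsampling_cap,
            ntc_ceiling=config.ntc_ceiling))
        concentrations[w.well_id] = est

    # --- metrics -----------------------------------------------------------
    meta = layout.by_well_id()
    by_cond: dict[tuple[str, str, str, int], list[str]] = {}
    for w in wells:
        if w.rt_condition == "NTC":
            continue
        key = (w.sample_id, w.target, w.rt_condition, w.replicate_index)
        by_cond.setdefault(key, []).append(w.well_id)

    metrics: list[dict] = []
    trace: dict[str, list[str]] = {}
    tpg_by_sample_target: dict[tuple[str, str], list[float]] = {}
    rtminus_by_sample_target: dict[tuple[str, str], dict[int, ConcentrationEstimate]] = {}

    pair_keys = sorted({(s, t) for (s, t, c, r) in by_cond if c == "RT_PLUS"})
    for sample, target in pair_keys:
        reps = sorted({r for (s, t, c, r) in by_cond
                       if s == sample and t == target and c == "RT_PLUS"})
        per_rep = []
        well_ids: list[str] = []
        flags: set[str] = set()
        for rep in reps:
            plus_ids = by_cond.get((sample, target, "RT_PLUS", rep), [])
            minus_ids = by_cond.get((sample, target, "RT_MINUS", rep), [])
            if not minus_ids:
                raise ValidationError(
                    f"{sample}/{target} replicate {rep}: RT- partner missing")
            ep = concentrations[plus_ids[0]] if len(plus_ids) == 1 else None
            em = concentrations[minus_ids[0]] if len(minus_ids) == 1 else None
            if ep is None or em is None:
                raise ValidationError(
                    f"{sample}/{target} replicate {rep}: expected one well per condition")
            well_ids += plus_ids + minus_ids
            flags |= ep.flags | em.flags
            rtminus_by_sample_target.setdefault((sample, target), {})[rep] = em
            if ep.saturated or em.saturated or em.copies_per_ul_sample <= 0:
                continue
            pair = SelfiePair(sample, target, ep, em)
            per_rep.append(transcripts_per_gene_from_pair(pair, level=config.ci_level))
        if not per_rep:
            continue
        values = [r.transcripts_per_gene for r in per_rep]
        tpg_by_sample_target[(sample, target)] = values
        mean, sem, n = aggregate_replicates(values)
        if n >= 2 and sem is not None:
            z = float(_stats.norm.ppf(0.5 + config.ci_level / 2))
            lo, hi = mean - z * sem, mean + z * sem
        else:
            lo, hi = per_rep[0].ci_low, per_rep[0].ci_high
        key = f"{sample}/{target}/transcripts_per_gene"
        trace[key] = sorted(well_ids)
        metrics.append(dict(sample=sample, target=target,
                            metric="transcripts_per_gene",
                            estimate=mean, ci_low=lo, ci_high=hi, n=n,
                            flags=";".join(sorted(flags))))

    ref = config.single_copy_reference
    if ref is not None:
        for sample, target in pair_keys:
            if target == ref or (sample, target) not in rtminus_by_sample_target:
                continue
            ref_reps = rtminus_by_sample_target.get((sample, ref))
            if not ref_reps:
                continue
            ratios = []
            for rep, em in rtminus_by_sample_target[(sample, target)].items():
                er = ref_reps.get(rep) or next(iter(ref_reps.values()))
                if em.saturated or er.saturated or er.copies_per_ul_sample <= 0:
                    continue
                ratios.append(copies_per_genome_from_estimates(
                    em, er, level=config.ci_level).copies_per_genome)
            if not ratios:
                continue
            mean, sem, n = aggregate_replicates(ratios)
            z = float(_stats.norm.ppf(0.5 + config.ci_level / 2))
            half = z * sem if sem is not None else math.nan
            metrics.append(dict(sample=sample, target=target,
                                metric="copies_per_genome",
                                estimate=mean, ci_low=mean - half,
                                ci_high=mean + half, n=n, flags=""))
            tpg = tpg_by_sample_target.get((sample, target))
            if tpg:
                tpgenome = [transcripts_per_genome(t, c)
                            for t, c in zip(tpg, ratios)]
                gmean, gsem, gn = aggregate_replicates(tpgenome)
                ghalf = z * gsem if gsem is not None else math.nan
                metrics.append(dict(sample=sample, target=target,
                                    metric="transcripts_per_genome",
                                    estimate=gmean, ci_low=gmean - ghalf,
                                    ci_high=gmean + ghalf, n=gn, flags=""))

    manifest = {
        "software": "selfiedpcr",
        "version": __version__,
        "config_sha256": config_hash(config),
        "seed": config.seed,
        "inputs": {"amplitude_table": str(config.amplitude_table),
                   "layout": str(config.layout)},
        "wells_per_metric": trace,
        "n_wells": len(wells),
    }
    return RunResult(counts=[counts[w.well_id] for w in wells],
                     concentrations=[concentrations[w.well_id] for w in wells
                                     if w.well_id in concentrations],
                     metrics=metrics, manifest=manifest)


# ---------------------------------------------------------------------------
# Report writing (byte-deterministic formats)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return "nan"
        return f"{x:.10g}"
    return str(x)


def write_counts_table(counts: list[ClassifiedCounts], path) -> None:
    with open(path, "w") as fh:
        fh.write("well,target,rt_condition,positives,negatives,total,threshold,method\n")
        for c in counts:
            well = ";".join(w for w, _ in c.sources)
            fh.write(f"{well},{c.target},{c.rt_condition},{c.positives},"
                     f"{c.negatives},{c.total},{_fmt(c.threshold)},{c.method}\n")


def write_concentration_table(ests: list[ConcentrationEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample,target,rt_condition,lambda,copies_per_reaction,"
                 "copies_per_ul_sample,ci_low,ci_high,flags\n")
        for e in ests:
            flags = ";".join(sorted(e.flags))
            fh.write(f"{e.sample_id},{e.target},{e.rt_condition},{_fmt(e.lam)},"
                     f"{_fmt(e.copies_per_reaction)},{_fmt(e.copies_per_ul_sample)},"
                     f"{_fmt(e.ci_low)},{_fmt(e.ci_high)},{flags}\n")


def write_metrics_table(metrics: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample,target,metric,estimate,ci_low,ci_high,n,flags\n")
        for m in metrics:
            fh.write(f"{m['sample']},{m['target']},{m['metric']},"
                     f"{_fmt(m['estimate'])},{_fmt(m['ci_low'])},"
                     f"{_fmt(m['ci_high'])},{m['n']},{m['flags']}\n")


def write_outputs(result: RunResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_table(result.counts, outdir / "counts.csv")
    write_concentration_table(result.concentrations, outdir / "concentrations.csv")
    write_metrics_table(result.metrics, outdir / "metrics.csv")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
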