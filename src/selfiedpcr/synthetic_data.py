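"""Generative model of paired RT+/RT- droplet experiments.

The simulator replaces the wet lab end to end: it draws molecule counts for
one reaction, partitions them into droplets, renders per-droplet fluorescence
amplitudes, and writes the same delimited files a droplet reader export would
provide — together with a ground-truth record for every intermediate count.

Generative model for one sample/target:

* amplifiable gene fragments per reaction ~ Poisson(genomes/µl · v_eff ·
  copies_per_genome / copies_per_fragment), where v_eff is the dilution
  chain's effective sample volume and ``copies_per_fragment`` models tandem
  copies left on one restriction fragment (1 = fully digested);
* transcripts per reaction ~ Poisson(genomes/µl · v_eff · copies_per_genome ·
  transcripts_per_gene); cDNA ~ Binomial(transcripts, rt_efficiency) and is
  present only in the RT+ aliquot;
* molecules are assigned to droplets by a multinomial throw (equivalent to
  independent Poisson occupancy); a droplet is positive when it holds >= 1
  amplifiable molecule;
* amplitudes are Gaussian around mu_neg / mu_pos with common sigma; an
  optional "rain" fraction of droplets is redrawn uniformly between the two
  modes.  The amplitude model is a fixture convention, not an instrument
  claim.

Enzyme treatments are modeled as multiplicative survival fractions on the
RNA and DNA pools (an RNase leaves ~0 RNA and ~81% DNA; a double-strand
specific DNase leaves ~10% DNA), enabling in-silico nuclease-validation
experiments.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .droplet_io import (DilutionChain, DropletWell, METHODS_CHAIN, PlateLayout,
                         WellMeta, effective_sample_volume,
                         write_amplitude_table, write_layout)
from .errors import ContractError, SaturationError

#: Fixture amplitude constants (arbitrary fluorescence units).
DEFAULT_MU_NEG = 2000.0
DEFAULT_MU_POS = 9000.0
DEFAULT_SIGMA = 300.0
DEFAULT_RAIN = 0.01

#: Refuse scenarios beyond this mean occupancy per droplet.
MAX_OCCUPANCY = 50.0

#: Survival fractions for in-silico nuclease treatments.
RNASE_TREATMENT = {"rna_survival": 0.0, "dna_survival": 0.81}
DSDNASE_TREATMENT = {"rna_survival": 0.95, "dna_survival": 0.10}


@dataclass(frozen=True)
class SimulationParams:
    """Ground truth of the generative model for one sample/target pair.

    Defaults emulate a whole-brain lysate assayed for a single-copy nuclear
    gene: ~608 gene copies per reaction (12160 genomes/µl through the default
    0.05 µl effective sample volume) carrying 1.95 transcripts per gene, in
    20,000 droplets.
    """

    genomes_per_ul: float = 12160.0
    gene_copies_per_genome: float = 1.0
    transcripts_per_gene: float = 1.95
    rt_efficiency: float = 1.0
    copies_per_fragment: int = 1
    droplet_count: int = 20000
    droplet_volume_nl: float = 0.85
    dilution_chain: DilutionChain = METHODS_CHAIN
    mu_neg: float = DEFAULT_MU_NEG
    mu_pos: float = DEFAULT_MU_POS
    sigma: float = DEFAULT_SIGMA
    rain_fraction: float = DEFAULT_RAIN
    rna_survival: float = 1.0
    dna_survival: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genomes_per_ul < 0 or self.gene_copies_per_genome < 0:
            raise ContractError("densities and copy numbers must be >= 0")
        if self.transcripts_per_gene < 0:
            raise ContractError("transcripts_per_gene must be >= 0")
        if not 0 < self.rt_efficiency <= 1:
            raise ContractError("rt_efficiency must be in (0, 1]")
        if self.copies_per_fragment < 1:
            raise ContractError("copies_per_fragment must be >= 1")
        if not 0 <= self.rain_fraction <= 0.2:
            raise ContractError("rain_fraction must be in [0, 0.2]")
        if self.droplet_count < 1:
            raise ContractError("droplet_count must be >= 1")
        if self.mu_pos <= self.mu_neg:
            raise ContractError("mu_pos must exceed mu_neg")

    @property
    def effective_sample_volume(self) -> float:
        return effective_sample_volume(self.dilution_chain)

    @property
    def mean_gene_copies_per_reaction(self) -> float:
        return (self.genomes_per_ul * self.effective_sample_volume
                * self.gene_copies_per_genome * self.dna_survival)

    @property
    def mean_fragments_per_reaction(self) -> float:
        return self.mean_gene_copies_per_reaction / self.copies_per_fragment

    @property
    def mean_transcripts_per_reaction(self) -> float:
        return (self.genomes_per_ul * self.effective_sample_volume
                * self.gene_copies_per_genome * self.transcripts_per_gene
                * self.rna_survival)


def _partition(n_molecules: int, n_droplets: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial throw of molecules into droplets; returns per-droplet counts."""
    if n_molecules == 0:
        return np.zeros(n_droplets, dtype=np.int64)
    return rng.multinomial(n_molecules, np.full(n_droplets, 1.0 / n_droplets))


def _amplitudes(occupied: np.ndarray, params: SimulationParams,
                rng: np.random.Generator) -> np.ndarray:
    # Rain is partial amplification of template-containing droplets, so the
    # uniform intermediate amplitudes are drawn from the occupied population.
    n = occupied.size
    amps = rng.normal(params.mu_neg, params.sigma, size=n)
    occ_idx = np.flatnonzero(occupied)
    amps[occ_idx] = rng.normal(params.mu_pos, params.sigma, size=occ_idx.size)
    n_rain = int(math.floor(params.rain_fraction * occ_idx.size))
    if n_rain:
        idx = rng.choice(occ_idx, size=n_rain, replace=False)
        amps[idx] = rng.uniform(params.mu_neg, params.mu_pos, size=n_rain)
    return amps


def _simulate_well(params: SimulationParams, n_molecules: int, well_id: str,
                   sample_id: str, target: str, rt_condition: str,
                   rng: np.random.Generator) -> tuple[DropletWell, np.ndarray]:
    counts = _partition(n_molecules, params.droplet_count, rng)
    occupied = counts > 0
    amps = _amplitudes(occupied, params, rng)
    well = DropletWell(well_id=well_id, sample_id=sample_id, target=target,
                       rt_condition=rt_condition, amplitudes=amps)
    return well, counts


def simulate_selfie_pair(params: SimulationParams,
                         rng: np.random.Generator | None = None,
                         sample_id: str = "sample", target: str = "target",
                         well_prefix: str = "A") -> tuple[DropletWell, DropletWell, dict]:
    """Simulate one RT+/RT- duplicate pair and return both wells plus truth.

    The two aliquots draw their molecule counts independently (they are
    physically separate sub-samples of the lysate).  The RT- well contains
    gene fragments only; the RT+ well additionally contains cDNA.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    mean_total_plus = (params.mean_fragments_per_reaction
                       + params.mean_transcripts_per_reaction)
    if mean_total_plus / params.droplet_count > MAX_OCCUPANCY:
        raise SaturationError(
            f"expected occupancy {mean_total_plus / params.droplet_count:.1f} "
            f"copies/droplet exceeds {MAX_OCCUPANCY}")

    frag_minus = int(rng.poisson(params.mean_fragments_per_reaction))
    frag_plus = int(rng.poisson(params.mean_fragments_per_reaction))
    transcripts = int(rng.poisson(params.mean_transcripts_per_reaction))
    cdna = int(rng.binomial(transcripts, params.rt_efficiency)) if transcripts else 0

    well_plus, counts_plus = _simulate_well(
        params, frag_plus + cdna, f"{well_prefix}01", sample_id, target,
        "RT_PLUS", rng)
    well_minus, counts_minus = _simulate_well(
        params, frag_minus, f"{well_prefix}02", sample_id, target,
        "RT_MINUS", rng)

    truth = {
        "params": params,
        "fragments_rt_minus": frag_minus,
        "fragments_rt_plus": frag_plus,
        "transcripts": transcripts,
        "cdna": cdna,
        "molecules_rt_plus": frag_plus + cdna,
        "molecules_rt_minus": frag_minus,
        "occupied_rt_plus": int(np.count_nonzero(counts_plus)),
        "occupied_rt_minus": int(np.count_nonzero(counts_minus)),
        "droplet_counts_rt_plus": counts_plus,
        "droplet_counts_rt_minus": counts_minus,
        "lambda_true_rt_plus": (frag_plus + cdna) / params.droplet_count,
        "lambda_true_rt_minus": frag_minus / params.droplet_count,
    }
    return well_plus, well_minus, truth


# ---------------------------------------------------------------------------
# Tissue panel
# ---------------------------------------------------------------------------

#: Per-tissue ground truth for the default panel: transcripts per gene of a
#: single-copy nuclear gene, of a ~107-copy ribosomal gene, mtDNA copies per
#: genome and per-strand mtDNA transcription (transcripts per mtDNA copy).
TISSUE_PANEL_TRUTH: dict[str, dict[str, float]] = {
    "brain": dict(single_copy_tpg=2.03, rna18s_tpg=349.0, mtdna_cpg=1096.0,
                  t_h=0.55, t_l=0.37),
    "heart": dict(single_copy_tpg=0.0, rna18s_tpg=1496.0, mtdna_cpg=2302.0,
                  t_h=0.58, t_l=0.37),
    "liver": dict(single_copy_tpg=0.25, rna18s_tpg=27.0, mtdna_cpg=1759.0,
                  t_h=1.70, t_l=0.44),
    "skeletal_muscle": dict(single_copy_tpg=0.25, rna18s_tpg=6.0, mtdna_cpg=1774.0,
                            t_h=0.56, t_l=0.36),
}

RNA18S_COPIES_PER_GENOME = 107.0

#: Target names used by the panel generator.
TARGET_SINGLE_COPY = "Gsk3b-81"
TARGET_RNA18S = "RNA18S-97"
TARGET_MTDNA_H = "mtDNA-67-H"
TARGET_MTDNA_L = "mtDNA-67-L"
TARGET_MTDNA_HL = "mtDNA-67-HL"


def _auto_dilution(expected_rt_plus_copies: float, droplet_count: int,
                   target_lambda: float = 3.5) -> float:
    """Extra dilution bringing expected RT+ occupancy down to target_lambda.

    A high working occupancy (still within the dynamic range) keeps the RT-
    aliquot of strongly transcribed targets countable in the same reaction.
    """
    if expected_rt_plus_copies <= 0:
        return 1.0
    lam = expected_rt_plus_copies / droplet_count
    if lam <= target_lambda:
        return 1.0
    return round(lam / target_lambda, 3)


def _diluted_chain(base: DilutionChain, factor: float) -> DilutionChain:
    if factor == 1.0:
        return base
    return DilutionChain(base.sample_input_volume,
                         base.steps + ((1.0, float(factor)),),
                         base.reaction_volume)


@dataclass
class PanelResult:
    wells: list[DropletWell]
    layout: PlateLayout
    chains: dict[str, DilutionChain]
    truth: dict


def simulate_tissue_panel(truth: dict[str, dict[str, float]] | None = None,
                          n_replicates: int = 3,
                          genomes_per_ul: float = 12160.0,
                          droplet_count: int = 20000,
                          rain_fraction: float = DEFAULT_RAIN,
                          seed: int = 0) -> PanelResult:
    """Simulate a multi-tissue plate: single-copy reference, a multi-copy
    ribosomal target and strand-specific mtDNA targets, each as RT+/RT-
    replicate pairs plus one NTC per target.

    Each target gets an automatic extra decade dilution keeping its RT+
    occupancy within the dynamic range, mirroring the practice of adjusting
    the analyzed sample volume per target; the per-target chains are returned
    so concentrations back-calculate onto a common per-sample scale.
    """
    truth = TISSUE_PANEL_TRUTH if truth is None else truth
    rng = np.random.default_rng(seed)
    wells: list[DropletWell] = []
    metas: list[WellMeta] = []
    chains: dict[str, DilutionChain] = {}
    record: dict = {"seed": seed, "n_replicates": n_replicates, "tissues": {}}

    target_specs = {
        TARGET_SINGLE_COPY: ("single_copy_tpg", 1.0),
        TARGET_RNA18S: ("rna18s_tpg", RNA18S_COPIES_PER_GENOME),
        TARGET_MTDNA_H: ("t_h", None),
        TARGET_MTDNA_L: ("t_l", None),
        TARGET_MTDNA_HL: (("t_h", "t_l"), None),
    }

    well_counter = 0

    def next_well_id() -> str:
        nonlocal well_counter
        row = chr(ord("A") + well_counter // 24)
        col = well_counter % 24 + 1
        well_counter += 1
        return f"{row}{col:02d}"

    for tissue, t in truth.items():
        record["tissues"][tissue] = dict(t)
        for target, (tpg_key, cpg) in target_specs.items():
            if isinstance(tpg_key, tuple):
                tpg = sum(t[k] for k in tpg_key)
            else:
                tpg = t[tpg_key]
            copies_per_genome = cpg if cpg is not None else t["mtdna_cpg"]
            expected_plus = (genomes_per_ul * effective_sample_volume(METHODS_CHAIN)
                             * copies_per_genome * (1.0 + tpg))
            factor = _auto_dilution(expected_plus, droplet_count)
            chain_id = f"{target}-d{factor:g}"
            chain = _diluted_chain(METHODS_CHAIN, factor)
            chains[chain_id] = chain
            params = SimulationParams(
                genomes_per_ul=genomes_per_ul,
                gene_copies_per_genome=copies_per_genome,
                transcripts_per_gene=tpg,
                droplet_count=droplet_count,
                dilution_chain=chain,
                rain_fraction=rain_fraction,
                seed=seed)
            for rep in range(n_replicates):
                wp, wm, _ = simulate_selfie_pair(
                    params, rng=rng, sample_id=tissue, target=target)
                for w, cond in ((wp, "RT_PLUS"), (wm, "RT_MINUS")):
                    wid = next_well_id()
                    w.well_id = wid
                    w.dilution_chain_id = chain_id
                    w.replicate_index = rep
                    wells.append(w)
                    metas.append(WellMeta(wid, tissue, target, cond, chain_id, rep))

    # one NTC per target (shared across tissues on the plate)
    for target in target_specs:
        wid = next_well_id()
        amps = rng.normal(DEFAULT_MU_NEG, DEFAULT_SIGMA, droplet_count)
        wells.append(DropletWell(well_id=wid, sample_id="NTC", target=target,
                                 rt_condition="NTC", amplitudes=amps))
        metas.append(WellMeta(wid, "NTC", target, "NTC", "default", 0))
    chains.setdefault("default", METHODS_CHAIN)

    layout = PlateLayout(tuple(metas))
    return PanelResult(wells=wells, layout=layout, chains=chains, truth=record)


# ---------------------------------------------------------------------------
# Tandem-linkage bias experiment
# ---------------------------------------------------------------------------

def linkage_bias_experiment(copies_per_fragment_grid: list[int],
                            gene_copies_per_genome: float = RNA18S_COPIES_PER_GENOME,
                            genomes_per_ul: float = 12160.0,
                            droplet_count: int = 20000,
                            n_wells: int = 4,
                            seed: int = 0) -> list[dict]:
    """Estimated copies/genome of a multi-copy target vs residual linkage.

    For each grid value the target is simulated with that many tandem copies
    left per undigested fragment and quantified against a fully digested
    single-copy reference on the same sample.  At copies_per_fragment = 1 the
    estimate recovers the true copy number; at full linkage it collapses to
    ~1 amplifiable fragment per genome.
    """
    from .classify import classify_well
    from .quantify import estimate_lambda

    rng = np.random.default_rng(seed)
    results = []
    for cpf in copies_per_fragment_grid:
        lam_t = 0.0
        lam_r = 0.0
        dil_t = None
        for _ in range(n_wells):
            expected = (genomes_per_ul * effective_sample_volume(METHODS_CHAIN)
                        * gene_copies_per_genome / cpf)
            factor = _auto_dilution(expected, droplet_count)
            dil_t = factor
            chain = _diluted_chain(METHODS_CHAIN, factor)
            target_params = SimulationParams(
                genomes_per_ul=genomes_per_ul,
                gene_copies_per_genome=gene_copies_per_genome,
                transcripts_per_gene=0.0, copies_per_fragment=cpf,
                droplet_count=droplet_count, dilution_chain=chain,
                rain_fraction=0.0, seed=seed)
            ref_params = dataclasses.replace(
                target_params, gene_copies_per_genome=1.0, copies_per_fragment=1,
                dilution_chain=METHODS_CHAIN)
            _, wm_t, _ = simulate_selfie_pair(target_params, rng=rng)
            _, wm_r, _ = simulate_selfie_pair(ref_params, rng=rng)
            lam_t += estimate_lambda(classify_well(wm_t)).lam * factor
            lam_r += estimate_lambda(classify_well(wm_r)).lam
        results.append({
            "copies_per_fragment": cpf,
            "estimated_copies_per_genome": lam_t / lam_r,
            "extra_dilution": dil_t,
        })
    return results


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_amplitude_csv(wells, path) -> None:
    """Emit the droplet_io amplitude dialect (alias kept for discoverability)."""
    write_amplitude_table(wells, path)


def write_truth_json(truth: dict, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            d = dataclasses.asdict(o)
            return d
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")
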