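"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: a proteome with a
consistent CDS and realistic proline-codon usage, post-search PSM tables
with injected substitutions, false identifications and decoys, logistic
growth curves on a 15-minute grid, and reporter-fluorescence tables.

Substitution is modelled at the detection level: a detected proline-
containing peptide yields a serine-substituted detection per proline site
with the per-codon probability p_c. Under this model the detection-fraction
statistic estimates p_c without bias, so generator/estimator round trips
test the pipeline against exact ground truth. The mapping from molecular
substitution rates to detection probabilities (ionization, abundance,
spectral quality) is deliberately not modelled.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .digest import build_peptide_index
from .proteome import CODON_TABLE, ProteinRecord, Proteome, write_proteome
from .psm import (
    ModKind,
    Modification,
    PSMRecord,
    generate_decoy_proteome,
    peptide_monoisotopic_mass,
    psms_to_frame,
)

#: amino-acid composition loosely following the yeast proteome
DEFAULT_AA_FREQS: Dict[str, float] = {
    "A": 0.055, "C": 0.013, "D": 0.058, "E": 0.065, "F": 0.045,
    "G": 0.050, "H": 0.022, "I": 0.065, "K": 0.073, "L": 0.095,
    "M": 0.021, "N": 0.061, "P": 0.044, "Q": 0.039, "R": 0.044,
    "S": 0.090, "T": 0.059, "V": 0.056, "W": 0.010, "Y": 0.034,
}

#: proline-codon usage, CCA most used as in yeast
DEFAULT_CODON_WEIGHTS: Dict[str, float] = {
    "CCA": 0.45, "CCU": 0.30, "CCC": 0.13, "CCG": 0.12,
}

#: synonymous DNA codons per residue (no stops)
_SYNONYMS: Dict[str, List[str]] = {}
for _codon, _aa in CODON_TABLE.items():
    _SYNONYMS.setdefault(_aa, []).append(_codon)
for _aa in _SYNONYMS:
    _SYNONYMS[_aa].sort()


@dataclass
class StrainGrowth:
    """Logistic growth parameters of one strain."""

    K: float = 1.2  # carrying capacity, OD600
    N0: float = 0.1  # inoculum, OD600
    doubling_time_min: float = 65.5
    noise_sd: float = 0.01  # additive OD noise


@dataclass
class SimulationConfig:
    """All knobs of the generators; seed is mandatory."""

    seed: int
    # proteome
    n_proteins: int = 500
    protein_len_mean: float = 250.0
    protein_len_sd: float = 50.0
    protein_len_min: int = 30
    aa_freqs: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_AA_FREQS))
    codon_weights: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CODON_WEIGHTS)
    )
    # digestion (mirrors the search settings)
    max_missed: int = 2
    min_len: int = 6
    max_len: Optional[int] = 50
    # PSM generation
    n_replicates: int = 3
    detection_prob: float = 0.3
    p_codon: Dict[str, float] = field(
        default_factory=lambda: {"CCA": 0.02, "CCG": 0.01, "CCU": 0.01, "CCC": 0.01}
    )
    oxidation_rate: float = 0.05  # on detected PSMs containing M
    acetyl_rate: float = 0.02  # extra acetylation on substituted PSMs
    withheld_base_rate: float = 0.05  # substituted PSMs whose base PSM is removed
    id_error_rate: float = 0.01  # fraction of target PSMs that are false
    false_sub_prob: float = 0.5  # false IDs landing on a substituted form
    correct_score_mean: float = 4.0
    correct_score_sd: float = 1.0
    incorrect_score_mean: float = 0.0
    incorrect_score_sd: float = 1.0
    ppm_jitter_sd: float = 5.0  # precursor mass error, ppm
    # growth curves: 15-min grid over 24 h
    sample_interval_min: float = 15.0
    duration_min: float = 1440.0
    growth_strains: Dict[str, StrainGrowth] = field(
        default_factory=lambda: {
            "reference": StrainGrowth(doubling_time_min=65.5),
            "G26A": StrainGrowth(doubling_time_min=88.9),
            "U39G": StrainGrowth(doubling_time_min=129.0),
        }
    )
    # fluorescence reporter
    heat_shock_folds: Dict[str, float] = field(
        default_factory=lambda: {"reference": 1.0, "G26A": 3.2, "U39G": 2.4}
    )
    fluor_cv: float = 0.10  # lognormal replicate noise
    fluor_replicates: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("detection_prob", "oxidation_rate", "acetyl_rate",
                     "withheld_base_rate", "id_error_rate", "false_sub_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for codon, p in self.p_codon.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_codon[{codon}]={p} outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "growth_strains" in data:
            data["growth_strains"] = {
                k: StrainGrowth(**v) for k, v in data["growth_strains"].items()
            }
        return cls(**data)


def _stage_rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    """Per-stage generator derived deterministically from the config seed."""
    return np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(stage + 1)[stage])


def gen_proteome(cfg: SimulationConfig) -> Proteome:
    """Random proteome with i.i.d. residues and configured P-codon usage.

    Non-proline residues take a synonymous codon uniformly at random; every
    proline codon is drawn from ``cfg.codon_weights``.
    """
    if cfg.aa_freqs.get("K", 0.0) <= 0.0:
        import warnings

        warnings.warn("zero lysine frequency: LysC digestion will be degenerate")
    rng = _stage_rng(cfg, 0)
    aas = sorted(cfg.aa_freqs)
    probs = np.array([cfg.aa_freqs[a] for a in aas], dtype=float)
    probs = probs / probs.sum()
    codons = sorted(cfg.codon_weights)
    cweights = np.array([cfg.codon_weights[c] for c in codons], dtype=float)
    cweights = cweights / cweights.sum()
    proteome = Proteome()
    for i in range(cfg.n_proteins):
        length = max(
            cfg.protein_len_min,
            int(round(rng.normal(cfg.protein_len_mean, cfg.protein_len_sd))),
        )
        aa_seq = "".join(rng.choice(aas, size=length, p=probs))
        cds_parts = []
        for aa in aa_seq:
            if aa == "P":
                cds_parts.append(codons[rng.choice(len(codons), p=cweights)].replace("U", "T"))
            else:
                syn = _SYNONYMS[aa]
                cds_parts.append(syn[rng.integers(len(syn))])
        proteome.add(ProteinRecord(f"prot{i + 1:04d}", aa_seq, "".join(cds_parts)))
    return proteome


def _jittered_mass(seq: str, mods, rng: np.random.Generator, ppm_sd: float) -> float:
    m = peptide_monoisotopic_mass(seq, mods)
    return m * (1.0 + rng.normal(0.0, ppm_sd) * 1e-6)


def gen_psm_dataset(
    proteome: Proteome,
    cfg: SimulationConfig,
    index=None,
    decoy_index=None,
) -> Tuple[List[PSMRecord], pd.DataFrame]:
    """Generate post-search PSMs plus the ground-truth substitution table.

    Per replicate: every distinct digest peptide is detected with
    ``detection_prob`` as a base PSM (correct-score distribution); each
    detected proline site additionally yields a substituted PSM with the
    probability of its codon. Configured fractions of substituted PSMs
    receive an extra modification or lose their base PSM, exercising the
    stringent filters. False target PSMs (random index peptides, half of
    them substituted by default) and decoy PSMs are drawn from the
    incorrect-score distribution with matching count distributions.

    Prebuilt target/decoy peptide indexes may be passed to avoid rebuilding
    them when many datasets are generated from one proteome.
    """
    rng = _stage_rng(cfg, 1)
    if index is None:
        index = build_peptide_index(
            proteome, max_missed=cfg.max_missed, min_len=cfg.min_len,
            max_len=cfg.max_len,
        )
    if decoy_index is None:
        decoy_index = build_peptide_index(
            generate_decoy_proteome(proteome),
            max_missed=cfg.max_missed,
            min_len=cfg.min_len,
            max_len=cfg.max_len,
        )
    all_seqs = sorted(e.seq for e in index)
    decoy_seqs = sorted(e.seq for e in decoy_index)
    psms: List[PSMRecord] = []
    truth_rows = []
    spectrum_counter = 0

    def next_id() -> str:
        nonlocal spectrum_counter
        spectrum_counter += 1
        return f"scan{spectrum_counter:07d}"

    for rep_i in range(cfg.n_replicates):
        rep = f"rep{rep_i + 1}"
        detected = [s for s in all_seqs if rng.random() < cfg.detection_prob]
        withheld: set = set()
        rep_psms: List[PSMRecord] = []
        # substituted detections first, so base withholding can apply
        for seq in detected:
            entry = index.lookup(seq)
            if not entry.proline_positions:
                continue
            site_codons = [
                (p, index.codons_at(seq, p)[0]) for p in entry.proline_positions
            ]
            sub_sites = [
                (p, c)
                for p, c in site_codons
                if rng.random() < cfg.p_codon.get(c, 0.0)
            ]
            for p, codon in sub_sites:
                mods = [Modification(ModKind.PRO_TO_SER, p)]
                extra = rng.random() < cfg.acetyl_rate
                if extra:
                    mods.append(Modification(ModKind.ACETYL_NTERM))
                base_withheld = rng.random() < cfg.withheld_base_rate
                if base_withheld:
                    withheld.add(seq)
                rep_psms.append(
                    PSMRecord(
                        spectrum_id=next_id(),
                        base_seq=seq,
                        mods=tuple(mods),
                        observed_mass=_jittered_mass(seq, mods, rng, cfg.ppm_jitter_sd),
                        score=rng.normal(cfg.correct_score_mean, cfg.correct_score_sd),
                        is_decoy=False,
                        replicate_id=rep,
                    )
                )
                truth_rows.append(
                    {
                        "replicate_id": rep,
                        "base_seq": seq,
                        "peptide_position": p + 1,
                        "codon": codon,
                        "extra_modification": int(extra),
                        "base_withheld": int(base_withheld),
                    }
                )
        for seq in detected:
            if seq in withheld:
                continue
            mods = []
            if "M" in seq and rng.random() < cfg.oxidation_rate:
                mods.append(Modification(ModKind.OXIDATION_M, seq.index("M")))
            rep_psms.append(
                PSMRecord(
                    spectrum_id=next_id(),
                    base_seq=seq,
                    mods=tuple(mods),
                    observed_mass=_jittered_mass(seq, mods, rng, cfg.ppm_jitter_sd),
                    score=rng.normal(cfg.correct_score_mean, cfg.correct_score_sd),
                    is_decoy=False,
                    replicate_id=rep,
                )
            )
        # false targets and decoys share a count distribution and score model
        n_correct = len(rep_psms)
        if cfg.id_error_rate > 0.0 and n_correct:
            p_false = cfg.id_error_rate / (1.0 - cfg.id_error_rate)
            n_false = rng.binomial(n_correct, p_false)
            n_decoy = rng.binomial(n_correct, p_false)
        else:
            n_false = n_decoy = 0
        for _ in range(n_false):
            seq = all_seqs[rng.integers(len(all_seqs))]
            entry = index.lookup(seq)
            mods = []
            if entry.proline_positions and rng.random() < cfg.false_sub_prob:
                p = entry.proline_positions[rng.integers(len(entry.proline_positions))]
                mods.append(Modification(ModKind.PRO_TO_SER, int(p)))
            rep_psms.append(
                PSMRecord(
                    spectrum_id=next_id(),
                    base_seq=seq,
                    mods=tuple(mods),
                    observed_mass=_jittered_mass(seq, mods, rng, cfg.ppm_jitter_sd),
                    score=rng.normal(cfg.incorrect_score_mean, cfg.incorrect_score_sd),
                    is_decoy=False,
                    replicate_id=rep,
                )
            )
        for _ in range(n_decoy):
            seq = decoy_seqs[rng.integers(len(decoy_seqs))]
            rep_psms.append(
                PSMRecord(
                    spectrum_id=next_id(),
                    base_seq=seq,
                    mods=(),
                    observed_mass=_jittered_mass(seq, (), rng, cfg.ppm_jitter_sd),
                    score=rng.normal(cfg.incorrect_score_mean, cfg.incorrect_score_sd),
                    is_decoy=True,
                    replicate_id=rep,
                )
            )
        psms.extend(rep_psms)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "replicate_id",
            "base_seq",
            "peptide_position",
            "codon",
            "extra_modification",
            "base_withheld",
        ],
    )
    return psms, truth


def growth_time_grid(cfg: SimulationConfig) -> np.ndarray:
    """Sampling grid in minutes, endpoints inclusive (97 points by default)."""
    return np.arange(0.0, cfg.duration_min + cfg.sample_interval_min / 2,
                     cfg.sample_interval_min)


def gen_growth_curves(cfg: SimulationConfig) -> pd.DataFrame:
    """Long-format growth table: logistic trajectories with additive noise."""
    from .phenotype import LN2, logistic

    rng = _stage_rng(cfg, 2)
    t = growth_time_grid(cfg)
    rows = []
    for strain in sorted(cfg.growth_strains):
        sp = cfg.growth_strains[strain]
        r = LN2 / sp.doubling_time_min
        model = logistic(t, sp.K, sp.N0, r)
        for rep_i in range(cfg.n_replicates):
            noise = (
                rng.normal(0.0, sp.noise_sd, size=t.size) if sp.noise_sd > 0 else 0.0
            )
            od = np.maximum(model + noise, 0.0)
            for ti, oi in zip(t, od):
                rows.append(
                    {
                        "strain_id": strain,
                        "replicate_id": f"rep{rep_i + 1}",
                        "time_min": ti,
                        "od600": oi,
                    }
                )
    return pd.DataFrame(rows, columns=["strain_id", "replicate_id", "time_min", "od600"])


def gen_fluorescence(cfg: SimulationConfig) -> pd.DataFrame:
    """Reporter readings: reference mean 1.0, variants at configured folds,
    lognormal replicate noise; densities are already normalized (od600=1)."""
    rng = _stage_rng(cfg, 3)
    sigma = np.sqrt(np.log1p(cfg.fluor_cv**2))
    rows = []
    for strain in sorted(cfg.heat_shock_folds):
        fold = cfg.heat_shock_folds[strain]
        if fold <= 0:
            raise ValueError(f"non-positive fold for strain {strain!r}")
        for rep_i in range(cfg.fluor_replicates):
            noise = (
                np.exp(rng.normal(-sigma**2 / 2, sigma)) if cfg.fluor_cv > 0 else 1.0
            )
            rows.append(
                {
                    "strain_id": strain,
                    "replicate_id": f"rep{rep_i + 1}",
                    "fluorescence": fold * noise,
                    "od600": 1.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["strain_id", "replicate_id", "fluorescence", "od600"]
    )


def simulate_all(cfg: SimulationConfig, outdir: str | Path) -> Dict[str, Path]:
    """Write every generated input to ``outdir``; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "aa_fasta": outdir / "proteome_aa.fasta",
        "cds_fasta": outdir / "proteome_cds.fasta",
        "psms": outdir / "psms.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "growth": outdir / "growth.tsv",
        "fluorescence": outdir / "fluorescence.tsv",
        "config": outdir / "config.yaml",
    }
    proteome = gen_proteome(cfg)
    write_proteome(proteome, paths["aa_fasta"], paths["cds_fasta"])
    psms, truth = gen_psm_dataset(proteome, cfg)
    psms_to_frame(psms).to_csv(
        paths["psms"], sep="\t", index=False, float_format="%.6f"
    )
    truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    gen_growth_curves(cfg).to_csv(
        paths["growth"], sep="\t", index=False, float_format="%.6f"
    )
    gen_fluorescence(cfg).to_csv(
        paths["fluorescence"], sep="\t", index=False, float_format="%.6f"
    )
    cfg.to_yaml(paths["config"])
    return paths
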