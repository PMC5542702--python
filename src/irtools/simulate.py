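"""Synthetic data with the statistical structure the analyses assume.

Each generator emulates one input of the pipeline — expression ratios with
spiked effects, binomial tube mortality, Hardy-Weinberg genotypes with an
optional phenotype association, dilution-series qPCR curves, and shifted
log-normal enzyme activities — and returns ground-truth labels alongside,
so every downstream stage can be tested for calibration and power without
external data.

A single integer seed drives everything; each generator derives its own
substream (``numpy`` SeedSequence spawn keys), so the components can be
regenerated independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ABSENT, DETECTED, MARGINAL, DEFAULT_CONTRASTS, ExpressionDataset
from .qpcr import QpcrExperiment

__all__ = [
    "ExpressionSimConfig",
    "BioassaySimConfig",
    "GenotypeSimConfig",
    "simulate_expression",
    "simulate_bioassay",
    "simulate_genotypes",
    "simulate_qpcr",
    "simulate_enzyme_activity",
]


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent substream ``stream`` of the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Configuration of the expression-ratio simulator.

    Defaults reproduce the array geometry of the study design: 9083
    detectable probes, three field-vs-reference contrasts with four
    replicate hybridizations each.
    """

    n_probes: int = 9083
    n_contrasts: int = 3
    n_reps: int = 4
    de_fraction_up: float = 0.0
    de_fraction_down: float = 0.0
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    dropout_prob: float = 0.0
    marginal_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probes < 1 or self.n_contrasts < 1 or self.n_reps < 2:
            raise ValueError("need n_probes >= 1, n_contrasts >= 1, n_reps >= 2")
        _check_prob(self.de_fraction_up, "de_fraction_up")
        _check_prob(self.de_fraction_down, "de_fraction_down")
        if self.de_fraction_up + self.de_fraction_down > 1:
            raise ValueError("de_fraction_up + de_fraction_down must be <= 1")
        if self.de_log2fc <= 0:
            raise ValueError(f"de_log2fc must be > 0, got {self.de_log2fc}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        _check_prob(self.dropout_prob, "dropout_prob")
        _check_prob(self.marginal_prob, "marginal_prob")


def simulate_expression(cfg: ExpressionSimConfig):
    """Simulate an :class:`ExpressionDataset` plus per-probe truth labels.

    Null probes have mean-0 log2-ratios; "up"/"down" probes have mean
    +/- ``de_log2fc`` in every contrast, all with SD ``noise_sd``.
    Detection flags are ``absent`` with probability ``dropout_prob``,
    otherwise ``marginal`` with probability ``marginal_prob`` and
    ``detected`` else.

    Returns
    -------
    (ExpressionDataset, pandas.DataFrame)
        The truth table has columns ``probe_id``, ``label`` in
        {null, up, down} and ``true_log2fc``.
    """
    rng = _rng(cfg.seed, 1)
    n = cfg.n_probes
    n_up = int(round(cfg.de_fraction_up * n))
    n_down = int(round(cfg.de_fraction_down * n))

    labels = np.array(["null"] * n, dtype=object)
    order = rng.permutation(n)
    up_idx, down_idx = order[:n_up], order[n_up:n_up + n_down]
    labels[up_idx] = "up"
    labels[down_idx] = "down"
    true_fc = np.zeros(n)
    true_fc[up_idx] = cfg.de_log2fc
    true_fc[down_idx] = -cfg.de_log2fc

    probe_ids = np.array([f"probe_{i:05d}" for i in range(n)])
    contrasts = [DEFAULT_CONTRASTS[j] if j < len(DEFAULT_CONTRASTS) else f"contrast_{j}"
                 for j in range(cfg.n_contrasts)]
    ratios, flags = {}, {}
    for label in contrasts:
        mat = rng.normal(loc=true_fc[:, None], scale=cfg.noise_sd,
                         size=(n, cfg.n_reps))
        u = rng.random((n, cfg.n_reps))
        fl = np.where(
            u < cfg.dropout_prob, ABSENT,
            np.where(u < cfg.dropout_prob + (1 - cfg.dropout_prob) * cfg.marginal_prob,
                     MARGINAL, DETECTED),
        )
        ratios[label] = mat
        flags[label] = fl

    truth = pd.DataFrame(
        {"probe_id": probe_ids, "label": labels, "true_log2fc": true_fc}
    )
    return ExpressionDataset(probe_ids, ratios, flags), truth


@dataclass(frozen=True)
class BioassaySimConfig:
    """Configuration of the tube-bioassay simulator.

    ``conditions`` maps (population, insecticide, synergist) to the true
    24 h mortality of that exposure; a control condition with
    ``control_mortality`` is always appended per population.
    """

    conditions: dict = field(
        default_factory=lambda: {("Funchal", "permethrin", "none"): 0.109}
    )
    n_tubes: int = 4
    tube_size: int = 25
    control_mortality: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tubes < 1 or self.tube_size < 1:
            raise ValueError("n_tubes and tube_size must be >= 1")
        for cond, p in self.conditions.items():
            _check_prob(p, f"true_mortality{cond}")
        _check_prob(self.control_mortality, "control_mortality")


def simulate_bioassay(cfg: BioassaySimConfig) -> pd.DataFrame:
    """Simulate a WHO tube bioassay: per-tube deaths ~ Binomial(tube_size, p).

    Returns the ``BioassayTable`` schema: population, insecticide,
    synergist, tube_id, n_exposed, n_dead_24h.  Control tubes (insecticide
    ``control``) draw from ``control_mortality``.
    """
    rng = _rng(cfg.seed, 2)
    rows = []
    populations = []
    for (pop, insecticide, synergist), p in cfg.conditions.items():
        if pop not in populations:
            populations.append(pop)
        for t in range(cfg.n_tubes):
            dead = int(rng.binomial(cfg.tube_size, p))
            rows.append((pop, insecticide, synergist,
                         f"{pop}-{insecticide}-{synergist}-t{t + 1}",
                         cfg.tube_size, dead))
    for pop in populations:
        for t in range(cfg.n_tubes):
            dead = int(rng.binomial(cfg.tube_size, cfg.control_mortality))
            rows.append((pop, "control", "none", f"{pop}-control-t{t + 1}",
                         cfg.tube_size, dead))
    return pd.DataFrame(rows, columns=[
        "population", "insecticide", "synergist", "tube_id",
        "n_exposed", "n_dead_24h",
    ])


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Configuration of the kdr genotype simulator.

    Genotypes are drawn from Hardy-Weinberg proportions at mutant-allele
    frequency ``allele_freq``; the resistance phenotype follows a logistic
    model whose odds multiply by ``phenotype_effect`` per mutant allele
    (1.0 = no association).
    """

    allele_freq: float = 0.17
    n_individuals: int = 91
    phenotype_effect: float = 1.0
    baseline_resistance_prob: float = 0.5
    locus: str = "V1016I"
    population: str = "Funchal"
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.allele_freq, "allele_freq")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.phenotype_effect <= 0:
            raise ValueError("phenotype_effect (odds multiplier) must be > 0")
        _check_prob(self.baseline_resistance_prob, "baseline_resistance_prob")


def simulate_genotypes(cfg: GenotypeSimConfig) -> pd.DataFrame:
    """Per-individual genotypes and phenotypes under HWE + logistic model.

    Returns columns: individual_id, locus, population, n_mutant_alleles
    (0/1/2), genotype (wildtype_hom/het/mutant_hom), phenotype
    (resistant/susceptible).
    """
    rng = _rng(cfg.seed, 3)
    q = cfg.allele_freq
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    n_alleles = rng.choice(3, size=cfg.n_individuals, p=probs)
    # clip to keep the logit finite at baseline probabilities of 0 or 1
    base = np.clip(cfg.baseline_resistance_prob, 1e-12, 1 - 1e-12)
    logit = np.log(base / (1 - base)) + n_alleles * np.log(cfg.phenotype_effect)
    p_res = 1.0 / (1.0 + np.exp(-logit))
    resistant = rng.random(cfg.n_individuals) < p_res
    genotype_name = np.array(["wildtype_hom", "het", "mutant_hom"])[n_alleles]
    return pd.DataFrame({
        "individual_id": [f"{cfg.population}_{i:04d}" for i in range(cfg.n_individuals)],
        "locus": cfg.locus,
        "population": cfg.population,
        "n_mutant_alleles": n_alleles,
        "genotype": genotype_name,
        "phenotype": np.where(resistant, "resistant", "susceptible"),
    })


def simulate_qpcr(
    efficiencies: dict,
    true_ratios: dict,
    reference_genes=("L8", "S7"),
    n_dilution_steps: int = 5,
    n_replicates: int = 4,
    noise_sd: float = 0.2,
    base_ct: float = 24.0,
    seed: int = 0,
) -> QpcrExperiment:
    """Simulate a qRT-PCR experiment with 5-fold dilution series.

    Per gene, Ct follows ``intercept - log_E(relative input) + noise``; in
    the sample wells the relative input of the field sample is the true
    ratio, so upregulated genes come up earlier.  Reference genes must have
    true ratio 1 (enforced).

    Parameters
    ----------
    efficiencies : dict gene -> E
        Per-cycle amplification factor, each in (1, 2.2].
    true_ratios : dict gene -> R
        True field/reference expression ratios (> 0).
    """
    for gene, e in efficiencies.items():
        if not 1.0 < e <= 2.2:
            raise ValueError(f"efficiency of {gene!r} must be in (1, 2.2], got {e}")
    if n_dilution_steps < 3:
        raise ValueError("need >= 3 dilution steps")
    missing = [g for g in true_ratios if g not in efficiencies]
    if missing:
        raise ValueError(f"no efficiency given for genes: {missing}")
    for g in reference_genes:
        if g not in efficiencies:
            raise ValueError(f"reference gene {g!r} missing from efficiencies")
        if true_ratios.get(g, 1.0) != 1.0:
            raise ValueError(f"reference gene {g!r} must have true ratio 1")

    rng = _rng(seed, 4)
    sample_rows, dilution_rows = [], []
    for gene, e in efficiencies.items():
        role = "reference" if gene in reference_genes else "target"
        ratio = true_ratios.get(gene, 1.0)
        if ratio <= 0:
            raise ValueError(f"true ratio of {gene!r} must be > 0")
        for rep in range(1, n_replicates + 1):
            ct_ctrl = base_ct + rng.normal(0.0, noise_sd)
            # field sample has `ratio` times the input -> earlier Ct
            ct_field = base_ct - np.log(ratio) / np.log(e) + rng.normal(0.0, noise_sd)
            sample_rows.append((gene, role, "reference_colony", rep, ct_ctrl))
            sample_rows.append((gene, role, "field", rep, ct_field))
        for step in range(n_dilution_steps):
            rel_input = 5.0 ** (-step)
            ct = base_ct - np.log(rel_input) / np.log(e) + rng.normal(0.0, noise_sd)
            dilution_rows.append((gene, step, ct))

    samples = pd.DataFrame(sample_rows, columns=[
        "gene", "role", "sample", "biological_replicate", "ct"])
    dilutions = pd.DataFrame(dilution_rows, columns=["gene", "dilution_step", "ct"])
    return QpcrExperiment(samples=samples, dilutions=dilutions)


def simulate_enzyme_activity(
    n_per_group: int = 40,
    reference_location: float = 0.0,
    reference_scale: float = 0.4,
    shift: float = 1.0,
    enzyme_family: str = "alpha-esterase",
    field_population: str = "Funchal",
    reference_population: str = "Rockefeller",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate per-individual enzyme activities for field vs reference.

    Activities are log-normal (location/scale on the log scale); the field
    group's activities are multiplied by ``shift`` (ground-truth fold
    elevation; 1 = identical distributions).  Returns the
    ``EnzymeActivityTable`` schema: population, enzyme_family,
    individual_id, activity.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if shift <= 0:
        raise ValueError("shift multiplier must be > 0")
    if reference_scale <= 0:
        raise ValueError("reference_scale must be > 0")
    rng = _rng(seed, 5)
    ref = rng.lognormal(reference_location, reference_scale, n_per_group)
    fld = rng.lognormal(reference_location + np.log(shift), reference_scale,
                        n_per_group)
    rows = []
    for i, a in enumerate(ref):
        rows.append((reference_population, enzyme_family,
                     f"{reference_population}_{i:03d}", a))
    for i, a in enumerate(fld):
        rows.append((field_population, enzyme_family,
                     f"{field_population}_{i:03d}", a))
    return pd.DataFrame(rows, columns=[
        "population", "enzyme_family", "individual_id", "activity"])
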