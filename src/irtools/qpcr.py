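"""Efficiency-corrected relative qRT-PCR quantification (Pfaffl method).

Amplification efficiency E (per-cycle amplification factor) is estimated
for each primer pair from a dilution-series regression of Ct on log10 of
the relative input: E = 10**(-1/slope).  Relative expression of a target
gene in the field sample versus the reference colony is then

    ratio = E_target**dCt_target / E_ref**dCt_ref,    dCt = Ct(control) - Ct(sample)

with the reference-gene term replaced by the geometric mean over the
normalizer genes (here the ribosomal proteins L8 and S7) when more than
one is used.  With all efficiencies equal to 2 this reduces to the familiar
2**(-ddCt) formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QpcrExperiment",
    "EfficiencyEstimate",
    "RelativeExpression",
    "estimate_efficiency",
    "pfaffl_ratio",
]

VALID_EFFICIENCY = (1.0, 2.2)
DILUTION_FACTOR = 5.0  # fivefold dilution series

SAMPLE_COLUMNS = ["gene", "role", "sample", "biological_replicate", "ct"]
DILUTION_COLUMNS = ["gene", "dilution_step", "ct"]


@dataclass
class QpcrExperiment:
    """Ct measurements of an experiment plus its dilution series.

    ``samples``: rows of gene, role (target/reference), sample label,
    biological_replicate, ct.  ``dilutions``: rows of gene, dilution_step
    (0-based index of a 5-fold series), ct.
    """

    samples: pd.DataFrame
    dilutions: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols, name in ((self.samples, SAMPLE_COLUMNS, "samples"),
                               (self.dilutions, DILUTION_COLUMNS, "dilutions")):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ValueError(f"{name} table missing columns {missing}")
        if (self.samples["ct"] <= 0).any() or (self.dilutions["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        bad = set(self.samples["role"]) - {"target", "reference"}
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")

    @property
    def genes(self) -> list:
        return list(dict.fromkeys(self.samples["gene"]))

    def reference_genes(self) -> list:
        mask = self.samples["role"] == "reference"
        return list(dict.fromkeys(self.samples.loc[mask, "gene"]))


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Dilution-series estimate of amplification efficiency for one gene."""

    gene: str
    slope: float
    efficiency: float
    r_squared: float
    n_points: int
    out_of_range: bool  # efficiency outside the valid (1, 2.2] assay window

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError(
                f"{self.gene}: dilution slope must be negative, got {self.slope}"
            )


@dataclass(frozen=True)
class RelativeExpression:
    """Pfaffl relative expression of one gene vs a reference colony."""

    gene: str
    reference_colony: str
    ratio: float
    ci95: tuple
    n_replicates: int
    replicate_ratios: tuple

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        lo, hi = self.ci95
        if not lo <= self.ratio <= hi:
            raise ValueError("ci95 must contain the point estimate")


def estimate_efficiency(dilutions: pd.DataFrame, gene: str | None = None,
                        dilution_factor: float = DILUTION_FACTOR) -> EfficiencyEstimate:
    """Fit Ct = a + slope*log10(relative input) and invert to E = 10**(-1/slope).

    ``dilutions`` rows need gene, dilution_step, ct; relative input of step
    k is ``dilution_factor**-k``.  Needs >= 3 distinct dilution points.
    """
    df = dilutions
    if gene is not None:
        df = df[df["gene"] == gene]
        if df.empty:
            raise ValueError(f"no dilution rows for gene {gene!r}")
    else:
        genes = df["gene"].unique()
        if len(genes) != 1:
            raise ValueError("pass gene= when the table holds several genes")
        gene = genes[0]
    steps = df["dilution_step"].to_numpy(dtype=float)
    if np.unique(steps).size < 3:
        raise ValueError(f"{gene}: need >= 3 distinct dilution points")
    log_input = -steps * np.log10(dilution_factor)
    fit = sps.linregress(log_input, df["ct"].to_numpy(dtype=float))
    if fit.slope >= 0:
        raise ValueError(f"{gene}: non-negative dilution slope {fit.slope:.3f} "
                         "(Ct must rise with dilution)")
    eff = 10.0 ** (-1.0 / fit.slope)
    lo, hi = VALID_EFFICIENCY
    return EfficiencyEstimate(
        gene=gene,
        slope=float(fit.slope),
        efficiency=float(eff),
        r_squared=float(fit.rvalue ** 2),
        n_points=int(len(df)),
        out_of_range=not (lo < eff <= hi),
    )


def _delta_ct(samples: pd.DataFrame, gene: str, control: str, sample: str) -> pd.Series:
    """Per-biological-replicate dCt = mean Ct(control) - Ct(sample)."""
    rows = samples[samples["gene"] == gene]
    ctrl = rows[rows["sample"] == control]
    smp = rows[rows["sample"] == sample]
    if ctrl.empty or smp.empty:
        raise ValueError(f"{gene}: missing Ct rows for {control!r} or {sample!r}")
    # technical replicates (duplicate rows per biological replicate) are
    # averaged before the ratio is formed
    ct_ctrl = float(ctrl.groupby("biological_replicate")["ct"].mean().mean())
    ct_smp = smp.groupby("biological_replicate")["ct"].mean()
    return ct_ctrl - ct_smp


def pfaffl_ratio(
    experiment: QpcrExperiment,
    gene: str,
    efficiencies: dict,
    sample: str = "field",
    control: str = "reference_colony",
    reference_genes=None,
) -> RelativeExpression:
    """Efficiency-corrected expression ratio of ``gene`` in sample vs control.

    Per biological replicate: E_t**dCt_t divided by the geometric mean of
    E_r**dCt_r over the reference genes; the point estimate is the mean of
    replicate ratios and ci95 a t-interval across them.
    """
    refs = list(reference_genes) if reference_genes is not None \
        else experiment.reference_genes()
    if not refs:
        raise ValueError("no reference genes in experiment")
    if gene in refs:
        raise ValueError(f"{gene!r} is a reference gene")
    for g in [gene, *refs]:
        e = efficiencies.get(g)
        if e is None:
            raise ValueError(f"no efficiency for gene {g!r}")
        if e <= 1.0:
            raise ValueError(f"efficiency of {g!r} must exceed 1, got {e}")

    d_t = _delta_ct(experiment.samples, gene, control, sample)
    target_term = efficiencies[gene] ** d_t
    log_ref = pd.DataFrame({
        g: np.log(efficiencies[g] ** _delta_ct(experiment.samples, g, control, sample))
        for g in refs
    })
    if len(log_ref) != len(d_t) or log_ref.index.symmetric_difference(d_t.index).size:
        raise ValueError("target and reference genes have mismatched replicates")
    ref_term = np.exp(log_ref.mean(axis=1))  # geometric mean across normalizers
    ratios = (target_term / ref_term).to_numpy()

    n = ratios.size
    point = float(ratios.mean())
    if n > 1 and ratios.std(ddof=1) > 0:
        half = sps.t.ppf(0.975, n - 1) * ratios.std(ddof=1) / np.sqrt(n)
    else:
        half = 0.0
    return RelativeExpression(
        gene=gene,
        reference_colony=control,
        ratio=point,
        ci95=(point - half, point + half),
        n_replicates=n,
        replicate_ratios=tuple(float(r) for r in ratios),
    )
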