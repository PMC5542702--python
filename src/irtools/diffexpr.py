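"""Replication-criterion differential-expression caller.

The model: for each probe on a two-color array, per-contrast log2
field/reference ratios across replicate hybridizations are tested against a
mean of zero (expression ratio of 1) with a one-sample t-test, and a signed
fold change is computed from the mean log2-ratio.  A probe is called
*significant* only when it passes both the significance threshold
(P < alpha) and the fold-change threshold (|FC| > fc_threshold), in the same
direction, in **every** contrast — the replication criterion.  Probes that
pass in all but one contrast are *potential* calls when every passing
contrast shows extreme expression (|FC| > rescue_fc).

The replication criterion is itself the multiplicity control: with K
independent contrasts the expected number of null probes passing the P
criterion everywhere is n_probes * alpha**K, computed by
:func:`expected_false_positives`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "DETECTED",
    "MARGINAL",
    "ABSENT",
    "FLAG_CODES",
    "ExpressionDataset",
    "DEConfig",
    "ReplicationDEModel",
    "DEResults",
    "filter_detectable",
    "signed_fold_change",
    "call_probe",
    "call_dataset",
    "expected_false_positives",
]

DETECTED = "detected"
MARGINAL = "marginal"
ABSENT = "absent"
FLAG_CODES = (DETECTED, MARGINAL, ABSENT)

DEFAULT_CONTRASTS = (
    "FunchalVsRockefeller",
    "FunchalVsNewOrleans",
    "PaulDoMarVsRockefeller",
)

STATUS_FILTERED = "filtered"
STATUS_NOT_SIGNIFICANT = "not_significant"
STATUS_POTENTIAL = "potential"
STATUS_SIGNIFICANT = "significant"


@dataclass
class ExpressionDataset:
    """Probe x replicate log2-ratio matrices for K contrasts.

    Parameters
    ----------
    probe_ids : sequence of str
        Shared probe identifiers (identical across contrasts).
    log2_ratios : dict of {contrast label: ndarray (n_probes, n_reps)}
        log2(field/reference) per replicate hybridization.
    flags : dict of {contrast label: ndarray (n_probes, n_reps) of str}
        Per-array detection calls, each one of ``detected``, ``marginal``
        or ``absent``.
    """

    probe_ids: np.ndarray
    log2_ratios: dict
    flags: dict

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        if not self.log2_ratios:
            raise ValueError("dataset has no contrasts")
        if set(self.log2_ratios) != set(self.flags):
            raise ValueError("log2_ratios and flags must cover the same contrasts")
        n = self.probe_ids.size
        for label, mat in self.log2_ratios.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != n:
                raise ValueError(f"contrast {label!r}: matrix shape {mat.shape} "
                                 f"does not match {n} probes")
            if mat.shape[1] < 2:
                raise ValueError(f"contrast {label!r}: need >= 2 replicates")
            if not np.isfinite(mat).all():
                raise ValueError(f"contrast {label!r}: non-finite log2-ratios")
            self.log2_ratios[label] = mat
            fl = np.asarray(self.flags[label])
            if fl.shape != mat.shape:
                raise ValueError(f"contrast {label!r}: flags shape {fl.shape} != "
                                 f"ratios shape {mat.shape}")
            bad = ~np.isin(fl, FLAG_CODES)
            if bad.any():
                raise ValueError(f"contrast {label!r}: unknown flag value "
                                 f"{fl[bad].flat[0]!r}")
            self.flags[label] = fl

    @property
    def contrasts(self) -> list:
        return list(self.log2_ratios)

    @property
    def n_probes(self) -> int:
        return int(self.probe_ids.size)


@dataclass(frozen=True)
class DEConfig:
    """Thresholds of the replication-criterion caller.

    ``required_passes``/``rescue_passes`` default to K and K-1 at fit time.
    """

    alpha: float = 0.05
    fc_threshold: float = 2.0
    rescue_fc: float = 20.0
    required_passes: int | None = None
    rescue_passes: int | None = None
    mean_fc_method: str = "arithmetic"  # or "geometric"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.rescue_fc <= self.fc_threshold:
            raise ValueError("rescue_fc must exceed fc_threshold")
        if self.mean_fc_method not in ("arithmetic", "geometric"):
            raise ValueError(f"unknown mean_fc_method {self.mean_fc_method!r}")

    def resolve(self, n_contrasts: int) -> "DEConfig":
        req = self.required_passes if self.required_passes is not None else n_contrasts
        res = self.rescue_passes if self.rescue_passes is not None else n_contrasts - 1
        if not 1 <= res <= req <= n_contrasts:
            raise ValueError(
                f"need 1 <= rescue_passes ({res}) <= required_passes ({req}) "
                f"<= K ({n_contrasts})"
            )
        return replace(self, required_passes=req, rescue_passes=res)


def filter_detectable(dataset: ExpressionDataset) -> np.ndarray:
    """Boolean mask of probes detectable (or marginal) in every array.

    A single ``absent`` flag on any array of any contrast removes the probe.
    """
    keep = np.ones(dataset.n_probes, dtype=bool)
    for label in dataset.contrasts:
        keep &= ~(dataset.flags[label] == ABSENT).any(axis=1)
    return keep


def signed_fold_change(log2_ratios) -> float:
    """Signed fold change from replicate log2-ratios.

    With m the mean log2-ratio: FC = 2**m for m >= 0 and -2**(-m)
    otherwise, so that |FC| >= 1 and underexpression is negative
    (an FC of -2 means half the reference level).
    """
    x = np.asarray(log2_ratios, dtype=float)
    if x.size < 1:
        raise ValueError("signed_fold_change needs at least one value")
    m = float(x.mean())
    return float(2.0 ** m) if m >= 0 else float(-(2.0 ** (-m)))


def _signed_fc_from_means(means: np.ndarray) -> np.ndarray:
    return np.where(means >= 0, 2.0 ** means, -(2.0 ** (-means)))


def call_probe(fc_p_pairs, cfg: DEConfig = DEConfig()) -> tuple:
    """Classify one probe from per-contrast (signed FC, P) pairs.

    Returns ``(status, direction)`` with status one of ``significant``,
    ``potential`` or ``not_significant`` and direction ``up``/``down``
    (``None`` when not called).
    """
    pairs = list(fc_p_pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 contrasts")
    fc = np.array([p[0] for p in pairs], dtype=float)
    pv = np.array([p[1] for p in pairs], dtype=float)
    if not (np.isfinite(fc).all() and np.isfinite(pv).all()):
        raise ValueError("non-finite FC or P input")
    cfg = cfg.resolve(len(pairs))
    status, direction = _classify(
        fc[None, :], pv[None, :], cfg
    )
    return status[0], direction[0]


def _classify(fc: np.ndarray, pv: np.ndarray, cfg: DEConfig):
    """Vectorized status assignment on (n, K) FC and P arrays."""
    n, k = fc.shape
    sign = np.where(fc >= 0, 1, -1)
    pass_both = (pv < cfg.alpha) & (np.abs(fc) > cfg.fc_threshold)

    status = np.full(n, STATUS_NOT_SIGNIFICANT, dtype=object)
    direction = np.full(n, None, dtype=object)

    for s in (1, -1):
        pass_s = pass_both & (sign == s)
        n_pass = pass_s.sum(axis=1)
        # a pass in the opposite direction voids both call levels
        opposite_pass = (pass_both & (sign == -s)).any(axis=1)
        # significant: every contrast passes, one common sign
        sig = (n_pass >= cfg.required_passes) & (sign == s).all(axis=1)
        status[sig] = STATUS_SIGNIFICANT
        direction[sig] = "up" if s == 1 else "down"
        # potential: >= rescue_passes contrasts pass with this sign and every
        # passing contrast shows extreme expression
        extreme_ok = np.where(pass_s, np.abs(fc) > cfg.rescue_fc, True).all(axis=1)
        pot = (~sig) & (status != STATUS_SIGNIFICANT) & (~opposite_pass) \
            & (n_pass >= cfg.rescue_passes) & extreme_ok
        status[pot] = STATUS_POTENTIAL
        direction[pot] = "up" if s == 1 else "down"
    return status, direction


def expected_false_positives(n_probes: int, alpha: float, required_passes: int) -> float:
    """Expected null probes passing P < alpha in all required contrasts.

    Assumes independence across contrasts and ignores the fold-change
    criterion: n_probes * alpha**required_passes.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if required_passes < 1:
        raise ValueError("required_passes must be >= 1")
    return float(n_probes) * alpha ** required_passes


class ReplicationDEModel:
    """Multi-contrast differential-expression model with replication calling.

    Parameters
    ----------
    dataset : ExpressionDataset
    config : DEConfig, optional

    Examples
    --------
    >>> model = ReplicationDEModel(dataset)
    >>> results = model.fit()
    >>> results.records.head()
    """

    def __init__(self, dataset: ExpressionDataset, config: DEConfig | None = None):
        self.dataset = dataset
        self.config = (config or DEConfig()).resolve(len(dataset.contrasts))

    def fit(self) -> "DEResults":
        ds, cfg = self.dataset, self.config
        labels = ds.contrasts
        keep = filter_detectable(ds)
        n = ds.n_probes
        k = len(labels)

        fc = np.full((n, k), np.nan)
        pv = np.full((n, k), np.nan)
        for j, label in enumerate(labels):
            mat = ds.log2_ratios[label]
            means = mat.mean(axis=1)
            fc[:, j] = _signed_fc_from_means(means)
            pv[:, j] = _t_pvalues(mat)

        status = np.full(n, STATUS_FILTERED, dtype=object)
        direction = np.full(n, None, dtype=object)
        st, di = _classify(fc[keep], pv[keep], cfg)
        status[keep] = st
        direction[keep] = di

        mean_fc = np.full(n, np.nan)
        if cfg.mean_fc_method == "arithmetic":
            mean_fc[keep] = fc[keep].mean(axis=1)
        else:
            # geometric mean on the ratio scale, sign from the mean log-ratio
            logs = np.log2(np.abs(fc[keep]))
            signed = np.sign(fc[keep]) * logs
            m = signed.mean(axis=1)
            mean_fc[keep] = np.where(m >= 0, 2.0 ** m, -(2.0 ** (-m)))

        combined_p = np.full(n, np.nan)
        # Fisher's method, vectorized: p-values from t-tests are in (0, 1]
        pk = np.clip(pv[keep], np.finfo(float).tiny, 1.0)
        x2 = -2.0 * np.log(pk).sum(axis=1)
        from scipy.stats import chi2
        combined_p[keep] = chi2.sf(x2, 2 * k)

        records = pd.DataFrame({"probe_id": ds.probe_ids})
        for j, label in enumerate(labels):
            records[f"fc_{label}"] = fc[:, j]
            records[f"p_{label}"] = pv[:, j]
        records["mean_fc"] = mean_fc
        records["combined_p"] = combined_p
        records["status"] = status
        records["direction"] = direction
        records = records.sort_values(
            "combined_p", na_position="last", kind="mergesort"
        ).reset_index(drop=True)
        return DEResults(model=self, records=records, retained_mask=keep)


def _t_pvalues(mat: np.ndarray) -> np.ndarray:
    """Row-wise two-sided one-sample t-test p-values against mean 0."""
    from scipy.stats import t as tdist

    n = mat.shape[1]
    means = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    p = np.empty(mat.shape[0])
    nz = sd > 0
    tstat = np.abs(means[nz]) / (sd[nz] / np.sqrt(n))
    p[nz] = 2.0 * tdist.sf(tstat, n - 1)
    # zero-variance rows: limiting convention of the one-sample t-test
    p[~nz] = np.where(means[~nz] == 0.0, 1.0, 0.0)
    return p


@dataclass
class DEResults:
    """Fitted differential-expression results.

    ``records`` holds one row per probe (sorted by combined p): per-contrast
    signed FC and raw P, mean FC, Fisher's-method combined P, status in
    {filtered, not_significant, potential, significant} and direction.
    """

    model: ReplicationDEModel
    records: pd.DataFrame
    retained_mask: np.ndarray

    @property
    def n_retained(self) -> int:
        return int(self.retained_mask.sum())

    def counts_by_status(self) -> pd.Series:
        return self.records["status"].value_counts()

    def expected_false_positives(self) -> dict:
        cfg = self.model.config
        n = self.n_retained
        return {
            "single_contrast": expected_false_positives(n, cfg.alpha, 1),
            "replication": expected_false_positives(n, cfg.alpha, cfg.required_passes),
        }

    def summary(self) -> str:
        cfg = self.model.config
        counts = self.counts_by_status()
        efp = self.expected_false_positives()
        lines = [
            "Replication-criterion differential expression",
            "=" * 46,
            f"probes:            {self.model.dataset.n_probes}",
            f"retained:          {self.n_retained}",
            f"contrasts:         {len(self.model.dataset.contrasts)}",
            f"alpha:             {cfg.alpha}",
            f"fc threshold:      {cfg.fc_threshold}",
            f"rescue fc:         {cfg.rescue_fc}",
            f"required passes:   {cfg.required_passes}",
            "-" * 46,
        ]
        for st in (STATUS_SIGNIFICANT, STATUS_POTENTIAL,
                   STATUS_NOT_SIGNIFICANT, STATUS_FILTERED):
            lines.append(f"{st + ':':<19}{int(counts.get(st, 0))}")
        lines += [
            "-" * 46,
            f"E[false +], single contrast: {efp['single_contrast']:.2f}",
            f"E[false +], replication:     {efp['replication']:.3f}",
        ]
        return "\n".join(lines)


def call_dataset(dataset: ExpressionDataset, config: DEConfig | None = None) -> DEResults:
    """Run the full caller: detectability filter, per-contrast FC and P,
    replication-criterion classification.  Functional wrapper around
    :class:`ReplicationDEModel`."""
    return ReplicationDEModel(dataset, config).fit()
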