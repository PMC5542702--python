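"""Table schemas, validated readers/writers and the pipeline orchestrator.

All inputs are plain CSV/TSV with a header row; every schema used by the
analysis stages is registered here so that errors can name the file, row
and column.  Unknown extra columns are accepted with a warning (forward
compatibility); missing values are rejected rather than imputed.

Numeric output precision is explicit: allele frequencies are written with
2 decimals, p-values with 3 significant figures, fold changes with 3
significant figures; machine-readable stage tables keep 6 significant
figures so that round-trips preserve the analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioassay as _bioassay
from . import popgen as _popgen
from . import qpcr as _qpcr
from .diffexpr import DEConfig, ExpressionDataset, call_dataset

log = logging.getLogger("irtools")

__all__ = [
    "SCHEMAS",
    "read_table",
    "write_table",
    "read_expression_dataset",
    "write_expression_dataset",
    "RunConfig",
    "run_pipeline",
]


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple
    dtypes: dict
    # column -> (min, max) bounds, None for unbounded
    bounds: dict = field(default_factory=dict)


SCHEMAS = {
    "bioassay": TableSchema(
        name="bioassay",
        columns=tuple(_bioassay.BIOASSAY_COLUMNS),
        dtypes={"n_exposed": int, "n_dead_24h": int},
        bounds={"n_exposed": (1, None), "n_dead_24h": (0, None)},
    ),
    "enzyme": TableSchema(
        name="enzyme",
        columns=tuple(_bioassay.ENZYME_COLUMNS),
        dtypes={"activity": float},
        bounds={"activity": (0.0, None)},
    ),
    "genotype": TableSchema(
        name="genotype",
        columns=tuple(_popgen.GENOTYPE_COLUMNS),
        dtypes={"n_wildtype_hom": int, "n_het": int, "n_mutant_hom": int},
        bounds={"n_wildtype_hom": (0, None), "n_het": (0, None),
                "n_mutant_hom": (0, None)},
    ),
    "qpcr_samples": TableSchema(
        name="qpcr_samples",
        columns=tuple(_qpcr.SAMPLE_COLUMNS),
        dtypes={"ct": float},
        bounds={"ct": (1e-9, None)},
    ),
    "qpcr_dilutions": TableSchema(
        name="qpcr_dilutions",
        columns=tuple(_qpcr.DILUTION_COLUMNS),
        dtypes={"dilution_step": int, "ct": float},
        bounds={"dilution_step": (0, None), "ct": (1e-9, None)},
    ),
}


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV/TSV against a registered schema.

    Raises ``ValueError`` naming the file, row (1-based data row) and
    column on any missing column, unparseable cell, missing value or bound
    violation.  Unknown extra columns produce a warning and are kept.
    """
    path = Path(path)
    sch = SCHEMAS[schema]
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such input file")
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in sch.columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing} "
                         f"for schema {schema!r}")
    extra = [c for c in df.columns if c not in sch.columns]
    if extra:
        warnings.warn(f"{path}: ignoring unknown column(s) {extra}", stacklevel=2)
    for col, typ in sch.dtypes.items():
        series = df[col]
        if series.isna().any():
            row = int(series[series.isna()].index[0]) + 1
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        try:
            df[col] = series.astype(typ)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: column {col!r} not parseable as "
                             f"{typ.__name__}: {exc}") from exc
        if typ is int and not np.array_equal(series.astype(float),
                                             df[col].astype(float)):
            raise ValueError(f"{path}: column {col!r} holds non-integer values")
    for col, (lo, hi) in sch.bounds.items():
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= df[col] < lo
        if hi is not None:
            bad |= df[col] > hi
        if bad.any():
            row = int(bad[bad].index[0]) + 1
            raise ValueError(f"{path}: column {col!r} out of bounds at row {row} "
                             f"(value {df[col][bad].iloc[0]!r})")
    # cross-column invariants
    if schema == "bioassay" and (df["n_dead_24h"] > df["n_exposed"]).any():
        bad = df["n_dead_24h"] > df["n_exposed"]
        row = int(bad[bad].index[0]) + 1
        raise ValueError(f"{path}: n_dead_24h exceeds n_exposed at row {row}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as CSV or TSV (by extension) with 6-sig-fig floats."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.6g")
    return path


def write_expression_dataset(dataset: ExpressionDataset, out_dir,
                             truth: pd.DataFrame | None = None) -> dict:
    """Write one TSV per contrast (probe_id, rep1..N, flag1..N) and an
    optional truth sidecar; returns {contrast label: path}."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label in dataset.contrasts:
        mat = dataset.log2_ratios[label]
        fl = dataset.flags[label]
        n_reps = mat.shape[1]
        df = pd.DataFrame({"probe_id": dataset.probe_ids})
        for j in range(n_reps):
            df[f"rep{j + 1}"] = mat[:, j]
        for j in range(n_reps):
            df[f"flag{j + 1}"] = fl[:, j]
        paths[label] = write_table(df, out_dir / f"expression_{label}.tsv")
    if truth is not None:
        write_table(truth, out_dir / "expression_truth.tsv")
    return paths


def read_expression_dataset(contrast_paths: dict) -> ExpressionDataset:
    """Read {contrast label: TSV path} into an :class:`ExpressionDataset`."""
    ratios, flags = {}, {}
    probe_ids = None
    for label, path in contrast_paths.items():
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"{path}: no such expression table")
        df = pd.read_csv(path, sep=_sep_for(path))
        if "probe_id" not in df.columns:
            raise ValueError(f"{path}: missing probe_id column")
        rep_cols = sorted((c for c in df.columns if c.startswith("rep")),
                          key=lambda c: int(c[3:]))
        flag_cols = sorted((c for c in df.columns if c.startswith("flag")),
                           key=lambda c: int(c[4:]))
        if len(rep_cols) < 2 or len(flag_cols) != len(rep_cols):
            raise ValueError(f"{path}: need matching rep1..N and flag1..N columns")
        if df[rep_cols].isna().any().any():
            raise ValueError(f"{path}: missing log2-ratio value")
        ids = df["probe_id"].to_numpy()
        if probe_ids is None:
            probe_ids = ids
        elif not np.array_equal(probe_ids, ids):
            raise ValueError(f"{path}: probe set differs between contrasts")
        ratios[label] = df[rep_cols].to_numpy(dtype=float)
        flags[label] = df[flag_cols].to_numpy(dtype=str)
    if probe_ids is None:
        raise ValueError("no contrast tables given")
    return ExpressionDataset(probe_ids, ratios, flags)


# ---------------------------------------------------------------------------
# pipeline orchestration


@dataclass
class RunConfig:
    """End-to-end run configuration (usually loaded from YAML).

    Only stages whose inputs are configured are executed.
    """

    out_dir: str = "irtools_out"
    seed: int = 0
    bioassay_path: str | None = None
    enzyme_path: str | None = None
    expression_paths: dict | None = None  # contrast label -> TSV path
    qpcr_samples_path: str | None = None
    qpcr_dilutions_path: str | None = None
    genotype_path: str | None = None
    de: DEConfig = field(default_factory=DEConfig)
    kdr_test_method: str = "genotype"  # or "allele"
    alpha: float = 0.05
    paper_mode: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        de = DEConfig(**raw.pop("de", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(de=de, **raw)


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="-"))


def _stage_bioassay(cfg: RunConfig, out: Path) -> dict:
    table = read_table(cfg.bioassay_path, "bioassay")
    summary = _bioassay.summarize_bioassay(table, paper_mode=cfg.paper_mode,
                                           alpha=cfg.alpha)
    write_table(summary, out / "bioassay_summary.tsv")
    return {
        "conditions": int(len(summary)),
        "classifications": {
            f"{r.population}/{r.insecticide}/{r.synergist}": r.classification
            for r in summary.itertuples()
        },
        "significant_synergist_effects": int(
            (summary["synergist_significant"] == True).sum()  # noqa: E712
        ),
    }


def _stage_biochem(cfg: RunConfig, out: Path) -> dict:
    table = read_table(cfg.enzyme_path, "enzyme")
    pops = [p for p in table["population"].unique() if p != "Rockefeller"]
    ref = "Rockefeller" if "Rockefeller" in set(table["population"]) \
        else table["population"].unique()[0]
    rows, report = [], {}
    for pop in pops:
        for fam in table.loc[table["population"] == pop, "enzyme_family"].unique():
            res, direction = _bioassay.compare_enzyme_activity(table, pop, ref, fam)
            rows.append({"population": pop, "enzyme_family": fam,
                         "reference": ref, "U": res.statistic,
                         "p_value": res.p_value, "direction": direction,
                         "significant": res.p_value < cfg.alpha})
            report[f"{pop}/{fam}"] = {"p": _round_sig(res.p_value),
                                      "direction": direction}
    write_table(pd.DataFrame(rows), out / "enzyme_comparisons.tsv")
    return report


def _stage_diffexpr(cfg: RunConfig, out: Path) -> dict:
    dataset = read_expression_dataset(cfg.expression_paths)
    results = call_dataset(dataset, cfg.de)
    write_table(results.records, out / "diffexpr_records.tsv")
    counts = results.counts_by_status()
    report = {
        "n_probes": dataset.n_probes,
        "n_retained": results.n_retained,
        "counts": {k: int(v) for k, v in counts.items()},
        "expected_false_positives": {
            k: _round_sig(v) for k, v in results.expected_false_positives().items()
        },
    }
    (out / "diffexpr_summary.txt").write_text(results.summary() + "\n")
    return report


def _stage_qpcr(cfg: RunConfig, out: Path) -> dict:
    samples = read_table(cfg.qpcr_samples_path, "qpcr_samples")
    dilutions = read_table(cfg.qpcr_dilutions_path, "qpcr_dilutions")
    exp = _qpcr.QpcrExperiment(samples=samples, dilutions=dilutions)
    effs, eff_rows = {}, []
    for gene in exp.genes:
        est = _qpcr.estimate_efficiency(dilutions, gene=gene)
        effs[gene] = est.efficiency
        eff_rows.append({"gene": gene, "slope": est.slope,
                         "efficiency": est.efficiency,
                         "r_squared": est.r_squared,
                         "out_of_range": est.out_of_range})
    refs = exp.reference_genes()
    targets = [g for g in exp.genes if g not in refs]
    ratio_rows, report = [], {}
    for gene in targets:
        rel = _qpcr.pfaffl_ratio(exp, gene, effs)
        ratio_rows.append({"gene": gene, "reference_colony": rel.reference_colony,
                           "ratio": rel.ratio, "ci95_low": rel.ci95[0],
                           "ci95_high": rel.ci95[1],
                           "n_replicates": rel.n_replicates})
        report[gene] = {"ratio": _round_sig(rel.ratio),
                        "ci95": [_round_sig(c) for c in rel.ci95]}
    write_table(pd.DataFrame(eff_rows), out / "qpcr_efficiencies.tsv")
    write_table(pd.DataFrame(ratio_rows), out / "qpcr_ratios.tsv")
    return {"efficiencies": {g: _round_sig(e) for g, e in effs.items()},
            "ratios": report}


def _split_phenotype_class(label: str):
    """Split e.g. 'cyfluthrin resistant' -> ('cyfluthrin', 'resistant')."""
    parts = label.replace("_", " ").rsplit(" ", 1)
    if len(parts) == 2 and parts[1].lower() in ("resistant", "susceptible"):
        return parts[0], parts[1].lower()
    return None


def _stage_kdr(cfg: RunConfig, out: Path) -> dict:
    df = read_table(cfg.genotype_path, "genotype")
    counts = {}
    freq_rows = []
    for row in df.itertuples():
        gc = _popgen.GenotypeCounts(
            locus=row.locus, population=row.population,
            phenotype_class=row.phenotype_class,
            n_wildtype_hom=row.n_wildtype_hom, n_het=row.n_het,
            n_mutant_hom=row.n_mutant_hom)
        counts[(row.locus, row.population, row.phenotype_class)] = gc
        fr = _popgen.allele_frequency(gc)
        freq_rows.append({
            "locus": gc.locus, "population": gc.population,
            "phenotype_class": gc.phenotype_class, "N": gc.n,
            "n_wildtype_hom": gc.n_wildtype_hom, "n_het": gc.n_het,
            "n_mutant_hom": gc.n_mutant_hom,
            "mutant_allele_freq": round(fr.frequency, 2),
            "fixed": fr.fixed,
        })
    tests = {}
    # population comparison on pooled ("all") strata, per locus
    for locus in df["locus"].unique():
        pooled = {pop: gc for (lc, pop, cls), gc in counts.items()
                  if lc == locus and cls == "all"}
        pops = sorted(pooled)
        if len(pops) == 2:
            a, b = pooled[pops[0]], pooled[pops[1]]
            fa, fb = _popgen.allele_frequency(a), _popgen.allele_frequency(b)
            if fa.fixed and fb.fixed:
                tests[f"{locus}: {pops[0]} vs {pops[1]}"] = "fixed (not tested)"
            else:
                res = _popgen.compare_population_frequencies(
                    a, b, method=cfg.kdr_test_method)
                tests[f"{locus}: {pops[0]} vs {pops[1]}"] = _round_sig(res.p_value)
    # association within each locus x population x insecticide
    for locus in df["locus"].unique():
        for pop in df["population"].unique():
            classes = {}
            for (lc, pp, cls), gc in counts.items():
                if lc == locus and pp == pop and (split := _split_phenotype_class(cls)):
                    classes.setdefault(split[0], {})[split[1]] = gc
            for insecticide, pair in classes.items():
                if set(pair) != {"resistant", "susceptible"}:
                    continue
                key = f"{locus}: {pop} {insecticide} association"
                try:
                    assoc = _popgen.association_test(
                        pair["resistant"], pair["susceptible"],
                        method=cfg.kdr_test_method)
                    tests[key] = _round_sig(assoc["test"].p_value)
                except ValueError as exc:
                    tests[key] = str(exc)
    write_table(pd.DataFrame(freq_rows), out / "kdr_frequencies.tsv")
    return {"strata": len(freq_rows), "tests": tests}


_STAGES = (
    ("bioassay", lambda c: c.bioassay_path, _stage_bioassay),
    ("biochem", lambda c: c.enzyme_path, _stage_biochem),
    ("diffexpr", lambda c: c.expression_paths, _stage_diffexpr),
    ("qpcr", lambda c: c.qpcr_samples_path and c.qpcr_dilutions_path, _stage_qpcr),
    ("kdr", lambda c: c.genotype_path, _stage_kdr),
)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every configured stage; write per-stage outputs and one
    consolidated JSON report; return the report as a dict."""
    from . import __version__

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    configured = [(name, fn) for name, pred, fn in _STAGES if pred(cfg)]
    if not configured:
        raise ValueError("no stage inputs configured; nothing to run")
    report = {
        "irtools_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()
                   if not k.startswith("_")},
        "stages": {},
    }
    for name, fn in configured:
        log.info("running stage %s", name)
        report["stages"][name] = fn(cfg, out)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
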