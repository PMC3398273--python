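"""End-to-end orchestration: orthology -> alignment prep -> codon models ->
expression metrics -> codon usage -> class statistics.

Stages run from a :class:`PipelineConfig` (YAML-serializable; defaults hold
the study's stated thresholds), persist their intermediates as TSV/JSON under
the output directory, and fold into a machine-readable
:class:`AnalysisReport`.  Re-running with identical config and seed
reproduces an identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import alignprep, classstats, codonusage, expression as em, orthology
from .codonmodel import CodonModel, ModelSpec, fdr_qvalues, lrt, nested_start
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("cardevol")

SPECIES = ("At", "Ci", "Cr")

#: likelihood-ratio tests: name -> (null model, alt model, stated df)
TESTS = {
    "B": ("M0", "FR", 3),
    "B_Ci": ("M0", "B2_Ci", 1),
    "B_Cr": ("M0", "B2_Cr", 1),
    "S_21": ("M1a", "M2a", 2),
    "S_87": ("M7", "M8", 2),
    "BS_Ci": (("BSA_null", "Ci"), ("BSA_alt", "Ci"), 1),
    "BS_Cr": (("BSA_null", "Cr"), ("BSA_alt", "Cr"), 1),
}


@dataclass
class PipelineConfig:
    """All stage inputs and thresholds; defaults are the study's values."""

    outdir: str = "cardevol_out"
    seed: int = 0
    # inputs: either three FASTA paths, or simulate
    fasta: dict = field(default_factory=dict)  # species -> path
    expression_path: Optional[str] = None
    samples_path: Optional[str] = None
    classes_path: Optional[str] = None
    transit_path: Optional[str] = None
    simulate: Optional[dict] = None  # SimulationConfig fields
    # thresholds (paper defaults)
    min_identity: float = 0.70
    min_coverage: float = 0.60
    overhang: float = 0.18
    min_contig_bp: int = 250
    expr_threshold: float = 75.0
    stress_fold: float = 3.0
    fdr_threshold: float = 0.20
    bootstrap_B: int = 10000
    # model fitting
    tests: list = field(default_factory=lambda: list(TESTS))
    restarts: int = 1
    max_genes: Optional[int] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class AnalysisReport:
    """Per-stage summaries with seed provenance; every number traces to a
    stage output file under ``outdir``."""

    config: dict
    stages: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps({"config": self.config, "stages": self.stages}, indent=1, sort_keys=True, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _base_id(at_id: str) -> str:
    return at_id[3:] if at_id.startswith("At_") else at_id


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(
    sequences: dict, expression_mat: Optional[pd.DataFrame] = None,
    class_table: Optional[pd.DataFrame] = None,
) -> list[str]:
    """Cross-check id consistency across inputs; returns warning strings.
    Duplicate gene ids within a species are an error."""
    diagnostics = []
    for sp, seqs in sequences.items():
        ids = list(seqs)
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicated gene ids in {sp} sequence set")
    at_bases = {_base_id(g) for g in sequences.get("At", {})}
    if expression_mat is not None:
        missing = sorted(at_bases - set(map(str, expression_mat.index)))
        diagnostics += [f"expression table missing gene {g}" for g in missing]
    if class_table is not None:
        known = set(class_table["gene_id"].astype(str))
        missing = sorted(at_bases - known)
        diagnostics += [f"class table missing gene {g}" for g in missing]
    return diagnostics


# ---------------------------------------------------------------------------
# stages


def orthology_stage(sequences: dict, cfg: PipelineConfig) -> orthology.TripletSet:
    """Six directed best-hit searches (contig length filter applied to the
    ingroup sets) -> filtered tables -> reciprocal best triplets."""
    params = orthology.AlignmentParams(overhang=cfg.overhang)
    records = {}
    for sp in SPECIES:
        recs = [
            orthology.SequenceRecord(gid, sp, seq)
            for gid, seq in sorted(sequences[sp].items())
            if sp == "At" or len(seq) >= cfg.min_contig_bp
        ]
        records[sp] = recs
    tables = {}
    pair_cache: dict = {}
    for a in SPECIES:
        for b in SPECIES:
            if a == b:
                continue
            hits = orthology.local_best_hits(records[a], records[b], params, pair_cache=pair_cache)
            tables[(a, b)] = orthology.filter_hits(hits, cfg.min_identity, cfg.min_coverage)
    return orthology.reciprocal_best_triplets(tables)


def prep_stage(
    triplets: orthology.TripletSet, sequences: dict, transit_table: dict, cfg: PipelineConfig
) -> dict:
    """Trimmed codon alignments per triplet, keyed by base gene id; genes
    failing preparation are logged and skipped."""
    alignments = {}
    for t in triplets:
        gid = _base_id(t.At)
        seqs = {
            "At": sequences["At"][t.At],
            "Ci": sequences["Ci"][t.Ci],
            "Cr": sequences["Cr"][t.Cr],
        }
        try:
            aln = alignprep.prepare_triplet(seqs, transit_table, gene_id=gid)
        except ValueError as e:
            log.warning("prep failed for %s: %s", gid, e)
            continue
        alignments[gid] = aln
    return alignments


def fit_stage(alignments: dict, cfg: PipelineConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit the free-ratio model (per-branch rates) and the configured
    likelihood-ratio tests per gene.

    Returns (gene rate table, LRT table with q-values per test family).
    """
    rate_rows, lrt_rows = [], []
    needed_models = {"M0", "FR"} if cfg.tests else {"FR"}
    for name in cfg.tests:
        null_m, alt_m, _ = TESTS[name]
        needed_models.add(null_m if isinstance(null_m, str) else null_m[0] + ":" + null_m[1])
        needed_models.add(alt_m if isinstance(alt_m, str) else alt_m[0] + ":" + alt_m[1])

    def spec_of(key):
        if ":" in key:
            m, fg = key.split(":")
            return ModelSpec(m, foreground=fg)
        return ModelSpec(key)

    nested_pairs = {"FR": "M0", "B2_Ci": "M0", "B2_Cr": "M0", "M2a": "M1a", "M8": "M7",
                    "BSA_alt:Ci": "BSA_null:Ci", "BSA_alt:Cr": "BSA_null:Cr"}

    for i, (gid, aln) in enumerate(sorted(alignments.items())):
        fits = {}
        order = sorted(needed_models, key=lambda k: (k in nested_pairs, k))
        for key in order:
            model = CodonModel(aln, spec_of(key))
            start = None
            null_key = nested_pairs.get(key)
            if null_key in fits:
                start = nested_start(model.spec, fits[null_key])
            fits[key] = model.fit(start=start, restarts=cfg.restarts, seed=seed + i)
        fr = fits["FR"].branch_rates()
        row = {"gene_id": gid, "n_codons": aln.n_codons, "lnL_FR": fits["FR"].llf,
               "kappa": fits["FR"].params["kappa"]}
        if "M0" in fits:
            row["lnL_M0"] = fits["M0"].llf
            row["omega_M0"] = fits["M0"].params["omega"]
        for b in ("Ci", "Cr", "At"):
            for k in ("dN", "dS", "omega", "t"):
                row[f"{k}_{b}"] = fr.branches[b][k]
        rate_rows.append(row)
        for name in cfg.tests:
            null_m, alt_m, df = TESTS[name]
            nk = null_m if isinstance(null_m, str) else null_m[0] + ":" + null_m[1]
            ak = alt_m if isinstance(alt_m, str) else alt_m[0] + ":" + alt_m[1]
            r = lrt(fits[nk], fits[ak], df_override=df)
            lrt_rows.append(
                {"gene_id": gid, "test": name, "stat": r.statistic, "df": r.df, "pvalue": r.pvalue}
            )
    rates = pd.DataFrame(rate_rows).set_index("gene_id") if rate_rows else pd.DataFrame()
    lrts = pd.DataFrame(lrt_rows)
    if not lrts.empty:
        lrts["qvalue"] = np.nan
        for name in cfg.tests:
            sel = lrts["test"] == name
            lrts.loc[sel, "qvalue"] = fdr_qvalues(lrts.loc[sel, "pvalue"].to_numpy())
    return rates, lrts


def expression_stage(matrix: pd.DataFrame, metadata: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    return em.breadth_profiles(matrix, metadata, threshold=cfg.expr_threshold, fold=cfg.stress_fold)


def codonusage_stage(sequences: dict, reference_ids: set, cfg: PipelineConfig) -> dict:
    """Optimal codons per ingroup species from the reference genes, then
    per-gene usage profiles (keyed by base gene id)."""
    out = {}
    for sp in ("Ci", "Cr"):
        ref = [
            codonusage.CodonCounts.from_sequence(seq, gid)
            for gid, seq in sorted(sequences[sp].items())
            if _strip_species(gid) in reference_ids
        ]
        optimal = codonusage.infer_optimal_codons(ref, species=sp)
        profiles = codonusage.usage_profiles(
            {_strip_species(gid): seq for gid, seq in sequences[sp].items()}, optimal
        )
        out[sp] = {"optimal": optimal, "profiles": profiles}
    return out


def _strip_species(gid: str) -> str:
    for sp in SPECIES:
        if gid.startswith(sp + "_"):
            return gid[len(sp) + 1 :]
    return gid


def build_gene_table(
    rates: pd.DataFrame,
    sequences: dict,
    class_table: Optional[pd.DataFrame],
    breadth: Optional[pd.DataFrame],
    usage: Optional[dict],
) -> pd.DataFrame:
    """Join per-branch rates, At gene length, class flags, breadth profile
    and codon-usage statistics into the per-gene analysis table."""
    table = rates.copy()
    at_len = {_base_id(g): len(s) for g, s in sequences["At"].items()}
    table["length"] = [at_len.get(g, np.nan) for g in table.index]
    if class_table is not None:
        ct = class_table.set_index(class_table["gene_id"].astype(str))
        labels = sorted({c for cs in ct["classes"].fillna("") for c in str(cs).split(",") if c})
        for label in labels:
            table[label] = [
                label in str(ct["classes"].get(g, "")).split(",") for g in table.index
            ]
        if "ribosomal" in ct.columns:
            table["ribosomal"] = [bool(ct["ribosomal"].get(g, 0)) for g in table.index]
    if breadth is not None:
        table = table.join(breadth, how="left")
    if usage is not None:
        for sp in ("Ci", "Cr"):
            prof = usage[sp]["profiles"]
            table[f"fop_{sp}"] = prof["fop"].reindex(table.index)
            table[f"gc3_{sp}"] = prof["gc3"].reindex(table.index)
    return table


def class_stats_stage(table: pd.DataFrame, cfg: PipelineConfig, seed: int) -> dict:
    """Class-vs-rest contrasts per lineage metric (length-corrected, Holm
    within each 8-test family), a bootstrap null for the significant
    contrasts, and the headline correlations."""
    out = {"class_tests": [], "bootstrap": [], "correlations": []}
    labels = [c for c in ("CRG", "CGO", "PGO", "SGO") if c in table.columns]
    for metric in ("omega_Ci", "omega_Cr", "dN_Ci", "dN_Cr", "dS_Ci", "dS_Cr"):
        if metric not in table.columns:
            continue
        family = []
        for label in labels:
            try:
                r = classstats.class_vs_rest(table, label, metric, correct_for="length")
            except ValueError as e:
                log.warning("class test skipped (%s, %s): %s", label, metric, e)
                continue
            family.append(r)
        if family:
            adj = classstats.holm_bonferroni([r.pvalue for r in family])
            for r, q in zip(family, adj):
                r.pvalue_corrected = float(q)
                r.correction = "holm"
                out["class_tests"].append(vars(r))
                if q < 0.05:
                    label = r.label.split(":")[0]
                    boot = classstats.bootstrap_class_null(
                        table, label, metric, B=cfg.bootstrap_B, seed=seed
                    )
                    out["bootstrap"].append(vars(boot))
    if "mean_expr" in table.columns:
        for b in ("Ci", "Cr"):
            sub = table[[f"omega_{b}", "mean_expr", "length"]].dropna()
            if len(sub) >= 4:
                r = classstats.spearman(
                    sub["mean_expr"], sub[f"omega_{b}"],
                    labels=("mean_expr", f"omega_{b}"),
                )
                out["correlations"].append(vars(r))
            if f"fop_{b}" in table.columns:
                sub = table[[f"fop_{b}", "mean_expr"]].dropna()
                if len(sub) >= 4:
                    r = classstats.spearman(
                        sub["mean_expr"], sub[f"fop_{b}"], labels=("mean_expr", f"fop_{b}")
                    )
                    out["correlations"].append(vars(r))
    return out


# ---------------------------------------------------------------------------
# the full run


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute all stages in order, persisting intermediates under
    ``config.outdir``; returns the analysis report (also written as JSON)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(config=asdict(config))
    rng_seed = config.seed

    # stage 0: inputs
    if config.simulate is not None:
        sim_cfg = SimulationConfig(**{**config.simulate, "seed": rng_seed})
        ds = simulate_dataset(sim_cfg)
        ds.write(outdir / "simulated")
        sequences = ds.sequences
        expr, samples = ds.expression, ds.layout
        class_table, transit = ds.class_table, dict(
            zip(ds.transit_table["gene_id"], ds.transit_table["cleavage_codon"])
        )
        report.stages["simulate"] = {
            "n_genes": sim_cfg.n_genes,
            "n_decoys": len(ds.decoy_ids),
            "seed": rng_seed,
        }
    else:
        sequences = {
            sp: {r.id: r.nucleotides for r in orthology.read_fasta(config.fasta[sp], sp)}
            for sp in SPECIES
        }
        expr = (
            pd.read_csv(config.expression_path, sep="\t", index_col=0)
            if config.expression_path
            else None
        )
        samples = pd.read_csv(config.samples_path, sep="\t") if config.samples_path else None
        class_table = pd.read_csv(config.classes_path, sep="\t") if config.classes_path else None
        transit = alignprep.load_transit_table(config.transit_path) if config.transit_path else {}

    diagnostics = validate_inputs(sequences, expr, class_table)
    for d in diagnostics:
        log.warning("%s", d)

    # stage 1: orthology
    triplets = orthology_stage(sequences, config)
    triplets.to_frame().to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    report.stages["orthology"] = {"n_triplets": len(triplets)}
    if len(triplets) == 0:
        log.warning("no triplets recovered; emitting empty report")
        report.stages["empty"] = True
        report.to_json(outdir / "report.json")
        return report

    # stage 2: alignment prep
    alignments = prep_stage(triplets, sequences, transit, config)
    if config.max_genes:
        keep = sorted(alignments)[: config.max_genes]
        alignments = {g: alignments[g] for g in keep}
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for gid, aln in alignments.items():
        alignprep.write_phylip(aln, aln_dir / f"{gid}.phy")
    report.stages["prep"] = {
        "n_alignments": len(alignments),
        "mean_codons": float(np.mean([a.n_codons for a in alignments.values()])),
    }

    # stage 3: codon models
    rates, lrts = fit_stage(alignments, config, rng_seed)
    rates.to_csv(outdir / "gene_rates.tsv", sep="\t")
    lrts.to_csv(outdir / "lrt_tests.tsv", sep="\t", index=False)
    summary = {}
    for b in ("Ci", "Cr"):
        w = rates[f"omega_{b}"].replace([np.inf], np.nan)
        summary[b] = {
            "mean_dN": float(rates[f"dN_{b}"].mean()),
            "mean_dS": float(rates[f"dS_{b}"].mean()),
            "mean_omega": float(w.mean(skipna=True)),
            "n_omega": int(w.notna().sum()),
        }
    outliers = {}
    if not lrts.empty:
        for name in config.tests:
            sel = lrts[(lrts["test"] == name) & (lrts["qvalue"] < config.fdr_threshold)]
            outliers[name] = sorted(sel["gene_id"])
    report.stages["codon_models"] = {"per_branch": summary, "outliers_fdr": outliers}

    # stage 4: expression metrics
    breadth = None
    if expr is not None and samples is not None:
        genes = [g for g in rates.index if g in expr.index]
        breadth = expression_stage(expr.loc[genes], samples, config)
        breadth.to_csv(outdir / "breadth_profiles.tsv", sep="\t")
        report.stages["expression"] = {"n_genes": len(breadth)}

    # stage 5: codon usage
    usage = None
    if class_table is not None and "ribosomal" in class_table.columns:
        ref_ids = set(class_table.loc[class_table["ribosomal"].astype(bool), "gene_id"].astype(str))
        try:
            usage = codonusage_stage(sequences, ref_ids, config)
            for sp in ("Ci", "Cr"):
                usage[sp]["optimal"].stats.to_csv(outdir / f"optimal_codons_{sp}.tsv", sep="\t", index=False)
                usage[sp]["profiles"].to_csv(outdir / f"usage_{sp}.tsv", sep="\t")
            report.stages["codon_usage"] = {
                sp: sorted(usage[sp]["optimal"].codons) for sp in ("Ci", "Cr")
            }
        except ValueError as e:
            log.warning("codon usage stage skipped: %s", e)

    # stage 6: class statistics
    table = build_gene_table(rates, sequences, class_table, breadth, usage)
    table.to_csv(outdir / "gene_table.tsv", sep="\t")
    report.stages["class_stats"] = class_stats_stage(table, config, rng_seed)

    report.stages["runtime_s"] = round(time.time() - t0, 2)
    report.to_json(outdir / "report.json")
    return report
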