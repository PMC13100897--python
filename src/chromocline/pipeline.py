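"""End-to-end orchestration: the simulation study and the real-data entry point.

`run_simulation_study` generates a full synthetic genome study — karyotype,
gene positions and rates, ortholog-tree fixtures, codon alignments, NG86
estimation with the exclusion rules, male/female depth tracks with X/Y/PAR
classification, and the positional-statistics battery — writing every table,
a machine-readable summary and a human-readable report to one directory,
reproducibly from (config, seed).

`run_real_data` consumes externally produced inputs in the declared formats
and emits the same report structure without any simulation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dnds as _dnds
from . import io as _io
from . import orthofilter as _ortho
from . import sexchrom as _sex
from .cline import ChromoclineModel, ChromoclineResults
from .synth import (
    ClineParams,
    DepthSimSpec,
    Karyotype,
    add_y_scaffolds,
    simulate_codon_pair,
    simulate_depth_tracks,
    simulate_gc_track,
    simulate_gene_rates,
    simulate_gene_trees,
    simulate_karyotype,
)

log = logging.getLogger("chromocline")

# fixed per-stage seed offsets derived from the run seed
_STAGE_OFFSETS = {
    "genes": 1, "trees": 2, "codons": 3, "depth": 4, "gc": 5, "perm": 6,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + 1_000_003 * _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class RunConfig:
    """Complete, serializable configuration of a simulation-study run.

    The defaults reproduce the study conditions of a shark-like genome:
    51 chromosomes spanning 3.97–185 Mb with the X ranked 40th by length,
    ~3.6 orthologs per Mb, a dS cline decaying from chromosome ends, a 30%
    X-specific dS reduction, two sub-Mb Y scaffolds, and 10-kb depth windows.
    """

    seed: int = 42
    # karyotype
    n_chrom: int = 51
    min_len: float = 3.97e6
    max_len: float = 185e6
    x_rank: int = 40
    x_len: float | None = 21e6  # anchor the X at its observed length
    # genes and rates
    genes_per_mb: float = 3.6
    n_codons: int = 500
    cline: ClineParams = field(default_factory=ClineParams)
    gc_center: float = 0.41
    gc_end: float = 0.46
    # ortholog-tree fixtures
    n_fail_paralog: int = 50
    n_fail_topology: int = 50
    n_translocated: int = 4
    # depth simulation
    window_bp: int = 10_000
    par_bp: int = 500_000
    y_lengths: tuple[int, ...] = (645_398, 195_000)
    overdispersion: float = 1.003
    # estimation and filtering
    estimator: str = "NG86"
    t_min: float = 0.01
    t_max: float = 2.0
    min_genes: int = 10
    ends_span_bp: float = 5e6
    center_span_bp: float = 10e6
    n_perm: int = 10_000
    # simulate codon sequences and estimate, or use direct rate draws
    simulate_sequences: bool = True

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["cline"] = asdict(self.cline)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "cline" in data and isinstance(data["cline"], dict):
            data["cline"] = ClineParams(**data["cline"])
        if "y_lengths" in data:
            data["y_lengths"] = tuple(data["y_lengths"])
        return cls(**data)


@dataclass
class ReportBundle:
    """In-memory results of one end-to-end run."""

    config: RunConfig | None
    karyotype: Karyotype
    genes: pd.DataFrame
    ortho_status: pd.DataFrame | None
    filter_report: _dnds.FilterReport | None
    translocated_removed: list[str]
    depth_results: _sex.DepthRatioResults | None
    cline_results: ChromoclineResults
    summary: dict


def _simulate_rates_and_estimates(config: RunConfig, karyotype: Karyotype) -> pd.DataFrame:
    """Per-gene rate table, either via codon-sequence simulation + NG86 or direct draws."""
    params = config.cline
    genes = simulate_gene_rates(
        karyotype, params, config.genes_per_mb,
        seed=_stage_seed(config.seed, "genes"),
        n_codons=None if config.simulate_sequences else config.n_codons,
    )
    if not config.simulate_sequences or genes.empty:
        return genes
    # re-estimate each gene's rates from a simulated codon alignment
    rng = np.random.default_rng(_stage_seed(config.seed, "codons"))
    rows = []
    for _, g in genes.iterrows():
        # per-gene omega chosen so that dN is unaffected by the X reduction
        omega_gene = g["dn"] / g["ds"] if g["ds"] > 0 else params.omega
        s1, s2 = simulate_codon_pair(
            g["ds"], omega_gene, config.n_codons, seed=int(rng.integers(2**31))
        )
        est = _dnds.pairwise_dnds(s1, s2, method=config.estimator)
        rows.append((est.dS, est.dN, est.omega, est.t, est.valid))
    est_df = pd.DataFrame(rows, columns=["ds", "dn", "omega", "t", "valid"])
    out = genes.copy()
    for col in ("ds", "dn", "omega", "t"):
        out[col] = est_df[col].to_numpy(dtype=float)
    out["valid"] = est_df["valid"].to_numpy(dtype=bool)
    return out


def run_simulation_study(config: RunConfig, outdir) -> ReportBundle:
    """Execute the full synthetic study and write its report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")  # config echo
    summary: dict = {"seed": config.seed}

    # --- karyotype --------------------------------------------------------
    karyotype = simulate_karyotype(
        config.n_chrom, config.min_len, config.max_len, config.x_rank,
        config.seed, x_len=config.x_len,
    )
    karyo_sex = add_y_scaffolds(karyotype, list(config.y_lengths))
    karyo_sex.as_dataframe().to_csv(outdir / "karyotype.tsv", sep="\t", index=False)
    x_id = karyotype.x_id
    log.info("karyotype: %d chromosomes, X = %s", len(karyotype), x_id)

    # --- genes, rates, estimation ----------------------------------------
    genes = _simulate_rates_and_estimates(config, karyotype)
    log.info("genes placed: %d", len(genes))
    summary["n_genes"] = int(len(genes))

    # --- ortholog-tree fixtures and monophyly filter ----------------------
    trees = simulate_gene_trees(
        len(genes), config.n_fail_paralog, config.n_fail_topology,
        seed=_stage_seed(config.seed, "trees"),
    )
    og_records = [(f"OG{i + 1:06d}", nwk) for i, (nwk, _) in enumerate(trees)]
    expected = {f"OG{i + 1:06d}": flag for i, (_, flag) in enumerate(trees)}
    passing, status = _ortho.select_ogs(og_records, _ortho_species()[0], _ortho_species()[1])
    status["expected_pass"] = status["og_id"].map(expected)
    status.to_csv(outdir / "orthofilter_status.tsv", sep="\t", index=False)
    mismatch = int((status["expected_pass"] != (status["status"] == "pass")).sum())
    log.info(
        "orthofilter: %d of %d OGs pass (%d planted-flag mismatches)",
        len(passing), len(status), mismatch,
    )
    summary["ortholog_groups"] = {
        "n_total": int(len(status)), "n_pass": int(len(passing)),
        "n_planted_mismatch": mismatch,
    }

    # --- exclusion rules ---------------------------------------------------
    filtered, freport = _dnds.filter_estimates(genes, config.t_min, config.t_max)
    log.info(
        "t-filter: kept %d of %d (invalid %d, t<%g %d, t>%g %d)",
        freport.n_kept, freport.n_input, freport.n_invalid,
        config.t_min, freport.n_below_t_min, config.t_max, freport.n_above_t_max,
    )
    rng_tr = np.random.default_rng(_stage_seed(config.seed, "perm") + 13)
    class_a = dict(zip(filtered["gene_id"], filtered["chrom_class"]))
    class_b = dict(class_a)
    n_tr = min(config.n_translocated, len(filtered))
    for gid in rng_tr.choice(filtered["gene_id"].to_numpy(), size=n_tr, replace=False):
        class_b[gid] = "X" if class_a[gid] == "autosome" else "autosome"
    kept_ids, removed_ids = _dnds.exclude_translocated(class_a, class_b)
    final = filtered[filtered["gene_id"].isin(kept_ids)].reset_index(drop=True)
    log.info("translocation exclusion: removed %d genes", len(removed_ids))
    summary["filters"] = {
        "n_estimated": freport.n_input, "n_invalid": freport.n_invalid,
        "n_t_below": freport.n_below_t_min, "n_t_above": freport.n_above_t_max,
        "n_translocated_removed": len(removed_ids), "n_final": int(len(final)),
    }
    _io.write_gene_table(final, outdir / "gene_rates.tsv")

    # --- depth simulation and sex-chromosome recovery ---------------------
    x_len = karyotype[x_id].length if x_id else 0
    par_spans = ()
    if x_id and config.par_bp > 0:
        par_spans = (
            (x_id, 0, min(config.par_bp, x_len)),
            (x_id, max(x_len - config.par_bp, 0), x_len),
        )
    depth_spec = DepthSimSpec(
        window_bp=config.window_bp,
        par_spans=par_spans,
        y_ids=tuple(c.id for c in karyo_sex if c.chrom_class == "y-candidate"),
        overdispersion=config.overdispersion,
    )
    female, male = simulate_depth_tracks(
        karyo_sex, depth_spec, seed=_stage_seed(config.seed, "depth")
    )
    _io.write_bedgraph(female, outdir / "depth_female.bedgraph")
    _io.write_bedgraph(male, outdir / "depth_male.bedgraph")
    depth_model = _sex.DepthRatioModel(female, male, karyo_sex.lengths)
    depth_results = depth_model.fit()
    depth_results.summaries.to_csv(outdir / "sexchrom_classification.tsv",
                                   sep="\t", index=False, float_format="%.6g")
    _io.write_par_bed(depth_results.pars, outdir / "par.bed")
    summary["sex_chromosomes"] = {
        "x_planted": x_id, "x_called": depth_results.x_ids,
        "y_planted": list(depth_spec.y_ids), "y_called": depth_results.y_ids,
        "pars_called": [
            {"chrom": p.chrom, "start": p.start, "end": p.end, "side": p.side}
            for p in depth_results.pars
        ],
        "pars_planted": [list(s) for s in par_spans],
    }
    log.info("sexchrom: X called %s, Y called %s", depth_results.x_ids, depth_results.y_ids)

    # --- GC cline ----------------------------------------------------------
    gc_track = simulate_gc_track(
        karyotype, config.gc_center, config.gc_end, config.cline.lambda_bp,
        config.window_bp, seed=_stage_seed(config.seed, "gc"),
    )
    _io.write_bedgraph(gc_track, outdir / "gc.bedgraph", value_col="gc")

    # --- positional statistics ---------------------------------------------
    model = ChromoclineModel(
        final, karyotype, min_genes=config.min_genes,
        ends_span_bp=config.ends_span_bp, center_span_bp=config.center_span_bp,
    )
    results = model.fit(
        n_perm=config.n_perm, seed=_stage_seed(config.seed, "perm"),
        gc_track=gc_track,
    )
    _write_cline_tables(results, outdir)
    summary["chromocline"] = _cline_summary_dict(results)

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report = results.summary() + "\n\n" + depth_results.summary() + "\n"
    (outdir / "report.txt").write_text(report)
    return ReportBundle(
        config=config, karyotype=karyo_sex, genes=final, ortho_status=status,
        filter_report=freport, translocated_removed=list(removed_ids),
        depth_results=depth_results, cline_results=results, summary=summary,
    )


def _ortho_species() -> tuple[str, str]:
    from .synth import FOCAL_A, FOCAL_B

    return FOCAL_A, FOCAL_B


def _write_cline_tables(results: ChromoclineResults, outdir: Path) -> None:
    fmt = "%.6g"
    results.chrom_summaries.to_csv(
        outdir / "chromosome_medians.tsv", sep="\t", index=False, float_format=fmt
    )
    rows = []
    for subset, by_resp in results.length_regressions.items():
        for resp, res in by_resp.items():
            rows.append({
                "subset": subset, "response": resp, "slope": res.slope,
                "slope_se": res.slope_se, "p_value": res.p_value,
                "r": res.r, "n": res.n, "transform": res.transform,
            })
    pd.DataFrame(rows).to_csv(
        outdir / "length_regressions.tsv", sep="\t", index=False, float_format=fmt
    )
    results.position_per_chrom.to_csv(
        outdir / "position_slopes.tsv", sep="\t", index=False, float_format=fmt
    )
    if results.x_effect is not None:
        results.x_effect.to_csv(
            outdir / "x_effect.tsv", sep="\t", index=False, float_format=fmt
        )
    if results.gc_regressions is not None:
        results.gc_regressions.to_csv(
            outdir / "gc_slopes.tsv", sep="\t", index=False, float_format=fmt
        )


def _cline_summary_dict(results: ChromoclineResults) -> dict:
    inc = results.chrom_summaries[results.chrom_summaries["included"]]
    t = results.position_tally
    out = {
        "n_chromosomes_summarized": int(len(inc)),
        "median_ds_range": [float(inc["ds"].min()), float(inc["ds"].max())] if len(inc) else None,
        "length_effect": {
            subset: {
                resp: {"slope": res.slope, "p_value": res.p_value, "n": res.n}
                for resp, res in by_resp.items()
            }
            for subset, by_resp in results.length_regressions.items()
        },
        "position_slopes": {
            "n_negative": t.n_negative,
            "n_negative_significant": t.n_negative_significant,
            "n_positive": t.n_positive,
            "n_positive_significant": t.n_positive_significant,
        },
        "n_u_shaped": int(sum(q.u_shaped for q in results.quadratics.values())),
        "n_quadratics": int(len(results.quadratics)),
    }
    if results.x_effect is not None:
        out["x_effect"] = results.x_effect.to_dict(orient="records")
    return out


def run_real_data(
    gene_table,
    karyotype_tsv,
    outdir,
    alignments_dir=None,
    female_bedgraph=None,
    male_bedgraph=None,
    trees_file=None,
    gc_bedgraph=None,
    focal_species: tuple[str, str] = ("Rty", "Sti"),
    t_min: float = 0.01,
    t_max: float = 2.0,
    min_genes: int = 10,
    n_perm: int = 10_000,
    seed: int = 0,
) -> ReportBundle:
    """Run the analysis battery on externally supplied inputs.

    The gene table must provide (gene_id, chrom, midpoint) and either
    precomputed (ds, dn, omega, t, valid) columns or ``alignments_dir`` with
    one paired-FASTA codon alignment named ``<gene_id>.fa`` per gene. Missing
    depth files skip the sex-chromosome section with a notice; the karyotype
    table then needs a chrom_class column to label the X.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    karyotype = _io.read_karyotype_table(karyotype_tsv)
    genes = _io.read_gene_table(gene_table)

    ortho_status = None
    if trees_file is not None:
        newicks = _io.read_newick_lines(trees_file)
        records = [(f"OG{i + 1:06d}", nwk) for i, nwk in enumerate(newicks)]
        passing, ortho_status = _ortho.select_ogs(records, *focal_species)
        ortho_status.to_csv(outdir / "orthofilter_status.tsv", sep="\t", index=False)
        log.info("orthofilter: %d of %d OGs pass", len(passing), len(ortho_status))

    if alignments_dir is not None:
        aln_dir = Path(alignments_dir)
        pairs = []
        for gid in genes["gene_id"]:
            fa = aln_dir / f"{gid}.fa"
            if not fa.exists():
                raise FileNotFoundError(f"missing alignment for gene {gid}: {fa}")
            pairs.append((gid, _io.read_paired_fasta(fa)))
        est = _dnds.estimate_batch(pairs)
        est = est.rename(columns={"dS": "ds", "dN": "dn"})
        genes = genes.merge(
            est[["gene_id", "ds", "dn", "omega", "t", "valid"]], on="gene_id"
        )
    for col in ("ds", "dn", "t"):
        if col not in genes.columns:
            raise ValueError(f"gene table lacks column {col!r} and no alignments given")
    if "valid" not in genes.columns:
        genes["valid"] = True
    if "omega" not in genes.columns:
        genes["omega"] = genes["dn"] / genes["ds"]

    filtered, freport = _dnds.filter_estimates(genes, t_min, t_max)
    log.info("t-filter: kept %d of %d", freport.n_kept, freport.n_input)

    depth_results = None
    if female_bedgraph is not None and male_bedgraph is not None:
        female = _io.read_bedgraph(female_bedgraph)
        male = _io.read_bedgraph(male_bedgraph)
        depth_results = _sex.DepthRatioModel(female, male, karyotype.lengths).fit()
        depth_results.summaries.to_csv(
            outdir / "sexchrom_classification.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        _io.write_par_bed(depth_results.pars, outdir / "par.bed")
    else:
        log.info("no depth tracks supplied; skipping sex-chromosome section")

    gc_track = None
    if gc_bedgraph is not None:
        gc_track = _io.read_bedgraph(gc_bedgraph, value_col="gc")

    model = ChromoclineModel(filtered, karyotype, min_genes=min_genes)
    results = model.fit(n_perm=n_perm, seed=seed, gc_track=gc_track)
    _write_cline_tables(results, outdir)
    summary = {"seed": seed, "n_genes": int(len(filtered)),
               "chromocline": _cline_summary_dict(results)}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    report = results.summary()
    if depth_results is not None:
        report += "\n\n" + depth_results.summary()
    (outdir / "report.txt").write_text(report + "\n")
    return ReportBundle(
        config=None, karyotype=karyotype, genes=filtered, ortho_status=ortho_status,
        filter_report=freport, translocated_removed=[], depth_results=depth_results,
        cline_results=results, summary=summary,
    )
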