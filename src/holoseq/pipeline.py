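"""Configuration-driven orchestration of the analysis profiles.

A profile names a stage sequence; parameters default to the frozen study
values in :data:`DEFAULTS` and may be overridden per run.  Unknown
configuration keys are rejected.  Each run writes its stage outputs as
TSV plus a JSON provenance record (resolved config, seed, package version,
output checksums); deterministic stages are byte-identical across reruns
with the same config.

Profiles
--------
``coverage_qc``   simulated (or supplied) alignments -> group BCI profiles
``total_rna``     stranded reads -> antisense discovery -> expression matrix
``mesc_dual``     dual matrices -> detection filter -> negative network
``hcc_dual``      dual matrices -> top-variant clustering -> oncomiR and
                  suppressor networks -> SE group activity
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from holoseq import __version__
from holoseq import antisense as as_mod
from holoseq import coverage as cov_mod
from holoseq import networks as net_mod
from holoseq import superenhancer as se_mod
from holoseq import subpopulations as sub_mod
from holoseq import synthetic as sim_mod
from holoseq import variability as var_mod
from holoseq.io import read_alignments, read_gene_models, read_matrix, write_matrix

PROFILES = ("coverage_qc", "total_rna", "mesc_dual", "hcc_dual")

# frozen stage parameter defaults (the study's printed values)
DEFAULTS = {
    "rpkm_threshold": 0.1,
    "min_reads": 10,
    "detection_fraction": 1 / 3,
    "se_window": 100_000,
    "round1_window": 1000,
    "round1_gap": 3000,
    "round2_window": 200,
    "round2_gap": 600,
    "min_inner_island": 401,
    "perplexity": 6.0,
    "n_top_mrna": 500,
    "n_top_mirna": 99,
    "n_clusters": 3,
    "alpha": 0.05,
    "coverage_profile": "uniform",
    "depth": 20_000,
    "min_window_reads": 1,
    "background_rate": 0.0,
    "oncomirs": [],
}


@dataclass
class PipelineConfig:
    profile: str
    seed: int = 0
    params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outdir: str = "holoseq_out"

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        unknown = set(self.params) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"profile", "seed", "params", "inputs", "outdir"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def resolved(self) -> dict:
        p = dict(DEFAULTS)
        p.update(self.params)
        return p


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run a profile; returns {output name: path} plus provenance."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.resolved()
    outputs: dict[str, Path] = {}
    stage = "setup"
    try:
        if config.profile == "coverage_qc":
            stage = "coverage_qc"
            outputs = _run_coverage_qc(config, p, outdir)
        elif config.profile == "total_rna":
            stage = "total_rna"
            outputs = _run_total_rna(config, p, outdir)
        elif config.profile == "mesc_dual":
            stage = "mesc_dual"
            outputs = _run_mesc_dual(config, p, outdir)
        else:
            stage = "hcc_dual"
            outputs = _run_hcc_dual(config, p, outdir)
    except Exception as exc:
        marker = outdir / "FAILED"
        marker.write_text(f"stage {stage} failed: {exc}\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    prov = {
        "profile": config.profile,
        "seed": config.seed,
        "version": __version__,
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()},
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "outputs": {name: _sha256(path) for name, path in outputs.items()},
    }
    prov_path = outdir / "provenance.json"
    prov_path.write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    outputs["provenance"] = prov_path
    return {name: str(path) for name, path in outputs.items()}


def _load_genes(config: PipelineConfig):
    path = config.inputs.get("genes")
    if path:
        return read_gene_models(Path(path).open())
    return None


def _run_coverage_qc(config: PipelineConfig, p: dict, outdir: Path) -> dict:
    genes = _load_genes(config)
    if config.inputs.get("alignments"):
        records = list(read_alignments(Path(config.inputs["alignments"]).open()))
    else:
        if genes is None:
            from holoseq.io import GeneModel, GenomicInterval

            genes = [
                GeneModel(
                    f"simgene{i}",
                    GenomicInterval("chr1", i * 20_000, i * 20_000 + L, "+"),
                    (GenomicInterval("chr1", i * 20_000, i * 20_000 + L, "+"),),
                )
                for i, L in enumerate([1000, 3000, 5000, 8000, 12_000, 15_000])
            ]
        records, _ = sim_mod.simulate_alignment_library(
            genes, p["coverage_profile"], p["depth"], seed=config.seed
        )
    per_gene = {}
    lengths = {}
    totals = {}
    for g in genes:
        bins = cov_mod.gene_bin_coverage(g, records)
        if bins.any():
            per_gene[g.gene_id] = bins
            lengths[g.gene_id] = g.exon_length
            totals[g.gene_id] = float(bins.sum())
    kept, _log = cov_mod.exclude_outlier_genes(totals)
    per_gene = {g: b for g, b in per_gene.items() if g in kept}
    profiles = cov_mod.aggregate_group_bci(per_gene, lengths)
    rows = []
    for label, prof in profiles.items():
        for b in range(cov_mod.N_BINS):
            rows.append(
                {
                    "group": label,
                    "bin": b + 1,
                    "bci": prof.bci[b],
                    "smoothed_bci": prof.smoothed_bci[b],
                    "n_genes": prof.n_genes,
                }
            )
    path = outdir / "bci.tsv"
    _write_tsv(pd.DataFrame(rows).set_index("group"), path)
    return {"bci": path}


def _run_total_rna(config: PipelineConfig, p: dict, outdir: Path) -> dict:
    genes = _load_genes(config)
    if config.inputs.get("alignments"):
        records = list(read_alignments(Path(config.inputs["alignments"]).open()))
    else:
        if genes is None:
            genes, planted = sim_mod.default_antisense_scenario(seed=config.seed)
        else:
            _, planted = sim_mod.default_antisense_scenario(seed=config.seed)
        records, _ = sim_mod.simulate_antisense_dataset(
            genes, planted, background_rate=p["background_rate"], seed=config.seed
        )
    calls = as_mod.discover_antisense(
        records,
        genes,
        round1=(p["round1_window"], p["round1_gap"]),
        round2=(p["round2_window"], p["round2_gap"]),
        min_window_reads=p["min_window_reads"],
    )
    rows = [
        {
            "chrom": t.interval.chrom,
            "start": t.interval.start,
            "end": t.interval.end,
            "strand": t.interval.strand,
            "status": t.status,
            "opposite_overlap_fraction": t.opposite_overlap_fraction,
        }
        for t in calls
    ]
    path = outdir / "antisense.tsv"
    _write_tsv(pd.DataFrame(rows, columns=list(rows[0]) if rows else None), path)
    mat = as_mod.antisense_expression(calls, {"pooled": records})
    mpath = outdir / "antisense_rpkm.tsv"
    with mpath.open("w") as fh:
        write_matrix(mat, fh)
    return {"antisense": path, "antisense_rpkm": mpath}


def _load_dual(config: PipelineConfig, n_cells: int, seed: int):
    if config.inputs.get("mrna") and config.inputs.get("mirna"):
        mrna = read_matrix(Path(config.inputs["mrna"]).open())
        mirna = read_matrix(Path(config.inputs["mirna"]).open())
        return mrna, mirna, None
    return sim_mod.simulate_dual_transcriptome(n_cells=n_cells, seed=seed)


def _load_catalog(config: PipelineConfig, truth) -> net_mod.TargetCatalog:
    if config.inputs.get("catalog"):
        return net_mod.TargetCatalog.from_tsv(Path(config.inputs["catalog"]).open())
    if truth is not None:
        return net_mod.TargetCatalog(
            tuple((m, g, "planted") for m, g, _ in truth.mirna_targets)
        )
    raise ValueError("a target catalog is required when matrices are supplied")


def _edges_frame(edges) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": e.mirna_id,
                "gene": e.gene_id,
                "rho": e.rho,
                "p": e.p,
                "filters": ",".join(e.passed_filters),
            }
            for e in edges
        ],
        columns=["mirna", "gene", "rho", "p", "filters"],
    ).set_index("mirna")


def _run_mesc_dual(config: PipelineConfig, p: dict, outdir: Path) -> dict:
    mrna, mirna, truth = _load_dual(config, n_cells=7, seed=config.seed)
    catalog = _load_catalog(config, truth)
    edges = net_mod.infer_negative_network(
        mirna.values,
        mrna.values,
        catalog,
        alpha=p["alpha"],
        detection="min_cells",
    )
    path = outdir / "edges.tsv"
    _write_tsv(_edges_frame(edges), path)
    return {"edges": path}


def _run_hcc_dual(config: PipelineConfig, p: dict, outdir: Path) -> dict:
    mrna, mirna, truth = _load_dual(config, n_cells=32, seed=config.seed)
    catalog = _load_catalog(config, truth)

    # feature selection and clustering into expression subpopulations
    top_m = var_mod.top_variant_features(mrna, p["n_top_mrna"])
    top_mi = var_mod.top_variant_features(mirna, p["n_top_mirna"])
    feats = pd.concat(
        [
            np.log2(mrna.values.loc[top_m] + 1.0),
            np.log2(mirna.values.loc[top_mi] + 1.0),
        ]
    )
    scaled = sub_mod.scale_features(feats, "zscore")
    clust = sub_mod.hierarchical_cluster(scaled, linkage="complete")
    labels = clust.labels_at_k(p["n_clusters"])
    lpath = outdir / "labels.tsv"
    _write_tsv(
        pd.DataFrame(
            {"cell": list(labels), "cluster": [labels[c] for c in labels]}
        ).set_index("cell"),
        lpath,
    )

    # map cluster indices to subpopulation names by cluster size (largest = I)
    sizes = pd.Series(list(labels.values())).value_counts()
    name_map = {k: n for k, n in zip(sizes.index, ["I", "II", "III"])}
    subpop = {c: name_map.get(k, "III") for c, k in labels.items()}

    oncomirs = p["oncomirs"] or [m for m, _, _ in catalog.pairs][:2]
    onco = net_mod.oncomir_module(
        mirna.values, mrna.values, catalog, oncomirs, subpop, alpha=p["alpha"]
    )
    opath = outdir / "edges_oncomir.tsv"
    _write_tsv(_edges_frame(onco), opath)

    subset = [c for c, s in subpop.items() if s in ("II", "III")]
    supp = net_mod.suppressor_module(
        mirna.values, mrna.values, catalog, oncomirs, subset, alpha=p["alpha"]
    )
    spath = outdir / "edges_suppressor.tsv"
    _write_tsv(_edges_frame(supp), spath)

    # SE group activity (planted blocks when simulating)
    apath = outdir / "se_activity.tsv"
    if truth is not None and truth.se_blocks:
        combined = pd.concat([mrna.values, mirna.values])
        log = np.log2(combined + 1.0)
        groups = {se_id: members for se_id, members in truth.se_blocks}
        acts = se_mod.score_groups(log, groups, log_transform=False)
        act_df = pd.DataFrame({a.group_id: a.group_act for a in acts}).T
        _write_tsv(act_df, apath)
        return {
            "labels": lpath,
            "edges_oncomir": opath,
            "edges_suppressor": spath,
            "se_activity": apath,
        }
    return {"labels": lpath, "edges_oncomir": opath, "edges_suppressor": spath}
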