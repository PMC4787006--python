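"""End-to-end orchestration of the synthetic two-morph experiment.

``run_pipeline`` executes the stages in dependency order

    simulate -> cluster -> stats -> de -> enrich -> families/gc/dnds -> qpcr

writing per-stage plain-text outputs, a JSON-lines summary (one record per
stage with record counts, parameters, declared output files and wall time)
and a log that captures package versions and the seed.  A manifest of
SHA-256 checksums makes re-running a completed directory with
``resume=True`` a no-op: a stage is skipped, and its outputs loaded from
disk, when the configuration hash and every output checksum still match.

All randomness flows from the single configuration seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .comparative import codon_gc, compare_rates, family_counts, find_orfs, ng86
from .enrichment import enrich
from .errors import ConfigError
from .expression import compute_shares, family_share, nb_de_test, size_factors
from .qpcr import fit_standard_curve, method_correlation, relative_expression
from .redundancy import MatchParams, assembly_stats, cluster_contigs, pairwise_matches, select_representatives
from .simulate import (
    SimSpec,
    gen_annotations,
    gen_codon_pairs,
    gen_counts,
    gen_family_membership,
    gen_qpcr,
    gen_transcriptome,
)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGE_NAMES = ("simulate", "cluster", "stats", "de", "enrich", "families", "gc", "dnds", "qpcr")
TOGGLEABLE = ("cluster", "enrich", "families", "gc", "dnds", "qpcr")

THRESHOLD_DEFAULTS = {
    "min_identity": 0.99,
    "min_match_len": 200,
    "min_coverage_both": 0.5,
    "p_biased": 0.01,
    "lfc_min": 1.0,
    "p_unbiased": 0.05,
    "fdr": 0.05,
    "min_codons": 100,
}

# non-synonymous intensity multipliers for the dN-by-bias-class groups,
# mirroring the observed ordering GA-biased > RA-biased > unbiased
DNDS_GROUP_FACTORS = {"GA_biased": 3.0, "RA_biased": 2.0, "unbiased": 1.0}


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: dict = dc_field(default_factory=dict)
    sim: dict = dc_field(default_factory=dict)
    thresholds: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(TOGGLEABLE)
        if unknown:
            raise ConfigError(f"unknown stage toggles: {sorted(unknown)}")
        for name, value in self.stages.items():
            if not isinstance(value, bool):
                raise ConfigError(f"stage toggle {name!r} must be boolean")
        sim_fields = set(SimSpec.__dataclass_fields__) - {"seed"}
        unknown = set(self.sim) - sim_fields
        if unknown:
            raise ConfigError(f"unknown sim parameters: {sorted(unknown)}")
        unknown = set(self.thresholds) - set(THRESHOLD_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown thresholds: {sorted(unknown)}")
        if int(self.seed) != self.seed or self.seed < 0:
            raise ConfigError("seed must be a non-negative integer")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    def threshold(self, name: str):
        return self.thresholds.get(name, THRESHOLD_DEFAULTS[name])

    def sim_spec(self) -> SimSpec:
        sim = {
            k: (tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v)
            for k, v in self.sim.items()
        }
        return SimSpec(seed=self.seed, **sim)

    def match_params(self) -> MatchParams:
        return MatchParams(
            min_identity=self.threshold("min_identity"),
            min_match_len=self.threshold("min_match_len"),
            min_coverage_both=self.threshold("min_coverage_both"),
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "stages": dict(self.stages),
            "sim": dict(self.sim),
            "thresholds": dict(self.thresholds),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        unknown = set(data) - {"seed", "stages", "sim", "thresholds"}
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(
            seed=data.get("seed", 0),
            stages=data.get("stages", {}) or {},
            sim=data.get("sim", {}) or {},
            thresholds=data.get("thresholds", {}) or {},
        )

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Runner:
    def __init__(self, config: PipelineConfig, outdir: Path, resume: bool):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.resume = resume
        self.cfg_hash = config.config_hash()
        self.manifest_path = self.outdir / "manifest.json"
        self.old_manifest = {}
        if resume and self.manifest_path.exists():
            self.old_manifest = json.loads(self.manifest_path.read_text())
        self.manifest: dict = {}
        self.summary: list[dict] = []
        self.state: dict = {}

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _skippable(self, stage: str) -> bool:
        entry = self.old_manifest.get(stage)
        if not entry or entry.get("config_hash") != self.cfg_hash:
            return False
        for fname, digest in entry["files"].items():
            p = self.path(fname)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def run_stage(self, stage: str, compute, load) -> None:
        t0 = time.perf_counter()
        if self.resume and self._skippable(stage):
            logger.info("stage %s: outputs up to date, skipping", stage)
            info = load()
            entry = self.old_manifest[stage]
            skipped = True
        else:
            info = compute()
            files = {f: _sha256(self.path(f)) for f in info.get("files", [])}
            entry = {"config_hash": self.cfg_hash, "files": files}
            skipped = False
        self.manifest[stage] = entry
        record = {
            "stage": stage,
            "skipped": skipped,
            "wall_time_s": round(time.perf_counter() - t0, 4),
            **{k: v for k, v in info.items() if k != "files"},
            "files": sorted(entry["files"]),
        }
        self.summary.append(record)


def _write_tsv(df: pd.DataFrame, path: Path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig, outdir, *, resume: bool = False) -> list[dict]:
    """Execute the configured stages; returns the per-stage summary records."""
    r = _Runner(config, Path(outdir), resume)
    out = r.outdir

    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phyllopipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    from . import __version__

    logger.info(
        "run start: seed=%d phyllopipe=%s numpy=%s pandas=%s python=%s",
        config.seed, __version__, np.__version__, pd.__version__, platform.python_version(),
    )
    spec = config.sim_spec()

    try:
        # ---------------------------------------------------------- simulate
        def sim_compute():
            contigs, truth_clusters = gen_transcriptome(spec)
            membership, truth_families = gen_family_membership(spec)
            cq, standards, qpcr_truth = gen_qpcr(spec)
            pio.write_fasta(contigs, r.path("contigs.fasta"))
            _write_tsv(truth_clusters, r.path("truth_clusters.tsv"))
            _write_tsv(membership, r.path("membership.tsv"))
            _write_tsv(truth_families, r.path("truth_families.tsv"))
            cq.to_csv(r.path("cq.csv"), index=False)
            standards.to_csv(r.path("standards.csv"), index=False)
            qpcr_truth["curves"].to_csv(r.path("truth_qpcr_curves.csv"), index=False)
            qpcr_truth["quantities"].to_csv(r.path("truth_qpcr_quantities.csv"), index=False)
            r.state.update(
                contigs=contigs, truth_clusters=truth_clusters, membership=membership,
                truth_families=truth_families, cq=cq, standards=standards, qpcr_truth=qpcr_truth,
            )
            return {
                "n_records": len(contigs),
                "params": {"n_base_transcripts": spec.n_base_transcripts, "seed": config.seed},
                "files": [
                    "contigs.fasta", "truth_clusters.tsv", "membership.tsv", "truth_families.tsv",
                    "cq.csv", "standards.csv", "truth_qpcr_curves.csv", "truth_qpcr_quantities.csv",
                ],
            }

        def sim_load():
            contigs = pio.read_fasta(r.path("contigs.fasta"))
            curves = pd.read_csv(r.path("truth_qpcr_curves.csv"))
            r.state.update(
                contigs=contigs,
                truth_clusters=pd.read_csv(r.path("truth_clusters.tsv"), sep="\t"),
                membership=pd.read_csv(r.path("membership.tsv"), sep="\t"),
                truth_families=pd.read_csv(r.path("truth_families.tsv"), sep="\t"),
                cq=pd.read_csv(r.path("cq.csv")),
                standards=pd.read_csv(r.path("standards.csv")),
                qpcr_truth={
                    "curves": curves,
                    "quantities": pd.read_csv(r.path("truth_qpcr_quantities.csv")),
                    "log2fc": curves.set_index("gene")["true_log2fc"],
                },
            )
            return {"n_records": len(contigs)}

        r.run_stage("simulate", sim_compute, sim_load)

        # ----------------------------------------------------------- cluster
        def cluster_compute():
            contigs = r.state["contigs"]
            if not config.enabled("cluster"):
                pio.write_fasta(contigs, r.path("reduced.fasta"))
                r.state["reduced"] = contigs
                return {
                    "n_records": len(contigs),
                    "unclustered": True,
                    "params": {},
                    "files": ["reduced.fasta"],
                }
            params = config.match_params()
            matches = pairwise_matches(contigs, params)
            clusters = cluster_contigs(contigs, matches)
            reduced = select_representatives(clusters, contigs)
            pio.write_blast_tabular(matches, r.path("matches.tsv"))
            rows = [
                {"representative_id": c.representative_id, "member_ids": ",".join(sorted(c.member_ids))}
                for c in clusters
            ]
            _write_tsv(pd.DataFrame(rows), r.path("clusters.tsv"))
            pio.write_fasta(reduced, r.path("reduced.fasta"))
            r.state["reduced"] = reduced
            return {
                "n_records": len(clusters),
                "n_input_contigs": len(contigs),
                "n_reduced": len(reduced),
                "params": params.__dict__,
                "files": ["matches.tsv", "clusters.tsv", "reduced.fasta"],
            }

        def cluster_load():
            r.state["reduced"] = pio.read_fasta(r.path("reduced.fasta"))
            return {"n_records": len(r.state["reduced"])}

        r.run_stage("cluster", cluster_compute, cluster_load)

        # ------------------------------------------------------------- stats
        def stats_compute():
            stats = assembly_stats(r.state["reduced"])
            (r.path("assembly_stats.json")).write_text(json.dumps(stats.__dict__, indent=2))
            return {"n_records": stats.n_contigs, "stats": stats.__dict__, "params": {},
                    "files": ["assembly_stats.json"]}

        r.run_stage("stats", stats_compute, lambda: {"n_records": len(r.state["reduced"])})

        # ---------------------------------------------------------------- de
        def de_compute():
            reduced = r.state["reduced"]
            cm, truth_expr = gen_counts(spec, reduced)
            pio.write_counts(cm, r.path("counts.tsv"), r.path("design.tsv"))
            _write_tsv(truth_expr, r.path("truth_expression.tsv"))
            de = nb_de_test(
                cm,
                p_biased=config.threshold("p_biased"),
                lfc_min=config.threshold("lfc_min"),
                p_unbiased=config.threshold("p_unbiased"),
            )
            de.to_csv(r.path("de_results.tsv"), sep="\t")
            shares = compute_shares(cm)
            fam_ids = truth_expr.loc[truth_expr["is_family"], "contig_id"]
            fam = family_share(shares, fam_ids)
            fam.rename("family_share_pct").to_csv(r.path("family_shares.tsv"), sep="\t")
            sf = size_factors(cm)
            bias_counts = de["bias"].value_counts().to_dict()
            r.state.update(cm=cm, truth_expr=truth_expr, de=de)
            return {
                "n_records": int(de["tested"].sum()),
                "bias_counts": bias_counts,
                "family_share_pct": {k: float(v) for k, v in fam.items()},
                "size_factors": {k: round(float(v), 4) for k, v in sf.items()},
                "params": {k: config.threshold(k) for k in ("p_biased", "lfc_min", "p_unbiased")},
                "files": ["counts.tsv", "design.tsv", "truth_expression.tsv",
                          "de_results.tsv", "family_shares.tsv"],
            }

        def de_load():
            cm = pio.read_counts(r.path("counts.tsv"), r.path("design.tsv"))
            de = pd.read_csv(r.path("de_results.tsv"), sep="\t", index_col="contig_id")
            r.state.update(
                cm=cm, de=de,
                truth_expr=pd.read_csv(r.path("truth_expression.tsv"), sep="\t"),
            )
            return {"n_records": int(de["tested"].sum())}

        r.run_stage("de", de_compute, de_load)

        # ------------------------------------------------------------ enrich
        def enrich_compute():
            if not config.enabled("enrich"):
                return {"n_records": 0, "disabled": True, "params": {}, "files": []}
            truth_expr = r.state["truth_expr"]
            ann, truth_go = gen_annotations(spec, r.state["reduced"], truth_expr)
            pio.write_go_mapping(ann, r.path("go_mapping.tsv"))
            _write_tsv(truth_go, r.path("truth_go.tsv"))
            de = r.state["de"]
            files = ["go_mapping.tsv", "truth_go.tsv"]
            n_sig = 0
            for biased in ("RA_biased", "GA_biased"):
                lst = list(de.index[de["bias"] == biased])
                unb = list(de.index[de["bias"] == "unbiased"])
                fname = f"enrichment_{biased}.tsv"
                annotated = [c for c in lst if ann.get(c)]
                if annotated and any(ann.get(c) for c in unb):
                    res = enrich(lst, unb, ann, fdr=config.threshold("fdr"))
                    n_sig += int(res["significant"].sum())
                else:
                    res = pd.DataFrame(
                        columns=["term", "a", "b", "c", "d", "odds_ratio", "p", "q", "significant"]
                    )
                _write_tsv(res, r.path(fname))
                files.append(fname)
            r.state["ann"] = ann
            return {"n_records": n_sig, "params": {"fdr": config.threshold("fdr")}, "files": files}

        r.run_stage("enrich", enrich_compute, lambda: {"n_records": None})

        # ---------------------------------------------------------- families
        def families_compute():
            if not config.enabled("families"):
                return {"n_records": 0, "disabled": True, "params": {}, "files": []}
            cats = family_counts(r.state["membership"])
            cats.to_csv(r.path("family_categories.tsv"), sep="\t")
            return {
                "n_records": int(cats.loc["total", "n_families"]),
                "gene_totals": {
                    "A": int(cats.loc["total", "genes_A"]),
                    "B": int(cats.loc["total", "genes_B"]),
                },
                "params": {},
                "files": ["family_categories.tsv"],
            }

        r.run_stage("families", families_compute, lambda: {"n_records": None})

        # ---------------------------------------------------------------- gc
        def gc_compute():
            if not config.enabled("gc"):
                return {"n_records": 0, "disabled": True, "params": {}, "files": []}
            min_codons = config.threshold("min_codons")
            cds = {}
            for contig in r.state["reduced"]:
                orf = find_orfs(contig.seq, min_codons=min_codons)
                if orf is not None:
                    cds[contig.id] = orf.cds
            gc1, gc2, gc3 = codon_gc(cds)
            payload = {"n_cds": len(cds), "gc1": gc1, "gc2": gc2, "gc3": gc3}
            (r.path("codon_gc.json")).write_text(json.dumps(payload, indent=2))
            return {"n_records": len(cds), "composition": payload,
                    "params": {"min_codons": min_codons}, "files": ["codon_gc.json"]}

        r.run_stage("gc", gc_compute, lambda: {"n_records": None})

        # -------------------------------------------------------------- dnds
        def dnds_compute():
            if not config.enabled("dnds"):
                return {"n_records": 0, "disabled": True, "params": {}, "files": []}
            n_pairs, n_codons, sub_prob, omega = spec.codonpair_params
            rows = []
            groups = {}
            for group, factor in DNDS_GROUP_FACTORS.items():
                gspec = spec.with_(
                    codonpair_params=(n_pairs, n_codons, sub_prob, min(1.0, omega * factor))
                )
                pairs, truth = gen_codon_pairs(gspec, stream=f"codonpairs/{group}")
                dn_values = []
                for pid, (a, b) in enumerate(pairs):
                    est = ng86(a, b)
                    rows.append(
                        {
                            "group": group, "pair_id": pid, "dN": est.dN, "dS": est.dS,
                            "Sd": est.Sd, "Nd": est.Nd, "saturated": est.saturated,
                            "true_syn": truth.loc[pid, "syn_diffs"],
                            "true_nonsyn": truth.loc[pid, "nonsyn_diffs"],
                        }
                    )
                    dn_values.append(est.dN)
                groups[group] = np.asarray(dn_values)
            results = pd.DataFrame(rows)
            _write_tsv(results, r.path("dnds_results.tsv"))
            summary, pairwise = compare_rates(groups)
            summary.to_csv(r.path("dnds_group_summary.tsv"), sep="\t")
            _write_tsv(pairwise, r.path("dnds_pairwise.tsv"))
            medians = {g: float(np.median(v)) for g, v in groups.items()}
            return {
                "n_records": len(results),
                "dn_medians": medians,
                "params": {"codonpair_params": list(spec.codonpair_params)},
                "files": ["dnds_results.tsv", "dnds_group_summary.tsv", "dnds_pairwise.tsv"],
            }

        r.run_stage("dnds", dnds_compute, lambda: {"n_records": None})

        # -------------------------------------------------------------- qpcr
        def qpcr_compute():
            if not config.enabled("qpcr"):
                return {"n_records": 0, "disabled": True, "params": {}, "files": []}
            standards = r.state["standards"]
            curves = {
                gene: fit_standard_curve(grp["log10_quantity"], grp["cq"], gene=gene)
                for gene, grp in standards.groupby("gene")
            }
            rel = relative_expression(r.state["cq"], curves, tuple(spec.qpcr_reference_genes))
            rel.to_csv(r.path("qpcr_results.tsv"), sep="\t")
            truth_lfc = r.state["qpcr_truth"]["log2fc"]
            targets = truth_lfc.drop(list(spec.qpcr_reference_genes))
            corr = method_correlation(targets, rel)
            payload = {
                "pearson_r": corr.pearson_r, "slope": corr.slope, "intercept": corr.intercept,
                "genes": list(corr.genes),
                "qpcr_log2fc": list(corr.qpcr_log2fc),
                "rnaseq_log2fc": list(corr.rnaseq_log2fc),
            }
            (r.path("qpcr_correlation.json")).write_text(json.dumps(payload, indent=2))
            return {
                "n_records": len(rel),
                "pearson_r": corr.pearson_r,
                "efficiencies": {g: round(c.efficiency, 4) for g, c in curves.items()},
                "params": {"reference_genes": list(spec.qpcr_reference_genes)},
                "files": ["qpcr_results.tsv", "qpcr_correlation.json"],
            }

        r.run_stage("qpcr", qpcr_compute, lambda: {"n_records": None})

        # --------------------------------------------------------- finalize
        r.manifest_path.write_text(json.dumps(r.manifest, indent=2, sort_keys=True))
        with open(out / "summary.jsonl", "w") as fh:
            for record in r.summary:
                fh.write(json.dumps(record, default=_json_default) + "\n")
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
        logger.info("run complete: %d stages", len(r.summary))
    finally:
        root.removeHandler(handler)
        handler.close()
    return r.summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
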