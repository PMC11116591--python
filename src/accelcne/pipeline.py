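"""End-to-end orchestration: subset -> conserve -> extract -> accelerate ->
converge -> assign/enrich -> DEG overlap, with plain-file artifacts per stage
and summary tables mirroring the three report shapes (lineage-share
histogram, DEG overlap by minimum lineage count, enriched GO terms per
target set). Every reported number is recomputable from the stage TSVs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_io
from .acceleration import LineageSet, scaled_tree_newick, test_all, AccelTestResult
from .cne import extract_cnes
from .conservation import ConservationParams, call_elements, decode
from .convergence import lineage_share, LineageShareTable
from .deg import DEGStudy, overlap_table, recurrent_degs
from .enrichment import GODag, assign_genes, go_enrichment, target_background_sets
from .simulate import HIBERNATOR_BRANCHES

logger = logging.getLogger(__name__)

REPORT_FILES = {
    "table1": "report_lineage_share.tsv",
    "table2": "report_deg_overlap.tsv",
    "table3": "report_go_enrichment.tsv",
}


@dataclass
class PipelineConfig:
    maf: str
    mod: str
    gff3: str
    out_dir: str
    go_edges: str | None = None
    go_annotations: str | None = None
    deg_studies: dict = field(default_factory=dict)  # study id -> TSV path
    conservation_species: list | None = None  # None = use all rows
    rho: float = 0.31
    expected_length: float = 45.0
    target_coverage: float = 0.3
    min_cne_length: int = 20
    lineages: tuple = HIBERNATOR_BRANCHES
    alpha: float = 0.05
    pooled_fdr: bool = False
    d_max: int = 1_000_000
    deg_m: int = 2
    enrichment_method: str = "elim"
    min_node_size: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.lineages = tuple(cfg.lineages)
        for p in (cfg.maf, cfg.mod, cfg.gff3):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lineages"] = list(self.lineages)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _checksum(path) -> str:
    h = hashlib.md5()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run(cfg: PipelineConfig) -> dict:
    """Run all stages; returns {artifact name: path}. Deterministic given
    identical config and inputs."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("accelcne")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    paths: dict = {}
    stage = "setup"
    try:
        logger.info("parameters: %s", asdict(cfg))
        for p in (cfg.maf, cfg.mod, cfg.gff3):
            logger.info("input %s md5=%s", p, _checksum(p))

        stage = "load"
        pm = genome_io.read_mod(cfg.mod)
        blocks = list(genome_io.read_maf(cfg.maf))

        stage = "subset"
        if cfg.conservation_species:
            cons_blocks = [
                genome_io.subset_species(b, cfg.conservation_species)
                for b in blocks
            ]
        else:
            cons_blocks = blocks

        stage = "conserve"
        params = ConservationParams(cfg.rho, cfg.expected_length,
                                    cfg.target_coverage)
        decodings = decode(cons_blocks, pm, params)
        conserved = call_elements(decodings)
        paths["conserved_bed"] = out / "conserved.bed"
        with open(paths["conserved_bed"], "w") as fh:
            genome_io.write_bed(
                fh, [e.interval for e in conserved],
                [round(1000 * e.mean_posterior) for e in conserved],
            )
        logger.info("conserve: %d elements", len(conserved))

        stage = "extract"
        with open(cfg.gff3) as fh:
            cds = genome_io.read_gff3_cds(fh)
        cnes = extract_cnes(conserved, cds, cfg.min_cne_length)
        paths["cnes_bed"] = out / "cnes.bed"
        with open(paths["cnes_bed"], "w") as fh:
            genome_io.write_bed(fh, [c.interval for c in cnes])
        pd.DataFrame(
            [{"cne_id": c.id, "source_id": c.source_id} for c in cnes]
        ).to_csv(out / "cne_sources.tsv", sep="\t", index=False)
        logger.info("extract: %d CNEs from %d conserved elements",
                    len(cnes), len(conserved))

        stage = "accelerate"
        lineages = LineageSet(cfg.lineages)
        results = test_all(cnes, blocks, pm, lineages, alpha=cfg.alpha,
                           pooled_fdr=cfg.pooled_fdr)
        paths["acceleration_tsv"] = out / "acceleration.tsv"
        results.to_csv(paths["acceleration_tsv"], sep="\t", index=False)
        sig = results[results["significant"]]
        trees = [
            {"cne_id": r.cne_id, "branch": r.branch,
             "newick": scaled_tree_newick(pm, AccelTestResult(**r._asdict()))}
            for r in sig.itertuples(index=False)
        ]
        pd.DataFrame(trees, columns=["cne_id", "branch", "newick"]).to_csv(
            out / "accelerated_trees.tsv", sep="\t", index=False
        )
        logger.info("accelerate: %d significant (CNE, branch) pairs", len(sig))

        stage = "converge"
        share = lineage_share(results, cfg.lineages)
        share.per_cne.to_csv(out / "lineage_share.tsv", sep="\t", index=False)
        share.summary.to_csv(out / REPORT_FILES["table1"], sep="\t", index=False)
        paths["share_tsv"] = out / "lineage_share.tsv"
        paths["table1"] = out / REPORT_FILES["table1"]

        stage = "assign"
        with open(cfg.gff3) as fh:
            genes = genome_io.read_gff3_genes(fh)
        cne_to_genes, gene_to_cnes = assign_genes(cnes, genes, cfg.d_max)
        rows = [
            {"cne_id": cid, "genes": ",".join(sorted(gs))}
            for cid, gs in sorted(cne_to_genes.items())
        ]
        paths["assignments_tsv"] = out / "assignments.tsv"
        pd.DataFrame(rows, columns=["cne_id", "genes"]).to_csv(
            paths["assignments_tsv"], sep="\t", index=False
        )

        stage = "enrich"
        enrich_frames = []
        if cfg.go_edges and cfg.go_annotations:
            dag = GODag.from_tables(
                pd.read_csv(cfg.go_edges, sep="\t"),
                pd.read_csv(cfg.go_annotations, sep="\t"),
            )
            targets = [("k>=%d" % k, dict(k_min=k))
                       for k in range(2, len(cfg.lineages) + 1)]
            targets += [(f"branch:{b}", dict(branch=b, results=results))
                        for b in cfg.lineages]
            for label, kw in targets:
                target, background = target_background_sets(
                    share, cne_to_genes, **kw
                )
                df = go_enrichment(target, background, dag,
                                   method=cfg.enrichment_method,
                                   alpha=cfg.alpha,
                                   min_node_size=cfg.min_node_size)
                df.insert(0, "target_set", label)
                df.insert(1, "n_target_genes", len(target))
                enrich_frames.append(df)
            enrich = pd.concat(enrich_frames, ignore_index=True)
        else:
            enrich = pd.DataFrame(
                columns=["target_set", "n_target_genes", "term", "bg_count",
                         "target_count", "expected", "p", "q", "significant"]
            )
        paths["table3"] = out / REPORT_FILES["table3"]
        enrich.to_csv(paths["table3"], sep="\t", index=False)

        stage = "deg"
        if cfg.deg_studies:
            studies = [DEGStudy.from_tsv(sid, path)
                       for sid, path in sorted(cfg.deg_studies.items())]
            degs = recurrent_degs(studies, cfg.deg_m)
            deg_table = overlap_table(
                degs, share, cne_to_genes,
                k_mins=tuple(range(2, len(cfg.lineages) + 1)),
            )
        else:
            deg_table = pd.DataFrame(columns=["k_min", "n_overlap", "genes"])
        paths["table2"] = out / REPORT_FILES["table2"]
        deg_table.to_csv(paths["table2"], sep="\t", index=False)
        logger.info("pipeline complete: %s", out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return {k: str(v) for k, v in paths.items()}


def report(out_dir) -> dict:
    """Load the three summary tables from a finished run directory."""
    out = Path(out_dir)
    tables = {}
    for key, fname in REPORT_FILES.items():
        path = out / fname
        if not path.exists():
            raise FileNotFoundError(f"missing stage output: {fname}")
        tables[key] = pd.read_csv(path, sep="\t")
    return tables
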