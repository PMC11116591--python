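"""Seeded synthetic inputs with ground truth for every pipeline stage.

The generator emulates the statistical structure of a reference-anchored
mammalian whole-genome alignment: neutral background columns evolved
along a fixed 16-taxon tree (two named internal nodes, ``batAnc`` and
``rodAnc``, mark the ancestral branches of a hibernating bat and rodent
clade), implanted conserved elements with rate multiplier rho < 1 and
geometrically distributed lengths, a subset of those elements
additionally accelerated by a multiplier lambda on one to five
designated hibernator branches, CDS intervals, gene models with TSS
positions, a small GO DAG with true-path annotations, and several DEG
study lists with planted recurrence.

Columns are sampled independently given the element structure — the
exact probabilistic model the likelihood machinery assumes — so
parameter-recovery tests double as generator/inference consistency
checks. Identical configurations and seeds give byte-identical output
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np

from . import genome_io
from .genome_io import AlignmentBlock, GeneRecord, MafRow
from .intervals import GenomicInterval
from .phylo import (
    BranchScaling,
    PhyloModel,
    PhyloTree,
    SubstModel,
    read_newick,
)

BASES_ARR = np.array(list("ACGT"))

HIBERNATOR_BRANCHES = ("echTel", "eleEdw", "eriEur", "batAnc", "rodAnc")
HIBERNATOR_LEAVES = (
    "echTel", "eleEdw", "eriEur",
    "eptFus", "myoLuc", "myoDav",   # bat clade
    "speTri", "jacJac", "mesAur",   # rodent clade
)


def default_tree_newick() -> str:
    """The frozen 16-leaf mammal-like topology shipped with the package."""
    return (
        resources.files("accelcne").joinpath("data/tree16.nwk").read_text().strip()
    )


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults follow the published analysis where it fixes a value
    (rho = 0.31, mean element length 45 bp, five hibernator lineages of
    which two are ancestral branches, lambda on accelerated branches);
    the remaining knobs (genome span, element counts, annotation sizes)
    are set to a desk-scale genome that keeps every stage exercised.
    """

    tree_newick: str = field(default_factory=default_tree_newick)
    lineages: tuple = HIBERNATOR_BRANCHES
    chrom: str = "chr1"
    ref_species: str = "homSap"
    genome_length: int = 200_000
    block_size: int = 10_000
    # neutral model
    kappa: float = 2.0
    pi: tuple = (0.3, 0.2, 0.2, 0.3)
    # conserved elements
    n_elements: int = 200
    element_length_mean: float = 45.0
    element_min_length: int = 20
    element_margin: int = 30  # minimum bp between implanted elements
    rho: float = 0.31
    # acceleration
    n_accel_all: int = 10
    n_accel_subset: int = 40
    accel_lambda: float = 4.0
    # annotation
    n_cds: int = 24
    cds_length: tuple = (100, 300)
    cds_overlap_fraction: float = 0.3  # fraction of CDS placed onto elements
    n_genes: int = 40
    gene_span: int = 2_000
    # GO universe
    n_go_terms: int = 30
    n_go_true_terms: int = 2
    go_background_terms: tuple = (1, 3)  # direct annotations per gene
    # DEG studies
    n_deg_studies: int = 5
    deg_study_size: int = 30
    n_deg_recurrent: int = 12
    deg_recurrence: int = 2
    seed: int = 0

    def phylo_model(self) -> PhyloModel:
        tree = read_newick(self.tree_newick)
        return PhyloModel(tree, SubstModel.hky85(self.kappa, np.asarray(self.pi)))


@dataclass
class TruthElement:
    id: str
    start: int
    end: int
    accelerated: dict  # branch -> lambda (empty for neutral-conserved)


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every pipeline stage."""

    chrom: str
    genome_length: int
    seed: int
    elements: list
    cds: list  # [start, end] pairs
    genes: list  # dicts: id, tss, strand, start, end
    go_true_terms: list
    go_true_genes: list
    recurrent_degs: list

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["elements"] = [asdict(e) for e in self.elements]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        d["elements"] = [TruthElement(**e) for e in d["elements"]]
        return cls(**d)

    def element_intervals(self, accelerated_on=None, min_k=None) -> list:
        out = []
        for e in self.elements:
            if accelerated_on is not None and accelerated_on not in e.accelerated:
                continue
            if min_k is not None and len(e.accelerated) < min_k:
                continue
            out.append(GenomicInterval(self.chrom, e.start, e.end, id=e.id))
        return out


# ---------------------------------------------------------------------------
# column sampling
# ---------------------------------------------------------------------------


def sample_columns(pm: PhyloModel, n_cols: int, rng: np.random.Generator,
                   scaling: BranchScaling | None = None) -> tuple:
    """(leaf names, int8 columns) sampled down the tree, root base from pi."""
    if n_cols < 1:
        raise ValueError("need at least one column")
    from .phylo import effective_lengths

    tree = pm.tree
    t_eff = effective_lengths(pm, scaling)
    P = pm.model.transition_matrices(t_eff)
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n_cols, p=pm.model.pi)
    for node in tree.postorder[::-1]:  # preorder: parents before children
        node = int(node)
        if node == tree.root:
            continue
        cum = np.cumsum(P[node], axis=1)
        r = rng.random(n_cols)
        states[node] = (r[:, None] > cum[states[tree.parent[node]]]).sum(axis=1)
    leaf_ids = [tree.label_to_node[nm] for nm in tree.leaf_names]
    return tree.leaf_names, states[leaf_ids]


def simulate_element_alignment(
    pm: PhyloModel,
    length: int,
    rho: float = 1.0,
    branch_lambdas: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple:
    """Columns for one element: all branches scaled by rho, plus per-branch
    multipliers on accelerated branches. Usable directly by the LRT."""
    if length < 1:
        raise ValueError("element length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scaling = BranchScaling(s=rho, branch_scales=dict(branch_lambdas or {}))
    return sample_columns(pm, length, rng, scaling)


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------


def _element_lengths(cfg: SimConfig, rng) -> np.ndarray:
    """Geometric lengths with floor element_min_length and the configured mean."""
    excess_mean = max(cfg.element_length_mean - cfg.element_min_length, 1.0)
    lengths = cfg.element_min_length + rng.geometric(1.0 / (excess_mean + 1.0),
                                                     cfg.n_elements) - 1
    return lengths.astype(np.int64)


def _place_elements(cfg: SimConfig, lengths: np.ndarray, rng) -> list:
    margin = cfg.element_margin
    free = cfg.genome_length - int(lengths.sum()) - margin * (len(lengths) + 1)
    if free < 0:
        raise ValueError(
            f"element placement overflow: {len(lengths)} elements totalling "
            f"{int(lengths.sum())} bp do not fit in {cfg.genome_length} bp"
        )
    w = rng.random(len(lengths) + 1)
    gaps = margin + np.floor(w / w.sum() * free).astype(np.int64)
    starts, pos = [], 0
    for gap, length in zip(gaps, lengths):
        pos += int(gap)
        starts.append(pos)
        pos += int(length)
    return starts


def _branch_assignments(cfg: SimConfig, rng) -> list:
    """Per element: branch -> lambda map (empty for neutral-conserved)."""
    n = cfg.n_elements
    if cfg.n_accel_all + cfg.n_accel_subset > n:
        raise ValueError("more accelerated elements than elements")
    idx = rng.permutation(n)
    accel: list = [dict() for _ in range(n)]
    for i in idx[: cfg.n_accel_all]:
        accel[i] = {b: cfg.accel_lambda for b in cfg.lineages}
    for i in idx[cfg.n_accel_all: cfg.n_accel_all + cfg.n_accel_subset]:
        k = int(rng.integers(1, len(cfg.lineages)))  # 1..4 branches
        chosen = rng.choice(len(cfg.lineages), size=k, replace=False)
        accel[i] = {cfg.lineages[j]: cfg.accel_lambda for j in sorted(chosen)}
    return accel


@dataclass
class SimResult:
    config: SimConfig
    pm: PhyloModel
    blocks: list
    truth: SyntheticTruth
    paths: dict = field(default_factory=dict)


def simulate(cfg: SimConfig, outdir=None) -> SimResult:
    """Generate the full synthetic input set (and write it if ``outdir``)."""
    rng = np.random.default_rng(cfg.seed)
    pm = cfg.phylo_model()
    for b in cfg.lineages:
        pm.tree.branch_node(b)
    species = pm.tree.leaf_names
    if cfg.ref_species not in species:
        raise ValueError(f"reference {cfg.ref_species!r} not a leaf of the tree")

    # --- implant elements ------------------------------------------------
    lengths = _element_lengths(cfg, rng)
    starts = _place_elements(cfg, lengths, rng)
    accel = _branch_assignments(cfg, rng)
    elements = [
        TruthElement(f"elem_{i:04d}", int(s), int(s + l), a)
        for i, (s, l, a) in enumerate(zip(starts, lengths, accel))
    ]

    # --- sample the alignment matrix -------------------------------------
    mat = np.empty((len(species), cfg.genome_length), dtype=np.int8)
    covered = np.zeros(cfg.genome_length, dtype=bool)
    for e in elements:
        scaling = BranchScaling(s=cfg.rho, branch_scales=e.accelerated)
        _, cols = sample_columns(pm, e.end - e.start, rng, scaling)
        mat[:, e.start:e.end] = cols
        covered[e.start:e.end] = True
    n_neutral = int((~covered).sum())
    _, neutral_cols = sample_columns(pm, n_neutral, rng, None)
    mat[:, ~covered] = neutral_cols

    # --- CDS: placed off accelerated elements (CNEs are non-coding by
    # definition), a fraction overlapping neutral-conserved elements ------
    neutral_elems = [e for e in elements if not e.accelerated]
    accel_spans = [(e.start, e.end) for e in elements if e.accelerated]
    cds: list = []
    n_overlap = int(round(cfg.n_cds * cfg.cds_overlap_fraction))
    pick = rng.choice(len(neutral_elems), size=min(n_overlap, len(neutral_elems)),
                      replace=False)
    for j in sorted(pick):
        e = neutral_elems[j]
        length = int(rng.integers(*cfg.cds_length))
        start = max(0, e.start + (e.end - e.start) // 2 - length // 2)
        cds.append((start, min(start + length, cfg.genome_length)))
    attempts = 0
    while len(cds) < cfg.n_cds and attempts < 10_000:
        attempts += 1
        length = int(rng.integers(*cfg.cds_length))
        start = int(rng.integers(0, cfg.genome_length - length))
        if any(start < e for s, e in accel_spans if s < start + length):
            continue
        cds.append((start, start + length))
    cds.sort()

    # --- genes ------------------------------------------------------------
    genes = []
    spacing = cfg.genome_length / cfg.n_genes
    for i in range(cfg.n_genes):
        jitter = int(rng.integers(-spacing // 4, spacing // 4 + 1))
        anchor = int(min(max(i * spacing + spacing / 2 + jitter, 0),
                         cfg.genome_length - cfg.gene_span - 1))
        strand = "+" if rng.random() < 0.5 else "-"
        start, end = anchor, anchor + cfg.gene_span
        tss = start if strand == "+" else end - 1
        genes.append(GeneRecord(f"G{i:04d}", cfg.chrom, tss, strand,
                                GenomicInterval(cfg.chrom, start, end,
                                                id=f"G{i:04d}", strand=strand)))

    # --- GO universe -------------------------------------------------------
    root = "GO:0008150"
    terms = [root] + [f"GO:9{i:06d}" for i in range(1, cfg.n_go_terms)]
    edges = []
    for i, t in enumerate(terms[1:], start=1):
        n_parents = 1 if rng.random() < 0.8 else 2
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((t, terms[int(p)]))
    leafish = [t for t in terms[1:] if t not in {p for _, p in edges}] or terms[1:]
    true_terms = [terms[int(j)]
                  for j in rng.choice(range(1, len(terms)),
                                      size=cfg.n_go_true_terms, replace=False)]
    accel_ivs = [GenomicInterval(cfg.chrom, e.start, e.end)
                 for e in elements if e.accelerated]
    near_accel = [
        g.gene_id for g in genes
        if any(abs(g.tss - (iv.start + iv.end) // 2) <= 50_000 for iv in accel_ivs)
    ]
    annotations = []
    for g in genes:
        k = int(rng.integers(cfg.go_background_terms[0],
                             cfg.go_background_terms[1] + 1))
        for j in rng.choice(len(leafish), size=min(k, len(leafish)), replace=False):
            annotations.append((g.gene_id, leafish[int(j)]))
    go_true_genes = []
    for gid in near_accel:
        if rng.random() < 0.9:
            go_true_genes.append(gid)
            for t in true_terms:
                annotations.append((gid, t))

    # --- DEG studies -------------------------------------------------------
    pool = near_accel if len(near_accel) >= cfg.n_deg_recurrent else [
        g.gene_id for g in genes
    ]
    planted = [pool[int(j)] for j in
               rng.choice(len(pool), size=min(cfg.n_deg_recurrent, len(pool)),
                          replace=False)]
    studies: dict = {f"study{k + 1}": [] for k in range(cfg.n_deg_studies)}
    study_ids = list(studies)
    for gid in planted:
        k = int(rng.integers(cfg.deg_recurrence, cfg.n_deg_studies + 1))
        for j in rng.choice(cfg.n_deg_studies, size=k, replace=False):
            studies[study_ids[int(j)]].append(gid)
    decoy_counter = 0
    for sid in study_ids:
        while len(studies[sid]) < cfg.deg_study_size:
            studies[sid].append(f"DG{decoy_counter:04d}")
            decoy_counter += 1
    from collections import Counter

    seen: Counter = Counter()
    for sid in study_ids:
        seen.update(set(studies[sid]))
    recurrent = sorted(g for g, n in seen.items() if n >= cfg.deg_recurrence)

    truth = SyntheticTruth(
        chrom=cfg.chrom,
        genome_length=cfg.genome_length,
        seed=cfg.seed,
        elements=elements,
        cds=[list(c) for c in cds],
        genes=[
            {"id": g.gene_id, "tss": g.tss, "strand": g.strand,
             "start": g.span.start, "end": g.span.end}
            for g in genes
        ],
        go_true_terms=sorted(true_terms),
        go_true_genes=sorted(set(go_true_genes)),
        recurrent_degs=recurrent,
    )

    blocks = _to_blocks(cfg, species, mat)
    result = SimResult(config=cfg, pm=pm, blocks=blocks, truth=truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": outdir / "alignment.maf",
            "gff3": outdir / "annotation.gff3",
            "mod": outdir / "neutral.mod",
            "go_edges": outdir / "go_edges.tsv",
            "go_annotations": outdir / "go_annotations.tsv",
            "truth": outdir / "truth.json",
        }
        with open(paths["maf"], "w") as fh:
            genome_io.write_maf(blocks, fh)
        cds_ivs = [GenomicInterval(cfg.chrom, s, e) for s, e in cds]
        with open(paths["gff3"], "w") as fh:
            genome_io.write_gff3(fh, genes=genes, cds=cds_ivs)
        with open(paths["mod"], "w") as fh:
            genome_io.write_mod(fh, pm)
        with open(paths["go_edges"], "w") as fh:
            fh.write("child\tparent\n")
            for c, p in edges:
                fh.write(f"{c}\t{p}\n")
        with open(paths["go_annotations"], "w") as fh:
            fh.write("gene\tterm\n")
            for g, t in annotations:
                fh.write(f"{g}\t{t}\n")
        for sid in study_ids:
            p = outdir / f"deg_{sid}.tsv"
            with open(p, "w") as fh:
                fh.write("gene\n")
                for g in studies[sid]:
                    fh.write(g + "\n")
            paths[f"deg_{sid}"] = p
        truth.to_json(paths["truth"])
        result.paths = {k: str(v) for k, v in paths.items()}
    return result


def _to_blocks(cfg: SimConfig, species, mat: np.ndarray) -> list:
    """Cut the genome matrix into reference-anchored MAF blocks."""
    ref_first = [cfg.ref_species] + [s for s in species if s != cfg.ref_species]
    row_of = {s: i for i, s in enumerate(species)}
    blocks = []
    for bi, off in enumerate(range(0, cfg.genome_length, cfg.block_size)):
        end = min(off + cfg.block_size, cfg.genome_length)
        rows = []
        for sp in ref_first:
            text = "".join(BASES_ARR[mat[row_of[sp], off:end]])
            rows.append(
                MafRow(sp, cfg.chrom, off, end - off, "+", cfg.genome_length, text)
            )
        blocks.append(AlignmentBlock(rows, index=bi))
    return blocks
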