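"""Per-CNE, per-branch likelihood-ratio test for accelerated evolution.

For each element the null model frees a single element-wide rate scale
``s``; the alternative additionally frees a multiplier ``lambda >= 1``
on the tested branch (terminal or named internal). The one-sided test
statistic LRT = 2*(lnL_alt - lnL_null) is compared to the boundary
mixture 0.5*chi2_0 + 0.5*chi2_1: p = 0.5*Pr(chi2_1 >= LRT) for LRT > 0
and p = 1 at LRT = 0. Significance is controlled by Benjamini-Hochberg
FDR, by default separately within each tested branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .phylo import (
    LAMBDA_BOUNDS,
    MISSING,
    BranchScaling,
    PhyloModel,
    fit_scales,
)

logger = logging.getLogger(__name__)

ALPHA = 0.05


@dataclass
class LineageSet:
    """The branch labels tested for acceleration (child-node names)."""

    branches: tuple

    def __post_init__(self):
        self.branches = tuple(self.branches)
        if len(set(self.branches)) != len(self.branches):
            raise ValueError("duplicate branch labels in lineage set")

    def validate(self, pm: PhyloModel) -> None:
        for b in self.branches:
            pm.tree.branch_node(b)


@dataclass
class AccelTestResult:
    cne_id: str
    branch: str
    n_columns: int
    lnl_null: float
    lnl_alt: float
    s_null: float
    s_alt: float
    lambda_hat: float
    lrt: float
    p: float
    q: float | None = None
    significant: bool | None = None
    low_quality: bool = False
    converged: bool = True


def accel_lrt(
    pm: PhyloModel,
    species,
    columns: np.ndarray,
    branch: str,
    cne_id: str = "",
    lambda_bounds: tuple = LAMBDA_BOUNDS,
) -> AccelTestResult:
    """One-sided acceleration LRT for one element on one branch."""
    columns = np.atleast_2d(np.asarray(columns))
    null = fit_scales(pm, species, columns)
    alt = fit_scales(pm, species, columns, branch=branch,
                     lambda_bounds=lambda_bounds)
    lrt = 2.0 * (alt.log_likelihood - null.log_likelihood)
    if lrt < 0:
        if lrt < -1e-8:
            # alt nests the null at lambda=1; worse fits signal an
            # optimizer failure rather than a numerical wobble
            logger.warning("LRT %.3g < 0 for %s/%s; clipping", lrt, cne_id, branch)
        else:
            logger.debug("clipping tiny negative LRT %.3g for %s/%s",
                         lrt, cne_id, branch)
        lrt = 0.0
    p = 1.0 if lrt == 0.0 else 0.5 * float(chi2.sf(lrt, df=1))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    missing_frac = np.mean(np.all(columns == MISSING, axis=1))
    return AccelTestResult(
        cne_id=cne_id,
        branch=branch,
        n_columns=columns.shape[1],
        lnl_null=null.log_likelihood,
        lnl_alt=alt.log_likelihood,
        s_null=null.scaling.s,
        s_alt=alt.scaling.s,
        lambda_hat=alt.scaling.branch_scales[branch],
        lrt=lrt,
        p=p,
        low_quality=bool(missing_frac >= 0.5),
        converged=null.converged and alt.converged,
    )


def bh_fdr(pvalues, alpha: float = ALPHA) -> tuple:
    """Benjamini-Hochberg step-up q-values and significance flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    flags, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, flags


def extract_cne_columns(cnes, blocks) -> dict:
    """Per-CNE alignment slices: {cne_id: (species, int8 columns)}.

    Reference-insertion columns carry no reference coordinate and are
    excluded; species missing from a covering block contribute missing
    data. CNEs with no aligned columns map to empty arrays.
    """
    out: dict = {}
    cne_by_chrom: dict = {}
    for c in cnes:
        cne_by_chrom.setdefault(c.interval.chrom, []).append(c)
    for blk in blocks:
        chrom = blk.reference.chrom
        targets = cne_by_chrom.get(chrom)
        if not targets:
            continue
        coords = blk.ref_coords()
        species, mat = blk.encoded()
        lo, hi = blk.ref_interval.start, blk.ref_interval.end
        for c in targets:
            if c.interval.end <= lo or c.interval.start >= hi:
                continue
            mask = (coords >= c.interval.start) & (coords < c.interval.end)
            if not mask.any():
                continue
            sub = mat[:, mask]
            if c.id not in out:
                out[c.id] = {}
            for sp, row in zip(species, sub):
                out[c.id][sp] = np.concatenate(
                    [out[c.id].get(sp, np.empty(0, dtype=np.int8)), row]
                )
    result = {}
    for c in cnes:
        per_sp = out.get(c.id, {})
        if not per_sp:
            result[c.id] = ([], np.empty((0, 0), dtype=np.int8))
            continue
        species = sorted(per_sp)
        width = max(len(v) for v in per_sp.values())
        mat = np.full((len(species), width), MISSING, dtype=np.int8)
        for i, sp in enumerate(species):
            mat[i, : len(per_sp[sp])] = per_sp[sp]
        result[c.id] = (species, mat)
    return result


def test_all(
    cnes,
    blocks,
    pm: PhyloModel,
    lineages: LineageSet,
    alpha: float = ALPHA,
    pooled_fdr: bool = False,
) -> pd.DataFrame:
    """Acceleration LRTs for every (CNE, branch) pair, with FDR applied.

    FDR is Benjamini-Hochberg within each branch across all CNEs
    (``pooled_fdr=True`` pools all pairs into a single correction).
    Rows are ordered by (cne_id, branch); results are independent of the
    input order of CNEs.
    """
    lineages.validate(pm)
    columns = extract_cne_columns(cnes, blocks)
    rows = []
    for c in sorted(cnes, key=lambda x: x.id):
        species, mat = columns[c.id]
        for branch in lineages.branches:
            if mat.size == 0:
                rows.append(
                    AccelTestResult(c.id, branch, 0, np.nan, np.nan, np.nan,
                                    np.nan, np.nan, 0.0, 1.0,
                                    low_quality=True, converged=False)
                )
            else:
                rows.append(accel_lrt(pm, species, mat, branch, cne_id=c.id))
    df = pd.DataFrame([vars(r) for r in rows])
    df["q"] = np.nan
    df["significant"] = False
    if pooled_fdr:
        q, flags = bh_fdr(df["p"].to_numpy(), alpha)
        df["q"], df["significant"] = q, flags
    else:
        for branch in lineages.branches:
            mask = df["branch"] == branch
            q, flags = bh_fdr(df.loc[mask, "p"].to_numpy(), alpha)
            df.loc[mask, "q"] = q
            df.loc[mask, "significant"] = flags
    return df.sort_values(["cne_id", "branch"], ignore_index=True)


def scaled_tree_newick(pm: PhyloModel, result: AccelTestResult) -> str:
    """Newick with branch lengths scaled by the fitted alternative model.

    Useful for rendering per-element rate trees (the accelerated branch
    carries length * s * lambda, all others length * s).
    """
    scaling = BranchScaling(
        s=result.s_alt, branch_scales={result.branch: result.lambda_hat}
    )
    tree = pm.tree
    scaled = tree.lengths * scaling.s
    scaled[tree.branch_node(result.branch)] *= result.lambda_hat

    def fmt(node):
        label = tree.names[node] or ""
        if tree.is_leaf(node):
            inner = label
        else:
            inner = "(" + ",".join(fmt(c) for c in tree.children[node]) + ")" + label
        if node == tree.root:
            return inner
        return f"{inner}:{scaled[node]:.6g}"

    return fmt(tree.root) + ";"
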