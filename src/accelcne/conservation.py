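"""Two-state phylogenetic HMM for conserved-element detection.

The HMM has a neutral state emitting column likelihoods under the
neutral model as-is and a conserved state emitting likelihoods with all
branch lengths multiplied by rho < 1. Transition probabilities are
parameterized the phastCons way: mu = 1 / expected_length out of the
conserved state, and nu chosen so the stationary conserved fraction
equals the target coverage. Elements are the maximal runs of the
conserved Viterbi state; posteriors are emitted alongside.

The chain is re-initialized with its stationary distribution at the
start of each alignment block: blocks are discontiguous slabs of the
genome, so no information is carried across them. Decoding a contiguous
region as one block or two therefore differs only near the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import AlignmentBlock
from .intervals import GenomicInterval
from .phylo import BranchScaling, PhyloModel, alignment_log_likelihoods


@dataclass
class ConservationParams:
    """phastCons-style parameters (defaults are the standard published run)."""

    rho: float = 0.31
    expected_length: float = 45.0
    target_coverage: float = 0.3

    def __post_init__(self):
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0,1)")
        if self.expected_length < 1:
            raise ValueError("expected_length must be >= 1 bp")
        if not 0 < self.target_coverage < 1:
            raise ValueError("target_coverage must be in (0,1)")

    @property
    def mu(self) -> float:
        return hmm_params(self.expected_length, self.target_coverage)[0]

    @property
    def nu(self) -> float:
        return hmm_params(self.expected_length, self.target_coverage)[1]


def hmm_params(expected_length: float, target_coverage: float) -> tuple:
    """(mu, nu): conserved->neutral and neutral->conserved probabilities.

    mu = 1/expected_length; nu = mu*c/(1-c) so that the stationary
    conserved fraction nu/(mu+nu) equals the target coverage c.
    """
    if expected_length < 1:
        raise ValueError("expected_length must be >= 1 bp")
    if not 0 < target_coverage < 1:
        raise ValueError("target_coverage must be in (0,1)")
    mu = 1.0 / expected_length
    nu = mu * target_coverage / (1.0 - target_coverage)
    if not (0 < mu < 1 and 0 < nu < 1):
        raise ValueError("derived transition probabilities outside (0,1)")
    return mu, nu


@dataclass
class BlockDecoding:
    """Decoding of one alignment block (state 1 = conserved)."""

    block: AlignmentBlock
    posterior: np.ndarray  # P(conserved | data) per column
    viterbi: np.ndarray  # boolean, True = conserved
    log_forward: float
    log_backward: float
    log_viterbi: float
    posterior_neutral: np.ndarray | None = None  # complement, kept for checks


def _emission_loglik(block: AlignmentBlock, pm: PhyloModel,
                     params: ConservationParams) -> tuple:
    species, cols = block.encoded()
    ll_neutral = alignment_log_likelihoods(pm, species, cols)
    ll_conserved = alignment_log_likelihoods(
        pm, species, cols, BranchScaling(s=params.rho)
    )
    return ll_neutral, ll_conserved


def decode_block(block: AlignmentBlock, pm: PhyloModel,
                 params: ConservationParams) -> BlockDecoding:
    """Forward-backward posteriors and Viterbi path for one block."""
    if block.width == 0:
        raise ValueError("empty alignment block")
    ll_n, ll_c = _emission_loglik(block, pm, params)
    mu, nu = hmm_params(params.expected_length, params.target_coverage)
    c = params.target_coverage
    # state order: 0 = neutral, 1 = conserved
    log_init = (math.log(1 - c), math.log(c))
    log_trans = (
        (math.log(1 - nu), math.log(nu)),
        (math.log(mu), math.log(1 - mu)),
    )
    em = np.stack([ll_n, ll_c], axis=1)
    n = em.shape[0]

    fwd = np.empty((n, 2))
    fwd[0] = log_init + em[0]
    for t in range(1, n):
        prev = fwd[t - 1]
        fwd[t, 0] = np.logaddexp(prev[0] + log_trans[0][0], prev[1] + log_trans[1][0]) + em[t, 0]
        fwd[t, 1] = np.logaddexp(prev[0] + log_trans[0][1], prev[1] + log_trans[1][1]) + em[t, 1]
    log_forward = float(np.logaddexp(fwd[-1, 0], fwd[-1, 1]))

    bwd = np.empty((n, 2))
    bwd[-1] = 0.0
    for t in range(n - 2, -1, -1):
        nxt0 = bwd[t + 1, 0] + em[t + 1, 0]
        nxt1 = bwd[t + 1, 1] + em[t + 1, 1]
        bwd[t, 0] = np.logaddexp(log_trans[0][0] + nxt0, log_trans[0][1] + nxt1)
        bwd[t, 1] = np.logaddexp(log_trans[1][0] + nxt0, log_trans[1][1] + nxt1)
    log_backward = float(
        np.logaddexp(log_init[0] + em[0, 0] + bwd[0, 0],
                     log_init[1] + em[0, 1] + bwd[0, 1])
    )

    posterior = np.exp(fwd[:, 1] + bwd[:, 1] - log_forward)
    posterior = np.clip(posterior, 0.0, 1.0)
    posterior_neutral = np.clip(np.exp(fwd[:, 0] + bwd[:, 0] - log_forward),
                                0.0, 1.0)

    vit = np.empty((n, 2))
    back = np.empty((n, 2), dtype=np.int8)
    vit[0] = log_init + em[0]
    for t in range(1, n):
        for j in (0, 1):
            cand0 = vit[t - 1, 0] + log_trans[0][j]
            cand1 = vit[t - 1, 1] + log_trans[1][j]
            if cand0 >= cand1:
                vit[t, j] = cand0 + em[t, j]
                back[t, j] = 0
            else:
                vit[t, j] = cand1 + em[t, j]
                back[t, j] = 1
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(vit[-1, 1] > vit[-1, 0])
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return BlockDecoding(
        block=block,
        posterior=posterior,
        viterbi=path.astype(bool),
        log_forward=log_forward,
        log_backward=log_backward,
        log_viterbi=float(vit[-1].max()),
        posterior_neutral=posterior_neutral,
    )


def decode(blocks, pm: PhyloModel, params: ConservationParams) -> list:
    """Decode a sequence of blocks independently (stationary initialization)."""
    decodings = [decode_block(b, pm, params) for b in blocks]
    if not decodings:
        raise ValueError("empty alignment: no blocks to decode")
    return decodings


@dataclass
class ConservedElement:
    interval: GenomicInterval
    mean_posterior: float
    score: float  # Viterbi-run mean log-odds of the conserved state

    def __post_init__(self):
        if not 0 <= self.mean_posterior <= 1:
            raise ValueError("posterior must be in [0,1]")


def call_elements(decodings, id_prefix: str = "cons") -> list:
    """Maximal conserved Viterbi runs mapped to reference coordinates.

    Insertion columns (gaps in the reference) inherit the decoded state
    but produce no coordinates. Runs abutting across a block boundary at
    adjacent reference coordinates are merged into one element.
    """
    raw = []  # (chrom, start, end, posteriors)
    for dec in decodings:
        coords = dec.block.ref_coords()
        chrom = dec.block.reference.chrom
        run_start = None
        run_post: list = []
        last_pos = None
        for i in range(dec.block.width):
            pos = coords[i]
            if dec.viterbi[i]:
                if pos >= 0:
                    if run_start is None:
                        run_start = pos
                    run_post.append(dec.posterior[i])
                    last_pos = pos
            else:
                if run_start is not None:
                    raw.append((chrom, int(run_start), int(last_pos) + 1, run_post))
                run_start, run_post, last_pos = None, [], None
        if run_start is not None:
            raw.append((chrom, int(run_start), int(last_pos) + 1, run_post))

    merged: list = []
    for chrom, start, end, post in raw:
        if merged and merged[-1][0] == chrom and merged[-1][2] == start:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], end, prev[3] + post)
        else:
            merged.append((chrom, start, end, post))

    elements = []
    for k, (chrom, start, end, post) in enumerate(merged):
        mean_post = float(np.mean(post)) if post else 0.0
        mean_post = min(mean_post, 1.0)
        with np.errstate(divide="ignore"):
            odds = np.log(np.clip(post, 1e-300, 1 - 1e-12)) - np.log1p(
                -np.clip(post, 0, 1 - 1e-12)
            )
        elements.append(
            ConservedElement(
                GenomicInterval(chrom, start, end, id=f"{id_prefix}_{k:06d}"),
                mean_posterior=mean_post,
                score=float(np.mean(odds)) if post else 0.0,
            )
        )
    return elements
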