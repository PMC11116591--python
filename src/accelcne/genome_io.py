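"""Readers and writers for the pipeline's on-disk formats.

MAF (UCSC dialect, via Bio.AlignIO), GFF3 (CDS intervals and gene TSS
records), BED6, and the minimal subset of PHAST-style ``.mod`` files
(BACKGROUND, RATE_MAT, TREE) that specifies a neutral model.

MAF blocks are exposed as :class:`AlignmentBlock`: a reference-anchored
slab of gapped rows whose non-reference strands have their source
coordinates pre-converted to forward-strand positions (the alignment
text itself is kept as written).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, merge_intervals
from .phylo import MISSING, PhyloModel, SubstModel, read_newick

logger = logging.getLogger(__name__)

_SEQ_RE = re.compile(r"^[ACGTUNacgtun.\-]+$")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


@dataclass
class MafRow:
    """One 's' line: src is '<species>.<chrom>'; coordinates as in the file."""

    species: str
    chrom: str
    start: int  # MAF start on the given strand
    size: int
    strand: str  # '+' or '-'
    src_size: int
    text: str

    @property
    def forward_start(self) -> int:
        """0-based forward-strand start regardless of the row's strand."""
        if self.strand == "+":
            return self.start
        return self.src_size - self.start - self.size

    @property
    def forward_interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.forward_start, self.forward_start + self.size,
            strand=self.strand,
        )


@dataclass
class AlignmentBlock:
    """An alignment block; the first row is the reference."""

    rows: list
    index: int = 0  # position in the source file, for error messages

    _ref_coords: np.ndarray | None = field(default=None, init=False, repr=False)

    def __post_init__(self):
        if not self.rows:
            raise FormatError(f"block {self.index}: no rows")
        widths = {len(r.text) for r in self.rows}
        if len(widths) != 1:
            raise FormatError(f"block {self.index}: row length mismatch {widths}")
        for r in self.rows:
            if not _SEQ_RE.match(r.text):
                bad = re.sub(r"[ACGTUNacgtun.\-]", "", r.text)[:5]
                raise FormatError(
                    f"block {self.index}: illegal characters {bad!r} in row "
                    f"{r.species}"
                )
            if sum(ch not in ".-" for ch in r.text) != r.size:
                raise FormatError(
                    f"block {self.index}: row {r.species} has size {r.size} but "
                    f"{sum(ch not in '.-' for ch in r.text)} non-gap characters"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0].text)

    @property
    def reference(self) -> MafRow:
        return self.rows[0]

    @property
    def ref_species(self) -> str:
        return self.reference.species

    @property
    def ref_interval(self) -> GenomicInterval:
        return self.reference.forward_interval

    @property
    def species(self) -> list:
        return [r.species for r in self.rows]

    def row(self, species: str) -> MafRow:
        for r in self.rows:
            if r.species == species:
                return r
        raise KeyError(f"species {species!r} not in block {self.index}")

    def ref_coords(self) -> np.ndarray:
        """Per-column reference position; -1 for insertions (reference gaps)."""
        if self._ref_coords is None:
            ref = self.reference
            coords = np.full(self.width, -1, dtype=np.int64)
            pos = ref.forward_start
            for i, ch in enumerate(ref.text):
                if ch not in ".-":
                    coords[i] = pos
                    pos += 1
            self._ref_coords = coords
        return self._ref_coords

    def encoded(self) -> tuple:
        """(species list, int8 array rows x columns; 4 = gap/N/missing)."""
        from .phylo import encode_base

        mat = np.empty((len(self.rows), self.width), dtype=np.int8)
        for i, r in enumerate(self.rows):
            mat[i] = [encode_base(c) for c in r.text]
        return self.species, mat


def read_maf(handle):
    """Iterate :class:`AlignmentBlock` from a MAF stream or path."""
    for i, msa in enumerate(AlignIO.parse(handle, "maf")):
        rows = []
        for rec in msa:
            species, _, chrom = rec.id.partition(".")
            ann = rec.annotations
            rows.append(
                MafRow(
                    species=species,
                    chrom=chrom,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann.get("strand", 1) in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                )
            )
        yield AlignmentBlock(rows, index=i)


def write_maf(blocks, handle) -> None:
    """Write blocks in MAF format (Bio.AlignIO 'maf' dialect)."""
    msas = []
    for block in blocks:
        records = []
        for r in block.rows:
            rec = SeqRecord(Seq(r.text), id=f"{r.species}.{r.chrom}")
            rec.annotations = {
                "start": r.start,
                "size": r.size,
                "strand": 1 if r.strand == "+" else -1,
                "srcSize": r.src_size,
            }
            records.append(rec)
        msas.append(MultipleSeqAlignment(records))
    AlignIO.write(msas, handle, "maf")


def subset_species(block: AlignmentBlock, keep) -> AlignmentBlock:
    """Drop rows outside ``keep`` and any columns left all-gap.

    The reference species must be kept; reference columns are never
    all-gap in the kept set, so the block's reference span is unchanged.
    Row source coordinates are unchanged because only all-gap columns
    are removed.
    """
    keep = set(keep)
    if block.ref_species not in keep:
        raise ValueError(
            f"reference species {block.ref_species!r} not in kept set"
        )
    rows = [r for r in block.rows if r.species in keep]
    texts = np.array([list(r.text) for r in rows])
    col_ok = ~np.all(np.isin(texts, (".", "-")), axis=0)
    new_rows = [
        MafRow(r.species, r.chrom, r.start, r.size, r.strand, r.src_size,
               "".join(np.asarray(list(r.text))[col_ok]))
        for r in rows
    ]
    return AlignmentBlock(new_rows, index=block.index)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    gene_id: str
    chrom: str
    tss: int  # 0-based position of the transcription start site
    strand: str
    span: GenomicInterval

    def __post_init__(self):
        if not (self.span.start <= self.tss < self.span.end):
            raise ValueError(f"TSS outside gene span for {self.gene_id}")


_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _read_gff3(handle) -> pd.DataFrame:
    df = pd.read_csv(
        handle, sep="\t", comment="#", names=_GFF_COLUMNS, header=None,
        dtype={"seqid": str, "type": str, "attributes": str},
    )
    if df.empty:
        return df
    if (df["end"] < df["start"]).any():
        bad = df[df["end"] < df["start"]].iloc[0]
        raise FormatError(
            f"GFF3 feature with end < start at {bad.seqid}:{bad.start}-{bad.end}"
        )
    return df


def read_gff3_cds(handle) -> list:
    """CDS features as merged 0-based half-open intervals per chromosome."""
    df = _read_gff3(handle)
    if df.empty:
        return []
    cds = df[df["type"] == "CDS"]
    ivs = [
        GenomicInterval(row.seqid, int(row.start) - 1, int(row.end))
        for row in cds.itertuples()
    ]
    return merge_intervals(ivs)


def _attr(attributes: str, key: str) -> str | None:
    m = re.search(rf"(?:^|;){key}=([^;]+)", attributes)
    return m.group(1) if m else None


def read_gff3_genes(handle) -> list:
    """Gene features with their TSS (start on '+', end on '-')."""
    df = _read_gff3(handle)
    genes = []
    if df.empty:
        return genes
    for row in df[df["type"] == "gene"].itertuples():
        start0, end = int(row.start) - 1, int(row.end)
        strand = row.strand if row.strand in ("+", "-") else "+"
        gid = _attr(row.attributes, "Name") or _attr(row.attributes, "ID")
        if gid is None:
            raise FormatError(f"gene feature without ID/Name: {row.attributes!r}")
        gid = gid.removeprefix("gene:")
        tss = start0 if strand == "+" else end - 1
        genes.append(
            GeneRecord(gid, row.seqid, tss, strand,
                       GenomicInterval(row.seqid, start0, end, id=gid,
                                       strand=strand))
        )
    return genes


def write_gff3(handle, genes=(), cds=()) -> None:
    """Write gene and CDS features (inverse of the readers)."""
    handle.write("##gff-version 3\n")
    for g in genes:
        handle.write(
            f"{g.chrom}\taccelcne\tgene\t{g.span.start + 1}\t{g.span.end}\t.\t"
            f"{g.strand}\t.\tID=gene:{g.gene_id};Name={g.gene_id}\n"
        )
    for i, iv in enumerate(cds):
        handle.write(
            f"{iv.chrom}\taccelcne\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand or '+'}\t0\tID=cds{i:05d}\n"
        )


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------


def write_bed(handle, intervals, scores=None) -> None:
    for i, iv in enumerate(intervals):
        score = 0 if scores is None else scores[i]
        handle.write(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id or i}\t{score:.0f}\t"
            f"{iv.strand or '+'}\n"
        )


def read_bed(handle) -> list:
    out = []
    for line in handle:
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        out.append(
            GenomicInterval(f[0], int(f[1]), int(f[2]),
                            id=f[3] if len(f) > 3 else None,
                            strand=f[5] if len(f) > 5 else None)
        )
    return out


# ---------------------------------------------------------------------------
# PHAST-style .mod files
# ---------------------------------------------------------------------------

_MOD_KEYS = {"BACKGROUND", "RATE_MAT", "TREE", "ALPHABET", "ORDER", "SUBST_MOD"}


def read_mod(handle) -> PhyloModel:
    """Parse the BACKGROUND / RATE_MAT / TREE subset of a PHAST .mod file.

    The rate matrix is renormalized to one expected substitution per unit
    branch length; other keys are ignored with a warning.
    """
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_mod(fh)
    lines = [ln.rstrip("\n") for ln in handle]
    fields: dict = {}
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        if key == "RATE_MAT":
            mat = []
            while i < len(lines) and len(mat) < 4:
                row = lines[i].strip()
                i += 1
                if row:
                    mat.append([float(x) for x in row.split()])
            if len(mat) != 4 or any(len(r) != 4 for r in mat):
                raise FormatError("RATE_MAT must be a 4x4 matrix")
            fields["RATE_MAT"] = np.array(mat)
        elif key in _MOD_KEYS:
            fields[key] = value.strip()
        else:
            logger.warning("ignoring unknown .mod key %r", key)
    for required in ("BACKGROUND", "RATE_MAT", "TREE"):
        if required not in fields:
            raise FormatError(f"missing {required} in .mod file")
    pi = np.array([float(x) for x in fields["BACKGROUND"].split()])
    if pi.shape != (4,):
        raise FormatError("BACKGROUND must have 4 frequencies")
    if abs(pi.sum() - 1.0) > 1e-3:
        raise FormatError(f"BACKGROUND sums to {pi.sum():.6f}, not 1")
    pi = pi / pi.sum()
    model = SubstModel.from_rate_matrix(fields["RATE_MAT"], pi)
    tree = read_newick(fields["TREE"])
    return PhyloModel(tree, model)


def write_mod(handle, pm: PhyloModel) -> None:
    handle.write("ALPHABET: A C G T\nORDER: 0\nSUBST_MOD: REV\n")
    handle.write("BACKGROUND: " + " ".join(f"{x:.10g}" for x in pm.model.pi) + "\n")
    handle.write("RATE_MAT:\n")
    for row in pm.model.Q:
        handle.write("  " + " ".join(f"{x: .10g}" for x in row) + "\n")
    handle.write("TREE: " + pm.tree.to_newick() + "\n")
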