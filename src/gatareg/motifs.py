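"""Orientation-aware IUPAC motif counting in windows around the TSS.

Counts occurrences of degenerate DNA motifs (e.g. the GATA element
5'-GATAA-3' and the carbon response element 5'-GYGGGG-3') on both genome
strands within signed distance windows around each gene's transcription
start site. Windows live in a gene-oriented frame: the TSS is 0, upstream
offsets are negative, and for minus-strand genes "upstream" is genomic
rightward. Per-window counts are reported as the categories 0 / 1 / "2 or
more", the binning used when relating promoter motif content to
expression changes in transcription-factor deletion mutants.

All coordinates are 0-based, end-exclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """A named degenerate DNA motif over the IUPAC alphabet."""

    name: str
    iupac: str

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("empty motif")
        bad = set(self.iupac.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC letter(s) {sorted(bad)} in {self.iupac}")
        object.__setattr__(self, "iupac", self.iupac.upper())

    def __len__(self) -> int:
        return len(self.iupac)


def _regex(iupac: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(f"[{IUPAC[c]}]" for c in iupac)
    return re.compile(f"(?=({body}))")


def iupac_matcher(motif: MotifSpec):
    """Predicate over DNA strings: True iff the string matches the motif."""
    pat = re.compile("".join(f"[{IUPAC[c]}]" for c in motif.iupac) + r"\Z")
    return lambda s: bool(pat.match(s.upper()))


def find_occurrences(seq: str, motif: MotifSpec) -> list[tuple[int, str]]:
    """All (start, genome_strand) occurrences of the motif on both strands
    of the forward sequence ``seq``. A '+' occurrence matches the motif
    itself; a '-' occurrence matches its reverse complement."""
    seq = seq.upper()
    out = [(m.start(), "+") for m in _regex(motif.iupac).finditer(seq)]
    rc = reverse_complement(motif.iupac)
    out += [(m.start(), "-") for m in _regex(rc).finditer(seq)]
    out.sort()
    return out


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand and a 0-based TSS genomic coordinate."""

    gene_id: str
    contig: str
    strand: str
    tss: int
    span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS")


@dataclass(frozen=True)
class MotifOccurrence:
    gene_id: str
    motif_name: str
    contig: str
    genomic_start: int
    genomic_end: int
    genome_strand: str
    signed_offset: int


def gene_frame_offset(gene: GeneModel, genomic_start: int, genomic_end: int) -> int:
    """Gene-frame coordinate of the 5'-most occupied base of an occurrence.

    For a plus-strand gene this is genomic_start - tss; for a minus-strand
    gene it is tss - (genomic_end - 1).
    """
    if gene.strand == "+":
        return genomic_start - gene.tss
    return gene.tss - (genomic_end - 1)


def _window_to_genomic(gene: GeneModel, window: tuple[int, int]) -> tuple[int, int]:
    lo, hi = window
    if gene.strand == "+":
        return gene.tss + lo, gene.tss + hi
    return gene.tss - hi + 1, gene.tss - lo + 1


def scan_window(
    genome: Mapping[str, str],
    gene: GeneModel,
    window: tuple[int, int],
    motif: MotifSpec,
) -> tuple[list[MotifOccurrence], bool]:
    """Motif occurrences whose gene-frame start lies in ``window``.

    ``window`` is a half-open signed interval like (-200, 0) or (0, 200)
    in the gene-oriented frame. Both genome strands are scanned. Returns
    the occurrences and a flag marking truncation at a contig edge.
    An occurrence belongs to the window iff its 5'-most base in the gene
    frame lies inside it; occurrences may extend past the window's
    downstream boundary.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must be non-empty, (lo, hi) with lo < hi")
    if gene.contig not in genome:
        raise KeyError(f"{gene.gene_id}: contig {gene.contig} not in genome")
    contig_seq = genome[gene.contig]
    clen = len(contig_seq)
    if not (0 <= gene.tss < clen):
        raise ValueError(f"{gene.gene_id}: TSS {gene.tss} off contig {gene.contig}")
    g_lo, g_hi = _window_to_genomic(gene, window)
    clipped = g_lo < 0 or g_hi > clen
    # allow occurrences starting in-window to extend L-1 past the
    # downstream (gene-frame) edge
    L = len(motif)
    if gene.strand == "+":
        e_lo, e_hi = g_lo, g_hi + L - 1
    else:
        e_lo, e_hi = g_lo - (L - 1), g_hi
    e_lo_c, e_hi_c = max(e_lo, 0), min(e_hi, clen)
    if e_lo_c >= e_hi_c:
        return [], clipped
    sub = contig_seq[e_lo_c:e_hi_c]
    occs = []
    for start, strand in find_occurrences(sub, motif):
        gs = e_lo_c + start
        ge = gs + L
        off = gene_frame_offset(gene, gs, ge)
        if lo <= off < hi:
            occs.append(
                MotifOccurrence(
                    gene_id=gene.gene_id,
                    motif_name=motif.name,
                    contig=gene.contig,
                    genomic_start=gs,
                    genomic_end=ge,
                    genome_strand=strand,
                    signed_offset=off,
                )
            )
    occs.sort(key=lambda o: (o.signed_offset, o.genome_strand))
    return occs, clipped


def default_intervals(max_distance: int = 2000, step: int = 200) -> list[tuple[int, int]]:
    """The window grid: (-d, 0) and (0, d) for d = step .. max_distance."""
    if step <= 0:
        raise ValueError("step must be positive")
    if max_distance % step != 0:
        raise ValueError("step must divide max_distance")
    ds = range(step, max_distance + 1, step)
    return [(-d, 0) for d in ds] + [(0, d) for d in ds]


def interval_label(iv: tuple[int, int]) -> str:
    return f"{iv[0]}:{iv[1]}"


@dataclass
class WindowCountMatrix:
    """Per-gene capped motif-count categories for a grid of TSS windows.

    ``category`` is genes x intervals with values in {0, 1, 2} where 2
    means "2 or more"; ``clipped`` flags windows truncated at a contig
    edge. In per-strand mode categories for each genome strand are kept
    separately in ``per_strand_category`` (index gene, columns
    (interval, strand)).
    """

    motif_name: str
    intervals: list[tuple[int, int]]
    category: pd.DataFrame
    clipped: pd.DataFrame
    counts: pd.DataFrame
    per_strand_category: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.category.index)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# motif {self.motif_name}: capped counts (0/1/2+) per TSS window\n")
            out = self.category.copy()
            for iv in self.intervals:
                out[f"clipped[{interval_label(iv)}]"] = self.clipped[interval_label(iv)]
            out.to_csv(fh, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "WindowCountMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        cat_cols = [c for c in df.columns if not c.startswith("clipped[")]
        intervals = [tuple(map(int, c.split(":"))) for c in cat_cols]
        clip = df[[f"clipped[{c}]" for c in cat_cols]].copy()
        clip.columns = cat_cols
        return cls(
            motif_name="",
            intervals=intervals,
            category=df[cat_cols],
            clipped=clip.astype(bool),
            counts=df[cat_cols].copy(),
        )


def count_matrix(
    genome: Mapping[str, str],
    genes: Sequence[GeneModel],
    motif: MotifSpec,
    max_distance: int = 2000,
    step: int = 200,
    cap: int = 2,
    per_strand: bool = False,
) -> WindowCountMatrix:
    """Capped motif-count categories over the full window grid.

    By default counts are combined over both genome strands before the
    cap is applied; ``per_strand=True`` additionally records per-strand
    capped categories. Each gene is scanned once over its full
    [-max_distance, max_distance) span and occurrences are binned by
    gene-frame start offset, which is equivalent to per-window scanning.
    """
    intervals = default_intervals(max_distance, step)
    labels = [interval_label(iv) for iv in intervals]
    gene_ids = [g.gene_id for g in genes]
    counts = np.zeros((len(genes), len(intervals)), dtype=int)
    clipped = np.zeros_like(counts, dtype=bool)
    strand_counts = {s: np.zeros_like(counts) for s in "+-"} if per_strand else None
    full = (-max_distance, max_distance)
    for gi, gene in enumerate(genes):
        occs, _ = scan_window(genome, gene, full, motif)
        offsets = np.array([o.signed_offset for o in occs], dtype=int)
        strands = [o.genome_strand for o in occs]
        contig_len = len(genome[gene.contig])
        for wi, iv in enumerate(intervals):
            lo, hi = iv
            g_lo, g_hi = _window_to_genomic(gene, iv)
            clipped[gi, wi] = g_lo < 0 or g_hi > contig_len
            if offsets.size:
                inside = (offsets >= lo) & (offsets < hi)
                counts[gi, wi] = int(inside.sum())
                if per_strand:
                    for s in "+-":
                        strand_counts[s][gi, wi] = sum(
                            1 for k in np.flatnonzero(inside) if strands[k] == s
                        )
    cat = pd.DataFrame(np.minimum(counts, cap), index=gene_ids, columns=labels)
    per_strand_df = None
    if per_strand:
        per_strand_df = pd.concat(
            {
                s: pd.DataFrame(
                    np.minimum(strand_counts[s], cap), index=gene_ids, columns=labels
                )
                for s in "+-"
            },
            axis=1,
        )
    return WindowCountMatrix(
        motif_name=motif.name,
        intervals=intervals,
        category=cat,
        clipped=pd.DataFrame(clipped, index=gene_ids, columns=labels),
        counts=pd.DataFrame(counts, index=gene_ids, columns=labels),
        per_strand_category=per_strand_df,
    )


def export_sites(occurrences: Iterable[MotifOccurrence], path) -> None:
    """Write occurrences as 6-column BED, sorted by (contig, start)."""
    rows = sorted(
        occurrences, key=lambda o: (o.contig, o.genomic_start, o.genomic_end, o.genome_strand)
    )
    with open(path, "w") as fh:
        fh.write("# contig\tstart\tend\tname\tscore\tstrand\n")
        for o in rows:
            name = f"{o.gene_id}:{o.motif_name}"
            fh.write(
                f"{o.contig}\t{o.genomic_start}\t{o.genomic_end}\t{name}\t0\t{o.genome_strand}\n"
            )


def read_sites_bed(path) -> pd.DataFrame:
    """Parse a BED file written by :func:`export_sites`."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )


# ---------------------------------------------------------------------------
# genome / gene-model input

def read_genome(path) -> dict[str, str]:
    """Load a genome FASTA into a dict of upper-case contig strings."""
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def read_genes_gff3(path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene models from GFF3; TSS is the strand-appropriate 5' end."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        start0 = feat.start - 1  # GFF3 is 1-based inclusive
        end0 = feat.end
        tss = start0 if feat.strand == "+" else end0 - 1
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(gene_id=gid, contig=feat.seqid, strand=feat.strand,
                      tss=tss, span=(start0, end0))
        )
    return genes


def read_genes_bed(path) -> list[GeneModel]:
    """Gene models from BED6; TSS is the strand-appropriate interval end."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    genes = []
    for row in df.itertuples():
        tss = row.start if row.strand == "+" else row.end - 1
        genes.append(
            GeneModel(gene_id=str(row.name), contig=row.contig, strand=row.strand,
                      tss=int(tss), span=(int(row.start), int(row.end)))
        )
    return genes
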