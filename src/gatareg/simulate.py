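"""Synthetic fixtures with exact ground truth.

Everything downstream of raw data is exercised on simulated inputs whose
truth is known by construction:

* genomes whose background is rejection-sampled to contain *zero*
  occurrences of the configured motifs on either strand, with gene
  models spaced widely enough that TSS windows never overlap — planted
  motif counts are then recovered exactly, not just on average;
* planted GATAA / GYGGGG instances at controlled counts and signed
  offsets from each TSS, verified by rescanning after every insertion;
* FPKM tables in which the mutant-vs-wild-type shift of each gene is
  beta * min(planted count, 2) per motif plus Gaussian replicate noise,
  mirroring the 0 / 1 / 2+ category statistic under test;
* proteomes of cysteine-free background sequence carrying planted
  spaced-cysteine domains and near-miss decoys (wrong spacing, broken
  conserved core, short tail).

Generators are pure functions of (parameters, seed). A master seed fans
out to per-component streams via CRC32-tagged child seeds, so components
are independent but jointly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import (
    GeneModel,
    MotifSpec,
    find_occurrences,
    reverse_complement,
    IUPAC,
)
from .expression import ExpressionMatrix

DEFAULT_MOTIFS = (MotifSpec("GATAA", "GATAA"), MotifSpec("GYGGGG", "GYGGGG"))

_DNA = np.array(list("ACGT"))
_AA_NO_C = np.array(list("ADEFGHIKLMNPQRSTVWY"))


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-component stream: seeded by (master seed, crc32(tag))."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(tag.encode())])


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to recompute every expected output.

    ``motif_sites[gene_id][motif_name]`` is a list of (signed_offset,
    genome_strand) planted occurrences; ``effects`` holds the expression
    model parameters (beta per motif, noise SD, baseline log2-FPKM
    mean/SD, mutant strain); ``domains[protein_id]`` records (start,
    spacing, strict) for planted zinc-finger domains and the decoy kind
    for near-misses.
    """

    seed: int
    motif_names: list[str] = field(default_factory=list)
    genes: dict = field(default_factory=dict)       # gene_id -> {tss, strand, contig}
    motif_sites: dict = field(default_factory=dict)  # gene_id -> motif -> [(off, strand)]
    effects: dict = field(default_factory=dict)
    domains: dict = field(default_factory=dict)      # protein_id -> record

    def expected_window_count(self, gene_id: str, motif: str,
                              window: tuple[int, int]) -> int:
        lo, hi = window
        sites = self.motif_sites.get(gene_id, {}).get(motif, [])
        return sum(1 for off, _ in sites if lo <= off < hi)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        raw["motif_sites"] = {
            g: {m: [tuple(s) for s in sites] for m, sites in per.items()}
            for g, per in raw["motif_sites"].items()
        }
        return cls(**raw)


_DNA_TABLE = bytes.maketrans(bytes([0, 1, 2, 3]), b"ACGT")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(rng.integers(0, 4, size=n, dtype=np.uint8)).translate(_DNA_TABLE).decode()


def _motif_free(seq: str, motifs, rng: np.random.Generator,
                max_rounds: int = 60) -> str:
    """Resample motif-hit spans until the sequence is clean on both strands."""
    for _ in range(max_rounds):
        spans = []
        for m in motifs:
            spans += [(start, len(m)) for start, _ in find_occurrences(seq, m)]
        if not spans:
            return seq
        chars = list(seq)
        for start, L in spans:
            chars[start : start + L] = _random_dna(rng, L)
        seq = "".join(chars)
    raise RuntimeError("could not rid background of motif occurrences")


def gen_genome_and_genes(
    n_genes: int,
    seed: int,
    intergenic_min: int = 4200,
    contig_length: int | None = None,
    margin: int = 2200,
    motifs=DEFAULT_MOTIFS,
    contig: str = "chr1",
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Motif-free random genome with well-separated genes on both strands.

    TSS positions are laid out with at least ``intergenic_min`` bp between
    consecutive genes (default 4200, so +/-2000 bp windows of neighbouring
    genes cannot overlap) and ``margin`` bp from each contig edge.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = child_rng(seed, "genome")
    jitter_max = 200
    needed = 2 * margin + (n_genes - 1) * (intergenic_min + jitter_max) + 1
    if contig_length is None:
        contig_length = needed
    elif contig_length < needed:
        raise ValueError(
            f"contig_length {contig_length} too short for {n_genes} genes "
            f"(needs >= {needed})"
        )
    seq = _random_dna(rng, contig_length)
    seq = _motif_free(seq, motifs, rng)
    genome = {contig: seq}

    tss = margin
    genes: list[GeneModel] = []
    truth = SyntheticTruth(seed=int(seed), motif_names=[m.name for m in motifs])
    width = len(str(n_genes - 1))
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{i:0{width}d}"
        span_len = 500
        if strand == "+":
            span = (tss, min(tss + span_len, contig_length))
        else:
            span = (max(tss - span_len + 1, 0), tss + 1)
        genes.append(GeneModel(gene_id=gid, contig=contig, strand=strand,
                               tss=int(tss), span=span))
        truth.genes[gid] = {"tss": int(tss), "strand": strand, "contig": contig}
        truth.motif_sites[gid] = {m.name: [] for m in motifs}
        tss += intergenic_min + int(rng.integers(0, jitter_max + 1))
    return genome, genes, truth


def _resolve_iupac(iupac: str, rng: np.random.Generator) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in iupac
    )


def plant_motifs(
    genome: dict[str, str],
    genes: list[GeneModel],
    truth: SyntheticTruth,
    motif: MotifSpec,
    seed: int,
    count_distribution: dict[int, float] | None = None,
    offset_range: tuple[int, int] = (-2000, 0),
    all_motifs=DEFAULT_MOTIFS,
    max_retries: int = 50,
) -> None:
    """Plant per-gene motif instances at sampled signed offsets.

    The number of sites per gene is drawn from ``count_distribution``
    (default uniform over 0-3); offsets are drawn uniformly from
    ``offset_range`` in the gene frame (the site's 5'-most base lands in
    the range), and each instance goes on a uniformly chosen genome
    strand. After planting, the gene's whole +/-2 kb span is rescanned
    for *all* configured motifs and the observed occurrence set must
    equal the planted truth exactly; on any collision the gene's planting
    is redone with fresh offsets. Updates ``genome`` and ``truth`` in
    place.
    """
    if count_distribution is None:
        count_distribution = {0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25}
    rng = child_rng(seed, f"plant:{motif.name}")
    counts = np.array(sorted(count_distribution))
    probs = np.array([count_distribution[c] for c in counts], dtype=float)
    probs = probs / probs.sum()
    L = len(motif)
    lo, hi = offset_range
    if hi - lo < L:
        raise ValueError("offset_range narrower than the motif")

    # mutate contigs as char lists; verification looks only at the local
    # +/- 2 kb neighbourhood of each gene, which is safe because genes are
    # generated with non-overlapping windows
    chars: dict[str, list[str]] = {c: list(s) for c, s in genome.items()}
    reach = 2000 + L
    for gene in genes:
        contig_chars = chars[gene.contig]
        clen = len(contig_chars)
        n_sites = int(rng.choice(counts, p=probs))
        if n_sites == 0:
            continue
        planted = None
        region_lo = max(gene.tss - reach, 0)
        region_hi = min(gene.tss + reach + 1, clen)
        for _attempt in range(max_retries):
            offsets = _distinct_offsets(rng, n_sites, lo, hi - L + 1, min_sep=L)
            strands = ["+" if rng.random() < 0.5 else "-" for _ in offsets]
            edits = []
            ok = True
            for off, strand in zip(offsets, strands):
                if gene.strand == "+":
                    gs = gene.tss + off
                else:
                    gs = gene.tss - off - L + 1
                if gs < region_lo or gs + L > region_hi:
                    ok = False
                    break
                inst = _resolve_iupac(motif.iupac, rng)
                if strand == "-":
                    inst = reverse_complement(inst)
                edits.append((gs, inst))
            if not ok:
                continue
            local = contig_chars[region_lo:region_hi]
            for gs, inst in edits:
                local[gs - region_lo : gs - region_lo + L] = inst
            local_seq = "".join(local)
            if _verify_gene_local(local_seq, region_lo, gene, truth, motif,
                                  list(zip(offsets, strands)), all_motifs):
                for gs, inst in edits:
                    contig_chars[gs : gs + L] = inst
                planted = list(zip(offsets, strands))
                break
        if planted is None:
            raise RuntimeError(
                f"could not plant {n_sites} {motif.name} sites for {gene.gene_id}"
            )
        truth.motif_sites[gene.gene_id][motif.name] = [
            (int(o), s) for o, s in sorted(planted)
        ]
    for c in genome:
        genome[c] = "".join(chars[c])


def _distinct_offsets(rng, n, lo, hi, min_sep):
    for _ in range(200):
        cand = sorted(int(rng.integers(lo, hi)) for _ in range(n))
        if all(b - a >= min_sep for a, b in zip(cand, cand[1:])):
            return cand
    raise RuntimeError("could not sample non-overlapping offsets")


def _verify_gene_local(local_seq, region_lo, gene, truth, motif,
                       planted, all_motifs) -> bool:
    """Planted occurrence sets must match a rescan of the gene's +/-2 kb span."""
    from .motifs import GeneModel, scan_window

    genome = {gene.contig: local_seq}
    local_gene = GeneModel(gene_id=gene.gene_id, contig=gene.contig,
                           strand=gene.strand, tss=gene.tss - region_lo)
    for m in all_motifs:
        if m.name == motif.name:
            expected = set(planted)
        else:
            expected = set(map(tuple, truth.motif_sites[gene.gene_id].get(m.name, [])))
        occs, _ = scan_window(genome, local_gene, (-2000, 2000), m)
        observed = {(o.signed_offset, o.genome_strand) for o in occs}
        if observed != expected:
            return False
    return True


def gen_expression(
    truth: SyntheticTruth,
    seed: int,
    beta: dict[str, float] | None = None,
    sigma: float = 0.5,
    replicates: int = 4,
    baseline_mean: float = 5.0,
    baseline_sd: float = 2.0,
    wt_strain: str = "WT",
    mutant_strain: str = "dgzf3",
    condition: str = "ammonium",
    cap: int = 2,
) -> ExpressionMatrix:
    """FPKM table with a motif-count-dependent mutant shift.

    Per gene, baseline log2 FPKM ~ Normal(baseline_mean, baseline_sd);
    every sample adds Normal(0, sigma) replicate noise, and mutant
    samples add sum over motifs of beta[motif] * min(planted count, cap).
    FPKM = 2 ** log2-value.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    beta = dict(beta or {"GATAA": 0.5})
    rng = child_rng(seed, "expression")
    gene_ids = list(truth.genes)
    base = rng.normal(baseline_mean, baseline_sd, size=len(gene_ids))
    shift = np.zeros(len(gene_ids))
    for gi, gid in enumerate(gene_ids):
        for m, b in beta.items():
            count = len(truth.motif_sites.get(gid, {}).get(m, []))
            shift[gi] += b * min(count, cap)
    cols = {}
    meta_rows = []
    for strain in (wt_strain, mutant_strain):
        for r in range(1, replicates + 1):
            sample = f"{strain}_{condition}_r{r}"
            noise = rng.normal(0.0, sigma, size=len(gene_ids))
            log2v = base + noise + (shift if strain == mutant_strain else 0.0)
            cols[sample] = np.power(2.0, log2v)
            meta_rows.append(
                {"sample": sample, "strain": strain,
                 "condition": condition, "replicate": r}
            )
    fpkm = pd.DataFrame(cols, index=gene_ids)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth.effects = {
        "beta": beta, "sigma": float(sigma), "cap": int(cap),
        "baseline_mean": float(baseline_mean), "baseline_sd": float(baseline_sd),
        "replicates": int(replicates),
        "wt_strain": wt_strain, "mutant_strain": mutant_strain,
        "condition": condition,
    }
    return ExpressionMatrix(fpkm=fpkm, samples=meta)


# ---------------------------------------------------------------------------
# proteome

DECOY_KINDS = ("spacing_16", "spacing_21", "no_T", "no_W", "no_R", "short_tail")


def _rand_aa(rng, n: int) -> str:
    return "".join(rng.choice(_AA_NO_C, size=n)) if n else ""


def _generic_domain(rng, spacing: int) -> str:
    mid = list(_rand_aa(rng, spacing))
    if spacing == 17 and len(mid) > 4 and mid[4] == "T":
        mid[4] = "A"  # keep plain spacing-17 plants from matching the strict core
    return "C" + _rand_aa(rng, 2) + "C" + "".join(mid) + "C" + _rand_aa(rng, 2) + "C"


def _strict_domain(rng) -> str:
    return (
        "C" + _rand_aa(rng, 2) + "C" + _rand_aa(rng, 4)
        + "T" + str(rng.choice(list("PS"))) + str(rng.choice(list("LV")))
        + "WR" + str(rng.choice(list("RK")))
        + _rand_aa(rng, 7) + "CN" + _rand_aa(rng, 1) + "C"
    )


def gen_proteome(
    seed: int,
    planted: list[tuple[int, bool]] | None = None,
    decoys: list[str] | None = None,
    n_background: int = 5,
    min_len: int = 150,
    max_len: int = 300,
    truth: SyntheticTruth | None = None,
) -> tuple[list, SyntheticTruth]:
    """Proteins over a Cys-free background with planted domains and decoys.

    ``planted`` lists one (spacing, strict) spec per domain-bearing
    protein; ``decoys`` draws from {spacing_16, spacing_21, no_T, no_W,
    no_R, short_tail}. Backgrounds contain no cysteine, so a planted
    domain yields exactly one scanner hit and decoys the failures they
    are built to produce.
    """
    from .zf_scan import ProteinRecord

    if planted is None:
        planted = [(17, True), (17, False), (18, False), (19, False), (20, False)]
    decoys = list(decoys or [])
    bad = set(decoys) - set(DECOY_KINDS)
    if bad:
        raise ValueError(f"unknown decoy kinds {sorted(bad)}")
    rng = child_rng(seed, "proteome")
    truth = truth or SyntheticTruth(seed=int(seed))
    proteins = []
    idx = 0

    def background(n):
        return _rand_aa(rng, n)

    def place(domain: str, tail_min: int = 25):
        head = background(int(rng.integers(20, 60)))
        tail = background(int(rng.integers(tail_min, tail_min + 80)))
        return head + domain + tail, len(head)

    for spacing, strict in planted:
        pid = f"p{idx:03d}"
        idx += 1
        domain = _strict_domain(rng) if strict else _generic_domain(rng, spacing)
        seq, start = place(domain)
        proteins.append(ProteinRecord(id=pid, sequence=seq, species="synthetic"))
        truth.domains[pid] = {
            "kind": "planted", "start": start, "spacing": int(spacing),
            "strict": bool(strict),
        }
    for kind in decoys:
        pid = f"p{idx:03d}"
        idx += 1
        if kind == "spacing_16":
            domain = _generic_domain(rng, 16)
        elif kind == "spacing_21":
            domain = _generic_domain(rng, 21)
        elif kind in ("no_T", "no_W", "no_R"):
            d = list(_strict_domain(rng))
            pos = {"no_T": 8, "no_W": 11, "no_R": 12}[kind]
            d[pos] = "G"
            domain = "".join(d)
        elif kind == "short_tail":
            domain = _strict_domain(rng)
        if kind == "short_tail":
            head = background(int(rng.integers(20, 60)))
            tail = background(int(rng.integers(0, 25)))  # < 25: strict must fail
            seq, start = head + domain + tail, len(head)
        else:
            seq, start = place(domain)
        proteins.append(ProteinRecord(id=pid, sequence=seq, species="synthetic"))
        truth.domains[pid] = {"kind": f"decoy:{kind}", "start": start}
    for _ in range(n_background):
        pid = f"p{idx:03d}"
        idx += 1
        seq = background(int(rng.integers(min_len, max_len + 1)))
        proteins.append(ProteinRecord(id=pid, sequence=seq, species="synthetic"))
        truth.domains[pid] = {"kind": "background"}
    return proteins, truth


# ---------------------------------------------------------------------------
# file output

def write_genome_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genes_gff3(genes, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start, end = g.span if g.span else (g.tss, g.tss + 1)
            fh.write(
                f"{g.contig}\tgatareg_sim\tgene\t{start + 1}\t{end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_proteins_fasta(proteins, path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def write_expression_tsv(expr: ExpressionMatrix, expr_path, meta_path) -> None:
    with open(expr_path, "w") as fh:
        fh.write("# synthetic FPKM table\n")
        expr.fpkm.to_csv(fh, sep="\t", index_label="gene_id")
    with open(meta_path, "w") as fh:
        fh.write("# sample metadata\n")
        expr.samples.to_csv(fh, sep="\t", index_label="sample")
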