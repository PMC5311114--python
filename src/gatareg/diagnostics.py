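"""Self-checks against independent oracles and planted synthetic truth.

Each routine regenerates its own inputs from a seed, runs the package's
implementation, and measures agreement with an independent reference:
a quadratic brute-force scanner, exhaustive combinatorial sums, additive
distance matrices from known trees, or the planted ground truth of the
synthetic-data generators. They are used by the test suite and by the
reproduction script; all are deterministic given the seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import expression as ex
from . import motifs as mo
from . import phylo as ph
from . import simulate as sim
from . import zf_scan as zf
from .simulate import child_rng

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


# ---------------------------------------------------------------------------
# zinc-finger scanner vs brute force

def brute_force_scan(seq: str, spacings=(17, 18, 19, 20)) -> list[tuple[int, int]]:
    """Quadratic oracle: test every (start, spacing) pair directly."""
    out = []
    for s in range(len(seq)):
        for n in sorted(spacings):
            e = s + n + 8
            if (
                e <= len(seq)
                and seq[s] == "C"
                and seq[s + 3] == "C"
                and seq[s + n + 4] == "C"
                and seq[s + n + 7] == "C"
            ):
                out.append((s, n))
    return out


def random_protein(rng, length: int = 200, c_frac: float = 0.25) -> str:
    """Random protein with cysteine enriched so spaced-Cys hits occur."""
    probs = np.full(len(_AA), (1 - c_frac) / (len(_AA) - 1))
    probs[list(_AA).index("C")] = c_frac
    return "".join(rng.choice(_AA, size=length, p=probs))


def scanner_oracle_agreement(n_proteins: int = 500, length: int = 200,
                             seed: int = 0) -> dict:
    """Fraction of random proteins whose hit list matches the brute force."""
    rng = child_rng(seed, "diag:scan")
    agree = 0
    total_hits = 0
    for i in range(n_proteins):
        seq = random_protein(rng, length)
        rec = zf.ProteinRecord(id=f"r{i}", sequence=seq)
        got = [(h.start, h.spacing_n) for h in zf.scan_generic(rec)]
        want = brute_force_scan(seq)
        total_hits += len(want)
        agree += got == sorted(want)
    return {"agreement_pct": 100.0 * agree / n_proteins,
            "n": n_proteins, "total_hits": total_hits}


def strict_consistency_violations(n_seqs: int = 10_000, seed: int = 0) -> dict:
    """Count strict-retention matches lacking a generic X17 hit at the
    same start (must be zero). Half the sequences are random, half are
    constructed strict domains with random point mutations."""
    rng = child_rng(seed, "diag:strict")
    violations = 0
    checked = 0
    for i in range(n_seqs):
        if i % 2 == 0:
            seq = random_protein(rng, 120, c_frac=0.3)
        else:
            core = sim._strict_domain(rng)
            seq = sim._rand_aa(rng, 10) + core + sim._rand_aa(rng, 30)
            chars = list(seq)
            for _ in range(int(rng.integers(0, 3))):
                pos = int(rng.integers(len(chars)))
                chars[pos] = str(rng.choice(_AA))
            seq = "".join(chars)
        rec = zf.ProteinRecord(id=f"s{i}", sequence=seq)
        generic_17 = {h.start for h in zf.scan_generic(rec, {17})}
        for start in range(len(seq)):
            if zf.matches_strict_retention(rec, start):
                checked += 1
                if start not in generic_17:
                    violations += 1
    return {"violations": violations, "n": n_seqs, "strict_matches": checked}


# ---------------------------------------------------------------------------
# neighbor joining vs additive matrices from known trees

def random_binary_tree(rng, n_leaves: int):
    """Random unrooted binary tree (trifurcating root) with branch
    lengths uniform in [0.01, 0.5]."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"L{i}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.uniform(0.01, 0.5))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.01, 0.5))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    return root


def _tip_dist_frame(tree) -> pd.DataFrame:
    ids, d = ph.tip_distances(tree)
    return pd.DataFrame(d, index=ids, columns=ids)


def nj_recovery(n_trees: int = 200, seed: int = 0, tol: float = 1e-9) -> dict:
    """Round-trip: additive matrix from a random tree -> NJ -> same tree.

    Success requires Robinson-Foulds distance 0 and every tip-to-tip
    path length reproduced within ``tol``.
    """
    rng = child_rng(seed, "diag:nj")
    ok = 0
    max_err = 0.0
    for _ in range(n_trees):
        n_leaves = int(rng.integers(4, 13))
        true = random_binary_tree(rng, n_leaves)
        tdf = _tip_dist_frame(true)
        ids = sorted(tdf.index)
        dm = ph.DistanceMatrix(ids=ids, d=tdf.loc[ids, ids].to_numpy())
        est = ph.nj_tree(dm)
        rf = true.compare_rfd(est)
        edf = _tip_dist_frame(est)
        err = float(np.abs(edf.loc[ids, ids].to_numpy() - tdf.loc[ids, ids].to_numpy()).max())
        max_err = max(max_err, err)
        ok += (rf == 0) and (err <= tol)
    return {"recovery_pct": 100.0 * ok / n_trees, "n": n_trees,
            "max_tip_distance_error": max_err}


# ---------------------------------------------------------------------------
# planted promoter-motif fixture (count recovery, effect slope, symmetry)

def make_planted_expression_fixture(n_genes: int = 2000, seed: int = 0,
                                    beta: float = 0.5, sigma: float = 0.5,
                                    replicates: int = 4):
    """Planted-motif genome + expression table: GATAA counts 0-3 in the
    (-200, 0) promoter window drive a beta * min(count, 2) expression
    shift; GYGGGG is planted across (-2000, 0) with no effect."""
    genome, genes, truth = sim.gen_genome_and_genes(n_genes, seed)
    sim.plant_motifs(genome, genes, truth, sim.DEFAULT_MOTIFS[0], seed,
                     offset_range=(-200, 0))
    sim.plant_motifs(genome, genes, truth, sim.DEFAULT_MOTIFS[1], seed,
                     offset_range=(-2000, 0))
    expr = sim.gen_expression(truth, seed, beta={"GATAA": beta},
                              sigma=sigma, replicates=replicates)
    return genome, genes, truth, expr


def count_truth_agreement(genome, genes, truth, motifs=sim.DEFAULT_MOTIFS) -> dict:
    """Percent of gene x interval cells where the capped count category
    equals the planted truth."""
    cells = 0
    equal = 0
    for spec in motifs:
        wcm = mo.count_matrix(genome, genes, spec)
        cats = wcm.category
        for iv in wcm.intervals:
            col = mo.interval_label(iv)
            expected = np.array(
                [min(truth.expected_window_count(g, spec.name, iv), 2)
                 for g in cats.index]
            )
            eq = (cats[col].to_numpy() == expected)
            cells += len(eq)
            equal += int(eq.sum())
    return {"agreement_pct": 100.0 * equal / cells, "n_cells": cells}


def motif_effect_slope(genome, genes, truth, expr,
                       interval=(-200, 0), motif="GATAA") -> dict:
    """Weighted LS slope of bin mean fold change vs capped count category."""
    eff = truth.effects
    contrast = ex.Contrast((eff["mutant_strain"], eff["condition"]),
                           (eff["wt_strain"], eff["condition"]))
    lfc = ex.log2_fold_change(expr, contrast)
    spec = next(m for m in sim.DEFAULT_MOTIFS if m.name == motif)
    wcm = mo.count_matrix(genome, genes, spec)
    bins = [b for b in ex.bin_by_motif_count(lfc, wcm) if b.interval == tuple(interval)]
    cats = np.array([b.category for b in bins if b.n > 0], dtype=float)
    means = np.array([b.mean_delta for b in bins if b.n > 0])
    ns = np.array([b.n for b in bins if b.n > 0], dtype=float)
    slope, intercept = np.polyfit(cats, means, 1, w=np.sqrt(ns))
    return {"slope": float(slope), "intercept": float(intercept),
            "n_genes": int(ns.sum()),
            "bin_means": {int(c): float(m) for c, m in zip(cats, means)}}


def strand_symmetry_agreement(genome, genes, motifs=sim.DEFAULT_MOTIFS) -> dict:
    """Reverse-complement every contig and flip every gene; categories
    must be unchanged."""
    flipped_genome = {c: mo.reverse_complement(s) for c, s in genome.items()}
    flipped_genes = [
        mo.GeneModel(
            gene_id=g.gene_id, contig=g.contig,
            strand="-" if g.strand == "+" else "+",
            tss=len(genome[g.contig]) - 1 - g.tss,
        )
        for g in genes
    ]
    cells = 0
    equal = 0
    for spec in motifs:
        a = mo.count_matrix(genome, genes, spec).category
        b = mo.count_matrix(flipped_genome, flipped_genes, spec).category
        eq = (a.to_numpy() == b.to_numpy())
        cells += eq.size
        equal += int(eq.sum())
    return {"agreement_pct": 100.0 * equal / cells, "n_cells": cells}


# ---------------------------------------------------------------------------
# expression statistics

def null_type1_error(n_sims: int = 1000, universe_n: int = 2000,
                     set_n: int = 50, alpha: float = 0.05,
                     seed: int = 0) -> dict:
    """Empirical rejection rate of the shift test on null data."""
    rng = child_rng(seed, "diag:null")
    genes = [f"g{i}" for i in range(universe_n)]
    universe = set(genes)
    rejections = 0
    for _ in range(n_sims):
        vals = pd.Series(rng.normal(size=universe_n), index=genes)
        lfc = ex.FoldChangeVector(
            contrast=ex.Contrast(("m", None), ("w", None)),
            lfc=vals, pseudocount=0.1,
        )
        members = set(rng.choice(genes, size=set_n, replace=False))
        res = ex.gene_set_shift_test(lfc, members, universe)
        rejections += res["p"] < alpha
    return {"type1_error": rejections / n_sims, "n": n_sims, "alpha": alpha}


def hypergeom_oracle_p(N: int, K: int, n: int, k: int) -> float:
    """Exhaustive upper-tail hypergeometric probability from binomial sums."""
    total = math.comb(N, n)
    num = sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
    )
    return num / total


def enrichment_oracle_error(N: int = 20, seed: int = 0) -> dict:
    """Max |p_raw - oracle| over every feasible (K, n, k) at universe N,
    plus a row-wise Bonferroni identity check."""
    genes = [f"u{i:02d}" for i in range(N)]
    universe = set(genes)
    max_err = 0.0
    cases = 0
    for K in range(1, N + 1):
        members = set(genes[:K])
        coll = ex.GeneSetCollection(universe=universe, sets={"S": members})
        for n in range(1, N + 1):
            for k in range(max(0, n + K - N), min(n, K) + 1):
                gene_list = genes[:k] + genes[K : K + (n - k)]
                rows = ex.enrich(gene_list, coll)
                err = abs(rows[0].p_raw - hypergeom_oracle_p(N, K, n, k))
                max_err = max(max_err, err)
                cases += 1
    # Bonferroni: m sets, p_corrected = min(1, p_raw * m) row by row
    rng = child_rng(seed, "diag:bonf")
    sets = {
        f"S{i}": set(rng.choice(genes, size=int(rng.integers(2, 10)),
                                replace=False))
        for i in range(10)
    }
    coll = ex.GeneSetCollection(universe=universe, sets=sets)
    rows = ex.enrich(genes[:5], coll)
    bonferroni_ok = all(
        r.p_corrected == min(1.0, r.p_raw * len(sets)) for r in rows
    )
    return {"max_abs_error": max_err, "n_cases": cases,
            "bonferroni_ok": bonferroni_ok}


def dga1_like_fold_change(seed: int = 0, true_fold: float = 14.0) -> dict:
    """Recover a constructed 14-fold ammonium-vs-peptone expression ratio.

    A well-expressed gene is given mean FPKM 10 * fold on ammonium and 10
    on peptone plus yeast extract across replicates; the measured
    fold change is 2 ** lfc with the default pseudocount.
    """
    rng = child_rng(seed, "diag:dga1")
    base = 10.0
    fpkm = pd.DataFrame(
        {
            "WT_ammonium_r1": [base * true_fold * (1 + 0.02 * rng.standard_normal())],
            "WT_ammonium_r2": [base * true_fold * (1 + 0.02 * rng.standard_normal())],
            "WT_peptoneYE_r1": [base * (1 + 0.02 * rng.standard_normal())],
            "WT_peptoneYE_r2": [base * (1 + 0.02 * rng.standard_normal())],
        },
        index=["dga1"],
    )
    meta = pd.DataFrame(
        {
            "strain": ["WT"] * 4,
            "condition": ["ammonium", "ammonium", "peptoneYE", "peptoneYE"],
            "replicate": [1, 2, 1, 2],
        },
        index=fpkm.columns,
    )
    expr = ex.ExpressionMatrix(fpkm=fpkm, samples=meta)
    lfc = ex.log2_fold_change(
        expr, ex.Contrast(("WT", "ammonium"), ("WT", "peptoneYE"))
    )
    return {"fold_change": float(2 ** lfc.lfc["dga1"]), "n": 1}
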