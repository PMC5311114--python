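"""Fold-change and gene-set statistics for mutant-vs-wild-type RNA-seq.

Consumes per-gene FPKM tables (genes x samples, with strain / condition /
replicate metadata) and provides the three statistics used to relate
promoter motif content and pathway membership to expression changes in
transcription-factor deletion mutants:

* log2 fold changes between sample groups, with a pseudocount;
* binning of per-gene fold changes by capped promoter motif-count
  category in each TSS window, reporting the mean expression difference
  per (window, category) bin;
* rank-sum (Mann-Whitney U) tests for a distribution shift of a gene
  set's fold changes against the rest of the genome, and hypergeometric
  enrichment of gene sets in a top-N gene list with Bonferroni
  correction.

A positive fold change means higher expression in the numerator group
(by convention, the mutant strain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import WindowCountMatrix, interval_label


@dataclass
class ExpressionMatrix:
    """Per-gene FPKM by sample, with (strain, condition, replicate) labels.

    ``fpkm`` is a genes x samples DataFrame; ``samples`` a DataFrame
    indexed by sample id with columns strain / condition / replicate.
    Optional precomputed q-value columns per contrast ride along in
    ``qvalues`` and are never recomputed here.
    """

    fpkm: pd.DataFrame
    samples: pd.DataFrame
    qvalues: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.fpkm.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        missing = set(self.fpkm.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def genes(self) -> list[str]:
        return list(self.fpkm.index)

    def group_samples(self, strain: str, condition: str | None = None) -> list[str]:
        meta = self.samples.loc[list(self.fpkm.columns)]
        mask = meta["strain"] == strain
        if condition is not None:
            mask &= meta["condition"] == condition
        ids = list(meta.index[mask])
        if not ids:
            raise ValueError(f"no samples for strain={strain!r} condition={condition!r}")
        return ids

    @classmethod
    def from_tsv(cls, expr_path, meta_path) -> "ExpressionMatrix":
        fpkm = pd.read_csv(expr_path, sep="\t", comment="#", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0)
        qcols = [c for c in fpkm.columns if c.startswith("q_")]
        q = fpkm[qcols] if qcols else None
        return cls(fpkm=fpkm.drop(columns=qcols), samples=meta, qvalues=q)


@dataclass(frozen=True)
class Contrast:
    """Numerator vs denominator sample groups, each (strain, condition)."""

    num: tuple[str, str | None]
    den: tuple[str, str | None]

    @classmethod
    def parse(cls, text: str) -> "Contrast":
        """Parse 'STRAIN:COND/STRAIN:COND' (condition optional)."""
        try:
            num, den = text.split("/")
        except ValueError:
            raise ValueError(f"contrast {text!r} must be NUM/DEN") from None

        def split(part: str) -> tuple[str, str | None]:
            if ":" in part:
                s, c = part.split(":", 1)
                return s, c
            return part, None

        return cls(num=split(num), den=split(den))


@dataclass
class FoldChangeVector:
    """Per-gene log2 fold change for one contrast."""

    contrast: Contrast
    lfc: pd.Series
    pseudocount: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# log2 fold change {self.contrast.num}/{self.contrast.den}, "
                f"pseudocount {self.pseudocount}\n"
            )
            self.lfc.rename("lfc").to_csv(fh, sep="\t", index_label="gene_id")


def log2_fold_change(
    expr: ExpressionMatrix,
    contrast: Contrast,
    pseudocount: float = 0.1,
    replicate_aggregation: str = "mean_fpkm",
) -> FoldChangeVector:
    """log2((mean FPKM numerator + eps) / (mean FPKM denominator + eps)).

    Replicates are averaged on the FPKM scale before the ratio
    (``mean_fpkm``); ``mean_ratio`` instead averages per-replicate log
    ratios (requires equal replicate counts, paired by order).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    num_ids = expr.group_samples(*contrast.num)
    den_ids = expr.group_samples(*contrast.den)
    if replicate_aggregation == "mean_fpkm":
        num = expr.fpkm[num_ids].mean(axis=1)
        den = expr.fpkm[den_ids].mean(axis=1)
        # difference of logs, not log of ratio: exactly antisymmetric
        lfc = np.log2(num + pseudocount) - np.log2(den + pseudocount)
    elif replicate_aggregation == "mean_ratio":
        if len(num_ids) != len(den_ids):
            raise ValueError("mean_ratio aggregation needs equal group sizes")
        ratios = [
            np.log2(expr.fpkm[a] + pseudocount) - np.log2(expr.fpkm[b] + pseudocount)
            for a, b in zip(num_ids, den_ids)
        ]
        lfc = pd.concat(ratios, axis=1).mean(axis=1)
    else:
        raise ValueError(f"unknown replicate_aggregation {replicate_aggregation!r}")
    return FoldChangeVector(contrast=contrast, lfc=lfc, pseudocount=pseudocount)


@dataclass(frozen=True)
class BinSummary:
    """Mean fold change of genes with a given capped motif count in a window."""

    interval: tuple[int, int]
    category: int
    mean_delta: float  # NaN when the bin is empty
    n: int


def bin_by_motif_count(
    lfc: FoldChangeVector,
    counts: WindowCountMatrix,
    drop_clipped: bool = False,
    categories: Sequence[int] = (0, 1, 2),
) -> list[BinSummary]:
    """Mean fold change per (TSS window, capped motif-count category)."""
    common = counts.category.index.intersection(lfc.lfc.index)
    if common.empty:
        raise ValueError("no genes shared between fold changes and count matrix")
    cat = counts.category.loc[common]
    clip = counts.clipped.loc[common]
    vals = lfc.lfc.loc[common]
    out: list[BinSummary] = []
    for iv in counts.intervals:
        col = interval_label(iv)
        keep = ~clip[col] if drop_clipped else pd.Series(True, index=common)
        for c in categories:
            members = vals[keep & (cat[col] == c)]
            out.append(
                BinSummary(
                    interval=iv,
                    category=c,
                    mean_delta=float(members.mean()) if len(members) else float("nan"),
                    n=int(len(members)),
                )
            )
    return out


def bins_to_frame(bins: Sequence[BinSummary], motif: str | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "interval": [interval_label(b.interval) for b in bins],
            "category": [b.category for b in bins],
            "mean_delta": [b.mean_delta for b in bins],
            "n": [b.n for b in bins],
        }
    )
    if motif is not None:
        df.insert(0, "motif", motif)
    return df


def motif_promoter_summary(
    lfc: FoldChangeVector,
    counts_by_motif: Mapping[str, WindowCountMatrix],
    drop_clipped: bool = False,
) -> pd.DataFrame:
    """Tidy (motif, interval, category, mean_delta, n) table across motifs."""
    if not counts_by_motif:
        raise ValueError("no count matrices supplied")
    frames = [
        bins_to_frame(bin_by_motif_count(lfc, wcm, drop_clipped), motif=name)
        for name, wcm in counts_by_motif.items()
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# gene sets

@dataclass
class GeneSetCollection:
    """Named gene sets over a gene universe (flat membership, no DAG)."""

    universe: set[str]
    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(
                    f"set {name!r} has genes outside the universe: {sorted(extra)[:5]}"
                )

    @classmethod
    def from_tsv(cls, path, universe: set[str]) -> "GeneSetCollection":
        """Two-column TSV: set_name <tab> gene_id. Genes outside the
        universe are dropped (unquantified members do not count)."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["set_name", "gene_id"], dtype=str)
        sets: dict[str, set[str]] = {}
        for name, sub in df.groupby("set_name"):
            sets[name] = set(sub["gene_id"]) & universe
        return cls(universe=universe, sets=sets)

    @classmethod
    def from_gmt(cls, path, universe: set[str]) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                sets[parts[0]] = set(parts[2:]) & universe
        return cls(universe=universe, sets=sets)


def default_universe(expr: ExpressionMatrix, min_mean_fpkm: float = 0.0) -> set[str]:
    """Quantified genes: mean FPKM across all samples above the threshold."""
    means = expr.fpkm.mean(axis=1)
    return set(means.index[means > min_mean_fpkm])


#: group sizes at or below which the rank-sum test uses exact enumeration
EXACT_TEST_MAX_N = 20


def gene_set_shift_test(
    lfc: FoldChangeVector,
    gene_set: set[str],
    background: set[str],
    exact_max_n: int = EXACT_TEST_MAX_N,
) -> dict:
    """Mann-Whitney U test of a set's fold changes against the rest.

    The set is compared to its complement within the background (the
    background may include the set). Exact enumeration is used when the
    smaller group has at most ``exact_max_n`` members, otherwise the
    normal approximation with tie correction. ``direction`` is the sign
    of (set median - complement median).
    """
    in_set = sorted((gene_set & background) & set(lfc.lfc.index))
    comp = sorted((background - gene_set) & set(lfc.lfc.index))
    if not in_set:
        raise ValueError("gene set empty after intersection with data")
    if not comp:
        raise ValueError("background complement empty")
    x = lfc.lfc.loc[in_set].to_numpy()
    y = lfc.lfc.loc[comp].to_numpy()
    method = "exact" if min(len(x), len(y)) <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    med_diff = float(np.median(x) - np.median(y))
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "direction": int(np.sign(med_diff)),
        "n_set": len(x),
        "n_background": len(y),
        "method": method,
    }


def top_n_genes(lfc: FoldChangeVector, n: int = 500, direction: str = "up") -> list[str]:
    """The n most up- (or down-) regulated genes; ties break by gene id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    asc = direction == "down"
    ordered = sorted(
        lfc.lfc.items(), key=lambda kv: (kv[1] if asc else -kv[1], kv[0])
    )
    return [g for g, _ in ordered[:n]]


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    k: int   # list genes in the set
    n: int   # list size
    K: int   # set size in the universe
    N: int   # universe size
    fold_enrichment: float
    p_raw: float
    p_corrected: float


def enrich(gene_list: Sequence[str], collection: GeneSetCollection) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of each set in a gene list.

    p_raw = P(X >= k) for X ~ Hypergeom(N, K, n); Bonferroni correction
    multiplies by the number of sets tested. Rows are sorted by
    (p_corrected, set_name); sets with no hits are retained.
    """
    genes = set(gene_list)
    if len(genes) != len(gene_list):
        raise ValueError("gene list contains duplicates")
    outside = genes - collection.universe
    if outside:
        raise ValueError(f"list genes outside the universe: {sorted(outside)[:5]}")
    N = len(collection.universe)
    n = len(genes)
    m = len(collection.sets)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        k = len(genes & members)
        fe = (k / n) / (K / N) if K > 0 and n > 0 else 0.0
        p_raw = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append(
            EnrichmentRow(
                set_name=name, k=k, n=n, K=K, N=N,
                fold_enrichment=fe,
                p_raw=p_raw,
                p_corrected=min(1.0, p_raw * m),
            )
        )
    rows.sort(key=lambda r: (r.p_corrected, r.set_name))
    return rows


def enrichment_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])
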