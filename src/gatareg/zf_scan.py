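"""Detection and classification of GATA-type zinc-finger domains.

GATA-family transcription factors contact DNA through a four-cysteine
zinc-finger module whose cysteines are arranged as Cys-X2-Cys-Xn-Cys-X2-Cys.
The canonical GATA factor has n = 17 residues between the inner cysteine
pairs; WC-2-like light-responsive factors carry n = 18 and Ash1-like
factors n = 19 or 20, shifts that track changes in DNA-binding specificity
(GATAA vs YCGAT/YTGAT-like elements).

This module scans protein sequences for all such spaced-cysteine domains,
classifies them by spacing, applies a stricter retention pattern that pins
the conserved Thr/Trp/Arg core and the Cys-Asn-X-Cys tail of true GATA
domains, picks one representative domain per multi-domain protein, and
collapses duplicate domains within a species.

Coordinates are 0-based, end-exclusive throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AMINO_ACIDS | {"X"}

#: spacings (residues between the 2nd and 3rd Cys) accepted by the scanner
VALID_SPACINGS = frozenset({17, 18, 19, 20})

FAMILY_BY_SPACING = {
    17: "canonical_17",
    18: "wc2_like_18",
    19: "ash1_like_19_20",
    20: "ash1_like_19_20",
}

#: minimum residue count required after the fourth Cys by the strict pattern
STRICT_TAIL_MIN = 25

#: default consensus used to rank multiple domains within one protein;
#: the canonical X17 cysteine scaffold with neutral filler residues
CANONICAL_CONSENSUS = "C" + "AA" + "C" + "A" * 17 + "C" + "AA" + "C"


class InvalidSequenceError(ValueError):
    """Protein sequence empty or containing letters outside the alphabet."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier and optional species label."""

    id: str
    sequence: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise InvalidSequenceError(
                f"{self.id}: invalid residue(s) {sorted(bad)}; "
                "allowed are the 20 amino acids plus X"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ZincFingerHit:
    """One spaced-cysteine domain hit.

    ``start`` is the offset of the first Cys; ``end`` is one past the
    fourth Cys, so ``end - start == spacing_n + 8`` and the four cysteines
    sit at domain offsets 0, 3, spacing_n + 4 and spacing_n + 7.
    ``strict_pass`` records whether the strict GATA retention pattern
    matched at ``start``; ``tail_ok`` whether at least 25 residues follow
    the fourth Cys.
    """

    protein_id: str
    start: int
    end: int
    spacing_n: int
    family_class: str
    domain_seq: str
    strict_pass: bool
    tail_ok: bool

    def __post_init__(self) -> None:
        n = self.spacing_n
        assert self.end - self.start == n + 8
        s = self.domain_seq
        assert s[0] == s[3] == s[n + 4] == s[n + 7] == "C"


def classify_spacing(spacing_n: int) -> str:
    """Map an inter-cysteine spacing to its family class.

    17 is the canonical GATA spacing, 18 the WC-2-like variant, and
    19/20 the Ash1-like variants.
    """
    try:
        return FAMILY_BY_SPACING[spacing_n]
    except KeyError:
        raise ValueError(
            f"spacing {spacing_n!r} outside the recognised set "
            f"{sorted(VALID_SPACINGS)}"
        ) from None


def _is_c(ch: str) -> bool:
    # 'X' (unknown residue) never satisfies a required position
    return ch == "C"


def matches_strict_retention(protein: ProteinRecord, start: int) -> bool:
    """Test the strict GATA retention pattern at ``start``.

    The pattern is C-X2-C-X4-T-(P/S)-(L/V)-W-R-(R/K)-X7-C-N-X-C followed
    by at least 25 residues, i.e. the canonical X17 domain with the
    conserved Thr/Trp/Arg core and Cys-Asn-X-Cys second cysteine pair
    pinned. 'X' in the input satisfies only the unconstrained positions.
    """
    seq = protein.sequence
    if start < 0 or start >= len(seq):
        raise ValueError(f"start {start} out of range for {protein.id}")
    # fixed positions relative to start: length of the cysteine core is 25
    if start + 25 + STRICT_TAIL_MIN > len(seq):
        return False
    s = seq[start : start + 25]
    return (
        s[0] == "C"
        and s[3] == "C"
        and s[8] == "T"
        and s[9] in "PS"
        and s[10] in "LV"
        and s[11] == "W"
        and s[12] == "R"
        and s[13] in "RK"
        and s[21] == "C"
        and s[22] == "N"
        and s[24] == "C"
    )


def scan_generic(
    protein: ProteinRecord,
    spacings: Iterable[int] = VALID_SPACINGS,
) -> list[ZincFingerHit]:
    """Find every Cys-X2-Cys-Xn-Cys-X2-Cys occurrence.

    All overlapping hits are reported, sorted by (start, spacing_n).
    Each hit carries its family class, whether the strict retention
    pattern also matches at that start, and whether >=25 residues follow
    the fourth Cys.
    """
    spacings = sorted(set(spacings))
    if not spacings:
        raise ValueError("empty spacing set")
    bad = set(spacings) - VALID_SPACINGS
    if bad:
        raise ValueError(f"unsupported spacings {sorted(bad)}")
    seq = protein.sequence
    L = len(seq)
    hits: list[ZincFingerHit] = []
    for start in range(L):
        if not _is_c(seq[start]):
            continue
        if start + 3 >= L or not _is_c(seq[start + 3]):
            continue
        for n in spacings:
            end = start + n + 8
            if end > L:
                continue
            if _is_c(seq[start + n + 4]) and _is_c(seq[start + n + 7]):
                strict = n == 17 and matches_strict_retention(protein, start)
                hits.append(
                    ZincFingerHit(
                        protein_id=protein.id,
                        start=start,
                        end=end,
                        spacing_n=n,
                        family_class=classify_spacing(n),
                        domain_seq=seq[start:end],
                        strict_pass=strict,
                        tail_ok=L - end >= STRICT_TAIL_MIN,
                    )
                )
    return hits


def best_domain(
    protein: ProteinRecord,
    hits: Sequence[ZincFingerHit],
    consensus: str = CANONICAL_CONSENSUS,
) -> ZincFingerHit:
    """Pick the single domain that aligns best to ``consensus``.

    Multi-domain proteins contribute one domain to downstream clustering;
    the winner is the hit whose domain sequence attains the maximum global
    alignment score against the consensus, ties broken by smallest start.
    """
    from .phylo import global_align

    if not hits:
        raise ValueError("best_domain requires at least one hit")
    for h in hits:
        if h.protein_id != protein.id:
            raise ValueError(f"hit {h.protein_id} does not belong to {protein.id}")
    scored = [(global_align(h.domain_seq, consensus).score, -h.start, h) for h in hits]
    best = max(scored, key=lambda t: (t[0], t[1]))
    return best[2]


def dedup_within_species(
    hits: Sequence[ZincFingerHit],
    species_of: Mapping[str, str],
) -> list[ZincFingerHit]:
    """Collapse identical domain sequences within each species.

    Within one species, hits with byte-identical ``domain_seq`` are reduced
    to the one with the lexicographically smallest (protein_id, start);
    identical domains in different species are all retained. Output is
    sorted by (species, protein_id, start).
    """
    missing = {h.protein_id for h in hits} - set(species_of)
    if missing:
        raise ValueError(f"no species mapping for {sorted(missing)}")
    survivors: dict[tuple[str, str], ZincFingerHit] = {}
    for h in hits:
        key = (species_of[h.protein_id], h.domain_seq)
        prev = survivors.get(key)
        if prev is None or (h.protein_id, h.start) < (prev.protein_id, prev.start):
            survivors[key] = h
    return sorted(
        survivors.values(),
        key=lambda h: (species_of[h.protein_id], h.protein_id, h.start),
    )


# ---------------------------------------------------------------------------
# I/O

def read_proteins(path, species_map: Mapping[str, str] | None = None) -> list[ProteinRecord]:
    """Read a protein multi-FASTA into ProteinRecords."""
    from Bio import SeqIO

    species_map = species_map or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                species=species_map.get(rec.id, ""),
            )
        )
    return records


def read_species_map(path) -> dict[str, str]:
    """Read a two-column TSV of protein_id -> species."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("species map needs two columns: protein_id, species")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def hits_to_frame(hits: Sequence[ZincFingerHit]):
    """Tabulate hits as a DataFrame in the on-disk TSV column order."""
    import pandas as pd

    cols = [
        "protein_id", "start", "end", "spacing_n",
        "family_class", "strict_pass", "domain_seq",
    ]
    rows = [{c: getattr(h, c) for c in cols} for h in hits]
    return pd.DataFrame(rows, columns=cols)


def write_hits(hits: Sequence[ZincFingerHit], tsv_path, fasta_path=None) -> None:
    """Write a hits TSV and, optionally, a FASTA of domain sequences."""
    df = hits_to_frame(hits)
    with open(tsv_path, "w") as fh:
        fh.write("# zinc-finger domain hits; 0-based end-exclusive coordinates\n")
        df.to_csv(fh, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for h in hits:
                fh.write(f">{h.protein_id}:{h.start}-{h.end}\n{h.domain_seq}\n")
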