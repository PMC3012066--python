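"""Nucleotide diversity (Pi) with sampling variance over alignment regions.

Pi is the average number of nucleotide differences per site between two
sequences drawn from the sample:

    pi = 2 / (n (n - 1)) * sum_{i<j} d_ij / L

with ``d_ij`` the number of differing sites between sequences i and j and
``L`` the number of comparable sites after the deletion rule.  The sampling
variance follows Nei (1987), eq. 10.7:

    V(pi) = (n + 1) / (3 (n - 1) L) * pi  +  2 (n^2 + n + 3) / (9 n (n - 1)) * pi^2

Complete deletion (drop every column containing a gap or N) is the default;
pairwise deletion scores each pair over its own comparable columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "Alignment",
    "GeneAnnotation",
    "DiversityEstimate",
    "extract_gene_region",
    "nucleotide_diversity",
    "sliding_pi",
    "segment_group_summary",
]

_VALID = frozenset("ACGTN-")
_MISSING = frozenset("N-")


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequences over the alphabet {A, C, G, T, -, N}."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - _VALID
            if bad:
                raise ValueError(f"sequence {sid}: invalid characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Rows as a (n, length) array of single-byte codes."""
        return np.frombuffer("".join(self.rows).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def slice(self, start: int, stop: int) -> "Alignment":
        """Column slice [start, stop) as a new alignment."""
        if not (0 <= start <= stop <= self.length):
            raise ValueError(f"slice [{start}, {stop}) outside alignment of {self.length}")
        return Alignment(self.ids, tuple(r[start:stop] for r in self.rows))

    def subset(self, ids: Iterable[str]) -> "Alignment":
        wanted = list(ids)
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise ValueError(f"unknown sequence ids: {missing}")
        return Alignment(tuple(wanted), tuple(self.rows[index[sid]] for sid in wanted))


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene landmarks in alignment columns (0-based half-open exons)."""

    gene_id: str
    start_codon: int
    exons: tuple[tuple[int, int], ...]
    polya: int
    strand: str = "+"
    truncated_at_exon: int | None = None  # e.g. 3DP1 ends at exon 5

    def __post_init__(self) -> None:
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if not (a < b <= c < d):
                raise ValueError(f"{self.gene_id}: exons must be sorted and non-overlapping")
        if self.start_codon > self.polya:
            raise ValueError(f"{self.gene_id}: start codon after polyadenylation site")


@dataclass(frozen=True)
class DiversityEstimate:
    pi: float
    variance: float
    n: int
    sites_used: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def extract_gene_region(aln: Alignment, ann: GeneAnnotation) -> Alignment:
    """Extract the standard per-gene window: 250 bp upstream of the start
    codon through the polyadenylation-site column (inclusive); genes flagged
    truncated end at their terminal exon instead."""
    if ann.polya >= aln.length or ann.start_codon >= aln.length:
        raise ValueError(f"{ann.gene_id}: annotation outside alignment")
    start = ann.start_codon - 250
    if start < 0:
        warnings.warn(
            f"{ann.gene_id}: start codon closer than 250 columns to alignment start; "
            "extract clamped to column 0"
        )
        start = 0
    if ann.truncated_at_exon is not None:
        end = ann.exons[ann.truncated_at_exon - 1][1]  # half-open exon end
    else:
        end = ann.polya + 1  # include the polyA column
    if end > aln.length:
        raise ValueError(f"{ann.gene_id}: annotation outside alignment")
    return aln.slice(start, end)


def _pairwise_counts(mat: np.ndarray, deletion: str) -> tuple[float, float, int]:
    """Sum of per-pair difference fractions and counts under the deletion rule.

    Returns (sum over pairs of d_ij / L_ij, number of pairs, sites used).
    For complete deletion every pair shares the same L.
    """
    n = mat.shape[0]
    ok = ~np.isin(mat, [b"N", b"-"])
    if deletion == "complete":
        keep = ok.all(axis=0)
        L = int(keep.sum())
        if L == 0:
            raise ValueError("no usable sites after complete deletion")
        sub = mat[:, keep]
        total = 0.0
        for i in range(n):
            diffs = (sub[i + 1 :] != sub[i]).sum(axis=1)
            total += float((diffs / L).sum())
        return total, n * (n - 1) / 2, L
    elif deletion == "pairwise":
        total = 0.0
        Ls = []
        for i in range(n):
            both = ok[i + 1 :] & ok[i]
            L_i = both.sum(axis=1)
            d_i = ((mat[i + 1 :] != mat[i]) & both).sum(axis=1)
            if (L_i == 0).any():
                raise ValueError("a sequence pair shares no usable sites")
            total += float((d_i / L_i).sum())
            Ls.extend(L_i.tolist())
        return total, n * (n - 1) / 2, int(round(float(np.mean(Ls))))
    raise ValueError(f"unknown deletion rule {deletion!r}")


def nucleotide_diversity(
    aln: Alignment, deletion: Literal["complete", "pairwise"] = "complete"
) -> DiversityEstimate:
    """Pi and its Nei (1987) eq. 10.7 sampling variance for an alignment."""
    n = aln.n
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    total, pairs, L = _pairwise_counts(aln.matrix(), deletion)
    pi = total / pairs
    variance = ((n + 1) / (3.0 * (n - 1) * L)) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return DiversityEstimate(pi=float(pi), variance=float(variance), n=n, sites_used=L)


def sliding_pi(
    aln: Alignment,
    window: int = 500,
    step: int = 100,
    deletion: Literal["complete", "pairwise"] = "complete",
) -> list[tuple[float, DiversityEstimate]]:
    """Per-window Pi profile: (window midpoint column, estimate) pairs.

    Windows tile the alignment every ``step`` columns; a trailing partial
    window is dropped.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > aln.length:
        raise ValueError("window exceeds alignment length")
    profile = []
    for start in range(0, aln.length - window + 1, step):
        est = nucleotide_diversity(aln.slice(start, start + window), deletion)
        profile.append((start + window / 2.0, est))
    return profile


def segment_group_summary(
    per_gene: Mapping[str, DiversityEstimate],
    grouping: Mapping[str, str],
) -> dict[str, dict]:
    """Group per-gene Pi values by motif-segment residence and average them.

    ``grouping`` maps each gene to a segment label (Cen-A, Cen-B, Tel-A,
    Tel-B).  Returns per group the arithmetic mean and the individual
    (gene, pi) points for plotting.
    """
    ungrouped = set(per_gene) - set(grouping)
    if ungrouped:
        raise ValueError(f"genes without a group label: {sorted(ungrouped)}")
    groups: dict[str, dict] = {}
    for gene in sorted(per_gene):
        label = grouping[gene]
        entry = groups.setdefault(label, {"points": [], "mean": np.nan})
        entry["points"].append((gene, per_gene[gene].pi))
    for label, entry in groups.items():
        if not entry["points"]:
            raise ValueError(f"empty group {label}")
        entry["mean"] = float(np.mean([pi for _, pi in entry["points"]]))
    return groups
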