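"""Synthetic-data generators with known truth for every pipeline stage.

Four generators cover the pipeline's inputs:

* :func:`simulate_cohort` draws diploid gene-content genotypes from a
  haplotype frequency vector (default: the pooled frequencies observed in
  the 192-donor multi-ethnic reference panel, including a 5.5% pool of rare
  "other" haplotypes) and types them through an assay panel, retaining the
  true haplotype pairs for recovery scoring.
* :func:`simulate_alignment_on_tree` evolves sequences along a dated tree
  under a Kimura two-parameter substitution process at a given rate in
  substitutions/site/My, for testing distance, tree and clock estimators.
* :func:`make_mosaic` splices two parental sequences at known breakpoints,
  emulating recombinant KIR segments with segmental evolutionary histories.
* :func:`simulate_ab_gene_fixture` builds per-gene alignments whose groups
  (Cen-A, Cen-B, Tel-A, Tel-B) have prescribed relative diversities, so
  segment-level ranking statements are testable.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .diversity import Alignment
from .inference import (
    AssayPanel,
    CohortObservations,
    GenotypeSignature,
    Individual,
    OTHER,
    _haplotype_links,
)
from .registry import KirRegistry, KirRegistryError

__all__ = [
    "TABLE_FREQUENCIES",
    "RareHaplotype",
    "rare_haplotypes",
    "simulate_cohort",
    "simulate_alignment_on_tree",
    "simulate_two_clade_alignment",
    "make_mosaic",
    "simulate_ab_gene_fixture",
]

#: Pooled haplotype frequencies observed in the 192-donor reference panel.
#: Derived from the per-population chromosome counts (which sum exactly to
#: 384); the published totals column carries one entry inconsistent with its
#: own population breakdown.
TABLE_FREQUENCIES: dict[str, float] = {
    "cA01|tA01": 232 / 384,
    "cA01|tB01": 44 / 384,
    "cB01|tB01": 10 / 384,
    "cB02|tA01": 34 / 384,
    "cB01|tA01": 28 / 384,
    "cB02|tB01": 13 / 384,
    "cB03|tA01": 2 / 384,
    OTHER: 21 / 384,
}


@dataclass(frozen=True)
class RareHaplotype:
    """A rare gene-content haplotype outside the registered structures.

    Emulates the uncharacterised chromosomes of real panels (deletion,
    insertion and hybrid variants).  Carries its own locus content and cis
    links so it can be pushed through the same typing machinery.
    """

    name: str
    gene_content: frozenset[str]
    links: frozenset[tuple[str, str]]


def rare_haplotypes(registry: KirRegistry) -> list[RareHaplotype]:
    """Three rare structures used for the "other" class.

    R1 deletes 2DL2L3 from a cB03-like centromeric motif while keeping
    2DS2; R2 is a tB01-like telomeric motif lacking 2DS1; R3 is a hybrid
    telomeric motif carrying 2DS1 next to the 3DL1/2DS4 block.  All three
    produce genotype patterns inconsistent with every registered haplotype
    pair for the common partner haplotypes, so they surface as unmatched
    ("other") chromosomes, as rare variants do in real panels.
    """
    cA01 = registry.motifs["cA01"]
    tA01 = registry.motifs["tA01"]
    f = frozenset
    framework = f({"3DL3", "3DP1", "2DL4", "3DL2"})
    cA01_content = f(registry.resolve_locus(e) for e in cA01.gene_order)
    tA01_content = f(registry.resolve_locus(e) for e in tA01.gene_order)
    cA01_links = f(cA01.adjacent_pairs())
    tA01_links = f(tA01.adjacent_pairs())
    return [
        RareHaplotype(
            name="rare:cDel2DL2L3|tA01",
            gene_content=f({"3DL3", "2DS2", "2DP1", "2DL1"}) | tA01_content | framework,
            links=f({("3DL3", "2DS2"), ("2DP1", "2DL1")}) | tA01_links,
        ),
        RareHaplotype(
            name="rare:cA01|tDel2DS1",
            gene_content=cA01_content | f({"2DL4", "3DL1S1", "2DL5", "2DS3S5", "3DL2"}) | framework,
            links=cA01_links | f({("2DL4", "3DS1"), ("3DS1", "2DL5A"), ("2DL5A", "2DS3S5")}),
        ),
        RareHaplotype(
            name="rare:cA01|tHyb2DS1",
            gene_content=cA01_content | f({"2DL4", "3DL1S1", "2DS4", "2DS1", "3DL2"}) | framework,
            links=cA01_links | f({("2DL4", "3DL1"), ("3DL1", "2DS4"), ("2DS1", "3DL2")}),
        ),
    ]


def _chromosome_signature(
    hap, registry: KirRegistry, panel: AssayPanel
) -> tuple[frozenset[str], frozenset[tuple[str, str]]]:
    if isinstance(hap, RareHaplotype):
        return hap.gene_content & panel.presence_assays, hap.links & panel.linking_assays
    return (
        hap.gene_content & panel.presence_assays,
        _haplotype_links(hap, registry, panel),
    )


def simulate_cohort(
    registry: KirRegistry,
    panel: AssayPanel,
    n: int = 192,
    frequencies: Mapping[str, float] | None = None,
    populations: Sequence[str] = ("AFA", "ASI", "HIS", "CAU"),
    seed: int | None = None,
) -> tuple[CohortObservations, list[tuple[str, str]]]:
    """Draw a typed diploid cohort from a haplotype frequency vector.

    2n chromosomes are drawn i.i.d. from ``frequencies`` (default: the
    pooled reference-panel vector).  Mass on the "other" key is spread
    uniformly over the three rare structures of :func:`rare_haplotypes`.
    Individuals are assigned round-robin to ``populations``.  Returns the
    observed cohort and the true haplotype-name pairs, index-aligned.
    """
    if frequencies is None:
        frequencies = TABLE_FREQUENCIES
    freqs = dict(frequencies)
    other_rate = freqs.pop(OTHER, 0.0)
    unknown = set(freqs) - set(registry.structures)
    if unknown:
        raise KirRegistryError(f"frequencies name unregistered haplotypes: {sorted(unknown)}")
    rare = rare_haplotypes(registry)
    pool = [registry.structures[name] for name in freqs] + list(rare)
    probs = np.array(list(freqs.values()) + [other_rate / len(rare)] * len(rare))
    if abs(probs.sum() - 1.0) > 1e-9:
        raise KirRegistryError(f"frequencies sum to {probs.sum():.6f}, not 1")
    if n <= 0:
        raise KirRegistryError("n must be positive")

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(pool), size=2 * n, p=probs)
    individuals, truth = [], []
    for k in range(n):
        h1, h2 = pool[draws[2 * k]], pool[draws[2 * k + 1]]
        p1, l1 = _chromosome_signature(h1, registry, panel)
        p2, l2 = _chromosome_signature(h2, registry, panel)
        sig = GenotypeSignature(presence=p1 | p2, links=l1 | l2)
        individuals.append(
            Individual(id=f"S{k:04d}", population=populations[k % len(populations)], signature=sig)
        )
        truth.append((h1.name, h2.name))
    return CohortObservations(individuals), truth


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(["A", "C", "G", "T"])
# transition partner of each base (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])


def _k2p_probs(d: float, kappa: float) -> tuple[float, float]:
    """K2P probabilities (transition, each transversion) for branch length d.

    ``d`` is expected substitutions/site; ``kappa`` the transition/
    transversion rate ratio alpha/beta.
    """
    if d < 0:
        raise ValueError("negative branch length")
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    p_ts = 0.25 + 0.25 * np.exp(-4.0 * beta_t) - 0.5 * np.exp(-2.0 * (alpha_t + beta_t))
    p_tv_each = 0.25 - 0.25 * np.exp(-4.0 * beta_t)
    return float(p_ts), float(p_tv_each)


def _evolve(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k2p_probs(d, kappa)
    u = rng.random(seq.shape)
    out = seq.copy()
    # order: [stay, transition, transversion1, transversion2]
    ts_mask = (u >= 1 - p_ts - 2 * p_tv) & (u < 1 - 2 * p_tv)
    tv1_mask = (u >= 1 - 2 * p_tv) & (u < 1 - p_tv)
    tv2_mask = u >= 1 - p_tv
    out[ts_mask] = _TRANSITION[seq[ts_mask]]
    # transversion partners: for purines -> C or T; for pyrimidines -> A or G
    is_purine = (seq == 0) | (seq == 2)
    out[tv1_mask] = np.where(is_purine[tv1_mask], 1, 0)
    out[tv2_mask] = np.where(is_purine[tv2_mask], 3, 2)
    return out


def simulate_alignment_on_tree(
    tree: dendropy.Tree | str,
    rate: float = 0.005,
    kappa: float = 2.0,
    length: int = 10_000,
    base_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int | None = None,
) -> tuple[Alignment, dendropy.Tree]:
    """Evolve sequences along a dated tree (edge lengths in My).

    Sites evolve independently under a Kimura two-parameter process; each
    edge of ``t`` My contributes ``rate * t`` expected substitutions/site.
    The root sequence is drawn from ``base_composition``.  Returns the leaf
    alignment and the tree actually used.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    comp = np.asarray(base_composition, dtype=float)
    comp = comp / comp.sum()
    root_seq = rng.choice(4, size=length, p=comp)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if t < 0:
            raise ValueError("negative branch length in dated tree")
        parent_seq = seqs[id(node.parent_node)]
        seqs[id(node)] = _evolve(parent_seq, rate * t, kappa, rng)

    ids, rows = [], []
    for leaf in tree.leaf_node_iter():
        ids.append(leaf.taxon.label)
        rows.append("".join(_BASES[seqs[id(leaf)]]))
    return Alignment(tuple(ids), tuple(rows)), tree


def simulate_two_clade_alignment(
    n_per_clade: int = 4,
    inter_divergence: float = 0.05,
    intra_divergence: float = 0.005,
    length: int = 1000,
    kappa: float = 2.0,
    seed: int | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[Alignment, set[str], set[str]]:
    """Two-clade alignment with specified inter- and intra-clade divergence.

    Expected pairwise divergence is ~``inter_divergence`` between clades
    and ~``intra_divergence`` within.  Returns the alignment plus the two
    leaf-id sets (ids are e.g. A1..An, B1..Bn).
    """
    if n_per_clade < 1:
        raise ValueError("need at least one sequence per clade")
    rng = np.random.default_rng(seed)
    root = rng.choice(4, size=length)
    ids, rows = [], []
    groups: tuple[set[str], set[str]] = (set(), set())
    for g, label in enumerate(labels):
        # clade ancestor sits inter/2 from the root on each side
        anc = _evolve(root, inter_divergence / 2.0, kappa, rng)
        for k in range(n_per_clade):
            tip = _evolve(anc, intra_divergence / 2.0, kappa, rng)
            sid = f"{label}{k + 1}"
            ids.append(sid)
            rows.append("".join(_BASES[tip]))
            groups[g].add(sid)
    return Alignment(tuple(ids), tuple(rows)), groups[0], groups[1]


def make_mosaic(parent_a: str, parent_b: str, breakpoints: Sequence[int]) -> str:
    """Splice two parental sequences, alternating segments starting with A."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents differ in length")
    bps = list(breakpoints)
    if bps != sorted(bps):
        raise ValueError("breakpoints must be sorted")
    if any(not (0 < b < len(parent_a)) for b in bps):
        raise ValueError("breakpoint out of range")
    bounds = [0, *bps, len(parent_a)]
    parents = (parent_a, parent_b)
    return "".join(parents[k % 2][a:b] for k, (a, b) in enumerate(zip(bounds, bounds[1:])))


def simulate_ab_gene_fixture(
    gene_groups: Mapping[str, str] | None = None,
    diversity_scale: Mapping[str, float] | None = None,
    base_diversity: float = 0.004,
    n_sequences: int = 6,
    length: int = 2000,
    seed: int | None = None,
) -> tuple[dict[str, Alignment], dict[str, str]]:
    """Per-gene alignments with group-controlled diversity levels.

    ``gene_groups`` maps gene name -> segment label (Cen-A/Cen-B/Tel-A/
    Tel-B); the default mirrors the KIR segment layout.  Each gene is
    simulated on a star genealogy with expected pairwise diversity
    ``base_diversity * diversity_scale[group]``.  Returns the alignments
    and the grouping map.
    """
    if gene_groups is None:
        gene_groups = {
            "3DL3-A": "Cen-A", "2DL3": "Cen-A", "2DP1-A": "Cen-A", "2DL1-A": "Cen-A",
            "2DS2": "Cen-B", "2DL2": "Cen-B", "2DL5B": "Cen-B", "2DS3S5-cen": "Cen-B",
            "3DL1": "Tel-A", "2DS4": "Tel-A", "2DL4-A": "Tel-A",
            "3DS1": "Tel-B", "2DL5A": "Tel-B", "2DS1": "Tel-B",
        }
    if diversity_scale is None:
        diversity_scale = {"Cen-A": 1.0, "Cen-B": 1.0, "Tel-A": 1.0, "Tel-B": 1.0}
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences per gene")
    rng = np.random.default_rng(seed)
    alignments: dict[str, Alignment] = {}
    for gene in sorted(gene_groups):
        group = gene_groups[gene]
        theta = base_diversity * diversity_scale.get(group, 1.0)
        root = rng.choice(4, size=length)
        ids, rows = [], []
        for k in range(n_sequences):
            tip = _evolve(root, theta / 2.0, 2.0, rng)
            ids.append(f"{gene}*{k + 1:03d}")
            rows.append("".join(_BASES[tip]))
        alignments[gene] = Alignment(tuple(ids), tuple(rows))
    return alignments, dict(gene_groups)
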