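"""Haplotype-pair deduction and EM frequency estimation from gene-content typing.

KIR typing by PCR-SSP yields, per individual, a presence/absence call for
each locus plus a set of *linking* results: PCR products spanning two
adjacent genes, proving the pair lies in cis on one chromosome.  From these
unphased observations the pair of gene-content haplotypes carried by an
individual can usually be deduced, because the registered haplotype
structures differ in content.  Some genotypes remain ambiguous — notably the
cross-central phase ambiguities such as cA01|tA01 + cB01|tB01 versus
cA01|tB01 + cB01|tA01, which no panel lacking an assay across the 3DP1-2DL4
junction can resolve — and some match no registered structure at all
("other" chromosomes, carrying rare haplotypes).

Haplotype frequencies are estimated by maximum likelihood with an EM
algorithm over the closed set of registered haplotypes plus one pooled
"other" class.  The E-step distributes each genotype over its compatible
haplotype pairs in proportion to 2*f_i*f_j (or f_i**2); the M-step is
expected allele counting.  An individual whose signature matches no
registered pair is decomposed as (registered haplotype, other) whenever one
registered haplotype explains part of the signature, otherwise as
(other, other); "other" chromosomes are tallied but not characterised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import FRAMEWORK_LOCI, HaplotypeStructure, KirRegistry, KirRegistryError

__all__ = [
    "AssayPanel",
    "GenotypeSignature",
    "Individual",
    "CohortObservations",
    "FrequencyEstimate",
    "default_panel",
    "signature_of",
    "compatible_pairs",
    "partial_explanations",
    "enumerate_ambiguity_classes",
    "em_estimate",
    "frequency_report",
    "read_cohort_tsv",
    "write_cohort_tsv",
]

OTHER = "other"


@dataclass(frozen=True)
class AssayPanel:
    """Presence assays (locus-level) and linking assays (allele-level pairs)."""

    presence_assays: frozenset[str]
    linking_assays: frozenset[tuple[str, str]]

    def validate(self, registry: KirRegistry) -> None:
        adjacencies = set()
        for motif in registry.motifs.values():
            adjacencies.update(motif.adjacent_pairs())
        adjacencies.add(("3DP1", "2DL4"))  # central framework junction
        for pair in self.linking_assays:
            if pair not in adjacencies:
                raise KirRegistryError(
                    f"linking assay {pair} is not adjacent in any registered motif"
                )
        for locus in self.presence_assays:
            registry.resolve_locus(locus)


@dataclass(frozen=True)
class GenotypeSignature:
    """Observable typing result: loci present plus detected cis links."""

    presence: frozenset[str]
    links: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class Individual:
    id: str
    population: str
    signature: GenotypeSignature


@dataclass
class CohortObservations:
    individuals: list[Individual]

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise KirRegistryError("duplicate individual ids in cohort")

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population)
        return list(seen)


@dataclass
class FrequencyEstimate:
    """EM-estimated haplotype frequencies (including the pooled "other" class)."""

    freqs: dict[str, float]
    log_likelihood: list[float]
    iterations: int
    unresolved_chromosomes: float
    n_individuals: int


def default_panel(registry: KirRegistry) -> AssayPanel:
    """Presence assays for every locus plus all within-motif linking assays.

    No assay spans the 3DP1-2DL4 central junction, so cross-central phase
    cannot be observed directly — the source of the classic pair ambiguities.
    """
    links = set()
    for motif in registry.motifs.values():
        links.update(motif.adjacent_pairs())
    return AssayPanel(
        presence_assays=frozenset(registry.loci),
        linking_assays=frozenset(links),
    )


def _haplotype_links(
    structure: HaplotypeStructure, registry: KirRegistry, panel: AssayPanel
) -> frozenset[tuple[str, str]]:
    links = set()
    for motif_id in (structure.cen, structure.tel):
        links.update(registry.motifs[motif_id].adjacent_pairs())
    return frozenset(links & panel.linking_assays)


def signature_of(
    h1: HaplotypeStructure,
    h2: HaplotypeStructure | None,
    registry: KirRegistry,
    panel: AssayPanel,
) -> GenotypeSignature:
    """Typing signature of a haplotype (pair): union of contents and cis links."""
    presence = set(h1.gene_content)
    links = set(_haplotype_links(h1, registry, panel))
    if h2 is not None:
        presence |= h2.gene_content
        links |= _haplotype_links(h2, registry, panel)
    return GenotypeSignature(
        presence=frozenset(presence & panel.presence_assays),
        links=frozenset(links),
    )


def _unordered_pairs(registry: KirRegistry):
    structures = registry.registered()
    return itertools.combinations_with_replacement(structures, 2)


def compatible_pairs(
    sig: GenotypeSignature, registry: KirRegistry, panel: AssayPanel
) -> list[tuple[HaplotypeStructure, HaplotypeStructure]]:
    """All unordered registered pairs whose signature equals ``sig``.

    An empty list flags an "other"/unmatched genotype.
    """
    out = []
    for h1, h2 in _unordered_pairs(registry):
        if signature_of(h1, h2, registry, panel) == sig:
            out.append((h1, h2))
    return sorted(out, key=lambda pair: (pair[0].name, pair[1].name))


def partial_explanations(
    sig: GenotypeSignature, registry: KirRegistry, panel: AssayPanel
) -> list[HaplotypeStructure]:
    """Registered haplotypes consistent with one chromosome of ``sig``.

    Used for genotypes matching no registered pair: a haplotype explains part
    of the signature when its assayed content and links are subsets of the
    observation, leaving the remainder to an uncharacterised chromosome.
    """
    out = []
    for structure in registry.registered():
        own = signature_of(structure, None, registry, panel)
        if own.presence <= sig.presence and own.links <= sig.links:
            out.append(structure)
    return sorted(out, key=lambda s: s.name)


def enumerate_ambiguity_classes(
    registry: KirRegistry, panel: AssayPanel
) -> list[list[tuple[HaplotypeStructure, HaplotypeStructure]]]:
    """Signature-collision classes: sets of >= 2 unordered pairs sharing a signature."""
    by_sig: dict[GenotypeSignature, list] = {}
    for h1, h2 in _unordered_pairs(registry):
        sig = signature_of(h1, h2, registry, panel)
        by_sig.setdefault(sig, []).append((h1, h2))
    classes = [
        sorted(pairs, key=lambda p: (p[0].name, p[1].name))
        for pairs in by_sig.values()
        if len(pairs) >= 2
    ]
    return sorted(classes, key=lambda cls: (cls[0][0].name, cls[0][1].name))


# ---------------------------------------------------------------------------
# EM frequency estimation
# ---------------------------------------------------------------------------


def _genotype_classes(
    obs: CohortObservations, registry: KirRegistry, panel: AssayPanel
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Collapse individuals into signature classes with pair index lists.

    Returns haplotype names (registered + "other"), an array of class
    weights (individual counts), and per-class (i, j) index pair arrays.
    """
    names = [s.name for s in registry.registered()]
    index = {name: k for k, name in enumerate(names)}
    other = len(names)

    class_pairs: dict[GenotypeSignature, list[tuple[int, int]]] = {}
    class_count: dict[GenotypeSignature, int] = {}
    for ind in obs.individuals:
        sig = ind.signature
        if sig not in class_pairs:
            pairs = compatible_pairs(sig, registry, panel)
            if pairs:
                idx = [(index[a.name], index[b.name]) for a, b in pairs]
            else:
                halves = partial_explanations(sig, registry, panel)
                if halves:
                    idx = [(index[h.name], other) for h in halves]
                else:
                    idx = [(other, other)]
            class_pairs[sig] = idx
            class_count[sig] = 0
        class_count[sig] += 1

    sigs = list(class_pairs)
    weights = np.array([class_count[s] for s in sigs], dtype=float)
    i_idx = [np.array([p[0] for p in class_pairs[s]]) for s in sigs]
    j_idx = [np.array([p[1] for p in class_pairs[s]]) for s in sigs]
    return names + [OTHER], weights, i_idx, j_idx


def em_estimate(
    obs: CohortObservations,
    registry: KirRegistry,
    panel: AssayPanel,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FrequencyEstimate:
    """Maximum-likelihood haplotype frequencies by EM.

    Initialisation is uniform; iteration stops when the log-likelihood
    improves by less than ``tol`` or after ``max_iter`` rounds.  The
    log-likelihood is checked to be non-decreasing every iteration.
    """
    if not obs.individuals:
        raise KirRegistryError("empty cohort")
    names, weights, i_idx, j_idx = _genotype_classes(obs, registry, panel)
    n_classes = len(weights)
    K = len(names)
    if all((i_idx[c] == K - 1).all() and (j_idx[c] == K - 1).all() for c in range(n_classes)):
        raise KirRegistryError("no individual matches any registered haplotype")

    n = weights.sum()
    freqs = np.full(K, 1.0 / K)
    loglik_trace: list[float] = []
    prev = -np.inf
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        counts = np.zeros(K)
        loglik = 0.0
        for c in range(n_classes):
            i, j = i_idx[c], j_idx[c]
            w = np.where(i == j, 1.0, 2.0) * freqs[i] * freqs[j]
            total = w.sum()
            if not np.isfinite(total) or total <= 0:
                raise KirRegistryError("non-finite or zero genotype likelihood")
            post = weights[c] * w / total
            np.add.at(counts, i, post)
            np.add.at(counts, j, post)
            loglik += weights[c] * np.log(total)
        if loglik < prev - 1e-9:
            raise AssertionError("EM log-likelihood decreased")
        loglik_trace.append(loglik)
        freqs = counts / (2.0 * n)
        if loglik - prev < tol and np.isfinite(prev):
            break
        prev = loglik

    freq_map = {name: float(f) for name, f in zip(names, freqs)}
    return FrequencyEstimate(
        freqs=freq_map,
        log_likelihood=loglik_trace,
        iterations=iterations,
        unresolved_chromosomes=float(freqs[-1] * 2 * n),
        n_individuals=int(n),
    )


def frequency_report(
    est: FrequencyEstimate,
    obs: CohortObservations,
    registry: KirRegistry,
    panel: AssayPanel,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-population and pooled haplotype frequency table.

    Per-population columns hold expected chromosome counts from a
    population-specific EM; the pooled column comes from ``est`` and carries
    percentages rounded to one decimal.  The "other" row pools unresolved
    chromosomes.
    """
    pops = obs.populations()
    rows = [name for name in est.freqs]
    table = pd.DataFrame(index=rows)
    for pop in pops:
        sub = CohortObservations([i for i in obs.individuals if i.population == pop])
        sub_est = em_estimate(sub, registry, panel, tol=tol)
        chroms = 2 * sub_est.n_individuals
        table[pop] = [sub_est.freqs[name] * chroms for name in rows]
    total_chroms = 2 * est.n_individuals
    table["total"] = [est.freqs[name] * total_chroms for name in rows]
    table["percent"] = [round(100.0 * est.freqs[name], 1) for name in rows]
    return table


def pooled_percentages(counts: pd.DataFrame) -> pd.Series:
    """Pooled percentages (1 decimal) from a per-population count table.

    ``counts`` has one row per haplotype (plus "other") and one integer
    column per population; chromosome totals are the column sums.
    """
    totals = counts.sum(axis=1)
    return (100.0 * totals / totals.sum()).round(1)


# ---------------------------------------------------------------------------
# Cohort TSV I/O: id, population, one 0/1 column per presence assay and per
# linking assay (link columns named "link:LOCUS1-LOCUS2").
# ---------------------------------------------------------------------------


def _link_col(pair: tuple[str, str]) -> str:
    return f"link:{pair[0]}-{pair[1]}"


def write_cohort_tsv(obs: CohortObservations, panel: AssayPanel, path: str) -> None:
    loci = sorted(panel.presence_assays)
    links = sorted(panel.linking_assays)
    rows = []
    for ind in obs.individuals:
        row: dict[str, object] = {"id": ind.id, "population": ind.population}
        for locus in loci:
            row[locus] = int(locus in ind.signature.presence)
        for pair in links:
            row[_link_col(pair)] = int(pair in ind.signature.links)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_tsv(path: str, panel: AssayPanel) -> CohortObservations:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "population": str})
    loci = sorted(panel.presence_assays)
    links = sorted(panel.linking_assays)
    individuals = []
    for _, row in df.iterrows():
        presence = frozenset(l for l in loci if int(row[l]) == 1)
        detected = frozenset(p for p in links if int(row[_link_col(p)]) == 1)
        individuals.append(
            Individual(
                id=str(row["id"]),
                population=str(row["population"]),
                signature=GenotypeSignature(presence=presence, links=detected),
            )
        )
    return CohortObservations(individuals)
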