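"""Canonical model of the KIR locus: loci, gene-content motifs, haplotype
structures and the motif-based haplotype nomenclature.

The human KIR gene family is modelled as 13 loci (11 genes, 2 pseudogenes)
anchored by four framework loci: 3DL3 at the centromeric end, 3DL2 at the
telomeric end, and the 3DP1-2DL4 pair in the middle.  Gene-content variation
is organised into centromeric (``cA01``, ``cB01``-``cB03``) and telomeric
(``tA01``, ``tB01``) motifs; a haplotype structure is one Cen motif combined
with one Tel motif and is named ``cXnn|tXnn``.  Allele-resolved haplotypes
add a 3-digit combination number per motif, e.g. ``cA01:001|tA01:001``.

Several allele-level names behave as alleles of a single locus (2DL2/2DL3,
3DL1/3DS1, 2DS3/2DS5, positional 2DL5A/2DL5B).  Gene-content operations work
at locus level, but motif definitions keep the allele-level (alias) identity
because motif membership depends on it: cA01 carries 2DL3 where cB01 and
cB02 carry 2DL2.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "KirRegistryError",
    "GeneLocus",
    "Motif",
    "HaplotypeStructure",
    "AlleleHaplotype",
    "KirRegistry",
    "load_registry",
    "default_registry",
    "parse_structure_name",
    "parse_full_name",
]

#: The four loci present on essentially every KIR haplotype.
FRAMEWORK_LOCI = frozenset({"3DL3", "3DP1", "2DL4", "3DL2"})

_STRUCTURE_NAME_RE = re.compile(r"^(c[A-Z]\d{2})\|(t[A-Z]\d{2})$")
_FULL_NAME_RE = re.compile(r"^(c[A-Z]\d{2}):(\d{3})\|(t[A-Z]\d{2}):(\d{3})$")


class KirRegistryError(ValueError):
    """Raised for registry documents or queries that violate locus/motif rules."""


@dataclass(frozen=True)
class GeneLocus:
    locus_id: str
    kind: str  # "gene" | "pseudogene"
    allele_aliases: tuple[str, ...] = ()
    framework: bool = False


@dataclass(frozen=True)
class Motif:
    """An ordered gene-content block on one side of the 3DP1-2DL4 framework."""

    motif_id: str
    side: str  # "Cen" | "Tel"
    gene_order: tuple[str, ...]  # allele-level (alias) entries

    def adjacent_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.gene_order, self.gene_order[1:]))


@dataclass(frozen=True)
class HaplotypeStructure:
    """A (Cen motif, Tel motif) combination with its derived gene content."""

    cen: str
    tel: str
    gene_content: frozenset[str]  # locus-level, includes all framework loci
    alias_content: frozenset[str]  # allele-level entries of both motifs

    @property
    def name(self) -> str:
        return f"{self.cen}|{self.tel}"


@dataclass(frozen=True)
class AlleleHaplotype:
    structure: HaplotypeStructure
    alleles: Mapping[str, str]
    cen_combo: int
    tel_combo: int

    @property
    def full_name(self) -> str:
        return f"{self.structure.cen}:{self.cen_combo:03d}|{self.structure.tel}:{self.tel_combo:03d}"


def parse_structure_name(name: str) -> tuple[str, str]:
    m = _STRUCTURE_NAME_RE.match(name)
    if not m:
        raise KirRegistryError(f"not a valid haplotype structure name: {name!r}")
    return m.group(1), m.group(2)


def parse_full_name(name: str) -> tuple[str, int, str, int]:
    m = _FULL_NAME_RE.match(name)
    if not m:
        raise KirRegistryError(f"not a valid allele-haplotype name: {name!r}")
    return m.group(1), int(m.group(2)), m.group(3), int(m.group(4))


class KirRegistry:
    """Validated collection of loci, motifs and registered haplotype structures.

    Also owns the allele-combination counters used by the nomenclature: the
    first distinct allele vector seen for a motif is numbered 001, the next
    002, and identical vectors reuse their number.
    """

    def __init__(self, loci: Sequence[GeneLocus], motifs: Sequence[Motif]):
        self.loci: dict[str, GeneLocus] = {}
        self.alias_to_locus: dict[str, str] = {}
        for locus in loci:
            if locus.locus_id in self.loci:
                raise KirRegistryError(f"duplicate locus_id {locus.locus_id}")
            self.loci[locus.locus_id] = locus
        for locus in loci:
            for alias in locus.allele_aliases:
                if alias in self.alias_to_locus or alias in self.loci:
                    raise KirRegistryError(f"alias {alias} mapped to two loci")
                self.alias_to_locus[alias] = locus.locus_id

        framework = {l.locus_id for l in loci if l.framework}
        if framework != FRAMEWORK_LOCI:
            raise KirRegistryError(
                f"framework loci must be exactly {sorted(FRAMEWORK_LOCI)}, got {sorted(framework)}"
            )

        self.motifs: dict[str, Motif] = {}
        for motif in motifs:
            if motif.motif_id in self.motifs:
                raise KirRegistryError(f"duplicate motif_id {motif.motif_id}")
            if motif.side not in ("Cen", "Tel"):
                raise KirRegistryError(f"motif {motif.motif_id}: side must be Cen or Tel")
            if not motif.gene_order:
                raise KirRegistryError(f"motif {motif.motif_id}: empty gene_order")
            for entry in motif.gene_order:
                self.resolve_locus(entry)
            if motif.side == "Cen" and self.resolve_locus(motif.gene_order[0]) != "3DL3":
                raise KirRegistryError(f"Cen motif {motif.motif_id} must begin with 3DL3")
            if motif.side == "Tel" and (
                self.resolve_locus(motif.gene_order[0]) != "2DL4"
                or self.resolve_locus(motif.gene_order[-1]) != "3DL2"
            ):
                raise KirRegistryError(
                    f"Tel motif {motif.motif_id} must begin with 2DL4 and end with 3DL2"
                )
            self.motifs[motif.motif_id] = motif

        self.structures: dict[str, HaplotypeStructure] = {}
        # per-motif registration-order list of allele vectors -> combo numbers
        self._combo_vectors: dict[str, list[tuple[tuple[str, str], ...]]] = {}

    # -- loci ---------------------------------------------------------------

    def resolve_locus(self, name: str) -> str:
        """Map a locus id or allele-level alias to its locus id."""
        if name in self.loci:
            return name
        if name in self.alias_to_locus:
            return self.alias_to_locus[name]
        raise KirRegistryError(f"unknown locus or alias: {name!r}")

    def gene_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci.values() if l.kind == "gene"]

    def pseudogene_loci(self) -> list[GeneLocus]:
        return [l for l in self.loci.values() if l.kind == "pseudogene"]

    # -- structures ---------------------------------------------------------

    def compose_structure(self, cen: str, tel: str) -> HaplotypeStructure:
        """Combine a Cen and a Tel motif into a haplotype structure.

        The gene content is the union of the two motifs' loci plus the four
        framework loci (3DP1, which sits at the centromeric side of the
        central framework, belongs to every structure even though it is not
        written in the motif gene orders).
        """
        for motif_id, side in ((cen, "Cen"), (tel, "Tel")):
            if motif_id not in self.motifs:
                raise KirRegistryError(f"unknown motif {motif_id!r}")
            if self.motifs[motif_id].side != side:
                raise KirRegistryError(
                    f"motif {motif_id} is {self.motifs[motif_id].side}, expected {side}"
                )
        entries = self.motifs[cen].gene_order + self.motifs[tel].gene_order
        content = frozenset(self.resolve_locus(e) for e in entries) | FRAMEWORK_LOCI
        return HaplotypeStructure(
            cen=cen, tel=tel, gene_content=content, alias_content=frozenset(entries)
        )

    def register_structure(self, cen: str, tel: str) -> HaplotypeStructure:
        structure = self.compose_structure(cen, tel)
        self.structures[structure.name] = structure
        return structure

    def registered(self) -> list[HaplotypeStructure]:
        return [self.structures[name] for name in sorted(self.structures)]

    def decompose_content(self, genes: Iterable[str]) -> list[HaplotypeStructure]:
        """All registered structures whose gene content matches ``genes``.

        ``genes`` may mix locus ids and allele-level aliases.  Matching is by
        locus-level set equality; any alias present in the input additionally
        constrains candidates: a structure is rejected if one of its own
        alias-level entries for that locus is not among the input aliases
        (an input naming 2DL2 but not 2DL3 excludes 2DL3-carrying motifs).
        """
        genes = set(genes)
        locus_set = frozenset(self.resolve_locus(g) for g in genes)
        if not FRAMEWORK_LOCI <= locus_set:
            raise KirRegistryError(
                f"input lacks framework loci {sorted(FRAMEWORK_LOCI - locus_set)}"
            )
        input_aliases = {g for g in genes if g in self.alias_to_locus}
        constrained_loci = {self.alias_to_locus[a] for a in input_aliases}
        out = []
        for structure in self.registered():
            if structure.gene_content != locus_set:
                continue
            ok = all(
                entry in input_aliases
                for entry in structure.alias_content
                if entry in self.alias_to_locus
                and self.alias_to_locus[entry] in constrained_loci
            )
            if ok:
                out.append(structure)
        return sorted(out, key=lambda s: (s.cen, s.tel))

    # -- allele-level nomenclature -------------------------------------------

    def _motif_allele_vector(
        self, motif: Motif, alleles: Mapping[str, str], extra: tuple[str, ...] = ()
    ) -> tuple[tuple[str, str], ...]:
        entries = motif.gene_order + extra
        vector = []
        for entry in entries:
            if entry in alleles:
                vector.append((entry, alleles[entry]))
            elif self.resolve_locus(entry) in alleles:
                vector.append((entry, alleles[self.resolve_locus(entry)]))
            else:
                raise KirRegistryError(f"no allele given for {entry} of motif {motif.motif_id}")
        return tuple(vector)

    def name_allele_haplotype(
        self, structure: HaplotypeStructure, alleles: Mapping[str, str]
    ) -> AlleleHaplotype:
        """Assign combination numbers to an allele-resolved haplotype.

        The centromeric vector covers the Cen motif's genes plus 3DP1 (the
        centromeric half of the central framework); the telomeric vector
        covers the Tel motif's genes.  Numbers are assigned in registration
        order starting at 001, and identical vectors reuse their number.
        """
        for name in alleles:
            if self.resolve_locus(name) not in structure.gene_content:
                raise KirRegistryError(f"allele given for {name}, absent from {structure.name}")
        covered = {self.resolve_locus(n) for n in alleles}
        missing = structure.gene_content - covered
        if missing:
            raise KirRegistryError(f"alleles missing for loci {sorted(missing)}")
        cen_vec = self._motif_allele_vector(self.motifs[structure.cen], alleles, extra=("3DP1",))
        tel_vec = self._motif_allele_vector(self.motifs[structure.tel], alleles)
        return AlleleHaplotype(
            structure=structure,
            alleles=dict(alleles),
            cen_combo=self._combo_number(structure.cen, cen_vec),
            tel_combo=self._combo_number(structure.tel, tel_vec),
        )

    def _combo_number(self, motif_id: str, vector: tuple[tuple[str, str], ...]) -> int:
        seen = self._combo_vectors.setdefault(motif_id, [])
        if vector in seen:
            return seen.index(vector) + 1
        seen.append(vector)
        return len(seen)


def find_identical_allele_content(
    panel: Sequence[AlleleHaplotype],
) -> list[list[AlleleHaplotype]]:
    """Groups (size >= 2) of haplotypes sharing structure and full allele vector."""
    if not panel:
        raise KirRegistryError("empty haplotype panel")
    groups: dict[tuple, list[AlleleHaplotype]] = {}
    for hap in panel:
        key = (hap.structure.name, tuple(sorted(hap.alleles.items())))
        groups.setdefault(key, []).append(hap)
    return [groups[key] for key in sorted(groups) if len(groups[key]) >= 2]


def load_registry(document: Mapping | str) -> KirRegistry:
    """Build a registry from a YAML document (mapping, YAML text, or path).

    The document has ``loci:`` and ``motifs:`` sections and optionally a
    ``haplotypes:`` list of structure names to register.
    """
    if isinstance(document, str):
        if "\n" not in document and document.endswith((".yaml", ".yml", ".json")):
            with open(document) as fh:
                document = yaml.safe_load(fh)
        else:
            document = yaml.safe_load(document)
    loci = [
        GeneLocus(
            locus_id=entry["locus_id"],
            kind=entry.get("kind", "gene"),
            allele_aliases=tuple(entry.get("allele_aliases", ())),
            framework=bool(entry.get("framework", False)),
        )
        for entry in document["loci"]
    ]
    motifs = [
        Motif(
            motif_id=entry["motif_id"],
            side=entry["side"],
            gene_order=tuple(entry["gene_order"]),
        )
        for entry in document["motifs"]
    ]
    registry = KirRegistry(loci, motifs)
    for name in document.get("haplotypes", ()):
        registry.register_structure(*parse_structure_name(name))
    return registry


def default_registry() -> KirRegistry:
    """The packaged locus/motif registry with the seven observed haplotypes."""
    text = resources.files("kirhaplo.data").joinpath("registry.yaml").read_text()
    return load_registry(text)


def all_possible_structures(registry: KirRegistry) -> list[HaplotypeStructure]:
    """Every Cen x Tel combination the motif inventory allows (8 with the
    default four Cen and two Tel motifs), registered or not."""
    cens = sorted(m.motif_id for m in registry.motifs.values() if m.side == "Cen")
    tels = sorted(m.motif_id for m in registry.motifs.values() if m.side == "Tel")
    return [registry.compose_structure(c, t) for c, t in itertools.product(cens, tels)]
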