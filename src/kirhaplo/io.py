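"""Readers and writers shared by all pipeline stages.

Formats: FASTA alignments (Biopython), Newick trees (dendropy), GFF3 gene
annotations (gffutils; 1-based inclusive on disk, 0-based half-open in
memory), BED-like TSV domain partitions, and TSV tables (pandas).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .diversity import Alignment, GeneAnnotation
from .phylo import DomainPartition

__all__ = [
    "read_alignment",
    "write_alignment",
    "read_tree",
    "write_tree",
    "read_gene_annotations",
    "read_partition_tsv",
    "write_diversity_table",
    "RunConfig",
    "run_pipeline",
]

_KNOWN = set("ACGTN-")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are uppercased, U becomes T, and any other unknown character
    becomes N with a warning.  Ragged records are an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    ids, rows = [], []
    length = None
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        unknown = set(seq) - _KNOWN
        if unknown:
            warnings.warn(
                f"record {rec.id}: characters {sorted(unknown)} replaced with N"
            )
            seq = "".join(c if c in _KNOWN else "N" for c in seq)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"ragged alignment: record {rec.id} has length {len(seq)}, expected {length}"
            )
        ids.append(rec.id)
        rows.append(seq)
    return Alignment(tuple(ids), tuple(rows))


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n")
            for k in range(0, len(row), 80):
                fh.write(row[k : k + 80] + "\n")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with 6-significant-digit branch lengths and supports as
    internal-node labels."""
    for node in tree.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf():
            node.label = f"{support:.0f}"
    tree.write(
        path=str(path),
        schema="newick",
        real_value_format_specifier=".6g",
        suppress_rooting=True,
    )


def read_gene_annotations(path: str | Path) -> dict[str, GeneAnnotation]:
    """Gene annotations from GFF3 (1-based inclusive -> 0-based half-open).

    Expected feature types per gene: ``start_codon``, ``exon`` (several),
    ``polyA_site``; features are grouped by their ``gene_id`` attribute.  A
    gene attribute ``truncated_at_exon=K`` marks genes whose usable region
    ends at exon K (e.g. 3DP1 at exon 5).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: dict[str, dict] = {}
    for feat in db.all_features():
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        info = genes.setdefault(
            gene_id, {"exons": [], "start_codon": None, "polya": None, "strand": feat.strand,
                      "truncated": None}
        )
        if feat.featuretype == "exon":
            info["exons"].append((feat.start - 1, feat.end))  # half-open
        elif feat.featuretype == "start_codon":
            info["start_codon"] = feat.start - 1
        elif feat.featuretype == "polyA_site":
            info["polya"] = feat.start - 1
        if "truncated_at_exon" in feat.attributes:
            info["truncated"] = int(feat.attributes["truncated_at_exon"][0])
    out = {}
    for gene_id, info in genes.items():
        if info["start_codon"] is None or info["polya"] is None:
            raise ValueError(f"gene {gene_id}: missing start_codon or polyA_site feature")
        out[gene_id] = GeneAnnotation(
            gene_id=gene_id,
            start_codon=info["start_codon"],
            exons=tuple(sorted(info["exons"])),
            polya=info["polya"],
            strand=info["strand"] or "+",
            truncated_at_exon=info["truncated"],
        )
    return out


def read_partition_tsv(path: str | Path) -> DomainPartition:
    """Domain partition from BED-like TSV: name, start, end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "start", "end"], comment="#")
    return DomainPartition(
        tuple((str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows())
    )


def write_diversity_table(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration for an end-to-end cohort run."""

    out_dir: str
    seed: int = 0
    n_individuals: int = 192
    registry_path: str | None = None  # None -> packaged registry
    cohort_path: str | None = None  # None -> simulate
    verbosity: int = 1


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate (or load) a cohort, infer frequencies, write report + manifest.

    Outputs ``cohort.tsv``, ``frequencies.tsv`` and ``manifest.json`` in
    ``cfg.out_dir``; identical config and seed give identical outputs.
    """
    from . import __version__
    from .inference import default_panel, em_estimate, frequency_report, read_cohort_tsv, write_cohort_tsv
    from .registry import default_registry, load_registry
    from .simulate import simulate_cohort

    if cfg.registry_path is not None:
        if not Path(cfg.registry_path).exists():
            raise FileNotFoundError(f"registry not found: {cfg.registry_path}")
        registry = load_registry(cfg.registry_path)
    else:
        registry = default_registry()
    panel = default_panel(registry)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate/load cohort"
    try:
        if cfg.cohort_path is not None:
            obs = read_cohort_tsv(cfg.cohort_path, panel)
        else:
            obs, _ = simulate_cohort(registry, panel, n=cfg.n_individuals, seed=cfg.seed)
        write_cohort_tsv(obs, panel, str(out / "cohort.tsv"))
        stage = "em_estimate"
        est = em_estimate(obs, registry, panel)
        stage = "frequency_report"
        report = frequency_report(est, obs, registry, panel)
        report.to_csv(out / "frequencies.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "n_individuals": cfg.n_individuals,
            "registry": cfg.registry_path or "packaged",
            "cohort": cfg.cohort_path or "simulated",
        },
        "outputs": {
            name: _sha256(out / name) for name in ("cohort.tsv", "frequencies.tsv")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
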