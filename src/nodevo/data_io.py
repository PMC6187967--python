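"""Readers, writers and domain types shared by the whole pipeline.

Every downstream module consumes only the types defined here:
expression records (one gene's nodule-over-root log2 fold change plus an
adjusted p-value), per-gene ortholog predictions, in-frame codon
alignments, and phylogenies.  All tabular formats are plain TSV, codon
alignments are FASTA, trees are Newick.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "DataError",
    "ExpressionRecord",
    "OrthologPrediction",
    "CodonAlignment",
    "Phylogeny",
    "RunConfig",
    "read_expression_table",
    "write_expression_table",
    "normalize_mt_records",
    "read_codon_fasta",
    "write_codon_fasta",
    "read_newick",
    "write_newick",
    "read_ortholog_predictions",
    "write_ortholog_predictions",
]


class DataError(ValueError):
    """Raised when an input file or record violates a type invariant."""


# --------------------------------------------------------------------------
# expression records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionRecord:
    """Differential expression of one gene (nodule over root) in one species."""

    gene_id: str
    species_id: str
    log2fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log2fc):
            raise DataError(
                f"{self.species_id}/{self.gene_id}: log2fc must be finite, "
                f"got {self.log2fc!r}"
            )
        if not (0.0 <= self.adj_p <= 1.0):
            raise DataError(
                f"{self.species_id}/{self.gene_id}: adjusted p-value "
                f"{self.adj_p!r} outside [0, 1]"
            )


def read_expression_table(path: str | Path, species_id: str) -> list[ExpressionRecord]:
    """Read a long-format TSV with columns ``gene_id``, ``log2fc``, ``adj_p``.

    Rows whose numeric fields do not parse are reported (warning) and
    skipped; a duplicated gene id is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"expression table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "log2fc", "adj_p"):
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    records: list[ExpressionRecord] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        if gid in seen:
            raise DataError(f"{path}: duplicate gene_id {gid!r}")
        seen.add(gid)
        try:
            fc = float(row.log2fc)
            p = float(row.adj_p)
        except (TypeError, ValueError):
            log.warning("%s: skipping unparseable row for gene %s", path, gid)
            continue
        if math.isnan(fc) or math.isnan(p):
            log.warning("%s: skipping row with missing numerics for gene %s", path, gid)
            continue
        try:
            records.append(ExpressionRecord(gid, species_id, fc, p))
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from exc
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2fc, r.adj_p) for r in records],
        columns=["gene_id", "log2fc", "adj_p"],
    )
    df.to_csv(path, sep="\t", index=False)


# Magnitude assigned to tissue-specific genes in the genome-wide legume
# table: large enough to dominate any observed fold change.
TISSUE_SPECIFIC_LOG2FC = 15.0


def normalize_mt_records(
    table: pd.DataFrame,
    species_id: str = "Mt",
    *,
    tissue_specific_significant: bool = False,
) -> list[ExpressionRecord]:
    """Fill in fold changes and p-values for a genome-wide legume table.

    ``table`` has columns ``gene_id``, ``root_expr``, ``nodule_expr`` and
    optionally ``log2fc`` / ``adj_p`` (NaN where the upstream differential
    expression analysis produced no value).  Genes expressed in neither
    tissue get (log2fc 0, adj_p 1).  Tissue-specific genes get log2fc
    +15 (nodule-only) or -15 (root-only); their missing p-values default
    to 1, or 0 when ``tissue_specific_significant`` is set, which treats
    an on/off expression pattern as significant by construction.
    """
    for col in ("gene_id", "root_expr", "nodule_expr"):
        if col not in table.columns:
            raise DataError(f"normalize_mt_records: missing column {col!r}")
    has_fc = "log2fc" in table.columns
    has_p = "adj_p" in table.columns
    ts_p = 0.0 if tissue_specific_significant else 1.0
    out: list[ExpressionRecord] = []
    for row in table.itertuples(index=False):
        gid = str(row.gene_id)
        root = float(row.root_expr)
        nod = float(row.nodule_expr)
        if root < 0 or nod < 0:
            raise DataError(f"{gid}: negative expression level")
        fc = float(getattr(row, "log2fc", np.nan)) if has_fc else np.nan
        p = float(getattr(row, "adj_p", np.nan)) if has_p else np.nan
        if root == 0.0 and nod == 0.0:
            fc, p = 0.0, 1.0
        elif root == 0.0:  # nodule-specific
            if not np.isnan(fc) and fc < 0:
                raise DataError(f"{gid}: flagged nodule-specific but log2fc < 0")
            fc = TISSUE_SPECIFIC_LOG2FC
            if np.isnan(p):
                p = ts_p
        elif nod == 0.0:  # root-specific
            if not np.isnan(fc) and fc > 0:
                raise DataError(f"{gid}: flagged root-specific but log2fc > 0")
            fc = -TISSUE_SPECIFIC_LOG2FC
            if np.isnan(p):
                p = ts_p
        else:
            if np.isnan(fc):
                raise DataError(f"{gid}: expressed in both tissues but no log2fc given")
            if np.isnan(p):
                p = 1.0
        out.append(ExpressionRecord(gid, species_id, fc, p))
    return out


# --------------------------------------------------------------------------
# ortholog predictions
# --------------------------------------------------------------------------

Member = tuple[str, str]  # (species_id, gene_id)


@dataclass(frozen=True)
class OrthologPrediction:
    """The predicted ortholog set of one query gene (itself included)."""

    query_gene: Member
    orthologs: frozenset[Member]

    def __post_init__(self) -> None:
        if not self.orthologs:
            raise DataError(f"{self.query_gene}: empty ortholog set")
        if self.query_gene not in self.orthologs:
            raise DataError(
                f"{self.query_gene}: query gene missing from its own ortholog set"
            )


def read_ortholog_predictions(path: str | Path) -> list[OrthologPrediction]:
    """Read an edge-list TSV: query_species, query_gene, species, gene.

    One row per (query gene, predicted ortholog) pair; the query gene
    itself need not be listed and is always added.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"ortholog prediction file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["query_species", "query_gene", "species", "gene"]
    for col in need:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    by_query: dict[Member, set[Member]] = {}
    for row in df.itertuples(index=False):
        q = (str(row.query_species), str(row.query_gene))
        by_query.setdefault(q, set()).add((str(row.species), str(row.gene)))
    preds = []
    for q, members in sorted(by_query.items()):
        members.add(q)
        preds.append(OrthologPrediction(q, frozenset(members)))
    return preds


def write_ortholog_predictions(
    predictions: Iterable[OrthologPrediction], path: str | Path
) -> None:
    rows = []
    for p in predictions:
        for sp, gene in sorted(p.orthologs):
            rows.append((p.query_gene[0], p.query_gene[1], sp, gene))
    pd.DataFrame(rows, columns=["query_species", "query_gene", "species", "gene"]).to_csv(
        path, sep="\t", index=False
    )


# --------------------------------------------------------------------------
# codon alignments
# --------------------------------------------------------------------------

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_NUC = set("ACGT")


def _is_resolved(codon: str) -> bool:
    return all(c in _NUC for c in codon)


@dataclass(frozen=True)
class CodonAlignment:
    """An in-frame codon alignment; gap/ambiguous codons count as missing."""

    sequences: dict[str, str]
    n_codons: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise DataError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise DataError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3 != 0:
            raise DataError(f"alignment length {length} not divisible by 3")
        for taxon, seq in self.sequences.items():
            seq = seq.upper()
            for i in range(0, length, 3):
                codon = seq[i : i + 3]
                if _is_resolved(codon) and codon in STOP_CODONS:
                    raise DataError(
                        f"internal stop codon {codon} in taxon {taxon!r} "
                        f"at codon index {i // 3}"
                    )
        object.__setattr__(
            self,
            "sequences",
            {t: s.upper() for t, s in self.sequences.items()},
        )
        object.__setattr__(self, "n_codons", length // 3)

    def codons(self, taxon: str) -> list[str]:
        seq = self.sequences[taxon]
        return [seq[i : i + 3] for i in range(0, len(seq), 3)]

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)


def read_codon_fasta(path: str | Path) -> CodonAlignment:
    from Bio import SeqIO

    path = Path(path)
    if not path.exists():
        raise DataError(f"alignment not found: {path}")
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise DataError(f"{path}: duplicate sequence name {record.id!r}")
        sequences[record.id] = str(record.seq)
    try:
        return CodonAlignment(sequences)
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_codon_fasta(aln: CodonAlignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon, seq in aln.sequences.items():
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# phylogenies
# --------------------------------------------------------------------------

DEFAULT_BRANCH_LENGTH = 0.1


@dataclass
class Phylogeny:
    """A taxon-labeled tree with branch lengths in substitutions/codon.

    Thin wrapper around :class:`dendropy.Tree`; branch-class labels used
    by the dN/dS machinery live in ``edge.branch_class`` annotations set
    by :mod:`nodevo.scenarios`.
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise DataError(f"duplicate tip label(s): {dup}")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node is self.tree.seed_node:
                continue
            if edge.length is None:
                log.warning(
                    "branch above %s has no length; defaulting to %s",
                    edge.head_node,
                    DEFAULT_BRANCH_LENGTH,
                )
                edge.length = DEFAULT_BRANCH_LENGTH
            elif edge.length < 0:
                raise DataError(f"negative branch length {edge.length}")

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def copy(self) -> "Phylogeny":
        return Phylogeny(self.tree.clone(depth=1))


def read_newick(source: str | Path) -> Phylogeny:
    """Read a Newick tree from a path (or a literal Newick string)."""
    text: str
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    elif isinstance(source, str) and source.lstrip().startswith("("):
        text = source
    else:
        raise DataError(f"tree file not found: {source}")
    if text.count("(") != text.count(")"):
        raise DataError("unbalanced parentheses in Newick input")
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises various parse errors
        raise DataError(f"could not parse Newick input: {exc}") from exc
    return Phylogeny(tree)


def write_newick(phy: Phylogeny, path: str | Path) -> None:
    phy.tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Tunable parameters for a full pipeline run.

    Per-species significance cutoffs default to the study design this
    package models: adjusted p < 0.005 for the low-replicate species
    (Ct) and < 0.001 otherwise, |log2fc| > 1 everywhere.
    """

    p_cutoffs: dict[str, float] = field(
        default_factory=lambda: {"Ct": 0.005, "Dg": 0.001, "Mt": 0.001}
    )
    fc_cutoff: float = 1.0
    n_permutations: int = 10_000
    seed: int = 0
    sh_alpha: float = 0.05
    kh_alpha: float = 0.05
    n_rell: int = 1000
    omega_bounds: tuple[float, float] = (1e-4, 20.0)
    kappa_bounds: tuple[float, float] = (0.1, 20.0)
    lnl_tol: float = 1e-6
    n_starts: int = 2
    branch_length_mode: str = "scale"  # scale | full | fixed
    tissue_specific_significant: bool = False
    permute_both_species: bool = True
    both_counts_for_core: bool = True

    def __post_init__(self) -> None:
        for sp, cut in self.p_cutoffs.items():
            if cut <= 0:
                raise DataError(f"p cutoff for {sp} must be > 0")
        if self.fc_cutoff <= 0:
            raise DataError("fold-change cutoff must be > 0")
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        for a in (self.sh_alpha, self.kh_alpha):
            if not (0 < a < 1):
                raise DataError("test alpha must lie in (0, 1)")
        if self.branch_length_mode not in ("scale", "full", "fixed"):
            raise DataError(f"unknown branch_length_mode {self.branch_length_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if "omega_bounds" in raw:
            cfg.omega_bounds = tuple(raw["omega_bounds"])  # type: ignore[assignment]
        if "kappa_bounds" in raw:
            cfg.kappa_bounds = tuple(raw["kappa_bounds"])  # type: ignore[assignment]
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=int(seed))
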