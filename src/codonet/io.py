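"""Input parsing and report writing.

Formats: FASTA codon alignments (gap-cleaned, in-frame), Newick trees
(optionally with codeml-style ``#1`` foreground tags), tab-separated edge
lists and annotation tables, and the TSV/JSON analysis reports.

Codons containing gaps or nucleotide ambiguity codes become MISSING states;
stop codons are rejected outright since inputs are declared to be cleaned
coding sequence.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import MISSING, GeneticCode, universal_code

logger = logging.getLogger(__name__)

CELL_TYPES = ("rod", "cone", "shared")
PROCESSES = ("development", "phototransduction", "retinoid_cycle")
FUNCTIONS = (
    "enzyme",
    "chaperone",
    "opsin",
    "g_protein",
    "phosphodiesterase",
    "signal_regulator",
    "ion_channel_exchanger",
    "guanylate_cyclase",
    "miscellaneous",
)

PER_GENE_COLUMNS = [
    "gene", "n_codons", "lnL", "kappa", "omega", "dN", "dS",
    "tree_length", "degree", "closeness", "betweenness",
    "cell_type", "process", "function", "protein_length",
]
SELECTION_COLUMNS = [
    "gene", "test", "branch", "lnL_alt", "lnL_null",
    "statistic", "df", "p_raw", "p_adjusted",
]


class AlignmentError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


class NetworkParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap-cleaned codon alignment over a fixed taxon set.

    ``codons`` is an (n_taxa, n_sites) int16 matrix of sense-codon state
    indices, with :data:`~codonet.genetic_code.MISSING` for gap/ambiguous
    codons.
    """

    gene_id: str
    taxa: list[str]
    codons: np.ndarray

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int16)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise AlignmentError("codon matrix must be (n_taxa, n_sites)")
        if len(self.taxa) < 2:
            raise AlignmentError("alignment needs at least 2 taxa")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codons.shape[1]

    def subset_taxa(self, keep: list[str]) -> "CodonAlignment":
        idx = [self.taxa.index(t) for t in keep]
        return CodonAlignment(self.gene_id, list(keep), self.codons[idx])


def _codon_state(codon: str, code: GeneticCode) -> int:
    codon = codon.upper().replace("U", "T")
    if any(c not in "TCAG" for c in codon):
        return MISSING
    if codon in code.stop_codons:
        raise AlignmentError("stop codon")
    return code.index(codon)


def read_codon_alignment(
    path, code: GeneticCode | None = None, gene_id: str | None = None
) -> CodonAlignment:
    """Read a FASTA codon alignment.

    Raises :class:`AlignmentError` naming the offending record on length
    mismatch, and a validation error with taxon and 1-based codon site on
    internal stop codons.
    """
    code = code or universal_code()
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    length = len(records[0].seq)
    rows = []
    taxa = []
    for rec in records:
        seq = str(rec.seq)
        if len(seq) != length:
            raise AlignmentError(
                f"record {rec.id!r} has length {len(seq)}, expected {length}"
            )
        if len(seq) % 3 != 0:
            raise AlignmentError(
                f"record {rec.id!r}: length {len(seq)} not divisible by 3"
            )
        states = []
        for s in range(0, len(seq), 3):
            try:
                states.append(_codon_state(seq[s : s + 3], code))
            except AlignmentError:
                raise AlignmentError(
                    f"stop codon in {rec.id!r} at codon site {s // 3 + 1}"
                ) from None
        taxa.append(rec.id)
        rows.append(states)
    name = gene_id or os.path.splitext(os.path.basename(str(path)))[0]
    return CodonAlignment(name, taxa, np.array(rows, dtype=np.int16))


def write_codon_alignment(
    alignment: CodonAlignment, path, code: GeneticCode | None = None
) -> None:
    code = code or universal_code()
    with open(path, "w") as fh:
        for t, row in zip(alignment.taxa, alignment.codons):
            seq = "".join(
                code.sense_codons[s] if s != MISSING else "---" for s in row
            )
            fh.write(f">{t}\n{seq}\n")


# ---------------------------------------------------------------------------
# pathway network (edge-list TSV)
# ---------------------------------------------------------------------------

def read_network(path):
    """Read a two-column, headerless, tab-separated edge list.

    Returns an undirected simple :class:`networkx.Graph`; duplicate edges
    are collapsed, self-loops dropped with a warning.
    """
    import networkx as nx

    G = nx.Graph()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise NetworkParseError(
                    f"{path}:{lineno}: expected two tab-separated gene IDs"
                )
            a, b = parts[0].strip(), parts[1].strip()
            n_rows += 1
            if a == b:
                logger.warning("%s:%d: self-loop on %s dropped", path, lineno, a)
                G.add_node(a)
                continue
            G.add_edge(a, b)
    if n_rows == 0:
        raise NetworkParseError(f"empty edge list: {path}")
    return G


def write_network(G, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in G.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# gene annotations
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Three-way functional classification plus protein length."""

    gene_id: str
    cell_type: str
    process: str
    function: str
    protein_length: int

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise AnnotationError(f"{self.gene_id}: bad cell_type {self.cell_type!r}")
        if self.process not in PROCESSES:
            raise AnnotationError(f"{self.gene_id}: bad process {self.process!r}")
        if self.function not in FUNCTIONS:
            raise AnnotationError(f"{self.gene_id}: bad function {self.function!r}")
        if self.protein_length <= 0:
            raise AnnotationError(f"{self.gene_id}: protein_length must be > 0")


def read_annotations(path) -> pd.DataFrame:
    """Read the annotation TSV (header row required, '#' comments allowed)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "cell_type", "process", "function", "protein_length"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing)}")
    for _, row in df.iterrows():
        GeneAnnotation(
            row["gene"], row["cell_type"], row["process"], row["function"],
            int(row["protein_length"]),
        )
    return df


def write_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(
    per_gene: pd.DataFrame,
    selection: pd.DataFrame,
    association: dict,
    outdir,
) -> dict[str, str]:
    """Write the analysis bundle.

    ``per_gene.tsv``: one row per gene with omega/dN/dS, centralities (empty
    for genes outside the network) and classifications, in the documented
    column order.  ``selection_tests.tsv``: one row per test with raw and
    adjusted p.  ``associations.json``: the association statistics.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    pg = per_gene.reindex(columns=PER_GENE_COLUMNS)
    paths["per_gene"] = os.path.join(outdir, "per_gene.tsv")
    pg.to_csv(paths["per_gene"], sep="\t", index=False, float_format="%.17g")

    sel = selection.reindex(columns=SELECTION_COLUMNS)
    paths["selection"] = os.path.join(outdir, "selection_tests.tsv")
    sel.to_csv(paths["selection"], sep="\t", index=False, float_format="%.17g")

    paths["association"] = os.path.join(outdir, "associations.json")
    with open(paths["association"], "w") as fh:
        json.dump(association, fh, indent=2, default=_json_default)
        fh.write("\n")
    return paths


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_per_gene_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
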