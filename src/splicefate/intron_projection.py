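"""Intron positions in protein coordinates, cross-species conservation, loss.

An intron with ``cds_offset`` coding nucleotides upstream interrupts codon
``ceil(cds_offset / 3)``.  The phase (offset mod 3) is rendered as a decimal
digit: phase 1 -> .3, phase 2 -> .6, and phase 0 (between codons n and n+1)
-> n.0.  So an intron splitting codon 18 after its first base is written
"18.3" and after the second base "18.6".

Projected positions are carried through a protein multiple alignment by
counting non-gap characters, so homologous introns across species land in
the same (alignment column, phase) class; a class is conserved when at
least *k* of the genes have an intron in it (default: all of them).  Losses
of a non-universal class are placed on a species tree under Dollo parsimony:
one gain at the most recent common ancestor of the species that have the
intron, and the minimum number of loss branches covering every absence
inside that clade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .gene_model_io import (
    ConsistencyError,
    GeneModel,
    SpeciesTree,
    ValidationError,
    derive_introns,
)
from .orf_ptc import translate_cds

PHASE_DECIMAL = {0: 0.0, 1: 0.3, 2: 0.6}
_PHASE_DIGIT = {0: "0", 1: "3", 2: "6"}


@dataclass(frozen=True)
class ProjectedIntron:
    """One intron position in decimal-phase protein coordinates."""

    gene_id: str
    intron_index: int
    residue: int
    phase_decimal: float
    notation: str


def project_intron(cds_offset: int, *, gene_id: str = "", intron_index: int = 0) -> ProjectedIntron:
    """Project a coding offset to (residue, phase) decimal notation.

    Pure and total on positive integers: ``residue = ceil(offset / 3)``,
    phase digit 0/3/6 for offset mod 3 = 0/1/2.
    """
    if cds_offset < 1:
        raise ValidationError(f"cds_offset must be >= 1, got {cds_offset}")
    residue = -(-cds_offset // 3)
    phase = cds_offset % 3
    return ProjectedIntron(
        gene_id=gene_id,
        intron_index=intron_index,
        residue=residue,
        phase_decimal=PHASE_DECIMAL[phase],
        notation=f"{residue}.{_PHASE_DIGIT[phase]}",
    )


def parse_notation(notation: str) -> tuple[int, int]:
    """Invert the decimal notation to ``(residue, phase)``; lossless."""
    res_s, _, dig = notation.partition(".")
    digits = {v: k for k, v in _PHASE_DIGIT.items()}
    if dig not in digits:
        raise ValidationError(f"bad phase digit in notation {notation!r}")
    return int(res_s), digits[dig]


def project_gene(model: GeneModel) -> list[ProjectedIntron]:
    """Project every CDS intron of a gene, in intron order."""
    return [
        project_intron(rec.cds_offset, gene_id=model.gene_id, intron_index=rec.intron_index)
        for rec in derive_introns(model)
    ]


# ---------------------------------------------------------------------------
# alignment mapping


@dataclass
class AlignedIntronMatrix:
    """Presence/absence of intron position classes over MSA columns.

    A class is an exact ``(0-based alignment column, phase)`` pair; cells
    hold the per-gene decimal notation.  ``conserved[cls]`` is true when at
    least ``k`` genes have an entry in the class.
    """

    gene_ids: list[str]
    classes: list[tuple[int, int]]
    cells: dict[tuple[str, tuple[int, int]], str]
    conserved: dict[tuple[int, int], bool]
    k: int

    @property
    def conserved_classes(self) -> list[tuple[int, int]]:
        return [c for c in self.classes if self.conserved[c]]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"c{col + 1}.{_PHASE_DIGIT[ph]}" for col, ph in self.classes]
        data = {
            name: [self.cells.get((g, cls), "-") for cls in self.classes]
            for g, name in zip(self.gene_ids, self.gene_ids)
        }
        df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        df.index.name = "gene"
        df.loc["conserved"] = ["yes" if self.conserved[c] else "no" for c in self.classes]
        return df


def _residue_to_column(aligned: str, residue: int) -> int:
    """0-based MSA column of the residue-th (1-based) non-gap character."""
    seen = 0
    for col, ch in enumerate(aligned):
        if ch != "-":
            seen += 1
            if seen == residue:
                return col
    raise ValidationError(f"residue {residue} beyond ungapped length {seen}")


def map_to_alignment(
    msa: Mapping[str, str],
    projections: Mapping[str, Sequence[ProjectedIntron]],
    *,
    k: int | None = None,
    proteins: Mapping[str, str] | None = None,
    models: Mapping[str, GeneModel] | None = None,
) -> AlignedIntronMatrix:
    """Group per-gene projections into aligned intron position classes.

    ``msa`` maps gene id to its aligned (gapped) protein row; each row's
    ungapped sequence must equal the gene's canonical protein when
    ``proteins`` (or ``models``, from which proteins are translated) is
    given.  Phase-0 introns sit between codons n and n+1 and are keyed on
    the column of residue n — a deterministic tie-break.
    """
    if models is not None and proteins is None:
        proteins = {g: translate_cds(m.canonical_cds())[0] for g, m in models.items()}
    gene_ids = sorted(projections)
    for g in gene_ids:
        if g not in msa:
            raise ConsistencyError(f"gene {g} has projections but no MSA row")
        if proteins is not None:
            ungapped = msa[g].replace("-", "")
            if ungapped != proteins[g]:
                raise ConsistencyError(
                    f"gene {g}: ungapped MSA row does not match its canonical protein"
                )

    cells: dict[tuple[str, tuple[int, int]], str] = {}
    counts: dict[tuple[int, int], set[str]] = {}
    for g in gene_ids:
        for p in projections[g]:
            col = _residue_to_column(msa[g], p.residue)
            phase = round(p.phase_decimal * 10) // 3  # 0.0/0.3/0.6 -> 0/1/2
            cls = (col, phase)
            cells[(g, cls)] = p.notation
            counts.setdefault(cls, set()).add(g)

    classes = sorted(counts)
    k_eff = len(gene_ids) if k is None else k
    conserved = {c: len(counts[c]) >= k_eff for c in classes}
    return AlignedIntronMatrix(gene_ids, classes, cells, conserved, k_eff)


# ---------------------------------------------------------------------------
# Dollo loss inference


@dataclass(frozen=True)
class LossEvent:
    """One inferred intron loss on a tree branch.

    ``clade`` is the set of leaf species below the branch; a single-species
    clade is a terminal-branch loss.
    """

    clade: frozenset[str]

    @property
    def branch(self) -> str:
        return "|".join(sorted(self.clade))

    @property
    def terminal(self) -> bool:
        return len(self.clade) == 1


def infer_intron_losses(
    presence: Mapping[str, bool], tree: SpeciesTree, *, gain: str = "root"
) -> list[LossEvent]:
    """Dollo-parsimony loss placement for one intron class.

    The intron is gained once and only lost thereafter.  With
    ``gain="root"`` (default) it is taken as ancestrally present at the
    tree root — the reading under which an intron missing only from two
    sister taxa was lost once on their common branch even when the supplied
    tree shows a single intron-bearing outgroup.  With ``gain="mrca"`` the
    gain sits at the most recent common ancestor of the intron-bearing
    leaves, and absences outside that clade need no event.  Losses are the
    maximal subtrees below the gain whose scored leaves all lack the
    intron; leaves absent from the profile constrain nothing.  Returns a
    deterministic, sorted list.
    """
    leaves = set(tree.leaf_names)
    unknown = set(presence) - leaves
    if unknown:
        raise ValidationError(f"profile references species absent from the tree: {sorted(unknown)}")
    present = {sp for sp, has in presence.items() if has}
    if not present:
        return []

    t = tree.tree
    if gain == "root":
        gain_node = t.seed_node
    elif gain == "mrca":
        taxa = [t.taxon_namespace.get_taxon(sp) for sp in sorted(present)]
        gain_node = t.mrca(taxa=taxa) if len(taxa) > 1 else t.find_node_for_taxon(taxa[0])
    else:
        raise ValidationError(f"gain must be 'root' or 'mrca', got {gain!r}")

    losses: list[LossEvent] = []

    def walk(node) -> None:
        below = {lf.taxon.label for lf in node.leaf_iter()}
        scored = {sp for sp in below if sp in presence}
        if scored and not (scored & present):
            losses.append(LossEvent(frozenset(below)))
            return
        for child in node.child_nodes():
            walk(child)

    for child in gain_node.child_nodes():
        walk(child)
    return sorted(losses, key=lambda e: e.branch)


def losses_for_matrix(
    matrix: AlignedIntronMatrix,
    tree: SpeciesTree,
    species_of_gene: Mapping[str, str] | None = None,
) -> dict[tuple[int, int], list[LossEvent]]:
    """Dollo losses for every class in the matrix.

    ``species_of_gene`` maps matrix rows to tree leaves (identity default).
    """
    out = {}
    for cls in matrix.classes:
        presence = {}
        for g in matrix.gene_ids:
            sp = species_of_gene.get(g, g) if species_of_gene else g
            presence[sp] = (g, cls) in matrix.cells
        out[cls] = infer_intron_losses(presence, tree)
    return out
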