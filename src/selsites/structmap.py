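"""Map selected protein sites onto PDB residue numbering and emit viewer
coloring scripts.

The chain sequence is taken from the coordinate (ATOM) records rather than
SEQRES, so every mapped site corresponds to a renderable residue; residues
missing from the coordinates simply cannot receive a color.  The reference
protein is globally aligned against the chain sequence (BLOSUM62, affine gaps,
open 11 / extend 1 by default) and each selected site inherits the author
residue number (plus insertion code) aligned opposite it.  Sites aligned to a
gap are reported unmapped.  Scripts are emitted for the Jmol and PyMOL
dialects using the merged-results color classes (red / green / blue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ChainSequence",
    "ResidueRef",
    "ResidueMap",
    "AlignmentParams",
    "read_chain",
    "map_sites_to_residues",
    "emit_viewer_script",
    "LowIdentityWarning",
]


class LowIdentityWarning(UserWarning):
    """Reference/chain alignment identity fell below the configured floor."""


@dataclass(frozen=True)
class ResidueRef:
    number: int
    icode: str = ""
    amino_acid: str = "X"

    def label(self) -> str:
        return f"{self.number}{self.icode}"


@dataclass
class ChainSequence:
    source: str
    chain_id: str
    residues: list[ResidueRef]

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    identity_floor: float = 0.30


@dataclass
class ResidueMap:
    """One-to-one, non-crossing correspondence between reference protein
    positions (1-based) and chain residues."""

    pairs: list[tuple[int, ResidueRef]]
    unmapped_reference: list[int]
    identity_fraction: float

    def residue_for_site(self, site: int) -> ResidueRef | None:
        for pos, res in self.pairs:
            if pos == site:
                return res
        return None


def _one_letter(residue_name: str) -> str:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None or not info.is_amino_acid():
        return "X"
    code = info.one_letter_code.upper()
    return code if code.isalpha() else "X"


def read_chain(path: str, chain_id: str) -> ChainSequence:
    """Observed sequence of one chain from a PDB file's coordinate records.

    Only the first model and the first alternate location are used; modified
    residues map to their parent one-letter code where tabulated (MSE -> M),
    otherwise 'X'.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if len(structure) == 0:
        raise ValueError(f"{path}: no models in structure")
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [ch.name for ch in model]
        raise KeyError(f"{path}: no chain {chain_id!r}; available chains: {available}")
    residues = []
    for res in chain:
        info = gemmi.find_tabulated_residue(res.name)
        if info is not None and info.is_water():
            continue
        residues.append(
            ResidueRef(
                number=res.seqid.num,
                icode=res.seqid.icode.strip(),
                amino_acid=_one_letter(res.name),
            )
        )
    if not residues:
        raise ValueError(f"{path}: chain {chain_id!r} has no residues in coordinates")
    return ChainSequence(source=str(path), chain_id=chain_id, residues=residues)


def map_sites_to_residues(
    protein: str,
    chain: ChainSequence,
    sites: list[int],
    params: AlignmentParams | None = None,
) -> tuple[ResidueMap, dict[int, ResidueRef | None]]:
    """Align the reference protein to the chain and map each site.

    Returns the full residue map plus a per-site lookup (None for sites the
    alignment leaves opposite a gap).  Emits :class:`LowIdentityWarning` when
    aligned identity drops below ``params.identity_floor``.
    """
    params = params or AlignmentParams()
    if not protein:
        raise ValueError("empty reference protein")
    if len(chain) == 0:
        raise ValueError("empty chain")
    for s in sites:
        if not 1 <= s <= len(protein):
            raise ValueError(f"site {s} outside reference protein 1..{len(protein)}")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    alignment = aligner.align(protein, chain.sequence)[0]

    ref_to_chain: dict[int, int] = {}
    identical = 0
    aligned_cols = 0
    for (r0, r1), (c0, c1) in zip(*alignment.aligned):
        for k in range(r1 - r0):
            ref_to_chain[r0 + k] = c0 + k
            aligned_cols += 1
            if protein[r0 + k] == chain.sequence[c0 + k]:
                identical += 1
    identity = identical / aligned_cols if aligned_cols else 0.0

    pairs = [
        (ref_idx + 1, chain.residues[chain_idx])
        for ref_idx, chain_idx in sorted(ref_to_chain.items())
    ]
    unmapped = [i + 1 for i in range(len(protein)) if i not in ref_to_chain]
    rmap = ResidueMap(pairs=pairs, unmapped_reference=unmapped, identity_fraction=identity)

    if identity < params.identity_floor:
        warnings.warn(
            f"reference/chain identity {identity:.2f} below floor "
            f"{params.identity_floor:.2f}; mapping may be unreliable",
            LowIdentityWarning,
            stacklevel=2,
        )

    by_site = {s: rmap.residue_for_site(s) for s in sites}
    return rmap, by_site


_COLOR_ORDER = ("red", "green", "blue")
_VALID_CLASSES = set(_COLOR_ORDER) | {"yellow", "orange", "magenta"}  # single-color schemes


def emit_viewer_script(
    residue_numbers_by_class: dict[str, list[int]],
    dialect: str,
    chain_id: str,
) -> str:
    """Deterministic Jmol (.spt) or PyMOL (.pml) coloring script.

    One select+color command per class, residues ascending; classes are
    emitted in the fixed order red, green, blue, then any single-color scheme
    colors alphabetically.
    """
    unknown = set(residue_numbers_by_class) - _VALID_CLASSES
    if unknown:
        raise ValueError(f"unknown color class(es): {sorted(unknown)}")

    ordered = [c for c in _COLOR_ORDER if c in residue_numbers_by_class]
    ordered += sorted(set(residue_numbers_by_class) - set(_COLOR_ORDER))

    if dialect == "pymol":
        lines = ["bg_color white", "hide everything", "show cartoon", "color gray80"]
        for color in ordered:
            resis = sorted(residue_numbers_by_class[color])
            if not resis:
                continue
            sel = "+".join(str(r) for r in resis)
            lines.append(f"select sel_{color}, chain {chain_id} and resi {sel}")
            lines.append(f"color {color}, sel_{color}")
            lines.append(f"show sticks, sel_{color}")
        lines.append("deselect")
        return "\n".join(lines) + "\n"
    if dialect == "jmol":
        lines = ["background white;", "select all;", "cartoons only;", "color gray;"]
        for color in ordered:
            resis = sorted(residue_numbers_by_class[color])
            if not resis:
                continue
            sel = ", ".join(f"{r}:{chain_id}" for r in resis)
            lines.append(f"select {sel};")
            lines.append(f"color {color};")
            lines.append("wireframe 0.3;")
        lines.append("select none;")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown script dialect {dialect!r}; use 'jmol' or 'pymol'")
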