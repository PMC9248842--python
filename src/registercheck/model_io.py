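"""Model coordinate I/O, chain extraction and test-window selection.

Protein chains are read with gemmi from PDB or mmCIF, keeping only the
first conformer of multi-conformer residues.  Chains are segmented into
continuous stretches — broken at residue-numbering gaps, intervening
non-standard residues and CA-CA distances above a configurable cutoff —
and each stretch is covered by overlapping fixed-length windows advanced
in steps of five residues, with one extra end-anchored window so chain
termini are always testable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .alphabet import STANDARD_RESIDUES, THREE_TO_ONE

logger = logging.getLogger(__name__)

#: Default CA-CA distance (Å) above which a chain is considered broken.
DEFAULT_MAX_CA_GAP = 4.5

#: Windows shorter than this are never scored.
MIN_WINDOW = 10


class EmptyModelError(ValueError):
    """The file contains no protein chains."""


class ModelParseError(ValueError):
    """The coordinate file could not be parsed."""


@dataclass(frozen=True)
class Residue:
    number: int
    insertion_code: str
    name: str                       # 3-letter code, upper case
    ca: np.ndarray | None           # CA position (Å) or None
    backbone: dict[str, np.ndarray]  # N/CA/C/O positions present in the model

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_RESIDUES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class ProteinChain:
    """One polymer chain: ordered residues plus bookkeeping.

    ``standard_fraction`` is the fraction of residues that are one of the
    20 standard amino-acid types; chains below the configured threshold are
    reported as skipped rather than silently dropped.
    """

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def standard_fraction(self) -> float:
        if not self.residues:
            return 0.0
        return sum(r.is_standard for r in self.residues) / len(self.residues)

    def sequence(self, start: int = 0, length: int | None = None) -> str:
        end = len(self.residues) if length is None else start + length
        return "".join(r.one_letter for r in self.residues[start:end])

    def residue_numbers(self, start: int, length: int) -> list[int]:
        return [r.number for r in self.residues[start:start + length]]


@dataclass(frozen=True)
class TestFragment:
    """A continuous chain window submitted to sequence assignment."""

    chain_id: str
    start_index: int
    length: int
    model_sequence: str
    residue_numbers: list[int]
    mean_local_resolution: float | None = None

    def __post_init__(self) -> None:
        if len(self.model_sequence) != self.length:
            raise ValueError("model_sequence length must equal fragment length")
        if len(self.residue_numbers) != self.length:
            raise ValueError("residue_numbers length must equal fragment length")


def _residue_from_gemmi(res: gemmi.Residue) -> Residue:
    backbone = {}
    ca = None
    seen: set[str] = set()
    for atom in res:
        if atom.name in seen:      # second conformer of the same atom
            continue
        seen.add(atom.name)
        if atom.name in ("N", "CA", "C", "O"):
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            backbone[atom.name] = pos
            if atom.name == "CA":
                ca = pos
    return Residue(
        number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        name=res.name.upper(),
        ca=ca,
        backbone=backbone,
    )


def load_model(path: str | Path, format: str | None = None) -> list[ProteinChain]:
    """Read protein chains from a PDB or mmCIF file.

    Only the first conformer of any multi-conformer residue is retained;
    waters and ligand-only chains are excluded.  Raises
    :class:`EmptyModelError` when no chain contains an amino-acid residue
    and :class:`ModelParseError` on unreadable input.
    """
    path = Path(path)
    if not path.exists():
        raise ModelParseError(f"model file not found: {path}")
    fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
    try:
        if format is None:
            structure = gemmi.read_structure(str(path))
        else:
            structure = gemmi.read_structure(str(path), format=fmt_map[format])
    except (RuntimeError, ValueError, KeyError) as exc:
        raise ModelParseError(f"cannot parse {path}: {exc}") from exc
    structure.setup_entities()
    structure.remove_ligands_and_waters()
    if len(structure) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = structure[0]
    chains: list[ProteinChain] = []
    for ch in model:
        residues = [_residue_from_gemmi(r) for r in ch.first_conformer()]
        # protein chain: at least one standard amino acid
        n_std = sum(r.is_standard for r in residues)
        if n_std == 0:
            continue
        chain = ProteinChain(chain_id=ch.name, residues=residues)
        logger.info("chain %s: %d residues, standard fraction %.3f",
                    ch.name, len(residues), chain.standard_fraction)
        chains.append(chain)
    if not chains:
        raise EmptyModelError(f"{path}: no protein chains")
    return chains


def write_model(chains: list[ProteinChain], path: str | Path) -> None:
    """Write chains back to a minimal PDB file (backbone atoms only).

    The round trip through :func:`load_model` preserves chain ids, residue
    numbering, residue names and backbone coordinates.
    """
    structure = gemmi.Structure()
    structure.name = "registercheck"
    model = gemmi.Model("1")
    for chain in chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for name, pos in res.backbone.items():
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element("C" if name.startswith("C") else name[0])
                atom.pos = gemmi.Position(*pos)
                atom.occ = 1.0
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def _consecutive(prev: Residue, curr: Residue) -> bool:
    """Numbering continuity; insertion codes extend a number, never break it."""
    if curr.number == prev.number + 1:
        return True
    if curr.number == prev.number and curr.insertion_code > prev.insertion_code:
        return True
    return False


def continuous_segments(chain: ProteinChain,
                        max_ca_gap: float = DEFAULT_MAX_CA_GAP) -> list[tuple[int, int]]:
    """Split a chain into continuous standard-residue stretches.

    A boundary is placed wherever residue numbering is non-consecutive,
    a non-standard residue intervenes, a CA atom is missing, or the CA-CA
    distance exceeds ``max_ca_gap``.  Returns ``(start_index, length)``
    pairs indexing into ``chain.residues``.
    """
    if not chain.residues:
        raise ValueError("empty chain")
    segments: list[tuple[int, int]] = []
    start: int | None = None
    prev: Residue | None = None
    for i, res in enumerate(chain.residues):
        usable = res.is_standard and res.ca is not None
        if not usable:
            if start is not None:
                segments.append((start, i - start))
                start = None
            prev = None
            continue
        if start is None:
            start = i
        elif prev is not None:
            broken = not _consecutive(prev, res)
            if not broken and prev.ca is not None:
                broken = float(np.linalg.norm(res.ca - prev.ca)) > max_ca_gap
            if broken:
                segments.append((start, i - start))
                start = i
        prev = res
    if start is not None:
        segments.append((start, len(chain.residues) - start))
    return segments


def select_windows(chain: ProteinChain, segment: tuple[int, int],
                   window: int = 20, step: int = 5) -> list[TestFragment]:
    """Cover a segment with overlapping fixed-length windows.

    Windows start at segment offsets 0, step, 2*step, ...; a final window
    anchored at the segment end is appended whenever the last regular
    window stops short, so every residue of the segment is covered.
    Segments shorter than ``window`` but at least :data:`MIN_WINDOW` long
    yield one full-segment window; shorter segments yield none.
    """
    if window < MIN_WINDOW:
        raise ValueError(f"window must be >= {MIN_WINDOW}")
    if step < 1:
        raise ValueError("step must be >= 1")
    seg_start, seg_len = segment
    starts: list[int] = []
    if seg_len < MIN_WINDOW:
        return []
    if seg_len <= window:
        starts = [0]
        window = seg_len
    else:
        starts = list(range(0, seg_len - window + 1, step))
        if starts[-1] + window < seg_len:
            starts.append(seg_len - window)
    frags = []
    for off in starts:
        begin = seg_start + off
        frags.append(TestFragment(
            chain_id=chain.chain_id,
            start_index=begin,
            length=window,
            model_sequence=chain.sequence(begin, window),
            residue_numbers=chain.residue_numbers(begin, window),
        ))
    return frags
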