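"""Synthetic fixtures: sequences, noisy profiles, shifted models, maps.

Everything the validation pipeline consumes can be generated here without
external data: reference sequences, per-residue type-probability profiles
whose quality is set either directly (expected probability mass on the
true type) or through a pseudo-local-resolution parameter, model stretches
carrying an injected register shift of chosen offset and span, independent
per-atom coordinate jitter at a target r.m.s.d., and small Gaussian-atom
density maps for exercising the baseline scorer end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_ORDER, N_TYPES, ONE_TO_THREE, seq_to_indices
from .geometry import BackboneResidue, build_backbone, sidechain_atoms, BACKBONE_WEIGHTS
from .map_ops import MapVolume, truncate_resolution
from .model_io import ProteinChain, Residue
from .scoring import ResidueTypeProfile

#: typical amino-acid background; mildly non-uniform like real proteomes
DEFAULT_COMPOSITION = np.full(N_TYPES, 1.0 / N_TYPES)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic chain.

    ``top1_accuracy`` is the expected probability mass the generated
    profiles place on the true residue type; ``pseudo_resolution`` (Å), if
    given, overrides it through a fixed logistic curve (0.9 at 2.5 Å
    falling to 0.1 at 8 Å), emulating how classifier confidence degrades
    with local resolution.  ``shift_offset``/``shift_span`` inject a
    register error; ``jitter_rmsd`` perturbs coordinates.
    """

    seed: int = 0
    chain_length: int = 200
    alphabet_composition: np.ndarray = field(
        default_factory=lambda: DEFAULT_COMPOSITION.copy())
    top1_accuracy: float = 0.6
    pseudo_resolution: float | None = None
    shift_offset: int = 0
    shift_span: tuple[int, int] | None = None
    jitter_rmsd: float = 0.0

    def __post_init__(self) -> None:
        if self.pseudo_resolution is not None:
            self.top1_accuracy = accuracy_from_resolution(self.pseudo_resolution)
        if not 0.05 < self.top1_accuracy <= 1.0:
            raise ValueError("top1_accuracy must be in (0.05, 1]")
        if self.shift_span is not None:
            s, e = self.shift_span
            if not (0 <= s < e <= self.chain_length):
                raise ValueError("shift span outside chain")
            if not (0 <= s + self.shift_offset and e + self.shift_offset <= self.chain_length):
                raise ValueError("shifted span outside reference")


def accuracy_from_resolution(d: float) -> float:
    """Fixed logistic mapping pseudo-resolution (Å) to profile accuracy.

    Anchored at 0.9 for 2.5 Å and 0.1 for 8 Å; floors at 0.051 so profiles
    always carry at least chance-level mass on the truth.
    """
    lo, hi, d0, k = 0.05, 0.95, 5.25, 1.0303
    acc = lo + (hi - lo) / (1.0 + math.exp(k * (d - d0)))
    return max(0.051, min(1.0, acc))


def random_sequence(rng: np.random.Generator, length: int,
                    composition: np.ndarray | None = None) -> str:
    comp = DEFAULT_COMPOSITION if composition is None else composition
    comp = np.asarray(comp, dtype=float)
    comp = comp / comp.sum()
    idx = rng.choice(N_TYPES, size=length, p=comp)
    return "".join(AA_ORDER[i] for i in idx)


def inject_register_shift(model_sequence: str, reference: str, offset: int,
                          span: tuple[int, int]) -> str:
    """Replace span letters by reference letters ``offset`` positions away.

    Emulates a register error: within ``span`` the returned sequence reads
    ``reference[i + offset]`` instead of the model letter at ``i``.
    """
    s, e = span
    if not (0 <= s <= e <= len(model_sequence)):
        raise ValueError(f"span {span} outside sequence of length {len(model_sequence)}")
    if s + offset < 0 or e + offset > len(reference):
        raise ValueError(f"span {span} shifted by {offset} exceeds the reference")
    out = list(model_sequence)
    out[s:e] = reference[s + offset:e + offset]
    return "".join(out)


def generate_profiles(spec: SyntheticSpec,
                      true_sequence: str | None = None,
                      reference: str | None = None,
                      ) -> tuple[str, str, ResidueTypeProfile]:
    """Generate (reference, density_sequence, profile) for a synthetic chain.

    The reference sequence is what the chain *should* read.  The density
    sequence is what the map actually shows at each model position: equal
    to the reference except inside an injected register-shift span, where
    it reads the reference ``shift_offset`` positions away.  Profiles are
    drawn per residue: the density-sequence type receives probability mass
    with expectation ``top1_accuracy`` (Beta-jittered), the remaining mass
    is Dirichlet-distributed over the other 19 types.  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if reference is None:
        reference = random_sequence(rng, spec.chain_length, spec.alphabet_composition)
    if true_sequence is None:
        true_sequence = reference
        if spec.shift_span is not None and spec.shift_offset != 0:
            true_sequence = inject_register_shift(
                reference, reference, spec.shift_offset, spec.shift_span)
    profile = profile_from_sequence(true_sequence, spec.top1_accuracy, rng)
    return reference, true_sequence, profile


def profile_from_sequence(sequence: str, top1_accuracy: float,
                          rng: np.random.Generator,
                          concentration: float = 1.0,
                          beta_strength: float = 30.0) -> ResidueTypeProfile:
    """Noisy profile rows around a known sequence.

    Each row gives the true type a probability drawn from a Beta
    distribution with mean ``top1_accuracy`` (one-hot in the limit 1.0)
    and spreads the rest over the other types with a symmetric Dirichlet.
    """
    idx = seq_to_indices(sequence)
    L = len(idx)
    if top1_accuracy >= 1.0:
        rows = np.zeros((L, N_TYPES))
        rows[np.arange(L), idx] = 1.0
        return ResidueTypeProfile(rows, source="synthetic")
    a = top1_accuracy * beta_strength
    b = (1.0 - top1_accuracy) * beta_strength
    p_true = rng.beta(a, b, size=L)
    rest = rng.dirichlet(np.full(N_TYPES - 1, concentration), size=L)
    rest *= (1.0 - p_true)[:, None]
    rows = np.empty((L, N_TYPES))
    for i in range(L):
        others = np.delete(np.arange(N_TYPES), idx[i])
        rows[i, idx[i]] = p_true[i]
        rows[i, others] = rest[i]
    return ResidueTypeProfile(rows, source="synthetic")


def jitter_coordinates(atoms: np.ndarray, rmsd: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """Independent isotropic Gaussian displacement per atom.

    Displacements are rescaled so the realized all-atom r.m.s.d. equals
    the target exactly; stereochemistry is deliberately ignored.
    """
    atoms = np.asarray(atoms, dtype=np.float64)
    if rmsd < 0:
        raise ValueError("rmsd must be >= 0")
    if rmsd == 0 or len(atoms) == 0:
        return atoms.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    disp = rng.standard_normal(atoms.shape)
    realized = math.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    return atoms + disp * (rmsd / realized)


# ---------------------------------------------------------------------------
# synthetic models and maps

@dataclass
class SyntheticModel:
    """An idealized chain with backbone and side-chain atoms."""

    sequence: str              # letters the density shows (may carry a shift)
    backbone: list[BackboneResidue]
    chain_id: str = "A"

    def backbone_dicts(self) -> list[dict[str, np.ndarray]]:
        return [{"N": r.n, "CA": r.ca, "C": r.c, "O": r.o} for r in self.backbone]

    def all_atoms(self) -> tuple[np.ndarray, np.ndarray]:
        """All atom positions and Gaussian weights (backbone + side chains)."""
        pos, wts = [], []
        for aa, res in zip(self.sequence, self.backbone):
            for name, p in (("N", res.n), ("CA", res.ca), ("C", res.c), ("O", res.o)):
                pos.append(p)
                wts.append(BACKBONE_WEIGHTS[name])
            sc_pos, sc_w = sidechain_atoms(aa, res.n, res.ca, res.c)
            pos.extend(sc_pos)
            wts.extend(sc_w)
        return np.array(pos), np.array(wts)

    def to_chain(self, first_number: int = 1,
                 model_sequence: str | None = None) -> ProteinChain:
        """As a :class:`ProteinChain`; ``model_sequence`` sets the recorded
        residue names (defaults to the density sequence)."""
        seq = model_sequence or self.sequence
        residues = []
        for i, (aa, res) in enumerate(zip(seq, self.backbone)):
            residues.append(Residue(
                number=first_number + i, insertion_code="",
                name=ONE_TO_THREE[aa], ca=res.ca,
                backbone={"N": res.n, "CA": res.ca, "C": res.c, "O": res.o}))
        return ProteinChain(chain_id=self.chain_id, residues=residues)

    def jittered(self, rmsd: float,
                 seed: int | np.random.Generator = 0) -> "SyntheticModel":
        """Copy with independent per-atom backbone jitter at the target r.m.s.d."""
        flat = np.array([[getattr(r, k) for k in ("n", "ca", "c", "o")]
                         for r in self.backbone]).reshape(-1, 3)
        moved = jitter_coordinates(flat, rmsd, seed).reshape(-1, 4, 3)
        bb = [BackboneResidue(n=m[0], ca=m[1], c=m[2], o=m[3]) for m in moved]
        return SyntheticModel(self.sequence, bb, self.chain_id)


def build_helix_model(sequence: str, chain_id: str = "A") -> SyntheticModel:
    """Ideal alpha-helical model carrying ``sequence``."""
    return SyntheticModel(sequence, build_backbone(len(sequence)), chain_id)


def synthesize_map(model: SyntheticModel, resolution: float = 2.5,
                   voxel: float = 1.0, pad: float = 6.0) -> MapVolume:
    """Gaussian-atom density on a regular grid, band-limited to ``resolution``.

    The box encloses all atoms with ``pad`` Å margin; atoms are shifted so
    the box corner is the coordinate origin (the returned map's frame).
    Raises ``ValueError`` for an empty model.
    """
    pos, wts = model.all_atoms()
    if len(pos) == 0:
        raise ValueError("cannot synthesize a map for an empty model")
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    origin = [int(math.floor(l / voxel)) for l in lo]
    dims = [max(8, int(math.ceil(h / voxel)) - o) for h, o in zip(hi, origin)]
    grid = np.zeros(dims, dtype=np.float64)
    sigma = 0.25 * resolution
    reach = 4.0 * sigma
    axes = [(o + np.arange(n)) * voxel for o, n in zip(origin, dims)]
    for p, w in zip(pos, wts):
        sl = []
        ok = True
        for ax, x in zip(axes, p):
            i0 = np.searchsorted(ax, x - reach)
            i1 = np.searchsorted(ax, x + reach)
            if i0 >= i1:
                ok = False
                break
            sl.append((i0, i1))
        if not ok:
            continue
        dx = axes[0][sl[0][0]:sl[0][1]] - p[0]
        dy = axes[1][sl[1][0]:sl[1][1]] - p[1]
        dz = axes[2][sl[2][0]:sl[2][1]] - p[2]
        d2 = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2)
        grid[sl[0][0]:sl[0][1], sl[1][0]:sl[1][1], sl[2][0]:sl[2][1]] += (
            w * np.exp(-d2 / (2.0 * sigma * sigma)))
    cell = tuple(n * voxel for n in dims) + (90.0, 90.0, 90.0)
    volume = MapVolume(grid=grid, cell=cell, origin=tuple(origin))
    return truncate_resolution(volume, resolution)


def shift_model_atoms(model: SyntheticModel, shift: np.ndarray) -> SyntheticModel:
    """Translate all atoms rigidly (used to move models into a map's frame)."""
    bb = [BackboneResidue(n=r.n + shift, ca=r.ca + shift, c=r.c + shift,
                          o=r.o + shift) for r in model.backbone]
    return SyntheticModel(model.sequence, bb, model.chain_id)


def write_fixture(directory: str | Path, spec: SyntheticSpec,
                  with_map: bool = False) -> dict[str, Path]:
    """Write a complete fixture: FASTA, profile TSV, PDB and optionally MRC.

    Returns the paths keyed by kind.  The model records the *reference*
    letters while profiles/map follow the density sequence, so a non-zero
    ``shift_offset`` produces a model with a genuine register error.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .map_ops import write_map
    from .model_io import write_model
    from .scoring import write_profile_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reference, density_seq, profile = generate_profiles(spec)
    paths = {}

    paths["fasta"] = directory / "reference.fasta"
    SeqIO.write([SeqRecord(Seq(reference), id="ref_1", description="synthetic reference")],
                str(paths["fasta"]), "fasta")

    paths["profiles"] = directory / "profiles.tsv"
    write_profile_table(paths["profiles"], {"A": (list(range(1, spec.chain_length + 1)), profile)})

    model = build_helix_model(density_seq)
    if spec.jitter_rmsd > 0:
        model = model.jittered(spec.jitter_rmsd, np.random.default_rng(spec.seed + 1))
    paths["pdb"] = directory / "model.pdb"
    write_model([model.to_chain(model_sequence=reference)], paths["pdb"])

    if with_map:
        volume = synthesize_map(model)
        paths["mrc"] = directory / "map.mrc"
        write_map(volume, paths["mrc"])
    return paths
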