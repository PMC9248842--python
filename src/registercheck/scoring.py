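"""Per-residue amino-acid-type probability profiles and scorer plug-ins.

A *scorer* estimates, for every residue of a backbone fragment, a probability
distribution over the 20 standard amino-acid types using only the backbone
coordinates and the density map — never the residue identities recorded in
the model.  The rest of the pipeline is agnostic to where profiles come
from; anything satisfying the :class:`Scorer` contract (the shipped
density-correlation baseline, a table of precomputed rows, or the synthetic
generator) can drive a validation run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .alphabet import AA_ORDER, AA_TO_INDEX, N_TYPES

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ResidueTypeProfile:
    """Per-residue probabilities over the 20 standard amino-acid types.

    ``probabilities`` has one row per residue of a continuous backbone
    stretch; columns follow :data:`registercheck.alphabet.AA_ORDER`.
    Rows sum to one.
    """

    probabilities: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 2 or p.shape[1] != N_TYPES:
            raise ValueError(f"profile must be (length, {N_TYPES}), got {p.shape}")
        if np.any(p < -_ROW_SUM_TOL) or np.any(p > 1 + _ROW_SUM_TOL):
            raise ValueError("profile entries must lie in [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("profile rows must sum to 1")
        object.__setattr__(self, "probabilities", p)

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    def log_probabilities(self, floor: float = 1e-10) -> np.ndarray:
        """Row-wise log probabilities with a floor guarding log(0)."""
        return np.log(np.clip(self.probabilities, floor, 1.0))

    def slice(self, start: int, length: int) -> "ResidueTypeProfile":
        """Sub-profile covering rows ``start:start+length``."""
        if start < 0 or start + length > self.length:
            raise IndexError("profile slice out of range")
        return ResidueTypeProfile(self.probabilities[start:start + length], self.source)

    def permute_columns(self, order: "np.ndarray") -> "ResidueTypeProfile":
        return ResidueTypeProfile(self.probabilities[:, order], self.source)


def uniform_profile(length: int, source: str = "uniform") -> ResidueTypeProfile:
    """Maximum-entropy profile: every type equally likely at every position."""
    return ResidueTypeProfile(np.full((length, N_TYPES), 1.0 / N_TYPES), source)


#: A scorer maps (fragment residue CA/backbone coordinates, map) to a profile.
#: Concrete signature is defined by the call sites in :mod:`registercheck.validator`;
#: the baseline lives in :mod:`registercheck.density_scorer`.
Scorer = Callable[..., ResidueTypeProfile]


def read_profile_table(path: str | Path) -> dict[str, tuple[list[int], ResidueTypeProfile]]:
    """Read precomputed profiles from a tab-separated table.

    Expected columns: ``chain``, ``resnum``, then the 20 probabilities in
    :data:`AA_ORDER` order (a header line starting with ``chain`` is
    accepted and ignored).  Returns, per chain, the residue numbers and the
    profile in file order.

    This is the bridge for running the statistical pipeline with profiles
    produced by any upstream residue-type classifier, without a map.
    """
    chains: dict[str, list[tuple[int, np.ndarray]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "chain":
                continue
            if len(parts) != 2 + N_TYPES:
                raise ValueError(
                    f"{path}:{lineno}: expected {2 + N_TYPES} columns, got {len(parts)}")
            chain, resnum = parts[0], int(parts[1])
            row = np.array([float(x) for x in parts[2:]])
            chains.setdefault(chain, []).append((resnum, row))
    out = {}
    for chain, rows in chains.items():
        numbers = [n for n, _ in rows]
        mat = np.vstack([r for _, r in rows])
        mat = mat / mat.sum(axis=1, keepdims=True)
        out[chain] = (numbers, ResidueTypeProfile(mat, source="external-profile"))
    return out


def write_profile_table(path: str | Path,
                        chains: Mapping[str, tuple[list[int], ResidueTypeProfile]]) -> None:
    """Inverse of :func:`read_profile_table`."""
    with open(path, "w") as fh:
        fh.write("chain\tresnum\t" + "\t".join(AA_ORDER) + "\n")
        for chain, (numbers, profile) in chains.items():
            for num, row in zip(numbers, profile.probabilities):
                vals = "\t".join(f"{v:.6g}" for v in row)
                fh.write(f"{chain}\t{num}\t{vals}\n")
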