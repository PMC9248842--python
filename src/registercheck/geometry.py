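"""Idealized peptide geometry: backbone frames and side-chain templates.

The baseline residue-type scorer needs, for each of the 20 amino-acid
types, an idealized side chain it can place on a backbone frame (N, CA, C)
to synthesize template density.  Templates are built once from internal
coordinates: the CB is placed with tetrahedral geometry, chain atoms
extend from it in a trans zig-zag approximating the most common rotamer,
branches fork sideways and aromatic rings are laid out as planar polygons.
Atom weights are electron counts, so sulfur-bearing and aromatic types are
heavier and bulkier than small ones — which is exactly the contrast a
density-correlation ranking exploits.

The same tables drive the synthetic map renderer, keeping template and
ground-truth density mutually consistent in end-to-end tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alphabet import AA_ORDER

# electron counts used as Gaussian-atom weights
_W = {"C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0}

_CB_BOND = 1.53
_CC_BOND = 1.52
_TET = math.radians(110.5)


class DegenerateFrameError(ValueError):
    """N, CA and C are (nearly) collinear; no side-chain frame exists."""


def backbone_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (3x3, rows f1,f2,f3) anchored at CA.

    f1 points away from the N-CA-C bisector (the side-chain hemisphere),
    f2 is the plane normal, f3 completes the triad.  Raises
    :class:`DegenerateFrameError` for collinear backbone atoms.
    """
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-6 or nv < 1e-6:
        raise DegenerateFrameError("zero-length backbone bond")
    u, v = u / nu, v / nv
    normal = np.cross(u, v)
    nn = np.linalg.norm(normal)
    if nn < 1e-3:
        raise DegenerateFrameError("collinear N-CA-C")
    f2 = normal / nn
    bis = u + v
    f1 = -bis / np.linalg.norm(bis)
    f3 = np.cross(f1, f2)
    return np.vstack([f1, f2, f3])


def _cb_local() -> np.ndarray:
    """CB position in the (f1, f2, f3) frame (Å from CA)."""
    # angle between CA->CB and the anti-bisector chosen so N-CA-CB = 110.5 deg
    half = math.radians(111.0) / 2.0
    cos_beta = -math.cos(_TET) / math.cos(half)
    beta = math.acos(min(1.0, cos_beta))
    return _CB_BOND * np.array([math.cos(beta), math.sin(beta), 0.0])


def _chain(n_atoms: int, elements: str) -> list[tuple[np.ndarray, float]]:
    """A trans zig-zag of ``n_atoms`` atoms extending beyond CB."""
    cb = _cb_local()
    d = cb / np.linalg.norm(cb)
    perp = np.array([d[1], -d[0], 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.array([0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)
    atoms = []
    pos = cb.copy()
    for i in range(n_atoms):
        pos = pos + 1.27 * d + (0.62 if i % 2 == 0 else -0.62) * perp
        atoms.append((pos.copy(), _W[elements[i]]))
    return atoms


def _branch(base: np.ndarray, elements: str, spread: float = 1.1) -> list[tuple[np.ndarray, float]]:
    """Two atoms forking sideways (out of the zig-zag plane) from ``base``."""
    cb = _cb_local()
    d = cb / np.linalg.norm(cb)
    out = np.array([0.0, 0.0, 1.0])
    a = base + 0.9 * d + spread * out
    b = base + 0.9 * d - spread * out
    return [(a, _W[elements[0]]), (b, _W[elements[1]])]


def _ring(center_dist: float, radius: float, n: int,
          elements: str) -> list[tuple[np.ndarray, float]]:
    """Planar ``n``-gon perpendicular-ish to the frame, beyond the CB."""
    cb = _cb_local()
    d = cb / np.linalg.norm(cb)
    out = np.array([0.0, 0.0, 1.0])
    center = cb + center_dist * d
    atoms = []
    for i in range(n):
        ang = 2 * math.pi * i / n
        pos = center + radius * (math.cos(ang) * d + math.sin(ang) * out)
        atoms.append((pos, _W[elements[i]]))
    return atoms


def _build_templates() -> dict[str, list[tuple[np.ndarray, float]]]:
    cb = (_cb_local(), _W["C"])
    t: dict[str, list[tuple[np.ndarray, float]]] = {}
    t["G"] = []
    t["A"] = [cb]
    t["S"] = [cb] + _chain(1, "O")
    t["C"] = [cb] + _chain(1, "S")
    t["T"] = [cb] + _branch(_cb_local(), "OC")
    t["V"] = [cb] + _branch(_cb_local(), "CC")
    t["P"] = [cb] + _chain(2, "CC")
    t["D"] = [cb] + _chain(1, "C") + _branch(_chain(1, "C")[0][0], "OO")
    t["N"] = [cb] + _chain(1, "C") + _branch(_chain(1, "C")[0][0], "ON")
    t["L"] = [cb] + _chain(1, "C") + _branch(_chain(1, "C")[0][0], "CC")
    t["I"] = [cb] + _branch(_cb_local(), "CC") + _chain(2, "CC")[1:]
    t["E"] = [cb] + _chain(2, "CC") + _branch(_chain(2, "CC")[1][0], "OO")
    t["Q"] = [cb] + _chain(2, "CC") + _branch(_chain(2, "CC")[1][0], "ON")
    t["M"] = [cb] + _chain(3, "CSC")
    t["K"] = [cb] + _chain(4, "CCCN")
    t["R"] = [cb] + _chain(3, "CCN") + _branch(_chain(3, "CCN")[2][0], "NN")
    t["H"] = [cb] + _ring(1.9, 1.15, 5, "CNCNC")
    t["F"] = [cb] + _ring(2.1, 1.39, 6, "CCCCCC")
    t["Y"] = [cb] + _ring(2.1, 1.39, 6, "CCCCCC") + _chain(4, "CCCO")[3:]
    t["W"] = ([cb] + _ring(1.8, 1.1, 5, "CCNCC")
              + _ring(3.4, 1.39, 6, "CCCCCC"))
    assert set(t) == set(AA_ORDER)
    return t


#: type -> list of (local position in the CA frame, electron weight)
SIDECHAIN_TEMPLATES: dict[str, list[tuple[np.ndarray, float]]] = _build_templates()

#: electron weights for backbone atoms included in every template
BACKBONE_WEIGHTS = {"N": _W["N"], "CA": _W["C"], "C": _W["C"], "O": _W["O"]}


def sidechain_atoms(aa: str, n: np.ndarray, ca: np.ndarray,
                    c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Idealized side-chain atoms for type ``aa`` on the given backbone.

    Returns ``(positions (k,3), weights (k,))``; glycine yields empty arrays.
    """
    template = SIDECHAIN_TEMPLATES[aa]
    if not template:
        return np.empty((0, 3)), np.empty(0)
    frame = backbone_frame(n, ca, c)
    local = np.vstack([p for p, _ in template])
    weights = np.array([w for _, w in template])
    return ca + local @ frame, weights


# ---------------------------------------------------------------------------
# backbone construction from internal coordinates (NeRF)

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position of atom D given A-B-C, |CD|, angle BCD and dihedral ABCD (radians)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class BackboneResidue:
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray


def build_backbone(length: int, phi: float = -57.0, psi: float = -47.0,
                   omega: float = 180.0) -> list[BackboneResidue]:
    """Ideal polypeptide backbone with the given dihedrals (degrees).

    Defaults build an alpha-helix; (-120, 120) gives an extended strand.
    """
    phi_r, psi_r, omega_r = (math.radians(x) for x in (phi, psi, omega))
    ang_nca_c = math.radians(111.0)
    ang_cac_n = math.radians(116.2)
    ang_cn_ca = math.radians(121.7)
    b_n_ca, b_ca_c, b_c_n = 1.458, 1.525, 1.329

    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([b_n_ca, 0.0, 0.0])
    c0 = place_atom(np.array([-1.0, 1.0, 0.0]), n0, ca0, b_ca_c, ang_nca_c, phi_r)
    residues = [[n0, ca0, c0]]
    for _ in range(1, length):
        n_prev, ca_prev, c_prev = residues[-1]
        n_i = place_atom(n_prev, ca_prev, c_prev, b_c_n, ang_cac_n, psi_r)
        ca_i = place_atom(ca_prev, c_prev, n_i, b_n_ca, ang_cn_ca, omega_r)
        c_i = place_atom(c_prev, n_i, ca_i, b_ca_c, ang_nca_c, phi_r)
        residues.append([n_i, ca_i, c_i])
    out = []
    for i, (n_i, ca_i, c_i) in enumerate(residues):
        if i + 1 < length:
            next_n = residues[i + 1][0]
            direction = c_i - 0.5 * (ca_i + next_n)
        else:
            direction = c_i - ca_i
        o_i = c_i + 1.23 * direction / np.linalg.norm(direction)
        out.append(BackboneResidue(n=n_i, ca=ca_i, c=c_i, o=o_i))
    return out
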