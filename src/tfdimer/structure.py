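"""Coordinate handling for monomer and dimer models.

The central container is :class:`Structure`, a thin column-oriented wrapper
around numpy arrays (chain id, residue number, residue name, atom name,
Cartesian coordinates in Å).  PDB reading and writing is delegated to
``biotite``; everything else (Kabsch superposition, domain-rotation
measurement, amide-proton construction) operates directly on the arrays.

Residue numbering follows full-length author numbering (1-based, inclusive
ranges).  Dimer models carry exactly two chains, "A" and "B", with protomer A
the reference for the two-fold symmetry.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation


class StructureError(ValueError):
    """Malformed coordinates, empty selections, or degenerate geometry."""


@dataclass
class Transform:
    """Proper rigid-body transform: y = rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise StructureError("transform must be a 3x3 rotation and 3-vector")
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise StructureError(f"rotation determinant {det} != +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Transform(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation angle from the matrix trace, reported in [0, 180] degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class Structure:
    """Atoms with chain/residue/atom identity and 3-D coordinates (Å)."""

    chain: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    atom: np.ndarray
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.chain = np.asarray(self.chain, dtype="U4")
        self.resid = np.asarray(self.resid, dtype=int)
        self.resname = np.asarray(self.resname, dtype="U4")
        self.atom = np.asarray(self.atom, dtype="U4")
        self.coord = np.asarray(self.coord, dtype=float).reshape(-1, 3)
        n = len(self.coord)
        if not all(len(a) == n for a in (self.chain, self.resid, self.resname, self.atom)):
            raise StructureError("field lengths disagree")
        if not np.all(np.isfinite(self.coord)):
            raise StructureError("non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(str(c))
        return list(seen)

    def mask(self, chain=None, resid=None, atom=None) -> np.ndarray:
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resid is not None:
            resid = np.atleast_1d(resid)
            m &= np.isin(self.resid, resid)
        if atom is not None:
            m &= self.atom == atom
        return m

    def select(self, chain=None, resid=None, atom=None) -> "Structure":
        m = self.mask(chain=chain, resid=resid, atom=atom)
        if not m.any():
            raise StructureError(
                f"empty selection (chain={chain}, resid={resid}, atom={atom})")
        return Structure(self.chain[m], self.resid[m], self.resname[m],
                         self.atom[m], self.coord[m])

    def coords_of(self, chain, resid, atom) -> np.ndarray:
        """Single-atom coordinate lookup."""
        m = self.mask(chain=chain, resid=int(resid), atom=atom)
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            raise StructureError(f"atom not found: {chain}/{resid}/{atom}")
        return self.coord[idx[0]]

    def transformed(self, t: Transform) -> "Structure":
        return Structure(self.chain, self.resid, self.resname, self.atom,
                         t.apply(self.coord))

    def with_chain(self, chain_id: str) -> "Structure":
        return Structure(np.full(len(self), chain_id, dtype="U4"), self.resid,
                         self.resname, self.atom, self.coord)

    def copy(self) -> "Structure":
        return Structure(self.chain.copy(), self.resid.copy(), self.resname.copy(),
                         self.atom.copy(), self.coord.copy())

    def validate_dimer(self) -> None:
        """A dimer has exactly two chains with identical residue composition."""
        ch = self.chains
        if len(ch) != 2:
            raise StructureError(f"expected 2 chains, found {ch}")
        a, b = (self.select(chain=c) for c in ch)
        key_a = sorted(zip(a.resid.tolist(), a.atom.tolist()))
        key_b = sorted(zip(b.resid.tolist(), b.atom.tolist()))
        if key_a != key_b:
            raise StructureError("chains differ in residue/atom composition")


@dataclass
class DomainMap:
    """Named residue ranges (inclusive, author numbering) plus flexible linkers."""

    domains: dict[str, list[tuple[int, int]]]
    linkers: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, ranges in self.domains.items():
            for lo, hi in ranges:
                if hi < lo:
                    raise StructureError(f"empty range {lo}-{hi} in domain {name}")

    def residues(self, name: str) -> np.ndarray:
        out: list[int] = []
        for lo, hi in self.domains[name]:
            out.extend(range(lo, hi + 1))
        return np.array(out, dtype=int)

    def to_json(self) -> str:
        import json
        return json.dumps({"domains": self.domains, "linkers": self.linkers},
                          indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DomainMap":
        import json
        raw = json.loads(text)
        return cls(domains={k: [tuple(r) for r in v]
                            for k, v in raw["domains"].items()},
                   linkers=[tuple(r) for r in raw.get("linkers", [])])

    def linker_residues(self) -> set[int]:
        out: set[int] = set()
        for lo, hi in self.linkers:
            out.update(range(lo, hi + 1))
        return out

    def in_linker(self, resid: int) -> bool:
        return any(lo <= resid <= hi for lo, hi in self.linkers)


def trigger_factor_domain_map() -> DomainMap:
    """Domain architecture of full-length E. coli Trigger Factor (432 aa).

    RBD 1-113, SBD 114-148 + 247-432, PPD 149-249, with the helical arms
    (Arm1 302-360, Arm2 361-412) and the ribosome-binding signature motif
    43-50 as sub-ranges; inter-domain linkers 112-115, 149-155, 241-261 are
    treated as flexible.
    """
    return DomainMap(
        domains={
            "RBD": [(1, 113)],
            "SBD": [(114, 148), (247, 432)],
            "PPD": [(149, 249)],
            "Arm1": [(302, 360)],
            "Arm2": [(361, 412)],
            "signature": [(43, 50)],
        },
        linkers=[(112, 115), (149, 155), (241, 261)],
    )


# ---------------------------------------------------------------------------
# PDB I/O (delegated to biotite)

def read_structure(pdb_text: str, model: int | None = None) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Keeps the first altloc; keeps the first model unless ``model`` is given.
    """
    try:
        pf = pdbio.PDBFile.read(io.StringIO(pdb_text))
        arr = pf.get_structure(model=model if model is not None else 1,
                               altloc="first")
    except Exception as exc:  # biotite raises several parse error types
        raise StructureError(f"PDB parse error: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError("no atoms in PDB input")
    return Structure(arr.chain_id, arr.res_id, arr.res_name, arr.atom_name,
                     arr.coord)


def write_structure(s: Structure | list[Structure]) -> str:
    """Render one Structure (or a multi-model list) as PDB text."""
    models = s if isinstance(s, list) else [s]
    pf = pdbio.PDBFile()
    arrays = []
    for m in models:
        arr = struc.AtomArray(len(m))
        arr.chain_id = m.chain
        arr.res_id = m.resid
        arr.res_name = m.resname
        arr.atom_name = m.atom
        arr.coord = m.coord
        arr.element = np.array([a[0] for a in m.atom], dtype="U2")
        arrays.append(arr)
    if len(arrays) == 1:
        pf.set_structure(arrays[0])
    else:
        pf.set_structure(struc.stack(arrays))
    out = io.StringIO()
    pf.write(out)
    return out.getvalue()


# ---------------------------------------------------------------------------
# Superposition and rotation measurement

def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Transform, float]:
    """Least-squares (Kabsch) superposition of paired coordinate sets.

    Returns the rigid transform carrying ``mobile`` onto ``reference`` and the
    RMSD after applying it.  Requires n >= 3 non-collinear points.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise StructureError("paired coordinate sets must have equal shape")
    if len(mob) < 3:
        raise StructureError("superposition needs at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = ref - cr, mob - cm
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) geometry")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = cr - R @ cm
    tr = Transform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((tr.apply(mob) - ref) ** 2, axis=1))))
    return tr, rmsd


def domain_rotation(model: Structure, reference: Structure,
                    align_range: tuple[int, int],
                    measure_range: tuple[int, int],
                    chain_model: str | None = None,
                    chain_reference: str | None = None) -> tuple[float, float]:
    """Rotation (deg) and displacement (Å) of one domain between two models.

    The two structures are first superposed on the CA atoms of
    ``align_range``; the rotation of the ``measure_range`` CA set of the
    aligned reference onto the model then gives the angle (via the matrix
    trace), and the distance between the measure-range CA centroids after the
    first superposition gives the displacement.
    """
    def ca(s: Structure, rng: tuple[int, int], chain) -> np.ndarray:
        resids = np.arange(rng[0], rng[1] + 1)
        sel_chain = chain if chain is not None else s.chains[0]
        sub = s.select(chain=sel_chain, atom="CA")
        present = np.isin(resids, sub.resid)
        if not present.all():
            missing = resids[~present].tolist()
            raise StructureError(f"missing CA atoms for residues {missing}")
        order = {r: i for i, r in enumerate(sub.resid)}
        return sub.coord[[order[r] for r in resids]]

    a_mod = ca(model, align_range, chain_model)
    a_ref = ca(reference, align_range, chain_reference)
    m_mod = ca(model, measure_range, chain_model)
    m_ref = ca(reference, measure_range, chain_reference)

    t_align, _ = superpose(a_ref, a_mod)   # carry reference into model frame
    m_ref_aligned = t_align.apply(m_ref)
    displacement = float(np.linalg.norm(m_ref_aligned.mean(axis=0) - m_mod.mean(axis=0)))
    t_dom, _ = superpose(m_ref_aligned, m_mod)
    return t_dom.angle_deg, displacement


# ---------------------------------------------------------------------------
# Amide proton construction

_N_H_LENGTH = 1.02  # Å, amide N-H bond length


def build_amide_protons(s: Structure) -> tuple[Structure, int]:
    """Add backbone amide protons (atom name "H") where they are missing.

    H is placed 1.02 Å from N, in the C(i-1)-N-CA plane, bisecting the
    external angle.  Prolines, chain N-termini, residues following a chain
    break, and residues with incomplete backbones are skipped; the number of
    skipped residues is returned alongside the new structure.
    """
    new_rows: list[tuple[str, int, str, str, np.ndarray]] = []
    skipped = 0
    for ch in s.chains:
        sub = s.select(chain=ch)
        resids = np.unique(sub.resid)
        for r in resids:
            rmask = sub.resid == r
            names = set(sub.atom[rmask])
            resname = sub.resname[rmask][0]
            if "H" in names or resname == "PRO":
                continue
            if r - 1 not in resids:
                skipped += 1  # N-terminus or chain break
                continue
            try:
                n = sub.coords_of(ch, r, "N")
                ca = sub.coords_of(ch, r, "CA")
                c_prev = sub.coords_of(ch, r - 1, "C")
            except StructureError:
                skipped += 1
                continue
            u1 = (n - c_prev) / np.linalg.norm(n - c_prev)
            u2 = (n - ca) / np.linalg.norm(n - ca)
            bis = u1 + u2
            nrm = np.linalg.norm(bis)
            if nrm < 1e-8:
                skipped += 1
                continue
            h = n + _N_H_LENGTH * bis / nrm
            new_rows.append((ch, int(r), str(resname), "H", h))
    if not new_rows:
        return s.copy(), skipped
    add = Structure(
        np.array([row[0] for row in new_rows]),
        np.array([row[1] for row in new_rows]),
        np.array([row[2] for row in new_rows]),
        np.array([row[3] for row in new_rows]),
        np.array([row[4] for row in new_rows]),
    )
    merged = concatenate([s, add])
    return merged, skipped


def concatenate(parts: list[Structure]) -> Structure:
    return Structure(
        np.concatenate([p.chain for p in parts]),
        np.concatenate([p.resid for p in parts]),
        np.concatenate([p.resname for p in parts]),
        np.concatenate([p.atom for p in parts]),
        np.concatenate([p.coord for p in parts]),
    )
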