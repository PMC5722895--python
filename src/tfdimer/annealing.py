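"""Two-phase C2-symmetric rigid-domain docking and annealing.

The engine replaces torsion-angle dynamics with rigid-domain Metropolis Monte
Carlo: protomer A is a set of rigid bodies (one per domain, flexible-linker
residues split between neighbors) moved by random 6-DOF perturbations, and
protomer B is regenerated at every step as the exact two-fold image of A
about a fixed C2 axis.  Non-crystallographic and C2 symmetry are therefore
exact by construction rather than penalized.

The energy is a sum of flat-bottom harmonic restraint terms (PRE, EFN, AIR,
distance-symmetry), a soft-sphere CA repulsion, and virtual-bond connectivity
terms capping the CA-CA distance across each flexible linker junction at
4.0 Å per peptide step.  Ambiguous restraints pool their candidate pairings
with an r⁻⁶-summed effective distance; "both"-mode lower bounds are applied
to each pairing separately.

Phase 1 (docking) runs with CSP-derived ambiguous interface restraints (AIR)
plus symmetry and repulsion only; its best model seeds phase 2, which turns
on the full PRE + EFN restraint set.  Each run is reproducible from the
master seed (per-run seeds are derived by fixed splitting and recorded in the
model provenance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .restraints import DistanceRestraint
from .structure import DomainMap, Structure, StructureError, Transform, superpose

#: Fixed two-fold symmetry operator: 180° rotation about the z axis.
C2_TRANSFORM = Transform(np.diag([-1.0, -1.0, 1.0]), np.zeros(3))

DEFAULT_WEIGHTS = {
    "PRE-bounded": 1.0, "PRE-upper": 1.0, "PRE-lower": 1.0,
    "EFN": 0.5, "AIR": 1.0, "symmetry": 1.0,
    "repulsion": 1.0, "connectivity": 1.0,
}

REPULSION_RADIUS_A = 3.5
LINKER_STEP_CAP_A = 4.0
AIR_UPPER_A = 3.0


@dataclass
class AnnealConfig:
    seed: int = 0
    n_runs: int = 100
    n_keep: int = 10
    t_start: float = 100.0
    t_end: float = 0.05
    n_steps: int = 3000
    n_polish: int = 800
    center_weight: float = 0.05
    rot_amp_deg: float = 25.0
    trans_amp_A: float = 5.0
    weights: dict = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    repulsion_radius_A: float = REPULSION_RADIUS_A

    def __post_init__(self) -> None:
        if self.n_keep > self.n_runs:
            raise ValueError("n_keep must not exceed n_runs")
        if not (self.t_end < self.t_start):
            raise ValueError("temperature schedule must decrease")


@dataclass
class DimerModel:
    structure: Structure          # chains A and B
    energy: dict[str, float]      # per-class breakdown incl. "total"
    provenance: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return self.energy["total"]


def effective_distance(distances) -> float:
    """r⁻⁶-pooled effective distance of an ambiguous restraint (Å)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("effective distance of an empty pair list")
    return float(np.sum(d**-6.0) ** (-1.0 / 6.0))


def air_restraints(active_a: set[int], passive_a: set[int],
                   active_b: set[int], passive_b: set[int],
                   s: Structure) -> list[DistanceRestraint]:
    """Ambiguous interface restraints from CSP-derived residue sets.

    Each active residue of one protomer is restrained to the union of active
    and passive residues of the other, with an r⁻⁶-pooled effective-distance
    upper bound of 3 Å over heavy atoms.
    """
    if not active_a or not active_b:
        raise ValueError("active residue sets must be non-empty")
    out: list[DistanceRestraint] = []
    for chain, other, act, act_o, pas_o in (
            ("A", "B", active_a, active_b, passive_b),
            ("B", "A", active_b, active_a, passive_a)):
        partners = sorted(act_o | pas_o)
        for res in sorted(act):
            out.append(DistanceRestraint(
                chain, res, "*", other, -1, "*",
                AIR_UPPER_A, 0.0, AIR_UPPER_A, "AIR", "ambiguous",
                meta={"partner_residues": partners}))
    return out


# ---------------------------------------------------------------------------
# Reference (loop-based) energy evaluation

def _flat_bottom(d: float, lower: float, upper: float) -> float:
    if np.isfinite(upper) and d > upper:
        return (d - upper) ** 2
    if np.isfinite(lower) and d < lower:
        return (lower - d) ** 2
    return 0.0


def _pairings(r: DistanceRestraint, dimer: Structure) -> list[tuple[str, float]]:
    """Candidate (label, distance) pairings of a possibly ambiguous restraint."""
    if r.chain1 == "*":
        p1 = dimer.coords_of("A", r.resid1, r.atom1)
        intra = float(np.linalg.norm(p1 - dimer.coords_of("A", r.resid2, r.atom2)))
        inter = float(np.linalg.norm(p1 - dimer.coords_of("B", r.resid2, r.atom2)))
        return [("intra", intra), ("inter", inter)]
    d = float(np.linalg.norm(dimer.coords_of(r.chain1, r.resid1, r.atom1)
                             - dimer.coords_of(r.chain2, r.resid2, r.atom2)))
    return [("fixed", d)]


def _heavy_coords(dimer: Structure, chain: str, resid: int) -> np.ndarray:
    sub = dimer.select(chain=chain, resid=resid)
    heavy = ~np.char.startswith(sub.atom.astype(str), "H")
    if not heavy.any():
        raise StructureError(f"no heavy atoms for {chain}/{resid}")
    return sub.coord[heavy]


def _air_distance(r: DistanceRestraint, dimer: Structure) -> float:
    a = _heavy_coords(dimer, r.chain1, r.resid1)
    parts = [_heavy_coords(dimer, r.chain2, p) for p in r.meta["partner_residues"]]
    b = np.vstack(parts)
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).ravel()
    return effective_distance(d)


def _symmetry_violation(r: DistanceRestraint, dimer: Structure) -> float:
    """|d(A_i, B_j) − d(B_i, A_j)| for a distance-symmetry restraint."""
    ai = dimer.coords_of("A", r.resid1, r.atom1)
    bj = dimer.coords_of("B", r.resid2, r.atom2)
    bi = dimer.coords_of("B", r.resid1, r.atom1)
    aj = dimer.coords_of("A", r.resid2, r.atom2)
    return abs(float(np.linalg.norm(ai - bj)) - float(np.linalg.norm(bi - aj)))


def restraint_energy(model: Structure | DimerModel,
                     rs: list[DistanceRestraint],
                     weights: dict[str, float] | None = None,
                     repulsion_radius: float = REPULSION_RADIUS_A,
                     junctions: list[tuple[int, int, float]] | None = None,
                     ) -> dict[str, float]:
    """Energy breakdown of a dimer model under a restraint list.

    Straightforward per-restraint evaluation (the annealer's vectorized path
    is cross-checked against this).  ``junctions`` optionally lists linker
    virtual bonds as (resid_i, resid_j, cap_Å) evaluated on both chains.
    Returns per-class energies plus "repulsion", "connectivity" and "total".
    """
    dimer = model.structure if isinstance(model, DimerModel) else model
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    out: dict[str, float] = {}
    for r in rs:
        wk = w.get(r.klass, 1.0)
        if r.klass == "symmetry":
            e = wk * _symmetry_violation(r, dimer) ** 2
        elif r.klass == "AIR":
            e = wk * _flat_bottom(_air_distance(r, dimer), r.lower, r.upper)
        elif r.klass == "EFN":
            e = sum(wk * _flat_bottom(
                float(np.linalg.norm(dimer.coords_of(c, r.resid1, r.atom1)
                                     - dimer.coords_of(c, r.resid2, r.atom2))),
                r.lower, r.upper) for c in ("A", "B"))
        else:  # PRE classes
            pair = _pairings(r, dimer)
            if r.ambiguity == "both":
                e = sum(wk * _flat_bottom(d, r.lower, r.upper) for _, d in pair)
            else:
                deff = effective_distance([d for _, d in pair])
                e = wk * _flat_bottom(deff, r.lower, r.upper)
        out[r.klass] = out.get(r.klass, 0.0) + e

    # soft-sphere CA repulsion: A-A pairs (B-B identical by symmetry when the
    # model is an exact C2 dimer -- evaluated explicitly here) and A-B pairs
    ca_a = dimer.select(chain="A", atom="CA")
    ca_b = dimer.select(chain="B", atom="CA")
    rep = 0.0
    for xs, ys, triangular in ((ca_a.coord, ca_a.coord, True),
                               (ca_b.coord, ca_b.coord, True),
                               (ca_a.coord, ca_b.coord, False)):
        d = np.linalg.norm(xs[:, None, :] - ys[None, :, :], axis=2)
        if triangular:
            d = d[np.triu_indices(len(xs), k=1)]
        else:
            d = d.ravel()
        close = d[d < repulsion_radius]
        rep += np.sum((repulsion_radius - close) ** 2)
    out["repulsion"] = w["repulsion"] * float(rep)

    conn = 0.0
    for i, j, cap in (junctions or []):
        for c in ("A", "B"):
            d = float(np.linalg.norm(dimer.coords_of(c, i, "CA")
                                     - dimer.coords_of(c, j, "CA")))
            conn += max(0.0, d - cap) ** 2
    out["connectivity"] = w["connectivity"] * conn
    out["total"] = float(sum(v for k, v in out.items() if k != "total"))
    return out


# ---------------------------------------------------------------------------
# Rigid-body partition

def rigid_bodies(protomer: Structure, dmap: DomainMap,
                 bodies: tuple[str, ...] = ("RBD", "PPD", "SBD"),
                 ) -> tuple[np.ndarray, list[tuple[int, int, float]]]:
    """Assign every residue to a rigid body; list linker virtual bonds.

    Core residues follow the domain map; linker (and any unassigned) residues
    join the body of the nearest core residue.  Junction virtual bonds are
    placed between sequence-consecutive residues belonging to different
    bodies, capped at 4.0 Å per peptide step.
    """
    resids = np.unique(protomer.resid)
    core: dict[int, int] = {}
    for b, name in enumerate(bodies):
        if name not in dmap.domains:
            continue
        for r in dmap.residues(name):
            if not dmap.in_linker(int(r)):
                core[int(r)] = b
    if len(set(core.values())) < 2:
        raise StructureError("need at least two rigid bodies")
    core_res = np.array(sorted(core))
    assign = {}
    for r in resids:
        r = int(r)
        if r in core:
            assign[r] = core[r]
        else:
            nearest = core_res[np.argmin(np.abs(core_res - r))]
            assign[r] = core[int(nearest)]
    body_of = np.array([assign[int(r)] for r in resids], dtype=int)
    junctions = []
    for k in range(len(resids) - 1):
        i, j = int(resids[k]), int(resids[k + 1])
        if assign[i] != assign[j]:
            junctions.append((i, j, LINKER_STEP_CAP_A * (j - i)))
    return body_of, junctions


# ---------------------------------------------------------------------------
# Compiled (vectorized) energy for the Monte-Carlo loop

class _CompiledEnergy:
    def __init__(self, protomer: Structure, rs: list[DistanceRestraint],
                 junctions: list[tuple[int, int, float]],
                 weights: dict[str, float], repulsion_radius: float):
        self.w = dict(DEFAULT_WEIGHTS)
        self.w.update(weights or {})
        self.rrad = repulsion_radius
        idx: dict[tuple[int, str], int] = {}
        for k in range(len(protomer)):
            idx[(int(protomer.resid[k]), str(protomer.atom[k]))] = k
        self.heavy_of: dict[int, np.ndarray] = {}
        for r in np.unique(protomer.resid):
            m = (protomer.resid == r) & \
                ~np.char.startswith(protomer.atom.astype(str), "H")
            self.heavy_of[int(r)] = np.flatnonzero(m)

        def atom_index(resid, atom, what):
            key = (int(resid), atom)
            if key not in idx:
                raise StructureError(f"restraint endpoint missing: {what} "
                                     f"resid {resid} atom {atom}")
            return idx[key]

        amb_i, amb_j, amb_lo, amb_hi, amb_w = [], [], [], [], []
        amb_target, amb_is_bounded = [], []
        low_i, low_j, low_lo, low_w = [], [], [], []
        efn_i, efn_j, efn_lo, efn_hi = [], [], [], []
        sym_i, sym_j = [], []
        air = []  # (chain1, atom-rows of resid1, atom-rows of partners, w)
        for r in rs:
            if r.klass in ("PRE-bounded", "PRE-upper"):
                amb_i.append(atom_index(r.resid1, r.atom1, r.klass))
                amb_j.append(atom_index(r.resid2, r.atom2, r.klass))
                amb_lo.append(r.lower)
                amb_hi.append(r.upper)
                amb_w.append(self.w.get(r.klass, 1.0))
                amb_target.append(r.target)
                amb_is_bounded.append(r.klass == "PRE-bounded")
            elif r.klass == "PRE-lower":
                low_i.append(atom_index(r.resid1, r.atom1, r.klass))
                low_j.append(atom_index(r.resid2, r.atom2, r.klass))
                low_lo.append(r.lower)
                low_w.append(self.w.get(r.klass, 1.0))
            elif r.klass == "EFN":
                efn_i.append(atom_index(r.resid1, r.atom1, "EFN"))
                efn_j.append(atom_index(r.resid2, r.atom2, "EFN"))
                efn_lo.append(r.lower)
                efn_hi.append(r.upper)
            elif r.klass == "symmetry":
                sym_i.append(atom_index(r.resid1, r.atom1, "symmetry"))
                sym_j.append(atom_index(r.resid2, r.atom2, "symmetry"))
            elif r.klass == "AIR":
                rows1 = self.heavy_of[int(r.resid1)]
                rows2 = np.concatenate([self.heavy_of[int(p)]
                                        for p in r.meta["partner_residues"]])
                air.append((r.chain1, rows1, rows2,
                            self.w.get("AIR", 1.0), r.lower, r.upper))
            else:
                raise ValueError(f"unknown restraint class {r.klass}")
        def as_arr(x):
            return np.asarray(x, dtype=float)
        self.amb = (np.asarray(amb_i, dtype=int), np.asarray(amb_j, dtype=int),
                    as_arr(amb_lo), as_arr(amb_hi), as_arr(amb_w))
        self.amb_target = as_arr(amb_target)
        self.amb_bounded = np.asarray(amb_is_bounded, dtype=bool)
        self.low = (np.asarray(low_i, dtype=int), np.asarray(low_j, dtype=int),
                    as_arr(low_lo), as_arr(low_w))
        self.efn = (np.asarray(efn_i, dtype=int), np.asarray(efn_j, dtype=int),
                    as_arr(efn_lo), as_arr(efn_hi))
        self.sym = (np.asarray(sym_i, dtype=int), np.asarray(sym_j, dtype=int))
        self.air = air
        self.ca_rows = np.flatnonzero(protomer.atom == "CA")
        self.junctions = [(atom_index(i, "CA", "junction"),
                           atom_index(j, "CA", "junction"), cap)
                          for i, j, cap in junctions]

    def __call__(self, p: np.ndarray) -> dict[str, float]:
        b = p @ C2_TRANSFORM.rotation.T
        out: dict[str, float] = {}
        self.center_term = 0.0

        ai, aj, lo, hi, ww = self.amb
        if len(ai):
            d1 = np.linalg.norm(p[ai] - p[aj], axis=1)
            d2 = np.linalg.norm(p[ai] - b[aj], axis=1)
            deff = (d1**-6.0 + d2**-6.0) ** (-1.0 / 6.0)
            viol = np.maximum(0.0, deff - hi) + np.maximum(0.0, lo - deff)
            out["PRE-ambiguous"] = float(np.sum(ww * viol**2))
            if self.amb_bounded.any():
                dev = deff[self.amb_bounded] - self.amb_target[self.amb_bounded]
                self.center_term = float(np.mean(dev**2))
            else:
                self.center_term = 0.0

        li, lj, llo, lw = self.low
        if len(li):
            d1 = np.linalg.norm(p[li] - p[lj], axis=1)
            d2 = np.linalg.norm(p[li] - b[lj], axis=1)
            v = np.maximum(0.0, llo - d1) ** 2 + np.maximum(0.0, llo - d2) ** 2
            out["PRE-lower"] = float(np.sum(lw * v))

        ei, ej, elo, ehi = self.efn
        if len(ei):
            d = np.linalg.norm(p[ei] - p[ej], axis=1)
            v = np.maximum(0.0, d - ehi) + np.maximum(0.0, elo - d)
            out["EFN"] = 2.0 * self.w["EFN"] * float(np.sum(v**2))

        si, sj = self.sym
        if len(si):
            d1 = np.linalg.norm(p[si] - b[sj], axis=1)
            d2 = np.linalg.norm(b[si] - p[sj], axis=1)
            out["symmetry"] = self.w["symmetry"] * float(np.sum((d1 - d2) ** 2))

        if self.air:
            e = 0.0
            for chain1, rows1, rows2, wk, lo_a, hi_a in self.air:
                c1 = p if chain1 == "A" else b
                c2 = b if chain1 == "A" else p
                d = np.linalg.norm(c1[rows1][:, None, :] - c2[rows2][None, :, :],
                                   axis=2)
                deff = float(np.sum(d**-6.0) ** (-1.0 / 6.0))
                e += wk * (max(0.0, deff - hi_a) ** 2 + max(0.0, lo_a - deff) ** 2)
            out["AIR"] = e

        ca_a = p[self.ca_rows]
        ca_b = b[self.ca_rows]
        daa = np.linalg.norm(ca_a[:, None, :] - ca_a[None, :, :], axis=2)
        iu = np.triu_indices(len(ca_a), k=1)
        close = daa[iu]
        close = close[close < self.rrad]
        rep = 2.0 * np.sum((self.rrad - close) ** 2)
        dab = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2).ravel()
        close = dab[dab < self.rrad]
        rep += np.sum((self.rrad - close) ** 2)
        out["repulsion"] = self.w["repulsion"] * float(rep)

        conn = 0.0
        for i, j, cap in self.junctions:
            conn += max(0.0, float(np.linalg.norm(p[i] - p[j])) - cap) ** 2
        out["connectivity"] = 2.0 * self.w["connectivity"] * conn

        out["total"] = float(sum(out.values()))
        return out


def _random_rotation(rng: np.random.Generator, max_angle_rad: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, max_angle_rad)
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(angle * axis).as_matrix()


def anneal_dimer(protomer: Structure, dmap: DomainMap,
                 rs: list[DistanceRestraint], cfg: AnnealConfig,
                 bodies: tuple[str, ...] = ("RBD", "PPD", "SBD"),
                 initial: Structure | None = None) -> list[DimerModel]:
    """Run ``cfg.n_runs`` independent annealing trajectories.

    Returns all final models sorted by total energy.  Chain B of every model
    is the exact C2 image of chain A.  ``initial`` optionally seeds every run
    from a previous model's chain A (phase-1 → phase-2 hand-off); otherwise
    each run starts from a random placement.
    """
    if not rs:
        raise ValueError("no restraints supplied")
    body_of, junctions = rigid_bodies(protomer, dmap, bodies)
    resids = np.unique(protomer.resid)
    for b in np.unique(body_of):
        n_ca = np.sum((protomer.atom == "CA")
                      & np.isin(protomer.resid, resids[body_of == b]))
        if n_ca < 3:
            raise StructureError(f"rigid body {b} has fewer than 3 CA atoms")
    atom_body = np.array(
        [body_of[np.searchsorted(resids, r)] for r in protomer.resid])
    energy = _CompiledEnergy(protomer, rs, junctions, cfg.weights,
                             cfg.repulsion_radius_A)
    present_bodies = np.unique(atom_body)
    x0 = protomer.coord.copy()
    seed_seq = np.random.SeedSequence(cfg.seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 seed_seq.spawn(cfg.n_runs)]

    models: list[DimerModel] = []
    for run, run_seed in enumerate(run_seeds):
        rng = np.random.default_rng(run_seed)
        if initial is not None:
            p = initial.select(chain="A").coord.copy() if "A" in initial.chains \
                else initial.coord.copy()
            p = p + rng.normal(0.0, 0.5, size=3)  # small de-correlating jitter
        else:
            c = x0.mean(axis=0)
            p = (x0 - c) @ _random_rotation(rng, math.pi).T
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = rng.uniform(8.0, 35.0)
            p = p + direction * offset
        e = energy(p)
        aux = e["total"] + cfg.center_weight * energy.center_term
        for step in range(cfg.n_steps):
            frac = step / max(cfg.n_steps - 1, 1)
            temp = cfg.t_start * (cfg.t_end / cfg.t_start) ** frac
            amp = max(0.08, math.sqrt(temp / cfg.t_start))
            if rng.random() < 0.4:
                sel = slice(None)          # whole-protomer move
            else:
                sel = atom_body == present_bodies[
                    rng.integers(len(present_bodies))]
            block = p[sel]
            centroid = block.mean(axis=0)
            rot = _random_rotation(rng, math.radians(cfg.rot_amp_deg) * amp)
            shift = rng.normal(0.0, cfg.trans_amp_A * amp, size=3)
            new_block = (block - centroid) @ rot.T + centroid + shift
            saved = block.copy()
            p[sel] = new_block
            e_new = energy(p)
            aux_new = e_new["total"] + cfg.center_weight * energy.center_term
            de = aux_new - aux
            if de <= 0 or rng.random() < math.exp(-de / temp):
                e, aux = e_new, aux_new
            else:
                p[sel] = saved
        # polish: the flat-bottom potential leaves a degenerate zero-energy
        # basin; greedy small moves biased toward the centers of the bounded
        # restraints (their targets are the measured distances, the margins
        # only absorb tag flexibility) pick the basin's most consistent pose
        e = energy(p)
        aux = e["total"] + cfg.center_weight * energy.center_term
        for _ in range(cfg.n_polish):
            sel = slice(None) if rng.random() < 0.4 \
                else atom_body == present_bodies[
                    rng.integers(len(present_bodies))]
            block = p[sel]
            centroid = block.mean(axis=0)
            rot = _random_rotation(rng, math.radians(cfg.rot_amp_deg) * 0.04)
            shift = rng.normal(0.0, cfg.trans_amp_A * 0.04, size=3)
            saved = block.copy()
            p[sel] = (block - centroid) @ rot.T + centroid + shift
            e_new = energy(p)
            aux_new = e_new["total"] + cfg.center_weight * energy.center_term
            if aux_new <= aux:
                e, aux = e_new, aux_new
            else:
                p[sel] = saved
        e = energy(p)
        e["restraint_center"] = energy.center_term  # excluded from "total"
        dimer = make_c2_dimer(Structure(protomer.chain, protomer.resid,
                                        protomer.resname, protomer.atom, p))
        models.append(DimerModel(dimer, e, provenance={
            "seed": cfg.seed, "run_seed": run_seed, "run": run,
            "n_steps": cfg.n_steps}))
    # runs routinely reach zero restraint energy, so the center term breaks
    # the tie toward the most target-consistent model
    models.sort(key=lambda m: (m.total_energy,
                               m.energy.get("restraint_center", 0.0),
                               m.provenance["run"]))
    return models


def make_c2_dimer(protomer: Structure,
                  symmetry: Transform = C2_TRANSFORM) -> Structure:
    """Assemble a two-chain dimer: chain A as given, chain B its C2 image."""
    from .structure import concatenate
    a = protomer.with_chain("A")
    b = protomer.transformed(symmetry).with_chain("B")
    return concatenate([a, b])


def select_models(models: list[DimerModel], n: int) -> list[DimerModel]:
    """The n lowest-energy models, ties broken by run index."""
    if not models:
        raise ValueError("no models to select from")
    if n > len(models):
        raise ValueError(f"cannot select {n} of {len(models)} models")
    ranked = sorted(models, key=lambda m: (m.total_energy,
                                           m.provenance.get("run", 0)))
    return ranked[:n]


def violation_report(model: DimerModel | Structure,
                     rs: list[DistanceRestraint]) -> pd.DataFrame:
    """Per-restraint effective distances, violations, and chosen pairings."""
    dimer = model.structure if isinstance(model, DimerModel) else model
    rows = []
    for k, r in enumerate(rs):
        if r.klass == "symmetry":
            v = _symmetry_violation(r, dimer)
            rows.append({"index": k, "klass": r.klass, "effective_A": np.nan,
                         "lower_A": 0.0, "upper_A": 0.0, "violation_A": v,
                         "pairing": "symmetry"})
            continue
        if r.klass == "AIR":
            deff = _air_distance(r, dimer)
            viol = max(0.0, deff - r.upper)
            rows.append({"index": k, "klass": r.klass, "effective_A": deff,
                         "lower_A": r.lower, "upper_A": r.upper,
                         "violation_A": viol, "pairing": "pooled"})
            continue
        if r.klass == "EFN":
            for c in ("A", "B"):
                d = float(np.linalg.norm(dimer.coords_of(c, r.resid1, r.atom1)
                                         - dimer.coords_of(c, r.resid2, r.atom2)))
                viol = max(0.0, d - r.upper) + max(0.0, r.lower - d)
                rows.append({"index": k, "klass": r.klass, "effective_A": d,
                             "lower_A": r.lower, "upper_A": r.upper,
                             "violation_A": viol, "pairing": c})
            continue
        pair = _pairings(r, dimer)
        if r.ambiguity == "both":
            for label, d in pair:
                viol = max(0.0, d - r.upper) + max(0.0, r.lower - d) \
                    if np.isfinite(r.upper) else max(0.0, r.lower - d)
                rows.append({"index": k, "klass": r.klass, "effective_A": d,
                             "lower_A": r.lower, "upper_A": r.upper,
                             "violation_A": viol, "pairing": label})
        else:
            deff = effective_distance([d for _, d in pair])
            viol = max(0.0, deff - r.upper) + max(0.0, r.lower - deff)
            chosen = min(pair, key=lambda t: t[1])[0]
            rows.append({"index": k, "klass": r.klass, "effective_A": deff,
                         "lower_A": r.lower, "upper_A": r.upper,
                         "violation_A": viol, "pairing": chosen})
    df = pd.DataFrame(rows, columns=["index", "klass", "effective_A",
                                     "lower_A", "upper_A", "violation_A",
                                     "pairing"])
    return df


def satisfied_fraction(report: pd.DataFrame, tol: float = 1e-9) -> pd.Series:
    """Fraction of restraints satisfied per class."""
    if report.empty:
        return pd.Series(dtype=float)
    ok = report["violation_A"] <= tol
    return ok.groupby(report["klass"]).mean()


def interface_contacts(model: DimerModel | Structure,
                       residues: list[int]) -> pd.DataFrame:
    """Minimal heavy-atom distance of each residue to the other chain."""
    dimer = model.structure if isinstance(model, DimerModel) else model
    if len(dimer.chains) != 2:
        raise StructureError("interface contacts need a two-chain model")
    rows = []
    other = {"A": "B", "B": "A"}
    for res in residues:
        for c in ("A",):
            a = _heavy_coords(dimer, c, int(res))
            sub = dimer.select(chain=other[c])
            heavy = ~np.char.startswith(sub.atom.astype(str), "H")
            b = sub.coord[heavy]
            d = float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :],
                                            axis=2)))
            rows.append({"residue": int(res), "chain": c, "min_distance_A": d})
    return pd.DataFrame(rows)


def interface_ca_rmsd(model: Structure | DimerModel,
                      truth: Structure | DimerModel,
                      cutoff: float = 10.0) -> float:
    """Interface CA-RMSD between two dimer models, chain-swap aware.

    Interface residues are those whose CA lies within ``cutoff`` of any CA of
    the partner chain in the truth model.  Both chain assignments
    (A→A/B→B and A→B/B→A) are tried after least-squares superposition on all
    interface CAs; the smaller RMSD is returned.
    """
    md = model.structure if isinstance(model, DimerModel) else model
    td = truth.structure if isinstance(truth, DimerModel) else truth
    ca_t = {c: td.select(chain=c, atom="CA") for c in ("A", "B")}
    d = np.linalg.norm(ca_t["A"].coord[:, None, :]
                       - ca_t["B"].coord[None, :, :], axis=2)
    iface_a = ca_t["A"].resid[d.min(axis=1) <= cutoff]
    iface_b = ca_t["B"].resid[d.min(axis=0) <= cutoff]
    if len(iface_a) == 0:
        raise StructureError("truth model has no interface within cutoff")

    def gather(s, chain, resids):
        sub = s.select(chain=chain, atom="CA")
        order = {int(r): k for k, r in enumerate(sub.resid)}
        return sub.coord[[order[int(r)] for r in resids]]

    ref = np.vstack([gather(td, "A", iface_a), gather(td, "B", iface_b)])
    best = math.inf
    for ca, cb in (("A", "B"), ("B", "A")):
        mob = np.vstack([gather(md, ca, iface_a), gather(md, cb, iface_b)])
        _, rmsd = superpose(mob, ref)
        best = min(best, rmsd)
    return best
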