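"""Ground-truth synthetic data for every stage of the pipeline.

Generates toy multi-domain protomers (compact self-avoiding CA traces with CB
and amide-H pseudo-atoms, joined by extended linkers), exact C2 dimer poses,
PRE peak-volume tables forward-simulated from spin-label-to-amide distances
(intra- plus intermolecular rates are additive over the two label copies of
the symmetric dimer), mass-action SEC-MALS curves, and mono-exponential
mixing decays — each paired with the generating parameters so recovery can be
asserted exactly.  Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annealing import make_c2_dimer
from .equilibrium import BindingCurve, mw_monomer_dimer
from .kinetics import DecayTrace, simulate_mixing
from .restraints import PREConfig, pre_from_distance
from .structure import DomainMap, Structure, Transform

CA_STEP_A = 3.8          # consecutive-CA virtual bond length
MIN_SEP_A = 3.5          # self-avoidance floor of the CA trace
BROADENED_RATIO = 0.05   # generator convention: ratio below this is emitted
                         # as broadened-beyond-detection (distinct from the
                         # 0.15 classification boundary)


@dataclass
class TruthRecord:
    """Generating parameters attached to each synthetic artifact."""

    seed: int
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Toy protomer

def _extend_trace(rng: np.random.Generator, placed: list[np.ndarray],
                  n: int, bias_point_fn, bias_strength: float,
                  max_tries: int = 400) -> None:
    """Grow a self-avoiding CA trace in place, biased toward a moving target.

    Every new point keeps >= MIN_SEP_A from all previously placed points
    except its direct predecessor (bonded at CA_STEP_A).
    """
    for _ in range(n):
        placed_arr = np.asarray(placed)
        success = False
        for _try in range(max_tries):
            direction = rng.normal(size=3)
            pull = bias_point_fn() - placed[-1]
            norm = np.linalg.norm(pull)
            if norm > 1e-9:
                direction = direction + bias_strength * pull / norm \
                    * min(norm / 6.0, 1.5)
            direction /= np.linalg.norm(direction)
            cand = placed[-1] + CA_STEP_A * direction
            if len(placed) > 1:
                d = np.linalg.norm(placed_arr[:-1] - cand, axis=1)
                if d.min() < MIN_SEP_A:
                    continue
            placed.append(cand)
            success = True
            break
        if not success:
            raise RuntimeError("could not place CA atom (packing too tight)")


def make_toy_protomer(seed: int,
                      domain_sizes: tuple[int, ...] = (36, 36, 36),
                      linker_lengths: tuple[int, ...] = (4, 4),
                      ) -> tuple[Structure, DomainMap]:
    """Toy protomer: compact domains joined by extended linkers.

    Each residue carries CA, CB (1.53 Å off-backbone) and an amide-H
    pseudo-atom (1.02 Å, roughly anti-parallel to CB), which is every
    endpoint type the restraint pipeline uses.  Domains are named RBD, PPD,
    SBD in sequence order to mirror the rigid-body split of the annealer.
    Deterministic per seed.
    """
    if len(domain_sizes) < 2:
        raise ValueError("need at least 2 domains")
    if len(linker_lengths) != len(domain_sizes) - 1:
        raise ValueError("need one linker length per domain junction")
    names = ["RBD", "PPD", "SBD"][:len(domain_sizes)] + \
        [f"D{k}" for k in range(3, len(domain_sizes))]

    domains: dict[str, list[tuple[int, int]]] = {}
    linkers: list[tuple[int, int]] = []
    for attempt in range(25):
        rng = np.random.default_rng((seed, attempt))
        try:
            placed: list[np.ndarray] = [np.zeros(3)]
            domains.clear()
            linkers.clear()
            resid = 0
            for k, size in enumerate(domain_sizes):
                dom_start = len(placed) - 1
                # compact but prolate domain (globular proteins are rarely
                # spherical): the bias target creeps along a random axis while
                # pulling toward the running centroid, giving ~2:1 aspect
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                entry = placed[-1].copy()

                def bias(i=[0], entry=entry, axis=axis, dom_start=dom_start):
                    i[0] += 1
                    along = entry + axis * (i[0] * CA_STEP_A * 0.18)
                    return 0.5 * (along + np.mean(placed[dom_start:], axis=0))
                _extend_trace(rng, placed, size - 1, bias, 0.9)
                domains[names[k]] = [(resid + 1, resid + size)]
                resid += size
                if k < len(domain_sizes) - 1:
                    nl = linker_lengths[k]
                    dom_centroid = np.mean(placed[dom_start:], axis=0)
                    # extended linker: bias away from the finished domain
                    _extend_trace(
                        rng, placed, nl + 1,
                        lambda: placed[-1] + (placed[-1] - dom_centroid) * 5.0,
                        1.2)
                    linkers.append((resid + 1, resid + nl))
                    resid += nl
            break
        except RuntimeError:
            if attempt == 24:
                raise
    ca = np.asarray(placed)
    n_res = len(ca)
    # pseudo side-chain and amide-proton directions from local backbone
    prev_pt = np.vstack([ca[:1], ca[:-1]])
    next_pt = np.vstack([ca[1:], ca[-1:]])
    outward = ca - 0.5 * (prev_pt + next_pt)
    norms = np.linalg.norm(outward, axis=1)
    fallback = rng.normal(size=(n_res, 3))
    fallback /= np.linalg.norm(fallback, axis=1, keepdims=True)
    small = norms < 1e-6
    outward[small] = fallback[small]
    outward /= np.linalg.norm(outward, axis=1, keepdims=True)
    cb = ca + 1.53 * outward
    axis = next_pt - prev_pt
    axis_norm = np.linalg.norm(axis, axis=1, keepdims=True)
    axis = np.divide(axis, axis_norm, out=fallback.copy(),
                     where=axis_norm > 1e-9)
    h_dir = np.cross(outward, axis)
    h_norm = np.linalg.norm(h_dir, axis=1, keepdims=True)
    h_dir = np.divide(h_dir, h_norm, out=fallback.copy(), where=h_norm > 1e-9)
    h = ca + 1.02 * h_dir

    resids = np.arange(1, n_res + 1)
    chain = np.full(3 * n_res, "A", dtype="U4")
    resid_col = np.repeat(resids, 3)
    resname = np.full(3 * n_res, "ALA", dtype="U4")
    atom = np.tile(np.array(["CA", "CB", "H"], dtype="U4"), n_res)
    coord = np.empty((3 * n_res, 3))
    coord[0::3], coord[1::3], coord[2::3] = ca, cb, h
    s = Structure(chain, resid_col, resname, atom, coord)
    return s, DomainMap(domains=domains, linkers=linkers)


# ---------------------------------------------------------------------------
# C2 dimer truth

def make_true_dimer(protomer: Structure, pose: Transform,
                    min_clearance: float = 3.0,
                    ) -> tuple[Structure, TruthRecord]:
    """Build the two-chain truth dimer from an exact two-fold pose.

    ``pose`` must be an involution (pose∘pose = identity to 1e-6) and must
    not bring inter-chain CA atoms closer than ``min_clearance``.
    """
    probe = protomer.coord[:3]
    back = pose.apply(pose.apply(probe))
    if np.max(np.linalg.norm(back - probe, axis=1)) > 1e-6:
        raise ValueError("pose is not a two-fold (pose∘pose != identity)")
    b = protomer.transformed(pose)
    ca_mask = protomer.atom == "CA"
    d = np.linalg.norm(protomer.coord[ca_mask][:, None, :]
                       - b.coord[ca_mask][None, :, :], axis=2)
    if d.min() < min_clearance:
        raise ValueError(f"pose clashes: min inter-chain CA distance "
                         f"{d.min():.2f} Å < {min_clearance} Å")
    from .structure import concatenate
    dimer = concatenate([protomer.with_chain("A"), b.with_chain("B")])
    rec = TruthRecord(seed=-1, params={"pose_rotation": pose.rotation.tolist(),
                                       "pose_translation": pose.translation.tolist()})
    return dimer, rec


def c2_pose_about_z(offset_x: float) -> Transform:
    """Two-fold pose: 180° about the z axis shifted to x = offset_x/2.

    Applying it to a protomer centered near the origin yields a C2 dimer
    whose chains are ~offset_x apart along x.
    """
    rot = np.diag([-1.0, -1.0, 1.0])
    return Transform(rot, np.array([offset_x, 0.0, 0.0]))


def find_contact_pose(protomer: Structure, target_gap: float = 4.5,
                      axis_shift_max: float = 120.0) -> Transform:
    """Slide the C2 axis along x until the chains just touch.

    Scans the two-fold pose offset until the minimum inter-chain CA distance
    is close to ``target_gap`` (bisection on the monotone far side).
    """
    ca = protomer.select(atom="CA").coord

    def min_dist(offset):
        b = c2_pose_about_z(offset).apply(ca)
        return np.min(np.linalg.norm(ca[:, None, :] - b[None, :, :], axis=2))

    lo, hi = 0.0, axis_shift_max
    if min_dist(hi) < target_gap:
        raise ValueError("protomer too large for the scanned axis range")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_dist(mid) < target_gap:
            lo = mid
        else:
            hi = mid
    return c2_pose_about_z(hi)


def place_head_to_tail(protomer: Structure, dmap: DomainMap,
                       head: str = "RBD", tail: str = "SBD",
                       target_gap: float = 4.5) -> Structure:
    """Reposition a protomer so the C2 image forms a head-to-tail dimer.

    The head→tail axis is rotated onto x, the midpoint centered, and the
    protomer shifted along +y until the two-fold image about the z axis
    (180°, :data:`~tfdimer.annealing.C2_TRANSFORM`) sits antiparallel with a
    minimum inter-chain CA distance of ``target_gap``: the head domain of
    each chain then faces the tail domain of the other — the avidity
    arrangement with two equivalent head/tail contact zones.
    """
    ca = protomer.select(atom="CA")
    c_head = ca.coord[np.isin(ca.resid, dmap.residues(head))].mean(axis=0)
    c_tail = ca.coord[np.isin(ca.resid, dmap.residues(tail))].mean(axis=0)
    ex = c_tail - c_head
    ex /= np.linalg.norm(ex)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, ex)) > 0.95:
        ref = np.array([0.0, 1.0, 0.0])
    ez = ref - np.dot(ref, ex) * ex
    ez /= np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    rot = np.vstack([ex, ey, ez])  # rows: new basis -> world-to-local
    mid = 0.5 * (c_head + c_tail)
    local = (protomer.coord - mid) @ rot.T
    ca_mask = protomer.atom == "CA"
    # point everything that is neither head nor tail (e.g. the middle domain)
    # toward +y, away from the partner chain, so the head/tail ends make the
    # first contact when sliding
    ht = set(dmap.residues(head)) | set(dmap.residues(tail))
    mid_res = np.array(sorted(set(protomer.resid.tolist()) - ht), dtype=int)
    if len(mid_res):
        sel = ca_mask & np.isin(protomer.resid, mid_res)
        c_mid = local[sel].mean(axis=0)
        phi = math.atan2(c_mid[2], c_mid[1])
        c, s = math.cos(-phi), math.sin(-phi)
        rx = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        local = local @ rx.T

    def min_dist(ty: float) -> float:
        a = local[ca_mask] + np.array([0.0, ty, 0.0])
        b = a @ np.diag([-1.0, -1.0, 1.0])
        return float(np.min(np.linalg.norm(a[:, None, :] - b[None, :, :],
                                           axis=2)))

    lo, hi = 0.0, 200.0
    if min_dist(hi) < target_gap:
        raise ValueError("protomer too large for the scanned shift range")
    for _ in range(60):
        m = 0.5 * (lo + hi)
        if min_dist(m) < target_gap:
            lo = m
        else:
            hi = m
    placed = local + np.array([0.0, hi, 0.0])
    return Structure(protomer.chain, protomer.resid, protomer.resname,
                     protomer.atom, placed)


# ---------------------------------------------------------------------------
# Forward-simulated observables

def simulate_pre_ratios(dimer: Structure, label_sites: list[int],
                        cfg: PREConfig, noise_sd: float = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Peak-volume table from spin-label CB to amide-H distances.

    For each (label site, residue) the intra- and intermolecular rates add
    (the symmetric dimer carries one label copy per chain):
    ratio = exp(-(PRE(d_intra) + PRE(d_inter)) · 2τ_INEPT).  Multiplicative
    Gaussian noise is applied to both volumes; ratios below 0.05 are emitted
    as broadened-beyond-detection.
    """
    rng = np.random.default_rng(seed)
    rows = []
    resids = np.unique(dimer.select(chain="A").resid)
    for site in label_sites:
        cb_a = dimer.coords_of("A", site, "CB")
        for res in resids:
            if int(res) == int(site):
                continue  # the mutated residue itself carries the label
            h_a = dimer.coords_of("A", int(res), "H")
            h_b = dimer.coords_of("B", int(res), "H")
            d_intra = float(np.linalg.norm(cb_a - h_a))
            d_inter = float(np.linalg.norm(cb_a - h_b))
            pre_total = pre_from_distance(d_intra, cfg) \
                + pre_from_distance(d_inter, cfg)
            ratio = math.exp(-pre_total * cfg.two_tau_inept_s)
            broadened = ratio < BROADENED_RATIO
            v_red = 1.0
            v_ox = ratio
            if noise_sd > 0:
                v_red *= 1.0 + noise_sd * rng.standard_normal()
                v_ox *= 1.0 + noise_sd * rng.standard_normal()
            rows.append({"residue": int(res), "v_ox": v_ox, "v_red": v_red,
                         "broadened": broadened, "overlapped": False,
                         "label_site": int(site),
                         "true_d_intra_A": d_intra,
                         "true_d_inter_A": d_inter})
    return pd.DataFrame(rows)


def simulate_secmals(kd_uM: float, monomer_mass_kDa: float,
                     concs_uM: np.ndarray, noise_sd: float = 0.01,
                     seed: int = 0) -> BindingCurve:
    """Mass-action M_w(c) curve with multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    concs = np.asarray(concs_uM, dtype=float)
    mw = mw_monomer_dimer(concs, kd_uM, monomer_mass_kDa)
    if noise_sd > 0:
        mw = mw * (1.0 + noise_sd * rng.standard_normal(len(concs)))
    return BindingCurve(concs, mw, monomer_mass_kDa,
                        label=f"synthetic kd={kd_uM}")


# ---------------------------------------------------------------------------
# Full fixture bundle

#: Temperature series and dead times of the mixing experiment (s).
MIXING_DEAD_TIMES_S = {15: 160.0, 20: 140.0, 25: 150.0, 30: 150.0, 35: 160.0}


@dataclass
class FixtureBundle:
    protomer: Structure
    domain_map: DomainMap
    truth_dimer: Structure
    pose: Transform
    peak_table: pd.DataFrame
    label_sites: list[int]
    active_residues: set[int]
    binding_curve: BindingCurve
    decay_traces: dict[int, DecayTrace]
    pre_config: PREConfig
    truth: TruthRecord


def make_full_fixture(seed: int, noise_sd: float = 0.0,
                      kd_uM: float = 2.5, k_off_per_s: float = 1.05e-3,
                      monomer_mass_kDa: float = 48.0) -> FixtureBundle:
    """End-to-end synthetic study emulating the experimental design.

    One toy protomer, a C2 truth dimer in contact, PRE tables for six label
    sites spread over the three domains, CSP-like active residues from true
    interface contacts (< 5 Å heavy-atom distance), a 12-point SEC-MALS
    curve at the micro-molar affinity scale, and mixing decays at five
    temperatures with the experimental dead times.  Bit-identical
    regeneration from (parameters, seed).
    """
    protomer, dmap = make_toy_protomer(seed)
    protomer = place_head_to_tail(protomer, dmap)
    from .annealing import C2_TRANSFORM
    pose = C2_TRANSFORM
    truth_dimer, rec = make_true_dimer(protomer, pose)
    rec.seed = seed
    rec.params.update({"kd_uM": kd_uM, "k_off_per_s": k_off_per_s,
                       "noise_sd": noise_sd})

    # Label-site placement mirrors the experimental logic: probes go where
    # they report on the dimer contact, i.e. the two residues per domain
    # whose CB lies closest to the partner chain (subject to a minimum
    # sequence separation so the two probes are not neighbors).
    ca_b = truth_dimer.select(chain="B").coord
    sites = []
    for name in ("RBD", "PPD", "SBD"):
        res = dmap.residues(name)
        cb = np.vstack([truth_dimer.coords_of("A", int(r), "CB") for r in res])
        dmin = np.min(np.linalg.norm(cb[:, None, :] - ca_b[None, :, :], axis=2),
                      axis=1)
        # candidates: the eight residues reporting most strongly on the partner
        cand = np.argsort(dmin)[:8]
        # pick the pair with the largest spatial spread, so the two probes
        # triangulate rather than duplicate each other
        best, best_sep = None, -1.0
        for ii in range(len(cand)):
            for jj in range(ii + 1, len(cand)):
                sep = float(np.linalg.norm(cb[cand[ii]] - cb[cand[jj]]))
                if sep > best_sep:
                    best, best_sep = (cand[ii], cand[jj]), sep
        sites.extend(int(res[k]) for k in best)
    sites = sorted(sites)

    cfg = PREConfig(noise_sd=noise_sd)
    peaks = simulate_pre_ratios(truth_dimer, sites, cfg, noise_sd=noise_sd,
                                seed=seed + 2)

    from .annealing import interface_contacts
    resids = [int(r) for r in np.unique(protomer.resid)]
    contacts = interface_contacts(truth_dimer, resids)
    active = set(contacts.loc[contacts["min_distance_A"] < 5.0, "residue"])

    concs = np.geomspace(0.2, 200.0, 12)
    curve = simulate_secmals(kd_uM, monomer_mass_kDa, concs,
                             noise_sd=noise_sd if noise_sd > 0 else 0.01,
                             seed=seed + 3)

    traces = {}
    for k, (temp, t0) in enumerate(sorted(MIXING_DEAD_TIMES_S.items())):
        # lifetime shortens with temperature around the given k_off scale
        k_off_t = k_off_per_s * (1.0 + 0.35 * (temp - 25) / 10.0)
        times = t0 + np.linspace(0.0, 4.0 / k_off_t, 60)
        traces[temp] = simulate_mixing(k_off_t, 10_000, times,
                                       mode="deterministic",
                                       dead_time_s=t0, temperature_C=temp)
    return FixtureBundle(protomer, dmap, truth_dimer, pose, peaks, sites,
                         active, curve, traces, cfg, rec)
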