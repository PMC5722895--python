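"""Chemical-shift analysis: secondary shifts, CSPs, and interface selection.

Amide chemical-shift perturbations are combined as

    Δδ_HN = sqrt(Δδ(1H)² + (0.2 · Δδ(15N))²)        [ppm]

and residues are called significant against a "corrected to zero" threshold:
outliers beyond mean + 3·SD are excluded iteratively until the retained set is
stable, and the threshold is the retained mean + k·SD (k = 1 for active-residue
selection, k = 2 for a stricter display threshold).  Residues whose resonances
broaden beyond detection carry a flag instead of a magnitude and are always
treated as significant.

Secondary ¹³C shifts are (δCA_obs − δCA_rc) − (δCB_obs − δCB_rc) relative to a
built-in random-coil table (user-replaceable), optionally smoothed with a
1-2-1 window over residues (i−1, i, i+1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Structure

#: Random-coil CA/CB chemical shifts (ppm), standard published reference set.
#: Keys are three-letter residue codes; Gly has no CB.  Replace wholesale via
#: the ``random_coil`` argument of :func:`secondary_shifts` if another
#: reference is preferred.
RANDOM_COIL_CACB: dict[str, tuple[float, float | None]] = {
    "ALA": (52.5, 19.1), "ARG": (56.0, 30.9), "ASN": (53.1, 38.9),
    "ASP": (54.2, 41.1), "CYS": (58.2, 28.0), "GLN": (55.7, 29.4),
    "GLU": (56.6, 29.9), "GLY": (45.1, None), "HIS": (55.0, 29.0),
    "ILE": (61.1, 38.8), "LEU": (55.1, 42.4), "LYS": (56.2, 33.1),
    "MET": (55.4, 32.9), "PHE": (57.7, 39.6), "PRO": (63.3, 31.7),
    "SER": (58.3, 63.8), "THR": (61.8, 69.8), "TRP": (57.5, 29.6),
    "TYR": (57.9, 38.8), "VAL": (62.2, 32.9),
}


@dataclass
class CSPRecord:
    """Per-residue amide perturbation with line-broadening/overlap flags."""

    residue: int
    d_h: float | None = None      # Δδ(1H), ppm
    d_n: float | None = None      # Δδ(15N), ppm
    broadened: bool = False
    overlapped: bool = False

    @property
    def csp_hn(self) -> float | None:
        """Combined Δδ_HN; None for broadened-beyond-detection peaks."""
        if self.broadened or self.d_h is None or self.d_n is None:
            return None
        return csp(self.d_h, self.d_n)


def csp(dH: float, dN: float) -> float:
    """Combined amide chemical-shift perturbation sqrt(dH² + (0.2·dN)²), ppm."""
    if not (np.isfinite(dH) and np.isfinite(dN)):
        raise ValueError("CSP inputs must be finite")
    return float(np.sqrt(dH**2 + (0.2 * dN) ** 2))


def secondary_shifts(observed: pd.DataFrame,
                     random_coil: dict[str, tuple[float, float | None]] | None = None,
                     ) -> pd.Series:
    """Per-residue secondary shift ΔδCA − ΔδCB relative to random coil.

    ``observed`` needs columns residue, resname, nucleus (CA/CB), shift_ppm.
    Glycines (no CB) contribute their CA term only.  Residues whose type is
    absent from the random-coil table are excluded (counted as warnings via
    the returned series' attrs).
    """
    rc = random_coil if random_coil is not None else RANDOM_COIL_CACB
    out: dict[int, float] = {}
    n_warn = 0
    for resid, grp in observed.groupby("residue"):
        resname = str(grp["resname"].iloc[0]).upper()
        if resname not in rc:
            n_warn += 1
            continue
        ca_rc, cb_rc = rc[resname]
        shifts = {str(n): v for n, v in zip(grp["nucleus"], grp["shift_ppm"])}
        if "CA" not in shifts:
            n_warn += 1
            continue
        val = shifts["CA"] - ca_rc
        if cb_rc is not None and "CB" in shifts:
            val -= shifts["CB"] - cb_rc
        out[int(resid)] = val
    ser = pd.Series(out, dtype=float).sort_index()
    ser.attrs["n_excluded"] = n_warn
    return ser


def smooth_121(values: pd.Series) -> pd.Series:
    """1-2-1 smoothing over residues (i−1, i, i+1).

    At sequence gaps and termini the weights renormalize over the neighbors
    that exist, so a lone value passes through unchanged.
    """
    idx = values.index.to_numpy()
    v = values.to_numpy(dtype=float)
    out = np.empty_like(v)
    lookup = {int(i): k for k, i in enumerate(idx)}
    for k, i in enumerate(idx):
        num, den = 2.0 * v[k], 2.0
        for nb in (i - 1, i + 1):
            j = lookup.get(int(nb))
            if j is not None:
                num += v[j]
                den += 1.0
        out[k] = num / den
    return pd.Series(out, index=values.index)


def _corrected_stats(values: np.ndarray) -> tuple[float, float]:
    """Mean/SD after iterative exclusion of values above mean + 3·SD."""
    vals = np.asarray(values, dtype=float)
    while True:
        mu, sd = float(vals.mean()), float(vals.std(ddof=0))
        keep = vals <= mu + 3.0 * sd
        if keep.all():
            return mu, sd
        vals = vals[keep]


def significance_threshold(csps: list[CSPRecord], k: int = 1) -> float:
    """Significance cutoff: corrected mean + k·SD of the Δδ_HN distribution.

    "Corrected to zero" means outliers beyond mean + 3·SD are excluded
    iteratively before the final mean and SD are taken, so that the strongly
    perturbed residues do not inflate their own threshold.
    """
    vals = np.array([r.csp_hn for r in csps
                     if r.csp_hn is not None and not r.overlapped])
    if len(vals) < 5:
        raise ValueError("need at least 5 quantified CSP records")
    mu, sd = _corrected_stats(vals)
    return mu + k * sd


def select_active(csps: list[CSPRecord], threshold: float) -> set[int]:
    """Interface (active) residues: Δδ_HN above threshold, or broadened away.

    Overlapped records are unusable and never selected; the threshold is
    strict (a record exactly at the cutoff is excluded).
    """
    out: set[int] = set()
    for r in csps:
        if r.overlapped:
            continue
        if r.broadened:
            out.add(r.residue)
        elif r.csp_hn is not None and r.csp_hn > threshold:
            out.add(r.residue)
    return out


def select_passive(active: set[int], s: Structure, radius: float = 6.5,
                   chain: str | None = None) -> set[int]:
    """Surface neighbors of the active set.

    A residue is passive when it is not active and its CA lies within
    ``radius`` Å of any heavy atom of an active residue.
    """
    if not active or radius <= 0:
        return set()
    ch = chain if chain is not None else s.chains[0]
    sub = s.select(chain=ch)
    heavy = ~np.char.startswith(sub.atom.astype(str), "H")
    act_mask = np.isin(sub.resid, list(active)) & heavy
    if not act_mask.any():
        return set()
    act_xyz = sub.coord[act_mask]
    ca_mask = sub.atom == "CA"
    ca_res = sub.resid[ca_mask]
    ca_xyz = sub.coord[ca_mask]
    d = np.linalg.norm(ca_xyz[:, None, :] - act_xyz[None, :, :], axis=2)
    near = d.min(axis=1) <= radius
    return {int(r) for r in ca_res[near] if int(r) not in active}


# ---------------------------------------------------------------------------
# Delimited-text I/O

def read_shift_table(text: str) -> pd.DataFrame:
    """TSV with columns residue, resname, nucleus, shift_ppm[, condition]."""
    from io import StringIO
    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    required = {"residue", "resname", "nucleus", "shift_ppm"}
    if not required.issubset(df.columns):
        raise ValueError(f"shift table needs columns {sorted(required)}")
    return df


def write_csp_table(csps: list[CSPRecord]) -> str:
    rows = []
    for r in csps:
        rows.append({
            "residue": r.residue,
            "d_h_ppm": "" if r.d_h is None else f"{r.d_h:.4f}",
            "d_n_ppm": "" if r.d_n is None else f"{r.d_n:.4f}",
            "csp_hn_ppm": "" if r.csp_hn is None else f"{r.csp_hn:.4f}",
            "broadened": int(r.broadened),
            "overlapped": int(r.overlapped),
        })
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)
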