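"""Ligand-IDR contact analysis of MD trajectories.

A residue is in contact with the ligand in a frame when at least one heavy
(non-hydrogen) atom of that residue lies within the cutoff (default 6.0
Angstrom, inclusive) of a ligand heavy atom. The bound fraction fB is the
fraction of frames with at least one such contact anywhere in the protein.
Statistical errors come from Flyvbjerg-Petersen blocking analysis, which
is robust to the long autocorrelation of binding/unbinding kinetics.

For a single protein-ligand pair in a closed cubic box of side L the
simulated dissociation constant is

    K_D = C0 * (1 - fB)^2 / fB,   C0 = 1 / (N_A * L^3)

since [P] = [L] = (1 - fB) * C0 and [PL] = fB * C0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import N_A

from .datatypes import ContactMatrix

__all__ = [
    "contact_matrix",
    "ContactSummary",
    "contact_summary",
    "BlockingResult",
    "blocking_se",
    "KdEstimate",
    "simulated_kd",
]

_HEAVY_ELEMENTS = {"C", "N", "O", "S", "P", "F", "CL", "BR", "I", "NA", "K", "MG", "ZN"}


def _is_hydrogen(element: str, name: str) -> bool:
    el = (element or "").strip().upper()
    if el:
        return el == "H"
    return name.strip().lstrip("0123456789").upper().startswith("H")


def _read_text_frames(path: str | Path, n_atoms: int) -> np.ndarray:
    """Read a plain-text trajectory table (frame,atom,x,y,z in Angstrom)."""
    df = pd.read_csv(path)
    required = {"frame", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(f"text trajectory must have columns {sorted(required)}")
    frames = np.sort(df["frame"].unique())
    coords = np.empty((frames.size, n_atoms, 3), dtype=float)
    for i, f in enumerate(frames):
        sub = df[df["frame"] == f].sort_values("atom")
        if len(sub) != n_atoms:
            raise ValueError(
                f"frame {f} has {len(sub)} atoms, topology has {n_atoms}"
            )
        coords[i] = sub[["x", "y", "z"]].to_numpy()
    return coords


def contact_matrix(
    topology: str | Path,
    frames: str | Path,
    ligand_selection: str = "resname LIG",
    cutoff: float = 6.0,
    residue_range: tuple[int, int] | None = None,
    stride: int = 1,
) -> ContactMatrix:
    """Boolean frames x residues heavy-atom contact matrix.

    ``topology`` is a PDB; ``frames`` is any trajectory MDAnalysis reads
    (XTC, DCD, multi-model PDB) or a plain-text ``frame,atom,x,y,z`` CSV.
    ``ligand_selection`` is an MDAnalysis selection string; every residue
    outside it (optionally restricted to ``residue_range``, inclusive
    resids) becomes a contact-matrix column. The cutoff is inclusive
    (distance <= cutoff counts). Minimum-image periodic distances are used
    whenever the trajectory carries box vectors.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.distances import distance_array

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = Path(frames)
    text_mode = frames.suffix.lower() in {".csv", ".txt"}
    if text_mode:
        u = mda.Universe(str(topology))
    else:
        u = mda.Universe(str(topology), str(frames))

    lig = u.select_atoms(ligand_selection)
    if lig.n_atoms == 0:
        raise ValueError(f"ligand selection {ligand_selection!r} matched no atoms")
    try:
        elements = [a.element for a in u.atoms]
    except Exception:
        elements = ["" for _ in u.atoms]
    names = [a.name for a in u.atoms]
    heavy = np.array(
        [not _is_hydrogen(elements[i], names[i]) for i in range(u.atoms.n_atoms)]
    )

    lig_idx = np.array([i for i in lig.indices if heavy[i]], dtype=int)
    if lig_idx.size == 0:
        raise ValueError("ligand selection contains no heavy atoms")
    lig_set = set(lig.indices.tolist())
    res_groups: list[tuple[int, np.ndarray]] = []
    for res in u.residues:
        idx = [i for i in res.atoms.indices if i not in lig_set and heavy[i]]
        if not idx:
            continue
        if residue_range is not None and not (
            residue_range[0] <= res.resid <= residue_range[1]
        ):
            continue
        res_groups.append((int(res.resid), np.array(idx, dtype=int)))
    if not res_groups:
        raise ValueError("no protein residues with heavy atoms selected")
    residue_ids = np.array([r for r, _ in res_groups])

    def frame_contacts(coords: np.ndarray, box) -> np.ndarray:
        row = np.zeros(len(res_groups), dtype=bool)
        lig_pos = coords[lig_idx]
        for j, (_, idx) in enumerate(res_groups):
            d = distance_array(lig_pos, coords[idx], box=box)
            row[j] = bool(d.min() <= cutoff)
        return row

    rows = []
    if text_mode:
        coords = _read_text_frames(frames, u.atoms.n_atoms)
        for f in range(0, coords.shape[0], stride):
            rows.append(frame_contacts(coords[f], None))
    else:
        for ts in u.trajectory[::stride]:
            box = ts.dimensions if ts.dimensions is not None and ts.dimensions[:3].all() else None
            rows.append(frame_contacts(ts.positions.astype(float), box))
    return ContactMatrix(np.array(rows, dtype=bool), residue_ids, cutoff=cutoff)


@dataclass
class BlockingResult:
    """Flyvbjerg-Petersen blocking error estimate with the full curve."""

    se: float
    level: int
    curve: pd.DataFrame  # columns: level, n_blocks, se, se_uncertainty


def blocking_se(series: np.ndarray) -> BlockingResult:
    """Standard error of the mean of a correlated series by blocking.

    The series is repeatedly pair-averaged; at each level the naive s.e.
    ``sqrt(var / n_blocks)`` is recorded together with its own sampling
    uncertainty ``se / sqrt(2 (n_blocks - 1))``. The reported s.e. is the
    first level whose increase over the previous level is within that
    uncertainty (the plateau); the conservative fallback is the maximum
    s.e. over levels retaining >= 32 blocks.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 16:
        raise ValueError("blocking analysis needs >= 16 samples")
    levels = []
    level = 0
    while x.size >= 4:
        n = x.size
        var = x.var(ddof=1)
        se = math.sqrt(var / n)
        dse = se / math.sqrt(2.0 * (n - 1))
        levels.append((level, n, se, dse))
        m = (n // 2) * 2
        x = 0.5 * (x[0:m:2] + x[1:m:2])
        level += 1
    curve = pd.DataFrame(levels, columns=["level", "n_blocks", "se", "se_uncertainty"])
    ses = curve["se"].to_numpy()
    dses = curve["se_uncertainty"].to_numpy()
    if np.all(ses == 0):
        return BlockingResult(0.0, 0, curve)
    chosen = None
    for k in range(len(ses) - 1):
        if ses[k + 1] - ses[k] <= dses[k + 1]:
            chosen = k
            break
    if chosen is None:
        eligible = curve[curve["n_blocks"] >= 32]
        chosen = int(eligible["se"].idxmax()) if not eligible.empty else len(ses) - 1
    return BlockingResult(float(ses[chosen]), int(chosen), curve)


@dataclass
class ContactSummary:
    """Per-residue contact probabilities and bound fraction with blocking
    standard errors. Invariant: fB >= max_i p_i (a frame with any contact
    is bound)."""

    residue_ids: np.ndarray
    p: np.ndarray
    p_se: np.ndarray
    fB: float
    fB_se: float
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"resid": self.residue_ids, "contact_probability": self.p, "se": self.p_se}
        )


def contact_summary(cm: ContactMatrix) -> ContactSummary:
    """Column means (per-residue contact probability) and bound fraction
    (fraction of frames with any contact), with blocking errors."""
    if cm.n_frames < 16:
        raise ValueError("need >= 16 frames for blocking errors")
    c = cm.contacts.astype(float)
    p = c.mean(axis=0)
    p_se = np.array([blocking_se(c[:, j]).se for j in range(c.shape[1])])
    bound = cm.contacts.any(axis=1).astype(float)
    fb = float(bound.mean())
    fb_se = blocking_se(bound).se
    return ContactSummary(cm.residue_ids, p, p_se, fb, fb_se, cm.n_frames)


@dataclass
class KdEstimate:
    """Single-pair closed-box dissociation constant."""

    box_length_nm: float
    C0_M: float
    KD_M: float
    KD_se_M: float | None
    fB: float

    @property
    def C0_mM(self) -> float:
        return self.C0_M * 1e3

    @property
    def KD_mM(self) -> float:
        return self.KD_M * 1e3

    @property
    def KD_se_mM(self) -> float | None:
        return None if self.KD_se_M is None else self.KD_se_M * 1e3


def simulated_kd(fB: float, box_length: float, fB_se: float | None = None) -> KdEstimate:
    """K_D from the bound fraction of a single pair in a cubic box.

    ``box_length`` in nm. The reference concentration of one molecule in
    the box is ``C0 = 1 / (N_A * L^3)`` (molar); with a single pair,
    ``[P] = [L] = (1 - fB) * C0`` and ``[PL] = fB * C0``, so
    ``K_D = C0 * (1 - fB)^2 / fB``. The standard error propagates by the
    delta method: ``dK_D/dfB = C0 * (1 - 1/fB^2)``.
    """
    if not 0 < fB < 1:
        raise ValueError("fB must be strictly between 0 and 1")
    if box_length <= 0:
        raise ValueError("box_length must be positive (nm)")
    L_dm = box_length * 1e-8  # nm -> dm, so L^3 is in liters
    C0 = 1.0 / (N_A * L_dm**3)
    kd = C0 * (1 - fB) ** 2 / fB
    se = None
    if fB_se is not None:
        se = abs(C0 * (1.0 - 1.0 / fB**2)) * fB_se
    return KdEstimate(
        box_length_nm=float(box_length),
        C0_M=float(C0),
        KD_M=float(kd),
        KD_se_M=None if se is None else float(se),
        fB=float(fB),
    )
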