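"""Synthetic data generators with known ground truth.

Every generator is a pure function of its arguments, including ``seed``:
calling twice with the same arguments reproduces outputs bit-identically.
Each returns the dataset together with a :class:`~condensakit.datatypes.GroundTruth`
carrying the true parameters, so every downstream estimator in the package
can be validated by parameter recovery rather than against opaque fixtures.

Noise is additive Gaussian throughout. The generators emulate the study
conditions of androgen-receptor condensate experiments: nuclei with
controllable intensity clustering (granularity), cytosolic condensate
time-lapses, FRAP traces with acquisition bleaching, sigmoidal turbidity
ramps, two-state ligand-binding contact trajectories, and log-logistic
dose-response tables.
"""
from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .datatypes import ContactMatrix, Curve, GroundTruth, ImageStack, TimeTrace

__all__ = [
    "PlacementError",
    "gen_nuclei_field",
    "gen_condensate_timelapse",
    "gen_frap_trace",
    "gen_turbidity_curve",
    "gen_contact_trajectory",
    "gen_coordinate_frames",
    "gen_dose_response",
]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed without overlap in the field."""


def _to_uint(img: np.ndarray, bit_depth: int) -> np.ndarray:
    hi = 2**bit_depth - 1
    return np.clip(np.rint(img), 0, hi).astype(np.uint16 if bit_depth == 16 else np.uint8)


def _place_nonoverlapping(rng, shape, n, radii_y, radii_x, margin=4, max_tries=5000):
    """Random non-overlapping ellipse centers; raises PlacementError on failure."""
    H, W = shape
    centers: list[tuple[float, float]] = []
    for i in range(n):
        ry, rx = radii_y[i], radii_x[i]
        for attempt in range(max_tries):
            cy = rng.uniform(ry + margin, H - ry - margin)
            cx = rng.uniform(rx + margin, W - rx - margin)
            ok = True
            for j, (oy, ox) in enumerate(centers):
                min_sep = max(ry, rx) + max(radii_y[j], radii_x[j]) + margin
                if (cy - oy) ** 2 + (cx - ox) ** 2 < min_sep**2:
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{n} without overlap in a "
                f"{H}x{W} field"
            )
    return centers


def gen_nuclei_field(
    n_nuclei: int,
    mean_intensity: float = 8000.0,
    cluster_count: int = 20,
    cluster_contrast: float = 1.0,
    psf_sigma: float = 1.0,
    noise_sd: float = 100.0,
    pixel_size: float = 100.0,
    seed: int = 0,
    shape: tuple[int, int] = (512, 512),
    nucleus_radius: float = 30.0,
    spot_sigma: float = 2.0,
) -> tuple[ImageStack, GroundTruth]:
    """Field of elliptical nuclei with Gaussian intracluster bright spots.

    Emulates fluorescence images of nuclei expressing a tagged transcription
    factor that forms sub-resolution clusters: each nucleus gets
    ``cluster_count`` Gaussian spots of amplitude
    ``cluster_contrast * mean_intensity``, raising the within-nucleus
    intensity s.d. (the granularity statistic) above the noise floor.

    Returns the 16-bit image and a GroundTruth whose ``extras`` carry the
    integer ``label_mask`` (pre-blur ellipse masks, label i+1 for nucleus i)
    and a ``spots`` array of (nucleus, y, x) spot centers.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if cluster_contrast < 0:
        raise ValueError("cluster_contrast must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    ry = rng.uniform(0.8 * nucleus_radius, 1.2 * nucleus_radius, n_nuclei)
    rx = rng.uniform(0.8 * nucleus_radius, 1.2 * nucleus_radius, n_nuclei)
    centers = _place_nonoverlapping(rng, shape, n_nuclei, ry, rx)

    img = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:H, 0:W]
    spots = []
    for i, (cy, cx) in enumerate(centers):
        mask = ((yy - cy) / ry[i]) ** 2 + ((xx - cx) / rx[i]) ** 2 <= 1.0
        labels[mask] = i + 1
        img[mask] += mean_intensity
        amp = cluster_contrast * mean_intensity
        for _ in range(cluster_count):
            # rejection-sample a spot center inside the ellipse
            while True:
                sy = rng.uniform(cy - ry[i], cy + ry[i])
                sx = rng.uniform(cx - rx[i], cx + rx[i])
                if ((sy - cy) / ry[i]) ** 2 + ((sx - cx) / rx[i]) ** 2 <= 0.8:
                    break
            if amp > 0:
                img += amp * np.exp(
                    -((yy - sy) ** 2 + (xx - sx) ** 2) / (2 * spot_sigma**2)
                )
            spots.append((i + 1, sy, sx))
    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    pixels = _to_uint(img, 16)

    gt = GroundTruth(
        params={
            "n_nuclei": n_nuclei,
            "mean_intensity": mean_intensity,
            "cluster_count": cluster_count,
            "cluster_contrast": cluster_contrast,
            "noise_sd": noise_sd,
            "psf_sigma": psf_sigma,
        },
        seed=seed,
        extras={
            "label_mask": labels,
            "spots": np.array(spots, dtype=float).reshape(-1, 3),
            "centers": np.array(centers, dtype=float).reshape(-1, 2),
        },
    )
    return ImageStack.from_2d(pixels, pixel_size), gt


def _rasterize_disk(shape, cy, cx, r):
    H, W = shape
    y0, y1 = max(0, int(cy - r) - 1), min(H, int(cy + r) + 2)
    x0, x1 = max(0, int(cx - r) - 1), min(W, int(cx + r) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    sub = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    mask = np.zeros(shape, dtype=bool)
    mask[y0:y1, x0:x1] = sub
    return mask


def gen_condensate_timelapse(
    n_cells: int = 3,
    rate_nucleation: float = 1.0,
    growth_rate: float = 2.0,
    timepoints: int = 10,
    seed: int = 0,
    dt_min: float = 5.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 200.0,
    cell_radius: float = 70.0,
    nucleus_radius: float = 28.0,
    initial_area: float = 12.0,
    cytosol_intensity: float = 1500.0,
    condensate_intensity: float = 12000.0,
    noise_sd: float = 50.0,
) -> tuple[ImageStack, GroundTruth]:
    """Time-lapse of cytosolic droplets nucleating and growing in cells.

    Emulates cytoplasmic condensates in cells expressing a receptor whose
    nuclear import is disabled: droplets nucleate in the cytosol at
    ``rate_nucleation`` per cell per minute, grow linearly in area at
    ``growth_rate`` px^2 per minute, and never appear inside the nucleus.

    GroundTruth extras: ``nuclear_mask`` (bool), ``cell_mask`` (bool),
    ``events`` table of (frame, cy, cx, radius_px, raster_area_px) per
    condensate per frame, and per-frame ``counts``.
    """
    if timepoints < 1:
        raise ValueError("timepoints must be >= 1")
    if rate_nucleation < 0 or growth_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    centers = _place_nonoverlapping(
        rng, shape, n_cells, [cell_radius] * n_cells, [cell_radius] * n_cells
    )
    yy, xx = np.mgrid[0:H, 0:W]
    cell_mask = np.zeros(shape, dtype=bool)
    nuc_mask = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        cell_mask |= d2 <= cell_radius**2
        nuc_mask |= d2 <= nucleus_radius**2

    # droplets: born at Poisson times, live to the end, grow linearly
    droplets = []  # (birth_frame, cy, cx)
    for t in range(timepoints):
        for cy, cx in centers:
            n_new = rng.poisson(rate_nucleation * dt_min)
            for _ in range(n_new):
                for _attempt in range(200):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = rng.uniform(nucleus_radius + 8, cell_radius - 8)
                    dy, dx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                    max_r = math.sqrt(
                        (initial_area + growth_rate * dt_min * (timepoints - t)) / math.pi
                    )
                    if all(
                        (dy - oy) ** 2 + (dx - ox) ** 2 > (2 * max_r + 2) ** 2
                        for _, oy, ox in droplets
                    ):
                        droplets.append((t, dy, dx))
                        break

    frames = np.zeros((timepoints, H, W), dtype=np.uint16)
    events = []
    counts = np.zeros(timepoints, dtype=int)
    for t in range(timepoints):
        img = np.where(cell_mask, cytosol_intensity, 0.0)
        for birth, dy, dx in droplets:
            if birth > t:
                continue
            area = initial_area + growth_rate * dt_min * (t - birth)
            r = math.sqrt(area / math.pi)
            mask = _rasterize_disk(shape, dy, dx, r)
            img[mask] = condensate_intensity
            events.append((t, dy, dx, r, int(mask.sum())))
            counts[t] += 1
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, shape)
        frames[t] = _to_uint(img, 16)

    pixels = frames[:, None, :, :, None]
    gt = GroundTruth(
        params={
            "n_cells": n_cells,
            "rate_nucleation": rate_nucleation,
            "growth_rate": growth_rate,
            "dt_min": dt_min,
            "cytosol_intensity": cytosol_intensity,
            "condensate_intensity": condensate_intensity,
        },
        seed=seed,
        extras={
            "nuclear_mask": nuc_mask,
            "cell_mask": cell_mask,
            "events": np.array(events, dtype=float).reshape(-1, 5),
            "counts": counts,
        },
    )
    return ImageStack(pixels, pixel_size), gt


def gen_frap_trace(
    mobile_fraction: float = 0.94,
    t_half: float = 2.29,
    bleach_depth: float = 0.8,
    acq_bleach_rate: float = 0.0,
    noise_sd: float = 0.0,
    n_pre: int = 20,
    n_post: int = 200,
    dt: float = 0.18,
    seed: int = 0,
    signal: float = 1000.0,
    whole_cell: float = 5000.0,
    background: float = 100.0,
) -> tuple[dict[str, TimeTrace], GroundTruth]:
    """FRAP trace triple (bleach ROI, whole cell, background).

    Defaults follow a spinning-disk bleaching protocol: 20 pre-bleach and
    200 post-bleach frames at 180 ms intervals. Post-bleach recovery in the
    bleached ROI follows ``I(t) = I0 + (Finf - I0)(1 - exp(-k t))`` with
    ``k = ln 2 / t_half``, ``I0 = 1 - bleach_depth`` and
    ``Finf = I0 + mobile_fraction * bleach_depth``. The whole trace is
    multiplied by acquisition bleaching ``exp(-acq_bleach_rate * t_acq)``
    (affecting bleach and whole-cell ROIs equally, so double normalization
    cancels it exactly) and offset by a constant background. The whole-cell
    ROI is treated as unaffected by the spot bleach itself.
    """
    if not 0 <= mobile_fraction <= 1:
        raise ValueError("mobile_fraction must be in [0, 1]")
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if not 0 <= bleach_depth <= 1:
        raise ValueError("bleach_depth must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t_pre = (np.arange(n_pre) - n_pre) * dt  # ..., -2dt, -dt
    t_post = np.arange(n_post) * dt  # 0 at first post-bleach frame
    t = np.concatenate([t_pre, t_post])
    k = math.log(2) / t_half
    i0 = 1.0 - bleach_depth
    f_inf = i0 + mobile_fraction * bleach_depth
    rel = np.where(t < 0, 1.0, i0 + (f_inf - i0) * (1.0 - np.exp(-k * np.maximum(t, 0))))
    acq = np.exp(-acq_bleach_rate * (t - t[0]))
    bleach = background + signal * rel * acq
    whole = background + whole_cell * acq
    bg = np.full_like(t, background)
    if noise_sd > 0:
        bleach = bleach + rng.normal(0, noise_sd, t.size)
        whole = whole + rng.normal(0, noise_sd, t.size)
        bg = bg + rng.normal(0, noise_sd, t.size)
    traces = {
        "bleach": TimeTrace(t, bleach, "bleach"),
        "whole": TimeTrace(t, whole, "whole"),
        "background": TimeTrace(t, bg, "background"),
    }
    gt = GroundTruth(
        params={
            "true_mobile_fraction": mobile_fraction,
            "true_t_half": t_half,
            "bleach_depth": bleach_depth,
            "acq_bleach_rate": acq_bleach_rate,
            "noise_sd": noise_sd,
            "dt": dt,
        },
        seed=seed,
    )
    return traces, gt


def gen_turbidity_curve(
    true_Tc: float = 34.0,
    width: float = 1.0,
    baseline: float = 0.05,
    amplitude: float = 0.8,
    T_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Curve, GroundTruth]:
    """Sigmoidal A340-vs-temperature turbidity ramp with LCST orientation.

    ``y(T) = baseline + amplitude * logistic((T - true_Tc) / width)``; the
    logistic midpoint, inflection and first-derivative maximum all coincide
    at ``true_Tc`` (the cloud point). Absorbance rises with temperature, as
    for a solution that demixes on heating.
    """
    if T_grid is None:
        T_grid = np.arange(20.0, 50.0 + 1e-9, 0.2)
    T = np.asarray(T_grid, dtype=float)
    if T.size >= 2 and not np.all(np.diff(T) > 0):
        raise ValueError("T_grid must be strictly increasing")
    rng = np.random.default_rng(seed)
    y = baseline + amplitude * expit((T - true_Tc) / width)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, T.size)
    in_range = bool(T.min() <= true_Tc <= T.max())
    gt = GroundTruth(
        params={
            "true_Tc": true_Tc,
            "width": width,
            "baseline": baseline,
            "amplitude": amplitude,
            "noise_sd": noise_sd,
            "tc_in_range": float(in_range),
        },
        seed=seed,
    )
    return Curve(T, y, meta={"kind": "turbidity"}), gt


def gen_contact_trajectory(
    n_frames: int,
    n_residues: int,
    p_stay_bound: float = 0.95,
    p_stay_unbound: float = 0.95,
    residue_profile: np.ndarray | None = None,
    seed: int = 0,
    start_state: int | None = None,
) -> tuple[ContactMatrix, GroundTruth]:
    """Two-state (bound/unbound) Markov contact trajectory.

    A latent Markov chain alternates between bound and unbound states with
    the given self-transition probabilities. In bound frames residue ``i``
    registers a contact with probability ``residue_profile[i]``; unbound
    frames have no contacts. The stationary bound fraction is
    ``fB* = (1 - p_stay_unbound) / ((1 - p_stay_bound) + (1 - p_stay_unbound))``
    and the chain's lag-1 autocorrelation is
    ``rho = p_stay_bound + p_stay_unbound - 1`` with integrated
    autocorrelation time ``tau = rho / (1 - rho)``.

    If every profile entry is < 1, a latent-bound frame can emit zero
    contacts, so the observed bound fraction (any contact) is
    ``fB* * (1 - prod(1 - p_i))``; GroundTruth stores both.

    ``start_state=None`` draws the initial state from the stationary
    distribution; pass 1 (bound) or 0 (unbound) to pin it.
    """
    for p in (p_stay_bound, p_stay_unbound):
        if not 0 <= p <= 1:
            raise ValueError("transition probabilities must be in [0, 1]")
    if residue_profile is None:
        residue_profile = np.full(n_residues, 0.5)
        residue_profile[0] = 1.0
    profile = np.asarray(residue_profile, dtype=float)
    if profile.size != n_residues:
        raise ValueError("residue_profile length must equal n_residues")
    rng = np.random.default_rng(seed)
    a, b = 1 - p_stay_bound, 1 - p_stay_unbound  # leave-bound, leave-unbound
    if a + b == 0:
        fb_star = 0.5 if start_state is None else float(start_state)
    else:
        fb_star = b / (a + b)
    state = (
        int(rng.random() < fb_star) if start_state is None else int(start_state)
    )
    # vectorised chain: draw all uniforms, then scan
    u = rng.random(n_frames)
    states = np.empty(n_frames, dtype=bool)
    for i in range(n_frames):
        states[i] = state
        stay = p_stay_bound if state else p_stay_unbound
        if u[i] >= stay:
            state = 1 - state
    contacts = np.zeros((n_frames, n_residues), dtype=bool)
    bound_idx = np.nonzero(states)[0]
    if bound_idx.size:
        contacts[bound_idx] = rng.random((bound_idx.size, n_residues)) < profile
    rho = p_stay_bound + p_stay_unbound - 1
    tau = rho / (1 - rho) if rho < 1 else np.inf
    fb_observed = fb_star * (1 - np.prod(1 - profile))
    gt = GroundTruth(
        params={
            "true_fB": fb_star,
            "true_fB_observed": fb_observed,
            "lag1_autocorr": rho,
            "autocorr_time": tau,
        },
        seed=seed,
        extras={"states": states, "residue_profile": profile},
    )
    cm = ContactMatrix(contacts, residue_ids=np.arange(1, n_residues + 1))
    return cm, gt


_DEFAULT_PROTEIN = [
    # (resid, resname, name, element, x, y, z)
    (1, "ALA", "CA", "C", 0.0, 0.0, 0.0),
    (1, "ALA", "HA", "H", 0.0, 1.0, 0.0),
    (2, "GLY", "CA", "C", 4.0, 0.0, 0.0),
    (2, "GLY", "HA", "H", 4.0, 1.0, 0.0),
    (3, "SER", "CA", "C", 8.0, 0.0, 0.0),
    (3, "SER", "HA", "H", 8.0, 1.0, 0.0),
]
_DEFAULT_LIGAND = [
    (10, "LIG", "C1", "C", 0.0, 0.0, 0.0),
    (10, "LIG", "H1", "H", 0.0, -1.0, 0.0),
]


def gen_coordinate_frames(
    n_frames: int,
    outdir: str | Path,
    protein_atoms: list[tuple] | None = None,
    ligand_atoms: list[tuple] | None = None,
    bound_geometry: tuple[float, float, float] = (4.0, 0.0, 5.0),
    unbound_geometry: tuple[float, float, float] = (4.0, 0.0, 30.0),
    bound_pattern: str | np.ndarray = "alternate",
    seed: int = 0,
    traj_format: str = "text",
) -> tuple[dict[str, Path], GroundTruth]:
    """Write a toy topology (PDB) plus trajectory with known bound frames.

    The ligand alternates (or follows ``bound_pattern``, a boolean array)
    between a pose whose heavy atom sits 5.0 Angstrom from residue 2's CA
    (bound: within the 6.0 Angstrom contact cutoff) and a pose > 20 Angstrom
    from every protein heavy atom (unbound). Hydrogens are placed closer
    than the heavy atoms in the bound pose so contact analyses that fail to
    exclude them are caught.

    ``traj_format``: ``"text"`` writes a ``frame,atom,x,y,z`` CSV;
    ``"pdb"`` writes a multi-model PDB readable by standard MD readers.
    """
    protein = protein_atoms if protein_atoms is not None else _DEFAULT_PROTEIN
    ligand = ligand_atoms if ligand_atoms is not None else _DEFAULT_LIGAND
    for rec in list(protein) + list(ligand):
        if str(rec[3]).strip().upper() not in {
            "H", "C", "N", "O", "S", "P", "F", "CL", "BR", "I",
        }:
            raise ValueError(f"unknown element symbol: {rec[3]!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if isinstance(bound_pattern, str):
        if bound_pattern == "alternate":
            bound = np.arange(n_frames) % 2 == 0
        elif bound_pattern == "bound":
            bound = np.ones(n_frames, dtype=bool)
        elif bound_pattern == "unbound":
            bound = np.zeros(n_frames, dtype=bool)
        else:
            raise ValueError(f"unknown bound_pattern {bound_pattern!r}")
    else:
        bound = np.asarray(bound_pattern, dtype=bool)
        if bound.size != n_frames:
            raise ValueError("bound_pattern length must equal n_frames")

    def frame_coords(is_bound: bool) -> np.ndarray:
        off = np.array(bound_geometry if is_bound else unbound_geometry)
        prot = np.array([[r[4], r[5], r[6]] for r in protein])
        lig = np.array([[r[4], r[5], r[6]] for r in ligand]) + off
        return np.vstack([prot, lig])

    atoms = list(protein) + list(ligand)
    top_path = outdir / "topology.pdb"
    with open(top_path, "w") as fh:
        coords0 = frame_coords(bool(bound[0])) if n_frames else frame_coords(True)
        for i, rec in enumerate(atoms):
            resid, resname, name, element = rec[0], rec[1], rec[2], rec[3]
            x, y, z = coords0[i]
            fh.write(
                f"ATOM  {i + 1:5d} {name:<4s} {resname:>3s} A{resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{str(element).upper():>2s}\n"
            )
        fh.write("END\n")

    if traj_format == "text":
        traj_path = outdir / "frames.csv"
        with open(traj_path, "w") as fh:
            fh.write("frame,atom,x,y,z\n")
            for f in range(n_frames):
                coords = frame_coords(bool(bound[f]))
                for i in range(len(atoms)):
                    x, y, z = coords[i]
                    fh.write(f"{f},{i},{x:.4f},{y:.4f},{z:.4f}\n")
    elif traj_format == "pdb":
        traj_path = outdir / "frames.pdb"
        with open(traj_path, "w") as fh:
            for f in range(n_frames):
                fh.write(f"MODEL     {f + 1:4d}\n")
                coords = frame_coords(bool(bound[f]))
                for i, rec in enumerate(atoms):
                    resid, resname, name, element = rec[0], rec[1], rec[2], rec[3]
                    x, y, z = coords[i]
                    fh.write(
                        f"ATOM  {i + 1:5d} {name:<4s} {resname:>3s} A{resid:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                        f"{str(element).upper():>2s}\n"
                    )
                fh.write("ENDMDL\n")
            fh.write("END\n")
    else:
        raise ValueError("traj_format must be 'text' or 'pdb'")

    gt = GroundTruth(
        params={"true_fB": float(bound.mean()) if n_frames else 0.0},
        seed=seed,
        extras={"bound_frames": bound},
    )
    return {"topology": top_path, "trajectory": traj_path}, gt


def gen_dose_response(
    true_IC50: float = 1.5,
    hill_b: float = 1.0,
    upper_d: float = 100.0,
    doses: np.ndarray | None = None,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Curve, GroundTruth]:
    """Dose-response table from a three-parameter log-logistic model.

    Responses follow ``f(x) = d / (1 + exp(b * (ln x - ln e)))`` with lower
    limit 0 (e.g. viable-nucleus counts under increasing inhibitor dose):
    ``e`` is the IC50 and ``b`` the hill slope (b > 0 for inhibition).
    """
    if true_IC50 <= 0 or upper_d <= 0:
        raise ValueError("true_IC50 and upper_d must be positive")
    if doses is None:
        doses = true_IC50 * np.logspace(-2, 2, 8)
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be >= 0 (zero allowed for controls)")
    rng = np.random.default_rng(seed)
    x = np.tile(doses, replicates)
    rep = np.repeat(np.arange(replicates), doses.size)
    with np.errstate(divide="ignore"):
        y = np.where(
            x > 0,
            upper_d / (1 + np.exp(hill_b * (np.log(np.where(x > 0, x, 1.0)) - math.log(true_IC50)))),
            upper_d if hill_b > 0 else 0.0,
        )
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, x.size)
    gt = GroundTruth(
        params={
            "true_IC50": true_IC50,
            "true_hill_b": hill_b,
            "true_upper_d": upper_d,
            "noise_sd": noise_sd,
        },
        seed=seed,
    )
    return Curve(x, y, replicate=rep, meta={"kind": "dose_response"}), gt
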