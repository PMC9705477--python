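"""Single-chain conformational observables.

Compactness and contact observables used to compare polymer conformations
across solution conditions: radius of gyration (Rg), end-to-end distance
(dee), their ensemble distributions, intramolecular contact-frequency maps,
and geometric hydrogen-bond counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from coacerlab.errors import InputError, ParameterError

__all__ = [
    "ChainEnsemble",
    "radius_of_gyration",
    "end_to_end",
    "ensemble_distributions",
    "compare_ensembles",
    "contact_map",
    "hbond_count",
    "ensemble_from_trajectory",
]


@dataclass
class ChainEnsemble:
    """Frames of per-site coordinates (nm) for one chain.

    ``terminal_indices`` mark the sites used for the end-to-end distance
    (default: first and last site, the backbone-terminus convention).
    """

    frames: np.ndarray  # (n_frames, n_sites, 3)
    masses: np.ndarray | None = None
    terminal_indices: tuple[int, int] | None = None
    labels: list[str] | None = None
    ground_truth: Any = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise InputError("frames must have shape (n_frames, n_sites, 3)")
        n_sites = self.frames.shape[1]
        if self.masses is None:
            self.masses = np.ones(n_sites)
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.masses) != n_sites:
            raise InputError("one mass per site required")
        if np.any(self.masses <= 0):
            raise InputError("masses must be positive")
        if self.terminal_indices is None:
            self.terminal_indices = (0, n_sites - 1)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_sites(self) -> int:
        return self.frames.shape[1]


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration of one frame, in the input units."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise InputError("need at least 2 sites")
    if masses is None:
        masses = np.ones(coords.shape[0])
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise InputError("total mass must be positive")
    com = (masses[:, None] * coords).sum(axis=0) / total
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt(np.sum(masses * d2) / total))


def end_to_end(
    coords: np.ndarray,
    terminal_indices: tuple[int, int] = (0, -1),
    box: np.ndarray | None = None,
) -> float:
    """Distance between the two terminal sites (minimum-image if boxed)."""
    i, j = terminal_indices
    coords = np.asarray(coords, dtype=float)
    if i % coords.shape[0] == j % coords.shape[0]:
        raise InputError("terminal indices must be distinct")
    d = coords[j] - coords[i]
    if box is not None:
        box = np.asarray(box, dtype=float)
        d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def _freedman_diaconis_bins(x: np.ndarray) -> int:
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr <= 0:
        return 1
    width = 2 * iqr / len(x) ** (1 / 3)
    return max(1, int(np.ceil((x.max() - x.min()) / width)))


def _series(ensemble: ChainEnsemble) -> tuple[np.ndarray, np.ndarray]:
    rg = np.array(
        [radius_of_gyration(f, ensemble.masses) for f in ensemble.frames]
    )
    dee = np.array(
        [end_to_end(f, ensemble.terminal_indices) for f in ensemble.frames]
    )
    return rg, dee


def ensemble_distributions(
    ensemble: ChainEnsemble,
    bins: int | str = "fd",
    min_frames: int = 30,
) -> dict:
    """Normalized Rg and dee distributions plus summary statistics.

    Histograms are probability densities (integrate to 1); the bin rule is
    Freedman–Diaconis unless an explicit bin count is given.
    """
    if ensemble.n_frames < min_frames:
        raise InputError(
            f"need >= {min_frames} frames to histogram, got {ensemble.n_frames}"
        )
    rg, dee = _series(ensemble)
    out = {}
    for name, x in (("rg", rg), ("dee", dee)):
        nb = _freedman_diaconis_bins(x) if bins == "fd" else int(bins)
        if np.ptp(x) == 0:  # point mass: histogram on a degenerate support
            edges = np.array([x[0] - 0.5, x[0] + 0.5])
            density = np.array([1.0])
        else:
            density, edges = np.histogram(x, bins=nb, density=True)
        out[name] = {
            "density": density,
            "edges": edges,
            "mean": float(x.mean()),
            "mode": float(edges[np.argmax(density)]),
            "series": x,
        }
    return out


def compare_ensembles(
    a: ChainEnsemble,
    b: ChainEnsemble,
    observable: str = "rg",
    n_boot: int = 2000,
    ci: float = 0.95,
    seed: int = 0,
) -> dict:
    """Difference of means (a − b) for Rg or dee with a bootstrap CI."""
    if observable not in ("rg", "dee"):
        raise ParameterError("observable must be 'rg' or 'dee'")
    xa = _series(a)[0 if observable == "rg" else 1]
    xb = _series(b)[0 if observable == "rg" else 1]
    diff = float(xa.mean() - xb.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (
            rng.choice(xa, len(xa)).mean() - rng.choice(xb, len(xb)).mean()
        )
    lo, hi = np.quantile(boots, [(1 - ci) / 2, (1 + ci) / 2])
    return {"difference": diff, "ci": (float(lo), float(hi)), "level": ci}


def contact_map(
    ensemble: ChainEnsemble,
    cutoff_nm: float = 0.6,
    min_sequence_separation: int = 3,
) -> np.ndarray:
    """Intramolecular contact frequencies across the ensemble.

    Entry (i, j) is the fraction of frames in which sites i and j are within
    ``cutoff_nm``; pairs closer in sequence than ``min_sequence_separation``
    are zeroed (trivially in contact through bonding).
    """
    if cutoff_nm <= 0:
        raise ParameterError("cutoff must be positive")
    if min_sequence_separation < 1:
        raise ParameterError("min_sequence_separation must be >= 1")
    n = ensemble.n_sites
    freq = np.zeros((n, n))
    for frame in ensemble.frames:
        d = np.linalg.norm(frame[:, None, :] - frame[None, :, :], axis=2)
        freq += d <= cutoff_nm
    freq /= ensemble.n_frames
    i, j = np.indices((n, n))
    freq[np.abs(i - j) < min_sequence_separation] = 0.0
    return freq


def hbond_count(
    donor_positions: np.ndarray,
    hydrogen_positions: np.ndarray,
    acceptor_positions: np.ndarray,
    d_cut_nm: float = 0.35,
    angle_cut_deg: float = 30.0,
) -> int:
    """Geometric hydrogen-bond count for one frame.

    A donor/hydrogen pair and an acceptor form a bond when the donor–acceptor
    distance is <= ``d_cut_nm`` and the D–H–A angle is within
    ``angle_cut_deg`` of linear (180°). Donors and their hydrogens are given
    as parallel arrays (one row per D–H pair).
    """
    donors = np.atleast_2d(np.asarray(donor_positions, dtype=float))
    hydrogens = np.atleast_2d(np.asarray(hydrogen_positions, dtype=float))
    acceptors = np.asarray(acceptor_positions, dtype=float).reshape(-1, 3)
    if donors.shape != hydrogens.shape:
        raise InputError("each donor needs a matching hydrogen position")
    if len(acceptors) == 0:
        return 0
    count = 0
    cos_cut = np.cos(np.deg2rad(180.0 - angle_cut_deg))
    for d_pos, h_pos in zip(donors, hydrogens):
        da = acceptors - d_pos
        dist = np.linalg.norm(da, axis=1)
        close = dist <= d_cut_nm
        if not np.any(close):
            continue
        hd = d_pos - h_pos
        ha = acceptors[close] - h_pos
        nhd = np.linalg.norm(hd)
        nha = np.linalg.norm(ha, axis=1)
        ok = (nhd > 0) & (nha > 0)
        cosang = np.einsum("j,ij->i", hd, ha) / np.where(ok, nhd * nha, 1.0)
        # linear D-H-A means angle(hd, ha) near 180 deg: cos <= cos(150°)
        count += int(np.count_nonzero(ok & (cosang <= cos_cut)))
    return count


def ensemble_from_trajectory(
    topology: str,
    trajectory: str | None = None,
    selection: str = "protein and name CA",
    terminal_indices: tuple[int, int] | None = None,
) -> ChainEnsemble:
    """Build a :class:`ChainEnsemble` from PDB/GRO(+XTC) files.

    Coordinates are converted Å → nm; masses come from the topology. The
    default selection keeps one backbone site per residue.
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(
        topology, trajectory
    )
    sites = u.select_atoms(selection)
    if len(sites) < 2:
        raise InputError(f"selection {selection!r} matched < 2 sites")
    frames = np.array([sites.positions.copy() / 10.0 for _ in u.trajectory])
    try:
        masses = sites.masses.copy()
        if np.any(masses <= 0):
            masses = None
    except Exception:
        masses = None
    labels = [f"{a.resname}{a.resid}" for a in sites]
    return ChainEnsemble(frames, masses, terminal_indices, labels)
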