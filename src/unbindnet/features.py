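"""Snapshot features: intermolecular distance vectors, DRMS, COM distances.

The dissimilarity between two snapshots is the distance root mean square
(DRMS): for distance vectors a and b over the same N ligand/site heavy-atom
pairs,

    DRMS(a, b) = sqrt( (1/N) * sum_k (a_k - b_k)^2 )   [Å]

DRMS requires no structural superposition, which is its key advantage over
coordinate RMSD for a small ligand moving in and out of a binding site.  The
1/N (mean-square) normalization makes a fixed clustering threshold scale-free
in the number of atom pairs; the convention is recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AtomSelection",
    "drms",
    "drms_to_many",
    "extract_features",
    "load_trajectory_features",
    "write_features_tsv",
    "read_features_tsv",
]

DRMS_NORMALIZATION = "mean-square (1/N) over intermolecular distance pairs"


@dataclass(frozen=True)
class AtomSelection:
    """Heavy-atom index selections for the ligand and the site residues."""

    ligand_atoms: tuple[int, ...]
    site_atoms: tuple[int, ...]
    site_residue_names: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.ligand_atoms or not self.site_atoms:
            raise ValueError("ligand and site selections must be non-empty")
        if set(self.ligand_atoms) & set(self.site_atoms):
            raise ValueError("ligand and site selections must be disjoint")

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Lexicographic (ligand_atom, site_atom) pair order — the recorded
        ordering of the distance vector."""
        return [(i, j) for i in self.ligand_atoms for j in self.site_atoms]


def drms(a: np.ndarray, b: np.ndarray) -> float:
    """Distance root mean square between two snapshot distance vectors (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"distance vectors must match in length, got {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def drms_to_many(x: np.ndarray, leaders: np.ndarray) -> np.ndarray:
    """DRMS from one vector to each row of ``leaders`` (vectorized)."""
    x = np.asarray(x, dtype=float)
    L = np.atleast_2d(np.asarray(leaders, dtype=float))
    if L.shape[1] != x.shape[0]:
        raise ValueError("vector length mismatch")
    return np.sqrt(np.mean((L - x[None, :]) ** 2, axis=1))


def extract_features(
    coords: np.ndarray,
    selection: AtomSelection,
    masses: np.ndarray | None = None,
    run_ids: np.ndarray | None = None,
    dt: float = 4.0,
) -> pd.DataFrame:
    """Per-frame distance vectors and ligand–site COM separation.

    Parameters
    ----------
    coords : (n_frames, n_atoms, 3) Cartesian coordinates in Å.
    selection : ligand/site heavy-atom indices.
    masses : per-atom masses for the COM (default: unit masses).
    run_ids : per-frame run identifier (default: single run 0).

    Returns the TSV feature dialect: run_id, frame, time, com_distance,
    d_1..d_N with the pair ordering of ``selection.pairs``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
    n_frames, n_atoms, _ = coords.shape
    needed = max(max(selection.ligand_atoms), max(selection.site_atoms))
    if needed >= n_atoms:
        raise ValueError(
            f"selection references atom {needed} but frames carry only {n_atoms} atoms"
        )
    if not np.all(np.isfinite(coords)):
        bad = np.argwhere(~np.isfinite(coords).all(axis=(1, 2)))[0, 0]
        raise ValueError(f"missing/non-finite coordinates at frame {bad}")
    if masses is None:
        masses = np.ones(n_atoms)
    masses = np.asarray(masses, dtype=float)

    lig = np.asarray(selection.ligand_atoms)
    site = np.asarray(selection.site_atoms)
    m_l = masses[lig] / masses[lig].sum()
    m_s = masses[site] / masses[site].sum()
    com_l = np.einsum("fad,a->fd", coords[:, lig, :], m_l)
    com_s = np.einsum("fad,a->fd", coords[:, site, :], m_s)
    com_dist = np.linalg.norm(com_l - com_s, axis=1)

    diff = coords[:, lig, None, :] - coords[:, None, site, :]
    dists = np.linalg.norm(diff, axis=3).reshape(n_frames, -1)

    if run_ids is None:
        run_ids = np.zeros(n_frames, dtype=int)
    run_ids = np.asarray(run_ids)
    frame_in_run = np.zeros(n_frames, dtype=int)
    for r in np.unique(run_ids):
        sel = run_ids == r
        frame_in_run[sel] = np.arange(sel.sum())

    out = pd.DataFrame(
        {
            "run_id": run_ids,
            "frame": frame_in_run,
            "time": frame_in_run * dt,
            "com_distance": com_dist,
        }
    )
    for k in range(dists.shape[1]):
        out[f"d_{k + 1}"] = dists[:, k]
    return out


def load_trajectory_features(
    trajectory_file,
    topology_file,
    selection: AtomSelection,
    dt: float = 4.0,
    run_id: int = 0,
) -> pd.DataFrame:
    """Read a DCD/XTC/PDB trajectory with mdtraj and extract features.

    Coordinates are converted from nm to Å; masses come from the topology.
    """
    import mdtraj as md  # binary trajectory I/O kept optional at import time

    traj = md.load(str(trajectory_file), top=str(topology_file))
    coords = traj.xyz * 10.0  # nm -> Å
    masses = np.array([a.element.mass for a in traj.topology.atoms])
    run_ids = np.full(traj.n_frames, run_id)
    return extract_features(coords, selection, masses=masses, run_ids=run_ids, dt=dt)


def write_features_tsv(df: pd.DataFrame, path) -> None:
    """Write the shared feature-table dialect, with the DRMS convention noted
    in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# drms_normalization: {DRMS_NORMALIZATION}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
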