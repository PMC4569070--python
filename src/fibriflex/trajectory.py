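"""Lightweight trajectory container and file I/O.

Coordinate trajectories are held as plain numpy arrays together with the
minimal topology needed for residue-range selections (chain id, residue
number, atom name per atom).  Files are read and written through
MDAnalysis, so PDB/mmCIF topologies and DCD/XTC trajectories all work;
coordinates keep whatever length unit the file uses (Å for PDB/DCD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SelectionError(KeyError):
    """A chain/residue selection resolved to no atoms."""


@dataclass
class Trajectory:
    """Cartesian coordinates for ``n_frames`` x ``n_atoms`` plus labels.

    Residue numbering is 1-based and inclusive, following the fibrinogen
    chain numbering used throughout (e.g. the E-region selection
    α50–58, β82–90, γ23–31).
    """

    coords: np.ndarray            # (n_frames, n_atoms, 3) float
    chain_ids: np.ndarray         # (n_atoms,) str
    resids: np.ndarray            # (n_atoms,) int
    atom_names: np.ndarray = field(default=None)  # (n_atoms,) str

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.atom_names is None:
            self.atom_names = np.full(self.n_atoms, "CA", dtype=object)
        else:
            self.atom_names = np.asarray(self.atom_names, dtype=object)
        for arr, name in ((self.chain_ids, "chain_ids"),
                          (self.resids, "resids"),
                          (self.atom_names, "atom_names")):
            if arr.shape != (self.n_atoms,):
                raise ValueError(f"{name} must have one entry per atom")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, chain_id: str, resid_range: tuple[int, int],
               names: tuple[str, ...] | None = ("CA",)) -> np.ndarray:
        """Indices of atoms in ``chain_id`` with resid in the inclusive range."""
        lo, hi = resid_range
        if lo > hi:
            raise ValueError(f"empty residue range {lo}–{hi}")
        mask = (self.chain_ids == chain_id) & (self.resids >= lo) & (self.resids <= hi)
        if names is not None:
            mask &= np.isin(self.atom_names, names)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise SelectionError(
                f"selection chain {chain_id!r} residues {lo}–{hi} "
                f"(names={names}) matched no atoms")
        return idx

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def write(self, topology_path: str, trajectory_path: str | None = None) -> None:
        """Write a PDB topology and optionally a DCD/XTC trajectory."""
        import MDAnalysis as mda

        n = self.n_atoms
        # one residue per distinct (chain, resid) pair, in order of appearance
        pairs = list(zip(self.chain_ids, self.resids))
        seen: dict[tuple, int] = {}
        res_index = np.empty(n, dtype=int)
        for i, p in enumerate(pairs):
            if p not in seen:
                seen[p] = len(seen)
            res_index[i] = seen[p]
        n_res = len(seen)
        res_chains = [None] * n_res
        res_resids = [None] * n_res
        for (ch, rid), k in seen.items():
            res_chains[k] = ch
            res_resids[k] = rid
        seg_ids = sorted(set(self.chain_ids))
        seg_index = [seg_ids.index(ch) for ch in res_chains]

        u = mda.Universe.empty(n, n_residues=n_res, n_segments=len(seg_ids),
                               atom_resindex=res_index,
                               residue_segindex=seg_index,
                               trajectory=True)
        u.add_TopologyAttr("names", list(self.atom_names))
        u.add_TopologyAttr("resids", res_resids)
        u.add_TopologyAttr("resnames", ["GLY"] * n_res)
        u.add_TopologyAttr("segids", seg_ids)
        u.add_TopologyAttr("chainIDs", list(self.chain_ids))
        u.atoms.positions = self.coords[0]
        u.atoms.write(topology_path)
        if trajectory_path is not None:
            with mda.Writer(trajectory_path, n) as w:
                for f in range(self.n_frames):
                    u.atoms.positions = self.coords[f]
                    w.write(u.atoms)


def load_trajectory(topology: str, trajectory: str | None = None) -> Trajectory:
    """Read a structure/trajectory pair (PDB[+DCD/XTC]) into a :class:`Trajectory`."""
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None else mda.Universe(topology, trajectory)
    try:
        chains = u.atoms.chainIDs
    except (AttributeError, mda.exceptions.NoDataError):
        chains = u.atoms.segids
    chains = np.asarray(chains, dtype=object)
    resids = np.asarray(u.atoms.resids, dtype=int)
    names = np.asarray(u.atoms.names, dtype=object)
    coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    return Trajectory(coords=coords, chain_ids=chains, resids=resids, atom_names=names)
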