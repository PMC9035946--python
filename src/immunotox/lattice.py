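"""Simulation space: hexagonal/cubic lattices, agent and field diffusion.

The space is either a 2D ``L x L`` hexagonal lattice (six neighbours per
site, "odd-r" offset coordinates) or a 3D ``L x L x L`` cubic lattice with
face adjacency (also six neighbours), with periodic boundary conditions or
hard walls.  Cell agents perform a symmetric nearest-neighbour random walk
(Brownian motion with a common diffusion coefficient); molecular species
live as per-site concentration fields that diffuse conservatively and decay
with a configured half-life.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Geometry",
    "Boundary",
    "Lattice",
    "MolecularField",
    "neighbors",
    "diffuse_agents",
    "diffuse_field",
    "decay_field",
]


class Geometry(enum.Enum):
    HEX2D = "hex2d"
    CUBIC3D = "cubic3d"


class Boundary(enum.Enum):
    PERIODIC = "periodic"
    HARD_WALL = "hard_wall"


# odd-r offset stencils: (drow, dcol) for even and odd rows
_HEX_EVEN = ((0, -1), (0, 1), (-1, -1), (-1, 0), (1, -1), (1, 0))
_HEX_ODD = ((0, -1), (0, 1), (-1, 0), (-1, 1), (1, 0), (1, 1))


class Lattice:
    """A discrete simulation space with a precomputed neighbour table.

    ``neighbor_table`` has shape ``(n_sites, 6)``; missing neighbours under
    HARD_WALL are ``-1``.  Site indices are 0-based row-major.
    """

    def __init__(
        self,
        geometry: Geometry = Geometry.HEX2D,
        side: int = 16,
        boundary: Boundary = Boundary.PERIODIC,
    ) -> None:
        if side < 3:
            raise ValueError(f"side must be >= 3, got {side}")
        if (
            geometry is Geometry.HEX2D
            and boundary is Boundary.PERIODIC
            and side % 2 != 0
        ):
            # odd-r parity only wraps consistently for an even number of rows
            raise ValueError("HEX2D periodic lattices require an even side")
        self.geometry = geometry
        self.side = side
        self.boundary = boundary
        self.n_sites = side * side if geometry is Geometry.HEX2D else side**3
        self.neighbor_table = self._build_table()
        # per-site list of valid neighbours and their counts (HARD_WALL varies)
        self.valid_counts = (self.neighbor_table >= 0).sum(axis=1)

    def _build_table(self) -> np.ndarray:
        L = self.side
        periodic = self.boundary is Boundary.PERIODIC
        table = np.full((self.n_sites, 6), -1, dtype=np.int64)
        if self.geometry is Geometry.HEX2D:
            for r in range(L):
                stencil = _HEX_EVEN if r % 2 == 0 else _HEX_ODD
                for c in range(L):
                    site = r * L + c
                    for k, (dr, dc) in enumerate(stencil):
                        rr, cc = r + dr, c + dc
                        if periodic:
                            rr %= L
                            cc %= L
                        elif not (0 <= rr < L and 0 <= cc < L):
                            continue
                        table[site, k] = rr * L + cc
        else:
            deltas = (
                (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
            )
            for x in range(L):
                for y in range(L):
                    for z in range(L):
                        site = (x * L + y) * L + z
                        for k, (dx, dy, dz) in enumerate(deltas):
                            xx, yy, zz = x + dx, y + dy, z + dz
                            if periodic:
                                xx %= L
                                yy %= L
                                zz %= L
                            elif not (
                                0 <= xx < L and 0 <= yy < L and 0 <= zz < L
                            ):
                                continue
                            table[site, k] = (xx * L + yy) * L + zz
        return table


@dataclass
class MolecularField:
    """Per-site non-negative concentration of one molecular species."""

    species: str
    conc: np.ndarray
    diffusion: float = 0.5
    half_life: float = 3.0

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if not (0.0 <= self.diffusion <= 1.0):
            raise ValueError(f"diffusion fraction must be in [0, 1], got {self.diffusion}")
        if self.half_life <= 0:
            raise ValueError(f"half-life must be positive, got {self.half_life}")

    @classmethod
    def zeros(cls, species: str, lattice: Lattice, **kw) -> "MolecularField":
        return cls(species, np.zeros(lattice.n_sites), **kw)

    def total(self) -> float:
        return float(self.conc.sum())


def neighbors(site: int, lattice: Lattice) -> list[int]:
    """Valid neighbour site indices of ``site`` (6 under PERIODIC)."""
    if not (0 <= site < lattice.n_sites):
        raise ValueError(f"site index {site} out of range [0, {lattice.n_sites})")
    row = lattice.neighbor_table[site]
    return [int(s) for s in row if s >= 0]


def diffuse_agents(
    positions: np.ndarray, lattice: Lattice, rng: np.random.Generator
) -> np.ndarray:
    """One Brownian step: each agent moves to a uniformly chosen neighbour.

    Under HARD_WALL the draw is over the valid neighbours only (no sticking
    bias).  Returns the new positions; the input array is not modified.
    """
    positions = np.asarray(positions, dtype=np.int64)
    if positions.size == 0:
        return positions.copy()
    table = lattice.neighbor_table
    if lattice.boundary is Boundary.PERIODIC:
        choice = rng.integers(0, 6, size=positions.size)
        return table[positions, choice]
    counts = lattice.valid_counts[positions]
    choice = rng.integers(0, counts)  # uniform in [0, k_site)
    # valid entries are not contiguous in the table; map the k-th valid slot
    new = np.empty_like(positions)
    for i, (site, k) in enumerate(zip(positions, choice)):
        row = table[site]
        new[i] = row[row >= 0][k]
    return new


def diffuse_field(fld: MolecularField, lattice: Lattice) -> MolecularField:
    """One conservative diffusion step.

    Each site keeps ``1 - D`` of its mass and sends ``D / k`` to each of its
    ``k`` neighbours (``k = 6`` under PERIODIC; under HARD_WALL the flux is
    split among existing neighbours only, so mass is conserved everywhere).
    """
    D = fld.diffusion
    if D == 0.0:
        return MolecularField(fld.species, fld.conc.copy(), D, fld.half_life)
    conc = fld.conc
    k = lattice.valid_counts
    out_per_edge = conc * (D / k)
    new = conc * (1.0 - D)
    table = lattice.neighbor_table
    for j in range(6):
        col = table[:, j]
        mask = col >= 0
        np.add.at(new, col[mask], out_per_edge[mask])
    return MolecularField(fld.species, new, D, fld.half_life)


def decay_field(fld: MolecularField) -> MolecularField:
    """One half-life decay step: every site is multiplied by ``2**(-1/h)``."""
    factor = 2.0 ** (-1.0 / fld.half_life)
    return MolecularField(fld.species, fld.conc * factor, fld.diffusion, fld.half_life)
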