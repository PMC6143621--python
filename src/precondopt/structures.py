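"""Atomic structures, periodic geometry, extended-XYZ I/O and synthetic fixtures.

Coordinates are Cartesian and in Å throughout; energies are in eV.  A
:class:`Structure` is the optimisation variable ``x`` flattened to a
3N-vector.  Fixtures emulate the two sources of ill-conditioning the
preconditioners address: widely separated stiffness scales (stiff bonds,
softer angles, soft torsions) and growing system size (periodic lattices,
optionally with a point defect).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Structure",
    "NeighborList",
    "FixtureSpec",
    "GeometryError",
    "ParseError",
    "read_xyz",
    "write_xyz",
    "minimum_image_vector",
    "build_neighbor_list",
    "make_fixture",
]


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent geometric input."""


class ParseError(ValueError):
    """Raised for malformed structure or parameter files."""


@dataclass
class Structure:
    """An atomic configuration: species labels, positions (N×3, Å), optional cell.

    ``pbc`` is a 3-vector of per-axis periodicity flags; a periodic axis
    requires a nonsingular ``cell`` (3×3, rows are lattice vectors, Å).
    """

    species: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GeometryError("positions must be an N×3 array")
        if len(self.species) != len(self.positions):
            raise GeometryError(
                f"{len(self.species)} species labels but {len(self.positions)} positions"
            )
        if len(self.species) < 1:
            raise GeometryError("structure needs at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise GeometryError("non-finite positions")
        self.pbc = np.asarray(self.pbc, dtype=bool)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise GeometryError("cell must be 3×3")
        if self.pbc.any():
            if self.cell is None:
                raise GeometryError("periodic structure without a cell")
            if abs(np.linalg.det(self.cell)) < 1e-12:
                raise GeometryError("singular cell with periodic boundary conditions")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def x(self) -> np.ndarray:
        """The configuration as a flat 3N optimisation vector."""
        return self.positions.ravel().copy()

    def with_x(self, x: np.ndarray) -> "Structure":
        """A copy of the structure with positions replaced by flat vector ``x``."""
        pos = np.asarray(x, dtype=float).reshape(self.n_atoms, 3)
        return replace(self, species=list(self.species), positions=pos.copy())


@dataclass
class NeighborList:
    """Pairs within a cutoff, possibly through several periodic images.

    Each entry k couples atom ``i[k]`` with the image of atom ``j[k]``
    shifted by ``shifts[k] @ cell``.  Pairs are canonical (i ≤ j; for
    i == j only lexicographically positive shifts) and sorted by (i, j).
    """

    i: np.ndarray
    j: np.ndarray
    shifts: np.ndarray
    distances: np.ndarray
    vectors: np.ndarray  # r_j(+shift) − r_i, Å

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class FixtureSpec:
    """Deterministic recipe for a synthetic structure plus matching toy force field."""

    kind: str  # chain-molecule | ring-molecule | toy-crystal | cubic-lattice | lattice-vacancy
    n: int = 10  # atoms for molecules; cells per axis for lattices
    perturbation: float = 0.05  # Gaussian displacement stddev, Å
    seed: int = 0
    motif: str = "fcc"  # lattice motif: fcc | diamond
    lattice_constant: float = 4.0  # Å
    n_molecules: int = 2  # toy-crystal only


def minimum_image_vector(structure: Structure, i: int, j: int) -> np.ndarray:
    """Shortest vector from atom i to atom j under the minimum-image convention.

    Non-periodic axes use the raw coordinate difference.  The candidate
    images adjacent to the fractional-wrapped representative are searched
    explicitly, so mildly skewed cells are handled correctly.
    """
    n = structure.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range: ({i}, {j}) with N={n}")
    d = structure.positions[j] - structure.positions[i]
    if not structure.pbc.any():
        return d
    cell = structure.cell
    frac = np.linalg.solve(cell.T, d)
    frac_wrapped = frac - np.where(structure.pbc, np.round(frac), 0.0)
    best, best_r2 = None, np.inf
    ranges = [(-1, 0, 1) if p else (0,) for p in structure.pbc]
    for shift in itertools.product(*ranges):
        cand = (frac_wrapped + np.array(shift)) @ cell
        r2 = cand @ cand
        if r2 < best_r2:
            best, best_r2 = cand, r2
    return best


def minimum_image_vectors(structure: Structure, idx_i: np.ndarray, idx_j: np.ndarray) -> np.ndarray:
    """Vectorised minimum-image vectors r_j − r_i for index arrays (M×3 output)."""
    idx_i = np.asarray(idx_i, dtype=int)
    idx_j = np.asarray(idx_j, dtype=int)
    d = structure.positions[idx_j] - structure.positions[idx_i]
    if not structure.pbc.any():
        return d
    cell = structure.cell
    frac = np.linalg.solve(cell.T, d.T).T
    frac -= np.where(structure.pbc, np.round(frac), 0.0)
    ranges = [(-1, 0, 1) if p else (0,) for p in structure.pbc]
    best = None
    best_r2 = np.full(len(d), np.inf)
    for shift in itertools.product(*ranges):
        cand = (frac + np.array(shift, dtype=float)) @ cell
        r2 = np.einsum("ij,ij->i", cand, cand)
        if best is None:
            best, best_r2 = cand, r2
        else:
            better = r2 < best_r2
            best[better] = cand[better]
            best_r2 = np.minimum(best_r2, r2)
    return best


def _shift_range(cell: np.ndarray, pbc: np.ndarray, r_cut: float) -> list[range]:
    """Per-axis image search range covering every image within r_cut."""
    inv = np.linalg.inv(cell)
    # perpendicular distance between lattice planes of axis a: 1/|row_a of inv.T|
    heights = 1.0 / np.linalg.norm(inv, axis=0)
    out = []
    for a in range(3):
        if pbc[a]:
            nmax = int(np.floor(r_cut / heights[a])) + 1
            out.append(range(-nmax, nmax + 1))
        else:
            out.append(range(0, 1))
    return out


def build_neighbor_list(structure: Structure, r_cut: float) -> NeighborList:
    """All atom pairs (including periodic images) with separation < r_cut.

    Self-image pairs (atom coupled to its own periodic copy) are included
    when they fall inside the cutoff; consumers that assemble Γ-point
    operators may skip them since their net contribution cancels.
    """
    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    pos = structure.positions
    n = structure.n_atoms
    ii, jj, ss, dd, vv = [], [], [], [], []
    if structure.pbc.any():
        ranges = _shift_range(structure.cell, structure.pbc, r_cut)
        shifts = [np.array(s) for s in itertools.product(*ranges)]
    else:
        shifts = [np.zeros(3, dtype=int)]
    for shift in shifts:
        nonzero = shift.any()
        if nonzero:
            # keep only the lexicographically positive half to avoid duplicates
            first = next(x for x in shift if x != 0)
            if first < 0:
                continue
        offset = shift @ structure.cell if structure.cell is not None else 0.0
        disp = pos[None, :, :] + offset - pos[:, None, :]
        dist = np.linalg.norm(disp, axis=2)
        within = dist < r_cut
        if not nonzero:
            within = np.triu(within, k=1)
        # nonzero positive shifts: keep every (i, j) including i > j and
        # self-images — each such edge has a unique representative since the
        # mirrored edge carries the (discarded) negative shift
        ai, aj = np.nonzero(within)
        for a, b in zip(ai, aj):
            ii.append(a)
            jj.append(b)
            ss.append(shift.copy())
            dd.append(dist[a, b])
            vv.append(disp[a, b])
    if ii:
        order = np.lexsort((np.asarray(jj), np.asarray(ii)))
    else:
        order = np.array([], dtype=int)
    return NeighborList(
        i=np.asarray(ii, dtype=int)[order] if len(ii) else np.empty(0, dtype=int),
        j=np.asarray(jj, dtype=int)[order] if len(jj) else np.empty(0, dtype=int),
        shifts=np.asarray(ss, dtype=int)[order] if len(ss) else np.empty((0, 3), dtype=int),
        distances=np.asarray(dd, dtype=float)[order] if len(dd) else np.empty(0),
        vectors=np.asarray(vv, dtype=float)[order] if len(vv) else np.empty((0, 3)),
    )


# ---------------------------------------------------------------------------
# extended-XYZ I/O


_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(comment: str) -> tuple[np.ndarray | None, np.ndarray]:
    cell = None
    pbc = np.zeros(3, dtype=bool)
    for m in _KV_RE.finditer(comment):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        if key.lower() == "lattice":
            nums = [float(t) for t in val.split()]
            if len(nums) != 9:
                raise ParseError("Lattice must contain 9 numbers")
            cell = np.array(nums).reshape(3, 3)
        elif key.lower() == "pbc":
            flags = val.replace(",", " ").split()
            if len(flags) != 3:
                raise ParseError("pbc must contain 3 flags")
            pbc = np.array([f.strip().upper() in ("T", "TRUE", "1") for f in flags])
    if cell is not None and not pbc.any():
        pbc = np.ones(3, dtype=bool)
    return cell, pbc


def read_xyz(path) -> Structure:
    """Read the first frame of an (extended) XYZ file.

    The comment line may carry ``Lattice="ax ay az bx by bz cx cy cz"`` and
    ``pbc="T T T"``; a Lattice without explicit pbc flags implies full
    periodicity, and no Lattice means a non-periodic structure.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        natoms = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: expected an atom count, got {lines[0]!r}") from None
    if len(lines) < natoms + 2:
        raise ParseError(
            f"{path}: header declares {natoms} atoms but only "
            f"{max(len(lines) - 2, 0)} atom records follow"
        )
    cell, pbc = _parse_comment(lines[1])
    species, positions = [], []
    for ln in range(2, 2 + natoms):
        parts = lines[ln].split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln + 1}: expected 'El x y z', got {lines[ln]!r}")
        species.append(parts[0])
        try:
            positions.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise ParseError(f"{path}:{ln + 1}: non-numeric coordinate") from None
    return Structure(species=species, positions=np.array(positions), cell=cell, pbc=pbc)


def write_xyz(structure: Structure, path, append: bool = False) -> None:
    """Write a structure as one extended-XYZ frame (16 significant digits)."""
    parts = ["Properties=species:S:1:pos:R:3"]
    if structure.cell is not None:
        flat = " ".join(f"{v:.16g}" for v in structure.cell.ravel())
        parts.append(f'Lattice="{flat}"')
        flags = " ".join("T" if p else "F" for p in structure.pbc)
        parts.append(f'pbc="{flags}"')
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{structure.n_atoms}\n")
        fh.write(" ".join(parts) + "\n")
        for el, (px, py, pz) in zip(structure.species, structure.positions):
            fh.write(f"{el} {px:.16g} {py:.16g} {pz:.16g}\n")


# ---------------------------------------------------------------------------
# synthetic fixtures

# Toy "mini-FF" stiffness defaults.  The ≥100× bond/torsion contrast makes the
# chain fixture deliberately ill-conditioned in the stiffness sense.
CHAIN_BOND_K = 40.0  # eV/Å²
CHAIN_BOND_R0 = 1.5  # Å
CHAIN_ANGLE_K = 4.0  # eV/rad²
CHAIN_ANGLE_T0 = 1.9106332362490186  # rad, ≈109.47°
CHAIN_TORSION_K = 0.05  # eV
LATTICE_BOND_K = 10.0  # eV/Å²


def _chain_positions(n: int) -> np.ndarray:
    """Ideal zigzag chain: bonds CHAIN_BOND_R0, bends CHAIN_ANGLE_T0, all-trans."""
    b, theta = CHAIN_BOND_R0, CHAIN_ANGLE_T0
    dx = b * np.sin(theta / 2.0)
    dz = b * np.cos(theta / 2.0)
    pos = np.zeros((n, 3))
    for k in range(n):
        pos[k] = (k * dx, 0.0, (k % 2) * dz)
    return pos


def _ring_positions(n: int) -> np.ndarray:
    radius = CHAIN_BOND_R0 / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(n)])


def _molecule_terms(n: int, ring: bool):
    """Bond/angle/torsion term records for a chain (open) or ring (cyclic)."""
    from .forcefield import FFTerm, QuadraticParams, TorsionParams

    terms = []
    npairs = n if ring else n - 1
    for a in range(npairs):
        terms.append(
            FFTerm("distance", (a, (a + 1) % n), "quadratic",
                   QuadraticParams(k=CHAIN_BOND_K, q0=CHAIN_BOND_R0))
        )
    ntrip = n if ring else n - 2
    if n >= 3:
        for a in range(ntrip):
            atoms = (a, (a + 1) % n, (a + 2) % n)
            theta0 = np.pi - 2.0 * np.pi / n if ring else CHAIN_ANGLE_T0
            terms.append(
                FFTerm("angle", atoms, "quadratic",
                       QuadraticParams(k=CHAIN_ANGLE_K, q0=theta0))
            )
    nquad = n if ring else n - 3
    if n >= 4:
        for a in range(nquad):
            atoms = (a, (a + 1) % n, (a + 2) % n, (a + 3) % n)
            # n=3, phi0=0 has minima at the trans (φ=π) geometry
            terms.append(
                FFTerm("dihedral", atoms, "torsion",
                       TorsionParams(k_phi=CHAIN_TORSION_K, n=3, phi0=0.0))
            )
    return terms


_MOTIFS = {
    "fcc": np.array([[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]),
    "diamond": np.array(
        [
            [0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0],
            [0.25, 0.25, 0.25], [0.25, 0.75, 0.75], [0.75, 0.25, 0.75], [0.75, 0.75, 0.25],
        ]
    ),
}


def _lattice_structure(spec: FixtureSpec, vacancy: bool) -> Structure:
    motif = _MOTIFS.get(spec.motif)
    if motif is None:
        raise ParseError(f"unknown lattice motif {spec.motif!r}")
    a0, nc = spec.lattice_constant, spec.n
    frac = []
    for cx, cy, cz in itertools.product(range(nc), repeat=3):
        for m in motif:
            frac.append((m + (cx, cy, cz)) / nc)
    frac = np.array(frac)
    cell = np.eye(3) * a0 * nc
    pos = frac @ cell
    if vacancy:
        pos = pos[1:]
    species = ["Si"] * len(pos)
    return Structure(species=species, positions=pos, cell=cell, pbc=np.ones(3, dtype=bool))


def _lattice_terms(structure: Structure, r_cut: float):
    """Quadratic pair springs on every neighbour-list pair (one term per image pair)."""
    from .forcefield import FFTerm, QuadraticParams

    nl = build_neighbor_list(structure, r_cut)
    terms = []
    for a, b, r in zip(nl.i, nl.j, nl.distances):
        if a == b:
            continue  # self-image springs add nothing at Γ
        terms.append(
            FFTerm("distance", (int(a), int(b)), "quadratic",
                   QuadraticParams(k=LATTICE_BOND_K, q0=float(r)))
        )
    return terms


def make_fixture(spec: FixtureSpec):
    """Build a seeded synthetic structure and its matching toy force field.

    Returns ``(structure, terms)`` where ``terms`` is a list of FF term
    records consumable by :mod:`precondopt.forcefield`.  The random
    perturbation is applied after the ideal geometry (and the lattice
    equilibrium bond lengths) are fixed, so the returned force field's
    minimum is the unperturbed geometry.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.perturbation < 0:
        raise ParseError("perturbation stddev must be ≥ 0")
    if spec.kind == "chain-molecule":
        if spec.n < 2:
            raise ParseError("chain-molecule needs n ≥ 2")
        structure = Structure(["C"] * spec.n, _chain_positions(spec.n))
        terms = _molecule_terms(spec.n, ring=False)
    elif spec.kind == "ring-molecule":
        if spec.n < 3:
            raise ParseError("ring-molecule needs n ≥ 3")
        structure = Structure(["C"] * spec.n, _ring_positions(spec.n))
        terms = _molecule_terms(spec.n, ring=True)
    elif spec.kind == "toy-crystal":
        # n_molecules short chains in a periodic box, bonded terms only:
        # intermolecular coupling is left to the Exp preconditioner.
        nmol, nat = spec.n_molecules, max(spec.n, 2)
        box = 6.0 * max(1, int(np.ceil(nmol ** (1 / 3))))
        species, pos, terms = [], [], []
        from .forcefield import FFTerm  # noqa: F401  (for type parity with branches)

        base = _chain_positions(nat)
        grid = int(np.ceil(nmol ** (1 / 3)))
        placed = 0
        for cx, cy, cz in itertools.product(range(grid), repeat=3):
            if placed >= nmol:
                break
            origin = np.array([cx, cy, cz]) * (box / grid) + 1.0
            offset = placed * nat
            for t in _molecule_terms(nat, ring=False):
                terms.append(
                    type(t)(t.kind, tuple(a + offset for a in t.atoms), t.form, t.params)
                )
            species += ["C"] * nat
            pos.append(base + origin)
            placed += 1
        structure = Structure(
            species, np.vstack(pos), cell=np.eye(3) * box, pbc=np.ones(3, dtype=bool)
        )
    elif spec.kind in ("cubic-lattice", "lattice-vacancy"):
        structure = _lattice_structure(spec, vacancy=spec.kind == "lattice-vacancy")
        nn = spec.lattice_constant * (np.sqrt(3) / 4 if spec.motif == "diamond" else np.sqrt(0.5))
        terms = _lattice_terms(structure, 1.2 * nn)
    else:
        raise ParseError(f"unknown fixture kind {spec.kind!r}")
    if spec.perturbation > 0:
        structure.positions = structure.positions + rng.normal(
            0.0, spec.perturbation, structure.positions.shape
        )
    return structure, terms
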