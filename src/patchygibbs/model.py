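"""Two-species patchy-particle model with a directional square-well attraction.

Protein-like particles (``P``) carry four tetrahedrally arranged patches;
regulator particles (``R``) carry two polar patches.  All patches on a species
together cover a fraction ``chi`` of the hard-core surface, so each patch is a
spherical disk whose spanning polar angle ``theta_S`` satisfies

    cos(theta_S) = 1 - 2 chi / m_S

where ``m_S`` is the patch count of species S.  Two particles interact through
a square well of depth ``eps_ij`` and width ``lam`` that is switched on only
when a patch on each particle faces the other particle (a "bond").

All lengths are in units of the hard-core diameter ``sigma`` and all energies
in units of the P-P well depth ``eps_PP``; reduced temperature is in units of
``eps_PP / k_B``.
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OVERLAP",
    "Species",
    "ModelParams",
    "Particle",
    "Configuration",
    "patch_cos_half_angle",
    "reference_patch_directions",
    "quat_to_matrix",
    "random_quaternion",
    "is_bonded",
    "pair_energy",
    "total_energy",
    "minimum_image",
]


class _OverlapType:
    """Sentinel returned when two hard cores overlap.

    A distinguished value, compared by identity, never summed into finite
    energies.  Using a sentinel instead of IEEE infinity keeps incremental
    energy bookkeeping free of ``inf - inf`` traps.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "OVERLAP"


OVERLAP = _OverlapType()


class Species(enum.IntEnum):
    """Particle species: P = droplet-forming protein, R = regulator."""

    P = 0
    R = 1


def patch_cos_half_angle(m: int, chi: float) -> float:
    """Cosine of the spanning polar angle of one patch.

    Parameters
    ----------
    m : int
        Number of patches on the species (>= 1).
    chi : float
        Total fraction of the core surface covered by all patches, 0 < chi < 1.

    Returns
    -------
    float
        ``1 - 2 * chi / m``.

    Raises
    ------
    ValueError
        If the inputs are out of range or the resulting cosine is <= -1
        (each patch would have to span more than a full hemisphere).
    """
    if m < 1:
        raise ValueError(f"patch count must be >= 1, got {m}")
    if not 0.0 < chi <= 1.0:
        raise ValueError(f"coverage fraction chi must be in (0, 1], got {chi}")
    c = 1.0 - 2.0 * chi / m
    if c <= -1.0:
        raise ValueError(
            f"patch spanning angle exceeds a hemisphere (cos theta = {c} <= -1)"
        )
    return c


# Fixed tetrahedral reference frame for the four P patches.  Any rigid frame is
# equivalent by symmetry; this one has pairwise dot products of exactly -1/3.
_TETRAHEDRON = np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, -1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
    ]
) / math.sqrt(3.0)

_POLES = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0]])


def reference_patch_directions(species: Species | int) -> np.ndarray:
    """Unit patch-center directions in the species' body frame.

    P particles carry four tetrahedral patches; R particles carry two patches
    at the poles.
    """
    species = Species(species)
    if species is Species.P:
        return _TETRAHEDRON.copy()
    return _POLES.copy()


@dataclass(frozen=True)
class ModelParams:
    """All interaction and geometry constants of the two-species model.

    Attributes
    ----------
    sigma : float
        Hard-core diameter (the unit of length).
    chi : float
        Total patch surface-coverage fraction, identical for both species.
    lam : float
        Square-well width in units of ``sigma``.
    m_P, m_R : int
        Patch counts of species P and R.
    eps_PP, eps_PR, eps_RR : float
        Well depths for the three pair classes, in units of ``eps_PP``.
        ``eps_RR = 0`` leaves regulators with steric repulsion only.
    """

    sigma: float = 1.0
    chi: float = 0.7
    lam: float = 0.5
    m_P: int = 4
    m_R: int = 2
    eps_PP: float = 1.0
    eps_PR: float = 0.0
    eps_RR: float = 0.0
    #: Reject parameter sets whose patches overlap on one particle (chi is
    #: only meaningful as a covered-area fraction for disjoint disks).  The
    #: isotropic chi -> 1 limit deliberately violates this for the 4-patch
    #: species and turns the check off.
    check_patch_overlap: bool = True

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.chi < 1.0:
            raise ValueError(f"chi must be in (0, 1), got {self.chi}")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        for name in ("eps_PP", "eps_PR", "eps_RR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # The patch frames are species-fixed (tetrahedron / poles), so the
        # patch counts are structural constants of the model.
        if self.m_P != 4 or self.m_R != 2:
            raise ValueError("the model is defined with m_P = 4 and m_R = 2")
        # Validates the (-1, 1) range of both cosines.
        cos_p = patch_cos_half_angle(self.m_P, self.chi)
        cos_r = patch_cos_half_angle(self.m_R, self.chi)
        if self.check_patch_overlap:
            self._check_patch_disjoint(self.m_P, cos_p)
            self._check_patch_disjoint(self.m_R, cos_r)

    @staticmethod
    def _check_patch_disjoint(m: int, cos_theta: float) -> None:
        # Patches on one particle must be non-overlapping disks: twice the
        # spanning angle of a patch may not exceed the angular separation of
        # the closest patch-center pair, otherwise chi loses its meaning as a
        # covered-area fraction.
        if m == 1:
            return
        dirs = _TETRAHEDRON if m == 4 else _POLES if m == 2 else None
        if dirs is None:
            raise ValueError(f"unsupported patch count {m}; expected 2 or 4")
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, -1.0)
        min_sep = math.acos(np.clip(dots.max(), -1.0, 1.0))
        theta = math.acos(cos_theta)
        if 2.0 * theta > min_sep + 1e-12:
            raise ValueError(
                f"patches overlap on one particle: spanning angle {theta:.4f} rad, "
                f"nearest-centre separation {min_sep:.4f} rad"
            )

    @property
    def cos_theta_P(self) -> float:
        return patch_cos_half_angle(self.m_P, self.chi)

    @property
    def cos_theta_R(self) -> float:
        return patch_cos_half_angle(self.m_R, self.chi)

    def cos_theta(self, species: Species | int) -> float:
        return self.cos_theta_P if Species(species) is Species.P else self.cos_theta_R

    def m(self, species: Species | int) -> int:
        return self.m_P if Species(species) is Species.P else self.m_R

    def eps(self, s1: Species | int, s2: Species | int) -> float:
        s1, s2 = Species(s1), Species(s2)
        if s1 is Species.P and s2 is Species.P:
            return self.eps_PP
        if s1 is Species.R and s2 is Species.R:
            return self.eps_RR
        return self.eps_PR

    @property
    def eps_matrix(self) -> np.ndarray:
        return np.array(
            [[self.eps_PP, self.eps_PR], [self.eps_PR, self.eps_RR]], dtype=float
        )

    @property
    def well_edge(self) -> float:
        """Outer edge of the square well, ``sigma + lam``."""
        return self.sigma + self.lam

    def content_hash(self) -> str:
        """Short stable hash of the parameter set, used in file headers."""
        text = repr(
            (
                self.sigma,
                self.chi,
                self.lam,
                self.m_P,
                self.m_R,
                self.eps_PP,
                self.eps_PR,
                self.eps_RR,
            )
        )
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion ``(w, x, y, z)``."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation as a unit quaternion (4-D Gaussian trick)."""
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


@dataclass
class Particle:
    """One rigid patchy particle: species, position and orientation.

    The orientation is a unit quaternion applied to the species' reference
    patch directions.
    """

    species: Species
    position: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(self.orientation)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"orientation quaternion norm {norm} != 1")
        self.species = Species(self.species)

    def patch_directions(self) -> np.ndarray:
        """World-frame unit vectors to the patch centers."""
        ref = reference_patch_directions(self.species)
        return ref @ quat_to_matrix(self.orientation).T


class Configuration:
    """A periodic cubic box of patchy particles.

    Stores positions, orientations and species as flat arrays; ``particles``
    offers a :class:`Particle` view for convenience.  Positions are always
    wrapped into ``[0, box_edge)^3``.
    """

    def __init__(
        self,
        positions: np.ndarray,
        orientations: np.ndarray,
        species: np.ndarray,
        box_edge: float,
    ) -> None:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
        species = np.atleast_1d(np.asarray(species, dtype=np.int64))
        if box_edge <= 0:
            raise ValueError("box_edge must be positive")
        n = len(species)
        if positions.shape != (n, 3) or orientations.shape != (n, 4):
            raise ValueError("inconsistent array shapes")
        norms = np.linalg.norm(orientations, axis=1)
        if n and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise ValueError("orientation quaternions must be unit norm")
        self.positions = np.mod(positions, box_edge)
        self.orientations = orientations.copy()
        self.species = species
        self.box_edge = float(box_edge)

    @classmethod
    def from_particles(cls, particles: list[Particle], box_edge: float) -> "Configuration":
        n = len(particles)
        pos = np.zeros((n, 3))
        quat = np.zeros((n, 4))
        spec = np.zeros(n, dtype=np.int64)
        for i, p in enumerate(particles):
            pos[i] = p.position
            quat[i] = p.orientation
            spec[i] = int(p.species)
        return cls(pos, quat, spec, box_edge)

    def __len__(self) -> int:
        return len(self.species)

    @property
    def n_P(self) -> int:
        return int(np.sum(self.species == int(Species.P)))

    @property
    def n_R(self) -> int:
        return int(np.sum(self.species == int(Species.R)))

    @property
    def volume(self) -> float:
        return self.box_edge**3

    @property
    def particles(self) -> list[Particle]:
        return [
            Particle(Species(int(s)), p.copy(), q.copy())
            for s, p, q in zip(self.species, self.positions, self.orientations)
        ]

    def patch_directions(self) -> np.ndarray:
        """World patch vectors, shape (N, 4, 3); unused rows (R) are NaN-free
        zero padding beyond the species' patch count."""
        n = len(self)
        out = np.zeros((n, 4, 3))
        for i in range(n):
            ref = reference_patch_directions(Species(int(self.species[i])))
            out[i, : len(ref)] = ref @ quat_to_matrix(self.orientations[i]).T
        return out

    def copy(self) -> "Configuration":
        return Configuration(
            self.positions.copy(),
            self.orientations.copy(),
            self.species.copy(),
            self.box_edge,
        )


def minimum_image(dr: np.ndarray, box_edge: float) -> np.ndarray:
    """Minimum-image displacement vector under cubic periodic boundaries."""
    return dr - box_edge * np.round(dr / box_edge)


def is_bonded(
    pi: Particle, pj: Particle, params: ModelParams, displacement: np.ndarray
) -> bool:
    """Geometric bond criterion for a pair already inside the square well.

    ``displacement`` is the minimum-image vector from ``pi`` to ``pj``.  The
    pair is bonded iff some patch alpha on i and some patch beta on j satisfy
    ``rhat . n_i_alpha > cos theta_i`` and ``-rhat . n_j_beta > cos theta_j``
    (strict inequalities).  A pair counts as one bond no matter how many patch
    pairs align.
    """
    r = float(np.linalg.norm(displacement))
    if r == 0.0:
        return False
    rhat = displacement / r
    cos_i = params.cos_theta(pi.species)
    cos_j = params.cos_theta(pj.species)
    ni = pi.patch_directions()
    nj = pj.patch_directions()
    if not np.any(ni @ rhat > cos_i):
        return False
    return bool(np.any(nj @ (-rhat) > cos_j))


def pair_energy(
    pi: Particle, pj: Particle, params: ModelParams, displacement: np.ndarray
):
    """Directional square-well pair energy.

    Returns the :data:`OVERLAP` sentinel for ``r <= sigma``, ``-eps_ij`` when
    the pair is inside the well (``sigma < r <= sigma + lam``) and bonded, and
    ``0.0`` otherwise.
    """
    r = float(np.linalg.norm(displacement))
    if r <= params.sigma:
        return OVERLAP
    if r > params.well_edge:
        return 0.0
    if is_bonded(pi, pj, params, displacement):
        return -params.eps(pi.species, pj.species)
    return 0.0


def total_energy(config: Configuration, params: ModelParams):
    """Total potential energy: sum of pair energies over all unordered pairs.

    Uses the minimum-image convention.  Returns :data:`OVERLAP` if any pair
    overlaps.  The result is always an exact sum of well depths, so equality
    comparisons against other implementations are legitimate.
    """
    parts = config.particles
    n = len(parts)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dr = minimum_image(
                parts[j].position - parts[i].position, config.box_edge
            )
            e = pair_energy(parts[i], parts[j], params, dr)
            if e is OVERLAP:
                return OVERLAP
            total += e
    return total
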