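"""Domain types and the state-augmented Kern-Frenkel pair potential.

The monomer is a hard disc of diameter ``sigma`` carrying three attractive
patches at 120 degrees.  Two particles i, j bind with square-well energy
``-epsilon`` when their centre distance lies in ``[sigma, sigma + delta)``,
a patch on each points at the other within half-opening angle ``theta_pw``,
and *both* patches are in the closed (bindable) state ``p = 1``.  The binary
patch state models the open/closed conformations of the stacking interface
of a trisymmetric DNA tile; ``p_open`` is the stationary probability that a
patch of an isolated particle is open (``p = 0``).

Energies are in units of k_B*T (beta = 1).  The hard core is handled as a
move rejection in the sampler; here it is reported through the ``overlap``
flag / an infinite energy sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "Particle",
    "Configuration",
    "minimum_image",
    "pair_energy",
    "total_energy",
    "random_configuration",
]

TWO_PI = 2.0 * math.pi
N_PATCHES = 3


def minimum_image(dx: np.ndarray, box_side: float) -> np.ndarray:
    """Wrap a displacement (or array of displacements) into the primary image.

    Each component of the result lies in ``[-box_side/2, box_side/2)``.
    """
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    dx = np.asarray(dx, dtype=float)
    return dx - box_side * np.floor(dx / box_side + 0.5)


@dataclass(frozen=True)
class ModelParams:
    """Physical and algorithmic parameters of the patchy-disc model.

    Parameters
    ----------
    sigma : hard-core diameter (sets the length unit).
    delta : square-well attraction range beyond contact.
    theta_pw : patch half-opening angle in radians (classical Kern-Frenkel
        convention: bonding requires angular deviation < theta_pw on both
        sides).
    epsilon : interaction strength in k_B*T (see ``normalize_patch_entropy``).
    p_open : stationary open probability of an isolated patch, in [0, 1].
    box_side : periodic square box edge.
    n_particles : particle count.
    normalize_patch_entropy : with the default True, ``epsilon`` is the
        per-bond interaction strength at fixed association entropy: the
        square-well depth is ``epsilon + 2 ln(pi / theta_pw)``, compensating
        the angular phase-space window ``(theta_pw / pi)**2`` of a bond so
        that patch width tunes bond geometry and flexibility, not effective
        bond strength.  Set False for the textbook Kern-Frenkel well of
        depth exactly ``epsilon``.
    """

    sigma: float = 1.0
    delta: float = 0.038
    theta_pw: float = 0.44
    epsilon: float = 6.0
    p_open: float = 0.8
    box_side: float = 34.0
    n_particles: int = 150
    normalize_patch_entropy: bool = True
    n_patches: int = field(default=N_PATCHES, init=False)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if not 0 <= self.delta < self.sigma:
            raise ValueError("delta must satisfy 0 <= delta << sigma")
        if not 0 < self.theta_pw < math.pi / 3:
            raise ValueError("theta_pw must lie in (0, pi/3)")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0 <= self.p_open <= 1:
            raise ValueError("p_open must lie in [0, 1]")
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.n_particles < 0:
            raise ValueError("n_particles must be non-negative")
        # single bond per patch: two partners of one patch would have to sit
        # within the patch cone while staying a hard-core diameter apart;
        # the worst case puts both at range sigma+delta, angular separation
        # acos(1 - sigma^2 / (2 (sigma+delta)^2)).
        rmax = self.sigma + self.delta
        min_sep = math.acos(1.0 - self.sigma**2 / (2.0 * rmax**2))
        if 2.0 * self.theta_pw >= min_sep:
            raise ValueError(
                "delta/theta_pw too large: a single patch could bind two "
                f"partners (2*theta_pw = {2*self.theta_pw:.3f} >= "
                f"{min_sep:.3f})"
            )

    @property
    def well_depth(self) -> float:
        """Square-well depth in k_B*T actually entering the Hamiltonian.

        Zero epsilon means no attraction in either convention.
        """
        if self.epsilon > 0 and self.normalize_patch_entropy:
            return self.epsilon + 2.0 * math.log(math.pi / self.theta_pw)
        return self.epsilon

    @property
    def area_fraction(self) -> float:
        return self.n_particles * math.pi * (self.sigma / 2.0) ** 2 / self.box_side**2

    @property
    def range_sq(self) -> float:
        return (self.sigma + self.delta) ** 2

    @staticmethod
    def for_area_fraction(area_fraction: float, n_particles: int, **kw) -> "ModelParams":
        """Build params with box_side chosen to hit a target area fraction."""
        sigma = kw.get("sigma", 1.0)
        box = math.sqrt(n_particles * math.pi * (sigma / 2.0) ** 2 / area_fraction)
        return ModelParams(box_side=box, n_particles=n_particles, **kw)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class Particle:
    """One monomer: centre, orientation of patch 0, three binary patch states."""

    x: float
    y: float
    orientation: float
    patch_states: tuple[int, int, int] = (1, 1, 1)

    def patch_direction(self, k: int) -> np.ndarray:
        a = self.orientation + k * TWO_PI / 3.0
        return np.array([math.cos(a), math.sin(a)])


class Configuration:
    """Particle coordinates, orientations and patch states at one step.

    Stored columnar (``pos`` (N,2), ``orient`` (N,), ``states`` (N,3) int8)
    for efficiency; :meth:`particles` materializes :class:`Particle` objects.
    """

    def __init__(
        self,
        pos: np.ndarray,
        orient: np.ndarray,
        states: np.ndarray,
        box_side: float,
        step_index: int = 0,
        params_ref: str = "",
    ) -> None:
        self.pos = np.array(pos, dtype=float).reshape(-1, 2)
        self.orient = np.array(orient, dtype=float).reshape(-1)
        self.states = np.array(states, dtype=np.int8).reshape(-1, 3)
        if not (len(self.pos) == len(self.orient) == len(self.states)):
            raise ValueError("pos, orient and states must have equal length")
        if not np.all(np.isfinite(self.pos)) or not np.all(np.isfinite(self.orient)):
            raise ValueError("non-finite coordinates")
        self.box_side = float(box_side)
        self.step_index = int(step_index)
        self.params_ref = params_ref
        self.pos %= self.box_side
        self.orient %= TWO_PI

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_particles(self) -> int:
        return len(self.pos)

    def particles(self) -> list[Particle]:
        return [
            Particle(self.pos[i, 0], self.pos[i, 1], self.orient[i],
                     tuple(int(s) for s in self.states[i]))
            for i in range(len(self))
        ]

    @staticmethod
    def from_particles(parts: Sequence[Particle], box_side: float, **kw) -> "Configuration":
        pos = np.array([[p.x, p.y] for p in parts], dtype=float).reshape(-1, 2)
        orient = np.array([p.orientation for p in parts], dtype=float)
        states = np.array([p.patch_states for p in parts], dtype=np.int8).reshape(-1, 3)
        return Configuration(pos, orient, states, box_side, **kw)

    def check_no_overlap(self, sigma: float) -> None:
        """Raise if any pair violates the hard core (minimum-image metric)."""
        n = len(self)
        for i in range(n):
            d = minimum_image(self.pos[i + 1:] - self.pos[i], self.box_side)
            r2 = np.einsum("ij,ij->i", d, d)
            bad = np.nonzero(r2 < sigma**2 * (1 - 1e-12))[0]
            if bad.size:
                j = i + 1 + int(bad[0])
                raise ValueError(f"hard-core overlap between particles {i} and {j}")


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % TWO_PI - math.pi


def pair_energy(
    pi: Particle,
    pj: Particle,
    params: ModelParams,
    dx: Optional[np.ndarray] = None,
) -> tuple[float, Optional[tuple[int, int]]]:
    """State-aware Kern-Frenkel pair energy and the bonding patch pair.

    Returns ``(inf, None)`` on hard-core overlap (callers treat it as a move
    rejection), ``(-params.well_depth, (alpha, beta))`` when patches alpha on
    i and beta on j satisfy range, angular and state criteria, else
    ``(0, None)``.
    Should several patch pairs qualify (geometrically excluded at default
    parameters), the pair with the smallest summed angular deviation wins and
    the energy stays ``-epsilon`` — a pair shares at most one bond.
    """
    for p in (pi, pj):
        if not all(map(math.isfinite, (p.x, p.y, p.orientation))):
            raise ValueError("non-finite particle coordinates")
    if dx is None:
        dx = minimum_image(np.array([pj.x - pi.x, pj.y - pi.y]), params.box_side)
    r2 = float(dx @ dx)
    if r2 < params.sigma**2:
        return math.inf, None
    if r2 >= params.range_sq:
        return 0.0, None
    phi = math.atan2(dx[1], dx[0])
    best: Optional[tuple[float, int, int]] = None
    for a in range(N_PATCHES):
        if pi.patch_states[a] != 1:
            continue
        dev_i = abs(_wrap_angle(pi.orientation + a * TWO_PI / 3.0 - phi))
        if dev_i >= params.theta_pw:
            continue
        for b in range(N_PATCHES):
            if pj.patch_states[b] != 1:
                continue
            dev_j = abs(_wrap_angle(pj.orientation + b * TWO_PI / 3.0 - phi - math.pi))
            if dev_j >= params.theta_pw:
                continue
            cand = (dev_i + dev_j, a, b)
            if best is None or cand < best:
                best = cand
    if best is None:
        return 0.0, None
    return -params.well_depth, (best[1], best[2])


def total_energy(config: Configuration, params: ModelParams, method: str = "cells") -> float:
    """Total bonded energy: sum of pair_energy over all unordered pairs.

    ``method="cells"`` uses the cell-list kernel, ``method="brute"`` the
    O(N^2) reference sum; the two agree to floating tolerance.  An overlap
    raises, naming the offending pair.
    """
    config.check_no_overlap(params.sigma)
    if method == "brute":
        parts = config.particles()
        e = 0.0
        for i in range(len(parts)):
            for j in range(i + 1, len(parts)):
                eij, _ = pair_energy(parts[i], parts[j], params)
                e += eij
        return e
    if method == "cells":
        from . import _kernels

        return _kernels.total_energy_cells(
            config.pos[:, 0].copy(), config.pos[:, 1].copy(),
            config.orient.copy(), config.states.astype(np.int8),
            config.box_side, params.sigma, params.delta,
            params.theta_pw, params.well_depth,
        )
    raise ValueError(f"unknown method {method!r}")


def random_configuration(
    params: ModelParams,
    rng: np.random.Generator,
    max_attempts_per_particle: int = 2000,
) -> Configuration:
    """Rejection-sample a non-overlapping random configuration.

    Orientations are uniform; patch states are Bernoulli with
    ``P(open) = p_open``.  Raises if the area fraction is too high to place
    all particles within the attempt budget.
    """
    n = params.n_particles
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    budget = max_attempts_per_particle * max(n, 1)
    while placed < n:
        cand = rng.uniform(0.0, params.box_side, size=2)
        if placed:
            d = minimum_image(pos[:placed] - cand, params.box_side)
            if np.min(np.einsum("ij,ij->i", d, d)) < params.sigma**2:
                attempts += 1
                if attempts > budget:
                    raise RuntimeError(
                        f"could not place {n} particles at area fraction "
                        f"{params.area_fraction:.3f}"
                    )
                continue
        pos[placed] = cand
        placed += 1
    orient = rng.uniform(0.0, TWO_PI, size=n)
    states = (rng.random((n, 3)) >= params.p_open).astype(np.int8)  # 1 = closed
    return Configuration(pos, orient, states, params.box_side)
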