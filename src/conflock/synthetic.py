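"""Seeded synthetic trajectory ensembles with planted ground truth.

The generator is a statistical emulator of the data a replicate MD study
produces, not an MD engine.  It plants, per system:

* ``K`` metastable basins: copies of a self-avoiding reference Calpha chain
  displaced along a two-dimensional "essential mode" plane, so that the
  dominant coordinate variance is genuinely two-dimensional and the basins
  appear as well-separated islands in the PC1/PC2 projection;
* a basin-hopping frame sequence with geometric dwell times whose stationary
  occupancies equal the requested basin occupancies (each new segment's basin
  is drawn independently from the occupancy vector, so stationarity is exact);
* ``m`` linearly interpolated transition frames at every basin switch,
  labelled -1 — these fall in low-density PC-space corridors, the population
  a density-based census should report as noise;
* optional rank-1 correlated-motion blocks: a shared scalar latent factor
  times a fixed unit direction added to every residue of both blocks, giving
  the closed-form inter-block correlation rho = g^2 / (g^2 + 3 sigma^2);
* an optional pseudo-ligand whose atoms sit at ideal contact geometry
  (H-bond 2.9 A, hydrophobic 4.0 A, ionic 3.5 A, water bridge 2.8 A via a
  pseudo-water) in a Bernoulli(bound_fraction) subset of frames and are
  displaced beyond every cutoff otherwise.

Replicate ``r`` is generated from ``seed + r`` (1-based), the static
structure (chain, basins, mode plane) from ``seed`` itself, so all replicates
of a system share geometry but not dynamics.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .errors import ParameterError, SelectionError
from .io import Ensemble, Topology

BOND_LENGTH = 3.8       # A, consecutive Calpha distance
MIN_SELF_DISTANCE = 3.0  # A, self-avoidance cutoff for the reference walk

CONTACT_GEOMETRY = {
    "hbond": 2.9,
    "hydrophobic": 4.0,
    "ionic": 3.5,
    "water_bridge": 2.8,  # each leg of the bridge
}
UNBOUND_DISTANCE = 10.0  # A, beyond every detection cutoff


@dataclasses.dataclass
class CorrelationBlock:
    """Two residue sets coupled through a shared latent factor."""

    residues_a: tuple
    residues_b: tuple
    rho: float
    sign: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= abs(self.rho) <= 1.0):
            raise ParameterError("|rho| must be <= 1")
        if self.sign not in (-1, 1):
            raise ParameterError("sign must be -1 or +1")


@dataclasses.dataclass
class LigandSpec:
    """Pseudo-ligand contacts: interaction type -> bound fraction."""

    contacts: dict
    pocket_residues: tuple | None = None

    def __post_init__(self) -> None:
        for t, f in self.contacts.items():
            if t not in CONTACT_GEOMETRY:
                raise ParameterError(f"unknown contact type {t!r}")
            if not (0.0 <= f <= 1.0):
                raise ParameterError("bound fractions must be in [0, 1]")


@dataclasses.dataclass
class SyntheticSpec:
    """Full description of a synthetic system.

    Defaults emulate a scaled-down version of a 3-replicate binding study:
    3 replicates, frames every 100 ps, ~10% of frames in transitions.
    """

    n_residues: int = 40
    n_basins: int = 3
    basin_separation: float = 5.0     # A, per-residue displacement magnitude
    intra_basin_sigma: float = 0.5    # A, isotropic within-basin noise
    basin_occupancies: tuple | None = None   # uniform when None
    mean_dwell: float | None = None   # frames; derived from noise target when None
    transition_length: int = 6        # interpolated frames per basin switch
    transition_bow: float = 0.08      # per-switch bow amplitude, fraction of inter-basin distance
    target_noise_fraction: float = 0.10
    correlation_blocks: tuple = ()
    ligand: LigandSpec | None = None
    flexible_residues: tuple = ()     # residues given extra mobility
    flexible_extra_sigma: float = 0.0
    n_replicates: int = 3
    n_frames: int = 1000              # per replicate
    frame_interval: float = 100.0     # ps
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_residues < 2:
            raise ParameterError("n_residues must be >= 2")
        if self.n_basins < 1:
            raise ParameterError("need at least one basin")
        if self.intra_basin_sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if self.basin_separation <= 0 and self.n_basins > 1:
            if self.basin_separation == 0:
                warnings.warn("basin_separation = 0: basins are degenerate")
            else:
                raise ParameterError("basin_separation must be positive")
        if not (0.0 <= self.target_noise_fraction < 1.0):
            raise ParameterError("target_noise_fraction must be in [0, 1)")
        if self.basin_occupancies is not None:
            occ = np.asarray(self.basin_occupancies, float)
            if occ.size != self.n_basins or np.any(occ < 0):
                raise ParameterError("occupancies must be non-negative, one per basin")
            if abs(occ.sum() - 1.0) > 1e-9:
                raise ParameterError("occupancies must sum to 1 (+-1e-9)")
        if self.transition_length < 1:
            raise ParameterError("transition_length must be >= 1")

    @property
    def occupancies(self) -> np.ndarray:
        if self.basin_occupancies is None:
            return np.full(self.n_basins, 1.0 / self.n_basins)
        return np.asarray(self.basin_occupancies, float)

    def effective_mean_dwell(self) -> float:
        """Dwell (basin frames per segment) hitting the noise target.

        A switch happens between segments with probability q = 1 - sum(pi^2)
        (the new segment's basin is drawn from the occupancies), inserting m
        transition frames, so the expected noise fraction is
        f = m q / (d + m q); inverting gives d.
        """
        if self.mean_dwell is not None:
            return float(self.mean_dwell)
        occ = self.occupancies
        q = 1.0 - float(np.sum(occ**2))
        f = self.target_noise_fraction
        if q <= 0 or f <= 0:
            return float(self.n_frames)  # single basin or no noise requested
        return self.transition_length * q * (1.0 - f) / f


@dataclasses.dataclass
class GroundTruth:
    """Planted truth for a generated system (all replicates concatenated)."""

    frame_labels: np.ndarray          # basin index per frame, -1 = transition
    noise_fraction: float             # realized transition-frame fraction
    basin_occupancies: np.ndarray     # planted stationary occupancies
    block_correlations: tuple         # expected signed rho per planted block
    contact_fractions: dict           # interaction type -> realized fraction
    basin_centers: np.ndarray         # (K, n_residues, 3)


# ---------------------------------------------------------------------------
# building blocks

def make_reference_chain(n_residues: int, seed: int) -> np.ndarray:
    """Self-avoiding 3-D random walk with fixed 3.8 A consecutive distance."""
    if n_residues < 2:
        raise ParameterError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    i = 1
    while i < n_residues:
        placed = False
        for _attempt in range(200):
            v = rng.normal(size=3)
            v *= BOND_LENGTH / np.linalg.norm(v)
            candidate = coords[i - 1] + v
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - candidate, axis=1)) >= MIN_SELF_DISTANCE:
                coords[i] = candidate
                placed = True
                break
        if placed:
            i += 1
        else:
            i = max(1, i - 1)  # backtrack out of a dead end
    return coords


def _mode_plane(rng: np.random.Generator, n_residues: int) -> tuple[np.ndarray, np.ndarray]:
    """Two per-residue-orthonormal direction fields spanning the basin plane."""
    a = rng.normal(size=(n_residues, 3))
    u1 = a / np.linalg.norm(a, axis=1, keepdims=True)
    b = rng.normal(size=(n_residues, 3))
    b -= (np.sum(b * u1, axis=1, keepdims=True)) * u1
    u2 = b / np.linalg.norm(b, axis=1, keepdims=True)
    return u1, u2


def _structure(spec: SyntheticSpec):
    """Static per-system geometry: chain, mode plane and basin centers."""
    chain = make_reference_chain(spec.n_residues, spec.seed)
    rng = np.random.default_rng((spec.seed, 1))
    u1, u2 = _mode_plane(rng, spec.n_residues)
    K = spec.n_basins
    if K == 1:
        return chain, u1, u2, chain[None].copy()
    if spec.basin_separation == 0:
        warnings.warn("basin_separation = 0: basins are degenerate copies")
    theta0 = rng.uniform(0, 2 * np.pi)
    basins = np.empty((K, spec.n_residues, 3))
    for k in range(K):
        th = theta0 + 2 * np.pi * k / K
        basins[k] = chain + spec.basin_separation * (np.cos(th) * u1 + np.sin(th) * u2)
    return chain, u1, u2, basins


def make_basins(spec: SyntheticSpec) -> np.ndarray:
    """K basin reference conformations: chain + in-plane displacements.

    Basin k displaces every residue by ``basin_separation`` Angstrom along a
    basin-specific direction in the planted mode plane (equally spaced
    angles with a random offset), so pairwise basin Calpha-RMSD is at least
    2 sin(pi/K) * basin_separation >= basin_separation / 2 for K <= 12.
    A single basin equals the reference chain itself.
    """
    return _structure(spec)[3]


def _basin_frame_plan(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-frame basin labels for one replicate, -1 for transition frames."""
    n, m = spec.n_frames, spec.transition_length
    occ = spec.occupancies
    dwell_mean = spec.effective_mean_dwell()
    p_leave = min(1.0, 1.0 / max(dwell_mean, 1.0))
    labels = np.empty(n, dtype=int)
    pos = 0
    state = int(rng.choice(spec.n_basins, p=occ))
    while pos < n:
        dwell = int(rng.geometric(p_leave))
        take = min(dwell, n - pos)
        labels[pos: pos + take] = state
        pos += take
        if pos >= n:
            break
        nxt = int(rng.choice(spec.n_basins, p=occ))
        if nxt != state:
            take = min(m, n - pos)
            labels[pos: pos + take] = -1
            pos += take
            state = nxt
    return labels


def _block_factor_strength(rho: float, sigma: float) -> float:
    """g with rho = g^2 / (g^2 + 3 sigma^2)."""
    if rho >= 1.0 or sigma == 0.0:
        return 1.0
    return float(np.sqrt(3.0 * sigma**2 * rho / (1.0 - rho)))


def _protein_replicate(
    spec: SyntheticSpec,
    basins: np.ndarray,
    mode_plane: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates (F, n_res, 3) and frame labels for one replicate."""
    u1, u2 = mode_plane
    labels = _basin_frame_plan(spec, rng)
    F, n = spec.n_frames, spec.n_residues
    coords = np.empty((F, n, 3))
    # centers: basin frames at their basin; transition runs interpolate along
    # a per-switch bowed path so repeated switches between the same basins do
    # not stack onto one line and accumulate density
    f = 0
    prev_state = None
    while f < F:
        lab = labels[f]
        if lab >= 0:
            g = f
            while g < F and labels[g] == lab:
                g += 1
            coords[f:g] = basins[lab]
            prev_state = lab
            f = g
        else:
            g = f
            while g < F and labels[g] == -1:
                g += 1
            nxt_state = labels[g] if g < F else prev_state
            a = basins[prev_state if prev_state is not None else 0]
            b = basins[nxt_state if nxt_state is not None else 0]
            amp = rng.normal(0.0, spec.transition_bow * np.linalg.norm(b - a))
            phi = rng.uniform(0.0, 2 * np.pi)
            bow_dir = np.cos(phi) * u1 + np.sin(phi) * u2
            mrun = g - f
            for j in range(mrun):
                t = (j + 1) / (mrun + 1)
                coords[f + j] = (1 - t) * a + t * b + (4 * t * (1 - t) * amp) * bow_dir
            f = g
    if spec.intra_basin_sigma > 0:
        coords += rng.normal(scale=spec.intra_basin_sigma, size=coords.shape)
    if spec.flexible_residues and spec.flexible_extra_sigma > 0:
        idx = np.asarray([r - 1 for r in spec.flexible_residues], int)
        coords[:, idx, :] += rng.normal(scale=spec.flexible_extra_sigma, size=(F, idx.size, 3))
    # rank-1 correlated-motion blocks
    block_rng = np.random.default_rng((spec.seed, 2))
    for blk in spec.correlation_blocks:
        u = block_rng.normal(size=3)
        u /= np.linalg.norm(u)
        g = _block_factor_strength(abs(blk.rho), spec.intra_basin_sigma)
        factor = rng.normal(size=F)
        ia = np.asarray([r - 1 for r in blk.residues_a], int)
        ib = np.asarray([r - 1 for r in blk.residues_b], int)
        disp = g * factor[:, None] * u[None, :]
        coords[:, ia, :] += disp[:, None, :]
        coords[:, ib, :] += blk.sign * np.sign(blk.rho) * disp[:, None, :]
    return coords, labels


def _make_protein_topology(spec: SyntheticSpec) -> Topology:
    n = spec.n_residues
    flags = {
        "alpha_carbon": np.ones(n, dtype=bool),
        "backbone": np.ones(n, dtype=bool),
    }
    return Topology(
        names=np.asarray(["CA"] * n, dtype=object),
        elements=np.asarray(["C"] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.asarray(["ALA"] * n, dtype=object),
        chains=np.asarray(["A"] * n, dtype=object),
        masses=np.full(n, 12.011),
        flags=flags,
    )


_LIGAND_ATOM = {
    # contact type -> (atom name, element, extra topology flags on the ligand
    #                  atom, flag required on the pocket partner)
    "hbond": ("O1L", "O", ("hbond_acceptor",), "hbond_donor_heavy"),
    "hydrophobic": ("C1L", "C", ("apolar_carbon",), "apolar_carbon"),
    "ionic": ("N1L", "N", ("charged_positive", "hbond_acceptor"), "charged_negative"),
    "water_bridge": ("O2L", "O", ("hbond_acceptor",), "hbond_donor_heavy"),
}


def plant_ligand(
    spec: SyntheticSpec,
    topology: Topology,
    replicate_coords: list[np.ndarray],
    rng_seeds: list[int],
) -> tuple[Topology, list[np.ndarray], dict]:
    """Append pseudo-ligand (and pseudo-water) atoms with planted contacts.

    Each requested contact type gets one dedicated ligand atom and one pocket
    residue; in a Bernoulli(bound_fraction) subset of frames the atom sits at
    ideal contact geometry, otherwise it is displaced to ~10 A.  Returns the
    extended topology, extended coordinates and the realized contact
    fraction per type.
    """
    lig = spec.ligand
    if lig is None:
        raise ParameterError("spec has no ligand section")
    types = sorted(lig.contacts)
    n = spec.n_residues
    if lig.pocket_residues is not None:
        pocket = list(lig.pocket_residues)
        if any(r < 1 or r > n for r in pocket):
            raise SelectionError("pocket residues outside the topology")
    else:
        pocket = [n // 2 + i + 1 for i in range(len(types))]
        if any(r > n for r in pocket):
            raise SelectionError("chain too short to host the binding pocket")
    names = list(topology.names)
    elements = list(topology.elements)
    resids = list(topology.resids)
    resnames = list(topology.resnames)
    chains = list(topology.chains)
    masses = list(topology.masses)
    flags = {k: list(v) for k, v in topology.flags.items()}
    lig_resid = int(max(topology.resids)) + 1

    def _append(name, elem, resname, resid, mass, on_flags):
        names.append(name)
        elements.append(elem)
        resids.append(resid)
        resnames.append(resname)
        chains.append("L")
        masses.append(mass)
        for k in flags:
            flags[k].append(k in on_flags)

    has_bridge = "water_bridge" in types
    for i, t in enumerate(types):
        name, elem, extra, partner_flag = _LIGAND_ATOM[t]
        pocket_res = pocket[i % len(pocket)]
        flags[partner_flag][pocket_res - 1] = True
        _append(name, elem, "LIG", lig_resid, 15.999 if elem == "O" else 14.007 if elem == "N" else 12.011,
                ("ligand",) + extra)
    if has_bridge:
        _append("O", "O", "HOH", lig_resid + 1, 15.999,
                ("water", "hbond_donor_heavy", "hbond_acceptor"))

    new_top = Topology(
        names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        resids=np.asarray(resids, dtype=int),
        resnames=np.asarray(resnames, dtype=object),
        chains=np.asarray(chains, dtype=object),
        masses=np.asarray(masses, dtype=float),
        flags={k: np.asarray(v, dtype=bool) for k, v in flags.items()},
    )

    realized = {t: [0, 0] for t in types}  # bound, total
    new_coords = []
    for rep, coords in enumerate(replicate_coords):
        rng = np.random.default_rng((rng_seeds[rep], 3))
        F = coords.shape[0]
        extra_n = len(types) + (1 if has_bridge else 0)
        out = np.empty((F, n + extra_n, 3))
        out[:, :n, :] = coords
        center = coords.mean(axis=1)
        for i, t in enumerate(types):
            pocket_pos = coords[:, pocket[i % len(pocket)] - 1, :]
            direction = pocket_pos - center
            norms = np.linalg.norm(direction, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            direction /= norms
            bound = rng.random(F) < lig.contacts[t]
            realized[t][0] += int(bound.sum())
            realized[t][1] += F
            if t == "water_bridge":
                leg = CONTACT_GEOMETRY[t]
                lig_dist = np.where(bound, 2 * leg, UNBOUND_DISTANCE + 5.0)
                wat_dist = np.where(bound, leg, UNBOUND_DISTANCE)
                out[:, n + i, :] = pocket_pos + direction * lig_dist[:, None]
                out[:, n + len(types), :] = pocket_pos + direction * wat_dist[:, None]
            else:
                d = np.where(bound, CONTACT_GEOMETRY[t], UNBOUND_DISTANCE)
                out[:, n + i, :] = pocket_pos + direction * d[:, None]
        new_coords.append(out)
    fractions = {t: b / tot for t, (b, tot) in realized.items()}
    return new_top, new_coords, fractions


def simulate(spec: SyntheticSpec) -> tuple[Topology, list[Ensemble], GroundTruth]:
    """Generate all replicates of a system plus its ground truth.

    Returns ``(topology, ensembles, ground_truth)`` with one Ensemble per
    replicate; :func:`conflock.io.concatenate` joins them for analysis.
    """
    _chain, u1, u2, basins = _structure(spec)
    topology = _make_protein_topology(spec)
    rep_coords, rep_labels, rep_seeds = [], [], []
    for r in range(spec.n_replicates):
        seed_r = spec.seed + r + 1
        rng = np.random.default_rng(seed_r)
        coords, labels = _protein_replicate(spec, basins, (u1, u2), rng)
        rep_coords.append(coords)
        rep_labels.append(labels)
        rep_seeds.append(seed_r)
    contact_fractions: dict = {}
    if spec.ligand is not None:
        topology, rep_coords, contact_fractions = plant_ligand(
            spec, topology, rep_coords, rep_seeds
        )
    ensembles = [
        Ensemble(c, frame_interval=spec.frame_interval, system_label=spec.label)
        for c in rep_coords
    ]
    all_labels = np.concatenate(rep_labels)
    truth = GroundTruth(
        frame_labels=all_labels,
        noise_fraction=float(np.mean(all_labels == -1)),
        basin_occupancies=spec.occupancies,
        block_correlations=tuple(
            b.sign * (-1 if b.rho < 0 else 1) * abs(b.rho)
            for b in spec.correlation_blocks
        ),
        contact_fractions=contact_fractions,
        basin_centers=basins,
    )
    return topology, ensembles, truth
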