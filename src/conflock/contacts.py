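"""Frame-by-frame protein-ligand interaction detection and occupancy fractions.

Four interaction classes are monitored between every protein residue and the
ligand: hydrogen bonds, hydrophobic contacts, ionic interactions and
water-mediated bridges.  The geometric criteria are standard-practice
defaults, all overridable through :class:`ContactCriteria`:

* hbond — donor-heavy to acceptor distance <= 3.5 A; when an explicit
  hydrogen is attached to the donor (within 1.25 A) the donor-H...acceptor
  angle must additionally be >= 120 degrees.  Without hydrogens (coarse
  pseudo-atom topologies) the distance rule alone applies.
* hydrophobic — any apolar-carbon pair <= 4.5 A.
* ionic — centroid of a residue's formally positive atoms within 4.0 A of
  the centroid of the partner's negative atoms, or vice versa.
* water_bridge — a single water oxygen satisfying the hbond distance rule to
  both the protein residue and the ligand in the same frame.

Occupancy is presence-based: a (residue, type) pair counts at most once per
frame regardless of how many atom pairs satisfy the criterion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .errors import ParameterError, ShapeError
from .io import Ensemble, Topology

INTERACTION_TYPES = ("hbond", "hydrophobic", "ionic", "water_bridge")


@dataclasses.dataclass
class ContactCriteria:
    """Geometric cutoffs (Angstrom / degrees) for each interaction class."""

    hbond_distance: float = 3.5
    hbond_angle: float = 120.0
    hydrophobic_distance: float = 4.5
    ionic_distance: float = 4.0

    def __post_init__(self) -> None:
        for name in ("hbond_distance", "hydrophobic_distance", "ionic_distance"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def _pairwise_min(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0 or b.size == 0:
        return np.inf
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())


def _hbond_pair(frame, heavy_i, acceptor_j, hydrogens, criteria) -> bool:
    """Donor-heavy i to acceptor j, with an angle check if i has a hydrogen."""
    d = np.linalg.norm(frame[heavy_i] - frame[acceptor_j])
    if d > criteria.hbond_distance:
        return False
    attached = [h for h in hydrogens if np.linalg.norm(frame[h] - frame[heavy_i]) <= 1.25]
    if not attached:
        return True  # heavy-atom fallback: no explicit hydrogens
    for h in attached:
        v1 = frame[heavy_i] - frame[h]
        v2 = frame[acceptor_j] - frame[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= criteria.hbond_angle:
            return True
    return False


def detect_contacts(
    frame: np.ndarray,
    topology: Topology,
    criteria: ContactCriteria | None = None,
) -> set:
    """Interactions present in one frame, as a set of (residue_number, type)."""
    criteria = criteria or ContactCriteria()
    frame = np.asarray(frame, float)
    if frame.shape != (topology.n_atoms, 3):
        raise ShapeError("frame does not match topology")
    f = topology.flags
    lig = np.flatnonzero(f["ligand"])
    if lig.size == 0:
        return set()
    protein = ~f["ligand"] & ~f["water"]
    hydrogens = np.flatnonzero(np.asarray([e.upper() == "H" for e in topology.elements]))
    waters_o = np.flatnonzero(f["water"] & np.asarray([e.upper() == "O" for e in topology.elements]))

    lig_donor = lig[f["hbond_donor_heavy"][lig]]
    lig_acc = lig[f["hbond_acceptor"][lig]]
    lig_apolar = lig[f["apolar_carbon"][lig]]
    lig_pos = frame[lig[f["charged_positive"][lig]]]
    lig_neg = frame[lig[f["charged_negative"][lig]]]

    found = set()
    for res in np.unique(topology.resids[protein]):
        ratoms = np.flatnonzero(protein & (topology.resids == res))
        r_donor = ratoms[f["hbond_donor_heavy"][ratoms]]
        r_acc = ratoms[f["hbond_acceptor"][ratoms]]
        r_apolar = ratoms[f["apolar_carbon"][ratoms]]
        r_pos = frame[ratoms[f["charged_positive"][ratoms]]]
        r_neg = frame[ratoms[f["charged_negative"][ratoms]]]
        if (r_donor.size + r_acc.size + r_apolar.size + r_pos.size + r_neg.size) == 0:
            continue  # residue cannot participate in any interaction class

        hb = any(
            _hbond_pair(frame, d, a, hydrogens, criteria)
            for d in r_donor for a in lig_acc
        ) or any(
            _hbond_pair(frame, d, a, hydrogens, criteria)
            for d in lig_donor for a in r_acc
        )
        if hb:
            found.add((int(res), "hbond"))

        if _pairwise_min(frame[r_apolar], frame[lig_apolar]) <= criteria.hydrophobic_distance:
            found.add((int(res), "hydrophobic"))

        ionic = False
        if r_pos.size and lig_neg.size:
            ionic |= np.linalg.norm(r_pos.mean(0) - lig_neg.mean(0)) <= criteria.ionic_distance
        if r_neg.size and lig_pos.size:
            ionic |= np.linalg.norm(r_neg.mean(0) - lig_pos.mean(0)) <= criteria.ionic_distance
        if ionic:
            found.add((int(res), "ionic"))

        for w in waters_o:
            to_res = any(
                np.linalg.norm(frame[w] - frame[a]) <= criteria.hbond_distance
                for a in np.concatenate([r_donor, r_acc])
            )
            to_lig = any(
                np.linalg.norm(frame[w] - frame[a]) <= criteria.hbond_distance
                for a in np.concatenate([lig_donor, lig_acc])
            )
            if to_res and to_lig:
                found.add((int(res), "water_bridge"))
                break
    return found


@dataclasses.dataclass
class ContactTimeline:
    """Boolean occupancy per frame for every observed (residue, type) pair."""

    occupancy: dict            # (residue, type) -> bool array of length F
    n_frames: int

    def __post_init__(self) -> None:
        for (res, typ), arr in self.occupancy.items():
            if typ not in INTERACTION_TYPES:
                raise ParameterError(f"unknown interaction type {typ!r}")
            if len(arr) != self.n_frames:
                raise ShapeError("timeline length mismatch")


def contact_timeline(
    ensemble: Ensemble,
    topology: Topology,
    criteria: ContactCriteria | None = None,
) -> ContactTimeline:
    """Run :func:`detect_contacts` over every frame."""
    criteria = criteria or ContactCriteria()
    occupancy: dict = {}
    F = ensemble.n_frames
    for fidx in range(F):
        for key in detect_contacts(ensemble.coordinates[fidx], topology, criteria):
            if key not in occupancy:
                occupancy[key] = np.zeros(F, dtype=bool)
            occupancy[key][fidx] = True
    return ContactTimeline(occupancy, F)


def interaction_fractions(timeline: ContactTimeline) -> pd.DataFrame:
    """Fraction of frames each (residue, type) contact is present.

    Returns a tidy DataFrame with columns residue, type, fraction, sorted by
    descending fraction — the stacked-bar "interaction fraction" summary.
    """
    rows = [
        {"residue": res, "type": typ, "fraction": float(arr.mean())}
        for (res, typ), arr in timeline.occupancy.items()
    ]
    df = pd.DataFrame(rows, columns=["residue", "type", "fraction"])
    return df.sort_values("fraction", ascending=False, ignore_index=True)


def plot_fractions(df: pd.DataFrame, path) -> None:
    """Stacked-bar occupancy chart per residue, coloured by interaction type."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"hbond": "tab:green", "hydrophobic": "tab:purple",
              "ionic": "tab:red", "water_bridge": "tab:blue"}
    residues = sorted(df["residue"].unique())
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(residues)), 3.5))
    bottoms = {r: 0.0 for r in residues}
    for typ in INTERACTION_TYPES:
        sub = df[df["type"] == typ].set_index("residue")["fraction"]
        heights = [float(sub.get(r, 0.0)) for r in residues]
        ax.bar([str(r) for r in residues], heights,
               bottom=[bottoms[r] for r in residues],
               color=colors[typ], label=typ)
        for r, h in zip(residues, heights):
            bottoms[r] += h
    ax.set_ylabel("interaction fraction")
    ax.set_xlabel("residue")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
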