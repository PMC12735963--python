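"""Superposition and stability metrics: RMSD, radius of gyration, RMSF.

All deviation metrics superpose with the Kabsch least-squares fit (proper
rotations only).  RMSF and downstream covariance analyses use an iterative
mean-structure alignment: frames are repeatedly fitted to the running mean
until the mean stops moving, which removes global drift without privileging
any single frame as the reference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (
    DegeneracyError,
    InsufficientDataError,
    SelectionError,
)
from .io import Ensemble, Topology
from .selection import SelectionMask


@dataclasses.dataclass
class MetricSeries:
    """A per-frame scalar metric in Angstrom."""

    values: np.ndarray
    metric_name: str
    units: str = "A"
    fit_mask: SelectionMask | None = None
    measure_mask: SelectionMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("MetricSeries values must be 1-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < -1e-12):
            raise ValueError("metric values must be finite and non-negative")


@dataclasses.dataclass
class ProfileSeries:
    """A per-entity scalar profile (per residue or per atom), in Angstrom."""

    values: np.ndarray
    labels: list
    metric_name: str
    units: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != self.values.size:
            raise ValueError("labels/values length mismatch")
        if len(set(map(str, self.labels))) != len(self.labels):
            raise ValueError("profile labels must be unique")


def _as_indices(mask) -> np.ndarray:
    if isinstance(mask, SelectionMask):
        return mask.indices
    idx = np.asarray(mask, dtype=int)
    if idx.size == 0:
        raise SelectionError("empty atom mask")
    return idx


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray, mask=None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    The transform is fitted on the masked atoms but applied to all of
    ``mobile``.  Returns ``(rotation, translation, aligned)`` with
    ``aligned = mobile @ rotation.T + translation``.  Reflections are
    corrected so the rotation is always proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    idx = _as_indices(mask) if mask is not None else np.arange(len(mobile))
    if idx.size < 3:
        raise DegeneracyError("superposition needs at least 3 fit atoms")
    P = mobile[idx]
    Q = reference[idx]
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    # rank < 2 means the fit atoms are collinear or coincident
    if np.linalg.matrix_rank(H, tol=1e-10) < 2:
        raise DegeneracyError("degenerate (collinear) fit atoms")
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    aligned = mobile @ R.T + t
    return R, t, aligned


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    ensemble: Ensemble,
    fit_mask,
    measure_mask=None,
    reference: np.ndarray | None = None,
) -> MetricSeries:
    """Per-frame RMSD after fitting each frame to a reference.

    By default the reference is the ensemble's first frame, so the series
    starts at zero; pass an external conformation to measure against e.g. a
    crystal structure.
    """
    fit_idx = _as_indices(fit_mask)
    meas_idx = _as_indices(measure_mask) if measure_mask is not None else fit_idx
    ref = ensemble.coordinates[0] if reference is None else np.asarray(reference, float)
    vals = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        _R, _t, aligned = kabsch_superpose(ensemble.coordinates[f], ref, fit_idx)
        vals[f] = rmsd(aligned[meas_idx], ref[meas_idx])
    return MetricSeries(vals, "rmsd", fit_mask=None, measure_mask=None)


def radius_of_gyration(
    ensemble: Ensemble,
    mask,
    topology: Topology | None = None,
    mass_weighted: bool = True,
) -> MetricSeries:
    """Per-frame radius of gyration over the masked atoms.

    Rg_t = sqrt( sum_i w_i |r_i - r_com|^2 / sum_i w_i ); mass-weighted by
    default (pass ``mass_weighted=False`` for the geometric variant, or omit
    the topology, in which case unit weights are used).
    """
    idx = _as_indices(mask)
    if mass_weighted and topology is not None:
        w = np.asarray(topology.masses, float)[idx]
    else:
        w = np.ones(idx.size)
    coords = ensemble.coordinates[:, idx, :]
    com = np.einsum("fnd,n->fd", coords, w) / w.sum()
    sq = np.sum((coords - com[:, None, :]) ** 2, axis=2)
    vals = np.sqrt(np.einsum("fn,n->f", sq, w) / w.sum())
    return MetricSeries(vals, "rg")


def iterative_mean_align(
    ensemble: Ensemble,
    fit_mask,
    tol: float = 1e-6,
    max_iter: int = 10,
) -> np.ndarray:
    """Align all frames to the converged mean structure.

    Iterates: fit every frame to the current mean on the fit atoms, recompute
    the mean, stop when the mean moves by less than ``tol`` Angstrom RMSD (or
    after ``max_iter`` rounds).  Returns the aligned (F, N, 3) coordinates.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("alignment to a mean needs at least 2 frames")
    fit_idx = _as_indices(fit_mask)
    coords = ensemble.coordinates.copy()
    # start from the raw coordinate mean: frame-order independent, so the
    # converged alignment (and every downstream fluctuation statistic) is
    # invariant under frame permutation
    mean = coords.mean(axis=0)
    for _ in range(max_iter):
        for f in range(coords.shape[0]):
            _R, _t, coords[f] = kabsch_superpose(coords[f], mean, fit_idx)
        new_mean = coords.mean(axis=0)
        shift = rmsd(new_mean[fit_idx], mean[fit_idx])
        mean = new_mean
        if shift < tol:
            break
    return coords


def rmsf_profile(
    ensemble: Ensemble,
    mask,
    topology: Topology | None = None,
    grouping: str = "by_atom",
) -> ProfileSeries:
    """Root-mean-square fluctuation per residue (Calpha) or per atom.

    RMSF_i = sqrt( < |r_i - <r_i>|^2 > ) after iterative mean alignment on
    the masked atoms.  ``by_residue`` labels entries with residue numbers
    (requires a topology); ``by_atom`` labels with atom indices.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames")
    idx = _as_indices(mask)
    aligned = iterative_mean_align(ensemble, idx)
    sub = aligned[:, idx, :]
    mean = sub.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    if grouping == "by_residue":
        if topology is None:
            raise ValueError("by_residue grouping requires a topology")
        labels = [int(topology.resids[i]) for i in idx]
    elif grouping == "by_atom":
        labels = [int(i) for i in idx]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if len(set(labels)) != len(labels):
        # multiple atoms per residue: keep the Calpha when flagged, else average
        out_labels, out_vals = [], []
        labels_arr = np.asarray(labels)
        for lab in dict.fromkeys(labels):
            sel = np.flatnonzero(labels_arr == lab)
            if topology is not None:
                ca = [s for s in sel if topology.flags["alpha_carbon"][idx[s]]]
                sel = np.asarray(ca, dtype=int) if ca else sel
            out_labels.append(lab)
            out_vals.append(float(fluct[sel].mean()))
        return ProfileSeries(np.asarray(out_vals), out_labels, "rmsf")
    return ProfileSeries(fluct, labels, "rmsf")
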