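"""Essential-dynamics PCA, density-based state census, free-energy landscape.

This is the quantitative core of the package: Calpha coordinates of the
concatenated replicates are projected onto the first two principal
components; the 2-D projection is clustered with DBSCAN (eps calibrated from
the elbow of a k-distance graph when not given); the resulting labels yield a
conformational-state census — number of stable states, fraction of frames in
low-density "transition" noise, population of the largest state — and the
projection's probability density gives the Gibbs free-energy landscape

    dG(bin) = -kB * T * ln( P(bin) / P_max ),  kB = 0.0019872 kcal/(mol K).

The model/results pair (:class:`ConformationalLandscape` /
:class:`LandscapeResults`) wraps these steps in a fit-then-inspect workflow;
the underlying operations are plain functions and usable on their own.

The DBSCAN here is a self-contained implementation (index-ordered expansion,
the neighbourhood count includes the point itself); scikit-learn is used in
the test suite only, as an independent cross-check.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import deque

import numpy as np
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, ParameterError
from .geometry import iterative_mean_align
from .io import Ensemble
from .selection import SelectionMask

KB_KCAL = 0.0019872  # kcal / (mol K)


class NoElbowWarning(UserWarning):
    """The k-distance curve has no pronounced elbow; eps is a guess."""


#: An elbow only counts as separating a sparse regime from the dense bulk
#: when its k-distance exceeds this multiple of the median k-distance.
_REGIME_RATIO = 3.0


# ---------------------------------------------------------------------------
# PCA

@dataclasses.dataclass
class PCModel:
    """Top principal components of the 3N-dimensional coordinate covariance."""

    mean: np.ndarray              # (3N,) mean conformation (flattened)
    eigenvectors: np.ndarray      # (n_components, 3N), orthonormal rows
    eigenvalues: np.ndarray       # full spectrum, non-increasing
    explained_variance: np.ndarray  # fraction per kept component
    projection: np.ndarray        # (F, n_components) scores

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, float)
        if np.any(np.diff(ev) > 1e-9) or np.any(ev < -1e-9):
            raise ValueError("eigenvalues must be non-increasing and non-negative")
        G = self.eigenvectors @ self.eigenvectors.T
        if not np.allclose(G, np.eye(len(G)), atol=1e-8):
            raise ValueError("eigenvectors must be orthonormal")


def _aligned_flat(ensemble: Ensemble, mask, pre_aligned: bool) -> np.ndarray:
    idx = mask.indices if isinstance(mask, SelectionMask) else np.asarray(mask, int)
    coords = ensemble.coordinates if pre_aligned else iterative_mean_align(ensemble, idx)
    sub = coords[:, idx, :]
    return sub.reshape(sub.shape[0], -1)


def pca_project(
    ensemble: Ensemble,
    calpha_mask,
    n_components: int = 2,
    pre_aligned: bool = False,
) -> PCModel:
    """PCA of the masked-atom coordinate covariance; scores for the top PCs.

    Frames are iteratively mean-aligned first.  Sign convention: each
    eigenvector's largest-magnitude component is made positive, so scores are
    reproducible across runs and implementations.
    """
    if ensemble.n_frames < 3:
        raise InsufficientDataError("PCA needs at least 3 frames")
    X = _aligned_flat(ensemble, calpha_mask, pre_aligned)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data matrix == eigendecomposition of the covariance
    _U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (X.shape[0] - 1)
    k = min(n_components, Vt.shape[0])
    vecs = Vt[:k].copy()
    scores = Xc @ vecs.T
    for c in range(k):
        if vecs[c, np.argmax(np.abs(vecs[c]))] < 0:
            vecs[c] = -vecs[c]
            scores[:, c] = -scores[:, c]
    total = eigvals.sum()
    frac = eigvals[:k] / total if total > 0 else np.zeros(k)
    return PCModel(mean, vecs, eigvals, frac, scores)


# ---------------------------------------------------------------------------
# DBSCAN and its calibration

@dataclasses.dataclass
class ClusterParams:
    """DBSCAN parameters in PC-score units."""

    eps: float
    min_samples: int = 4
    k: int = 4  # neighbor rank used for eps calibration

    def __post_init__(self) -> None:
        if not (self.eps > 0):
            raise ParameterError(f"eps must be positive, got {self.eps}")
        if self.min_samples < 1:
            raise ParameterError("min_samples must be >= 1")
        if self.k < 1:
            raise ParameterError("k must be >= 1")


def kdistance_eps(projection: np.ndarray, k: int = 4, return_curve: bool = False):
    """Calibrate eps from the elbow of the k-distance graph.

    For every point the distance to its k-th nearest neighbour (self
    excluded) is computed; the distances are sorted ascending and the elbow
    is the point of maximum perpendicular distance to the chord joining the
    curve's endpoints (Kneedle construction, axes normalised to [0, 1]).
    Emits :class:`NoElbowWarning` when the curve is nearly straight.
    """
    X = np.asarray(projection, float)
    n = len(X)
    if n <= k:
        raise InsufficientDataError(f"need more than k={k} points, got {n}")
    tree = cKDTree(X)
    dists, _ = tree.query(X, k=k + 1)
    kdist = np.sort(dists[:, k])
    span = kdist[-1] - kdist[0]
    if span <= 0:
        warnings.warn("k-distance curve is flat; no clear elbow", NoElbowWarning)
        eps = float(kdist[-1]) if kdist[-1] > 0 else 1.0
        return (eps, kdist) if return_curve else eps
    x = np.linspace(0.0, 1.0, n)
    y = (kdist - kdist[0]) / span
    # perpendicular distance to the chord y = x (unit diagonal)
    dist_to_chord = np.abs(y - x) / np.sqrt(2.0)
    elbow = int(np.argmax(dist_to_chord))
    eps = float(kdist[elbow])
    # A meaningful elbow separates two density regimes, so its value must
    # stand well clear of the bulk neighbour scale.  When it does not, all
    # points belong to one regime and the curve's maximum is the only eps
    # that respects that (everything is "dense").
    median = float(np.median(kdist))
    if dist_to_chord[elbow] < 0.05 or (median > 0 and eps < _REGIME_RATIO * median):
        warnings.warn("k-distance curve has no pronounced elbow", NoElbowWarning)
        eps = float(kdist[-1])
    if eps <= 0:
        positive = kdist[kdist > 0]
        eps = float(positive[0]) if positive.size else 1.0
    return (eps, kdist) if return_curve else eps


def dbscan(projection: np.ndarray, params: ClusterParams) -> np.ndarray:
    """Density-based clustering with noise; returns per-point labels (-1 = noise).

    A point is core iff its closed eps-neighbourhood (Euclidean, including
    itself) holds at least ``min_samples`` points.  Clusters are the
    connected components of density-reachability; border points join the
    first cluster that reaches them in index-ordered expansion.
    """
    X = np.asarray(projection, float)
    n = len(X)
    tree = cKDTree(X)
    neighbors = tree.query_ball_point(X, params.eps)
    core = np.fromiter((len(nb) >= params.min_samples for nb in neighbors), bool, n)
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for seed in range(n):
        if labels[seed] != -1 or not core[seed]:
            continue
        labels[seed] = cluster
        queue = deque([seed])
        while queue:
            p = queue.popleft()
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(q)
        cluster += 1
    return labels


# ---------------------------------------------------------------------------
# Census and populations

@dataclasses.dataclass
class StateCensus:
    """Conformational-state bookkeeping from cluster labels."""

    labels: np.ndarray
    n_states: int
    noise_fraction: float
    populations: np.ndarray        # per-state fractions, sorted descending
    largest_state_fraction: float

    @property
    def n_frames(self) -> int:
        return self.labels.size


def census(labels: np.ndarray) -> StateCensus:
    """Count stable states, noise fraction and state populations."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ParameterError("labels are empty")
    n = labels.size
    noise = float(np.sum(labels == -1)) / n
    states, counts = np.unique(labels[labels >= 0], return_counts=True)
    pops = np.sort(counts / n)[::-1]
    return StateCensus(
        labels=labels,
        n_states=int(states.size),
        noise_fraction=noise,
        populations=pops,
        largest_state_fraction=float(pops[0]) if pops.size else 0.0,
    )


def population_table(c: StateCensus, n_top: int = 6):
    """Top-n macrostates S1..Sn plus an aggregated "Other" bar.

    "Other" collects the remaining low-population states together with the
    noise fraction; the returned fractions sum to 1.
    """
    rows = []
    top = c.populations[:n_top]
    for i, p in enumerate(top, start=1):
        rows.append((f"S{i}", float(p)))
    other = float(c.populations[n_top:].sum() + c.noise_fraction)
    rows.append(("Other", other))
    return rows


# ---------------------------------------------------------------------------
# Free-energy landscape

@dataclasses.dataclass
class FreeEnergyLandscape:
    """2-D probability grid over PC1/PC2 mapped to Gibbs free energy."""

    xedges: np.ndarray
    yedges: np.ndarray
    probability: np.ndarray     # sums to 1
    delta_g: np.ndarray         # kcal/mol, min exactly 0 at the modal bin
    temperature: float
    n_levels: int = 100

    @property
    def cap(self) -> float:
        return float(self.delta_g.max())


def fel(
    projection: np.ndarray,
    temperature: float = 310.0,
    n_bins: int = 50,
    n_levels: int = 100,
) -> FreeEnergyLandscape:
    """Free-energy landscape dG = -kB T ln(P / P_max) on a PC1/PC2 histogram.

    Empty bins carry a finite cap (max finite dG plus one contour-level
    spacing) so grids stay renderable and serialisable.
    """
    X = np.asarray(projection, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ParameterError("projection must be (F, >=2)")
    if n_bins < 2:
        raise ParameterError("need at least 2 bins per axis")
    H, xe, ye = np.histogram2d(X[:, 0], X[:, 1], bins=n_bins)
    P = H / H.sum()
    pmax = P.max()
    with np.errstate(divide="ignore"):
        dg = -KB_KCAL * temperature * np.log(P / pmax)
    finite = dg[np.isfinite(dg)]
    max_finite = float(finite.max()) if finite.size else 0.0
    spacing = max_finite / (n_levels - 1) if max_finite > 0 else KB_KCAL * temperature * np.log(2.0)
    dg[~np.isfinite(dg)] = max_finite + spacing
    return FreeEnergyLandscape(xe, ye, P, dg, temperature, n_levels)


# ---------------------------------------------------------------------------
# Model / Results

class ConformationalLandscape:
    """Conformational-landscape model of a trajectory ensemble.

    Parameters
    ----------
    ensemble:
        Concatenated replicate trajectory of one system.
    calpha_mask:
        Atoms (normally protein Calpha) defining the conformational space.
    temperature:
        Kelvin, used for the free-energy landscape (default 310, body
        temperature, matching a physiological simulation setup).
    """

    def __init__(
        self,
        ensemble: Ensemble,
        calpha_mask,
        temperature: float = 310.0,
        n_bins: int = 50,
        pre_aligned: bool = False,
    ) -> None:
        if temperature <= 0:
            raise ParameterError("temperature must be positive")
        self.ensemble = ensemble
        self.calpha_mask = calpha_mask
        self.temperature = float(temperature)
        self.n_bins = int(n_bins)
        self.pre_aligned = pre_aligned

    def fit(
        self,
        eps: float | None = None,
        min_samples: int = 4,
        k: int = 4,
    ) -> "LandscapeResults":
        """Project, calibrate (if ``eps`` is None), cluster and summarise."""
        pc = pca_project(self.ensemble, self.calpha_mask, pre_aligned=self.pre_aligned)
        auto = eps is None
        if auto:
            eps = kdistance_eps(pc.projection, k=k)
        params = ClusterParams(eps=eps, min_samples=min_samples, k=k)
        labels = dbscan(pc.projection, params)
        cen = census(labels)
        land = fel(pc.projection, temperature=self.temperature, n_bins=self.n_bins)
        return LandscapeResults(self, pc, params, auto, cen, land)


class LandscapeResults:
    """Fitted conformational landscape: projection, census and dG grid."""

    def __init__(self, model, pc_model, params, eps_calibrated, state_census, landscape):
        self.model = model
        self.pc_model: PCModel = pc_model
        self.params: ClusterParams = params
        self.eps_calibrated: bool = eps_calibrated
        self.census: StateCensus = state_census
        self.landscape: FreeEnergyLandscape = landscape

    @property
    def n_states(self) -> int:
        return self.census.n_states

    @property
    def noise_fraction(self) -> float:
        return self.census.noise_fraction

    @property
    def largest_state_fraction(self) -> float:
        return self.census.largest_state_fraction

    def population_table(self, n_top: int = 6):
        return population_table(self.census, n_top=n_top)

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "noise_fraction": self.noise_fraction,
            "largest_state_fraction": self.largest_state_fraction,
            "populations": self.census.populations.tolist(),
            "eps": self.params.eps,
            "min_samples": self.params.min_samples,
            "eps_calibrated": self.eps_calibrated,
            "explained_variance": self.pc_model.explained_variance.tolist(),
            "temperature": self.model.temperature,
        }

    def summary(self) -> str:
        ev = self.pc_model.explained_variance
        lines = [
            "Conformational landscape census",
            "================================",
            f"frames                  {self.census.n_frames}",
            f"PC1/PC2 explained var   {ev[0]:.3f} / {ev[1]:.3f}" if ev.size >= 2 else
            f"PC1 explained var       {ev[0]:.3f}",
            f"eps ({'k-distance' if self.eps_calibrated else 'fixed'})        "
            f"{self.params.eps:.4g}   min_samples {self.params.min_samples}",
            f"stable states           {self.n_states}",
            f"noise (transitions)     {100 * self.noise_fraction:.1f} %",
            f"largest state           {100 * self.largest_state_fraction:.1f} %",
        ]
        for name, frac in self.population_table():
            lines.append(f"  {name:<6s} {100 * frac:5.1f} %")
        return "\n".join(lines)

    def plot_landscape(self, path) -> None:
        """Filled-contour dG(PC1, PC2) figure (100 levels)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        L = self.landscape
        xc = 0.5 * (L.xedges[:-1] + L.xedges[1:])
        yc = 0.5 * (L.yedges[:-1] + L.yedges[1:])
        fig, ax = plt.subplots(figsize=(5, 4))
        cs = ax.contourf(xc, yc, L.delta_g.T, levels=L.n_levels, cmap="viridis")
        fig.colorbar(cs, ax=ax, label=r"$\Delta G$ (kcal/mol)")
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)

    def plot_states(self, path) -> None:
        """PC1/PC2 scatter coloured by state; noise in grey."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        X = self.pc_model.projection
        lab = self.census.labels
        fig, ax = plt.subplots(figsize=(5, 4))
        noise = lab == -1
        ax.scatter(X[noise, 0], X[noise, 1], s=4, c="lightgrey", label="noise")
        for s in np.unique(lab[lab >= 0]):
            sel = lab == s
            ax.scatter(X[sel, 0], X[sel, 1], s=4)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
        ax.set_title(f"{self.n_states} states, {100 * self.noise_fraction:.1f}% noise")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
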