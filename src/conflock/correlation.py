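"""Dynamic cross-correlation matrices and domain-level motion networks.

The DCCM quantifies co- and anti-correlated motion of Calpha atoms:

    C_ij = <dr_i . dr_j> / sqrt( <|dr_i|^2> <|dr_j|^2> )

with dr the deviation from the time-mean position after iterative mean
alignment.  Averaging C_ij over residue sets reduces the matrix to a small
signed network over named functional domains (e.g. CTD, NTD, a docking
domain, single catalytic residues), which is how allosteric coupling between
regions is summarised and displayed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DegeneracyError, InsufficientDataError, MappingError, ParameterError
from .geometry import iterative_mean_align
from .io import Ensemble
from .selection import SelectionMask


@dataclasses.dataclass
class CorrelationMatrix:
    """Residue-pair correlation matrix with residue labels."""

    values: np.ndarray
    residue_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.residue_labels = np.asarray(self.residue_labels, dtype=int)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or self.residue_labels.size != n:
            raise ValueError("inconsistent correlation matrix shape")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("correlations outside [-1, 1]")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class DomainMap:
    """Named functional domains -> sets of residue numbers.

    The C-terminal domain default (residues 339-480) follows the standard
    Sestrin2 domain annotation; all other regions are study-specific and must
    come from configuration.
    """

    domains: dict[str, frozenset]

    def __post_init__(self) -> None:
        clean = {}
        for name, residues in self.domains.items():
            rs = frozenset(int(r) for r in residues)
            if not rs:
                raise MappingError(f"domain {name!r} is empty")
            clean[name] = rs
        if len(clean) != len(self.domains):
            raise MappingError("duplicate domain names")
        self.domains = clean

    @classmethod
    def sestrin2_default(cls) -> "DomainMap":
        return cls({"CTD": frozenset(range(339, 481)), "Cys125": frozenset({125})})

    @classmethod
    def from_config(cls, mapping: dict) -> "DomainMap":
        domains = {}
        for name, spec in mapping.items():
            if isinstance(spec, str) and "-" in spec:
                lo, hi = (int(x) for x in spec.split("-"))
                domains[name] = frozenset(range(lo, hi + 1))
            elif isinstance(spec, int):
                domains[name] = frozenset({spec})
            else:
                domains[name] = frozenset(int(r) for r in spec)
        return cls(domains)


@dataclasses.dataclass
class DomainNetwork:
    """Signed mean-correlation network over named domains."""

    nodes: list
    weights: dict  # frozenset({a,b}) or frozenset({a}) -> float

    def weight(self, a: str, b: str | None = None) -> float:
        key = frozenset({a}) if b is None or a == b else frozenset({a, b})
        return self.weights[key]

    def edge_table(self, threshold: float = 0.0):
        """Sorted (domain_a, domain_b, weight) rows with |w| >= threshold."""
        rows = []
        for i, a in enumerate(self.nodes):
            for b in self.nodes[i + 1:]:
                w = self.weight(a, b)
                if abs(w) >= threshold:
                    rows.append((a, b, w))
        rows.sort(key=lambda r: -abs(r[2]))
        return rows


def dccm(ensemble: Ensemble, calpha_mask, pre_aligned: bool = False) -> CorrelationMatrix:
    """Dynamic cross-correlation matrix over the masked Calpha atoms.

    Frames are iteratively mean-aligned first (skip with ``pre_aligned`` when
    the ensemble is already in a common frame).  Raises
    :class:`DegeneracyError` if any atom has zero positional variance, since
    its correlation is undefined.
    """
    if ensemble.n_frames < 2:
        raise InsufficientDataError("DCCM needs at least 2 frames")
    idx = calpha_mask.indices if isinstance(calpha_mask, SelectionMask) else np.asarray(calpha_mask, int)
    coords = ensemble.coordinates if pre_aligned else iterative_mean_align(ensemble, idx)
    sub = coords[:, idx, :]
    dev = sub - sub.mean(axis=0)
    # inner products of 3-vectors averaged over frames
    inner = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(inner)
    # relative threshold: exact-zero variance leaves rounding residue ~1e-30
    zero = np.flatnonzero(var <= 1e-12 * max(float(var.max()), 1e-300))
    if zero.size:
        raise DegeneracyError(
            f"zero-variance atom(s) at mask position(s) {zero.tolist()}: correlation undefined"
        )
    denom = np.sqrt(np.outer(var, var))
    C = inner / denom
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(C, np.asarray(idx, dtype=int))


def domain_network(
    C: CorrelationMatrix,
    domain_map: DomainMap,
    residue_numbers: np.ndarray | None = None,
) -> DomainNetwork:
    """Reduce a residue correlation matrix to a domain network.

    Inter-domain weight = mean C_ij over i in a, j in b; self-weight = mean
    over unordered intra-domain pairs i < j.  ``residue_numbers`` maps matrix
    rows to residue numbers (defaults to the matrix's own labels).
    """
    resnums = np.asarray(residue_numbers if residue_numbers is not None else C.residue_labels, int)
    if resnums.size != C.n_residues:
        raise MappingError("residue_numbers length does not match matrix")
    pos = {}
    for name, residues in domain_map.domains.items():
        rows = np.flatnonzero(np.isin(resnums, list(residues)))
        missing = residues - set(resnums.tolist())
        if missing:
            raise MappingError(f"domain {name!r} references residues absent from the matrix: {sorted(missing)[:5]}")
        pos[name] = rows
    nodes = list(domain_map.domains)
    weights: dict = {}
    for i, a in enumerate(nodes):
        ra = pos[a]
        if ra.size >= 2:
            block = C.values[np.ix_(ra, ra)]
            iu = np.triu_indices(ra.size, k=1)
            weights[frozenset({a})] = float(block[iu].mean())
        else:
            weights[frozenset({a})] = 1.0  # single residue: trivially self-correlated
        for b in nodes[i + 1:]:
            rb = pos[b]
            weights[frozenset({a, b})] = float(C.values[np.ix_(ra, rb)].mean())
    return DomainNetwork(nodes, weights)


def network_report(
    network: DomainNetwork,
    threshold: float = 0.25,
    figure_path=None,
    seed: int = 0,
):
    """Edge table above threshold, optionally rendered as a graph figure.

    Edges with |weight| below the threshold are suppressed; positive edges
    are drawn blue, negative red, width proportional to |weight|.  Layout is
    deterministic under the seed.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    edges = network.edge_table(threshold)
    if figure_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(network.nodes)
        for a, b, w in edges:
            G.add_edge(a, b, weight=w)
        pos = nx.spring_layout(G, seed=seed)
        fig, ax = plt.subplots(figsize=(5, 5))
        nx.draw_networkx_nodes(G, pos, ax=ax, node_color="#cccccc", node_size=900)
        nx.draw_networkx_labels(G, pos, ax=ax, font_size=8)
        for a, b, w in edges:
            nx.draw_networkx_edges(
                G, pos, edgelist=[(a, b)], ax=ax,
                width=1 + 6 * abs(w), edge_color="tab:blue" if w > 0 else "tab:red",
            )
        ax.set_axis_off()
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return edges
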