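"""Feature-based molecular networking from MS/MS spectra.

Spectra become nodes; a pair is connected when its modified cosine (cosine
similarity allowing fragment matches shifted by the precursor mass
difference) clears a score threshold with enough matched fragment ions.
The raw similarity graph is then sparsified GNPS-style: an edge survives
only if each endpoint ranks in the other's top-K scores, and any connected
component larger than the cap is broken up by removing its weakest edges.

Default parameters: fragment tolerance 0.02 Da, precursor tolerance
0.01 Da, cosine >= 0.70, >= 4 matched ions, top-10 rank filter, component
size cap 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf


@dataclass
class Spectrum:
    """One MS/MS spectrum: precursor m/z plus a centroided peak list,
    kept sorted by m/z."""

    id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int = 1

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.id!r} has no peaks")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError(f"spectrum {self.id!r} has invalid intensities")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class NetworkParams:
    """Topology parameters of the molecular network."""

    precursor_tol_da: float = 0.01
    fragment_tol_da: float = 0.02
    min_cosine: float = 0.70
    min_matched_peaks: int = 4
    top_k: int = 10
    max_component: int = 100
    intensity_power: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.min_cosine <= 1:
            raise ValueError("min_cosine must be in (0, 1]")
        if min(self.precursor_tol_da, self.fragment_tol_da) <= 0:
            raise ValueError("tolerances must be positive")
        if min(self.min_matched_peaks, self.top_k, self.max_component) <= 0:
            raise ValueError("count parameters must be positive")


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    cosine: float
    matched_peaks: int
    precursor_delta: float


@dataclass
class Network:
    nodes: list[str]
    edges: list[Edge]
    component_id: dict[str, int]
    precursor_mz: dict[str, float] = field(default_factory=dict)

    def component_sizes(self) -> list[int]:
        sizes: dict[int, int] = {}
        for cid in self.component_id.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sorted(sizes.values(), reverse=True)


@dataclass(frozen=True)
class FamilyStats:
    """Component-size histogram collapsed to the conventional bins."""

    singletons: int
    pairs: int
    triples: int
    larger: int


def read_mgf(path) -> list[Spectrum]:
    """Read spectra from an MGF file; peaks are sorted and zero-intensity
    peaks dropped on read."""
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, block in enumerate(reader):
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"MGF block {i}: missing PEPMASS")
            sid = str(params.get("title", f"spectrum_{i}"))
            mz = np.asarray(block["m/z array"], dtype=float)
            inten = np.asarray(block["intensity array"], dtype=float)
            keep = inten > 0
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 1
            spectra.append(Spectrum(id=sid, precursor_mz=float(pepmass[0]),
                                    mz=mz[keep], intensity=inten[keep],
                                    charge=charge))
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Deterministic MGF writer (fixed field order and float formatting)."""
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.5f}\n")
            fh.write(f"CHARGE={sp.charge}+\n")
            for mz, inten in zip(sp.mz, sp.intensity):
                fh.write(f"{mz:.5f} {inten:.2f}\n")
            fh.write("END IONS\n")


def modified_cosine(a: Spectrum, b: Spectrum, fragment_tol_da: float = 0.02,
                    intensity_power: float = 0.5) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count of two spectra.

    Peaks i (in a) and j (in b) may pair either directly
    (|mz_a - mz_b| <= tol) or shifted by the precursor difference
    (|mz_a - (mz_b + prec_a - prec_b)| <= tol).  A one-to-one matching is
    built greedily by descending pair score over power-scaled intensities;
    the score is normalized by the Euclidean norms so identical spectra
    score 1.
    """
    wa = a.intensity ** intensity_power
    wb = b.intensity ** intensity_power
    norm = float(np.linalg.norm(wa) * np.linalg.norm(wb))
    if norm == 0:
        return 0.0, 0
    delta = a.precursor_mz - b.precursor_mz
    pairs: dict[tuple[int, int], float] = {}
    for shift in (0.0, delta):
        diff = np.abs(a.mz[:, None] - (b.mz[None, :] + shift))
        for i, j in zip(*np.nonzero(diff <= fragment_tol_da)):
            pairs[(int(i), int(j))] = float(wa[i] * wb[j])
    # greedy one-to-one matching, deterministic tie-break by peak indices
    ordered = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    matched = 0
    for (i, j), score in ordered:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += score
        matched += 1
    return min(total / norm, 1.0), matched


def _mutual_top_k(edges: list[Edge], top_k: int) -> list[Edge]:
    ranked: dict[str, list[tuple[float, str]]] = {}
    for e in edges:
        ranked.setdefault(e.a, []).append((e.cosine, e.b))
        ranked.setdefault(e.b, []).append((e.cosine, e.a))
    top: dict[str, set[str]] = {}
    for node, neigh in ranked.items():
        neigh.sort(key=lambda t: (-t[0], t[1]))
        top[node] = {other for _, other in neigh[:top_k]}
    return [e for e in edges if e.b in top[e.a] and e.a in top[e.b]]


def _cap_components(graph: nx.Graph, max_component: int) -> None:
    """Remove weakest edges until every component fits under the cap.

    Tie-break inside a component: lowest cosine, then largest absolute
    precursor delta, then lexicographic id pair — fully deterministic.
    """
    while True:
        oversized = [c for c in nx.connected_components(graph)
                     if len(c) > max_component]
        if not oversized:
            return
        comp = oversized[0]
        worst = min(
            (e for *_, e in graph.edges(comp, data="edge")),
            key=lambda e: (e.cosine, -abs(e.precursor_delta), (e.a, e.b)))
        graph.remove_edge(worst.a, worst.b)


def build_network(spectra: Sequence[Spectrum],
                  params: NetworkParams = NetworkParams()) -> Network:
    """Compute all pairwise modified cosines and assemble the filtered
    molecular network (score/match thresholds, mutual top-K rank filter,
    component size cap)."""
    if not spectra:
        raise ValueError("no spectra supplied")
    ids = [sp.id for sp in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique")
    candidates: list[Edge] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            a, b = spectra[i], spectra[j]
            cosine, matched = modified_cosine(
                a, b, params.fragment_tol_da, params.intensity_power)
            if cosine >= params.min_cosine and matched >= params.min_matched_peaks:
                first, second = sorted((a, b), key=lambda s: s.id)
                candidates.append(Edge(
                    a=first.id, b=second.id, cosine=cosine,
                    matched_peaks=matched,
                    precursor_delta=first.precursor_mz - second.precursor_mz))
    kept = _mutual_top_k(candidates, params.top_k)

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for e in kept:
        graph.add_edge(e.a, e.b, edge=e)
    _cap_components(graph, params.max_component)

    component_id: dict[str, int] = {}
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    for cid, comp in enumerate(components):
        for node in comp:
            component_id[node] = cid
    final_edges = sorted((data for *_, data in graph.edges(data="edge")),
                         key=lambda e: (e.a, e.b))
    return Network(nodes=ids, edges=final_edges, component_id=component_id,
                   precursor_mz={sp.id: sp.precursor_mz for sp in spectra})


def family_stats(network: Network) -> FamilyStats:
    """Histogram of component ('molecular family') sizes, binned 1/2/3/>3."""
    sizes: dict[int, int] = {}
    for cid in network.component_id.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    bins = {1: 0, 2: 0, 3: 0, "larger": 0}
    for size in sizes.values():
        if size in bins:
            bins[size] += 1
        else:
            bins["larger"] += 1
    return FamilyStats(singletons=bins[1], pairs=bins[2],
                       triples=bins[3], larger=bins["larger"])


def node_table(network: Network) -> pd.DataFrame:
    comp_sizes: dict[int, int] = {}
    for cid in network.component_id.values():
        comp_sizes[cid] = comp_sizes.get(cid, 0) + 1
    return pd.DataFrame([
        {"id": node,
         "precursor_mz": network.precursor_mz.get(node, float("nan")),
         "component_id": network.component_id[node],
         "component_size": comp_sizes[network.component_id[node]]}
        for node in network.nodes])


def edge_table(network: Network) -> pd.DataFrame:
    return pd.DataFrame([
        {"a": e.a, "b": e.b, "cosine": e.cosine,
         "matched_peaks": e.matched_peaks,
         "precursor_delta": e.precursor_delta}
        for e in network.edges],
        columns=["a", "b", "cosine", "matched_peaks", "precursor_delta"])


def write_graphml(network: Network, path) -> None:
    """GraphML export for network viewers (e.g. Cytoscape)."""
    graph = nx.Graph()
    for node in network.nodes:
        graph.add_node(node,
                       precursor_mz=network.precursor_mz.get(node, 0.0),
                       component_id=network.component_id[node])
    for e in network.edges:
        graph.add_edge(e.a, e.b, cosine=e.cosine,
                       matched_peaks=e.matched_peaks,
                       precursor_delta=e.precursor_delta)
    nx.write_graphml(graph, str(path))
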