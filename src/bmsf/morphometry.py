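"""SWC neuron reconstructions and L-measure-style morphometric indices.

A digital reconstruction is a rooted tree of nodes ``(id, type, x, y, z,
radius, parent)``; every non-root node defines a cylindrical compartment
from its parent's position to its own, carrying its own radius.  From that
tree this module computes a core subset of the canonical L-measure catalog:
topology counts, PCA extents, summed lengths/surfaces/volumes, soma-to-tip
distances, per-branch contraction and taper, bifurcation diameter ratios
and Rall-exponent statistics, branch angles, and terminal-bifurcation
diameter summaries.

Conventions (documented in docs/methods.md): compartments are cylinders
with the child node's radius; soma nodes are ``type == 1``; a *stem* is a
neurite node whose parent is a soma node; a *branch* is a maximal
compartment run between critical points (soma, bifurcation, tip); angles
are degrees in [0, 180] via clipped arccos.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SWCNode",
    "SWCReconstruction",
    "SWCParseError",
    "MorphometricProfile",
    "parse_swc",
    "topology_counts",
    "spatial_extents",
    "size_metrics",
    "distance_metrics",
    "branch_metrics",
    "bifurcation_metrics",
    "terminal_metrics",
    "compute_profile",
    "batch_extract",
    "CORE_METRICS",
    "ALL_FEATURE_NAMES",
]

SOMA_TYPE = 1

#: Implemented metric keys, in canonical catalog order.
CORE_METRICS: tuple[str, ...] = (
    "SS", "N_s", "N_bi", "N_br", "N_t", "NW", "NH", "ND", "Di", "Dp",
    "Le", "Su", "SA", "Vo", "ED", "PD", "BO", "Ta1", "Ta2", "Bpl", "Co",
    "Fr", "DR", "PDR", "Pa", "RP", "Pk", "Pc", "Pk2", "Bal", "Bar",
    "Btl", "Btr", "Btol", "Btor", "Lpd", "Dt", "HT",
)

#: The full 43-name catalog (synthetic tables carry all of these; the five
#: names absent from CORE_METRICS are not computed from SWC here).
ALL_FEATURE_NAMES: tuple[str, ...] = (
    "SS", "N_s", "N_bi", "N_br", "N_t", "NW", "NH", "ND", "Ty", "Di",
    "Dp", "Le", "Su", "SA", "Vo", "ED", "PD", "BO", "Td", "TS", "Ta1",
    "Ta2", "Bpl", "Co", "Fr", "DR", "PDR", "Pa", "RP", "Pk", "Pc", "Pk2",
    "Bal", "Bar", "Btl", "Btr", "Btol", "Btor", "Lpd", "Dt", "HT", "He",
    "FD",
)


class SWCParseError(ValueError):
    """Raised for malformed or structurally invalid SWC input."""


@dataclass(frozen=True)
class SWCNode:
    """One reconstruction point.

    ``type_code`` follows the SWC convention: 1 soma, 2 axon, 3 dendrite,
    4 apical dendrite; other positive codes are allowed.  ``parent_id`` is
    -1 for a root.  Coordinates and radius are micrometres.
    """

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass
class SWCReconstruction:
    """A validated rooted tree of :class:`SWCNode`, plus derived indices."""

    nodes: list[SWCNode]
    source_name: str = "<swc>"

    # derived structure, built in __post_init__
    index: dict[int, SWCNode] = field(default_factory=dict, repr=False)
    children: dict[int, list[int]] = field(default_factory=dict, repr=False)
    roots: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise SWCParseError(f"{self.source_name}: no nodes")
        self.index = {}
        self.children = {n.id: [] for n in self.nodes}
        self.roots = []
        for n in self.nodes:
            if n.id in self.index:
                raise SWCParseError(
                    f"{self.source_name}: duplicate node id {n.id}")
            self.index[n.id] = n
        for n in self.nodes:
            if n.parent_id == -1:
                self.roots.append(n.id)
            elif n.parent_id not in self.index:
                raise SWCParseError(
                    f"{self.source_name}: node {n.id} references missing "
                    f"parent {n.parent_id}")
            else:
                self.children[n.parent_id].append(n.id)
        if not self.roots:
            raise SWCParseError(f"{self.source_name}: no root node")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[int] = set()
        stack = list(self.roots)
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SWCParseError(
                    f"{self.source_name}: cycle involving node {nid}")
            seen.add(nid)
            stack.extend(self.children[nid])
        if len(seen) != len(self.nodes):
            orphans = sorted(set(self.index) - seen)
            raise SWCParseError(
                f"{self.source_name}: cycle or disconnected nodes "
                f"{orphans[:5]}")

    # -- structural helpers -------------------------------------------------

    @property
    def root(self) -> SWCNode:
        return self.index[self.roots[0]]

    def soma_ids(self) -> set[int]:
        """Soma node ids; falls back to the root for somaless files."""
        soma = {n.id for n in self.nodes if n.type_code == SOMA_TYPE}
        return soma if soma else {self.roots[0]}

    def is_neurite(self, nid: int) -> bool:
        return nid not in self.soma_ids()

    def n_children(self, nid: int) -> int:
        return len(self.children[nid])

    def compartment_length(self, nid: int) -> float:
        node = self.index[nid]
        parent = self.index[node.parent_id]
        return float(np.linalg.norm(node.position - parent.position))

    def tips(self) -> list[int]:
        soma = self.soma_ids()
        return [n.id for n in self.nodes
                if n.id not in soma and not self.children[n.id]]

    def bifurcations(self) -> list[int]:
        """Neurite nodes with >= 2 children (multifurcations included)."""
        soma = self.soma_ids()
        return [n.id for n in self.nodes
                if n.id not in soma and len(self.children[n.id]) >= 2]

    def stems(self) -> list[int]:
        soma = self.soma_ids()
        return [n.id for n in self.nodes
                if n.id not in soma and n.parent_id in soma]

    def subtree_tip_counts(self) -> dict[int, int]:
        """Tips at-or-below each node (a tip counts itself as 1)."""
        counts: dict[int, int] = {}
        soma = self.soma_ids()
        order: list[int] = []
        stack = list(self.roots)
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(self.children[nid])
        for nid in reversed(order):
            kids = self.children[nid]
            if not kids:
                counts[nid] = 0 if nid in soma else 1
            else:
                counts[nid] = sum(counts[k] for k in kids)
        return counts

    def next_critical(self, nid: int) -> int:
        """Follow single-child runs from ``nid`` to the next bifurcation
        or tip (``nid`` itself if it already is one)."""
        current = nid
        while len(self.children[current]) == 1:
            current = self.children[current][0]
        return current

    def previous_critical(self, nid: int) -> int:
        """Walk rootward from ``nid``'s parent to the nearest soma node,
        bifurcation, or root."""
        soma = self.soma_ids()
        current = self.index[nid].parent_id
        while (current not in soma
               and self.index[current].parent_id != -1
               and len(self.children[current]) < 2):
            current = self.index[current].parent_id
        return current

    def parent_bifurcation(self, nid: int) -> int | None:
        """Nearest strictly rootward neurite bifurcation, or None."""
        soma = self.soma_ids()
        current = self.index[nid].parent_id
        while current != -1 and current not in soma:
            if len(self.children[current]) >= 2:
                return current
            current = self.index[current].parent_id
        return None


def parse_swc(text: str, source_name: str = "<swc>") -> SWCReconstruction:
    """Parse 7-column SWC text into a validated reconstruction.

    Lines starting with ``#`` and blank lines are ignored.  Raises
    :class:`SWCParseError` naming the offending line for malformed rows,
    non-positive radii, missing parents, duplicate ids or cycles.
    """
    nodes: list[SWCNode] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SWCParseError(
                f"{source_name}:{lineno}: expected 7 columns, got "
                f"{len(parts)}")
        try:
            nid = int(parts[0])
            type_code = int(parts[1])
            x, y, z, radius = (float(v) for v in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SWCParseError(
                f"{source_name}:{lineno}: malformed value ({exc})") from exc
        if nid <= 0:
            raise SWCParseError(
                f"{source_name}:{lineno}: node id must be positive")
        if radius <= 0:
            raise SWCParseError(
                f"{source_name}:{lineno}: non-positive radius {radius}")
        nodes.append(SWCNode(nid, type_code, x, y, z, radius, parent))
    if not nodes:
        raise SWCParseError(f"{source_name}: no nodes")
    return SWCReconstruction(nodes, source_name=source_name)


@dataclass
class MorphometricProfile:
    """Metric values keyed by catalog abbreviation.

    ``undefined`` lists metrics reported as 0 because the reconstruction
    lacks the structure that defines them (e.g. bifurcation statistics on
    an unbranched neurite).
    """

    values: dict[str, float]
    undefined: frozenset[str] = frozenset()
    source_name: str = "<swc>"

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.source_name)


# ---------------------------------------------------------------------------
# metric groups


def topology_counts(rec: SWCReconstruction) -> dict[str, float]:
    """Stem / bifurcation / tip / branch counts, fragmentation, max
    branch order.  ``N_br = N_bi + N_t`` by definition."""
    n_bi = len(rec.bifurcations())
    n_t = len(rec.tips())
    bo = 0
    bif_set = set(rec.bifurcations())
    # DFS accumulating bifurcation count along root-to-tip paths
    stack: list[tuple[int, int]] = [(r, 0) for r in rec.roots]
    while stack:
        nid, nbif = stack.pop()
        if nid in bif_set:
            nbif += 1
        kids = rec.children[nid]
        if not kids and rec.is_neurite(nid):
            bo = max(bo, nbif if nid not in bif_set else nbif)
        for k in kids:
            stack.append((k, nbif))
    # a tip on a path through b bifurcations has order b; the tip itself
    # is never a bifurcation so nbif at the tip is the path count
    return {
        "N_s": float(len(rec.stems())),
        "N_bi": float(n_bi),
        "N_t": float(n_t),
        "N_br": float(n_bi + n_t),
        "Fr": float(len(rec.nodes)),
        "BO": float(bo),
    }


def spatial_extents(rec: SWCReconstruction) -> dict[str, float]:
    """Central-95% extents of node projections on the PCA axes.

    NH: first principal axis; NW: second; ND: third.  Extent along an
    axis is the 97.5th minus the 2.5th percentile of node projections.
    """
    coords = np.array([[n.x, n.y, n.z] for n in rec.nodes], dtype=float)
    if coords.shape[0] < 2:
        return {"NW": 0.0, "NH": 0.0, "ND": 0.0}
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    axes = eigvecs[:, order]
    proj = centred @ axes
    lo, hi = np.percentile(proj, [2.5, 97.5], axis=0)
    extents = hi - lo
    return {"NH": float(extents[0]), "NW": float(extents[1]),
            "ND": float(extents[2])}


def size_metrics(rec: SWCReconstruction) -> dict[str, float]:
    """Summed cylinder geometry plus soma surface.

    Le/Su/Vo sum neurite compartment length, lateral surface (2*pi*r*l)
    and volume (pi*r^2*l); SA repeats Su (total arborization surface);
    Di is the mean compartment diameter and Dp the mean diameter^1.5.
    SS uses the sphere formula for single-node somas, cylinder sums
    otherwise.
    """
    soma = rec.soma_ids()
    le = su = vo = 0.0
    diam: list[float] = []
    for n in rec.nodes:
        if n.parent_id == -1 or n.id in soma:
            continue
        length = rec.compartment_length(n.id)
        le += length
        su += 2.0 * math.pi * n.radius * length
        vo += math.pi * n.radius ** 2 * length
        diam.append(n.diameter)
    soma_nodes = [rec.index[i] for i in sorted(soma)]
    if len(soma_nodes) == 1:
        ss = 4.0 * math.pi * soma_nodes[0].radius ** 2
    else:
        ss = sum(
            2.0 * math.pi * n.radius * rec.compartment_length(n.id)
            for n in soma_nodes
            if n.parent_id != -1 and n.parent_id in soma)
    di = float(np.mean(diam)) if diam else 0.0
    dp = float(np.mean([d ** 1.5 for d in diam])) if diam else 0.0
    return {"SS": float(ss), "Di": di, "Dp": dp, "Le": le, "Su": su,
            "SA": su, "Vo": vo}


def distance_metrics(rec: SWCReconstruction) -> dict[str, float]:
    """Maximum straight-line (ED) and along-tree (PD) soma-to-tip
    distances; PD >= ED on every tip by the triangle inequality."""
    root_pos = rec.root.position
    # path distance from root to every node
    dist: dict[int, float] = {r: 0.0 for r in rec.roots}
    stack = list(rec.roots)
    while stack:
        nid = stack.pop()
        for k in rec.children[nid]:
            dist[k] = dist[nid] + rec.compartment_length(k)
            stack.append(k)
    ed = pd_ = 0.0
    for tip in rec.tips():
        ed = max(ed, float(np.linalg.norm(rec.index[tip].position - root_pos)))
        pd_ = max(pd_, dist[tip])
    return {"ED": ed, "PD": pd_}


@dataclass(frozen=True)
class _Branch:
    """Maximal compartment run between critical points."""
    proximal_id: int        # soma node or bifurcation the branch hangs off
    node_ids: tuple[int, ...]   # first neurite node ... end critical node
    path_length: float
    euclidean: float
    d_init: float
    d_final: float


def _branches(rec: SWCReconstruction) -> list[_Branch]:
    soma = rec.soma_ids()
    bifs = set(rec.bifurcations())
    out: list[_Branch] = []
    # branch starts: stems, and children of bifurcations
    starts = list(rec.stems())
    for b in bifs:
        starts.extend(rec.children[b])
    for start in starts:
        chain = [start]
        current = start
        while len(rec.children[current]) == 1 and current not in bifs:
            current = rec.children[current][0]
            chain.append(current)
        proximal = rec.index[start].parent_id
        path = sum(rec.compartment_length(n) for n in chain)
        p0 = rec.index[proximal].position
        p1 = rec.index[chain[-1]].position
        if proximal in soma:
            d_init = rec.index[start].diameter
        else:
            d_init = rec.index[proximal].diameter
        out.append(_Branch(
            proximal_id=proximal,
            node_ids=tuple(chain),
            path_length=path,
            euclidean=float(np.linalg.norm(p1 - p0)),
            d_init=d_init,
            d_final=rec.index[chain[-1]].diameter,
        ))
    return out


def branch_metrics(rec: SWCReconstruction) -> dict[str, float]:
    """Per-branch averages: path length (Bpl), contraction (Co, the
    euclidean/path ratio), and the two taper statistics.

    Ta1 = (d_init - d_final) / path length; Ta2 = (d_init - d_final) /
    d_init with d_init at the proximal critical point.  Negative taper is
    retained.  Zero-length branches are excluded from the averages.
    """
    branches = [b for b in _branches(rec) if b.path_length > 0]
    if not branches:
        return {"Bpl": 0.0, "Co": 0.0, "Ta1": 0.0, "Ta2": 0.0}
    bpl = float(np.mean([b.path_length for b in branches]))
    co = float(np.mean([b.euclidean / b.path_length for b in branches]))
    ta1 = float(np.mean([(b.d_init - b.d_final) / b.path_length
                         for b in branches]))
    ta2_vals = [(b.d_init - b.d_final) / b.d_init
                for b in branches if b.d_init > 0]
    ta2 = float(np.mean(ta2_vals)) if ta2_vals else 0.0
    return {"Bpl": bpl, "Co": co, "Ta1": ta1, "Ta2": ta2}


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float | None:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return None
    c = float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _plane_normal(u: np.ndarray, v: np.ndarray) -> np.ndarray | None:
    n = np.cross(u, v)
    norm = np.linalg.norm(n)
    return None if norm == 0 else n / norm


def _fit_rall_exponent(d1: float, d2: float, dp: float) -> float:
    """Grid-search n in [0, 5] (step 0.01) minimizing
    |d1^n + d2^n - dp^n|."""
    n = np.arange(0.0, 5.0 + 1e-9, 0.01)
    err = np.abs(d1 ** n + d2 ** n - dp ** n)
    return float(n[int(np.argmin(err))])


def bifurcation_metrics(rec: SWCReconstruction) -> dict[str, float]:
    """Averages over bifurcations of diameter ratios, partition
    asymmetry, Rall-exponent statistics and branch angles.

    At multifurcations the two largest-diameter daughters are used for
    diameter/angle statistics; partition asymmetry counts tips in all
    subtrees (largest daughter vs the rest pooled).  If the tree has no
    bifurcation every value is 0 and flagged undefined.
    """
    bifs = rec.bifurcations()
    out = {k: 0.0 for k in ("DR", "PDR", "Pa", "RP", "Pk", "Pc", "Pk2",
                            "Bal", "Bar", "Btl", "Btr", "Btol", "Btor")}
    if not bifs:
        out["_undefined"] = list(out)
        return out
    tip_counts = rec.subtree_tip_counts()
    acc: dict[str, list[float]] = {k: [] for k in out}

    for b in bifs:
        node = rec.index[b]
        kids = sorted(rec.children[b],
                      key=lambda k: rec.index[k].radius, reverse=True)
        c1, c2 = kids[0], kids[1]
        d1, d2 = rec.index[c1].diameter, rec.index[c2].diameter
        dp = node.diameter
        if min(d1, d2) > 0:
            acc["DR"].append(max(d1, d2) / min(d1, d2))
        if dp > 0:
            acc["PDR"].append((d1 / dp + d2 / dp) / 2.0)
            acc["Pc"].append((d1 ** 1.5 + d2 ** 1.5) / dp ** 1.5)
            acc["Pk2"].append((d1 ** 2 + d2 ** 2) / dp ** 2)
            fitted = _fit_rall_exponent(d1, d2, dp)
            acc["RP"].append(fitted)
            acc["Pk"].append(fitted)
        n1 = tip_counts[kids[0]]
        n2 = sum(tip_counts[k] for k in kids[1:])
        if n1 + n2 > 2:
            acc["Pa"].append(abs((n1 - n2) / (n1 + n2 - 2)))
        else:
            acc["Pa"].append(0.0)  # symmetric terminal bifurcation

        pos = node.position
        v1_local = rec.index[c1].position - pos
        v2_local = rec.index[c2].position - pos
        r1, r2 = rec.next_critical(c1), rec.next_critical(c2)
        v1_remote = rec.index[r1].position - pos
        v2_remote = rec.index[r2].position - pos
        a = _angle_deg(v1_local, v2_local)
        if a is not None:
            acc["Bal"].append(a)
        a = _angle_deg(v1_remote, v2_remote)
        if a is not None:
            acc["Bar"].append(a)

        parent_pos = rec.index[node.parent_id].position
        p_local = pos - parent_pos
        p_remote = pos - rec.index[rec.previous_critical(b)].position
        for pvec, key, dvecs in ((p_local, "Btl", (v1_local, v2_local)),
                                 (p_remote, "Btr", (v1_remote, v2_remote))):
            angles = [_angle_deg(pvec, dv) for dv in dvecs]
            angles = [a for a in angles if a is not None]
            if angles:
                acc[key].append(float(np.mean(angles)))

        pb = rec.parent_bifurcation(b)
        if pb is not None:
            pb_kids = sorted(rec.children[pb],
                             key=lambda k: rec.index[k].radius, reverse=True)
            pb_pos = rec.index[pb].position
            for key, own in (("Btol", (v1_local, v2_local)),
                             ("Btor", (v1_remote, v2_remote))):
                if key == "Btol":
                    pvs = [rec.index[k].position - pb_pos
                           for k in pb_kids[:2]]
                else:
                    pvs = [rec.index[rec.next_critical(k)].position - pb_pos
                           for k in pb_kids[:2]]
                n_own = _plane_normal(*own)
                n_par = _plane_normal(*pvs)
                if n_own is not None and n_par is not None:
                    a = _angle_deg(n_own, n_par)
                    if a is not None:
                        acc[key].append(min(a, 180.0 - a))

    undefined = []
    for key in out:
        if acc[key]:
            out[key] = float(np.mean(acc[key]))
        else:
            undefined.append(key)
    if undefined:
        out["_undefined"] = undefined
    return out


def terminal_metrics(rec: SWCReconstruction) -> dict[str, float]:
    """Diameter summaries at terminal bifurcations (both daughters lead
    only to tips): last-parent diameter (Lpd), mean first-daughter-
    compartment diameter (Dt), and the Hillman threshold
    HT = 0.5*dp + 0.25*d1 + 0.25*d2, averaged over terminal
    bifurcations."""
    bif_set = set(rec.bifurcations())

    def subtree_has_bif(nid: int) -> bool:
        stack = [nid]
        while stack:
            cur = stack.pop()
            if cur in bif_set:
                return True
            stack.extend(rec.children[cur])
        return False

    lpd, dt, ht = [], [], []
    for b in bif_set:
        kids = rec.children[b]
        if any(subtree_has_bif(k) for k in kids):
            continue
        kids_sorted = sorted(kids, key=lambda k: rec.index[k].radius,
                             reverse=True)
        d1 = rec.index[kids_sorted[0]].diameter
        d2 = rec.index[kids_sorted[1]].diameter
        dp = rec.index[b].diameter
        lpd.append(dp)
        dt.append((d1 + d2) / 2.0)
        ht.append(0.5 * dp + 0.25 * d1 + 0.25 * d2)
    if not ht:
        return {"Lpd": 0.0, "Dt": 0.0, "HT": 0.0, "_undefined":
                ["Lpd", "Dt", "HT"]}
    return {"Lpd": float(np.mean(lpd)), "Dt": float(np.mean(dt)),
            "HT": float(np.mean(ht))}


_METRIC_GROUPS = (
    (("N_s", "N_bi", "N_br", "N_t", "Fr", "BO"), topology_counts),
    (("NW", "NH", "ND"), spatial_extents),
    (("SS", "Di", "Dp", "Le", "Su", "SA", "Vo"), size_metrics),
    (("ED", "PD"), distance_metrics),
    (("Bpl", "Co", "Ta1", "Ta2"), branch_metrics),
    (("DR", "PDR", "Pa", "RP", "Pk", "Pc", "Pk2", "Bal", "Bar", "Btl",
      "Btr", "Btol", "Btor"), bifurcation_metrics),
    (("Lpd", "Dt", "HT"), terminal_metrics),
)


def compute_profile(rec: SWCReconstruction,
                    metric_set: Sequence[str] | None = None,
                    ) -> MorphometricProfile:
    """Assemble the requested metrics into a profile.

    ``metric_set`` defaults to every implemented metric; unknown keys
    raise ``ValueError`` listing the supported ones.  Deterministic for a
    fixed reconstruction.
    """
    requested = tuple(CORE_METRICS if metric_set is None else metric_set)
    unknown = [m for m in requested if m not in CORE_METRICS]
    if unknown:
        raise ValueError(
            f"unknown metric keys {unknown}; supported: {list(CORE_METRICS)}")
    values: dict[str, float] = {}
    undefined: set[str] = set()
    wanted = set(requested)
    for keys, fn in _METRIC_GROUPS:
        if wanted & set(keys):
            result = fn(rec)
            undefined.update(result.pop("_undefined", ()))
            values.update(result)
    ordered = {m: values[m] for m in requested}
    return MorphometricProfile(values=ordered,
                               undefined=frozenset(undefined & wanted),
                               source_name=rec.source_name)


def batch_extract(swc_dir: str | Path,
                  labels: Mapping[str, str] | str | Path,
                  metric_set: Sequence[str] | None = None,
                  ) -> pd.DataFrame:
    """Extract profiles for every ``*.swc`` file in a directory.

    ``labels`` maps file names (with or without extension) to class
    labels, or is a path to a two-column CSV ``file,label``.  Unreadable
    files are skipped with a warning; zero parsed files is an error.
    Returns one row per reconstruction with metric columns in catalog
    order plus a final ``label`` column.
    """
    swc_dir = Path(swc_dir)
    if not isinstance(labels, Mapping):
        lab_df = pd.read_csv(labels, dtype=str)
        labels = dict(zip(lab_df.iloc[:, 0], lab_df.iloc[:, 1]))
    labels = {Path(k).stem: v for k, v in labels.items()}

    rows: list[pd.Series] = []
    row_labels: list[str] = []
    skipped = 0
    for path in sorted(swc_dir.glob("*.swc")):
        stem = path.stem
        if stem not in labels:
            warnings.warn(f"no label for {path.name}; skipped")
            skipped += 1
            continue
        try:
            rec = parse_swc(path.read_text(), source_name=path.name)
            profile = compute_profile(rec, metric_set)
        except SWCParseError as exc:
            warnings.warn(f"skipping {path.name}: {exc}")
            skipped += 1
            continue
        rows.append(profile.as_series().rename(stem))
        row_labels.append(labels[stem])
    if not rows:
        raise ValueError(f"no SWC file in {swc_dir} could be processed")
    table = pd.DataFrame(rows)
    table["label"] = row_labels
    table.attrs["skipped"] = skipped
    return table
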