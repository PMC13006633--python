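"""Time-resolved nonparametric group inference on envelope maps.

The question is whether two groups of participants differ in low-beta
amplitude anywhere over the scalp and the analysis window, while
controlling the family-wise error over ~44,000 (electrode × millisecond)
comparisons. The machinery is the standard cluster-based permutation test:

1. a two-sample t statistic at every (electrode, 1-ms sample);
2. a pointwise permutation p at each point, from re-randomizing the
   participant group labels (the same label permutations are shared across
   all points);
3. supra-threshold points (pointwise p below the formation threshold)
   grouped into spatio-temporally contiguous, sign-consistent clusters
   (temporal adjacency along one electrode; spatial adjacency between
   neighboring electrodes at the same sample);
4. each cluster scored by its mass (sum of member t values), compared
   against the permutation distribution of the maximal cluster mass;
5. a persistence criterion discarding significant clusters that never
   exceed 10 ms of contiguous extent on any single electrode.

Participants — not trials — are the exchangeable units: group labels are
permuted over participant-mean envelopes, which respects unequal trial
counts and the between-group design.

Temporal conventions: at 1 kHz each sample covers 1 ms, so a k-sample run
counts as k ms; a cluster interval (start, end) spans [start, start + k ms).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .montage import AdjacencyGraph

DEFAULT_N_PERM = 1000
DEFAULT_FORMATION_P = 0.05
DEFAULT_MIN_DURATION_S = 0.010
DEFAULT_GAP_TOLERANCE_S = 0.015


@dataclass
class PermutationNull:
    """Max-|cluster-mass| sample over label permutations."""

    n_perm: int
    seed: Optional[int]
    max_mass: np.ndarray
    exact: bool = False

    def __post_init__(self) -> None:
        self.max_mass = np.asarray(self.max_mass, dtype=float)
        if self.max_mass.size != self.n_perm:
            raise ValueError("null sample length must equal n_perm")


@dataclass(eq=False)  # identity comparison; members hold arrays
class Cluster:
    """A sign-consistent, spatio-temporally contiguous supra-threshold
    region. ``electrodes``/``samples`` are aligned member arrays (sample
    indices into the analysis window); extents are per-electrode
    (start_s, end_s) intervals."""

    electrodes: np.ndarray
    samples: np.ndarray
    mass: float
    direction: int
    extents: Dict[str, List[Tuple[float, float]]]
    max_run_s: float
    p: float = math.nan

    @property
    def start_s(self) -> float:
        return min(iv[0] for ivs in self.extents.values() for iv in ivs)

    @property
    def end_s(self) -> float:
        return max(iv[1] for ivs in self.extents.values() for iv in ivs)

    @property
    def electrode_names(self) -> Tuple[str, ...]:
        return tuple(sorted(self.extents))


@dataclass
class RepresentativeWindow:
    """Reporting aggregate of temporally consecutive / spatially adjacent
    significant clusters of one direction."""

    start_s: float
    end_s: float
    electrodes: Tuple[str, ...]
    direction: int
    cluster_indices: Tuple[int, ...]


@dataclass
class ClusterAnalysis:
    """Full output of the cluster permutation test."""

    t_obs: np.ndarray
    p_obs: np.ndarray
    clusters: List[Cluster]
    null: PermutationNull
    threshold: float
    min_duration_s: float
    montage: Tuple[str, ...]
    time_offset_s: float
    fs: float
    adjacency_fingerprint: str

    def significant(self, alpha: float = 0.05) -> List[Cluster]:
        """Clusters passing both cluster-level significance and the
        persistence criterion."""
        return persistence_filter(
            [c for c in self.clusters if c.p < alpha], self.min_duration_s
        )


# ---------------------------------------------------------------------------
# pointwise statistics


def _pooled_tmaps(X: np.ndarray, labels_a: np.ndarray) -> np.ndarray:
    """Pooled two-sample t (group A minus group B) for each column of X
    under one or many label assignments.

    X: (n_participants, n_points); labels_a: (n_assignments,
    n_participants) boolean membership of group A. Returns (n_assignments,
    n_points).
    """
    # float32 throughout: the permutation matrices are large and the t
    # statistic does not need double precision.
    n, _ = X.shape
    na = int(labels_a[0].sum())
    nb = n - na
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 participants")
    X = np.ascontiguousarray(X, dtype=np.float32)
    L = labels_a.astype(np.float32)
    total = X.sum(axis=0)
    total2 = (X * X).sum(axis=0)
    SA = L @ X
    ma = SA / np.float32(na)
    mb = SA
    np.subtract(total[np.newaxis, :], SA, out=mb)
    mb /= np.float32(nb)
    # pooled SS = Σx² − na·ma² − nb·mb² (within-group splits cancel)
    ss = ma * ma
    ss *= np.float32(-na)
    ss -= np.float32(nb) * (mb * mb)
    ss += total2[np.newaxis, :]
    np.clip(ss, 0.0, None, out=ss)
    se = ss
    se *= np.float32((1.0 / na + 1.0 / nb) / (n - 2))
    np.sqrt(se, out=se)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = ma
        t -= mb
        t /= se
    t[~np.isfinite(t)] = 0.0
    return t


def _label_matrix_random(
    n: int, na: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    L = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        idx = rng.permutation(n)[:na]
        L[i, idx] = True
    return L


def _label_matrix_exhaustive(n: int, na: int) -> np.ndarray:
    combos = list(itertools.combinations(range(n), na))
    L = np.zeros((len(combos), n), dtype=bool)
    for i, c in enumerate(combos):
        L[i, list(c)] = True
    return L


@dataclass
class PointwiseResult:
    """Observed t/p maps plus the permutation t sample and the formation
    threshold derived from it."""

    t_obs: np.ndarray        # (n_el, n_t)
    p_obs: np.ndarray        # (n_el, n_t), permutation p, two-sided
    abs_t_perm: np.ndarray   # (n_perm, n_points) float32
    t_perm_signed: np.ndarray  # (n_perm, n_points) float32
    n_perm: int
    seed: Optional[int]
    exact: bool


def pointwise_tmap(
    env_a: np.ndarray,
    env_b: np.ndarray,
    *,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = 0,
    exact: bool = False,
    chunk: int = 250,
) -> PointwiseResult:
    """Two-sample t and pointwise permutation p at every (electrode, ms).

    ``env_a``/``env_b``: (participants × electrodes × samples)
    participant-mean envelopes on a common time base. With ``exact=True``
    all C(n, n_a) label assignments are enumerated (small cohorts only) and
    p is the exact permutation probability; otherwise ``n_perm`` random
    label permutations give p = (1 + #{|t_perm| ≥ |t_obs|}) / (1 + n_perm).
    """
    env_a = np.asarray(env_a, dtype=np.float64)
    env_b = np.asarray(env_b, dtype=np.float64)
    if env_a.ndim != 3 or env_b.ndim != 3 or env_a.shape[1:] != env_b.shape[1:]:
        raise ValueError("envelope stacks must be (participants × el × t)")
    na, n_el, n_t = env_a.shape
    nb = env_b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 participants")
    n = na + nb
    X = np.concatenate([env_a, env_b], axis=0).reshape(n, n_el * n_t)
    obs_labels = np.zeros((1, n), dtype=bool)
    obs_labels[0, :na] = True
    t_obs = _pooled_tmaps(X, obs_labels)[0]

    if exact:
        L = _label_matrix_exhaustive(n, na)
        n_perm = L.shape[0]
    else:
        rng = np.random.default_rng(seed)
        L = _label_matrix_random(n, na, n_perm, rng)

    abs_obs = np.abs(t_obs)
    count_ge = np.zeros(n_el * n_t, dtype=np.int64)
    t_perm_signed = np.empty((n_perm, n_el * n_t), dtype=np.float32)
    for start in range(0, n_perm, chunk):
        block = _pooled_tmaps(X, L[start : start + chunk])
        t_perm_signed[start : start + block.shape[0]] = block
        # tiny relative slack so exact ties (e.g. the label-swapped
        # assignment) survive float32 rounding
        count_ge += (
            np.abs(block) >= abs_obs[np.newaxis, :] * np.float32(1 - 1e-6)
        ).sum(axis=0)

    if exact:
        p_obs = count_ge / n_perm
    else:
        p_obs = (1.0 + count_ge) / (1.0 + n_perm)
    return PointwiseResult(
        t_obs=t_obs.reshape(n_el, n_t),
        p_obs=p_obs.reshape(n_el, n_t),
        abs_t_perm=np.abs(t_perm_signed),
        t_perm_signed=t_perm_signed,
        n_perm=n_perm,
        seed=seed,
        exact=exact,
    )


def formation_threshold(
    pw: PointwiseResult,
    threshold: float = DEFAULT_FORMATION_P,
    *,
    for_null: bool = False,
) -> np.ndarray:
    """Per-point |t| cut equivalent to 'pointwise permutation p < threshold'.

    For the Monte-Carlo p (1 + count)/(1 + n_perm) < θ reduces to
    |t| strictly above the (m+1)-th largest permutation |t| at that point,
    with m = floor(θ·(1 + n_perm) − 1); exact enumeration reduces the same
    way with m = floor(θ·n_perm).

    With ``for_null=True`` the cut is shifted one order statistic down
    (the (m+2)-th largest): when the rule is applied to a permutation's own
    t map, that map is itself a member of the reference sample, so its
    self-count must be discounted for the permuted datasets to be treated
    exactly like the observed one. (Exact enumeration already contains the
    observed labeling, so both cuts coincide there.)
    """
    n_perm = pw.n_perm
    if pw.exact:
        m = int(math.floor(threshold * n_perm))
        k = m  # observed labeling is part of the enumeration
    else:
        m = int(math.floor(threshold * (1 + n_perm) - 1))
        k = m + 1 if for_null else m
    if m < 1 or k >= n_perm:
        raise ValueError(
            f"n_perm={n_perm} too small to resolve formation threshold {threshold}"
        )
    # (k+1)-th largest value per column
    part = np.partition(pw.abs_t_perm, n_perm - k - 1, axis=0)
    return part[n_perm - k - 1]


# ---------------------------------------------------------------------------
# cluster formation


class _GridConnectivity:
    """Precomputed edge lists for the (electrode × sample) grid under an
    electrode adjacency graph: temporal edges along each electrode row and
    spatial edges between adjacent electrodes at equal samples."""

    def __init__(self, graph: AdjacencyGraph, n_t: int) -> None:
        n_el = len(graph.montage)
        rows = []
        cols = []
        t_idx = np.arange(n_t - 1)
        for e in range(n_el):
            rows.append(e * n_t + t_idx)
            cols.append(e * n_t + t_idx + 1)
        tt = np.arange(n_t)
        for a, b in graph.edge_index_pairs():
            rows.append(a * n_t + tt)
            cols.append(b * n_t + tt)
        self.rows = np.concatenate(rows)
        self.cols = np.concatenate(cols)
        self.n_el = n_el
        self.n_t = n_t
        self.n_nodes = n_el * n_t

    def component_labels(self, supra: np.ndarray, sign: np.ndarray):
        """Connected-component labels over supra-threshold nodes of common
        sign. Returns (labels, n_components) over the full grid; only
        labels at supra nodes are meaningful."""
        keep = (
            supra[self.rows]
            & supra[self.cols]
            & (sign[self.rows] == sign[self.cols])
        )
        r = self.rows[keep]
        c = self.cols[keep]
        g = coo_matrix(
            (np.ones(r.size, dtype=np.int8), (r, c)),
            shape=(self.n_nodes, self.n_nodes),
        )
        n_comp, labels = connected_components(g, directed=False)
        return labels, n_comp

    def max_cluster_mass(self, t_flat: np.ndarray, tau: np.ndarray) -> float:
        """Largest |sum of t| over clusters formed at |t| > tau."""
        supra = np.abs(t_flat) > tau
        if not supra.any():
            return 0.0
        sign = np.sign(t_flat).astype(np.int8)
        labels, n_comp = self.component_labels(supra, sign)
        masses = np.bincount(
            labels[supra], weights=t_flat[supra], minlength=n_comp
        )
        return float(np.abs(masses).max())


def _runs(sorted_samples: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous runs [(first, last), ...] of sorted integer samples."""
    breaks = np.flatnonzero(np.diff(sorted_samples) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [sorted_samples.size - 1]])
    return [(int(sorted_samples[s]), int(sorted_samples[e])) for s, e in zip(starts, ends)]


def form_clusters(
    tmap: np.ndarray,
    pmap: np.ndarray,
    graph: AdjacencyGraph,
    *,
    threshold: float = DEFAULT_FORMATION_P,
    time_offset_s: float = 0.0,
    fs: float = 1000.0,
    connectivity: Optional[_GridConnectivity] = None,
) -> List[Cluster]:
    """Group supra-threshold points (pmap < threshold) of common sign into
    spatio-temporally contiguous clusters.

    Connectivity: consecutive samples on one electrode, and equal-sample
    links between adjacent electrodes — so temporally overlapping
    supra-threshold runs on neighboring electrodes merge. Mass is the sum
    of member t values. Clusters are returned largest-|mass| first.
    """
    tmap = np.asarray(tmap, dtype=float)
    pmap = np.asarray(pmap, dtype=float)
    if tmap.shape != pmap.shape or tmap.ndim != 2:
        raise ValueError("tmap and pmap must be equal-shape (el × t)")
    n_el, n_t = tmap.shape
    if n_el != len(graph.montage):
        raise ValueError("map rows must match the adjacency montage")
    conn = connectivity or _GridConnectivity(graph, n_t)
    t_flat = tmap.ravel()
    supra = pmap.ravel() < threshold
    clusters: List[Cluster] = []
    if supra.any():
        sign = np.sign(t_flat).astype(np.int8)
        labels, n_comp = conn.component_labels(supra, sign)
        masses = np.bincount(labels[supra], weights=t_flat[supra], minlength=n_comp)
        supra_idx = np.flatnonzero(supra)
        order = np.argsort(labels[supra_idx], kind="stable")
        supra_idx = supra_idx[order]
        lab_sorted = labels[supra_idx]
        boundaries = np.flatnonzero(np.diff(lab_sorted)) + 1
        for member_idx in np.split(supra_idx, boundaries):
            el = member_idx // n_t
            sm = member_idx % n_t
            mass = float(masses[labels[member_idx[0]]])
            extents: Dict[str, List[Tuple[float, float]]] = {}
            max_run = 0
            for e in np.unique(el):
                s_sorted = np.sort(sm[el == e])
                ivs = []
                for first, last in _runs(s_sorted):
                    ivs.append(
                        (
                            time_offset_s + first / fs,
                            time_offset_s + (last + 1) / fs,
                        )
                    )
                    max_run = max(max_run, last - first + 1)
                extents[graph.montage[e]] = ivs
            clusters.append(
                Cluster(
                    electrodes=el,
                    samples=sm,
                    mass=mass,
                    direction=int(np.sign(mass)),
                    extents=extents,
                    max_run_s=max_run / fs,
                )
            )
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def cluster_pvalues(
    clusters: Sequence[Cluster], null: PermutationNull
) -> List[Cluster]:
    """Attach permutation p to each cluster from the max-mass null:
    p = (1 + #{null max ≥ |mass|}) / (1 + n_perm)."""
    for c in clusters:
        count = int(np.sum(null.max_mass >= abs(c.mass)))
        c.p = (1.0 + count) / (1.0 + null.n_perm)
    return list(clusters)


def persistence_filter(
    clusters: Sequence[Cluster], min_duration_s: float = DEFAULT_MIN_DURATION_S
) -> List[Cluster]:
    """Keep clusters whose longest single-electrode contiguous run strictly
    exceeds ``min_duration_s`` (default 10 ms)."""
    return [c for c in clusters if c.max_run_s > min_duration_s + 1e-12]


def aggregate_windows(
    clusters: Sequence[Cluster],
    graph: AdjacencyGraph,
    *,
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
) -> List[RepresentativeWindow]:
    """Merge significant clusters into representative reporting windows.

    Two same-direction clusters merge when their overall time intervals
    overlap or are separated by at most ``gap_tolerance_s``, or when they
    contain adjacent electrodes with overlapping intervals; merging is
    transitive. Purely a reporting convenience — inference never depends
    on it.
    """
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def mergeable(a: Cluster, b: Cluster) -> bool:
        if a.direction != b.direction:
            return False
        gap = max(a.start_s, b.start_s) - min(a.end_s, b.end_s)
        if gap <= gap_tolerance_s + 1e-12:
            return True
        if gap <= 1e-12:
            return True
        overlap = a.start_s < b.end_s and b.start_s < a.end_s
        if overlap:
            for ea in a.electrode_names:
                for eb in b.electrode_names:
                    if ea == eb or graph.are_adjacent(ea, eb):
                        return True
        return False

    for i in range(n):
        for j in range(i + 1, n):
            if mergeable(clusters[i], clusters[j]):
                union(i, j)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    windows = []
    for members in groups.values():
        cs = [clusters[i] for i in members]
        electrodes = sorted({e for c in cs for e in c.electrode_names})
        windows.append(
            RepresentativeWindow(
                start_s=min(c.start_s for c in cs),
                end_s=max(c.end_s for c in cs),
                electrodes=tuple(electrodes),
                direction=cs[0].direction,
                cluster_indices=tuple(sorted(members)),
            )
        )
    windows.sort(key=lambda w: (w.start_s, w.end_s))
    return windows


# ---------------------------------------------------------------------------
# end-to-end test


def cluster_permutation_test(
    env_a: np.ndarray,
    env_b: np.ndarray,
    graph: AdjacencyGraph,
    *,
    n_perm: int = DEFAULT_N_PERM,
    seed: Optional[int] = 0,
    threshold: float = DEFAULT_FORMATION_P,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    time_offset_s: float = 0.0,
    fs: float = 1000.0,
    exact: bool = False,
) -> ClusterAnalysis:
    """Full spatio-temporal cluster permutation test between two groups of
    participant-mean envelope maps (participants × electrodes × samples).

    The same label permutations drive the pointwise p map, the formation
    threshold, and the max-cluster-mass null, so observed and permuted
    datasets are treated identically.
    """
    pw = pointwise_tmap(env_a, env_b, n_perm=n_perm, seed=seed, exact=exact)
    n_el, n_t = pw.t_obs.shape
    conn = _GridConnectivity(graph, n_t)
    tau_null = formation_threshold(pw, threshold, for_null=True)

    clusters = form_clusters(
        pw.t_obs,
        pw.p_obs,
        graph,
        threshold=threshold,
        time_offset_s=time_offset_s,
        fs=fs,
        connectivity=conn,
    )
    max_mass = np.empty(pw.n_perm)
    for i in range(pw.n_perm):
        max_mass[i] = conn.max_cluster_mass(pw.t_perm_signed[i], tau_null)
    null = PermutationNull(
        n_perm=pw.n_perm, seed=seed, max_mass=max_mass, exact=exact
    )
    cluster_pvalues(clusters, null)
    return ClusterAnalysis(
        t_obs=pw.t_obs,
        p_obs=pw.p_obs,
        clusters=clusters,
        null=null,
        threshold=threshold,
        min_duration_s=min_duration_s,
        montage=graph.montage,
        time_offset_s=time_offset_s,
        fs=fs,
        adjacency_fingerprint=graph.fingerprint(),
    )
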