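"""Static montage metadata: the 19-site scalp montage, its electrode
neighborhood graph, and the electrode→Brodmann-area annotation table.

The montage follows the international 10–20 system with 10–10 extensions
(reference CPz and ground AFz are not analysis channels).  The adjacency
table lists nearest physical neighbors on that layout, bridging the absent
C-row through the nearest present site; it is symmetric, irreflexive, and
user-overridable from a two-column CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

#: Analysis channels, in recording order.
MONTAGE_19: Tuple[str, ...] = (
    "FC1", "FC2", "FC5", "FC6",
    "CP1", "CP2", "CP5", "CP6",
    "P3", "P4", "P7", "P8",
    "O1", "O2",
    "FCz", "Cz", "Pz", "POz", "Oz",
)

#: Nearest-neighbor lists on the 10–20/10–10 layout restricted to the
#: 19-site montage. Gaps left by absent sites (the C row, CPz) are bridged
#: to the nearest present electrode.
DEFAULT_ADJACENCY: Dict[str, Tuple[str, ...]] = {
    "FC5": ("FC1", "CP5"),
    "FC1": ("FC5", "FCz", "Cz", "CP1"),
    "FCz": ("FC1", "FC2", "Cz"),
    "FC2": ("FCz", "FC6", "Cz", "CP2"),
    "FC6": ("FC2", "CP6"),
    "Cz": ("FC1", "FCz", "FC2", "CP1", "CP2"),
    "CP5": ("FC5", "CP1", "P7", "P3"),
    "CP1": ("FC1", "Cz", "CP5", "CP2", "P3", "Pz"),
    "CP2": ("FC2", "Cz", "CP1", "CP6", "P4", "Pz"),
    "CP6": ("FC6", "CP2", "P8", "P4"),
    "P7": ("CP5", "P3", "O1"),
    "P3": ("CP5", "CP1", "P7", "Pz", "O1"),
    "Pz": ("CP1", "CP2", "P3", "P4", "POz"),
    "P4": ("CP2", "CP6", "P8", "Pz", "O2"),
    "P8": ("CP6", "P4", "O2"),
    "POz": ("Pz", "O1", "Oz", "O2"),
    "O1": ("P7", "P3", "POz", "Oz"),
    "O2": ("P8", "P4", "POz", "Oz"),
    "Oz": ("O1", "O2", "POz"),
}


class AdjacencyGraph:
    """Symmetric, irreflexive electrode neighborhood over a montage."""

    def __init__(self, neighbors: Dict[str, Sequence[str]],
                 montage: Sequence[str] = MONTAGE_19) -> None:
        montage = tuple(montage)
        if len(set(montage)) != len(montage):
            raise ValueError("montage electrode names must be unique")
        adj: Dict[str, set] = {name: set() for name in montage}
        for a, nbrs in neighbors.items():
            if a not in adj:
                raise ValueError(f"unknown electrode in adjacency: {a}")
            for b in nbrs:
                if b not in adj:
                    raise ValueError(f"unknown electrode in adjacency: {b}")
                if a == b:
                    raise ValueError(f"self-adjacency not allowed: {a}")
                adj[a].add(b)
                adj[b].add(a)
        self.montage = montage
        self._adj = {k: frozenset(v) for k, v in adj.items()}

    def neighbors(self, electrode: str) -> FrozenSet[str]:
        return self._adj[electrode]

    def are_adjacent(self, a: str, b: str) -> bool:
        return b in self._adj[a]

    def edges(self) -> List[Tuple[str, str]]:
        """Each undirected edge once, lexicographically ordered."""
        out = []
        for a in self.montage:
            for b in self._adj[a]:
                if a < b:
                    out.append((a, b))
        return sorted(out)

    def edge_index_pairs(self) -> List[Tuple[int, int]]:
        """Edges as (row, col) index pairs into the montage order."""
        pos = {name: i for i, name in enumerate(self.montage)}
        return [(pos[a], pos[b]) for a, b in self.edges()]

    def fingerprint(self) -> str:
        """Stable short description for reports (montage size + edge list
        hash-free digest)."""
        return f"{len(self.montage)}ch:" + ",".join(
            f"{a}-{b}" for a, b in self.edges()
        )


def default_adjacency(montage: Sequence[str] = MONTAGE_19) -> AdjacencyGraph:
    """The shipped neighborhood graph, restricted to ``montage``."""
    montage = tuple(montage)
    keep = set(montage)
    sub = {
        a: tuple(b for b in nbrs if b in keep)
        for a, nbrs in DEFAULT_ADJACENCY.items()
        if a in keep
    }
    return AdjacencyGraph(sub, montage)


def read_adjacency_csv(path, montage: Sequence[str] = MONTAGE_19) -> AdjacencyGraph:
    """Load a user adjacency override: CSV with columns electrode,neighbor
    (one edge per row; symmetry is enforced on load)."""
    neighbors: Dict[str, list] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"electrode", "neighbor"} <= set(
            reader.fieldnames
        ):
            raise ValueError("adjacency CSV needs columns electrode,neighbor")
        for row in reader:
            neighbors.setdefault(row["electrode"].strip(), []).append(
                row["neighbor"].strip()
            )
    return AdjacencyGraph(neighbors, montage)


@dataclass(frozen=True)
class ElectrodeAtlasEntry:
    """Probabilistic electrode→cortex annotation (Talairach mm, ±SD).

    Report annotation only; scalp electrodes do not localize sources.
    """

    electrode: str
    brodmann: str
    region: str
    x_mm: float
    y_mm: float
    z_mm: float
    sd_x_mm: float
    sd_y_mm: float
    sd_z_mm: float


#: Probabilistic Talairach mapping for the electrodes discussed in the
#: analysis reports.
ELECTRODE_ATLAS: Dict[str, ElectrodeAtlasEntry] = {
    e.electrode: e
    for e in (
        ElectrodeAtlasEntry("O2", "BA18", "middle occipital gyrus",
                            25.0, -95.2, 6.2, 5.7, 5.8, 11.4),
        ElectrodeAtlasEntry("CP2", "BA7", "postcentral gyrus",
                            25.8, -47.1, 66.0, 6.2, 9.2, 7.5),
        ElectrodeAtlasEntry("P3", "BA7", "inferior parietal lobule / precuneus",
                            -41.4, -67.8, 42.4, 5.7, 8.4, 9.5),
        ElectrodeAtlasEntry("P4", "BA7", "inferior parietal lobule",
                            44.2, -65.8, 42.7, 6.5, 8.1, 8.5),
        ElectrodeAtlasEntry("CP5", "BA40", "supramarginal gyrus",
                            -61.8, -46.2, 22.5, 4.7, 8.0, 7.6),
        ElectrodeAtlasEntry("FC1", "BA6", "superior frontal gyrus",
                            -24.7, 0.3, 66.4, 5.7, 8.5, 4.6),
    )
}


def annotate_electrode(electrode: str) -> str:
    """Human-readable annotation like 'CP5 (BA40, supramarginal gyrus)';
    falls back to the bare electrode name off-atlas."""
    entry = ELECTRODE_ATLAS.get(electrode)
    if entry is None:
        return electrode
    return f"{electrode} ({entry.brodmann}, {entry.region})"
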