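"""Readers, writers and core containers for association networks and MeSH trees.

The two on-disk artifacts are plain TSV:

* an association table with columns ``disease``, ``lncrna`` and an optional
  ``source`` column (``#`` comment lines are ignored, a header row is
  auto-detected);
* a disease -> MeSH-tree-number table with columns ``disease`` and
  ``tree_numbers`` (semicolon-delimited dot coordinates such as
  ``C04.588.894.797``).

Disease and lncRNA names are normalized on ingestion -- trimmed, internal
whitespace collapsed, casefolded -- so that tables from differently curated
databases merge deterministically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationNetwork",
    "MeshForest",
    "normalize_name",
    "network_from_pairs",
    "read_associations",
    "write_associations",
    "merge_networks",
    "read_mesh_forest",
    "write_mesh_forest",
    "network_density",
    "read_matrix",
    "write_matrix",
]

_WS = re.compile(r"\s+")
_TREE_SEGMENT = re.compile(r"^[A-Za-z0-9]+$")


def normalize_name(name: str) -> str:
    """Trim, collapse internal whitespace and casefold an entity name."""
    return _WS.sub(" ", name.strip()).casefold()


@dataclass
class AssociationNetwork:
    """Labeled binary adjacency of a disease-lncRNA bipartite graph.

    Rows of ``A`` are diseases, columns are lncRNAs; ``A[i, j] == 1`` records
    an experimentally verified association between ``disease_names[i]`` and
    ``lncrna_names[j]``.
    """

    disease_names: list[str]
    lncrna_names: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.disease_names), len(self.lncrna_names)):
            raise ValueError(
                f"adjacency shape {self.A.shape} does not match "
                f"{len(self.disease_names)} diseases x {len(self.lncrna_names)} lncRNAs"
            )
        if len(set(self.disease_names)) != len(self.disease_names):
            raise ValueError("duplicate disease names after normalization")
        if len(set(self.lncrna_names)) != len(self.lncrna_names):
            raise ValueError("duplicate lncRNA names after normalization")
        uniq = np.unique(self.A)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")

    @property
    def n_diseases(self) -> int:
        return len(self.disease_names)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrna_names)

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def disease_index(self, name: str) -> int:
        try:
            return self.disease_names.index(normalize_name(name))
        except ValueError:
            raise KeyError(f"unknown disease: {name!r}") from None

    def pairs(self) -> list[tuple[str, str]]:
        """Known (disease, lncRNA) pairs in row-major order."""
        di, lj = np.nonzero(self.A)
        return [(self.disease_names[i], self.lncrna_names[j]) for i, j in zip(di, lj)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.disease_names, columns=self.lncrna_names)


@dataclass
class MeshForest:
    """Disease -> set of MeSH tree-number coordinates.

    Each tree number is a dot-delimited coordinate (``C04.588.894.797``);
    truncating the last segment yields the parent term's coordinate, so the
    mapping alone determines every disease's ancestor DAG.  Diseases absent
    from the mapping simply have no DAG.
    """

    tree_numbers: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, disease: str) -> bool:
        return normalize_name(disease) in self.tree_numbers

    def get(self, disease: str) -> frozenset[str]:
        return self.tree_numbers.get(normalize_name(disease), frozenset())

    @property
    def diseases(self) -> list[str]:
        return sorted(self.tree_numbers)


def validate_tree_number(tn: str) -> str:
    """Check a dot-delimited MeSH coordinate; returns it unchanged."""
    segments = tn.split(".")
    if not segments or any(not _TREE_SEGMENT.match(s) for s in segments):
        raise ValueError(f"malformed tree number: {tn!r}")
    return tn


def network_from_pairs(pairs: Iterable[tuple[str, str]]) -> AssociationNetwork:
    """Build a network from (disease, lncRNA) pairs.

    Names are normalized, duplicates collapse, and label order is first
    appearance in the input stream.
    """
    disease_order: dict[str, int] = {}
    lncrna_order: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for d_raw, l_raw in pairs:
        d, l = normalize_name(d_raw), normalize_name(l_raw)
        if not d or not l:
            raise ValueError(f"empty name in pair {(d_raw, l_raw)!r}")
        disease_order.setdefault(d, len(disease_order))
        lncrna_order.setdefault(l, len(lncrna_order))
        seen.add((d, l))
    if not seen:
        raise ValueError("no associations provided")
    A = np.zeros((len(disease_order), len(lncrna_order)))
    for d, l in seen:
        A[disease_order[d], lncrna_order[l]] = 1.0
    return AssociationNetwork(list(disease_order), list(lncrna_order), A)


def _iter_table_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def read_associations(
    path: str | Path | Sequence[str | Path],
    columns: tuple[int, int] = (0, 1),
) -> AssociationNetwork:
    """Read one or more association TSVs into a single network.

    ``columns`` gives the (disease, lncRNA) column positions.  A first row
    whose cells look like the canonical header (``disease`` / ``lncrna``) is
    skipped.  Rows missing either field raise with the offending line number.
    """
    paths = [Path(path)] if isinstance(path, (str, Path)) else [Path(p) for p in path]
    d_col, l_col = columns
    pairs: list[tuple[str, str]] = []
    for p in paths:
        if not p.exists():
            raise FileNotFoundError(p)
        rows = list(_iter_table_rows(p))
        if not rows:
            raise ValueError(f"{p}: empty association table")
        start = 0
        head = [c.strip().casefold() for c in rows[0][1]]
        if max(d_col, l_col) < len(head) and head[d_col] == "disease":
            start = 1
        for lineno, cells in rows[start:]:
            if max(d_col, l_col) >= len(cells) or not cells[d_col].strip() or not cells[l_col].strip():
                raise ValueError(f"{p}:{lineno}: row is missing a disease or lncRNA field")
            pairs.append((cells[d_col], cells[l_col]))
    if not pairs:
        raise ValueError("no association rows found")
    return network_from_pairs(pairs)


def merge_networks(nets: Sequence[AssociationNetwork]) -> AssociationNetwork:
    """Union of several networks' association pairs (names already normalized)."""
    pairs: list[tuple[str, str]] = []
    for net in nets:
        pairs.extend(net.pairs())
    return network_from_pairs(pairs)


def write_associations(net: AssociationNetwork, path: str | Path) -> None:
    path = Path(path)
    lines = ["disease\tlncrna"]
    lines += [f"{d}\t{l}" for d, l in net.pairs()]
    path.write_text("\n".join(lines) + "\n")


def read_mesh_forest(path: str | Path) -> MeshForest:
    """Read a disease -> semicolon-delimited tree-number TSV.

    A disease listed on several rows accumulates the union of its tree
    numbers.  An empty file yields an empty forest (every downstream semantic
    similarity is then zero).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping: dict[str, set[str]] = {}
    for lineno, cells in _iter_table_rows(path):
        head = cells[0].strip().casefold()
        if lineno == 1 and head == "disease":
            continue
        if len(cells) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
        disease = normalize_name(cells[0])
        entry = mapping.setdefault(disease, set())
        for tn in cells[1].split(";"):
            tn = tn.strip()
            if not tn:
                continue
            entry.add(validate_tree_number(tn))
    return MeshForest({d: frozenset(v) for d, v in mapping.items() if v})


def write_mesh_forest(forest: MeshForest, path: str | Path) -> None:
    path = Path(path)
    lines = ["disease\ttree_numbers"]
    for d in sorted(forest.tree_numbers):
        lines.append(f"{d}\t{';'.join(sorted(forest.tree_numbers[d]))}")
    path.write_text("\n".join(lines) + "\n")


def network_density(net: AssociationNetwork) -> float:
    """Edges divided by possible edges, ``|E| / (N_d * N_l)``."""
    cells = net.n_diseases * net.n_lncrnas
    if cells == 0:
        raise ValueError("empty network has no density")
    return net.n_associations / cells


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t")
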