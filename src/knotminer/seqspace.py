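"""Biophysical "sequence space": descriptor matrices, PCA, neighbours.

Each aligned position of each sequence is encoded by six descriptors —
molecular weight, net charge, Kyte–Doolittle hydropathy, TOP-IDP
disorder propensity, disulfide potential (1 for Cys) and occupancy
(1 for a residue, 0 for a gap) — and the resulting matrix is projected
by PCA after centring and unit-variance scaling.  Physicochemical
similarity between peptides is Euclidean distance in the projected
score space (the first three components by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .regional_msa import GAP, RegionalAlignment

PROPERTY_NAMES = ("mw", "charge", "kd_hydro", "top_idp", "ss_potential",
                  "occupancy")


@dataclass(frozen=True)
class PropertyTable:
    """Per-residue physicochemical values, loaded from the packaged table."""

    values: dict[str, tuple[float, float, float, float, float]]
    version: str = "v1"

    @classmethod
    def default(cls) -> "PropertyTable":
        text = resources.files("knotminer.data").joinpath(
            "properties.tsv").read_text()
        values: dict[str, tuple[float, ...]] = {}
        for line in text.splitlines():
            if line.startswith("#") or line.startswith("aa\t") \
                    or not line.strip():
                continue
            aa, *vals = line.split("\t")
            values[aa] = tuple(float(v) for v in vals)
        if set(values) != set("ACDEFGHIKLMNPQRSTVWY"):
            raise ValueError("property table must cover all 20 residues")
        return cls(values=values)


@dataclass(frozen=True)
class FeatureMatrix:
    ids: tuple[str, ...]
    X: np.ndarray                 # (n_seq, width * 6)
    column_labels: tuple[str, ...]


@dataclass(frozen=True)
class PCAResult:
    ids: tuple[str, ...]
    scores: np.ndarray            # (n_seq, n_components)
    loadings: np.ndarray          # (n_components, n_kept_columns)
    explained_variance_ratio: np.ndarray
    kept_columns: tuple[int, ...]  # indices into the FeatureMatrix columns
    dropped_columns: tuple[int, ...]


@dataclass(frozen=True)
class NeighborReport:
    query: str
    neighbors: tuple[tuple[str, float], ...]
    k: int
    space: str
    note: str = ""


def featurize(aln: RegionalAlignment,
              table: PropertyTable | None = None,
              on_unknown: str = "zero",
              ) -> FeatureMatrix:
    """Encode an alignment as a (sequences x positions*6) descriptor matrix.

    Gaps contribute zero for the five physical properties and occupancy
    zero; residues contribute occupancy one.  Residues absent from the
    table (e.g. X) are zero-filled by default (``on_unknown="zero"``) or
    raise with ``on_unknown="error"``.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    table = table or PropertyTable.default()
    width = aln.width
    nprop = len(PROPERTY_NAMES)
    X = np.zeros((len(aln), width * nprop))
    for i, row in enumerate(aln.rows):
        for j, c in enumerate(row):
            base = j * nprop
            if c == GAP:
                continue
            vals = table.values.get(c)
            if vals is None:
                if on_unknown == "error":
                    raise ValueError(f"residue {c!r} absent from table")
                X[i, base + nprop - 1] = 1.0  # occupancy still 1
                continue
            X[i, base:base + nprop - 1] = vals
            X[i, base + nprop - 1] = 1.0
    labels = tuple(f"pos{j + 1}:{p}" for j in range(width)
                   for p in PROPERTY_NAMES)
    return FeatureMatrix(ids=aln.ids, X=X, column_labels=labels)


def pca_project(fm: FeatureMatrix, n_components: int = 3) -> PCAResult:
    """Centre, scale and project the feature matrix onto top components.

    Constant columns are dropped (and recorded); the remaining columns
    are scaled to unit variance; scores come from the SVD of the scaled
    matrix.  The sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    X = fm.X
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    kept = np.where(std > 1e-12)[0]
    dropped = np.where(std <= 1e-12)[0]
    Z = (X[:, kept] - mean[kept]) / std[kept]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2
    ratio = var / var.sum() if var.sum() > 0 else var
    ncomp = min(n_components, s.size)
    scores = U[:, :ncomp] * s[:ncomp]
    loadings = Vt[:ncomp]
    # deterministic sign: largest |loading| entry of each component positive
    for c in range(ncomp):
        j = int(np.argmax(np.abs(loadings[c])))
        if loadings[c, j] < 0:
            loadings[c] = -loadings[c]
            scores[:, c] = -scores[:, c]
    return PCAResult(
        ids=fm.ids,
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:ncomp],
        kept_columns=tuple(int(j) for j in kept),
        dropped_columns=tuple(int(j) for j in dropped),
    )


def nearest_neighbors(result: PCAResult, query: str, k: int = 10,
                      space: str = "3pc") -> NeighborReport:
    """Rank the physicochemically closest sequences to a query.

    Euclidean distance in the chosen score space (``"3pc"`` restricts to
    at most the first three components, ``"full"`` uses all retained
    components).  Ties broken by id; the query never lists itself.
    """
    if query not in result.ids:
        raise KeyError(f"query {query!r} not in PCA result")
    if space not in ("3pc", "full"):
        raise ValueError("space must be '3pc' or 'full'")
    S = result.scores[:, :3] if space == "3pc" else result.scores
    qi = result.ids.index(query)
    dists = np.sqrt(((S - S[qi]) ** 2).sum(axis=1))
    others = [(result.ids[i], float(dists[i]))
              for i in range(len(result.ids)) if i != qi]
    others.sort(key=lambda t: (t[1], t[0]))
    note = ""
    if k >= len(others):
        note = (f"k={k} >= {len(others)} other sequences; returning all")
        k_eff = len(others)
    else:
        k_eff = k
    return NeighborReport(query=query, neighbors=tuple(others[:k_eff]),
                          k=k, space=space, note=note)
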