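"""On-disk formats, run configuration and dataset containers.

Association edge lists are two-column TSV/CSV (miRNA id, disease id);
similarity matrices are labelled square tables. Nothing here is specific to
any one database dump — the loaders only assume pre-matched identifiers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .similarity import SimilarityMatrix

__all__ = [
    "AssociationDataset",
    "RunConfig",
    "read_associations",
    "write_associations",
    "read_similarity",
    "write_similarity",
    "write_predictions",
    "load_config",
]


class ParseError(ValueError):
    pass


@dataclass
class AssociationDataset:
    """A 0/1 miRNA-disease indicator matrix with its observed-index set.

    ``A[i, j] == 1`` exactly when ``(i, j)`` is in ``omega`` (a known
    association); every other entry is exactly 0, meaning *unknown*, not
    negative.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    A: np.ndarray
    omega: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        self.mirna_ids = list(self.mirna_ids)
        self.disease_ids = list(self.disease_ids)
        self.A = np.asarray(self.A, dtype=float)
        self.omega = frozenset((int(i), int(j)) for i, j in self.omega)

    @classmethod
    def from_matrix(
        cls, A: np.ndarray, mirna_ids: Sequence[str], disease_ids: Sequence[str]
    ) -> "AssociationDataset":
        A = np.asarray(A, dtype=float)
        rows, cols = np.nonzero(A)
        omega = frozenset(zip(rows.tolist(), cols.tolist()))
        return cls(list(mirna_ids), list(disease_ids), A, omega).validate()

    @property
    def n_m(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_d(self) -> int:
        return len(self.disease_ids)

    def validate(self) -> "AssociationDataset":
        if len(set(self.mirna_ids)) != len(self.mirna_ids):
            raise ValueError("duplicate miRNA ids")
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("duplicate disease ids")
        if self.A.shape != (self.n_m, self.n_d):
            raise ValueError(
                f"A has shape {self.A.shape}, expected ({self.n_m}, {self.n_d})"
            )
        ones = {(int(i), int(j)) for i, j in zip(*np.nonzero(self.A))}
        if ones != set(self.omega):
            raise ValueError("omega does not match the nonzero entries of A")
        if not np.isin(self.A, (0.0, 1.0)).all():
            raise ValueError("A must be a 0/1 indicator matrix")
        return self


@dataclass
class RunConfig:
    """Hyperparameters, rank rule and solver/CV controls for one run.

    The latent ranks default to one sixth of the corresponding entity count
    (round half up), the regularization weights to lambda1 = lambda2 = 10,
    lambda3 = 1.
    """

    lambda1: float = 10.0
    lambda2: float = 10.0
    lambda3: float = 1.0
    rank_fraction: float = 1.0 / 6.0
    r_m: Optional[int] = None
    r_d: Optional[int] = None
    seed: int = 0
    folds: int = 5
    repeats: int = 50
    solver: "object" = None  # ApgSettings; filled lazily to avoid import cycle

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambda parameters must be nonnegative")
        if self.rank_fraction <= 0:
            raise ValueError("rank_fraction must be positive")
        if self.solver is None:
            from .core import ApgSettings

            self.solver = ApgSettings()

    def resolve_ranks(self, n_m: int, n_d: int) -> tuple[int, int]:
        """Return (r_m, r_d), applying the one-sixth rule where unset."""

        def round_half_up(x: float) -> int:
            return int(np.floor(x + 0.5))

        r_m = self.r_m if self.r_m is not None else max(1, round_half_up(n_m * self.rank_fraction))
        r_d = self.r_d if self.r_d is not None else max(1, round_half_up(n_d * self.rank_fraction))
        if r_m > n_m or r_d > n_d:
            raise ValueError("requested rank exceeds matrix dimension")
        return r_m, r_d


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    return pd.read_csv(path, sep=sep, engine="python")


def read_associations(
    path,
    mirna_universe: Optional[Sequence[str]] = None,
    disease_universe: Optional[Sequence[str]] = None,
) -> AssociationDataset:
    """Read a two-column (miRNA id, disease id) edge list.

    Ids are ordered by first appearance unless explicit universes are given;
    duplicate pairs collapse to a single association. Files may or may not
    carry a header line; a header is detected by the first line not recurring
    as a data pair.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",")]
            parts = [p for p in parts if p != ""]
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pairs.append((parts[0], parts[1]))
    if pairs and pairs[0] == ("mirna", "disease"):
        pairs = pairs[1:]

    seen_m: dict[str, int] = {}
    seen_d: dict[str, int] = {}
    if mirna_universe is not None:
        seen_m = {m: i for i, m in enumerate(mirna_universe)}
    if disease_universe is not None:
        seen_d = {d: j for j, d in enumerate(disease_universe)}
    for m, d in pairs:
        if mirna_universe is not None and m not in seen_m:
            raise ValueError(f"miRNA id {m!r} not in the supplied universe")
        if disease_universe is not None and d not in seen_d:
            raise ValueError(f"disease id {d!r} not in the supplied universe")
        if mirna_universe is None and m not in seen_m:
            seen_m[m] = len(seen_m)
        if disease_universe is None and d not in seen_d:
            seen_d[d] = len(seen_d)

    A = np.zeros((len(seen_m), len(seen_d)))
    for m, d in pairs:
        A[seen_m[m], seen_d[d]] = 1.0
    return AssociationDataset.from_matrix(A, list(seen_m), list(seen_d))


def write_associations(dataset: AssociationDataset, path) -> None:
    """Write the edge list of known associations (row-major order)."""
    with open(path, "w") as fh:
        fh.write("mirna\tdisease\n")
        for i, j in sorted(dataset.omega):
            fh.write(f"{dataset.mirna_ids[i]}\t{dataset.disease_ids[j]}\n")


def read_similarity(path, ids: Sequence[str]) -> SimilarityMatrix:
    """Read a labelled square similarity table and reindex it to ``ids``.

    The matrix is symmetrized as (S + S^T)/2 — with a warning if the
    asymmetry exceeds 1e-8 — and the diagonal is forced to 1.
    """
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    missing = [i for i in ids if i not in df.index or i not in df.columns]
    if missing:
        raise ValueError(f"similarity file {path} is missing ids: {missing}")
    S = df.loc[list(ids), list(ids)].to_numpy(dtype=float)
    if S.min() < -1e-6 or S.max() > 1 + 1e-6:
        raise ValueError(f"similarity values outside [0, 1] in {path}")
    asym = np.abs(S - S.T).max()
    if asym > 1e-8:
        warnings.warn(
            f"similarity matrix {path} asymmetric by {asym:.3g}; symmetrizing",
            stacklevel=2,
        )
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, 0.0, 1.0)
    return SimilarityMatrix(ids=list(ids), S=S).validate()


def write_similarity(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids).to_csv(path, sep="\t")


def write_predictions(
    model_scores: np.ndarray,
    dataset: AssociationDataset,
    path,
    top_t: int = 50,
    exclude_known: bool = True,
    diseases: Optional[Sequence[str]] = None,
) -> None:
    """Write per-disease ranked miRNA lists from a completed score matrix.

    Scores sort descending; ties break lexicographically on miRNA id so the
    output is platform-independent. Known pairs are dropped from the ranking
    when ``exclude_known`` is set (the novel-prediction use case).
    """
    scores = np.asarray(model_scores, dtype=float)
    if scores.shape != (dataset.n_m, dataset.n_d):
        raise ValueError(
            f"score matrix shape {scores.shape} != ({dataset.n_m}, {dataset.n_d})"
        )
    if diseases is None:
        diseases = dataset.disease_ids
    d_index = {d: j for j, d in enumerate(dataset.disease_ids)}
    with open(path, "w") as fh:
        fh.write("disease\trank\tmirna\tscore\n")
        for d in diseases:
            if d not in d_index:
                raise ValueError(f"unknown disease id {d!r}")
            j = d_index[d]
            candidates = [
                (-scores[i, j], dataset.mirna_ids[i], i)
                for i in range(dataset.n_m)
                if not (exclude_known and (i, j) in dataset.omega)
            ]
            if not candidates:
                warnings.warn(f"no candidate miRNAs left for disease {d!r}", stacklevel=2)
                continue
            candidates.sort()
            for rank, (neg, mid, i) in enumerate(candidates[:top_t], start=1):
                fh.write(f"{d}\t{rank}\t{mid}\t{-neg:.6g}\n")


def load_config(path, **overrides) -> RunConfig:
    """Load a flat YAML/JSON mirror of :class:`RunConfig`; kwargs override."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    raw = raw or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    solver_kwargs = raw.pop("solver", None)
    cfg = RunConfig(**raw)
    if solver_kwargs:
        from .core import ApgSettings

        cfg.solver = ApgSettings(**solver_kwargs)
    return cfg
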