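"""Subject QC and consensus community detection on weighted brain graphs.

The parcellation of nodes into modules is data-driven: subject matrices are
averaged, negative entries removed, and the resulting weighted graph is
partitioned by Louvain community detection (resolution parameter gamma)
refined with a Kernighan-Lin style single-node fine-tuning pass. Because the
algorithm is stochastic it is run many times, the runs are gathered in a
node x node co-assignment (consensus) matrix, and the consensus matrix is
itself re-partitioned until all runs agree. The resolution is tuned by
maximizing the normalized mutual information between consensus partitions at
adjacent resolutions (a stability-plateau criterion).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import igraph as ig
import numpy as np
import pandas as pd
from sklearn.metrics import normalized_mutual_info_score

from ._utils import check_symmetric_zero_diag, edge_index, rng_from, vectorize_edges


@dataclass
class ConnectivityDataset:
    """Per-subject symmetric connectivity matrices plus QC covariates."""

    subjects: np.ndarray
    matrices: np.ndarray  # (n_subjects, n_nodes, n_nodes)
    covariates: pd.DataFrame  # subject, age, sex, site, fd, dof, volume
    wave: int = 1

    def __post_init__(self):
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_subjects, n_nodes, n_nodes)")
        if len(self.subjects) != self.matrices.shape[0] or len(self.covariates) != len(self.subjects):
            raise ValueError("subjects, matrices and covariates must align")

    @property
    def n_nodes(self) -> int:
        return self.matrices.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.matrices.shape[0]

    def features(self) -> np.ndarray:
        """Vectorized edges, canonical (i < j, row-major) order."""
        return vectorize_edges(self.matrices)

    def subset(self, mask) -> "ConnectivityDataset":
        mask = np.asarray(mask)
        return ConnectivityDataset(
            subjects=self.subjects[mask],
            matrices=self.matrices[mask],
            covariates=self.covariates.iloc[mask].reset_index(drop=True),
            wave=self.wave,
        )

    def write(self, directory) -> None:
        """One dense matrix TSV per subject + manifest + covariates TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for s, subj in enumerate(self.subjects):
            fname = f"fc_sub{int(subj):05d}_w{self.wave}.tsv"
            np.savetxt(directory / fname, self.matrices[s], delimiter="\t", fmt="%.6g")
            rows.append({"subject": subj, "wave": self.wave, "file": fname})
        pd.DataFrame(rows).to_csv(directory / "manifest.tsv", sep="\t", index=False)
        self.covariates.to_csv(directory / "covariates.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory, wave: Optional[int] = None) -> "ConnectivityDataset":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        if wave is not None:
            manifest = manifest[manifest["wave"] == wave]
        covariates = pd.read_csv(directory / "covariates.tsv", sep="\t")
        mats = np.stack([np.loadtxt(directory / f, delimiter="\t") for f in manifest["file"]])
        subjects = manifest["subject"].to_numpy()
        covariates = covariates.set_index("subject").loc[subjects].reset_index()
        return cls(
            subjects=subjects,
            matrices=mats,
            covariates=covariates,
            wave=int(manifest["wave"].iloc[0]) if len(manifest) else (wave or 1),
        )


@dataclass
class ConsensusPartition:
    labels: np.ndarray          # node -> module, contiguous from 1
    gamma: float
    consensus_matrix: np.ndarray  # co-assignment frequencies, unit diagonal
    n_runs: int

    @property
    def n_modules(self) -> int:
        return int(self.labels.max())

    def modules(self) -> dict[int, np.ndarray]:
        return {m: np.flatnonzero(self.labels == m) for m in range(1, self.n_modules + 1)}

    def write(self, path) -> None:
        pd.DataFrame({"node": np.arange(self.labels.size), "module": self.labels}).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def exclude_high_motion(dataset: ConnectivityDataset, threshold_mm: float = 0.3):
    """Drop subjects with mean framewise displacement above the threshold."""
    fd = dataset.covariates["fd"].to_numpy(float)
    if np.isnan(fd).any():
        raise ValueError("framewise displacement missing for some subjects")
    keep = fd <= threshold_mm
    if not keep.any():
        raise ValueError(f"no subjects left: all mean FD > {threshold_mm} mm")
    excluded = dataset.subjects[~keep]
    return dataset.subset(keep), list(excluded)


def group_mean_fc(dataset: ConnectivityDataset) -> np.ndarray:
    """Element-wise mean over subjects with negative entries removed."""
    if dataset.n_subjects == 0:
        raise ValueError("empty dataset")
    mean = dataset.matrices.mean(axis=0)
    mean = np.clip(mean, 0.0, None)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return mean


# ---------------------------------------------------------------------------
# modularity + Louvain + fine-tuning
# ---------------------------------------------------------------------------


def modularity(W: np.ndarray, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Weighted Newman modularity with resolution gamma."""
    m2 = W.sum()
    if m2 <= 0:
        raise ValueError("modularity undefined for an all-zero graph")
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += W[np.ix_(idx, idx)].sum() / m2 - gamma * (k[idx].sum() / m2) ** 2
    return float(q)


def _fine_tune(W: np.ndarray, labels: np.ndarray, gamma: float,
               rng: np.random.Generator, max_passes: int = 50) -> np.ndarray:
    """Single-node best-move refinement until no move improves modularity."""
    labels = labels.copy()
    n = labels.size
    m2 = W.sum()
    k = W.sum(axis=1)
    for _ in range(max_passes):
        improved = False
        for i in rng.permutation(n):
            w_i = np.bincount(labels, weights=W[i], minlength=labels.max() + 1)
            sum_k = np.bincount(labels, weights=k, minlength=labels.max() + 1)
            a = labels[i]
            # gain of moving i from a to c
            base = w_i[a] / m2 * 2 - gamma * 2 * k[i] * (sum_k[a] - k[i]) / m2**2
            gains = w_i / m2 * 2 - gamma * 2 * k[i] * sum_k / m2**2 - base
            gains[a] = 0.0
            c = int(np.argmax(gains))
            if gains[c] > 1e-12:
                labels[i] = c
                improved = True
        if not improved:
            break
    # relabel contiguously
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def louvain_partition(W: np.ndarray, gamma: float = 1.0, seed=0,
                      fine_tune: bool = True) -> np.ndarray:
    """One stochastic Louvain run with modularity fine-tuning.

    Returns node -> module labels, contiguous from 1. W must be nonnegative
    and symmetric with zero diagonal.
    """
    W = np.asarray(W, float)
    check_symmetric_zero_diag(W, "W")
    if np.any(W < 0):
        raise ValueError("louvain_partition requires a nonnegative weight matrix")
    if W.sum() == 0:
        raise ValueError("all-zero weight matrix has no community structure")
    rng = rng_from(seed)
    i, j = edge_index(W.shape[0])
    wvals = W[i, j]
    nz = wvals > 0
    g = ig.Graph(n=W.shape[0], edges=list(zip(i[nz].tolist(), j[nz].tolist())))
    # igraph's multilevel Louvain is stochastic through the node order seed
    ig.set_random_number_generator(random.Random(int(rng.integers(2**31 - 1))))
    member = g.community_multilevel(weights=wvals[nz].tolist(), resolution=gamma).membership
    labels = np.asarray(member, int)
    if fine_tune:
        labels = _fine_tune(W, labels, gamma, rng)
    else:
        _, labels = np.unique(labels, return_inverse=True)
    return labels + 1


def _coassignment(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_partition(W: np.ndarray, gamma: float = 1.0, n_runs: int = 100,
                        seed=0, max_iter: int = 20) -> ConsensusPartition:
    """Consensus clustering over repeated stochastic Louvain runs.

    The co-assignment frequency matrix of ``n_runs`` runs is itself
    re-partitioned (at unit resolution) until every run agrees; the agreed
    partition is returned together with the first-level consensus matrix.
    """
    rng = rng_from(seed)
    runs = [louvain_partition(W, gamma, seed=rng) for _ in range(n_runs)]
    consensus = np.mean([_coassignment(r) for r in runs], axis=0)
    first_level = consensus.copy()
    np.fill_diagonal(first_level, 1.0)

    for _ in range(max_iter):
        mats = [_coassignment(r) for r in runs]
        if all(np.array_equal(mats[0], m) for m in mats[1:]):
            return ConsensusPartition(
                labels=runs[0], gamma=gamma, consensus_matrix=first_level, n_runs=n_runs
            )
        consensus = np.mean(mats, axis=0)
        cw = consensus.copy()
        np.fill_diagonal(cw, 0.0)
        runs = [louvain_partition(cw, 1.0, seed=rng) for _ in range(n_runs)]
    raise RuntimeError(
        f"consensus clustering did not converge in {max_iter} iterations "
        f"(last run had {max(int(r.max()) for r in runs)} modules)"
    )


def nmi(p: np.ndarray, q: np.ndarray) -> float:
    """Normalized mutual information, arithmetic-mean normalization."""
    return float(normalized_mutual_info_score(p, q, average_method="arithmetic"))


def tune_gamma(W: np.ndarray, gamma_grid: Sequence[float], n_runs: int = 100,
               seed=0) -> tuple[float, pd.DataFrame]:
    """Pick the resolution on a stability plateau.

    Computes a consensus partition per grid value and scores each gamma by
    the mean NMI between its partition and the partitions at adjacent grid
    values; the maximizer wins, ties to the smaller gamma.
    """
    grid = sorted(gamma_grid)
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    rng = rng_from(seed)
    parts = [consensus_partition(W, g, n_runs=n_runs, seed=rng) for g in grid]
    if len(grid) == 1:
        diag = pd.DataFrame({"gamma": grid, "n_modules": [parts[0].n_modules], "stability": [1.0]})
        return grid[0], diag
    scores = []
    for idx in range(len(grid)):
        neigh = [j for j in (idx - 1, idx + 1) if 0 <= j < len(grid)]
        scores.append(np.mean([nmi(parts[idx].labels, parts[j].labels) for j in neigh]))
    best = int(np.argmax(scores))  # argmax takes the first (smallest gamma) on ties
    diag = pd.DataFrame({
        "gamma": grid,
        "n_modules": [p.n_modules for p in parts],
        "stability": scores,
    })
    return grid[best], diag
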