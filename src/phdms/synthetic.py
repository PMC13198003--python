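"""Synthetic tissues with planted nested domains and frontier mixing.

The generator emulates the two features the pipeline is built to detect:
hierarchical organization (a prominent large-scale domain containing
smaller ones, like a cortical region containing subfields) and boundary
mixing (spots near a domain frontier oscillating between neighboring
domains, like the mixed border of a tumor microenvironment).

Spots sit on a regular square grid with unit spacing. Level 1 partitions
the grid into ``branching`` seeded-Voronoi domains; each deeper level
splits every parent into up to ``branching`` seeded-Voronoi children
inside the parent, so every child is a subset of exactly one parent. The
observed clustering sequence shows each level at ``scales_per_level``
consecutive scales, and at every scale each frontier spot's label is
independently flipped, with probability ``rho``, to a uniformly chosen
spatially adjacent domain. Interior spots never flip, so at ``rho = 0``
the sequence is perfectly nested, and at ``rho > 0`` frontier spots
acquire sub-maximal coreness while cores stay stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    ClusteringSequence,
    GroundTruthAnnotation,
    ScaleClustering,
    SpotSet,
    UNASSIGNED,
)

__all__ = ["PlantedHierarchy", "generate_hierarchy", "degrade_to_clusterings"]


@dataclass(frozen=True)
class PlantedHierarchy:
    """Nested planted domains on a grid, with a frontier mask.

    ``levels[l]`` holds per-spot integer domain labels, coarse to fine:
    level 0 is the coarsest partition and each deeper level strictly
    refines its parent. ``frontier_mask`` flags spots within one grid step
    (Chebyshev) of a differing label at any level.
    """

    spots: SpotSet
    levels: tuple[np.ndarray, ...]
    frontier_mask: np.ndarray
    grid_side: int
    branching: int
    seed: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def domains_at(self, level: int) -> dict[int, np.ndarray]:
        labels = self.levels[level]
        return {int(k): np.where(labels == k)[0] for k in np.unique(labels)}

    def truth_annotation(self, level: int) -> GroundTruthAnnotation:
        labels = np.array(
            [f"domain_{v}" for v in self.levels[level]], dtype=object
        )
        return GroundTruthAnnotation(spots=self.spots, labels=labels)

    def to_json(self, path) -> None:
        payload = {
            "grid_side": self.grid_side,
            "branching": self.branching,
            "seed": self.seed,
            "levels": [lv.tolist() for lv in self.levels],
            "frontier_mask": self.frontier_mask.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def _voronoi_split(
    coords: np.ndarray, members: np.ndarray, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Partition ``members`` into <=k seeded-Voronoi cells (empty cells pruned)."""
    k = min(k, len(members))
    seeds = rng.choice(members, size=k, replace=False)
    d2 = ((coords[members][:, None, :] - coords[seeds][None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    return [members[assign == j] for j in range(k) if (assign == j).any()]


def generate_hierarchy(
    grid_side: int = 32,
    n_levels: int = 2,
    branching: int = 2,
    seed: int = 0,
) -> PlantedHierarchy:
    """Plant a nested seeded-Voronoi hierarchy on a ``grid_side²`` grid."""
    if grid_side < 8:
        raise ValueError("grid_side must be at least 8")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if branching < 2:
        raise ValueError("branching must be at least 2")

    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(grid_side), np.arange(grid_side))
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n = grid_side * grid_side
    ids = np.array([f"spot_{i}" for i in range(n)], dtype=object)
    spots = SpotSet(ids, coords)

    levels: list[np.ndarray] = []
    parents = [np.arange(n)]
    for _ in range(n_levels):
        labels = np.empty(n, dtype=np.int64)
        children: list[np.ndarray] = []
        next_label = 0
        for block in parents:
            for cell in _voronoi_split(coords, block, branching, rng):
                labels[cell] = next_label
                next_label += 1
                children.append(cell)
        levels.append(labels)
        parents = children

    frontier = np.zeros(n, dtype=bool)
    for labels in levels:
        grid = labels.reshape(grid_side, grid_side)
        diff = np.zeros_like(grid, dtype=bool)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == dy == 0:
                    continue
                shifted = np.roll(np.roll(grid, dx, axis=0), dy, axis=1)
                valid = np.ones_like(diff)
                if dx == 1:
                    valid[0, :] = False
                elif dx == -1:
                    valid[-1, :] = False
                if dy == 1:
                    valid[:, 0] = False
                elif dy == -1:
                    valid[:, -1] = False
                diff |= valid & (shifted != grid)
        frontier |= diff.ravel()

    return PlantedHierarchy(
        spots=spots,
        levels=tuple(levels),
        frontier_mask=frontier,
        grid_side=grid_side,
        branching=branching,
        seed=seed,
    )


def _neighbor_labels(
    labels: np.ndarray, grid_side: int
) -> list[list[int]]:
    """Distinct adjacent (8-neighborhood) foreign labels per spot."""
    grid = labels.reshape(grid_side, grid_side)
    out: list[list[int]] = [[] for _ in range(labels.size)]
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == dy == 0:
                continue
            for i in range(grid_side):
                ni = i + dx
                if not 0 <= ni < grid_side:
                    continue
                for j in range(grid_side):
                    nj = j + dy
                    if not 0 <= nj < grid_side:
                        continue
                    if grid[ni, nj] != grid[i, j]:
                        flat = i * grid_side + j
                        lab = int(grid[ni, nj])
                        if lab not in out[flat]:
                            out[flat].append(lab)
    return out


def degrade_to_clusterings(
    hierarchy: PlantedHierarchy,
    scales_per_level: int = 2,
    rho: float = 0.0,
    seed: int = 0,
) -> ClusteringSequence:
    """Observe the hierarchy as a fine-to-coarse clustering sequence with
    boundary-mixing label noise.

    Each level is emitted at ``scales_per_level`` consecutive scales. At
    every scale, independently, each frontier spot flips to a uniformly
    chosen spatially adjacent domain of that level with probability
    ``rho``; noise is redrawn per scale, so the same level observed twice
    differs at the frontier — the source of sub-maximal frontier coreness.
    """
    if not 0.0 <= rho < 0.5:
        raise ValueError("rho must lie in [0, 0.5)")
    if scales_per_level < 1:
        raise ValueError("scales_per_level must be at least 1")

    rng = np.random.default_rng(seed)
    k_total = hierarchy.n_levels * scales_per_level
    resolutions = np.linspace(0.95, 0.15, k_total)
    # grid spots ordered row-major; levels stored coarse -> fine
    scales: list[ScaleClustering] = []
    scale_index = 0
    for level in reversed(range(hierarchy.n_levels)):  # fine -> coarse
        base = hierarchy.levels[level]
        neighbors = _neighbor_labels(base, hierarchy.grid_side) if rho > 0 else None
        for _ in range(scales_per_level):
            labels = base.copy()
            if rho > 0:
                flips = np.where(
                    hierarchy.frontier_mask & (rng.random(len(base)) < rho)
                )[0]
                for s in flips:
                    options = neighbors[s]
                    if options:
                        labels[s] = options[rng.integers(len(options))]
            scales.append(
                ScaleClustering(
                    scale_index=scale_index,
                    resolution=float(resolutions[scale_index]),
                    labels=labels,
                )
            )
            scale_index += 1
    return ClusteringSequence(spots=hierarchy.spots, scales=tuple(scales))
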