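"""Model/Results interface over the multiscale-domain pipeline.

``MultiscaleDomainModel`` wraps a spot set plus a fine-to-coarse clustering
sequence; ``fit()`` runs the full pipeline — overlap graph, 0-D persistence,
component filtering, coreness, ranking, heterogeneity — and returns a
``MultiscaleDomainResults`` carrying the persistence diagram, the domains,
the per-spot score maps, and writers/plotters for all standard outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import domains as _domains
from . import filtration as _filtration
from . import metrics as _metrics
from . import persistence as _persistence
from .io import (
    ClusteringSequence,
    GroundTruthAnnotation,
    SpotSet,
    read_label_matrix,
    read_spot_table,
)

__all__ = ["MultiscaleDomainModel", "MultiscaleDomainResults", "RunConfig"]

logger = logging.getLogger("phdms")


@dataclass
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    index_kind: str = "containment"
    min_lifetime: float = 0.0
    min_clusters: int = 2
    top_k: int = 25
    seed: int = 0
    output_dir: str = "phdms_output"
    subsample_threshold: int = 5000

    def __post_init__(self) -> None:
        if self.index_kind not in ("containment", "jaccard"):
            raise ValueError(f"unknown index kind {self.index_kind!r}")
        if not 0.0 <= self.min_lifetime <= 1.0:
            raise ValueError("min_lifetime must lie in [0, 1]")
        if self.min_clusters < 1 or self.top_k < 1:
            raise ValueError("min_clusters and top_k must be at least 1")
        if self.subsample_threshold < 1:
            raise ValueError("subsample_threshold must be positive")

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        return cls(**yaml.safe_load(Path(path).read_text()))


class MultiscaleDomainModel:
    """Multiscale spatial-domain model over a clustering sequence.

    Parameters
    ----------
    sequence
        Fine-to-coarse partitions of one spot set, e.g. a Leiden resolution
        sweep over a spatially-aware embedding.
    index_kind
        Overlap dissimilarity for the filtration: ``"containment"`` for
        largely nested sweeps (the default), ``"jaccard"`` for arbitrary
        ones.
    """

    def __init__(
        self, sequence: ClusteringSequence, index_kind: str = "containment"
    ) -> None:
        self.sequence = sequence
        self.spots: SpotSet = sequence.spots
        self.index_kind = index_kind

    @classmethod
    def from_tables(
        cls, spot_table, label_table, index_kind: str = "containment"
    ) -> "MultiscaleDomainModel":
        """Build from delimited text tables (``spot_id,x,y`` and per-scale labels)."""
        spots = read_spot_table(spot_table)
        seq = read_label_matrix(label_table, spots)
        return cls(seq, index_kind=index_kind)

    @classmethod
    def from_anndata(
        cls,
        adata,
        label_keys,
        spatial_key: str = "spatial",
        index_kind: str = "containment",
    ) -> "MultiscaleDomainModel":
        from .io import from_anndata

        _, seq, _ = from_anndata(adata, label_keys, spatial_key=spatial_key)
        return cls(seq, index_kind=index_kind)

    def fit(
        self,
        min_lifetime: float = 0.0,
        min_clusters: int = 2,
        top_k: int = 25,
        include_zero_persistence: bool = False,
    ) -> "MultiscaleDomainResults":
        """Run the pipeline and return results.

        ``min_lifetime``/``min_clusters`` filter which persistent components
        are reported as domains (the defaults hide singleton components);
        zero-persistence components carry no multiscale information and are
        excluded from reporting unless ``include_zero_persistence`` is set.
        ``top_k`` bounds the ranked list by persistence weighted by support
        size.
        """
        filt = _filtration.build_overlap_graph(self.sequence, self.index_kind)
        logger.info(
            "filtration: %d nodes, %d edges (%s index)",
            filt.n_nodes,
            len(filt.edges),
            self.index_kind,
        )
        diagram, components = _persistence.compute_persistence(filt)
        logger.info(
            "persistence: %d diagram points, %d immortal",
            len(diagram),
            sum(1 for p in diagram if math.isinf(p.death)),
        )
        reported = _persistence.filter_components(
            components, min_lifetime=min_lifetime, min_clusters=min_clusters
        )
        if not include_zero_persistence:
            reported = [c for c in reported if c.lifetime > 0]
        all_domains = [
            _domains.compute_coreness(c, self.spots) for c in reported
        ]
        ranked = _domains.rank_domains(all_domains, top_k=top_k)
        logger.info("domains: %d reported, %d ranked", len(all_domains), len(ranked))
        heterogeneity = (
            _domains.heterogeneity_map(all_domains)
            if all_domains
            else np.zeros(self.spots.n)
        )
        return MultiscaleDomainResults(
            model=self,
            filtration=filt,
            diagram=diagram,
            components=components,
            domains=all_domains,
            ranked_domains=ranked,
            heterogeneity=heterogeneity,
            params={
                "min_lifetime": min_lifetime,
                "min_clusters": min_clusters,
                "top_k": top_k,
            },
        )


@dataclass
class MultiscaleDomainResults:
    """Fitted multiscale domains with score maps and diagnostics."""

    model: MultiscaleDomainModel
    filtration: "_filtration.ClusterFiltration"
    diagram: list
    components: list
    domains: list = field(default_factory=list)
    ranked_domains: list = field(default_factory=list)
    heterogeneity: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    # -- tabular views ------------------------------------------------------

    def diagram_frame(self) -> pd.DataFrame:
        return _persistence.diagram_frame(self.diagram, self.components)

    def coreness_frame(self, ranked_only: bool = True) -> pd.DataFrame:
        doms = self.ranked_domains if ranked_only else self.domains
        data = {"spot_id": self.model.spots.ids}
        for d in doms:
            data[f"domain_{d.id}"] = d.normalized_coreness
        return pd.DataFrame(data)

    def heterogeneity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"spot_id": self.model.spots.ids, "h": self.heterogeneity}
        )

    def summary(self) -> str:
        """Human-readable fit summary: filtration, diagram, top domains."""
        seq = self.model.sequence
        lines = [
            "Multiscale spatial domains (0-D persistence on a cluster filtration)",
            "=" * 68,
            f"spots: {self.model.spots.n}   scales: {seq.n_scales} "
            f"(clusters per scale: {seq.cluster_counts()})",
            f"filtration: {self.filtration.n_nodes} cluster nodes, "
            f"{len(self.filtration.edges)} overlap edges "
            f"({self.filtration.index_kind} index)",
            f"diagram: {len(self.diagram)} points, "
            f"{sum(1 for p in self.diagram if math.isinf(p.death))} immortal "
            f"components",
            f"reported domains: {len(self.domains)} "
            f"(min_lifetime={self.params.get('min_lifetime')}, "
            f"min_clusters={self.params.get('min_clusters')})",
            "",
            f"{'id':>4} {'death':>8} {'lifetime':>9} {'clusters':>9} "
            f"{'support':>8} {'score':>9}",
            "-" * 54,
        ]
        for d in self.ranked_domains:
            death = "inf" if math.isinf(d.component.death) else f"{d.component.death:.4f}"
            lines.append(
                f"{d.id:>4} {death:>8} {d.lifetime:>9.4f} "
                f"{d.component.n_clusters:>9} {d.support_size:>8} "
                f"{d.lifetime * d.support_size:>9.1f}"
            )
        return "\n".join(lines)

    # -- analysis -----------------------------------------------------------

    def domains_at(self, x: float, y: float) -> list[tuple["_domains.MultiscaleDomain", float]]:
        """Domains containing the spot nearest (x, y), by coreness there."""
        coords = self.model.spots.coords
        nearest = int(np.argmin(((coords - [x, y]) ** 2).sum(axis=1)))
        hits = [
            (d, float(d.normalized_coreness[nearest]))
            for d in self.domains
            if d.normalized_coreness[nearest] > 0
        ]
        hits.sort(key=lambda t: (-t[1], t[0].id))
        return hits

    def match_to_truth(self, truth: GroundTruthAnnotation, **kwargs):
        return _metrics.match_to_truth(self.domains, truth, **kwargs)

    def select_best_subset(self, truth: GroundTruthAnnotation, **kwargs):
        return _metrics.select_best_subset(self.domains, truth, **kwargs)

    # -- output -------------------------------------------------------------

    def save(self, output_dir, plots: bool = True) -> None:
        """Write diagram.csv, coreness.csv, heterogeneity.csv and plots."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.diagram_frame().to_csv(out / "diagram.csv", index=False)
        self.coreness_frame().to_csv(out / "coreness.csv", index=False)
        self.heterogeneity_frame().to_csv(out / "heterogeneity.csv", index=False)
        if plots:
            from . import plotting

            plotting.plot_persistence_diagram(
                self.diagram, path=out / "persistence_diagram.png"
            )
            plotting.plot_heterogeneity_map(
                self.heterogeneity,
                self.model.spots,
                path=out / "heterogeneity.png",
            )
            for d in self.ranked_domains:
                plotting.plot_coreness_map(
                    d, self.model.spots, path=out / f"domain_{d.id}.png"
                )
        logger.info("results written to %s", out)
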