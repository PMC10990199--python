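"""Per-species and joint-species atlas pipelines.

``run_species`` chains the full per-species analysis — filtering, pairwise
distances, haplotype collapsing, diversity indices, grid-averaged G_ST,
sampling completeness, PCoA colors, the MST network and per-area pies —
with each stage gated by its own eligibility rule. A stage that cannot run
(too few specimens, single haplotype, ...) records a status and reason
instead of failing the bundle; missing statistics stay missing, never 0,
because 0 is a meaningful G_ST value here.

``run_joint`` treats two or more species as a single entity: one pooled
distance matrix, embedding, color scheme and network, with per-species map
layers sharing the colors — the hybrid-zone view. ``run_atlas`` produces
the summary table (one row per species) and the bivariate sqrt(pi) vs G_ST
plot data with per-axis medians.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import completeness as cmp_mod
from . import diversity as div_mod
from .distances import (DistanceMatrix, HaplotypeTable, collapse_haplotypes,
                        distance_matrix, haplotype_distance_matrix,
                        steps_matrix)
from .embedding import Embedding, assign_colors, pcoa_embed
from .network import AreaPie, HaplotypeNetwork, build_network, group_by_area
from .records import Dataset, filter_records
from .spatial import GstResult, multiscale_gst


@dataclass
class AtlasConfig:
    min_unambiguous: int = 500
    min_specimens_spatial: int = 10   # G_ST / completeness need more than this
    min_per_cell: int = 3
    cell_sizes: tuple[float, ...] = (100.0, 200.0, 300.0, 400.0)
    offsets: tuple[float, ...] = (0.0, 0.5)
    area_cell_km: float = 200.0
    network_orders: int = 50
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SpeciesBundle:
    species: str
    n_records: int
    diversity: div_mod.DiversitySummary | None
    gst: GstResult | None
    completeness: cmp_mod.CompletenessResult | None
    haplotypes: HaplotypeTable | None
    embedding: Embedding | None
    colors: dict[str, tuple[float, float, float]] | None
    network: HaplotypeNetwork | None
    area_pies: list[AreaPie] | None
    statuses: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def summary_row(self) -> dict:
        d = self.diversity
        c = self.completeness
        return {
            "species": self.species,
            "N": self.n_records,
            "H": self.haplotypes.n_haplotypes if self.haplotypes else None,
            "h": d.h if d else None,
            "pi": d.pi if d else None,
            "max_intra": d.max_intra if d else None,
            "nnd": d.nnd if d else None,
            "nn_species": d.nn_species if d else None,
            "R": c.R if c else None,
            "L": c.L if c else None,
            "gst": self.gst.gst_mean if self.gst else None,
            "gst_status": self.gst.status if self.gst else
                          self.statuses.get("gst", ""),
        }


def run_species(dataset: Dataset, species: str,
                config: AtlasConfig | None = None,
                prefiltered: bool = False) -> SpeciesBundle:
    """Full per-species bundle with per-stage eligibility statuses."""
    config = config or AtlasConfig()
    if species not in dataset.species_names:
        raise ValueError(f"species {species!r} not present in dataset")
    if prefiltered:
        sub = dataset.subset(species)
    else:
        filtered, _ = filter_records(dataset, config.min_unambiguous)
        if species not in filtered.species_names:
            raise ValueError(f"species {species!r} empty after filtering")
        sub = filtered.subset(species)

    statuses: dict[str, str] = {}
    n = sub.n_records

    dmat: DistanceMatrix | None = None
    diversity = None
    table = None
    if n >= 2:
        dmat = distance_matrix(sub)
        if dmat.complete:
            table = collapse_haplotypes(sub, dmat)
            diversity = div_mod.DiversitySummary(
                N=n, H=table.n_haplotypes,
                pi=div_mod.nucleotide_diversity(dmat),
                h=div_mod.haplotype_diversity(table.counts()),
                max_intra=div_mod.max_intraspecific(dmat),
            )
            statuses["diversity"] = "computed"
        else:
            statuses["diversity"] = "incomplete distance matrix"
    else:
        table = collapse_haplotypes(sub, None)
        statuses["diversity"] = "withheld: fewer than 2 specimens"

    gst = None
    if dmat is not None and dmat.complete and n > config.min_specimens_spatial:
        gst = multiscale_gst(sub, dmat, cell_sizes=config.cell_sizes,
                             offsets=config.offsets,
                             min_per_cell=config.min_per_cell,
                             min_total=config.min_specimens_spatial)
        statuses["gst"] = gst.status
    else:
        statuses["gst"] = (f"withheld: requires more than "
                           f"{config.min_specimens_spatial} specimens")

    compl = None
    if table is not None:
        try:
            compl = cmp_mod.asymptotic_richness(
                table.counts(), min_n=config.min_specimens_spatial)
            statuses["completeness"] = "computed"
        except cmp_mod.InsufficientSamplingError as e:
            statuses["completeness"] = f"withheld: {e}"

    embedding = colors = net = pies = None
    if table is not None and table.n_haplotypes >= 1:
        hap_dmat = haplotype_distance_matrix(table)
        if hap_dmat.complete:
            embedding = pcoa_embed(hap_dmat)
            colors = assign_colors(embedding)
            net = build_network(table, steps_matrix(table),
                                n_orders=config.network_orders,
                                seed=config.seed)
            pies = group_by_area(sub, table, colors,
                                 area_cell_km=config.area_cell_km)
            statuses["network"] = "computed"
        else:
            statuses["network"] = "incomplete haplotype distances"

    return SpeciesBundle(
        species=species, n_records=n, diversity=diversity, gst=gst,
        completeness=compl, haplotypes=table, embedding=embedding,
        colors=colors, network=net, area_pies=pies, statuses=statuses,
        provenance={"config": config.digest(), "seed": str(config.seed)},
    )


def attach_nearest_neighbors(dataset: Dataset,
                             bundles: dict[str, SpeciesBundle]) -> None:
    """Fill nnd / nn_species across a multi-species dataset, in place."""
    parts = dataset.partition_by_species()
    if len(parts) < 2:
        return
    for sp, bundle in bundles.items():
        if bundle.diversity is None:
            continue
        others = {s: d for s, d in parts.items() if s != sp}
        try:
            nnd, nn_sp = div_mod.nearest_neighbor(parts[sp], others)
            bundle.diversity.nnd = nnd
            bundle.diversity.nn_species = nn_sp
        except div_mod.DistanceError:
            bundle.statuses["nearest_neighbor"] = "no comparable pairs"


@dataclass
class JointBundle:
    """Joint multi-species analysis sharing one color scheme and network."""

    species_list: list[str]
    haplotypes: HaplotypeTable
    embedding: Embedding
    colors: dict[str, tuple[float, float, float]]
    network: HaplotypeNetwork
    per_species_pies: dict[str, list[AreaPie]]
    shared_haplotypes: list[str]        # haplotype ids spanning >1 species


def run_joint(dataset: Dataset, species_list: list[str],
              config: AtlasConfig | None = None) -> JointBundle:
    """Pool species into one entity: shared haplotype space, separate maps."""
    config = config or AtlasConfig()
    species_list = list(dict.fromkeys(species_list))
    if len(species_list) < 2:
        raise ValueError("joint analysis requires >= 2 distinct species")
    filtered, _ = filter_records(dataset, config.min_unambiguous)
    pooled_records = [r for r in filtered.records if r.species in species_list]
    missing = set(species_list) - {r.species for r in pooled_records}
    if missing:
        raise ValueError(f"species absent after filtering: {sorted(missing)}")
    pooled = Dataset(pooled_records, filtered.alignment_length,
                     provenance="joint:" + ",".join(species_list))
    dmat = distance_matrix(pooled)
    dmat.require_complete("joint analysis")
    table = collapse_haplotypes(pooled, dmat)
    hap_dmat = haplotype_distance_matrix(table)
    embedding = pcoa_embed(hap_dmat)
    colors = assign_colors(embedding)
    net = build_network(table, steps_matrix(table),
                        n_orders=config.network_orders, seed=config.seed)

    species_of = {r.specimen_id: r.species for r in pooled.records}
    shared = [h.haplotype_id for h in table.haplotypes
              if len({species_of[m] for m in h.member_specimen_ids}) > 1]

    pies = {}
    for sp in species_list:
        sp_ds = pooled.subset(sp)
        pies[sp] = group_by_area(sp_ds, table, colors,
                                 area_cell_km=config.area_cell_km)
    return JointBundle(species_list, table, embedding, colors, net, pies, shared)


@dataclass
class AtlasResult:
    summary: pd.DataFrame
    bundles: dict[str, SpeciesBundle]
    plot_points: pd.DataFrame            # species, sqrt_pi, gst
    medians: dict[str, float | None]
    exclusions: pd.DataFrame             # species, reason


def run_atlas(dataset: Dataset, config: AtlasConfig | None = None) -> AtlasResult:
    """Summary table plus bivariate sqrt(pi)-vs-G_ST plot data.

    Every input species lands either in the summary table or in the
    exclusion log with a reason. Species with withheld G_ST keep their row
    (empty G_ST field) and are excluded from the G_ST median.
    """
    config = config or AtlasConfig()
    filtered, _ = filter_records(dataset, config.min_unambiguous)
    excluded = [{"species": sp, "reason": "no records after filtering"}
                for sp in dataset.species_names
                if sp not in filtered.species_names]
    bundles: dict[str, SpeciesBundle] = {}
    for sp in filtered.species_names:
        bundles[sp] = run_species(filtered, sp, config, prefiltered=True)
    attach_nearest_neighbors(filtered, bundles)

    rows = [b.summary_row() for b in bundles.values()]
    summary = pd.DataFrame(rows)

    pts = []
    for b in bundles.values():
        if (b.diversity is not None and b.diversity.pi is not None
                and b.gst is not None and b.gst.gst_mean is not None):
            pts.append({"species": b.species,
                        "sqrt_pi": math.sqrt(b.diversity.pi),
                        "gst": b.gst.gst_mean})
    plot_points = pd.DataFrame(pts, columns=["species", "sqrt_pi", "gst"])
    medians = {
        "sqrt_pi": float(plot_points["sqrt_pi"].median()) if len(pts) else None,
        "gst": float(plot_points["gst"].median()) if len(pts) else None,
    }
    exclusions = pd.DataFrame(excluded, columns=["species", "reason"])
    return AtlasResult(summary, bundles, plot_points, medians, exclusions)
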