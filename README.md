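# haploatlas

Tools for building a *genetic atlas* from georeferenced DNA barcode
records: given aligned mitochondrial COI sequences with specimen
coordinates and species labels, the package computes, per species,

- **haplotype maps** — specimens collapsed into haplotypes, colored by
  position in a PCoA embedding overlaid on a white/yellow/blue/black
  corner square (color similarity tracks genetic similarity), and
  aggregated into per-grid-cell pie charts;
- **haplotype networks** — minimum spanning trees over mutational steps,
  with tie-equivalent alternative links flagged;
- **diversity indices** — nucleotide diversity π (mean pairwise
  p-distance), Nei haplotype diversity *h* with the N/(N−1) correction,
  maximum intraspecific distance, and the nearest-neighbor distance to any
  other species (zero ⇒ barcode sharing);
- **spatial genetic structure** — Nei's G<sub>ST</sub> = D<sub>ST</sub>/H<sub>T</sub>
  with D<sub>ST</sub> = H<sub>T</sub> − H<sub>S</sub>, computed on geographic
  grids and averaged over 4 cell sizes (100–400 km) × 2 grid placements
  (8 replicates), with eligibility thresholds and clamping of negative
  artefacts at 0;
- **sampling completeness** — a Chao1-family asymptotic haplotype richness
  with hypergeometric rarefaction, reported as the fraction of haplotype
  diversity retrieved (R) and the number of haplotypes likely remaining (L).

Joint multi-species analyses pool species into one distance matrix, color
scheme and network while mapping each species separately — the view used to
localize hybrid zones and mitochondrial introgression.

All distances are raw p-distances with **pairwise deletion**: any site that
is not A/C/G/T (IUPAC ambiguity codes, `N`, gaps) in either sequence of a
pair is excluded for that pair. A synthetic-data generator
(`haploatlas.synthetic`) produces truth-known georeferenced multi-species
datasets with controllable deme structure, divergence, ambiguity masking
and cross-species haplotype sharing, so every stage is testable against
known ground truth.

## Worked example

```python
import haploatlas as ha

# two demes 600 km apart, fully private haplotype pools split by
# 10 ancestral substitutions, 30 specimens each
ds, truth = ha.simulate(ha.preset("two_deme_split"))
bundle = ha.run_species(ds, "Species fissa", prefiltered=True)
print(bundle.summary_row())
```

prints (seed 42, the preset default):

```
{'species': 'Species fissa', 'N': 60, 'H': 6, 'h': 0.83616, 'pi': 0.01738,
 'max_intra': 0.03416, 'nnd': None, 'nn_species': None,
 'R': 1.0, 'L': 0.0, 'gst': 0.9184, 'gst_status': 'computed'}
```

Sixty specimens collapse into 6 haplotypes (*H*); π ≈ 0.017 reflects the
deep split (maximum intraspecific distance 0.034 ≈ 2 × 10 substitutions /
658 sites, plus within-deme variants); R = 1 means sampling recovered the
estimated asymptotic haplotype richness (no singleton haplotypes remain);
and G<sub>ST</sub> ≈ 0.92 — most diversity lies *between* the two grid
cells, correctly recovering the simulated structure. A panmictic preset
under the same pipeline averages G<sub>ST</sub> ≈ 0.01.

The same pipeline runs from a shell:

```sh
atlas simulate --preset two_deme_split --out sim/
atlas ingest --fasta sim/sequences.fasta --meta sim/metadata.tsv --out out/
atlas run    --fasta sim/sequences.fasta --meta sim/metadata.tsv --out out/
atlas gst    --fasta sim/sequences.fasta --meta sim/metadata.tsv \
             --species "Species fissa" --out out/gst.json
```

`atlas run` writes the species summary TSV (one row per species; withheld
statistics are empty fields with a reason, never 0), per-species network
TSV/JSON, GeoJSON map layers, the bivariate √π-vs-G<sub>ST</sub> plot data
with per-axis medians, and an exclusion log.

## Input formats

FASTA (one record per specimen, ids matching the metadata) plus
tab-separated metadata with columns `specimen_id`, `species`, `lat`, `lon`
and optional `country`. Records are filtered to ≥ 500 unambiguous base
pairs and valid coordinates by default. See `docs/methods.md` for the
statistical details and design choices.
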