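# viranet

Comparative genomics of the NAD+/ADP-ribose (ADPr) protein-domain network
across viral genomes, packaged as a reusable, tested pipeline.

Viruses — especially large DNA phages and the biggest positive-strand RNA
viruses — carry protein domains that make, sense, or destroy NAD+ and
ADPr derivatives (ADP-ribosyltransferases, Macro, NADAR, ARG, SLOG, Nudix
and the NAD+ salvage enzymes NadM/NadV) as weapons and counter-weapons in
host–virus conflict.  Surveys of this network share a common procedure,
which this package implements end to end:

1. **Collection building** — genome metadata (TSV), gene coordinates
   (CDS-only GFF3) and protein sequences (FASTA), made non-redundant by
   keeping the largest proteome per NCBI taxid.
2. **Domain detection** — position-specific scoring profiles built from
   seed alignments, ungapped sliding-window scanning, empirical E-values
   from background decoys, and iterative profile inclusion at
   E ≤ 0.01: hits join the alignment, the profile is rebuilt, and the
   scan repeats until the included set is stable.
3. **Family clustering** — Smith–Waterman pairwise scores (BLOSUM62,
   affine gaps) converted to bits via `(λ·raw − ln K)/ln 2`; sequences are
   linked when bit-score *density* (bits per alignment column) and
   coverage pass thresholds, clustered single-linkage, and merged on
   independent evidence (reciprocal best hits, shared annotations, shared
   genome context).
4. **Gene-neighborhood mining** — operon-proxy neighborhoods bounded by a
   100-nt inter-gene distance cutoff; recurrent (anchor, partner) family
   pairs filtered by support and a phyletic criterion (distinct taxids);
   plus contextual-absence queries (e.g. deconjugases with *no* coupled
   ADP-ribosyltransferase nearby).
5. **Survey statistics** — prevalence as a function of genome length
   (with the characteristic rises near 17.5 kb for RNA and 60 kb for DNA
   viruses), size-class fractions (small < 25 kb, medium 100–180 kb,
   jumbo ≥ 180 kb), per-1000 morphology rates, chi-square morphology
   enrichment, and pairwise co-occurrence under the fixed-margin
   hypergeometric null with Benjamini–Hochberg correction.

Because the underlying GenBank snapshots are not redistributable, the
package ships a synthetic genome generator that plants all of these
signals — length-dependent carriage with distinct DNA/RNA midpoints,
myovirus bias, conserved neighborhoods, positive co-occurrence — together
with complete truth tables, so every stage is testable offline.  See
`docs/methods.md` for the models and their assumptions.

## Worked example

```python
from viranet import synthetic_genomes as sg, profile_scan as ps, netstats as ns
from viranet import genome_context as gc

coll, truth = sg.generate_collection(sg.GeneratorConfig(n_genomes=120, seed=7))

profile = ps.build_profile(sg.seed_alignment("NADAR"), pseudocount_weight=0.5,
                           family_id="NADAR")
result = ps.iterative_search(profile, coll, inclusion_E=0.01, seed=1)
print(f"NADAR: {len(result.hits)} hits in {result.iterations} iterations")

positives = {g for g, fams in truth.genome_truth.items()
             if fams & set(sg.DEFAULT_NETWORK_FAMILIES)}
print(ns.class_prevalence(coll.genomes, positives).to_string(index=False))

ann = {pid: frozenset({fam}) for pid, (fam, _, _) in truth.hit_truth.items()}
nbs = gc.extract_neighborhoods(coll, sorted(ann), window=5, gap_cutoff=100)
for c in gc.mine_contexts(nbs, ann, coll.genome_taxids, min_support=3)[:3]:
    print(c.anchor_family, c.partner_family, c.orientation, c.support)
```

prints

```
NADAR: 23 hits in 2 iterations
size_class  n_genomes  n_positive  fraction
     small         50          16  0.320000
    medium         12          11  0.916667
     jumbo          9           9  1.000000
 unclassed         49          39  0.795918
ART TerL same_strand 40
Macro SLOG same_strand 9
NADAR NadM same_strand 19
```

Reading the output: the scanner recovered every planted NADAR segment and
converged after one profile update; the fraction of genomes carrying at
least one network domain climbs steeply with genome size (all nine jumbo
genomes are positive, matching the planted carriage curves); and the
miner reports the planted neighborhoods — terminase-adjacent ART genes
and the NADAR–NadM salvage pairing — on the same strand, with their
genome support counts.

## Command line

```sh
viranet run --out RUNDIR                 # simulate → dedup → scan → cluster → context → stats
viranet simulate --n-genomes 300 --seed 1 --out DIR
viranet dedup -m metadata.tsv -g genomes.gff3 -f proteins.faa --out DIR
viranet scan --profiles SEEDS/ --collection DIR --E 0.01 --out hits.tsv
viranet cluster --collection DIR --density 0.8 --coverage 0.6 --out clusters.tsv
viranet context --collection DIR --hits hits.tsv --min-support 3 --gap 100 --out contexts.tsv
viranet stats --collection DIR --hits hits.tsv --out STATS/
```

`viranet run` writes a manifest (config, seed, per-stage row counts,
SHA-256 of every output); reruns with the same config and seed are
byte-identical.

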