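# transgenemap

Map meganuclease-mediated transgene integration sites at base-pair
resolution from paired-end whole-genome sequencing, estimate the inserted
copy number from GC-corrected coverage ratios, and annotate the junctions
for the short homologies that mark microhomology-mediated end joining
(MMEJ).

## The problem

I-SceI transgenesis inserts a linearized cassette (promoter + reporter +
vector backbone, flanked by 18-bp I-SceI recognition sites) into a host
genome, typically as a tandem concatemer at one or two loci, on one
homologue only (hemizygous). Whole-genome sequencing of a carrier animal
can recover, without any prior knowledge of the landing site:

- **Where** the transgene landed: read pairs with one mate on the host and
  one on the cassette bracket the locus; reads that *span* a junction align
  with a soft-clipped end whose clipped tail maps to the other sequence,
  giving single-base boundary coordinates.
- **What the insertion did to the target site**: the relative order of the
  left and right boundary coordinates classifies the lesion — `R = L+1` is
  a blunt joint, `R > L+1` a target-site deletion of `L+1..R-1`, `R ≤ L` a
  tandem target-site duplication of `R..L`.
- **How many copies** went in: read depth is proportional to template copy
  number, so `copies = ploidy · depth(region)/depth(background) −
  endogenous_copies`. A hemizygous 6-copy concatemer shows ~80x over a
  promoter with 2 endogenous copies and ~60x over the reporter at a 20x
  diploid background.
- **How the ends were joined**: I-SceI cleavage leaves a 4-nt 3′ overhang
  (`ATAA`); exact short matches between the junction flanks and the
  cassette termini or the recognition site are the signature of MMEJ
  repair.

Because real carrier genomes are large, the package ships a matched
simulator: a toy chromosome with two insertion loci 108 bp apart (an 11-bp
deletion at the first, a 15-bp duplication at the second), six cassette
copies split 3+3 head-to-tail, the endogenous promoter planted elsewhere,
and MMEJ-style homology planted in the junction flanks. Every stage of the
pipeline runs, and is tested, at desk scale against this ground truth.

## Worked example

Simulate a 200-kb carrier genome at 20x, align with the built-in seed
aligner, and call the integration sites (about 12 s on one CPU):

```sh
transgenemap call -s host_length=200000 -o demo/
```

Output (abridged; `demo/report.json` has the full report):

```json
{
 "half_sites": [],
 "sites": [
  {
   "name": "I1",
   "left":  {"contig": "chr1", "pos": 120000, "side": "left",
             "construct_terminus": "start", "construct_orient": "+",
             "split_support": 6, "pair_support": 8},
   "right": {"contig": "chr1", "pos": 120012, "side": "right",
             "construct_terminus": "end", "construct_orient": "+",
             "split_support": 8, "pair_support": 4},
   "lesion": {"kind": "deletion", "start": 120001, "end": 120011, "length": 11},
   "total_support": 26
  },
  {
   "name": "I2",
   "left":  {"pos": 120134, "construct_terminus": "start"},
   "right": {"pos": 120120, "construct_terminus": "end"},
   "lesion": {"kind": "duplication", "start": 120120, "end": 120134, "length": 15},
   "total_support": 22
  }
 ]
}
```

Both sites are recovered at the simulator's generating coordinates: an
11-bp target-site deletion and, 108 bp away, a 15-bp target-site
duplication. Copy number from the same run:

```sh
transgenemap cn -s host_length=200000 -o demo/
```

```json
{
 "promoter": {"region": "chr1:40102-43799", "region_depth": 77.89,
              "background_depth": 19.94, "endogenous_copies": 2,
              "copies_fractional": 5.81, "copies": 6},
 "egfp":     {"region": "transgene:4101-4800", "region_depth": 62.07,
              "endogenous_copies": 0, "copies_fractional": 6.23, "copies": 6},
 "vector":   {"region": "transgene:4901-7900", "region_depth": 58.53,
              "copies_fractional": 5.87, "copies": 6}
}
```

The promoter piles up to ~80x (2 endogenous + 6 transgene copies), the
reporter to ~60x (6 hemizygous copies), both rounding to 6 estimated
transgene copies. `transgenemap mh` prints the junction microhomology
report (the 4-nt `ATAA` overhang match, recognition-site remnants, and the
inter-site flank homology that flags a tandem-duplication signature), and
`transgenemap run-all` writes everything: `report.json`, `sites.bed`,
`copy_number.tsv`, both SAM files, the corrected depth bedGraph, and the
table of sub-threshold junction candidates.

Configuration lives in a YAML file (`--config run.yaml`) with `-s
key=value` overrides; `transgenemap run-all --help` lists the fields.
Every run echoes its full configuration into the report, and rerunning the
same seed reproduces the report byte for byte.

## Library use

```python
from transgenemap.pipeline import PipelineConfig, run_all

result = run_all(PipelineConfig(seed=1, host_length=200_000), "demo/")
for site in result.sites:
    print(site.boundary_positions, site.lesion.kind, site.lesion.length)
# (120000, 120012) deletion 11
# (120134, 120120) duplication 15
```

The stages are importable on their own: `transgenemap.simulate` (genome,
haplotype and read simulation with truth tracking), `transgenemap.align`
(k-mer seed-and-extend aligner with an affine-gap DP rescue, end-to-end
and local modes, SAM I/O), `transgenemap.coverage` (depth, GC-bias
correction, coverage-ratio copy number), `transgenemap.junctions`
(junction pairs, split reads, boundary clustering, site pairing, lesion
classification, concatemer junctions, in-silico PCR),
`transgenemap.microhomology` (cleavage model and exact maximal-match
scanning).

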