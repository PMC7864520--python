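# seedquant

Quantification of seeded serum-amyloid-A (SAA) aggregation from
fluorescence micrographs, with sequence-homology analysis of the SAA
families behind it — and a synthetic-data generator that makes the whole
pipeline testable without any external data.

## The problem

In AA amyloidosis, SAA-derived fibrils deposit in organs.  Fibril-
containing extracts (amyloid-enhancing factor, AEF) act as seeds that
dramatically shorten the onset of aggregation, and seeding activity
differs between donor species.  Two quantitative questions drive this
package:

1. **How much aggregate is in a micrograph, and how fast does it
   form?**  The readout is the standard deviation of pixel brightness,
   SD(img): a uniform field has SD near the read noise, while bright
   aggregates raise it monotonically with aggregate mass.  Time courses
   of SD are summarised as mean ± SEM over replicates, fitted with a
   Boltzmann sigmoid (half-time t50, lag t50 − 2/slope), and dose series
   with a rising four-parameter logistic whose midpoint is the EC50
   analogue on the AEF-fraction axis.  Z-stacks yield thickness maps;
   a texture classifier separates "dotted" (punctate) from "mesh"
   (filament-network) aggregates; endpoint SDs rank species activity.

2. **Does seeding activity track sequence homology?**  The sequence
   side aligns SAA protein families (affine-gap Gotoh pairwise
   alignment, progressive MSA along a UPGMA guide tree), reports percent
   identity and the family's minimum pairwise identity, assigns
   per-column conservation classes, builds UPGMA trees, and scans
   alignment columns for sites whose side-chain chemistry cleanly
   separates high- from low-activity species groups (e.g. basic versus
   non-basic).

Seeded kinetics follow the minimal nucleation–elongation model
dF/dt = (k_n + k₊F)(c_tot − F) with the seed as initial fibril mass, so
larger seeds strictly shorten t50.  The synthetic generator renders
those kinetics into micrographs in both morphologies and simulates
SAA-like sequence families with a controlled clade structure and planted
discriminative sites, giving every estimator a known ground truth.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

```python
import seedquant as sq

# seeded kinetics: AEF seed shortens the half-time
for aef in (0.0, 0.5, 1.0):
    p = sq.KineticParams(elongation_rate=0.085, nucleation_rate=1e-4,
                         seed_fraction=aef * 0.1)
    print(f"aef={aef:.1f}  t50={sq.half_time(p):7.1f} h")

# micrographs: SD tracks the amount of aggregate
for mass in (0.0, 0.3, 0.8):
    img = sq.render_micrograph(mass, sq.ImagingParams(rng_seed=1))
    print(f"mass={mass:.1f}  SD={sq.sd_statistic(img):6.1f}")

# sequence family: homology and discriminative sites
fam = sq.simulate_sequence_family(sq.SequenceSimParams(rng_seed=1))
aln = sq.progressive_msa(list(fam.records))
print(f"min pairwise identity: "
      f"{sq.overall_homology(aln).min_pairwise_identity:.2f}%")
for s in sq.discriminative_site_scan(aln, {"mouse", "cat"},
                                     {"camel", "cattle", "goat"},
                                     strictness="disjoint"):
    print(f"column {s.column}: high={''.join(s.group_a_residues)} "
          f"({s.group_a_class or 'mixed'})  "
          f"low={''.join(s.group_b_residues)} ({s.group_b_class})")
```

prints

```
aef=0.0  t50=   79.3 h
aef=0.5  t50=   34.4 h
aef=1.0  t50=   25.7 h
mass=0.0  SD=  19.9
mass=0.3  SD= 164.4
mass=0.8  SD= 280.3
min pairwise identity: 77.69%
column 48: high=IQ (mixed)  low=KKK (basic)
column 125: high=EE (acidic)  low=AAA (hydrophobic)
```

Seeding shortens the half-time threefold; image SD rises monotonically
with aggregate mass from the 20-count read-noise floor; the simulated
six-species family keeps ≥ 77.7% pairwise identity yet carries exactly
two chemistry-switching columns — Gln/Ile versus basic Lys at 48 and
acidic Asp/Glu versus Ala at 125 — which the scan recovers exactly.

## Command line

```sh
seedquant all --seed 1 --outdir run1          # simulate -> quantify -> homology -> report
seedquant simulate --config my_config.yaml    # individual stages: simulate,
seedquant quantify --outdir run1              #   quantify, dose, homology, report
```

`simulate` writes TIFF micrographs plus a CSV manifest, a FASTA family
and ground-truth files; `quantify` turns the manifest into tidy CSVs
(per-image SDs, time courses, dose–response, fits, morphology, activity
ranking); `homology` writes the alignment, tree, conservation classes
and site reports; `report` collects tables and plots into a
self-contained directory.  Exit codes: 0 ok, 1 configuration error,
2 runtime failure.  All outputs are byte-identical across reruns with
the same config and seed.

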