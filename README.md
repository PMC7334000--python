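# fourcstab

4C-seq viewpoint analysis with trio-phased allele-specific contact bias
testing.

## The problem

Circular chromosome conformation capture sequencing (4C-seq) measures how
often one anchor locus — the *viewpoint* — touches every restriction
fragment along the chromosome. A recurring question at disease loci with
expanded short tandem repeats (e.g., the CTG repeat at *DMPK* in myotonic
dystrophy, the CAG repeat at *HTT* in Huntington disease) is whether the
expansion reorganizes local 3D chromatin contacts. Because patients are
heterozygous, an effect confined to the expanded homolog can be masked by
the normal one; resolving the two requires phasing nearby SNPs with
parental genotypes and comparing read coverage per allele.

`fourcstab` implements that viewpoint-centric workflow end to end:

1. **fragment map** — in-silico double digestion (DpnII `GATC` primary,
   BfaI `CTAG` secondary; blind-side flagging) and viewpoint placement
   with a ±2.5 kb exclusion zone;
2. **counting** — read-to-fragment assignment, exclusion accounting, the
   mean-count ≥ 20 candidate filter, replicate QC correlations;
3. **profiles** — reads-per-million normalization, 5-fragment running
   mean, replicate averaging, bedGraph export;
4. **interaction calling** — isotonic (PAVA) fit of log1p counts against
   distance per side of the viewpoint, z-scores against a sliding-bin
   robust scale (1.4826 × MAD), significance at z ≥ 1.96 with
   Benjamini–Hochberg FDR ≤ 0.1, plus a 3-state Gaussian HMM segmenting
   high/low/non-interacting domains;
5. **differential analysis** — negative-binomial Wald test between
   conditions (median-of-ratios size factors, trend-shrunk moment
   dispersions, nominal p < 0.05), region merging, domain overlap counts;
6. **allelic bias** — trio phasing (proband heterozygous + at least one
   parent homozygous; the chromosome from the affected parent carries the
   expansion), allele-winner tallies over (SNP, library) samples with
   ≥ 10 reads, and a two-sided exact binomial test of the winner
   proportion against 0.5.

A seeded synthetic-data generator (`fourcstab.simulate`) produces every
input — genome, counts with power-law decay and NB noise, trio genotypes,
allelic coverage — so the full pipeline runs at desk scale.

## The core statistic

For a region with *n* eligible samples of which *k* have more reads on the
expanded chromosome, the no-bias null is `K ~ Binomial(n, 0.5)` and the
two-sided exact P-value follows the minimum-likelihood rule

```
P = Σ_{i : Pr(K=i) ≤ Pr(K=k)} Pr(K=i)
```

which at p₀ = 0.5 equals `2·min(P(K≤k), P(K≥k))` capped at 1.

## Worked example

```
$ python examples/allelic_bias.py
50 SNPs, 20 phase-resolvable (20/20 match the simulated haplotype truth)
simulated trio: 56 eligible samples (>= 10 reads), 23 expanded wins vs 33 normal wins, exact P = 0.23 (no bias expected)

published winner tallies (total, normal wins, expanded wins):
  DM1-A  ACTA1    5   1   4 -> P = 0.38
  DM1-A  DMPK    41  26  15 -> P = 0.12
  HD-B   ACTA1   12   7   5 -> P = 0.77
  HD-B   HTT     43  20  23 -> P = 0.76
none falls below 0.05: no allelic bias in chromatin contacts.
```

The first block exercises the whole allelic machinery on a simulated trio
with no true bias: phasing recovers the haplotype truth exactly and the
test stays non-significant. The second block applies the exact binomial
test to the published patient-trio winner tallies; no region shows a
significant departure from the 0.5 null, i.e., the viewpoints contact both
homologs equally.

Other narrative scripts in `examples/` cover the fragment map and RPM
profile (`digest_and_profile.py`), significant-interaction calling with
spiked truth (`interaction_calling.py`), and differential analysis with
domain overlap (`differential_analysis.py`).

## Command line

Every stage is also exposed as a thin CLI:

```
4cstab digest | count | profile | call | diff | allelic | simulate | run
```

`4cstab run --config cfg.yaml --out-dir out/ [--seed N]` executes the full
stage chain (digest → count → profile → call → diff → allelic) and writes
a `manifest.json` with config snapshot, input digests and per-stage
timings. Exit codes: 2 for a config schema violation (the message names
the field), 3 for a missing input file.

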